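"""Shared fixtures: small synthetic cohorts, pixel bags and stub models."""

from __future__ import annotations

import numpy as np
import pytest

from milgrade.io import labelset_from_row
from milgrade.mil import PixelBag, pixel_bag_from_image
from milgrade.synthetic import SyntheticCohortSpec, generate_cohort
from milgrade.tiling import build_bag


class OracleModel:
    """Scores a tile 1.0 iff it contains dark-nucleus pixels.

    Motif tiles carry dense dark ellipses whose minimum channel sits far
    below anything in plain tissue or background, so a dark-pixel
    fraction threshold recovers the instance truth exactly.  Used as the
    known-perfect instance scorer in MIL contract tests.
    """

    tasks = ("grade",)

    def forward_probs(self, x: np.ndarray) -> np.ndarray:
        # x: (N, 3, S, S) in [0, 1]
        dark = (x.min(axis=1) < 85.0 / 255.0).mean(axis=(1, 2))
        return (dark > 0.025).astype(float)[:, None]


class ProbeModel:
    """Reads its output probability straight from each tile's first pixel.

    Lets tests construct bags with arbitrary prescribed tile scores.
    """

    tasks = ("grade",)

    def forward_probs(self, x: np.ndarray) -> np.ndarray:
        return x[:, 0, 0, 0][:, None]


def cohort_pixel_bags(cohort) -> list[PixelBag]:
    labels = cohort.labels.set_index("slide_id")
    bags = []
    for sid, image in cohort.iter_slides():
        bag, report = build_bag(image, sid, labels=labelset_from_row(labels.loc[sid]))
        if not report.excluded:
            bags.append(pixel_bag_from_image(image, bag))
    return bags


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-slide cohort with 6x6 grids, shared across read-only tests."""
    spec = SyntheticCohortSpec(n_slides=10, tiles_per_side=6, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_pixel_bags(small_cohort):
    return cohort_pixel_bags(small_cohort)


@pytest.fixture()
def oracle_model():
    return OracleModel()


@pytest.fixture()
def probe_model():
    return ProbeModel()
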