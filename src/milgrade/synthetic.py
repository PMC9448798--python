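"""Synthetic whole-slide cohorts with the statistical structure MIL assumes.

Real graded cohorts of whole-slide images are essentially never public, so
this module fabricates one: square slides built from a grid of 224 px
tiles, where a *positive* (high-grade) slide carries a minority fraction
of discriminative "motif" tiles and a negative slide carries none — the
standard-instance MIL assumption.  Around the bag labels it draws
correlated auxiliary labels (component scores, receptor status) and
grade-dependent exponential survival outcomes, so the grading, evaluation
and survival modules can all be exercised end to end.

Tile appearance
---------------
Motif tiles show many small dark basophilic ellipses (nuclei-like) on a
pink eosin-like field; ordinary tissue tiles show fewer, larger, pale
blobs.  Blob counts are randomized so the per-tile mean color of the two
classes overlaps heavily: a classifier must use texture, not mean
intensity, which is what the MIL training loop is supposed to learn.
Background tiles are near-white, as in scanned slides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from skimage.draw import ellipse

__all__ = ["SyntheticCohortSpec", "SyntheticCohort", "generate_slide", "generate_cohort", "write_cohort"]

TILE_SIZE = 224

# tile plan categories
_BACKGROUND = 0
_TISSUE = 1
_MOTIF = 2

# blob colors and densities are calibrated so motif and plain-tissue tiles
# have near-identical expected mean RGB: density/size texture is the only
# reliable signal, so a mean-color shortcut cannot solve the bag labels
_PINK_FIELD = np.array([231.0, 186.0, 205.0])
_DARK_NUCLEUS = np.array([72.0, 46.0, 128.0])
_PALE_BLOB = np.array([150.0, 112.0, 165.0])
_WHITE = 250.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror a balanced high-vs-low/intermediate grading cohort:
    roughly half the slides high grade, a 20% prevalence of discriminative
    tiles within positive slides, a quarter of each slide background, high
    (90%) agreement between auxiliary labels and the grade label, and an
    overall-survival process with hazard ratio 2 between grade groups at a
    low baseline hazard, administratively censored at 8 years.
    """

    n_slides: int = 80
    positive_fraction: float = 0.5
    motif_prevalence: float = 0.2
    tiles_per_side: int = 10
    white_fraction: float = 0.25
    aux_label_agreement: float = 0.9
    hazard_ratio_high_vs_low: float = 2.0
    baseline_hazard: float = 0.02
    censor_horizon: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        def err(name: str, msg: str):
            return ValueError(f"invalid SyntheticCohortSpec.{name}: {msg}")

        if self.n_slides < 2:
            raise err("n_slides", f"must be >= 2, got {self.n_slides}")
        if not 0.0 < self.positive_fraction < 1.0:
            raise err("positive_fraction", f"must be in (0,1), got {self.positive_fraction}")
        if not 0.0 < self.motif_prevalence <= 1.0:
            raise err("motif_prevalence", f"must be in (0,1], got {self.motif_prevalence}")
        if self.tiles_per_side < 1:
            raise err("tiles_per_side", f"must be >= 1, got {self.tiles_per_side}")
        if not 0.0 <= self.white_fraction < 1.0:
            raise err("white_fraction", f"must be in [0,1), got {self.white_fraction}")
        if not 0.5 <= self.aux_label_agreement <= 1.0:
            raise err("aux_label_agreement", f"must be in [0.5,1], got {self.aux_label_agreement}")
        if not self.hazard_ratio_high_vs_low > 0:
            raise err("hazard_ratio_high_vs_low", f"must be > 0, got {self.hazard_ratio_high_vs_low}")
        if not self.baseline_hazard > 0:
            raise err("baseline_hazard", f"must be > 0, got {self.baseline_hazard}")
        if not self.censor_horizon > 0:
            raise err("censor_horizon", f"must be > 0, got {self.censor_horizon}")

    @property
    def slide_pixels(self) -> int:
        return self.tiles_per_side * TILE_SIZE


def _plan_tiles(label: int, spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Assign a category (background / tissue / motif) to each grid cell.

    Positive slides with at least one tissue tile are guaranteed >= 1
    motif tile: a zero-motif binomial draw is redrawn, since the MIL bag
    assumption requires a positive bag to contain a positive instance.
    """
    n = spec.tiles_per_side
    plan = np.where(
        rng.random((n, n)) < spec.white_fraction, _BACKGROUND, _TISSUE
    ).astype(np.int8)
    if label == 1:
        tissue = np.argwhere(plan == _TISSUE)
        if len(tissue) > 0:
            while True:
                motif_mask = rng.random(len(tissue)) < spec.motif_prevalence
                if motif_mask.any():
                    break
            for r, c in tissue[motif_mask]:
                plan[r, c] = _MOTIF
    return plan


def _render_tile(category: int, rng: np.random.Generator) -> np.ndarray:
    """Render one 224x224 RGB uint8 tile for the given category."""
    s = TILE_SIZE
    if category == _BACKGROUND:
        img = np.full((s, s, 3), _WHITE) + rng.normal(0.0, 2.0, (s, s, 3))
        return np.clip(img, 0, 255).astype(np.uint8)

    # per-tile stain jitter emulates staining variability across the slide
    field = _PINK_FIELD + rng.normal(0.0, 5.0, 3)
    img = np.tile(field, (s, s, 1)).copy()
    img += rng.normal(0.0, 4.0, (s, s, 3))
    if category == _MOTIF:
        n_blobs = max(6, int(round(rng.normal(18.0, 4.0))))
        radius_lo, radius_hi = 8.0, 14.0
        color, color_sd = _DARK_NUCLEUS, 12.0
    else:
        n_blobs = max(3, int(round(rng.normal(16.0, 5.0))))
        radius_lo, radius_hi = 12.0, 20.0
        color, color_sd = _PALE_BLOB, 10.0
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, s, size=2)
        ry = rng.uniform(radius_lo, radius_hi)
        rx = rng.uniform(radius_lo, radius_hi)
        angle = rng.uniform(0, math.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(s, s), rotation=angle)
        img[rr, cc] = color + rng.normal(0.0, color_sd, 3)
    return np.clip(img, 0, 255).astype(np.uint8)


def _render_plan(plan: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = plan.shape[0]
    s = TILE_SIZE
    img = np.empty((n * s, n * s, 3), dtype=np.uint8)
    for r in range(n):
        for c in range(n):
            img[r * s:(r + 1) * s, c * s:(c + 1) * s] = _render_tile(int(plan[r, c]), rng)
    return img


def generate_slide(
    label: int, spec: SyntheticCohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one slide image and its per-tile motif truth grid.

    Returns ``(image, tile_truth)`` where image is an RGB uint8 raster of
    side ``tiles_per_side * 224`` and tile_truth is a
    (tiles_per_side, tiles_per_side) int grid with 1 on motif tiles.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    plan = _plan_tiles(label, spec, rng)
    image = _render_plan(plan, rng)
    return image, (plan == _MOTIF).astype(np.int8)


@dataclass
class SyntheticCohort:
    """A generated cohort: label table, truth grids, and lazy slide images.

    Slide images are re-rendered deterministically from per-slide child
    seeds on each access, so a full cohort never has to fit in memory.
    """

    spec: SyntheticCohortSpec
    labels: pd.DataFrame                       # one row per slide
    tile_truth: dict[str, np.ndarray]          # slide_id -> motif grid
    background_truth: dict[str, np.ndarray]    # slide_id -> background grid
    _slide_seeds: list[np.random.SeedSequence] = field(repr=False, default_factory=list)

    @property
    def slide_ids(self) -> list[str]:
        return list(self.labels["slide_id"])

    def slide_image(self, slide_id: str) -> np.ndarray:
        idx = self.slide_ids.index(slide_id)
        label = int(self.labels.iloc[idx]["grade"])
        rng = np.random.default_rng(self._slide_seeds[idx])
        image, truth = generate_slide(label, self.spec, rng)
        assert np.array_equal(truth, self.tile_truth[slide_id])
        return image

    def iter_slides(self) -> Iterator[tuple[str, np.ndarray]]:
        for sid in self.slide_ids:
            yield sid, self.slide_image(sid)

    def tile_truth_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.slide_ids:
            grid = self.tile_truth[sid]
            for r in range(grid.shape[0]):
                for c in range(grid.shape[1]):
                    rows.append((sid, r, c, int(grid[r, c])))
        return pd.DataFrame(rows, columns=["slide_id", "row", "col", "motif"])


def _draw_survival(
    grade: np.ndarray, spec: SyntheticCohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Grade-dependent exponential outcome times, censored administratively.

    Death follows the spec'd hazard ``baseline * HR^grade``; distant and
    local recurrence run as independent exponentials proportional to it
    (1.2x and 0.6x) so the recurrence endpoints are slightly more frequent
    than death, as in real grading cohorts; second primaries arrive at a
    small grade-independent rate.
    """
    n = grade.size
    hazard = spec.baseline_hazard * spec.hazard_ratio_high_vs_low ** grade
    death = rng.exponential(1.0 / hazard)
    distant = rng.exponential(1.0 / (1.2 * hazard))
    local = rng.exponential(1.0 / (0.6 * hazard))
    second_primary = rng.exponential(1.0 / 0.01, size=n)
    horizon = spec.censor_horizon

    frame = pd.DataFrame(
        {
            "death_time": np.where(death <= horizon, death, np.nan),
            "distant_recurrence_time": np.where(distant <= horizon, distant, np.nan),
            "any_recurrence_time": np.where(
                np.minimum(distant, local) <= horizon, np.minimum(distant, local), np.nan
            ),
            "second_primary_time": np.where(
                second_primary <= horizon, second_primary, np.nan
            ),
            "last_followup_time": np.minimum(
                np.where(np.isnan(death), np.inf, death), horizon
            ),
        }
    )
    frame["os_time"] = np.fmin(death, horizon)
    frame["os_event"] = (death <= horizon).astype(int)
    return frame


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate the full cohort: labels, auxiliary labels, outcomes, truth grids.

    The binary grade is Bernoulli(positive_fraction); each auxiliary label
    (nuclear, tubular, mitotic, hr, her2) independently equals the grade
    with probability ``aux_label_agreement``.  Per-slide random streams are
    split off the cohort seed so slides render identically regardless of
    access order.
    """
    root = np.random.SeedSequence(spec.seed)
    cohort_seed, *slide_seeds = root.spawn(spec.n_slides + 1)
    rng = np.random.default_rng(cohort_seed)

    grade = (rng.random(spec.n_slides) < spec.positive_fraction).astype(int)
    aux = {}
    for name in ("nuclear", "tubular", "mitotic", "hr", "her2"):
        agree = rng.random(spec.n_slides) < spec.aux_label_agreement
        aux[name] = np.where(agree, grade, 1 - grade)

    labels = pd.DataFrame({"slide_id": [f"slide_{i:04d}" for i in range(spec.n_slides)], "grade": grade, **aux})
    labels["subtype"] = np.select(
        [
            (labels.hr == 1) & (labels.her2 == 0),
            (labels.hr == 0) & (labels.her2 == 0),
            (labels.hr == 1) & (labels.her2 == 1),
        ],
        ["HR+/HER2-", "HR-/HER2-", "HR+/HER2+"],
        default="HR-/HER2+",
    )
    labels = pd.concat([labels, _draw_survival(grade, spec, rng)], axis=1)

    tile_truth: dict[str, np.ndarray] = {}
    background: dict[str, np.ndarray] = {}
    for i, sid in enumerate(labels["slide_id"]):
        plan_rng = np.random.default_rng(slide_seeds[i])
        plan = _plan_tiles(int(grade[i]), spec, plan_rng)
        tile_truth[sid] = (plan == _MOTIF).astype(np.int8)
        background[sid] = (plan == _BACKGROUND).astype(np.int8)

    return SyntheticCohort(
        spec=spec,
        labels=labels,
        tile_truth=tile_truth,
        background_truth=background,
        _slide_seeds=list(slide_seeds),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write slides as single-level tiled TIFFs plus label and truth CSVs."""
    import tifffile

    out = Path(out_dir)
    slides_dir = out / "slides"
    slides_dir.mkdir(parents=True, exist_ok=True)
    for sid, image in cohort.iter_slides():
        tifffile.imwrite(
            slides_dir / f"{sid}.tiff", image, tile=(TILE_SIZE, TILE_SIZE),
            photometric="rgb",
        )
    labels_path = out / "labels.csv"
    cohort.labels.to_csv(labels_path, index=False)
    truth_path = out / "tile_truth.csv"
    cohort.tile_truth_frame().to_csv(truth_path, index=False)
    return {"slides": slides_dir, "labels": labels_path, "tile_truth": truth_path}
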