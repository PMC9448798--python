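"""Agreement metrics between predicted and reference binary labels.

Cohen's kappa, accuracy, 2x2 confusion matrices and bootstrap standard
deviations, as used to compare model grading against pathologist grading.
Kappa is the chance-corrected agreement (p_o - p_e) / (1 - p_e) where the
chance term p_e comes from the raters' marginal label frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ConfusionMatrix2x2",
    "confusion",
    "cohens_kappa",
    "accuracy",
    "bootstrap_sd",
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts for a binary confusion matrix (reference in rows)."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=int)

    def normalized(self, axis: str = "row") -> np.ndarray:
        """Row- ('row', by true class) or column-normalized proportions."""
        m = self.as_array().astype(float)
        if axis == "row":
            sums = m.sum(axis=1, keepdims=True)
        elif axis == "col":
            sums = m.sum(axis=0, keepdims=True)
        else:
            raise ValueError("axis must be 'row' or 'col'")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, m / sums, np.nan)
        return out


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.size == 0 or p.size == 0:
        raise ValueError("label vectors must be non-empty")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            raise ValueError(f"{name} contains non-binary values")
    return t.astype(int), p.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix2x2:
    t, p = _check_pair(y_true, y_pred)
    return ConfusionMatrix2x2(
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tp=int(((t == 1) & (p == 1)).sum()),
    )


def cohens_kappa(y_true, y_pred) -> float:
    """Cohen's kappa between two binary raters, in [-1, 1].

    When both raters use a single identical class (chance agreement 1 and
    observed agreement 1) the agreement is perfect and 1.0 is returned;
    any other degenerate marginal raises, since kappa is undefined.
    """
    t, p = _check_pair(y_true, y_pred)
    n = t.size
    p_o = float((t == p).mean())
    # chance agreement from marginals
    t1 = float((t == 1).mean())
    p1 = float((p == 1).mean())
    p_e = t1 * p1 + (1.0 - t1) * (1.0 - p1)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 (single-class marginals)")
    return (p_o - p_e) / (1.0 - p_e)


def accuracy(y_true, y_pred) -> float:
    t, p = _check_pair(y_true, y_pred)
    return float((t == p).mean())


def bootstrap_sd(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    y_true,
    y_pred,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap standard deviation of a paired agreement metric.

    Slides are resampled with replacement jointly (true, pred) so the
    agreement structure is preserved.  Resamples on which the metric is
    undefined (e.g. kappa with single-class marginals) are redrawn, with
    a cap of ``10 * n_boot`` total draws.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    t, p = _check_pair(y_true, y_pred)
    rng = np.random.default_rng(seed)
    n = t.size
    values = np.empty(n_boot)
    collected = 0
    attempts = 0
    cap = 10 * n_boot
    while collected < n_boot:
        if attempts >= cap:
            raise RuntimeError(
                "bootstrap resampling cap exceeded; too many degenerate "
                "resamples — more data or a different metric is needed"
            )
        idx = rng.integers(0, n, size=n)
        attempts += 1
        try:
            values[collected] = metric_fn(t[idx], p[idx])
        except ValueError:
            continue
        collected += 1
    return float(values.std(ddof=1))
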