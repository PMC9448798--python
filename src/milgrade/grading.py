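"""Nottingham grading arithmetic.

The Nottingham (Bloom–Richardson modification) system scores three
morphological components of an invasive breast carcinoma — nuclear
pleomorphism, tubule formation and mitotic count — each on a 1–3 scale.
The final histologic grade is derived from the component sum: grade 1
(low) for sums 3–5, grade 2 (intermediate) for 6–7, grade 3 (high) for
8–9.  For binary classification the three grades collapse to
low/intermediate (grades 1–2) versus high (grade 3).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ComponentScores",
    "grade_from_components",
    "binarize_grade",
    "binarize_component",
]

_VALID_SCORES = {1, 2, 3}


@dataclass(frozen=True)
class ComponentScores:
    """The three Nottingham component scores, each in {1, 2, 3}."""

    nuclear: int
    tubular: int
    mitotic: int

    def __post_init__(self) -> None:
        for name in ("nuclear", "tubular", "mitotic"):
            value = getattr(self, name)
            if value not in _VALID_SCORES:
                raise ValueError(
                    f"component score {name!r} must be 1, 2 or 3; got {value!r}"
                )

    @property
    def total(self) -> int:
        return self.nuclear + self.tubular + self.mitotic


def grade_from_components(scores: ComponentScores) -> int:
    """Map component scores to the final Nottingham grade (1, 2 or 3).

    Grade 1 for component sums 3–5, grade 2 for 6–7, grade 3 for 8–9.
    """
    s = scores.total
    if s <= 5:
        return 1
    if s <= 7:
        return 2
    return 3


def binarize_grade(grade: int) -> int:
    """Collapse grade 1–3 to binary: 0 = low/intermediate (1–2), 1 = high (3)."""
    if grade not in _VALID_SCORES:
        raise ValueError(f"grade must be 1, 2 or 3; got {grade!r}")
    return 1 if grade == 3 else 0


def binarize_component(score: int) -> int:
    """Binarize a single component score: 0 for scores 1–2, 1 for score 3.

    This is the per-component analogue of the low/intermediate-vs-high
    grade conversion and is used to derive the auxiliary binary training
    labels (nuclear, tubular, mitotic) from 1–3 component scores.
    """
    if score not in _VALID_SCORES:
        raise ValueError(f"component score must be 1, 2 or 3; got {score!r}")
    return 1 if score == 3 else 0
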