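"""CSV interchange helpers shared by the CLI subcommands."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mil import LabelSet, PixelBag, SlidePrediction, pixel_bag_from_image
from .survival import PatientOutcome
from .tiling import bag_from_manifest, read_slide_image

__all__ = [
    "load_label_table",
    "labelset_from_row",
    "load_pixel_bags",
    "predictions_to_frame",
    "outcomes_from_frame",
]

_AUX = ("nuclear", "tubular", "mitotic", "hr", "her2")


def load_label_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "slide_id" not in df.columns or "grade" not in df.columns:
        raise ValueError(f"{path}: label table needs slide_id and grade columns")
    return df.set_index("slide_id", drop=False)


def labelset_from_row(row) -> LabelSet:
    def opt(name):
        if name not in row or pd.isna(row[name]):
            return None
        return int(row[name])

    return LabelSet(grade=int(row["grade"]), **{a: opt(a) for a in _AUX})


def load_pixel_bags(
    bags_dir: str | Path,
    labels: pd.DataFrame,
    input_size: int,
    slides_dir: str | Path | None = None,
) -> list[PixelBag]:
    """Load per-slide bag manifests and their tile pixels.

    Each manifest references its slide image (slide_path column); pass
    ``slides_dir`` to override the recorded location.
    """
    bags: list[PixelBag] = []
    for manifest_path in sorted(Path(bags_dir).glob("*.csv")):
        if manifest_path.name == "summary.csv":
            continue
        frame = pd.read_csv(manifest_path, keep_default_na=False)
        sid = str(frame["slide_id"].iloc[0])
        label_set = labelset_from_row(labels.loc[sid]) if sid in labels.index else None
        bag = bag_from_manifest(frame, labels=label_set)
        if len(bag) == 0:
            continue
        slide_path = frame["slide_path"].iloc[0]
        if slides_dir is not None:
            slide_path = Path(slides_dir) / Path(slide_path).name
        image = read_slide_image(slide_path)
        bags.append(pixel_bag_from_image(image, bag, input_size))
    if not bags:
        raise ValueError(f"no non-empty bags found under {bags_dir}")
    return bags


def predictions_to_frame(preds: list[SlidePrediction]) -> pd.DataFrame:
    rows = []
    for p in preds:
        rows.append(
            {
                "slide_id": p.slide_id,
                "predicted_label": p.label,
                "votes_positive": p.votes_positive,
                "top_tiles": json.dumps(
                    [
                        {"row": ref.row, "col": ref.col, "grade_prob": round(prob, 6)}
                        for ref, prob in p.top_tiles
                    ]
                ),
            }
        )
    return pd.DataFrame(rows)


def outcomes_from_frame(df: pd.DataFrame, group_col: str = "grade") -> list[PatientOutcome]:
    """Build PatientOutcome records from a cohort table.

    Expects per-row follow-up columns (last_followup_time plus optional
    death/recurrence/second-primary times), a binary group column and an
    optional ``subtype`` column.
    """
    id_col = "patient_id" if "patient_id" in df.columns else "slide_id"

    def opt(row, name):
        if name not in df.columns or pd.isna(row[name]):
            return None
        return float(row[name])

    outcomes = []
    for _, row in df.iterrows():
        outcomes.append(
            PatientOutcome(
                patient_id=str(row[id_col]),
                last_followup_time=float(row["last_followup_time"]),
                death_time=opt(row, "death_time"),
                distant_recurrence_time=opt(row, "distant_recurrence_time"),
                any_recurrence_time=opt(row, "any_recurrence_time"),
                second_primary_time=opt(row, "second_primary_time"),
                grade_group=int(row[group_col]),
                subtype_stratum=(str(row["subtype"]) if "subtype" in df.columns else None),
            )
        )
    return outcomes
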