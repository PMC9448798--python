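"""Tile-probability heatmaps and top-tile export for interpretability.

Scores every tissue tile of a slide (no subsampling) with the grade head,
arranges the probabilities on the tile grid, and renders a color-mapped
overlay on a slide thumbnail with the top-k tiles outlined.  Scoring goes
through the same code path as MIL inference, so the heatmap shows exactly
what the slide-level vote saw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mil import PixelBag, TrainingConfig, _score_indices, predict_slide
from .tiling import extract_tile

__all__ = ["HeatmapGrid", "score_all_tiles", "render_overlay", "export_top_tiles"]


@dataclass(frozen=True)
class HeatmapGrid:
    """Per-tile grade probabilities on the slide's tile grid.

    Background (non-tissue) cells are NaN.
    """

    slide_id: str
    probs: np.ndarray  # (n_rows, n_cols) float, NaN on background
    tile_size: int
    working_level: int = 0

    def __post_init__(self) -> None:
        vals = self.probs[~np.isnan(self.probs)]
        if vals.size and not ((vals >= 0).all() and (vals <= 1).all()):
            raise ValueError("probabilities must lie in [0, 1]")

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.probs.shape[0]):
            for c in range(self.probs.shape[1]):
                v = self.probs[r, c]
                rows.append({"slide_id": self.slide_id, "row": r, "col": c,
                             "prob": (None if np.isnan(v) else float(v))})
        return pd.DataFrame(rows)


def score_all_tiles(model, pixel_bag: PixelBag, config: TrainingConfig) -> HeatmapGrid:
    """Score every tissue tile in the bag (all tiles, no 512 subsampling)."""
    bag = pixel_bag.bag
    if len(bag) == 0:
        raise ValueError("empty bag cannot be scored")
    grade_idx = model.tasks.index("grade")
    idx = np.arange(len(bag))
    probs = _score_indices(model, pixel_bag, idx, config.batch_size)
    grid = np.full((bag.n_rows, bag.n_cols), np.nan)
    for i, ref in enumerate(bag.tiles):
        grid[ref.row, ref.col] = probs[i, grade_idx]
    size = bag.tiles[0].size
    return HeatmapGrid(slide_id=bag.slide_id, probs=grid, tile_size=size)


def _thumbnail(slide_image: np.ndarray, max_side: int = 1120) -> np.ndarray:
    """Integer-factor block-mean thumbnail, at most max_side pixels wide."""
    h, w = slide_image.shape[:2]
    f = max(1, int(np.ceil(max(h, w) / max_side)))
    hh, ww = (h // f) * f, (w // f) * f
    img = slide_image[:hh, :ww].astype(np.float64)
    img = img.reshape(hh // f, f, ww // f, f, 3).mean(axis=(1, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_overlay(
    slide_image: np.ndarray,
    grid: HeatmapGrid,
    alpha: float = 0.4,
    top_tiles: list[tuple[int, int]] | None = None,
    colormap: str = "viridis",
    max_side: int = 1120,
) -> np.ndarray:
    """Alpha-blend the probability grid over a slide thumbnail.

    Background cells stay fully transparent; ``top_tiles`` (row, col)
    cells get a red outline; a vertical colorbar strip is appended on the
    right.  The output is a deterministic function of its inputs.
    """
    from matplotlib import colormaps

    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    thumb = _thumbnail(slide_image, max_side).astype(np.float64)
    th, tw = thumb.shape[:2]
    cmap = colormaps[colormap]

    # nearest-neighbor upsample of the grid to thumbnail size
    rr = np.minimum((np.arange(th) * grid.probs.shape[0]) // th, grid.probs.shape[0] - 1)
    cc = np.minimum((np.arange(tw) * grid.probs.shape[1]) // tw, grid.probs.shape[1] - 1)
    up = grid.probs[np.ix_(rr, cc)]
    tissue = ~np.isnan(up)
    colored = cmap(np.nan_to_num(up))[:, :, :3] * 255.0

    out = thumb.copy()
    out[tissue] = (1.0 - alpha) * thumb[tissue] + alpha * colored[tissue]

    if top_tiles:
        cell_h, cell_w = th / grid.probs.shape[0], tw / grid.probs.shape[1]
        for r, c in top_tiles:
            y0, y1 = int(r * cell_h), min(int((r + 1) * cell_h), th) - 1
            x0, x1 = int(c * cell_w), min(int((c + 1) * cell_w), tw) - 1
            out[y0:y1 + 1, [x0, x1]] = (255.0, 0.0, 0.0)
            out[[y0, y1], x0:x1 + 1] = (255.0, 0.0, 0.0)

    # colorbar strip: probability 1 at the top, 0 at the bottom
    bar_w = max(8, tw // 50)
    ramp = np.linspace(1.0, 0.0, th)
    bar = np.tile(cmap(ramp)[:, None, :3] * 255.0, (1, bar_w, 1))
    margin = np.full((th, max(2, bar_w // 4), 3), 255.0)
    out = np.concatenate([out, margin, bar], axis=1)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def export_top_tiles(
    model,
    pixel_bag: PixelBag,
    slide_image: np.ndarray,
    config: TrainingConfig,
    out_dir: str | Path,
    k: int | None = None,
) -> pd.DataFrame:
    """Write the top-k tiles as PNGs (full resolution) plus a metadata CSV.

    Files are named ``{slide_id}_rank{r}_row{row}_col{col}.png``; the
    returned frame (also written as top_tiles.csv) holds probabilities.
    """
    from PIL import Image

    if k is not None:
        config = TrainingConfig(**{**_config_dict(config), "top_k": k})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pred = predict_slide(model, pixel_bag, config)
    rows = []
    for rank, (ref, prob) in enumerate(pred.top_tiles, start=1):
        tile = extract_tile(slide_image, ref)
        name = f"{pred.slide_id}_rank{rank}_row{ref.row}_col{ref.col}.png"
        Image.fromarray(tile).save(out / name)
        rows.append({"slide_id": pred.slide_id, "rank": rank, "row": ref.row,
                     "col": ref.col, "grade_prob": prob, "file": name})
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "top_tiles.csv", index=False)
    return frame


def _config_dict(config: TrainingConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    from .mil import AugmentationConfig

    d["augmentation"] = AugmentationConfig(**d["augmentation"])
    return d
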