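"""Whole-slide tiling: grid construction, tissue filtering, bag assembly.

A slide is cut into non-overlapping 224x224 tiles at the working
magnification (10x by default); tiles that are mostly white background
are discarded and the surviving tissue tiles form the slide's MIL "bag".
Coordinates are 0-based, half-open, tile origin at the top-left; partial
edge tiles are dropped rather than padded, matching the fixed network
input size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TILE_SIZE",
    "DEFAULT_WHITE_INTENSITY_CUTOFF",
    "DEFAULT_WHITE_FRACTION_CUTOFF",
    "TileRef",
    "Bag",
    "SlideInfo",
    "TilingReport",
    "EmptySlideWarning",
    "resolve_working_level",
    "tile_grid",
    "is_tissue",
    "extract_tile",
    "build_bag",
    "bag_manifest",
    "bag_from_manifest",
    "read_slide_image",
]

DEFAULT_TILE_SIZE = 224
#: a pixel is "white" when its minimum channel reaches this value; the
#: min channel (not luminance) is used so pale eosin-stained regions,
#: which are bright but pink, still count as tissue.
DEFAULT_WHITE_INTENSITY_CUTOFF = 240
#: a tile is background when more than this fraction of pixels is white.
DEFAULT_WHITE_FRACTION_CUTOFF = 0.5


class EmptySlideWarning(UserWarning):
    """Raised as a warning when a slide yields no tissue tiles."""


@dataclass(frozen=True)
class TileRef:
    """One tile's position within a slide at the working level."""

    slide_id: str
    col: int
    row: int
    size: int = DEFAULT_TILE_SIZE

    def __post_init__(self) -> None:
        if self.col < 0 or self.row < 0 or self.size <= 0:
            raise ValueError(f"invalid tile reference {self!r}")

    @property
    def x(self) -> int:
        """Pixel x-origin (column direction) at the working level."""
        return self.col * self.size

    @property
    def y(self) -> int:
        return self.row * self.size


@dataclass
class Bag:
    """A slide's tissue tiles plus its slide-level labels."""

    slide_id: str
    tiles: list[TileRef]
    labels: Any = None
    n_rows: int = 0
    n_cols: int = 0

    def __len__(self) -> int:
        return len(self.tiles)


@dataclass(frozen=True)
class SlideInfo:
    """Pyramid metadata needed to pick a working level.

    ``level_downsamples`` holds the downsample factor of each pyramid
    level relative to level 0 (always starting at 1 for level 0);
    ``native_magnification`` is the scan magnification of level 0.
    """

    native_magnification: float
    level_downsamples: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not self.native_magnification or self.native_magnification <= 0:
            raise ValueError(
                "native magnification unknown or invalid; pass it explicitly "
                "(CLI: --native-mag)"
            )
        if len(self.level_downsamples) == 0 or self.level_downsamples[0] != 1.0:
            raise ValueError("level_downsamples must start at 1.0 for level 0")


def resolve_working_level(
    info: SlideInfo, target_magnification: float = 10.0
) -> tuple[int, float]:
    """Choose the pyramid level to read and the residual downsample factor.

    Returns ``(level, factor)`` where ``factor`` is the additional
    downsampling to apply after reading (1.0 when a level sits at the
    target).  The level whose magnification is closest to the target (in
    log ratio) is used if it is within 1.5x; otherwise the nearest finer
    level is read and downsampled by the exact remaining factor.
    """
    mags = [info.native_magnification / d for d in info.level_downsamples]
    ratios = [max(m / target_magnification, target_magnification / m) for m in mags]
    best = int(np.argmin(ratios))
    if ratios[best] <= 1.5:
        return best, mags[best] / target_magnification
    finer = [i for i, m in enumerate(mags) if m > target_magnification]
    if not finer:
        raise ValueError(
            f"no pyramid level at or finer than {target_magnification}x "
            f"(available magnifications: {mags}); cannot reach the working "
            "magnification without upsampling"
        )
    level = min(finer, key=lambda i: mags[i])
    return level, mags[level] / target_magnification


def tile_grid(
    slide_shape: tuple[int, ...] | np.ndarray,
    slide_id: str,
    size: int = DEFAULT_TILE_SIZE,
) -> list[TileRef]:
    """All complete non-overlapping tiles, row-major; edge remainders dropped."""
    if isinstance(slide_shape, np.ndarray):
        slide_shape = slide_shape.shape
    h, w = slide_shape[0], slide_shape[1]
    n_rows, n_cols = h // size, w // size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"slide {slide_id}: image {h}x{w} smaller than one {size}px tile",
            EmptySlideWarning,
        )
        return []
    return [
        TileRef(slide_id=slide_id, col=c, row=r, size=size)
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def is_tissue(
    tile_image: np.ndarray,
    white_intensity_cutoff: int = DEFAULT_WHITE_INTENSITY_CUTOFF,
    white_fraction_cutoff: float = DEFAULT_WHITE_FRACTION_CUTOFF,
) -> bool:
    """False (background) iff the white-pixel fraction strictly exceeds the cutoff.

    A pixel is white when its minimum channel is >= ``white_intensity_cutoff``.
    """
    if tile_image.ndim != 3 or tile_image.shape[2] != 3:
        raise ValueError("tile must be an RGB raster")
    white = tile_image.min(axis=2) >= white_intensity_cutoff
    return not float(white.mean()) > white_fraction_cutoff


def extract_tile(slide_image: np.ndarray, ref: TileRef) -> np.ndarray:
    return slide_image[ref.y:ref.y + ref.size, ref.x:ref.x + ref.size]


@dataclass
class TilingReport:
    """Provenance of one slide's tiling run."""

    slide_id: str
    n_grid: int
    n_kept: int
    n_discarded: int
    excluded: bool = False


def build_bag(
    slide_image: np.ndarray,
    slide_id: str,
    labels: Any = None,
    size: int = DEFAULT_TILE_SIZE,
    white_intensity_cutoff: int = DEFAULT_WHITE_INTENSITY_CUTOFF,
    white_fraction_cutoff: float = DEFAULT_WHITE_FRACTION_CUTOFF,
) -> tuple[Bag, TilingReport]:
    """Tile a slide and keep exactly the tiles passing the tissue filter.

    A slide with zero tissue tiles yields an empty bag, a report flagged
    ``excluded`` and an :class:`EmptySlideWarning` — downstream training
    and inference refuse empty bags.
    """
    grid = tile_grid(slide_image.shape, slide_id, size)
    kept = [
        ref for ref in grid
        if is_tissue(extract_tile(slide_image, ref), white_intensity_cutoff, white_fraction_cutoff)
    ]
    report = TilingReport(
        slide_id=slide_id,
        n_grid=len(grid),
        n_kept=len(kept),
        n_discarded=len(grid) - len(kept),
        excluded=len(kept) == 0,
    )
    if report.excluded and len(grid) > 0:
        warnings.warn(
            f"slide {slide_id}: no tissue tiles after filtering; excluded",
            EmptySlideWarning,
        )
    h, w = slide_image.shape[0], slide_image.shape[1]
    return (
        Bag(slide_id=slide_id, tiles=kept, labels=labels,
            n_rows=h // size, n_cols=w // size),
        report,
    )


def bag_manifest(bag: Bag, report: TilingReport | None = None,
                 slide_path: str | None = None) -> pd.DataFrame:
    """Serialize the full grid with kept flags (kept + discarded = grid)."""
    kept_set = {(t.row, t.col) for t in bag.tiles}
    size = bag.tiles[0].size if bag.tiles else DEFAULT_TILE_SIZE
    rows = []
    for r in range(bag.n_rows):
        for c in range(bag.n_cols):
            rows.append(
                {
                    "slide_id": bag.slide_id,
                    "col": c,
                    "row": r,
                    "x": c * size,
                    "y": r * size,
                    "size": size,
                    "kept": int((r, c) in kept_set),
                    "slide_path": slide_path or "",
                }
            )
    return pd.DataFrame(rows)


def bag_from_manifest(frame: pd.DataFrame, labels: Any = None) -> Bag:
    if frame.empty:
        raise ValueError("empty bag manifest")
    slide_id = str(frame["slide_id"].iloc[0])
    kept = frame[frame["kept"] == 1]
    tiles = [
        TileRef(slide_id=slide_id, col=int(r.col), row=int(r.row), size=int(r.size))
        for r in kept.itertuples()
    ]
    return Bag(
        slide_id=slide_id,
        tiles=tiles,
        labels=labels,
        n_rows=int(frame["row"].max()) + 1,
        n_cols=int(frame["col"].max()) + 1,
    )


def read_slide_image(path: str | Path) -> np.ndarray:
    """Read a single-level slide image (TIFF or PNG) as an RGB uint8 array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        import tifffile

        image = tifffile.imread(path)
    else:
        from PIL import Image

        image = np.asarray(Image.open(path).convert("RGB"))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    return image
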