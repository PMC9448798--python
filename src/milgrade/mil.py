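"""The iterative MIL training loop with multi-task heads.

A whole-slide image is a bag of tissue tiles carrying one slide-level
label (binary tumor grade, plus optional auxiliary labels).  Training
alternates two steps:

1. *Inference*: up to 512 randomly sampled tissue tiles per slide are
   scored by the current network's tumor-grade head, and the top-5
   highest-probability tiles per slide are selected (always on the grade
   head, even when auxiliary heads are trained).
2. *Training*: the selected tiles, each assigned its slide's full label
   set, are used for one pass of SGD (lr 0.007, momentum 0.9, batch 256,
   weight decay 0.01) against the unweighted sum of per-task binary
   cross-entropies; missing auxiliary labels are masked out.

After each iteration the model is evaluated on a validation split by
Cohen's kappa between predicted and reference grade, and the best model
is snapshotted.  At prediction time a slide's label is the majority vote
of its top-5 tiles, each thresholded at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .backbone import build_backbone, SmallConvNet
from .evaluation import cohens_kappa
from .tiling import Bag, TileRef, extract_tile

__all__ = [
    "TASK_SETS",
    "LabelSet",
    "AugmentationConfig",
    "TrainingConfig",
    "TileScore",
    "SlidePrediction",
    "MILState",
    "PixelBag",
    "pixel_bag_from_image",
    "sample_tiles",
    "augment",
    "mtl_loss",
    "inference_step",
    "select_top_k",
    "training_step",
    "predict_slide",
    "train_mil",
    "top_tile_motif_fraction",
    "save_checkpoint",
    "load_checkpoint",
]

TASK_SETS: dict[str, tuple[str, ...]] = {
    "grade_only": ("grade",),
    "grade+components": ("grade", "nuclear", "tubular", "mitotic"),
    "grade+components+receptors": (
        "grade", "nuclear", "tubular", "mitotic", "hr", "her2",
    ),
}


@dataclass(frozen=True)
class LabelSet:
    """Slide-level labels: binary grade plus optional auxiliary labels."""

    grade: int
    nuclear: int | None = None
    tubular: int | None = None
    mitotic: int | None = None
    hr: int | None = None
    her2: int | None = None

    def __post_init__(self) -> None:
        if self.grade not in (0, 1):
            raise ValueError(f"grade must be 0 or 1, got {self.grade!r}")
        for name in ("nuclear", "tubular", "mitotic", "hr", "her2"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"label {name!r} must be 0, 1 or missing; got {v!r}")

    def vector(self, tasks: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(values, mask) over the given tasks; missing labels masked out."""
        values = np.zeros(len(tasks))
        mask = np.zeros(len(tasks))
        for j, t in enumerate(tasks):
            v = getattr(self, t)
            if v is not None:
                values[j] = v
                mask[j] = 1.0
        return values, mask


@dataclass(frozen=True)
class AugmentationConfig:
    """Random tile augmentation: the group of 90-degree rotations and
    flips, plus photometric jitter within the stated maxima."""

    rot90: bool = True
    hflip: bool = True
    vflip: bool = True
    brightness_max: float = 0.35
    contrast_max: float = 0.5
    hue_max: float = 0.1
    saturation_max: float = 0.1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the MIL loop; defaults are the study settings."""

    tile_size: int = 224
    working_magnification: float = 10.0
    n_sample_tiles: int = 512
    top_k: int = 5
    learning_rate: float = 0.007
    momentum: float = 0.9
    batch_size: int = 256
    weight_decay: float = 0.01
    n_iterations: int = 300
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    task_set: str = "grade+components"
    backbone: str = "smallcnn"
    vote_aggregation: str = "vote"  # "vote" (per-tile 0.5 threshold) or "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k % 2 == 0 or self.top_k < 1:
            raise ValueError(f"top_k must be odd and positive, got {self.top_k}")
        if self.top_k > self.n_sample_tiles:
            raise ValueError("top_k cannot exceed n_sample_tiles")
        if self.task_set not in TASK_SETS:
            raise ValueError(f"task_set must be one of {sorted(TASK_SETS)}")
        if self.vote_aggregation not in ("vote", "mean"):
            raise ValueError("vote_aggregation must be 'vote' or 'mean'")

    @property
    def tasks(self) -> tuple[str, ...]:
        return TASK_SETS[self.task_set]


@dataclass(frozen=True)
class TileScore:
    tile: TileRef
    prob: np.ndarray  # per-task probabilities

    def __post_init__(self) -> None:
        p = np.asarray(self.prob)
        if not (np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()):
            raise ValueError("probabilities must be finite and in [0, 1]")


@dataclass(frozen=True)
class SlidePrediction:
    slide_id: str
    label: int
    top_tiles: tuple[tuple[TileRef, float], ...]
    votes_positive: int


@dataclass
class MILState:
    """Everything train_mil produces: the model, its best snapshot, the log."""

    model: SmallConvNet
    config: TrainingConfig
    iteration: int
    best_validation_kappa: float
    best_snapshot: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)

    def best_model(self) -> SmallConvNet:
        model = build_backbone(self.config.backbone, self.config.tasks,
                               np.random.default_rng(0))
        model.load_snapshot(self.best_snapshot)
        return model


# ---------------------------------------------------------------------------
# pixel bags: tiles held in memory at the backbone's input resolution


@dataclass
class PixelBag:
    """A bag plus its tile rasters, block-averaged to the model input size.

    Holding every 224-px tile of a cohort in memory is wasteful when the
    backbone consumes a smaller raster; tiles are stored already reduced
    (uint8) and normalized to [0, 1] channel-first on demand.
    """

    bag: Bag
    pixels: np.ndarray  # (n_tiles, s, s, 3) uint8

    def __post_init__(self) -> None:
        if len(self.bag) != len(self.pixels):
            raise ValueError("pixel array does not match bag tiles")

    def __len__(self) -> int:
        return len(self.bag)

    def model_input(self, indices: np.ndarray | Sequence[int]) -> np.ndarray:
        x = self.pixels[np.asarray(indices, dtype=int)]
        return x.astype(np.float64).transpose(0, 3, 1, 2) / 255.0


def _block_mean(tile: np.ndarray, out_size: int) -> np.ndarray:
    s = tile.shape[0]
    if s % out_size != 0:
        raise ValueError(f"tile size {s} not divisible by model input size {out_size}")
    f = s // out_size
    return (
        tile.reshape(out_size, f, out_size, f, 3).mean(axis=(1, 3))
    ).astype(np.uint8)


def pixel_bag_from_image(
    slide_image: np.ndarray, bag: Bag, input_size: int = SmallConvNet.input_size
) -> PixelBag:
    pixels = np.stack(
        [_block_mean(extract_tile(slide_image, ref), input_size) for ref in bag.tiles]
    ) if bag.tiles else np.zeros((0, input_size, input_size, 3), np.uint8)
    return PixelBag(bag=bag, pixels=pixels)


# ---------------------------------------------------------------------------
# operations


def sample_tiles(bag: Bag | PixelBag, n: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of min(n, len(bag)) distinct tiles, uniform without replacement."""
    size = len(bag)
    if size == 0:
        raise ValueError("cannot sample from an empty bag")
    if size <= n:
        return np.arange(size)
    return rng.choice(size, size=n, replace=False)


def _rank_key(ref: TileRef) -> tuple[int, int]:
    return (ref.row, ref.col)


def _ranked_indices(probs: np.ndarray, tiles: Sequence[TileRef]) -> list[int]:
    """Indices sorted by descending probability, ties broken by (row, col)."""
    return sorted(range(len(tiles)), key=lambda i: (-probs[i], _rank_key(tiles[i])))


def inference_step(
    model,
    pixel_bags: Sequence[PixelBag],
    config: TrainingConfig,
    rng: np.random.Generator,
) -> dict[str, list[tuple[int, TileScore]]]:
    """Score a random tile sample of each bag and rank by grade probability.

    Ranking uses the tumor-grade head only, even in multitask mode.
    Returns per slide a list of (tile index within bag, TileScore) in
    descending grade-probability order.
    """
    grade_idx = model.tasks.index("grade")
    out: dict[str, list[tuple[int, TileScore]]] = {}
    for pb in pixel_bags:
        idx = sample_tiles(pb, config.n_sample_tiles, rng)
        probs = _score_indices(model, pb, idx, config.batch_size)
        tiles = [pb.bag.tiles[i] for i in idx]
        order = _ranked_indices(probs[:, grade_idx], tiles)
        out[pb.bag.slide_id] = [
            (int(idx[j]), TileScore(tile=tiles[j], prob=probs[j])) for j in order
        ]
    return out


def _score_indices(model, pb: PixelBag, idx: np.ndarray, batch_size: int) -> np.ndarray:
    chunks = []
    for start in range(0, len(idx), batch_size):
        x = pb.model_input(idx[start:start + batch_size])
        chunks.append(model.forward_probs(x))
    return np.concatenate(chunks, axis=0)


def select_top_k(
    ranked: Sequence[tuple[int, TileScore]], k: int
) -> list[tuple[int, TileScore]]:
    """The k top-ranked tiles; fewer than k available returns all, warning."""
    if len(ranked) == 0:
        raise ValueError("no scored tiles to select from")
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} tiles available for top-{k} selection",
            UserWarning,
        )
        return list(ranked)
    return list(ranked[:k])


def mtl_loss(
    per_task_probabilities: Mapping[str, float],
    label_set: LabelSet,
    task_set: str,
) -> float:
    """Unweighted sum of per-task binary cross-entropies.

    Tasks whose label is missing contribute zero.  Probabilities are
    clamped to [1e-7, 1 - 1e-7] before the logs.
    """
    total = 0.0
    for t in TASK_SETS[task_set]:
        y = getattr(label_set, t)
        if y is None:
            continue
        p = float(np.clip(per_task_probabilities[t], 1e-7, 1.0 - 1e-7))
        total += -(y * np.log(p) + (1 - y) * np.log(1.0 - p))
    return float(total)


# --------------------------------------------------------------- augmentation


def augment(
    tile_image: np.ndarray, config: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Randomly augmented copy of an RGB uint8 tile, same shape and range.

    Geometry: a rotation from {0, 90, 180, 270} degrees and independent
    horizontal/vertical flips.  Photometry: brightness, contrast and
    saturation factors drawn uniformly in [1 - m, 1 + m] and a hue shift
    uniform in [-m, +m] (fraction of the hue circle).
    """
    img = tile_image
    if config.rot90:
        img = np.rot90(img, k=int(rng.integers(0, 4)))
    if config.hflip and rng.random() < 0.5:
        img = img[:, ::-1]
    if config.vflip and rng.random() < 0.5:
        img = img[::-1, :]

    x = img.astype(np.float64) / 255.0
    if config.brightness_max > 0:
        x = x * rng.uniform(1.0 - config.brightness_max, 1.0 + config.brightness_max)
    if config.contrast_max > 0:
        factor = rng.uniform(1.0 - config.contrast_max, 1.0 + config.contrast_max)
        gray_mean = x.mean()
        x = gray_mean + (x - gray_mean) * factor
    if config.saturation_max > 0:
        factor = rng.uniform(1.0 - config.saturation_max, 1.0 + config.saturation_max)
        gray = x.mean(axis=2, keepdims=True)
        x = gray + (x - gray) * factor
    if config.hue_max > 0:
        from skimage.color import rgb2hsv, hsv2rgb

        shift = rng.uniform(-config.hue_max, config.hue_max)
        hsv = rgb2hsv(np.clip(x, 0.0, 1.0))
        hsv[:, :, 0] = (hsv[:, :, 0] + shift) % 1.0
        x = hsv2rgb(hsv)
    return np.clip(np.rint(x * 255.0), 0, 255).astype(np.uint8)


# ------------------------------------------------------------------ training


def training_step(
    model,
    selected: Sequence[tuple[np.ndarray, LabelSet]],
    config: TrainingConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """One pass of SGD over the selected tiles in shuffled mini-batches.

    Each element of ``selected`` is (tile raster uint8, its bag's labels);
    every tile is augmented before entering the batch.  Returns mean
    per-task losses over the pass.  Zero selected tiles is a warned no-op.
    """
    if len(selected) == 0:
        warnings.warn("training step called with zero selected tiles", UserWarning)
        return {t: float("nan") for t in model.tasks}

    order = rng.permutation(len(selected))
    tasks = model.tasks
    loss_sums = {t: 0.0 for t in tasks}
    loss_counts = {t: 0 for t in tasks}
    for start in range(0, len(order), config.batch_size):
        batch_idx = order[start:start + config.batch_size]
        rasters, labels, masks = [], [], []
        for i in batch_idx:
            tile, label_set = selected[i]
            tile = augment(tile, config.augmentation, rng)
            rasters.append(tile.astype(np.float64).transpose(2, 0, 1) / 255.0)
            v, m = label_set.vector(tasks)
            labels.append(v)
            masks.append(m)
        losses = model.train_batch(
            np.stack(rasters), np.stack(labels), np.stack(masks),
            lr=config.learning_rate, momentum=config.momentum,
            weight_decay=config.weight_decay,
        )
        for t, v in losses.items():
            if np.isfinite(v):
                loss_sums[t] += v
                loss_counts[t] += 1
    return {t: (loss_sums[t] / loss_counts[t] if loss_counts[t] else 0.0) for t in tasks}


# ---------------------------------------------------------------- prediction


def predict_slide(
    model,
    pixel_bag: PixelBag,
    config: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> SlidePrediction:
    """Majority vote over the top-k tiles' thresholded grade probabilities.

    If the bag holds fewer than top_k tiles the vote uses the largest odd
    available count, so the majority is never tied.  With
    ``vote_aggregation='mean'`` the mean top-k probability is thresholded
    at 0.5 instead.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grade_idx = model.tasks.index("grade")
    idx = sample_tiles(pixel_bag, config.n_sample_tiles, rng)
    probs = _score_indices(model, pixel_bag, idx, config.batch_size)
    tiles = [pixel_bag.bag.tiles[i] for i in idx]
    order = _ranked_indices(probs[:, grade_idx], tiles)
    ranked = [(int(idx[j]), TileScore(tile=tiles[j], prob=probs[j])) for j in order]
    top = select_top_k(ranked, config.top_k)

    top_probs = np.array([score.prob[grade_idx] for _, score in top])
    n_vote = len(top) if len(top) % 2 == 1 else len(top) - 1
    if config.vote_aggregation == "mean":
        label = int(top_probs.mean() > 0.5)
        votes = int((top_probs > 0.5).sum())
    else:
        votes = int((top_probs[:n_vote] > 0.5).sum())
        label = int(votes > n_vote / 2)
    return SlidePrediction(
        slide_id=pixel_bag.bag.slide_id,
        label=label,
        top_tiles=tuple((score.tile, float(score.prob[grade_idx])) for _, score in top),
        votes_positive=votes,
    )


# ------------------------------------------------------------------ the loop


def _validation_kappa(model, val_bags, config, rng) -> float:
    y_true = np.array([pb.bag.labels.grade for pb in val_bags])
    y_pred = np.array(
        [predict_slide(model, pb, config, rng).label for pb in val_bags]
    )
    try:
        return cohens_kappa(y_true, y_pred)
    except ValueError:
        # single-class marginals with disagreement: no better than chance
        return -1.0


def train_mil(
    train_bags: Sequence[PixelBag],
    val_bags: Sequence[PixelBag],
    config: TrainingConfig,
) -> MILState:
    """Run the two-step MIL loop for ``config.n_iterations`` iterations.

    Every iteration: fresh 512-tile samples are scored, the top-k per
    slide are selected on the grade head, and one SGD pass trains on them
    with the bag's labels.  Validation kappa is computed each iteration
    and the best model snapshotted; the returned state carries the final
    model, the best snapshot and the full per-iteration metric log.
    """
    if len(val_bags) == 0:
        raise ValueError("validation set must be non-empty (model selection needs it)")
    if any(len(pb) == 0 for pb in list(train_bags) + list(val_bags)):
        raise ValueError("empty bags must be excluded before training")
    train_ids = {pb.bag.slide_id for pb in train_bags}
    if train_ids & {pb.bag.slide_id for pb in val_bags}:
        raise ValueError("train and validation slide sets must be disjoint")

    root = np.random.SeedSequence(config.seed)
    ss_init, ss_sample, ss_train, ss_val = root.spawn(4)
    rng_sample = np.random.default_rng(ss_sample)
    rng_train = np.random.default_rng(ss_train)
    rng_val = np.random.default_rng(ss_val)

    model = build_backbone(config.backbone, config.tasks, np.random.default_rng(ss_init))

    kappa0 = _validation_kappa(model, val_bags, config, rng_val)
    best_kappa = kappa0
    best_snapshot = model.state_snapshot()
    history: list[dict] = [
        {"iteration": 0, "val_kappa": kappa0, "best_val_kappa": best_kappa, "losses": {}}
    ]

    for it in range(1, config.n_iterations + 1):
        ranked = inference_step(model, train_bags, config, rng_sample)
        selected: list[tuple[np.ndarray, LabelSet]] = []
        for pb in train_bags:
            top = select_top_k(ranked[pb.bag.slide_id], config.top_k)
            for tile_idx, _score in top:
                selected.append((pb.pixels[tile_idx], pb.bag.labels))
        losses = training_step(model, selected, config, rng_train)
        kappa = _validation_kappa(model, val_bags, config, rng_val)
        if kappa > best_kappa:
            best_kappa = kappa
            best_snapshot = model.state_snapshot()
        history.append(
            {"iteration": it, "val_kappa": kappa, "best_val_kappa": best_kappa,
             "losses": losses}
        )

    return MILState(
        model=model,
        config=config,
        iteration=config.n_iterations,
        best_validation_kappa=best_kappa,
        best_snapshot=best_snapshot,
        history=history,
    )


def top_tile_motif_fraction(
    model,
    pixel_bags: Sequence[PixelBag],
    tile_truth: Mapping[str, np.ndarray],
    config: TrainingConfig,
) -> float:
    """Mean fraction of motif tiles among top-k selections in positive bags.

    The instance-discovery diagnostic: after training, the top-k tiles of
    positive bags should be enriched in true motif tiles relative to the
    motif prevalence.
    """
    fractions = []
    for pb in pixel_bags:
        if pb.bag.labels.grade != 1:
            continue
        pred = predict_slide(model, pb, config)
        truth = tile_truth[pb.bag.slide_id]
        hits = [truth[ref.row, ref.col] for ref, _p in pred.top_tiles]
        fractions.append(float(np.mean(hits)))
    if not fractions:
        raise ValueError("no positive bags supplied")
    return float(np.mean(fractions))


# ---------------------------------------------------------------- checkpoint


def save_checkpoint(state: MILState, path: str | Path) -> None:
    """Single-file archive: best parameters, config, metric log, version."""
    import json

    cfg = asdict(state.config)
    payload = json.dumps(
        {"format_version": 1, "config": cfg, "iteration": state.iteration,
         "best_validation_kappa": state.best_validation_kappa,
         "history": state.history}
    )
    np.savez(
        path,
        __checkpoint__=np.frombuffer(payload.encode(), dtype=np.uint8),
        **{f"param_{k}": v for k, v in state.best_snapshot.items()},
    )


def load_checkpoint(path: str | Path) -> MILState:
    import json

    data = np.load(path, allow_pickle=False)
    payload = json.loads(bytes(data["__checkpoint__"]).decode())
    cfg_dict = payload["config"]
    cfg_dict["augmentation"] = AugmentationConfig(**cfg_dict["augmentation"])
    config = TrainingConfig(**cfg_dict)
    snapshot = {
        k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
    }
    model = build_backbone(config.backbone, config.tasks, np.random.default_rng(0))
    model.load_snapshot(snapshot)
    return MILState(
        model=model,
        config=config,
        iteration=payload["iteration"],
        best_validation_kappa=payload["best_validation_kappa"],
        best_snapshot=snapshot,
        history=payload["history"],
    )
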