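"""The MIL engine: sampling, selection, loss, augmentation, the loop."""

import numpy as np
import pytest

from milgrade.mil import (
    AugmentationConfig,
    LabelSet,
    PixelBag,
    TrainingConfig,
    augment,
    inference_step,
    load_checkpoint,
    mtl_loss,
    predict_slide,
    sample_tiles,
    save_checkpoint,
    select_top_k,
    top_tile_motif_fraction,
    train_mil,
)
from milgrade.tiling import Bag, TileRef

from conftest import cohort_pixel_bags


def make_pixel_bag(slide_id, probs, grade=1, n_cols=4):
    """A bag whose ProbeModel scores equal ``probs`` (via the first pixel)."""
    tiles, pixels = [], []
    for i, p in enumerate(probs):
        r, c = divmod(i, n_cols)
        tiles.append(TileRef(slide_id=slide_id, col=c, row=r, size=224))
        px = np.full((32, 32, 3), 128, np.uint8)
        px[0, 0, 0] = int(round(p * 255))
        pixels.append(px)
    bag = Bag(slide_id=slide_id, tiles=tiles, labels=LabelSet(grade=grade),
              n_rows=(len(probs) + n_cols - 1) // n_cols, n_cols=n_cols)
    return PixelBag(bag=bag, pixels=np.stack(pixels))


# ------------------------------------------------------------------ sampling


def test_sample_returns_all_when_bag_smaller_than_n():
    bag = make_pixel_bag("s", [0.5] * 100)
    idx = sample_tiles(bag, 512, np.random.default_rng(0))
    assert sorted(idx.tolist()) == list(range(100))


def test_sample_distinct_and_deterministic():
    bag = make_pixel_bag("s", [0.5] * 40)
    a = sample_tiles(bag, 16, np.random.default_rng(9))
    b = sample_tiles(bag, 16, np.random.default_rng(9))
    assert np.array_equal(a, b)
    assert len(set(a.tolist())) == 16


def test_sample_empty_bag_is_error():
    bag = Bag(slide_id="s", tiles=[], labels=LabelSet(grade=0))
    empty = PixelBag(bag=bag, pixels=np.zeros((0, 32, 32, 3), np.uint8))
    with pytest.raises(ValueError, match="empty"):
        sample_tiles(empty, 5, np.random.default_rng(0))


# ----------------------------------------------------------------- selection


def test_select_top_k_takes_highest(probe_model):
    pb = make_pixel_bag("s", [0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
    cfg = TrainingConfig(top_k=5, n_sample_tiles=8, batch_size=8)
    ranked = inference_step(probe_model, [pb], cfg, np.random.default_rng(0))["s"]
    top = select_top_k(ranked, 5)
    got = sorted(i for i, _ in top)
    assert got == [0, 1, 2, 3, 4]


def test_select_top_k_clamps_with_warning(probe_model):
    pb = make_pixel_bag("s", [0.9, 0.8, 0.7])
    cfg = TrainingConfig(top_k=5, n_sample_tiles=8, batch_size=8)
    ranked = inference_step(probe_model, [pb], cfg, np.random.default_rng(0))["s"]
    with pytest.warns(UserWarning, match="3 tiles"):
        top = select_top_k(ranked, 5)
    assert len(top) == 3


def test_equal_scores_rank_by_row_col(probe_model):
    pb = make_pixel_bag("s", [0.5] * 8, n_cols=4)
    cfg = TrainingConfig(top_k=3, n_sample_tiles=8, batch_size=8)
    ranked = inference_step(probe_model, [pb], cfg, np.random.default_rng(0))["s"]
    coords = [(score.tile.row, score.tile.col) for _, score in ranked]
    assert coords == sorted(coords)


def test_scores_invariant_to_tile_order(oracle_model, small_cohort, small_pixel_bags):
    pb = next(b for b in small_pixel_bags if b.bag.labels.grade == 1)
    cfg = TrainingConfig(n_sample_tiles=512, batch_size=64)
    ranked = inference_step(oracle_model, [pb], cfg, np.random.default_rng(0))
    perm = np.random.default_rng(1).permutation(len(pb))
    shuffled = PixelBag(
        bag=Bag(slide_id=pb.bag.slide_id,
                tiles=[pb.bag.tiles[i] for i in perm],
                labels=pb.bag.labels, n_rows=pb.bag.n_rows, n_cols=pb.bag.n_cols),
        pixels=pb.pixels[perm],
    )
    ranked_s = inference_step(oracle_model, [shuffled], cfg, np.random.default_rng(0))
    coords = [(s.tile.row, s.tile.col) for _, s in ranked[pb.bag.slide_id]]
    coords_s = [(s.tile.row, s.tile.col) for _, s in ranked_s[pb.bag.slide_id]]
    assert coords == coords_s


def test_oracle_scorer_puts_motif_tiles_on_top(oracle_model, small_cohort, small_pixel_bags):
    cfg = TrainingConfig(n_sample_tiles=512, batch_size=64)
    for pb in small_pixel_bags:
        if pb.bag.labels.grade != 1:
            continue
        truth = small_cohort.tile_truth[pb.bag.slide_id]
        n_motif = int(truth.sum())
        ranked = inference_step(oracle_model, [pb], cfg, np.random.default_rng(0))
        top = select_top_k(ranked[pb.bag.slide_id], min(5, n_motif) | 1)
        k_checked = min(len(top), n_motif)
        hits = [truth[s.tile.row, s.tile.col] for _, s in top[:k_checked]]
        assert all(hits)


# ---------------------------------------------------------------------- loss


def test_mtl_loss_closed_forms():
    labels = LabelSet(grade=1, nuclear=1, tubular=0, mitotic=1)
    half = {t: 0.5 for t in ("grade", "nuclear", "tubular", "mitotic")}
    assert mtl_loss(half, labels, "grade_only") == pytest.approx(np.log(2))
    assert mtl_loss(half, labels, "grade+components") == pytest.approx(4 * np.log(2))
    perfect = {"grade": 1.0, "nuclear": 1.0, "tubular": 0.0, "mitotic": 1.0}
    assert mtl_loss(perfect, labels, "grade+components") == pytest.approx(0.0, abs=1e-5)


def test_mtl_loss_skips_missing_labels():
    labels = LabelSet(grade=1)  # no auxiliary labels
    half = {t: 0.5 for t in ("grade", "nuclear", "tubular", "mitotic")}
    assert mtl_loss(half, labels, "grade+components") == pytest.approx(np.log(2))


# ---------------------------------------------------------------- augmenting


def _identity_config():
    return AugmentationConfig(rot90=False, hflip=False, vflip=False,
                              brightness_max=0.0, contrast_max=0.0,
                              hue_max=0.0, saturation_max=0.0)


def test_augment_identity_when_all_off():
    rng = np.random.default_rng(0)
    tile = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
    out = augment(tile, _identity_config(), rng)
    assert np.array_equal(out, tile)


def test_augment_geometric_only_yields_dihedral_variant():
    rng = np.random.default_rng(1)
    tile = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
    cfg = AugmentationConfig(rot90=True, hflip=True, vflip=True,
                             brightness_max=0.0, contrast_max=0.0,
                             hue_max=0.0, saturation_max=0.0)
    variants = []
    base = tile
    for k in range(4):
        r = np.rot90(base, k)
        variants += [r, r[:, ::-1], r[::-1, :], r[::-1, ::-1]]
    for _ in range(10):
        out = augment(tile, cfg, rng)
        assert any(np.array_equal(out, v) for v in variants)


def test_augment_deterministic_under_seed():
    tile = np.random.default_rng(2).integers(0, 256, (32, 32, 3)).astype(np.uint8)
    cfg = AugmentationConfig()
    a = augment(tile, cfg, np.random.default_rng(5))
    b = augment(tile, cfg, np.random.default_rng(5))
    assert np.array_equal(a, b)


def test_augment_preserves_shape_dtype_range():
    tile = np.random.default_rng(3).integers(0, 256, (32, 32, 3)).astype(np.uint8)
    out = augment(tile, AugmentationConfig(), np.random.default_rng(4))
    assert out.shape == tile.shape and out.dtype == np.uint8


# --------------------------------------------------------------- prediction


def test_majority_vote_three_of_five(probe_model):
    pb = make_pixel_bag("s", [0.9, 0.9, 0.9, 0.1, 0.1], grade=1)
    cfg = TrainingConfig(top_k=5, n_sample_tiles=8, batch_size=8)
    pred = predict_slide(probe_model, pb, cfg)
    assert pred.votes_positive == 3 and pred.label == 1


def test_majority_vote_all_below_half_is_negative(probe_model):
    pb = make_pixel_bag("s", [0.4] * 5)
    cfg = TrainingConfig(top_k=5, n_sample_tiles=8, batch_size=8)
    pred = predict_slide(probe_model, pb, cfg)
    assert pred.votes_positive == 0 and pred.label == 0


def test_vote_truncates_to_odd_count_when_bag_small(probe_model):
    pb = make_pixel_bag("s", [0.9, 0.9, 0.1, 0.1])  # 4 tiles, top_k=5
    cfg = TrainingConfig(top_k=5, n_sample_tiles=8, batch_size=8)
    with pytest.warns(UserWarning):
        pred = predict_slide(probe_model, pb, cfg)
    # vote over largest odd count (3): tiles 0.9, 0.9, 0.1 -> positive
    assert pred.label == 1


def test_oracle_predicts_generator_bag_labels(oracle_model, small_cohort, small_pixel_bags):
    """MIL bag-label consistency: a perfect instance scorer reproduces the
    slide labels wherever positive bags hold enough motif tiles."""
    cfg = TrainingConfig(n_sample_tiles=512, batch_size=64)
    for pb in small_pixel_bags:
        truth = small_cohort.tile_truth[pb.bag.slide_id]
        if pb.bag.labels.grade == 1 and truth.sum() < 3:
            continue  # too few positive instances for a 5-tile majority
        pred = predict_slide(oracle_model, pb, cfg)
        assert pred.label == pb.bag.labels.grade


def test_config_validation():
    with pytest.raises(ValueError, match="odd"):
        TrainingConfig(top_k=4)
    with pytest.raises(ValueError):
        TrainingConfig(top_k=7, n_sample_tiles=5)
    with pytest.raises(ValueError):
        TrainingConfig(task_set="grades")


# ------------------------------------------------------------------ the loop


def _tiny_cohort_bags(seed):
    from milgrade.synthetic import SyntheticCohortSpec, generate_cohort

    spec = SyntheticCohortSpec(n_slides=8, tiles_per_side=4, white_fraction=0.1,
                               motif_prevalence=0.4, seed=seed)
    cohort = generate_cohort(spec)
    return cohort, cohort_pixel_bags(cohort)


def _tiny_config(n_iterations, seed=0):
    return TrainingConfig(n_iterations=n_iterations, batch_size=16,
                          task_set="grade_only", learning_rate=0.1, seed=seed)


def test_zero_iterations_returns_initial_model():
    cohort, bags = _tiny_cohort_bags(31)
    state = train_mil(bags[:6], bags[6:], _tiny_config(0))
    assert state.iteration == 0
    assert len(state.history) == 1
    assert "val_kappa" in state.history[0]


def test_metric_log_reproducible_under_seed():
    cohort, bags = _tiny_cohort_bags(32)
    a = train_mil(bags[:6], bags[6:], _tiny_config(2, seed=5))
    b = train_mil(bags[:6], bags[6:], _tiny_config(2, seed=5))
    assert a.history == b.history


def test_best_validation_kappa_monotone():
    cohort, bags = _tiny_cohort_bags(33)
    state = train_mil(bags[:6], bags[6:], _tiny_config(4))
    best = [h["best_val_kappa"] for h in state.history]
    assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))


def test_train_rejects_overlapping_or_empty_splits():
    cohort, bags = _tiny_cohort_bags(34)
    with pytest.raises(ValueError, match="disjoint"):
        train_mil(bags, bags, _tiny_config(1))
    with pytest.raises(ValueError, match="validation"):
        train_mil(bags, [], _tiny_config(1))


def test_checkpoint_round_trip_preserves_predictions(tmp_path):
    cohort, bags = _tiny_cohort_bags(35)
    cfg = _tiny_config(2)
    state = train_mil(bags[:6], bags[6:], cfg)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(state, path)
    restored = load_checkpoint(path)
    assert restored.config == cfg
    assert restored.best_validation_kappa == state.best_validation_kappa
    model_a, model_b = state.best_model(), restored.best_model()
    x = bags[0].model_input(np.arange(min(4, len(bags[0]))))
    assert np.allclose(model_a.forward_probs(x), model_b.forward_probs(x))


def test_motif_fraction_oracle_is_full_enrichment(oracle_model, small_cohort, small_pixel_bags):
    cfg = TrainingConfig(n_sample_tiles=512, batch_size=64, top_k=3)
    frac = top_tile_motif_fraction(oracle_model, small_pixel_bags,
                                   small_cohort.tile_truth, cfg)
    assert frac > 0.9
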