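import numpy as np
import pytest

from wingcpm import (
    SearchSpec,
    SimilarityTransform,
    WingModel,
    align_recursive,
    initial_outline_alignment,
    register_to_model,
    similarity_score,
)

RES = 96


@pytest.fixture(scope="session")
def wing_grid(alleles):
    return alleles["arc"].rasterize(RES)


def test_model_frequencies_normalized(wing_grid):
    tfs = [SimilarityTransform(), SimilarityTransform(tx=3, ty=-2, theta=5, s=1.02)]
    model = WingModel.from_patterns([wing_grid, wing_grid], tfs)
    assert model.check_normalized()
    assert (model.support >= 1).any()


def test_outline_alignment_recovers_translation(wing_grid):
    shifted = SimilarityTransform(tx=10, ty=-4).warp_grid(wing_grid)
    tfs = initial_outline_alignment([wing_grid, shifted])
    rel = tfs[1].compose(tfs[0].inverse())
    assert abs(rel.tx - (-10)) <= 0.5 and abs(rel.ty - 4) <= 0.5


def test_outline_alignment_identity_for_identical_masks(wing_grid):
    tfs = initial_outline_alignment([wing_grid, wing_grid])
    assert tfs[0] == tfs[1]


def test_outline_alignment_recovers_scale(wing_grid):
    scaled = SimilarityTransform(s=1.2).warp_grid(wing_grid)
    tfs = initial_outline_alignment([wing_grid, scaled], target_area=float((wing_grid > 0).sum()))
    assert abs(tfs[1].s - 1 / 1.2) / (1 / 1.2) <= 0.01


def test_outline_alignment_excludes_degenerate_mask(wing_grid):
    tiny = np.zeros_like(wing_grid)
    tiny[10, 10] = 1
    with pytest.warns(UserWarning, match="degenerate"):
        tfs = initial_outline_alignment([wing_grid, tiny, wing_grid])
    assert tfs[1] is None and tfs[0] is not None


def test_score_is_one_for_pattern_matching_single_wing_model(wing_grid):
    model = WingModel.from_patterns([wing_grid])
    assert similarity_score(wing_grid, model, SimilarityTransform()) == 1.0


def test_score_zero_for_all_background_pattern(wing_grid):
    model = WingModel.from_patterns([wing_grid])
    # restrict to wing pixels: there the background frequency is 0
    sub = model.support.copy()
    model.support[:] = 0
    model.support[wing_grid > 0] = sub[wing_grid > 0]
    blank = np.zeros_like(wing_grid)
    assert similarity_score(blank, model, SimilarityTransform()) == 0.0


def test_score_one_for_duplicate_wing_model(wing_grid):
    model = WingModel.from_patterns([wing_grid, wing_grid])
    assert similarity_score(wing_grid, model, SimilarityTransform()) == 1.0


def test_register_recovers_known_transform(wing_grid):
    tf = SimilarityTransform(tx=5, ty=-3, theta=10, s=1.05)
    native = tf.warp_grid(wing_grid)
    model = WingModel.from_patterns([wing_grid])
    rec = register_to_model(native, model)
    assert rec.is_close(tf.inverse(), 0.5, 0.5, 0.01)


def test_register_returns_identity_on_exact_match(wing_grid):
    model = WingModel.from_patterns([wing_grid])
    rec = register_to_model(wing_grid, model)
    assert rec == SimilarityTransform()


def test_register_survives_pure_noise(wing_grid, rng):
    noise = rng.integers(0, 4, wing_grid.shape).astype(np.int16)
    model = WingModel.from_patterns([wing_grid])
    rec = register_to_model(noise, model)
    score = similarity_score(noise, model, rec)
    assert 0.0 <= score < 0.9


def test_empty_search_grid_raises():
    with pytest.raises(ValueError, match="empty grid"):
        SearchSpec(t_step=0)


def test_align_requires_at_least_one_iteration(wing_grid):
    with pytest.raises(ValueError):
        align_recursive([wing_grid, wing_grid], n_iter=0)


def test_already_aligned_set_keeps_identity_and_averages(wing_grid):
    res = align_recursive([wing_grid, wing_grid, wing_grid], n_iter=2, tol=1e-3)
    for tf in res.transforms:
        assert tf.is_close(SimilarityTransform(), 0.3, 0.3, 0.005)
    np.testing.assert_allclose(
        res.model.freq.max(axis=0)[res.model.support > 0], 1.0
    )
    assert res.trace[0]["model_delta"] < 1e-3  # single iteration to converge


def test_recursive_alignment_score_non_decreasing_and_tight(wing_grid, rng):
    pats = []
    for _ in range(5):
        tf = SimilarityTransform(
            float(rng.uniform(-6, 6)), float(rng.uniform(-6, 6)),
            float(rng.uniform(-6, 6)), float(rng.uniform(0.97, 1.03)),
        )
        pats.append(tf.warp_grid(wing_grid))
    res = align_recursive(pats, n_iter=3, tol=1e-4,
                          search=SearchSpec(t_range=8, t_step=4, theta_range=8,
                                            theta_step=4, s_range=0.08, s_step=0.04))
    scores = [t["mean_score"] for t in res.trace]
    assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))
    assert res.mean_score > 0.95
    assert res.model.check_normalized()


def test_alignment_equivariant_to_common_pre_transform(wing_grid, rng):
    """Pre-composing all inputs with one rigid shift leaves the aligned
    patterns (mutual disagreement) unchanged."""
    common = SimilarityTransform(tx=4, ty=-3)
    base = []
    for _ in range(4):
        tf = SimilarityTransform(float(rng.uniform(-4, 4)), float(rng.uniform(-4, 4)),
                                 float(rng.uniform(-4, 4)), 1.0)
        base.append(tf.warp_grid(wing_grid))
    shifted = [common.warp_grid(g) for g in base]
    spec = SearchSpec(t_range=8, t_step=4, theta_range=8, theta_step=4,
                      s_range=0.04, s_step=0.04)
    res_a = align_recursive(base, n_iter=2, tol=1e-4, search=spec)
    res_b = align_recursive(shifted, n_iter=2, tol=1e-4, search=spec)

    def mean_disagreement(res):
        grids = [p.grid for p in res.aligned]
        area = np.mean([(g > 0).sum() for g in grids])
        ds = [
            (grids[i] != grids[j]).sum() / area
            for i in range(len(grids)) for j in range(i + 1, len(grids))
        ]
        return np.mean(ds)

    assert abs(mean_disagreement(res_a) - mean_disagreement(res_b)) < 0.01
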