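"""Canvas construction and the layered projection family."""

import numpy as np
import pytest
from scipy.stats import chi2

from morphokit.geometry import ShapeMatrix
from morphokit.ordination import anc_states_bm, pca
from morphokit.refinement import fit_shape_regression
from morphokit import viz


@pytest.fixture
def canvas_and_shapes(rng):
    sm = ShapeMatrix(rng.normal(size=(25, 8)) + 2.0, kind="landmarks2d", k=4)
    ordn = pca(sm)
    return viz.build_canvas(ordn, axes=(0, 1), grid=(6, 5)), sm


# ---------------------------------------------------------------------------
# canvas + extract_shapes
# ---------------------------------------------------------------------------


def test_canvas_origin_gives_mean_shape(canvas_and_shapes):
    canvas, sm = canvas_and_shapes
    shape = viz.extract_shapes(canvas.ordination, [[0.0, 0.0]])
    assert np.abs(shape - sm.X.mean(0)).max() < 1e-12


def test_canvas_grid_matches_linear_reconstruction(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    ordn = canvas.ordination
    vi = ordn.loadings[:, 0]
    vj = ordn.loadings[:, 1]
    for pos, shape in zip(canvas.grid_scores, canvas.grid_shapes):
        oracle = ordn.center + pos[0] * vi + pos[1] * vj
        assert np.abs(shape - oracle).max() < 1e-10


def test_canvas_training_specimen_plane_projection(canvas_and_shapes):
    canvas, sm = canvas_and_shapes
    ordn = canvas.ordination
    s = ordn.scores[3, :2]
    shape = viz.extract_shapes(ordn, [s])
    oracle = ordn.center + s[0] * ordn.loadings[:, 0] + \
        s[1] * ordn.loadings[:, 1]
    assert np.abs(shape - oracle).max() < 1e-10


def test_canvas_rows_equally_spaced(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    r, c = canvas.grid_dims
    grid = canvas.grid_shapes.reshape(c, r, -1)
    second_diff = np.diff(grid, n=2, axis=1)
    assert np.abs(second_diff).max() < 1e-10


def test_canvas_same_axis_rejected(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    with pytest.raises(ValueError, match="differ"):
        viz.build_canvas(canvas.ordination, axes=(1, 1))


def test_canvas_axes_out_of_range(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    with pytest.raises(ValueError, match="out of range"):
        viz.build_canvas(canvas.ordination, axes=(0, 99))


# ---------------------------------------------------------------------------
# proj_shapes
# ---------------------------------------------------------------------------


def test_proj_training_data_recovers_scores(canvas_and_shapes):
    canvas, sm = canvas_and_shapes
    sc = viz.proj_shapes(canvas, sm)
    assert np.abs(sc - canvas.ordination.scores[:, :2]).max() < 1e-10


def test_proj_mean_shape_is_origin(canvas_and_shapes):
    canvas, sm = canvas_and_shapes
    sc = viz.proj_shapes(canvas, sm.X.mean(0)[None, :])
    assert np.abs(sc).max() < 1e-10


def test_extract_then_project_roundtrip(canvas_and_shapes, rng):
    canvas, _ = canvas_and_shapes
    s = rng.normal(size=(7, 2))
    shapes = viz.extract_shapes(canvas.ordination, s)
    back = viz.proj_shapes(canvas, shapes)
    assert np.abs(back - s).max() < 1e-9


def test_proj_dimension_mismatch_cites_p(canvas_and_shapes, rng):
    canvas, _ = canvas_and_shapes
    with pytest.raises(ValueError, match="p=8"):
        viz.proj_shapes(canvas, rng.normal(size=(3, 5)))


def test_projection_does_not_mutate_ordination(canvas_and_shapes, rng):
    canvas, sm = canvas_and_shapes
    before = canvas.ordination.loadings.copy()
    viz.proj_shapes(canvas, sm)
    viz.proj_groups(canvas, rng.normal(size=(20, 2)),
                    np.repeat(["a", "b"], 10), style="ellipse")
    viz.proj_axis(canvas, rng.normal(size=8))
    assert np.array_equal(canvas.ordination.loadings, before)


# ---------------------------------------------------------------------------
# groups
# ---------------------------------------------------------------------------


def test_hull_of_triangle_is_the_triangle(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    out = viz.proj_groups(canvas, pts, ["g"] * 3, style="hull")
    verts = {tuple(v) for v in out["g"].vertices}
    assert verts == {(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)}


def test_isotropic_ellipse_is_chi2_circle(canvas_and_shapes, rng):
    canvas, _ = canvas_and_shapes
    # construct scores with exactly unit isotropic covariance
    raw = rng.normal(size=(500, 2))
    raw -= raw.mean(0)
    cov = np.cov(raw, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    W = vecs @ np.diag(vals ** -0.5) @ vecs.T   # symmetric inverse sqrt
    pts = raw @ W
    out = viz.proj_groups(canvas, pts, ["g"] * 500, style="ellipse",
                          level=0.95)
    radii = np.linalg.norm(out["g"].vertices - out["g"].center, axis=1)
    assert np.abs(radii - np.sqrt(chi2.ppf(0.95, 2))).max() < 1e-8


def test_degenerate_group_skipped_with_warning(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.5, 0.9],
                    [0.1, 0.2], [0.9, 0.3]])
    labels = ["line"] * 3 + ["ok"] * 3
    with pytest.warns(UserWarning, match="degenerate"):
        out = viz.proj_groups(canvas, pts, labels, style="hull")
    assert "line" not in out and "ok" in out


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------


def test_loading_column_projects_horizontally(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    proj = viz.proj_axis(canvas, canvas.ordination.loadings[:, 0])
    assert np.abs(proj.segment[:, 1]).max() < 1e-10
    assert np.ptp(proj.segment[:, 0]) > 0


def test_direction_orthogonal_to_plane_degenerates(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    proj = viz.proj_axis(canvas, canvas.ordination.loadings[:, 3])
    assert np.abs(proj.segment).max() < 1e-10


def test_zero_direction_rejected(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    with pytest.raises(ValueError, match="non-zero"):
        viz.proj_axis(canvas, np.zeros(8))


def test_allometric_axis_aligns_with_score_drift(rng):
    """Fitted allometric direction tracks size-ordered score centroids."""
    n, p = 120, 10
    size = rng.uniform(1.0, 3.0, n)
    v = rng.normal(size=p)
    v /= np.linalg.norm(v)
    X = 1.0 + 0.5 * np.outer(size, v) + rng.normal(scale=0.02, size=(n, p))
    sm = ShapeMatrix(X, kind="landmarks2d", k=5)
    ordn = pca(sm)
    canvas = viz.build_canvas(ordn)
    model = fit_shape_regression(sm, np.column_stack([np.ones(n), size]))
    proj = viz.proj_axis(canvas, model)
    seg = proj.segment[1] - proj.segment[0]
    # drift of score centroids between small and large thirds
    sc = ordn.scores[:, :2]
    order = np.argsort(size)
    drift = sc[order[-40:]].mean(0) - sc[order[:40]].mean(0)
    cos = abs(seg @ drift / np.linalg.norm(seg) / np.linalg.norm(drift))
    assert cos > 0.99


# ---------------------------------------------------------------------------
# phylogeny projection
# ---------------------------------------------------------------------------


def test_identical_tips_collapse_phylomorphospace(balanced_tree4, rng):
    shape = rng.normal(size=8)
    sm = ShapeMatrix(np.tile(shape, (4, 1)) +
                     rng.normal(scale=1e-4, size=(4, 8)),
                     kind="landmarks2d", k=4, ids=list("ABCD"))
    base = ShapeMatrix(rng.normal(size=(10, 8)), kind="landmarks2d", k=4)
    canvas = viz.build_canvas(pca(base))
    identical = ShapeMatrix(np.tile(shape, (4, 1)), kind="landmarks2d",
                            k=4, ids=list("ABCD"))
    ph = viz.proj_phylogeny(canvas, balanced_tree4, identical)
    all_scores = ph.all_scores
    assert np.abs(all_scores - all_scores[0]).max() < 1e-9


def test_projection_commutes_with_ancestral_estimation(random_tree5, rng):
    """Estimate-then-project equals project-then-estimate (both linear)."""
    sm = ShapeMatrix(rng.normal(size=(5, 6)), kind="landmarks2d", k=3,
                     ids=list(random_tree5.tip_labels))
    ordn = pca(sm)
    canvas = viz.build_canvas(ordn)
    ph = viz.proj_phylogeny(canvas, random_tree5, sm)
    # other order: project tips first, then BM-estimate in score space
    i, j = canvas.axes
    tip_scores = ordn.scores[:, [i, j]]
    node_scores, _ = anc_states_bm(random_tree5, tip_scores)
    assert np.abs(ph.node_scores - node_scores).max() < 1e-9


def test_star_tree_root_at_gls_mean(star_tree5, rng):
    sm = ShapeMatrix(rng.normal(size=(5, 6)), kind="landmarks2d", k=3,
                     ids=list(star_tree5.tip_labels))
    canvas = viz.build_canvas(pca(sm))
    ph = viz.proj_phylogeny(canvas, star_tree5, sm)
    # equal-branch star: GLS weights are uniform -> root at tip-score mean
    assert np.abs(ph.node_scores[0] - ph.tip_scores.mean(0)).max() < 1e-9


def test_phylo_label_mismatch_lists_labels(balanced_tree4, rng):
    sm = ShapeMatrix(rng.normal(size=(4, 6)), kind="landmarks2d", k=3,
                     ids=["A", "B", "C", "Z"])
    base = ShapeMatrix(rng.normal(size=(8, 6)), kind="landmarks2d", k=3)
    canvas = viz.build_canvas(pca(base))
    with pytest.raises(ValueError, match="Z"):
        viz.proj_phylogeny(canvas, balanced_tree4, sm)


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------


def test_constant_landscape_is_flat(canvas_and_shapes, rng):
    canvas, _ = canvas_and_shapes
    pos = rng.normal(size=(10, 2))
    land = viz.proj_landscape(canvas, pos, np.full(10, 3.3))
    assert np.abs(land.grid_values - 3.3).max() < 1e-8


def test_planar_field_reproduced_exactly(canvas_and_shapes, rng):
    canvas, _ = canvas_and_shapes
    pos = rng.normal(size=(12, 2))
    vals = 2 * pos[:, 0] + 3 * pos[:, 1]
    land = viz.proj_landscape(canvas, pos, vals)
    GX, GY = np.meshgrid(land.grid_x, land.grid_y)
    assert np.abs(land.grid_values - (2 * GX + 3 * GY)).max() < 1e-6


def test_landscape_exact_at_supports(canvas_and_shapes, rng):
    canvas, _ = canvas_and_shapes
    pos = rng.normal(size=(15, 2))
    vals = rng.normal(size=15)
    land = viz.proj_landscape(canvas, pos, vals)
    assert np.abs(land.predict(pos) - vals).max() < 1e-6


def test_collinear_supports_rejected(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    pos = np.column_stack([np.arange(6.0), np.arange(6.0)])
    with pytest.raises(ValueError, match="coverage"):
        viz.proj_landscape(canvas, pos, np.arange(6.0))


# ---------------------------------------------------------------------------
# Pareto fronts
# ---------------------------------------------------------------------------


def test_pareto_single_point():
    res = viz.pareto_front(np.array([[1.0, 2.0]]))
    assert list(res.front) == [0] and list(res.rank) == [1]


def test_pareto_mutually_nondominated_triple():
    res = viz.pareto_front(np.array([[1, 0], [0, 1], [0.5, 0.5]]), "max")
    assert sorted(res.front.tolist()) == [0, 1, 2]


def test_pareto_matches_bruteforce_oracle(rng):
    V = rng.normal(size=(50, 2))
    res = viz.pareto_front(V, "max")
    brute = [i for i in range(50)
             if not any(np.all(V[j] >= V[i]) and np.any(V[j] > V[i])
                        for j in range(50) if j != i)]
    assert sorted(res.front.tolist()) == sorted(brute)


def test_pareto_rank_partitions_points(rng):
    V = rng.normal(size=(40, 2))
    res = viz.pareto_front(V, ["max", "min"])
    assert res.rank.min() >= 1
    assert res.rank.size == 40
    assert set(res.front) == set(np.flatnonzero(res.rank == 1))
    opt = res.optimality()
    assert opt.max() == 1.0 and opt.min() > 0.0


def test_pareto_nan_rejected():
    with pytest.raises(ValueError, match="NaN"):
        viz.pareto_front(np.array([[1.0, np.nan]]))


# ---------------------------------------------------------------------------
# phenogram + hybrid
# ---------------------------------------------------------------------------


def test_phenogram_ultrametric_tip_times_equal(balanced_tree4, rng):
    data = viz.phenogram(balanced_tree4, rng.normal(size=4))
    tip_times = data.times[:4]
    assert np.abs(tip_times - tip_times[0]).max() < 1e-10


def test_phenogram_constant_values_flat(balanced_tree4):
    data = viz.phenogram(balanced_tree4, np.full(4, 1.7))
    assert np.abs(data.values - 1.7).max() < 1e-9


def test_phenogram_node_heights_match_traversal_oracle(random_tree5, rng):
    data = viz.phenogram(random_tree5, rng.normal(size=5))

    heights = {}

    def walk(node, h):
        heights[id(node)] = h
        for child in node.child_nodes():
            walk(child, h + child.edge.length)

    walk(random_tree5.tree.seed_node, 0.0)
    oracle = np.array(
        [heights[id(nd)] for nd in
         random_tree5.tip_nodes + random_tree5.internal_nodes])
    assert np.abs(data.times - oracle).max() < 1e-12


def test_hybrid_scatter_identity(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    scores = canvas.ordination.scores[:, 0]
    hv = viz.hybrid_view(canvas, scores, kind="scatter")
    assert np.array_equal(hv.axis_scores, hv.covariate)


def test_hybrid_box_medians(canvas_and_shapes, rng):
    canvas, _ = canvas_and_shapes
    labels = np.array(["u"] * 13 + ["v"] * 12)
    hv = viz.hybrid_view(canvas, labels, kind="box")
    scores = canvas.ordination.scores[:, 0]
    assert hv.summaries["u"]["median"] == pytest.approx(
        np.median(scores[:13]))
    assert hv.summaries["v"]["median"] == pytest.approx(
        np.median(scores[13:]))


def test_hybrid_margin_models_equal_extract_shapes(canvas_and_shapes):
    canvas, _ = canvas_and_shapes
    hv = viz.hybrid_view(canvas, canvas.ordination.scores[:, 0],
                         kind="scatter", axis_models=True, n_models=4)
    at = np.column_stack([hv.margin_positions, np.zeros(4)])
    oracle = viz.extract_shapes(canvas.ordination, at, axes=canvas.axes)
    assert np.abs(hv.margin_shapes - oracle).max() < 1e-12


def test_plotting_smoke(canvas_and_shapes, rng):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    canvas, sm = canvas_and_shapes
    sc = viz.proj_shapes(canvas, sm)
    groups = viz.proj_groups(canvas, sc, np.repeat(["a", "b"], [13, 12]),
                             style="ellipse")
    land = viz.proj_landscape(canvas, sc[:10], rng.normal(size=10))
    ax = viz.plot_layers(canvas, scatter=sc, groups=groups, landscape=land)
    assert ax is not None
    plt.close("all")
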