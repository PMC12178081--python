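"""The morphospace canvas and its layered projections.

A :class:`MorphospaceCanvas` is a pair of ordination axes with a grid of
regularly spaced background shape models computed by inverse-mapping grid
scores back to shape space (non-plotted axes held at zero, so the models
visualise the plotted plane's variation only).  Onto this canvas a family of
``proj_*`` functions layers empirical or theoretical elements:

* scatter points for any compatible shapes (:func:`proj_shapes`);
* convex hulls or confidence ellipses per group (:func:`proj_groups`);
* morphometric axes/vectors (:func:`proj_axis`);
* phylomorphospaces — trees with BM ancestral shapes at the internal nodes
  (:func:`proj_phylogeny`);
* performance landscapes interpolated over the plane
  (:func:`proj_landscape`) and Pareto fronts/optimality ranks for metrics
  in trade-off (:func:`pareto_front`).

Every projection obeys the single affine contract
``scores = (x - center) @ loadings`` and never mutates the canvas's
ordination.  Hybrid views pair one shape axis with a non-shape variable
(:func:`hybrid_view`) and :func:`phenogram` plots an axis against time along
a phylogeny.  Plotting helpers render to matplotlib, but every overlay is a
plain data structure exportable without the plotting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import ConvexHull
from scipy.stats import chi2

from .geometry import (TPSMap, as_shape_matrix, efa_reconstruct,
                       tps_fit, tps_warp)
from .ordination import Ordination, Phylogeny, anc_states_bm
from .refinement import LinearShapeModel

__all__ = [
    "MorphospaceCanvas",
    "Landscape",
    "ParetoResult",
    "GroupOverlay",
    "AxisProjection",
    "PhyloProjection",
    "PhenogramData",
    "HybridView",
    "build_canvas",
    "extract_shapes",
    "proj_shapes",
    "proj_groups",
    "proj_axis",
    "proj_phylogeny",
    "proj_landscape",
    "pareto_front",
    "phenogram",
    "hybrid_view",
    "plot_canvas",
]


# ---------------------------------------------------------------------------
# canvas
# ---------------------------------------------------------------------------


@dataclass
class MorphospaceCanvas:
    """An axis pair of an ordination with background shape models."""

    ordination: Ordination
    axes: tuple
    xlim: tuple
    ylim: tuple
    grid_scores: np.ndarray        # (r*c, 2) background positions
    grid_shapes: np.ndarray        # (r*c, p) background shapes
    grid_dims: tuple               # (r, c)
    padding: float
    wireframe: Optional[Sequence] = None     # landmark index pairs
    template: Optional[np.ndarray] = None    # (t, m) polyline through shape space
    point_size: float = 12.0

    @property
    def shape_meta(self) -> dict:
        return self.ordination.extras.get("shape_meta",
                                          {"kind": "landmarks2d", "k": None,
                                           "m": 2, "h": None})


def build_canvas(ordination: Ordination, axes=(0, 1), grid=(6, 5),
                 padding: float = 0.05, wireframe=None, template=None,
                 point_size: float = 12.0) -> MorphospaceCanvas:
    """Build a morphospace canvas over a pair of ordination axes.

    ``grid=(r, c)`` deploys r columns by c rows of background shape models,
    evenly spaced over the plotted score range extended by ``padding`` on
    each side; each model is ``center + s_i v_i + s_j v_j``.
    """
    i, j = axes
    if i == j:
        raise ValueError("the two canvas axes must differ")
    if not (0 <= i < ordination.n_axes and 0 <= j < ordination.n_axes):
        raise ValueError(f"axes {axes} out of range for an ordination with "
                         f"{ordination.n_axes} axes")
    r, c = grid
    sx = ordination.scores[:, i]
    sy = ordination.scores[:, j]
    span_x = sx.max() - sx.min()
    span_y = sy.max() - sy.min()
    xlim = (sx.min() - padding * span_x, sx.max() + padding * span_x)
    ylim = (sy.min() - padding * span_y, sy.max() + padding * span_y)
    gx = np.linspace(*xlim, r)
    gy = np.linspace(*ylim, c)
    GX, GY = np.meshgrid(gx, gy)
    grid_scores = np.column_stack([GX.ravel(), GY.ravel()])
    grid_shapes = extract_shapes(ordination, grid_scores, axes=axes)
    return MorphospaceCanvas(ordination=ordination, axes=(i, j), xlim=xlim,
                             ylim=ylim, grid_scores=grid_scores,
                             grid_shapes=grid_shapes, grid_dims=(r, c),
                             padding=padding, wireframe=wireframe,
                             template=template, point_size=point_size)


def extract_shapes(ordination: Ordination, at: np.ndarray,
                   axes=(0, 1)) -> np.ndarray:
    """Theoretical shapes at arbitrary score positions on an axis pair.

    ``at`` is (q, 2); the returned (q, p) shapes are
    ``center + at[:, 0] v_i + at[:, 1] v_j`` (all other axes at zero).
    """
    at = np.atleast_2d(np.asarray(at, dtype=float))
    if at.shape[1] != 2:
        raise ValueError("positions must be (q, 2) scores on the axis pair")
    return ordination.inverse(at, axes=list(axes))


def proj_shapes(canvas: MorphospaceCanvas, shapes,
                full: bool = False) -> np.ndarray:
    """Project compatible shapes as scatter points into the canvas.

    Returns the (n, 2) scores on the canvas's axis pair (or the full (n, q)
    score matrix with ``full=True``).  Shapes need not have been part of
    the ordination, but must share its variables (same landmarks or the
    same number of harmonics).
    """
    if isinstance(shapes, np.ndarray) and shapes.ndim <= 2:
        X = np.atleast_2d(np.asarray(shapes, dtype=float))
    else:
        X = as_shape_matrix(shapes).X
    scores = canvas.ordination.project(X)
    if full:
        return scores
    i, j = canvas.axes
    return scores[:, [i, j]]


# ---------------------------------------------------------------------------
# groups
# ---------------------------------------------------------------------------


@dataclass
class GroupOverlay:
    """Hull vertices or ellipse parameters for one group of scores."""

    label: object
    style: str                       # "hull" | "ellipse"
    vertices: np.ndarray             # polygon vertices (closed not required)
    center: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None
    radius2: Optional[float] = None  # squared Mahalanobis radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Ellipse membership test (Mahalanobis distance within radius)."""
        if self.style != "ellipse":
            raise ValueError("containment test is defined for ellipses")
        d = np.atleast_2d(points) - self.center
        sol = np.linalg.solve(self.cov, d.T)
        return np.einsum("ij,ji->i", d, sol) <= self.radius2


def _ellipse_polygon(center, cov, radius2, n=100):
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, 0.0)
    t = np.linspace(0, 2 * np.pi, n)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    return center + circle * np.sqrt(vals * radius2) @ vecs.T


def proj_groups(canvas: MorphospaceCanvas, scores: np.ndarray,
                labels: Sequence, style: str = "hull", level: float = 0.95,
                mean_ellipse: bool = False) -> dict:
    """Convex hulls or confidence ellipses per group of (n, 2) scores.

    Ellipses are data ellipses of the group's score covariance at the
    chi-squared(2) quantile of ``level``; with ``mean_ellipse`` the
    covariance is divided by the group size, giving a confidence region for
    the group mean instead.  Degenerate groups are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have the same length")
    if style not in ("hull", "ellipse"):
        raise ValueError("style must be 'hull' or 'ellipse'")
    out = {}
    for lev in dict.fromkeys(labels.tolist()):
        pts = scores[labels == lev]
        if style == "hull":
            if pts.shape[0] < 3 or \
                    np.linalg.matrix_rank(pts - pts.mean(0), tol=1e-12) < 2:
                warnings.warn(f"group {lev!r} is degenerate (needs >= 3 "
                              "non-collinear points); skipped", stacklevel=2)
                continue
            hull = ConvexHull(pts)
            out[lev] = GroupOverlay(label=lev, style="hull",
                                    vertices=pts[hull.vertices])
        else:
            if pts.shape[0] < 3:
                warnings.warn(f"group {lev!r} has fewer than 3 points; "
                              "skipped", stacklevel=2)
                continue
            center = pts.mean(axis=0)
            cov = np.cov(pts, rowvar=False)
            if mean_ellipse:
                cov = cov / pts.shape[0]
            r2 = float(chi2.ppf(level, df=2))
            out[lev] = GroupOverlay(label=lev, style="ellipse",
                                    vertices=_ellipse_polygon(center, cov, r2),
                                    center=center, cov=cov, radius2=r2)
    return out


# ---------------------------------------------------------------------------
# axes / vectors
# ---------------------------------------------------------------------------


@dataclass
class AxisProjection:
    segment: np.ndarray          # (2, 2) endpoints in the score plane
    endpoint_shapes: np.ndarray  # (2, p)
    direction: np.ndarray        # unit p-vector


def proj_axis(canvas: MorphospaceCanvas,
              direction: Union[np.ndarray, LinearShapeModel],
              extent: float = 1.0) -> AxisProjection:
    """Project a morphometric axis (a shape-space direction) onto the canvas.

    ``direction`` is a p-vector, or a fitted shape regression with a single
    non-intercept term (its slope row is used — e.g. an allometric axis).
    The shape-space segment mean ± extent*direction is projected onto the
    plotted plane; the endpoint shapes are returned for display.
    """
    if isinstance(direction, LinearShapeModel):
        if direction.d != 2:
            raise ValueError("pass the p-vector explicitly for models with "
                             "more than one non-intercept term")
        direction = direction.coefficients[1]
    v = np.asarray(direction, dtype=float).ravel()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("axis direction must be a non-zero vector")
    if v.size != canvas.ordination.p:
        raise ValueError(f"direction must have length {canvas.ordination.p}")
    v = v / nrm
    center = canvas.ordination.center
    ends = np.vstack([center - extent * v, center + extent * v])
    seg = proj_shapes(canvas, ends)
    return AxisProjection(segment=seg, endpoint_shapes=ends, direction=v)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PhyloProjection:
    """A phylomorphospace: tip and ancestral-node scores plus tree edges."""

    tip_scores: np.ndarray           # (s, 2)
    node_scores: np.ndarray          # (n_internal, 2)
    tip_labels: Sequence[str]
    node_labels: Sequence[str]
    edges: Sequence[tuple]           # (parent, child) indices into all_scores
    node_shapes: np.ndarray          # (n_internal, p) ancestral shapes

    @property
    def all_scores(self) -> np.ndarray:
        """Tips first, internal nodes after — edge indices refer to this."""
        return np.vstack([self.tip_scores, self.node_scores])


def proj_phylogeny(canvas: MorphospaceCanvas, tree: Phylogeny,
                   tip_shapes) -> PhyloProjection:
    """Project a phylogeny into morphospace.

    Ancestral shapes are estimated at the internal nodes by maximum-
    likelihood Brownian motion in the full shape space and then projected
    with the same affine contract as any other shape; edges connect
    parent-child score pairs.
    """
    sm = as_shape_matrix(tip_shapes)
    ids = list(sm.ids)
    missing = [t for t in tree.tip_labels if t not in ids]
    extra = [i for i in ids if i not in tree.tip_labels]
    if missing or extra:
        raise ValueError(f"tip/shape label mismatch; tips without shapes: "
                         f"{missing}; shapes without tips: {extra}")
    X = sm.X[[ids.index(t) for t in tree.tip_labels]]
    node_shapes, node_labels = anc_states_bm(tree, X)
    tip_scores = proj_shapes(canvas, X)
    node_scores = proj_shapes(canvas, node_shapes)
    index = {}
    for ti, nd in enumerate(tree.tip_nodes):
        index[id(nd)] = ti
    for vi, nd in enumerate(tree.internal_nodes):
        index[id(nd)] = tree.n_tips + vi
    edges = []
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is not None:
            edges.append((index[id(nd.parent_node)], index[id(nd)]))
    return PhyloProjection(tip_scores=tip_scores, node_scores=node_scores,
                           tip_labels=list(tree.tip_labels),
                           node_labels=node_labels, edges=edges,
                           node_shapes=node_shapes)


# ---------------------------------------------------------------------------
# landscapes & Pareto fronts
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """An interpolated performance surface over the canvas plane."""

    positions: np.ndarray            # (q, 2) support scores
    values: np.ndarray               # (q,) performance at supports
    grid_x: np.ndarray               # (G,)
    grid_y: np.ndarray               # (G,)
    grid_values: np.ndarray          # (G, G), row = y index
    mode: str                        # "empirical" | "theoretical"
    interpolator: str                # "tps" | "idw"
    _tps: Optional[TPSMap] = field(default=None, repr=False)

    def predict(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._tps is not None:
            return tps_warp(self._tps, points).ravel()
        return _idw(self.positions, self.values, points)


def _idw(supports, values, points, power=2.0, eps=1e-12):
    d = np.linalg.norm(points[:, None, :] - supports[None, :, :], axis=2)
    w = 1.0 / np.maximum(d, eps) ** power
    exact = d < eps
    out = (w * values).sum(axis=1) / w.sum(axis=1)
    hit = exact.any(axis=1)
    if hit.any():
        out[hit] = values[exact.argmax(axis=1)[hit]]
    return out


def proj_landscape(canvas: MorphospaceCanvas, positions: np.ndarray,
                   values: np.ndarray, mode: str = "empirical",
                   interpolator: str = "tps",
                   grid_size: int = 30) -> Landscape:
    """Interpolate a performance surface over the canvas plane.

    ``positions`` are (q, 2) scores (empirical specimens, or the canvas's
    own background-model grid for a theoretical landscape) with a measured
    performance value each.  A 2D thin-plate spline interpolates exactly at
    the supports and reproduces affine (planar) performance fields; an
    inverse-distance-weighting fallback handles near-singular supports.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if positions.shape[0] != values.size:
        raise ValueError("positions and values must have the same length")
    if mode not in ("empirical", "theoretical"):
        raise ValueError("mode must be 'empirical' or 'theoretical'")
    if positions.shape[0] < 4:
        raise ValueError("need at least 4 support positions")
    if np.linalg.matrix_rank(positions - positions.mean(0), tol=1e-10) < 2:
        raise ValueError("support positions are collinear; a landscape "
                         "needs broader coverage of the plane")
    tps = None
    used = interpolator
    if interpolator == "tps":
        try:
            tps = tps_fit(positions, values[:, None])
        except (np.linalg.LinAlgError, ValueError) as err:
            warnings.warn(f"TPS interpolation failed ({err}); falling back "
                          "to inverse-distance weighting", stacklevel=2)
            used = "idw"
    elif interpolator != "idw":
        raise ValueError("interpolator must be 'tps' or 'idw'")
    gx = np.linspace(*canvas.xlim, grid_size)
    gy = np.linspace(*canvas.ylim, grid_size)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    land = Landscape(positions=positions, values=values, grid_x=gx, grid_y=gy,
                     grid_values=np.empty((grid_size, grid_size)), mode=mode,
                     interpolator=used, _tps=tps)
    land.grid_values = land.predict(pts).reshape(grid_size, grid_size)
    return land


@dataclass
class ParetoResult:
    """Pareto front and iterative peel ranks for points under trade-off."""

    front: np.ndarray                # indices of non-dominated points
    rank: np.ndarray                 # (q,) peel rank, 1 = front
    orientation: Sequence[str]

    def optimality(self) -> np.ndarray:
        """Normalised optimality in (0, 1]: 1 - (rank-1)/max_rank."""
        return 1.0 - (self.rank - 1) / self.rank.max()


def _dominates(a, b):
    """True if a dominates b (all >=, at least one >) after orientation."""
    return np.all(a >= b) and np.any(a > b)


def pareto_front(values: np.ndarray,
                 orientation: Union[str, Sequence[str]] = "max"
                 ) -> ParetoResult:
    """Non-dominated set and peel ranks for q points by r metrics.

    ``orientation`` gives, per metric, whether larger ("max") or smaller
    ("min") is better; a single string applies to all metrics.  Ranks come
    from iterative front peeling: rank 1 is the front, rank 2 the front of
    the remainder, and so on.
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    if np.isnan(V).any():
        raise ValueError("performance values contain NaN")
    q, r = V.shape
    if isinstance(orientation, str):
        orientation = [orientation] * r
    if len(orientation) != r:
        raise ValueError("one orientation per metric is required")
    sign = np.array([1.0 if o == "max" else -1.0 for o in orientation])
    if not all(o in ("max", "min") for o in orientation):
        raise ValueError("orientation entries must be 'max' or 'min'")
    W = V * sign
    rank = np.zeros(q, dtype=int)
    remaining = np.arange(q)
    level = 0
    while remaining.size:
        level += 1
        sub = W[remaining]
        nd = []
        for ii in range(remaining.size):
            if not any(_dominates(sub[jj], sub[ii])
                       for jj in range(remaining.size) if jj != ii):
                nd.append(ii)
        idx = remaining[nd]
        rank[idx] = level
        remaining = np.setdiff1d(remaining, idx)
    return ParetoResult(front=np.flatnonzero(rank == 1), rank=rank,
                        orientation=list(orientation))


# ---------------------------------------------------------------------------
# phenograms & hybrid views
# ---------------------------------------------------------------------------


@dataclass
class PhenogramData:
    """Time (node height) and axis value per node, plus tree edges."""

    times: np.ndarray
    values: np.ndarray
    labels: Sequence[str]
    edges: Sequence[tuple]
    n_tips: int


def phenogram(tree: Phylogeny, tip_values: np.ndarray,
              node_values: Optional[np.ndarray] = None) -> PhenogramData:
    """Evolution of one ordination axis through time along a phylogeny.

    x is the node height (root-to-node path length, time units), y the axis
    value; internal-node values default to BM ancestral estimates.  Parent
    and child are joined by straight segments.
    """
    tip_values = np.asarray(tip_values, dtype=float).ravel()
    if tip_values.size != tree.n_tips:
        raise ValueError("one tip value per tree tip is required")
    if node_values is None:
        nv, _ = anc_states_bm(tree, tip_values[:, None])
        node_values = nv.ravel()
    node_values = np.asarray(node_values, dtype=float).ravel()
    times = np.array([tree.depth(nd) for nd in tree.tip_nodes] +
                     [tree.depth(nd) for nd in tree.internal_nodes])
    values = np.concatenate([tip_values, node_values])
    labels = list(tree.tip_labels) + list(tree.node_labels)
    index = {id(nd): i for i, nd in
             enumerate(tree.tip_nodes + tree.internal_nodes)}
    edges = [(index[id(nd.parent_node)], index[id(nd)])
             for nd in tree.tree.preorder_node_iter()
             if nd.parent_node is not None]
    return PhenogramData(times=times, values=values, labels=labels,
                         edges=edges, n_tips=tree.n_tips)


@dataclass
class HybridView:
    """One shape axis paired with a non-shape variable."""

    kind: str                        # "scatter" | "box" | "violin"
    axis_scores: np.ndarray
    covariate: np.ndarray
    levels: Optional[Sequence] = None
    summaries: Optional[dict] = None     # per-level five-number summaries
    margin_shapes: Optional[np.ndarray] = None
    margin_positions: Optional[np.ndarray] = None


def hybrid_view(canvas: MorphospaceCanvas, covariate: Sequence,
                axis: Optional[int] = None, kind: str = "scatter",
                axis_models: bool = False, n_models: int = 5) -> HybridView:
    """Pair an ordination axis with an external variable.

    ``scatter`` pairs a continuous covariate with the axis scores; ``box``
    and ``violin`` summarise the scores within each level of a categorical
    covariate.  With ``axis_models`` the margin carries background shape
    models along the shape axis (the other canvas axis held at zero),
    identical to :func:`extract_shapes` along that single axis.
    """
    i, j = canvas.axes
    if axis is None:
        axis = i
    scores = canvas.ordination.scores[:, axis]
    covariate = np.asarray(covariate)
    if covariate.shape[0] != scores.shape[0]:
        raise ValueError("covariate length must match the number of "
                         "ordinated shapes")
    if kind not in ("scatter", "box", "violin"):
        raise ValueError("kind must be 'scatter', 'box' or 'violin'")
    levels = None
    summaries = None
    if kind in ("box", "violin"):
        levels = list(dict.fromkeys(covariate.tolist()))
        summaries = {}
        for lev in levels:
            vals = scores[covariate == lev]
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summaries[lev] = {"median": med, "q1": q1, "q3": q3,
                              "min": vals.min(), "max": vals.max(),
                              "n": int(vals.size), "values": vals}
    margin_shapes = margin_positions = None
    if axis_models:
        other = j if axis == i else i
        lo, hi = scores.min(), scores.max()
        s = np.linspace(lo, hi, n_models)
        at = np.column_stack([s, np.zeros(n_models)])
        margin_shapes = extract_shapes(canvas.ordination, at,
                                       axes=(axis, other))
        margin_positions = s
    return HybridView(kind=kind, axis_scores=scores, covariate=covariate,
                      levels=levels, summaries=summaries,
                      margin_shapes=margin_shapes,
                      margin_positions=margin_positions)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _draw_shape(ax, shape_row: np.ndarray, meta: dict, at: np.ndarray,
                scale: float, canvas: MorphospaceCanvas, color="0.65"):
    """Draw one background model centered at ``at`` in score units."""
    if meta["kind"] == "fourier":
        coeffs = shape_row.reshape(meta["h"], 4)
        poly = efa_reconstruct(coeffs, 120)
        poly = poly - poly.mean(axis=0)
        span = np.abs(poly).max() or 1.0
        poly = poly / span * scale + at
        ax.fill(poly[:, 0], poly[:, 1], color=color, lw=0.5, alpha=0.6)
        return
    k, m = meta["k"], meta["m"]
    pts = shape_row.reshape(k, m)[:, :2]
    ctr = pts - pts.mean(axis=0)
    span = np.abs(ctr).max() or 1.0
    pts2 = ctr / span * scale + at
    if canvas.template is not None:
        consensus = canvas.ordination.center.reshape(k, m)
        tmap = tps_fit(consensus, shape_row.reshape(k, m))
        curve = tps_warp(tmap, np.asarray(canvas.template, dtype=float))[:, :2]
        curve = (curve - curve.mean(axis=0)) / span * scale + at
        ax.plot(curve[:, 0], curve[:, 1], color=color, lw=0.8)
    ax.scatter(pts2[:, 0], pts2[:, 1], s=4, color=color, zorder=3)
    if canvas.wireframe is not None:
        for a, b in canvas.wireframe:
            ax.plot(pts2[[a, b], 0], pts2[[a, b], 1], color=color, lw=0.8)


def plot_canvas(canvas: MorphospaceCanvas, ax=None, model_color="0.7"):
    """Render the canvas: empty axis pair with background shape models."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    meta = canvas.shape_meta
    r, c = canvas.grid_dims
    cell = min((canvas.xlim[1] - canvas.xlim[0]) / max(r, 1),
               (canvas.ylim[1] - canvas.ylim[0]) / max(c, 1))
    for pos, row in zip(canvas.grid_scores, canvas.grid_shapes):
        _draw_shape(ax, row, meta, pos, 0.35 * cell, canvas,
                    color=model_color)
    i, j = canvas.axes
    ax.set_xlim(*canvas.xlim)
    ax.set_ylim(*canvas.ylim)
    ax.set_xlabel(f"axis {i + 1}")
    ax.set_ylabel(f"axis {j + 1}")
    return ax


def plot_layers(canvas: MorphospaceCanvas, ax=None, scatter=None,
                scatter_labels=None, groups=None, landscape=None,
                phylo=None, axis_proj=None):
    """Render projection layers on top of a canvas."""
    import matplotlib.pyplot as plt

    ax = plot_canvas(canvas, ax=ax)
    if landscape is not None:
        ax.contourf(landscape.grid_x, landscape.grid_y,
                    landscape.grid_values, levels=12, cmap="viridis",
                    alpha=0.35, zorder=0)
    if groups:
        for ov in groups.values():
            ax.fill(ov.vertices[:, 0], ov.vertices[:, 1], alpha=0.2)
    if scatter is not None:
        if scatter_labels is not None:
            labs = np.asarray(scatter_labels)
            for lev in dict.fromkeys(labs.tolist()):
                pts = scatter[labs == lev]
                ax.scatter(pts[:, 0], pts[:, 1], s=canvas.point_size,
                           label=str(lev))
            ax.legend(fontsize=7)
        else:
            ax.scatter(scatter[:, 0], scatter[:, 1], s=canvas.point_size)
    if phylo is not None:
        allsc = phylo.all_scores
        for a, b in phylo.edges:
            ax.plot(allsc[[a, b], 0], allsc[[a, b], 1], color="k", lw=0.7)
        ax.scatter(phylo.node_scores[:, 0], phylo.node_scores[:, 1],
                   color="k", s=8, zorder=4)
    if axis_proj is not None:
        ax.plot(axis_proj.segment[:, 0], axis_proj.segment[:, 1],
                color="crimson", lw=1.5)
    return ax


def plot_phenogram(data: PhenogramData, ax=None):
    """Render a phenogram (time vs. axis value, straight edges)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for a, b in data.edges:
        ax.plot(data.times[[a, b]], data.values[[a, b]], color="0.3", lw=0.9)
    ax.scatter(data.times[:data.n_tips], data.values[:data.n_tips], zorder=3)
    ax.set_xlabel("time")
    ax.set_ylabel("axis score")
    return ax
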