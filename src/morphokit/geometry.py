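"""Geometric substrate for shape analysis.

This module holds the shape containers and the three geometric engines the
rest of the package is built on:

* generalized Procrustes analysis (GPA) — removal of position, scale and
  orientation differences from landmark configurations;
* thin-plate spline (TPS) interpolation — the minimal-bending-energy map
  between two landmark sets, used to warp templates and deformation grids;
* elliptic Fourier analysis (EFA) — the decomposition of a closed 2D outline
  into per-harmonic coefficient quadruples (a, b, c, d), and its inverse.

All landmark arrays are ``(k, m)`` with ``m`` in {2, 3}; sets of
configurations are ``(n, k, m)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LandmarkSet",
    "OutlineCoefficients",
    "ShapeMatrix",
    "TPSMap",
    "centroid_size",
    "procrustes_align",
    "procrustes_distance",
    "tps_fit",
    "tps_warp",
    "efa_decompose",
    "efa_reconstruct",
]

_DEGENERATE_TOL = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """A set of landmark configurations sharing landmarks and dimension.

    Parameters
    ----------
    coords
        ``(n, k, m)`` array of coordinates, ``m`` in {2, 3}.  Raw units
        before alignment, dimensionless after.
    ids
        ``n`` specimen labels.
    """

    coords: np.ndarray
    ids: Sequence[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be an (n, k, m) array")
        if self.coords.shape[2] not in (2, 3):
            raise ValueError("landmark dimension m must be 2 or 3")
        if np.isnan(self.coords).any():
            raise ValueError("landmark coordinates contain NaN")
        self.ids = list(self.ids)
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("number of ids does not match number of configurations")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def dim(self) -> int:
        return self.coords.shape[2]

    def to_matrix(self) -> "ShapeMatrix":
        """Flatten to an ``(n, k*m)`` shape matrix (landmark-major order)."""
        n, k, m = self.coords.shape
        kind = "landmarks2d" if m == 2 else "landmarks3d"
        return ShapeMatrix(self.coords.reshape(n, k * m), kind=kind, k=k, m=m,
                           ids=self.ids)


@dataclass
class OutlineCoefficients:
    """Elliptic Fourier coefficients for a set of closed outlines.

    ``coeffs`` is ``(n, h, 4)`` with the per-harmonic quadruple
    ``(a_j, b_j, c_j, d_j)``; ``offset`` optionally stores the per-specimen
    center terms ``(A0, C0)``.
    """

    coeffs: np.ndarray
    offset: Optional[np.ndarray] = None
    ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[2] != 4:
            raise ValueError("coeffs must be an (n, h, 4) array")
        if self.coeffs.shape[1] < 1:
            raise ValueError("need at least one harmonic")
        if self.offset is not None:
            self.offset = np.asarray(self.offset, dtype=float).reshape(
                self.coeffs.shape[0], 2)
        if self.ids is None:
            self.ids = [f"outline{i}" for i in range(self.coeffs.shape[0])]
        self.ids = list(self.ids)

    @property
    def n_specimens(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[1]

    def to_matrix(self) -> "ShapeMatrix":
        """Flatten to ``(n, 4h)``, harmonic-major (a1,b1,c1,d1,a2,...)."""
        n, h, _ = self.coeffs.shape
        return ShapeMatrix(self.coeffs.reshape(n, 4 * h), kind="fourier", h=h,
                           ids=self.ids)


@dataclass
class ShapeMatrix:
    """Flattened ``(n, p)`` shape variables — the common currency of all
    ordinations.

    ``kind`` records how rows un-flatten: ``landmarks2d``/``landmarks3d``
    rows are landmark-major, coordinate-minor (x1, y1[, z1], x2, ...);
    ``fourier`` rows are harmonic-major (a1, b1, c1, d1, a2, ...).  ``mean``
    stores the column means at construction time and acts as the matrix's
    center.
    """

    X: np.ndarray
    kind: str
    k: Optional[int] = None
    m: Optional[int] = None
    h: Optional[int] = None
    ids: Optional[Sequence[str]] = None
    mean: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2D (n, p) matrix")
        if self.kind not in ("landmarks2d", "landmarks3d", "fourier"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        p = self.X.shape[1]
        if self.kind == "fourier":
            if self.h is None:
                if p % 4:
                    raise ValueError("fourier shape matrix width must be 4h")
                self.h = p // 4
            elif 4 * self.h != p:
                raise ValueError("column count inconsistent with h harmonics")
        else:
            m = 2 if self.kind == "landmarks2d" else 3
            if self.m is None:
                self.m = m
            elif self.m != m:
                raise ValueError("m inconsistent with kind tag")
            if self.k is None:
                if p % m:
                    raise ValueError("landmark shape matrix width must be k*m")
                self.k = p // m
            elif self.k * self.m != p:
                raise ValueError("column count inconsistent with k landmarks")
        if self.ids is None:
            self.ids = [f"obs{i}" for i in range(self.X.shape[0])]
        self.ids = list(self.ids)
        if self.mean is None:
            self.mean = self.X.mean(axis=0)
        else:
            self.mean = np.asarray(self.mean, dtype=float)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def unflatten_row(self, row: np.ndarray) -> np.ndarray:
        """Un-flatten one p-vector to its native representation.

        Returns ``(k, m)`` landmarks, or ``(h, 4)`` Fourier coefficients.
        """
        row = np.asarray(row, dtype=float).ravel()
        if row.size != self.p:
            raise ValueError(f"expected a length-{self.p} row")
        if self.kind == "fourier":
            return row.reshape(self.h, 4)
        return row.reshape(self.k, self.m)

    def to_landmarks(self) -> LandmarkSet:
        if self.kind == "fourier":
            raise ValueError("fourier shape matrix cannot unflatten to landmarks")
        return LandmarkSet(self.X.reshape(self.n, self.k, self.m), ids=self.ids)

    def to_coeffs(self) -> OutlineCoefficients:
        if self.kind != "fourier":
            raise ValueError("landmark shape matrix cannot unflatten to coefficients")
        return OutlineCoefficients(self.X.reshape(self.n, self.h, 4), ids=self.ids)

    def with_data(self, X: np.ndarray) -> "ShapeMatrix":
        """New ShapeMatrix with the same un-flattening metadata."""
        return ShapeMatrix(np.asarray(X, dtype=float), kind=self.kind, k=self.k,
                           m=self.m, h=self.h, ids=self.ids)


def as_shape_matrix(shapes) -> ShapeMatrix:
    """Coerce a LandmarkSet / OutlineCoefficients / ShapeMatrix to a matrix."""
    if isinstance(shapes, ShapeMatrix):
        return shapes
    if isinstance(shapes, LandmarkSet):
        return shapes.to_matrix()
    if isinstance(shapes, OutlineCoefficients):
        return shapes.to_matrix()
    raise TypeError(f"cannot interpret {type(shapes).__name__} as shape data")


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared distances to the centroid."""
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 1:
        raise ValueError("config must be a (k, m) array with k >= 1")
    dev = config - config.mean(axis=0)
    cs = float(np.sqrt((dev ** 2).sum()))
    if cs <= _DEGENERATE_TOL:
        raise ValueError("degenerate configuration: all landmarks coincide "
                         "(centroid size 0)")
    return cs


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||A @ R - B||_F for centered A, B."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    m = A.shape[1]
    D = np.eye(m)
    D[-1, -1] = d if d != 0 else 1.0
    return U @ D @ Vt


def _center_and_scale(config: np.ndarray, label: str = "") -> np.ndarray:
    dev = config - config.mean(axis=0)
    cs = float(np.sqrt((dev ** 2).sum()))
    if cs <= _DEGENERATE_TOL:
        name = f" {label!r}" if label else ""
        raise ValueError(f"degenerate configuration{name}: centroid size 0")
    return dev / cs


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, then optimally
    rotated (reflections forbidden); the distance is the root summed squared
    difference after superimposition.
    """
    za = _center_and_scale(np.asarray(a, dtype=float))
    zb = _center_and_scale(np.asarray(b, dtype=float))
    R = _optimal_rotation(za, zb)
    return float(np.linalg.norm(za @ R - zb))


def procrustes_align(raw: LandmarkSet, tol: float = 1e-10,
                     max_iter: int = 100, return_history: bool = False):
    """Generalized Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size (full
    Procrustes) and rotated onto an iteratively updated consensus.  The
    consensus is initialised with the first specimen and iterated until its
    change drops below ``tol`` (or ``max_iter`` iterations).  Reflections
    are forbidden in the rotation step.

    Returns
    -------
    (aligned, consensus) — or (aligned, consensus, history) when
    ``return_history`` is set, where history holds the per-iteration sum of
    squared distances of the aligned shapes to the consensus.
    """
    if raw.n_specimens < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if raw.n_landmarks < 3:
        raise ValueError("GPA needs at least 3 landmarks")
    Z = np.array([_center_and_scale(cfg, label)
                  for cfg, label in zip(raw.coords, raw.ids)])
    consensus = Z[0].copy()
    history = []
    for _ in range(max_iter):
        aligned = np.array([cfg @ _optimal_rotation(cfg, consensus) for cfg in Z])
        history.append(float(((aligned - consensus) ** 2).sum()))
        new = aligned.mean(axis=0)
        new = _center_and_scale(new)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new
    aligned = np.array([cfg @ _optimal_rotation(cfg, consensus) for cfg in Z])
    out = LandmarkSet(aligned, ids=raw.ids)
    if return_history:
        return out, consensus, history
    return out, consensus


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------


def _tps_kernel(r: np.ndarray, m: int) -> np.ndarray:
    """Radial kernel: r^2 log r^2 in 2D (U(0)=0), r in 3D."""
    if m == 2:
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz] ** 2)
        return out
    return r


@dataclass
class TPSMap:
    """A fitted thin-plate spline map between two landmark sets.

    ``weights`` holds the k non-affine coefficients per output dimension,
    ``affine`` the ``(m+1, d)`` affine part (first row is the intercept).
    The map interpolates exactly: evaluating at ``source[i]`` returns
    ``target[i]``.
    """

    source: np.ndarray
    target: np.ndarray
    weights: np.ndarray
    affine: np.ndarray

    @property
    def dim(self) -> int:
        return self.source.shape[1]

    def __call__(self, query: np.ndarray) -> np.ndarray:
        return tps_warp(self, query)

    def bending_energy(self) -> float:
        """Non-negative bending energy; 0 iff the map is affine."""
        K = _tps_kernel(cdist(self.source, self.source), self.dim)
        q = float(np.trace(self.weights.T @ K @ self.weights))
        # sign convention: the 3D kernel U(r)=r is conditionally negative
        # definite on the constraint subspace, the 2D one positive.
        if self.dim == 3:
            q = -q
        return max(q, 0.0)


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSMap:
    """Fit a thin-plate spline mapping ``source`` landmarks onto ``target``.

    ``source`` is ``(k, m)`` with m in {2, 3}; ``target`` is ``(k, d)`` for
    any d >= 1 (d = m for shape warps; d = 1 for scalar fields such as
    performance landscapes).  Solves the standard bordered linear system
    with kernel ``r^2 log r^2`` (2D) or ``r`` (3D).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.ndim != 2 or source.shape[1] not in (2, 3):
        raise ValueError("source must be (k, m) with m in {2, 3}")
    if target.ndim == 1:
        target = target[:, None]
    k, m = source.shape
    if target.shape[0] != k:
        raise ValueError("source and target must have the same number of points")
    if k <= m + 1:
        raise ValueError(f"need more than {m + 1} landmarks for an {m}D TPS")
    D = cdist(source, source)
    dup = np.argwhere((D < 1e-12) & ~np.eye(k, dtype=bool))
    if dup.size:
        pairs = sorted({tuple(sorted(p)) for p in dup})
        raise ValueError(f"repeated source landmarks (singular system): {pairs}")
    if np.linalg.matrix_rank(source - source.mean(axis=0), tol=1e-10) < m:
        kind = "collinear" if m == 2 else "coplanar"
        raise ValueError(f"source landmarks are {kind}; TPS system is singular")
    K = _tps_kernel(D, m)
    P = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + m + 1, k + m + 1))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.vstack([target, np.zeros((m + 1, target.shape[1]))])
    sol = np.linalg.solve(L, rhs)
    return TPSMap(source=source, target=target, weights=sol[:k], affine=sol[k:])


def tps_warp(tps: TPSMap, query: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS map at ``(q, m)`` query points."""
    query = np.asarray(query, dtype=float)
    single = query.ndim == 1
    if single:
        query = query[None, :]
    if query.shape[1] != tps.dim:
        raise ValueError(f"query dimension {query.shape[1]} does not match "
                         f"the map's source dimension {tps.dim}")
    U = _tps_kernel(cdist(query, tps.source), tps.dim)
    out = tps.affine[0] + query @ tps.affine[1:] + U @ tps.weights
    return out[0] if single else out


# ---------------------------------------------------------------------------
# elliptic Fourier analysis
# ---------------------------------------------------------------------------


def efa_decompose(outline: np.ndarray, h: int):
    """Elliptic Fourier decomposition of a closed 2D outline.

    Chord-length parameterisation; harmonics 1..h.  No starting-point or
    rotation normalisation is applied — inputs are assumed pre-normalised
    upstream.

    Returns
    -------
    (coeffs, offset) : ``(h, 4)`` array of ``(a_j, b_j, c_j, d_j)`` and the
    ``(A0, C0)`` center terms.
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("outline must be a (t, 2) polyline")
    if h < 1:
        raise ValueError("need at least one harmonic")
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.diff(pts, axis=0)
    dt = np.hypot(seg[:, 0], seg[:, 1])
    keep = dt > 1e-15
    seg, dt = seg[keep], dt[keep]
    if dt.size < 2 or dt.sum() <= 1e-15:
        raise ValueError("degenerate outline: zero perimeter")
    if pts.shape[0] - 1 < 2 * h + 1:
        raise ValueError(f"need at least {2 * h + 1} outline points for h={h}")
    pts = np.vstack([pts[0], pts[0] + np.cumsum(seg, axis=0)])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    j = np.arange(1, h + 1)[:, None]                      # (h, 1)
    cos_d = np.cos(j * phi[1:]) - np.cos(j * phi[:-1])    # (h, nseg)
    sin_d = np.sin(j * phi[1:]) - np.sin(j * phi[:-1])
    const = T / (2.0 * (j.ravel() * np.pi) ** 2)
    dxdt = seg[:, 0] / dt
    dydt = seg[:, 1] / dt
    a = const * (cos_d @ dxdt)
    b = const * (sin_d @ dxdt)
    c = const * (cos_d @ dydt)
    d = const * (sin_d @ dydt)
    # center terms: exact arc-length mean of the piecewise-linear outline
    mid = 0.5 * (pts[:-1] + pts[1:])
    A0, C0 = (mid * dt[:, None]).sum(axis=0) / T
    return np.column_stack([a, b, c, d]), np.array([A0, C0])


def efa_reconstruct(coeffs: np.ndarray, n_points: int,
                    offset: Optional[np.ndarray] = None) -> np.ndarray:
    """Inverse elliptic Fourier transform: render a closed outline.

    x(t) = A0 + sum_j a_j cos(jt) + b_j sin(jt), and likewise y(t) with
    (C0, c_j, d_j), for t in [0, 2*pi]; the returned ``(n_points, 2)``
    polyline is closed (last point equals the first).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 2 or coeffs.shape[1] != 4:
        raise ValueError("coeffs must be an (h, 4) array")
    if n_points < 3:
        raise ValueError("need at least 3 points to render an outline")
    A0, C0 = (0.0, 0.0) if offset is None else np.asarray(offset, dtype=float)
    t = np.linspace(0.0, 2.0 * np.pi, n_points)
    j = np.arange(1, coeffs.shape[0] + 1)[:, None]
    cos_jt = np.cos(j * t)
    sin_jt = np.sin(j * t)
    x = A0 + coeffs[:, 0] @ cos_jt + coeffs[:, 1] @ sin_jt
    y = C0 + coeffs[:, 2] @ cos_jt + coeffs[:, 3] @ sin_jt
    return np.column_stack([x, y])
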