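"""Ordination of shape data.

Six families of linear ordinations are provided, each returning an
:class:`Ordination` with a common affine contract — stored scores equal
``(X - center) @ loadings`` — so that every downstream projection can treat
them uniformly:

* :func:`pca` — principal component analysis of the sample covariance;
* :func:`bg_pca` — between-groups PCA (PCA of the group mean shapes, all
  observations projected; at most g-1 axes), optionally with leave-one-out
  cross-validated scores to counter spurious group separation when p >> n;
* :func:`pls_shapes` — two-block partial least squares: SVD of the
  cross-covariance between the shape block and an external block;
* :func:`burnaby_ordination` — PCA inside the subspace orthogonal to
  nuisance directions (Burnaby projection);
* :func:`ppca` — phylogenetic PCA: eigenanalysis of the GLS (Brownian
  motion weighted) evolutionary covariance of species means;
* :func:`paca` — phylogenetically aligned component analysis: axes ordered
  by covariation with phylogenetic structure rather than by variance.

Phylogenies are thin wrappers around dendropy trees; the Brownian-motion
tip covariance matrix C (C[i, j] = shared root-to-MRCA path length) and
maximum-likelihood BM ancestral states are computed here because ppca, paca
and the phylomorphospace projections all need them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import dendropy

from .geometry import ShapeMatrix, as_shape_matrix

__all__ = [
    "Ordination",
    "Phylogeny",
    "PhyloCovariance",
    "pca",
    "bg_pca",
    "pls_shapes",
    "burnaby_ordination",
    "phylo_covariance",
    "ppca",
    "paca",
    "anc_states_bm",
]

_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """A fitted linear ordination.

    ``loadings`` is (p, q) with unit-norm columns; ``scores`` is (n, q) and
    always equals ``(X - center) @ loadings``; ``explained`` holds per-axis
    variances (PCA families) or singular values (PLS).
    """

    center: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained: np.ndarray
    method: str
    extras: dict = field(default_factory=dict)

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    def explained_ratio(self) -> np.ndarray:
        tot = self.explained.sum()
        return self.explained / tot if tot > 0 else self.explained * 0.0

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scores of new shapes under the affine contract (x - center) @ V."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"expected shapes with p={self.p} variables, "
                             f"got {X.shape[1]}")
        return (X - self.center) @ self.loadings

    def inverse(self, scores: np.ndarray,
                axes: Optional[Sequence[int]] = None) -> np.ndarray:
        """Map scores back to shape space: center + sum_a s_a v_a.

        ``axes`` selects which ordination axes the score columns refer to
        (default: the leading ones); unlisted axes are held at 0.
        """
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if axes is None:
            axes = list(range(scores.shape[1]))
        V = self.loadings[:, list(axes)]
        if scores.shape[1] != V.shape[1]:
            raise ValueError("score columns do not match the axes requested")
        return self.center + scores @ V.T


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def _shape_meta(sm: ShapeMatrix) -> dict:
    return {"kind": sm.kind, "k": sm.k, "m": sm.m, "h": sm.h}


# ---------------------------------------------------------------------------
# ordinations on plain data
# ---------------------------------------------------------------------------


def pca(shapes) -> Ordination:
    """Principal component analysis of the sample covariance matrix."""
    sm = as_shape_matrix(shapes)
    if sm.n < 2:
        raise ValueError("PCA needs at least 2 observations")
    center = sm.X.mean(axis=0)
    Xc = sm.X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = _fix_signs(Vt.T)
    eigvals = s ** 2 / (sm.n - 1)
    scores = Xc @ V
    return Ordination(center=center, loadings=V, scores=scores,
                      explained=eigvals, method="pca",
                      extras={"shape_meta": _shape_meta(sm), "ids": sm.ids})


def bg_pca(shapes, groups: Sequence, loocv: bool = False,
           weighted: bool = False) -> Ordination:
    """Between-groups PCA: PCA of group means, all observations projected.

    Group means are unweighted by default (each group counts once).  With
    ``loocv`` each observation's scores are recomputed from axes fitted with
    that observation excluded from its own group mean (the standard
    leave-one-out guard against spurious separation when p >> n).
    """
    sm = as_shape_matrix(shapes)
    labels = np.asarray(groups)
    if labels.shape[0] != sm.n:
        raise ValueError("group labels must match the number of shapes")
    levels = list(dict.fromkeys(labels.tolist()))
    g = len(levels)
    if g < 2:
        raise ValueError("between-groups PCA needs at least 2 groups")
    counts = {lev: int((labels == lev).sum()) for lev in levels}

    def _axes(means: np.ndarray):
        if weighted:
            w = np.array([counts[lev] for lev in levels], dtype=float)
            gm = (means * w[:, None]).sum(axis=0) / w.sum()
        else:
            gm = means.mean(axis=0)
        Mc = means - gm
        _, s, Vt = np.linalg.svd(Mc, full_matrices=False)
        q = min(g - 1, sm.p)
        V = _fix_signs(Vt.T[:, :q])
        eig = (s ** 2 / max(g - 1, 1))[:q]
        return gm, V, eig

    means = np.array([sm.X[labels == lev].mean(axis=0) for lev in levels])
    gm, V, eig = _axes(means)
    scores = (sm.X - gm) @ V
    if loocv:
        scores = np.empty((sm.n, V.shape[1]))
        level_index = {lev: i for i, lev in enumerate(levels)}
        for i in range(sm.n):
            lev = labels[i]
            n_g = counts[lev]
            if n_g < 2:
                raise ValueError(f"group {lev!r} has a single member; "
                                 "leave-one-out would empty it")
            means_i = means.copy()
            gi = level_index[lev]
            means_i[gi] = (means[gi] * n_g - sm.X[i]) / (n_g - 1)
            gm_i, V_i, _ = _axes(means_i)
            scores[i] = (sm.X[i] - gm_i) @ V_i
    return Ordination(center=gm, loadings=V, scores=scores, explained=eig,
                      method="bgpca",
                      extras={"shape_meta": _shape_meta(sm), "ids": sm.ids,
                              "group_means": means, "group_levels": levels,
                              "groups": labels, "loocv": loocv})


def pls_shapes(shapes, Y: np.ndarray) -> Ordination:
    """Two-block partial least squares of shapes against a second block.

    Singular value decomposition of the (p, py) cross-covariance matrix;
    paired singular vectors, scores for both blocks, singular values in
    ``explained``.  Second-block loadings/scores live in ``extras``.
    """
    sm = as_shape_matrix(shapes)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != sm.n:
        raise ValueError("both blocks must have the same number of rows")
    if sm.n < 3:
        raise ValueError("two-block PLS needs at least 3 observations")
    xc = sm.X.mean(axis=0)
    yc = Y.mean(axis=0)
    Xc, Yc = sm.X - xc, Y - yc
    S = Xc.T @ Yc / (sm.n - 1)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    q = min(sm.p, Y.shape[1], sm.n - 1)
    U, s, V = U[:, :q], s[:q], Vt.T[:, :q]
    if np.all(s < 1e-14):
        warnings.warn("cross-covariance between blocks is zero; singular "
                      "values are all 0", stacklevel=2)
    # joint sign fix so paired axes stay paired
    for j in range(q):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return Ordination(center=xc, loadings=U, scores=Xc @ U, explained=s,
                      method="pls",
                      extras={"shape_meta": _shape_meta(sm), "ids": sm.ids,
                              "y_center": yc, "y_loadings": V,
                              "y_scores": Yc @ V})


def burnaby_ordination(shapes, nuisance: np.ndarray) -> Ordination:
    """PCA in the subspace orthogonal to nuisance variation.

    ``nuisance`` is either an (n, d) block of covariates — in which case the
    removed directions F are the multivariate regression coefficient rows of
    the centered shapes on the centered covariates — or directly a (p, f)
    matrix of shape-space directions.  Scores of the data along span(F) are
    exactly zero.
    """
    sm = as_shape_matrix(shapes)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    center = sm.X.mean(axis=0)
    Xc = sm.X - center
    if nuisance.shape[0] == sm.n and nuisance.shape[0] != sm.p:
        Zc = nuisance - nuisance.mean(axis=0)
        B, *_ = np.linalg.lstsq(Zc, Xc, rcond=None)
        F = B.T                                   # (p, d)
    elif nuisance.shape[0] == sm.p:
        F = nuisance
    else:
        raise ValueError("nuisance must be (n, d) covariates or (p, f) "
                         "shape-space directions")
    f = F.shape[1]
    if np.linalg.matrix_rank(F) < f:
        raise ValueError("nuisance directions are rank-deficient")
    P = np.eye(sm.p) - F @ np.linalg.solve(F.T @ F, F.T)
    Xp = Xc @ P
    U, s, Vt = np.linalg.svd(Xp, full_matrices=False)
    eig = s ** 2 / (sm.n - 1)
    keep = eig > _RANK_TOL * max(eig.max(), 1.0)
    V = _fix_signs(Vt.T[:, keep])
    return Ordination(center=center, loadings=V, scores=Xc @ V,
                      explained=eig[keep], method="burnaby",
                      extras={"shape_meta": _shape_meta(sm), "ids": sm.ids,
                              "removed_directions": F})


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree with branch lengths whose tips label species data."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("phylogeny has edges without branch lengths")
        self._index_nodes()

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def _index_nodes(self) -> None:
        self.tip_nodes = [nd for nd in self.tree.leaf_node_iter()]
        self.tip_labels = [nd.taxon.label for nd in self.tip_nodes]
        self.internal_nodes = [nd for nd in
                               self.tree.preorder_internal_node_iter()]
        n_int = 0
        self.node_labels = []
        for nd in self.internal_nodes:
            if nd.label:
                self.node_labels.append(nd.label)
            else:
                self.node_labels.append(f"node{n_int}")
            n_int += 1
        self._depth = {}
        self._anc = {}
        for nd in self.tree.preorder_node_iter():
            parent = nd.parent_node
            d = 0.0 if parent is None else \
                self._depth[id(parent)] + (nd.edge.length or 0.0)
            self._depth[id(nd)] = d
            chain = dict(self._anc[id(parent)]) if parent is not None else {}
            chain[id(nd)] = d
            self._anc[id(nd)] = chain

    @property
    def n_tips(self) -> int:
        return len(self.tip_nodes)

    def depth(self, node) -> float:
        return self._depth[id(node)]

    def mrca_depth(self, a, b) -> float:
        """Root-to-MRCA path length for two nodes."""
        ca = self._anc[id(a)]
        cb = self._anc[id(b)]
        common = [d for k, d in ca.items() if k in cb]
        return max(common)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


@dataclass
class PhyloCovariance:
    """Brownian-motion tip covariance: shared branch length to the root."""

    C: np.ndarray
    tip_labels: Sequence[str]


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """C[i, j] = shared path length from the root to MRCA(tip_i, tip_j)."""
    s = tree.n_tips
    C = np.empty((s, s))
    for i, a in enumerate(tree.tip_nodes):
        for jj, b in enumerate(tree.tip_nodes[: i + 1]):
            C[i, jj] = C[jj, i] = tree.mrca_depth(a, b)
    if np.any(np.diag(C) <= 0):
        raise ValueError("tree has tips at zero distance from the root")
    return PhyloCovariance(C=C, tip_labels=list(tree.tip_labels))


def _align_tips(tree: Phylogeny, sm: ShapeMatrix) -> np.ndarray:
    """Reorder shape rows to the tree's tip order, or raise listing misses."""
    ids = list(sm.ids)
    missing = [t for t in tree.tip_labels if t not in ids]
    extra = [i for i in ids if i not in tree.tip_labels]
    if missing or extra:
        raise ValueError(f"tip/shape label mismatch; tips without data: "
                         f"{missing}; data without tips: {extra}")
    order = [ids.index(t) for t in tree.tip_labels]
    return sm.X[order]


def _gls_root(C: np.ndarray, X: np.ndarray) -> np.ndarray:
    """GLS estimate of the root state: (1'C^-1 1)^-1 1'C^-1 X."""
    Cinv_1 = np.linalg.solve(C, np.ones(C.shape[0]))
    return Cinv_1 @ X / Cinv_1.sum()


def ppca(shapes, tree: Phylogeny) -> Ordination:
    """Phylogenetic PCA of species mean shapes (covariance mode).

    The data are centered on the GLS root estimate a and the evolutionary
    covariance R = (X - 1a)' C^-1 (X - 1a) / (s - 1) is eigendecomposed.
    Scores are (X - 1a) V for the tips; with all axes retained the scores
    preserve the original pairwise geometry of the species means.
    """
    sm = as_shape_matrix(shapes)
    if sm.n < 3:
        raise ValueError("phylogenetic PCA needs at least 3 species")
    X = _align_tips(tree, sm)
    pc = phylo_covariance(tree)
    C = pc.C
    if np.linalg.cond(C) > 1e12:
        raise ValueError("phylogenetic covariance matrix is singular")
    a = _gls_root(C, X)
    Xa = X - a
    R = Xa.T @ np.linalg.solve(C, Xa) / (sm.n - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    V = _fix_signs(eigvecs[:, order])
    return Ordination(center=a, loadings=V, scores=Xa @ V,
                      explained=np.maximum(eigvals[order], 0.0), method="ppca",
                      extras={"shape_meta": _shape_meta(sm),
                              "ids": list(tree.tip_labels),
                              "tree": tree, "C": C, "evol_cov": R})


def paca(shapes, tree: Phylogeny) -> Ordination:
    """Phylogenetically aligned component analysis.

    Axes are ordered by the covariation of their scores with phylogenetic
    structure: with alignment matrix A = C (the BM tip covariance), the
    loadings are the eigenvectors of Xc' A Xc, so the first axis maximises
    the phylogenetically weighted score covariation among all unit shape
    directions.  Loadings form an orthonormal rotation of shape space.
    """
    sm = as_shape_matrix(shapes)
    if sm.n < 3:
        raise ValueError("PACA needs at least 3 species")
    X = _align_tips(tree, sm)
    pc = phylo_covariance(tree)
    center = X.mean(axis=0)
    Xc = X - center
    M = Xc.T @ pc.C @ Xc
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    V = _fix_signs(eigvecs[:, order])
    return Ordination(center=center, loadings=V, scores=Xc @ V,
                      explained=np.maximum(eigvals[order], 0.0), method="paca",
                      extras={"shape_meta": _shape_meta(sm),
                              "ids": list(tree.tip_labels),
                              "tree": tree, "C": pc.C})


def anc_states_bm(tree: Phylogeny, tip_values: np.ndarray):
    """Maximum-likelihood Brownian-motion ancestral states, per variable.

    The GLS root estimate anchors the process and each internal node's state
    is the conditional (ML) estimate a + C_nt C_tt^-1 (X - 1a), where C_nt
    holds shared root-to-MRCA path lengths between internal nodes and tips.

    Returns ``(node_values, node_labels)`` over the internal nodes in
    preorder (the root first).
    """
    X = np.atleast_2d(np.asarray(tip_values, dtype=float))
    if X.shape[0] == 1 and tree.n_tips > 1:
        X = X.T
    if X.shape[0] != tree.n_tips:
        raise ValueError("tip_values rows must match the number of tips")
    pc = phylo_covariance(tree)
    C = pc.C
    a = _gls_root(C, X)
    n_int = len(tree.internal_nodes)
    Cnt = np.empty((n_int, tree.n_tips))
    for vi, v in enumerate(tree.internal_nodes):
        for ti, t in enumerate(tree.tip_nodes):
            Cnt[vi, ti] = tree.mrca_depth(v, t)
    node_values = a + Cnt @ np.linalg.solve(C, X - a)
    return node_values, list(tree.node_labels)
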