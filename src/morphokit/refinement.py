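"""Refinement of shape variation before ordination.

Nuisance variation (allometry, locality, age, individual identity, ...) is
removed either by taking the residuals of a multivariate linear model of the
shape variables on the nuisance design (detrending), or by projecting the
shape data onto the subspace orthogonal to a set of nuisance directions
(Burnaby projection, P = I - F (F'F)^-1 F').  Model-predicted shapes (group
means, points on an allometric regression line) are available through
:func:`expected_shapes`.

Design matrices can be built from a covariate table with a small formula
syntax, ``"~ log_size + locality"``: numeric columns enter as-is, categorical
columns are dummy-coded against their first level, and an intercept is always
included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import ShapeMatrix, as_shape_matrix

__all__ = [
    "LinearShapeModel",
    "design_matrix",
    "fit_shape_regression",
    "detrend_shapes",
    "expected_shapes",
    "burnaby_filter",
    "detrend_by_group",
]


@dataclass
class LinearShapeModel:
    """OLS fit of an (n, p) shape matrix on an (n, d) design matrix.

    ``fitted + residuals`` reconstructs the data exactly, and the residuals
    are orthogonal to every design column.
    """

    design: np.ndarray
    coefficients: np.ndarray          # (d, p)
    fitted: np.ndarray                # (n, p)
    residuals: np.ndarray             # (n, p)
    design_names: Sequence[str] = field(default_factory=list)
    template: Optional[ShapeMatrix] = None   # un-flattening metadata

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def d(self) -> int:
        return self.design.shape[1]

    @property
    def p(self) -> int:
        return self.coefficients.shape[1]

    def predict(self, at: np.ndarray) -> np.ndarray:
        at = np.atleast_2d(np.asarray(at, dtype=float))
        if at.shape[1] != self.d:
            raise ValueError(f"design rows must have {self.d} columns, "
                             f"got {at.shape[1]}")
        return at @ self.coefficients


def design_matrix(table: pd.DataFrame, formula: str):
    """Build an intercept-first design matrix from ``"~ col1 + col2"``.

    Numeric columns enter untouched; non-numeric columns are dummy-coded
    with the first level (in order of appearance) as reference.

    Returns ``(D, names)``.
    """
    rhs = formula.strip()
    if rhs.startswith("~"):
        rhs = rhs[1:]
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    cols = [np.ones(len(table))]
    names = ["(intercept)"]
    for term in terms:
        if term not in table.columns:
            raise KeyError(f"formula term {term!r} not found in covariate table")
        col = table[term]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = list(pd.unique(col))
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names


def _check_full_rank(design: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase the rank when added
        bad = []
        r = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, :j + 1])
            if rj == r:
                bad.append(names[j] if j < len(names) else f"col{j}")
            r = rj
        raise ValueError(f"design matrix is rank-deficient; collinear "
                         f"columns: {bad}")


def fit_shape_regression(shapes, design: np.ndarray,
                         design_names: Optional[Sequence[str]] = None
                         ) -> LinearShapeModel:
    """Multivariate OLS of shape variables on a design matrix (via QR)."""
    sm = as_shape_matrix(shapes)
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    n, d = design.shape
    if sm.n != n:
        raise ValueError("design and shapes have different numbers of rows")
    if n <= d:
        raise ValueError(f"need more observations ({n}) than design "
                         f"columns ({d})")
    names = list(design_names) if design_names is not None else \
        [f"col{j}" for j in range(d)]
    _check_full_rank(design, names)
    coef, *_ = np.linalg.lstsq(design, sm.X, rcond=None)
    fitted = design @ coef
    residuals = sm.X - fitted
    return LinearShapeModel(design=design, coefficients=coef, fitted=fitted,
                            residuals=residuals, design_names=names,
                            template=sm)


def detrend_shapes(model: LinearShapeModel,
                   displace_to: Optional[np.ndarray] = None) -> ShapeMatrix:
    """Remove modelled variation, keeping the residual shape variation.

    The residuals are displaced to the grand mean shape by default, or to
    the model prediction at ``displace_to`` (a single design row) — e.g. the
    shape predicted at maximum size when studying static morphology.
    """
    if displace_to is None:
        anchor = (model.fitted + model.residuals).mean(axis=0)
    else:
        displace_to = np.asarray(displace_to, dtype=float).ravel()
        if displace_to.size != model.d:
            raise ValueError(f"displace_to must have length {model.d}, "
                             f"got {displace_to.size}")
        anchor = model.predict(displace_to)[0]
    out = model.residuals + anchor
    if model.template is not None:
        return model.template.with_data(out)
    return ShapeMatrix(out, kind="landmarks2d")


def expected_shapes(model: LinearShapeModel, at: np.ndarray) -> ShapeMatrix:
    """Model-predicted shapes at the given design rows.

    For a groups-only (dummy-coded) design this returns group mean shapes;
    for an allometric design, shapes sitting on the regression line.
    """
    pred = model.predict(at)
    if model.template is not None:
        return ShapeMatrix(pred, kind=model.template.kind, k=model.template.k,
                           m=model.template.m, h=model.template.h)
    return ShapeMatrix(pred, kind="landmarks2d")


def burnaby_filter(shapes, F: np.ndarray) -> ShapeMatrix:
    """Project shapes onto the subspace orthogonal to the columns of ``F``.

    The centered data are multiplied by P = I - F (F'F)^-1 F' and the mean
    shape is added back.  ``F`` is a (p, f) matrix of shape-space directions
    (e.g. an allometric vector) with full column rank, f < p.
    """
    sm = as_shape_matrix(shapes)
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    p, f = F.shape
    if p != sm.p:
        raise ValueError(f"F must have {sm.p} rows, got {p}")
    if f >= p:
        raise ValueError("number of nuisance directions must be < p")
    if np.linalg.matrix_rank(F) < f:
        raise ValueError("F is rank-deficient")
    P = np.eye(p) - F @ np.linalg.solve(F.T @ F, F.T)
    assert np.allclose(P @ P, P, atol=1e-10), "projector not idempotent"
    mean = sm.X.mean(axis=0)
    out = (sm.X - mean) @ P + mean
    return sm.with_data(out)


def detrend_by_group(shapes, table: pd.DataFrame, formula: str,
                     group: Union[str, Sequence],
                     displace_to_max_of: Optional[str] = None) -> ShapeMatrix:
    """Fit and detrend the same formula within each group separately.

    Each group's shapes are replaced by its own model residuals displaced to
    the group's mean shape — or, when ``displace_to_max_of`` names a numeric
    formula term, to the shape the group's model predicts at that term's
    within-group maximum (remaining numeric terms held at the group mean,
    dummies at their group mean frequency).
    """
    sm = as_shape_matrix(shapes)
    labels = np.asarray(table[group]) if isinstance(group, str) \
        else np.asarray(group)
    if labels.shape[0] != sm.n:
        raise ValueError("group labels must match the number of shapes")
    out = np.empty_like(sm.X)
    for lev in pd.unique(labels):
        idx = np.flatnonzero(labels == lev)
        D, names = design_matrix(table.iloc[idx], formula)
        sub = ShapeMatrix(sm.X[idx], kind=sm.kind, k=sm.k, m=sm.m, h=sm.h)
        model = fit_shape_regression(sub, D, design_names=names)
        if displace_to_max_of is None:
            out[idx] = detrend_shapes(model).X
        else:
            if displace_to_max_of not in names:
                raise KeyError(f"{displace_to_max_of!r} is not a term of "
                               f"{formula!r}")
            row = D.mean(axis=0)
            j = names.index(displace_to_max_of)
            row[j] = D[:, j].max()
            out[idx] = detrend_shapes(model, displace_to=row).X
    return sm.with_data(out)
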