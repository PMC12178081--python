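"""Deterministic synthetic datasets for every workflow stage.

Three generators emulate the statistical structure of the kinds of data the
morphospace workflow targets, so that each stage is testable end-to-end
without external downloads:

* :func:`make_outline_dataset` — group-structured elliptic Fourier outline
  coefficients (a bivalve-shell-like scenario): a shared base outline, four
  species with their own harmonic perturbations, size-linked coefficient
  drift (allometry) and iid coefficient noise, plus a species/size/age
  covariate table.
* :func:`make_landmark_dataset` — group-structured 2D landmark
  configurations with within-individual longitudinal size series,
  allometric deformation along a fixed shape direction, nuisance locality
  and age effects, iid landmark noise, and (optionally) randomised
  position/orientation/scale so that Procrustes alignment is exercised.
* :func:`make_bm_tips` — multivariate Brownian motion along a phylogeny,
  giving species mean shapes with known rate for comparative analyses.

Every generator is a pure function of its spec (including the seed): the
same spec always reproduces the identical dataset.  Injected effect sizes
are chosen so the corresponding estimators recover them — that recovery is
the module's core test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import LandmarkSet, OutlineCoefficients
from .ordination import Phylogeny

__all__ = [
    "OutlineFixtureSpec",
    "LandmarkFixtureSpec",
    "make_outline_dataset",
    "make_landmark_dataset",
    "make_bm_tips",
    "demo_tree",
]


# ---------------------------------------------------------------------------
# outlines (shell-like, 4 species, allometry + noise)
# ---------------------------------------------------------------------------


@dataclass
class OutlineFixtureSpec:
    """Conditions for the outline fixture.

    Defaults mirror the scale of a typical fossil-outline study: 137
    specimens in four congeneric species ordered along a morphocline,
    seven harmonics, a species separation of 0.3 in coefficient space
    (clearly distinct species: about three times the aggregate coefficient
    noise), an allometric drift of 0.08 per unit log-size along a fixed
    direction, and iid coefficient noise of sd 0.02.
    """

    n_per_group: Tuple[int, ...] = (35, 34, 34, 34)
    harmonics: int = 7
    group_effect: float = 0.3
    allometric_slope: float = 0.08
    noise_sd: float = 0.02
    age_range: Tuple[float, float] = (127.0, 132.0)
    seed: int = 0


def _base_outline_coeffs(h: int) -> np.ndarray:
    """A smooth shell-like base outline: dominant ellipse + decaying detail."""
    base = np.zeros((h, 4))
    base[0] = [1.0, 0.0, 0.0, 0.65]
    for j in range(2, h + 1):
        base[j - 1] = [0.12 / j ** 2, 0.05 / j ** 2,
                       -0.04 / j ** 2, 0.09 / j ** 2]
    return base


def make_outline_dataset(spec: OutlineFixtureSpec = OutlineFixtureSpec()):
    """Generate outline coefficients plus a species/size/age table.

    Returns ``(OutlineCoefficients, DataFrame)`` with columns
    ``specimen, species, size, log_size, age``.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.harmonics
    p = 4 * h
    base = _base_outline_coeffs(h).ravel()
    g = len(spec.n_per_group)
    # congeneric species are ordered along a shared morphocline with small
    # idiosyncratic deviations, so between-species variation is quasi-1D
    morphocline = rng.normal(size=p)
    morphocline /= np.linalg.norm(morphocline)
    idio = rng.normal(size=(g, p))
    idio /= np.linalg.norm(idio, axis=1, keepdims=True)
    positions = np.linspace(-1.0, 1.0, g)
    offsets = spec.group_effect * (positions[:, None] * morphocline +
                                   0.35 * idio)
    allo = rng.normal(size=p)
    allo /= np.linalg.norm(allo)
    rows, species, sizes, ages = [], [], [], []
    for gi, n_g in enumerate(spec.n_per_group):
        size = rng.lognormal(mean=1.0 + 0.1 * gi, sigma=0.25, size=n_g)
        age = rng.uniform(*spec.age_range, size=n_g)
        logs = np.log(size)
        centered = logs - 1.0 - 0.1 * gi          # drift around group mean
        for i in range(n_g):
            coef = base + offsets[gi] + \
                spec.allometric_slope * centered[i] * allo + \
                rng.normal(scale=spec.noise_sd, size=p)
            rows.append(coef)
            species.append(f"sp{gi + 1}")
        sizes.extend(size)
        ages.extend(age)
    X = np.array(rows)
    ids = [f"spm{i:03d}" for i in range(X.shape[0])]
    coeffs = OutlineCoefficients(X.reshape(-1, h, 4), ids=ids)
    table = pd.DataFrame({"specimen": ids, "species": species,
                          "size": sizes, "log_size": np.log(sizes),
                          "age": ages})
    # injected truth, for estimator-recovery checks
    table.attrs["base"] = base
    table.attrs["group_offsets"] = offsets
    table.attrs["allometric_direction"] = allo
    table.attrs["allometric_slope"] = spec.allometric_slope
    table.attrs["log_size_centers"] = np.array(
        [1.0 + 0.1 * gi for gi in range(g)])
    return coeffs, table


# ---------------------------------------------------------------------------
# landmarks (longitudinal, nuisance factors, optional pose jitter)
# ---------------------------------------------------------------------------


@dataclass
class LandmarkFixtureSpec:
    """Conditions for the landmark fixture.

    Defaults mirror a longitudinal ontogenetic design: 7 species, 10
    individuals each, 4 size-ordered measurements per individual (280
    shapes), 9 2D landmarks; allometric deformation of 0.25 per unit
    log-size (so ontogeny dominates the within-individual variation, as in
    a growth series), locality and age nuisance effects, landmark noise sd
    0.01.  Set ``measures_per_individual=1`` and more groups for a
    cross-sectional (species-comparative) design.
    """

    n_groups: int = 7
    individuals_per_group: int = 10
    measures_per_individual: int = 4
    k: int = 9
    m: int = 2
    group_effect: float = 0.05
    allometric_slope: float = 0.25
    individual_sd: float = 0.02
    locality_effect: float = 0.03
    age_effect: float = 0.02
    noise_sd: float = 0.01
    jitter_pose: bool = True
    seed: int = 0


def _template_polygon(k: int, m: int) -> np.ndarray:
    """A k-landmark template: points on an ellipse (unit centroid size)."""
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    pts = np.column_stack([np.cos(t), 0.6 * np.sin(t)])
    if m == 3:
        pts = np.column_stack([pts, 0.2 * np.sin(2 * t)])
    pts -= pts.mean(axis=0)
    return pts / np.sqrt((pts ** 2).sum())


def make_landmark_dataset(spec: LandmarkFixtureSpec = LandmarkFixtureSpec()):
    """Generate landmark configurations plus a covariate table.

    Returns ``(LandmarkSet, DataFrame)`` with columns ``specimen,
    individual, species, size, log_size, locality, age``.  With
    ``jitter_pose`` each configuration is randomly rotated, translated and
    scaled by its size so that Procrustes alignment is required.
    """
    rng = np.random.default_rng(spec.seed)
    k, m = spec.k, spec.m
    p = k * m
    template = _template_polygon(k, m)
    group_dirs = rng.normal(size=(spec.n_groups, p))
    group_dirs /= np.linalg.norm(group_dirs, axis=1, keepdims=True)
    allo = rng.normal(size=p)
    allo /= np.linalg.norm(allo)
    loc_dir = rng.normal(size=p)
    loc_dir /= np.linalg.norm(loc_dir)
    age_dir = rng.normal(size=p)
    age_dir /= np.linalg.norm(age_dir)
    coords, recs = [], []
    spm = 0
    for gi in range(spec.n_groups):
        for ii in range(spec.individuals_per_group):
            ind = f"sp{gi + 1}_ind{ii + 1}"
            ind_dev = rng.normal(scale=spec.individual_sd, size=p)
            locality = rng.choice(["north", "south"])
            age = rng.uniform(0.0, 1.0)
            base_size = rng.lognormal(mean=0.5, sigma=0.2)
            growth = np.sort(rng.uniform(1.0, 2.5,
                                         spec.measures_per_individual))
            for mi in range(spec.measures_per_individual):
                size = base_size * growth[mi]
                logs = np.log(size)
                shape = template.ravel() + \
                    spec.group_effect * group_dirs[gi] + \
                    spec.allometric_slope * (logs - 0.9) * allo + \
                    ind_dev + \
                    (spec.locality_effect if locality == "south" else 0.0) \
                    * loc_dir + \
                    spec.age_effect * (age - 0.5) * age_dir + \
                    rng.normal(scale=spec.noise_sd, size=p)
                cfg = shape.reshape(k, m)
                if spec.jitter_pose:
                    cfg = _jitter(cfg, size, rng)
                coords.append(cfg)
                recs.append({"specimen": f"spm{spm:03d}", "individual": ind,
                             "species": f"sp{gi + 1}", "size": size,
                             "log_size": logs, "locality": locality,
                             "age": age})
                spm += 1
    table = pd.DataFrame(recs)
    lms = LandmarkSet(np.array(coords), ids=table["specimen"].tolist())
    return lms, table


def _jitter(cfg: np.ndarray, size: float, rng: np.random.Generator):
    m = cfg.shape[1]
    if m == 2:
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    else:
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        R = Q
    return size * cfg @ R + rng.uniform(-5, 5, size=m)


# ---------------------------------------------------------------------------
# Brownian motion on a tree
# ---------------------------------------------------------------------------


def make_bm_tips(tree: Phylogeny, rate: float, p: int, seed: int,
                 root: Optional[np.ndarray] = None):
    """Simulate p independent Brownian traits along a phylogeny.

    Each edge contributes a Normal(0, sqrt(rate * branch_length)) increment
    per trait.  Returns ``(tip_values, tip_labels)`` with rows in the
    tree's tip order; across replicates the tip covariance of each trait is
    rate * C, with C the tree's BM covariance matrix.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    root = np.zeros(p) if root is None else np.asarray(root, dtype=float)
    values = {id(tree.tree.seed_node): root}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        bl = nd.edge.length or 0.0
        step = rng.normal(scale=np.sqrt(rate * bl), size=p) if rate * bl > 0 \
            else np.zeros(p)
        values[id(nd)] = values[id(nd.parent_node)] + step
    tips = np.array([values[id(nd)] for nd in tree.tip_nodes])
    return tips, list(tree.tip_labels)


def demo_tree(n_tips: int = 13, seed: int = 0, depth: float = 1.0) -> Phylogeny:
    """A random ultrametric tree (coalescent-style) for demonstrations."""
    rng = np.random.default_rng(seed)
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa,
        rng=_RngAdapter(rng))
    tree.is_rooted = True
    # normalise total depth
    maxd = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / maxd * depth
    return Phylogeny(tree)


class _RngAdapter:
    """Adapt numpy Generator to the random.Random API dendropy expects."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def sample(self, population, k):
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def expovariate(self, lambd):
        return float(self._rng.exponential(1.0 / lambd))

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def random(self):
        return float(self._rng.random())

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def shuffle(self, x):
        self._rng.shuffle(x)

    def choice(self, seq):
        return seq[int(self._rng.integers(len(seq)))]
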