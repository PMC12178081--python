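"""Readers, writers, run configuration and the staged pipeline.

File formats:

* TPS landmark files (``LM=k`` / coordinate lines / ``ID=label`` records,
  optional ``SCALE=``) — the de-facto landmark exchange format;
* wide CSV — one row per specimen, columns ``x1,y1[,z1],x2,...``;
* outline-coefficient CSV — columns ``a1..ah, b1..bh, c1..ch, d1..dh``
  (optional ``A0, C0``);
* Newick trees with branch lengths;
* ordination bundles — a directory of ``center.csv``, ``loadings.csv``,
  ``scores.csv``, ``explained.csv`` and ``meta.yaml``.

CSV files written here are UTF-8 with '.' decimal and start with a schema
comment line; landmark indices are 1-based in files, 0-based in memory.
:func:`run_pipeline` chains align → detrend → ordinate → canvas → project →
hybrid from a validated :class:`RunConfig`; the same config and seed always
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import LandmarkSet, OutlineCoefficients, \
    as_shape_matrix, procrustes_align
from .ordination import (Ordination, Phylogeny, bg_pca, burnaby_ordination,
                         paca, pca, pls_shapes, ppca)
from .refinement import design_matrix, detrend_by_group, detrend_shapes, \
    fit_shape_regression
from . import viz

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_tps",
    "write_tps",
    "read_wide_csv",
    "write_wide_csv",
    "read_coeffs_csv",
    "write_coeffs_csv",
    "read_newick",
    "save_ordination",
    "load_ordination",
    "run_pipeline",
]

_SCHEMA_LINE = "# morphokit csv schema 1"


class ValidationError(ValueError):
    """Invalid input or configuration (CLI exit code 2)."""


# ---------------------------------------------------------------------------
# TPS files
# ---------------------------------------------------------------------------


def read_tps(path) -> LandmarkSet:
    """Read a TPS landmark file (LM=/LM3= records, ID=, optional SCALE=)."""
    text = Path(path).read_text(encoding="utf-8")
    records = []
    cur = None
    dim = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            if cur is not None:
                records.append(cur)
            d = 3 if upper.startswith("LM3=") else 2
            if dim is None:
                dim = d
            elif dim != d:
                raise ValidationError(f"line {lineno}: mixed 2D/3D records")
            k = int(line.split("=", 1)[1])
            cur = {"k": k, "coords": [], "id": None, "scale": None}
        elif upper.startswith("ID="):
            if cur is None:
                raise ValidationError(f"line {lineno}: ID= before any LM=")
            cur["id"] = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            cur["scale"] = float(line.split("=", 1)[1])
        elif upper.startswith(("IMAGE=", "CURVES=", "POINTS=", "COMMENT=")):
            continue
        else:
            if cur is None:
                raise ValidationError(f"line {lineno}: coordinates before LM=")
            vals = [float(v) for v in line.replace(",", " ").split()]
            if len(vals) != dim:
                raise ValidationError(f"line {lineno}: expected {dim} "
                                      f"coordinates, got {len(vals)}")
            cur["coords"].append(vals)
    if cur is not None:
        records.append(cur)
    if not records:
        raise ValidationError(f"{path}: no landmark records found")
    k0 = records[0]["k"]
    coords, ids = [], []
    for ri, rec in enumerate(records):
        if rec["k"] != k0 or len(rec["coords"]) != rec["k"]:
            raise ValidationError(
                f"record {ri + 1}: inconsistent landmark count "
                f"(declared {rec['k']}, found {len(rec['coords'])}, "
                f"first record has {k0})")
        arr = np.asarray(rec["coords"], dtype=float)
        if rec["scale"] is not None:
            arr = arr * rec["scale"]
        coords.append(arr)
        ids.append(rec["id"] if rec["id"] is not None else f"spm{ri}")
    return LandmarkSet(np.array(coords), ids=ids)


def write_tps(lms: LandmarkSet, path) -> None:
    """Write a LandmarkSet as a TPS file (full float precision)."""
    tag = "LM3" if lms.dim == 3 else "LM"
    lines = []
    for cfg, label in zip(lms.coords, lms.ids):
        lines.append(f"{tag}={lms.n_landmarks}")
        for pt in cfg:
            lines.append(" ".join(repr(float(v)) for v in pt))
        lines.append(f"ID={label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSVs
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path, index=False) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_SCHEMA_LINE + "\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def _read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def read_wide_csv(path, dim: int) -> LandmarkSet:
    """Read one-row-per-specimen landmarks (columns x1,y1[,z1],x2,...)."""
    if dim not in (2, 3):
        raise ValidationError("dim must be 2 or 3")
    df = _read_csv(path)
    idcol = None
    for cand in ("id", "specimen"):
        if cand in df.columns:
            idcol = cand
            break
    ids = df[idcol].astype(str).tolist() if idcol else \
        [f"spm{i}" for i in range(len(df))]
    data = df.drop(columns=[idcol] if idcol else [])
    p = data.shape[1]
    if p % dim:
        raise ValidationError(f"{path}: {p} coordinate columns are not a "
                              f"multiple of dim={dim}")
    coords = data.to_numpy(dtype=float).reshape(len(df), p // dim, dim)
    return LandmarkSet(coords, ids=ids)


def write_wide_csv(lms: LandmarkSet, path) -> None:
    n, k, m = lms.coords.shape
    axes = "xyz"[:m]
    cols = [f"{a}{i + 1}" for i in range(k) for a in axes]
    df = pd.DataFrame(lms.coords.reshape(n, k * m), columns=cols)
    df.insert(0, "id", lms.ids)
    _write_csv(df, path)


def read_coeffs_csv(path) -> OutlineCoefficients:
    """Read elliptic Fourier coefficients (a1..ah,b1..,c1..,d1..[,A0,C0])."""
    df = _read_csv(path)
    idcol = "id" if "id" in df.columns else None
    ids = df[idcol].astype(str).tolist() if idcol else None
    h = sum(1 for c in df.columns if c.startswith("a") and c[1:].isdigit())
    if h < 1:
        raise ValidationError(f"{path}: no harmonic columns (a1, b1, ...) "
                              "found")
    arr = np.empty((len(df), h, 4))
    for j in range(1, h + 1):
        for ci, letter in enumerate("abcd"):
            col = f"{letter}{j}"
            if col not in df.columns:
                raise ValidationError(f"{path}: missing column {col!r}")
            arr[:, j - 1, ci] = df[col].to_numpy(dtype=float)
    offset = None
    if "A0" in df.columns and "C0" in df.columns:
        offset = df[["A0", "C0"]].to_numpy(dtype=float)
    return OutlineCoefficients(arr, offset=offset, ids=ids)


def write_coeffs_csv(co: OutlineCoefficients, path) -> None:
    n, h, _ = co.coeffs.shape
    data = {"id": co.ids}
    for ci, letter in enumerate("abcd"):
        for j in range(1, h + 1):
            data[f"{letter}{j}"] = co.coeffs[:, j - 1, ci]
    if co.offset is not None:
        data["A0"] = co.offset[:, 0]
        data["C0"] = co.offset[:, 1]
    _write_csv(pd.DataFrame(data), path)


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree; branch lengths are required."""
    try:
        return Phylogeny.from_file(path)
    except Exception as err:
        raise ValidationError(f"{path}: cannot parse Newick tree: {err}") \
            from err


# ---------------------------------------------------------------------------
# ordination bundles
# ---------------------------------------------------------------------------


def save_ordination(ordn: Ordination, outdir) -> None:
    """Write an ordination as a documented CSV bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_csv(pd.DataFrame({"center": ordn.center}), outdir / "center.csv")
    _write_csv(pd.DataFrame(ordn.loadings,
                            columns=[f"axis{j + 1}"
                                     for j in range(ordn.n_axes)]),
               outdir / "loadings.csv")
    sc = pd.DataFrame(ordn.scores,
                      columns=[f"axis{j + 1}" for j in range(ordn.n_axes)])
    ids = ordn.extras.get("ids")
    if ids is not None:
        sc.insert(0, "id", list(ids))
    _write_csv(sc, outdir / "scores.csv")
    _write_csv(pd.DataFrame({"explained": ordn.explained}),
               outdir / "explained.csv")
    meta = {"method": ordn.method, "schema": 1,
            "shape_meta": ordn.extras.get("shape_meta")}
    (outdir / "meta.yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")


def load_ordination(outdir) -> Ordination:
    outdir = Path(outdir)
    center = _read_csv(outdir / "center.csv")["center"].to_numpy()
    loadings = _read_csv(outdir / "loadings.csv").to_numpy(dtype=float)
    sc = _read_csv(outdir / "scores.csv")
    ids = sc["id"].tolist() if "id" in sc.columns else None
    scores = sc.drop(columns=["id"] if ids else []).to_numpy(dtype=float)
    explained = _read_csv(outdir / "explained.csv")["explained"].to_numpy()
    meta = yaml.safe_load((outdir / "meta.yaml").read_text(encoding="utf-8"))
    extras = {"shape_meta": meta.get("shape_meta")}
    if ids is not None:
        extras["ids"] = ids
    return Ordination(center=center, loadings=loadings, scores=scores,
                      explained=explained, method=meta["method"],
                      extras=extras)


# ---------------------------------------------------------------------------
# run configuration & pipeline
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"input", "covariates", "detrend", "ordination", "canvas",
                "projections", "output", "seed"}
_INPUT_KEYS = {"path", "kind", "dim", "tree"}
_DETREND_KEYS = {"formula", "group", "displace_to_max_of"}
_ORD_KEYS = {"method", "groups", "loocv", "block", "nuisance"}
_CANVAS_KEYS = {"axes", "grid", "padding"}
_LAYER_KEYS = {"layer", "style", "column", "level", "values", "axis",
               "kind"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Unknown keys anywhere in the mapping are rejected; the parsed config is
    serialised into the output directory for provenance.
    """

    input: dict
    output: str
    covariates: Optional[str] = None
    detrend: Optional[dict] = None
    ordination: dict = field(default_factory=lambda: {"method": "pca"})
    canvas: dict = field(default_factory=dict)
    projections: Sequence[dict] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ValidationError("config must be a mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in (("input", _INPUT_KEYS), ("detrend", _DETREND_KEYS),
                             ("ordination", _ORD_KEYS),
                             ("canvas", _CANVAS_KEYS)):
            section = raw.get(key)
            if section is not None:
                bad = set(section) - allowed
                if bad:
                    raise ValidationError(
                        f"unknown keys in {key!r}: {sorted(bad)}")
        for layer in raw.get("projections", []):
            bad = set(layer) - _LAYER_KEYS
            if bad:
                raise ValidationError(f"unknown keys in projection layer: "
                                      f"{sorted(bad)}")
        cfg = cls(input=raw.get("input", {}), output=raw.get("output", "out"),
                  covariates=raw.get("covariates"),
                  detrend=raw.get("detrend"),
                  ordination=raw.get("ordination", {"method": "pca"}),
                  canvas=raw.get("canvas", {}) or {},
                  projections=raw.get("projections", []) or [],
                  seed=int(raw.get("seed", 0)))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if "path" not in self.input:
            raise ValidationError("input.path is required")
        kind = self.input.get("kind", "landmarks")
        if kind not in ("landmarks", "fourier", "tps"):
            raise ValidationError(f"unknown input kind {kind!r}")
        method = self.ordination.get("method", "pca")
        if method not in ("pca", "bgpca", "pls", "burnaby", "ppca", "paca"):
            raise ValidationError(f"unknown ordination method {method!r}")
        if method in ("ppca", "paca") and not self.input.get("tree"):
            raise ValidationError(f"{method} requires input.tree")
        axes = self.canvas.get("axes", [1, 2])
        if len(axes) != 2 or axes[0] == axes[1] or min(axes) < 1:
            raise ValidationError(f"canvas.axes must be two distinct "
                                  f"1-based axis numbers, got {axes}")
        for layer in self.projections:
            if layer.get("layer") not in ("shapes", "groups", "phylogeny",
                                          "landscape", "axis"):
                raise ValidationError(
                    f"unknown projection layer {layer.get('layer')!r}")


def _load_input(cfg: RunConfig):
    kind = cfg.input.get("kind", "landmarks")
    path = cfg.input["path"]
    if kind == "tps":
        return read_tps(path)
    if kind == "fourier":
        return read_coeffs_csv(path)
    return read_wide_csv(path, dim=int(cfg.input.get("dim", 2)))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the staged workflow and write the artifact bundle.

    Stages run in order: align (landmarks only) → detrend → ordinate →
    canvas → project → hybrid exports.  A failure aborts with the stage
    name; artifacts from completed stages stay on disk.  Returns a dict of
    in-memory artifacts.
    """
    outdir = Path(cfg.output)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("morphokit.pipeline")
    handler = logging.FileHandler(outdir / "run.log", mode="w",
                                  encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict = {}
    stage = "setup"
    try:
        (outdir / "config.yaml").write_text(
            yaml.safe_dump({"input": dict(cfg.input), "output": cfg.output,
                            "covariates": cfg.covariates,
                            "detrend": cfg.detrend,
                            "ordination": dict(cfg.ordination),
                            "canvas": dict(cfg.canvas),
                            "projections": [dict(l) for l in cfg.projections],
                            "seed": cfg.seed}), encoding="utf-8")
        t0 = time.perf_counter()
        stage = "input"
        data = _load_input(cfg)
        table = _read_csv(cfg.covariates) if cfg.covariates else None
        log.info("stage input done (%.3fs)", time.perf_counter() - t0)

        stage = "align"
        t0 = time.perf_counter()
        if isinstance(data, LandmarkSet):
            aligned, consensus = procrustes_align(data)
            write_wide_csv(aligned, outdir / "aligned.csv")
            shapes = aligned.to_matrix()
            artifacts["consensus"] = consensus
        else:
            shapes = as_shape_matrix(data)
        artifacts["shapes"] = shapes
        log.info("stage align done (%.3fs)", time.perf_counter() - t0)

        stage = "detrend"
        t0 = time.perf_counter()
        if cfg.detrend:
            if table is None:
                raise ValidationError("detrend requires a covariate table")
            formula = cfg.detrend["formula"]
            group = cfg.detrend.get("group")
            if group:
                shapes = detrend_by_group(
                    shapes, table, formula, group,
                    displace_to_max_of=cfg.detrend.get("displace_to_max_of"))
            else:
                D, names = design_matrix(table, formula)
                model = fit_shape_regression(shapes, D, names)
                shapes = detrend_shapes(model)
            artifacts["shapes"] = shapes
        log.info("stage detrend done (%.3fs)", time.perf_counter() - t0)

        stage = "ordinate"
        t0 = time.perf_counter()
        method = cfg.ordination.get("method", "pca")
        tree = read_newick(cfg.input["tree"]) if cfg.input.get("tree") \
            else None
        if method == "pca":
            ordn = pca(shapes)
        elif method == "bgpca":
            col = cfg.ordination.get("groups")
            if table is None or col not in table.columns:
                raise ValidationError("bgpca needs ordination.groups naming "
                                      "a covariate column")
            ordn = bg_pca(shapes, table[col].to_numpy(),
                          loocv=bool(cfg.ordination.get("loocv", False)))
        elif method == "pls":
            col = cfg.ordination.get("block")
            if table is None or col not in table.columns:
                raise ValidationError("pls needs ordination.block naming a "
                                      "covariate column")
            ordn = pls_shapes(shapes, table[col].to_numpy(dtype=float))
        elif method == "burnaby":
            col = cfg.ordination.get("nuisance")
            if table is None or col not in table.columns:
                raise ValidationError("burnaby needs ordination.nuisance "
                                      "naming a covariate column")
            ordn = burnaby_ordination(shapes,
                                      table[col].to_numpy(dtype=float))
        elif method == "ppca":
            ordn = ppca(shapes, tree)
        else:
            ordn = paca(shapes, tree)
        save_ordination(ordn, outdir / "ordination")
        artifacts["ordination"] = ordn
        log.info("stage ordinate done (%.3fs)", time.perf_counter() - t0)

        stage = "canvas"
        t0 = time.perf_counter()
        axes = [a - 1 for a in cfg.canvas.get("axes", [1, 2])]
        grid = tuple(cfg.canvas.get("grid", (6, 5)))
        canvas = viz.build_canvas(ordn, axes=tuple(axes), grid=grid,
                                  padding=float(cfg.canvas.get("padding",
                                                               0.05)))
        _write_csv(pd.DataFrame(
            np.hstack([canvas.grid_scores, canvas.grid_shapes]),
            columns=["score_x", "score_y"] +
                    [f"v{j + 1}" for j in range(canvas.grid_shapes.shape[1])]),
            outdir / "canvas_models.csv")
        artifacts["canvas"] = canvas
        log.info("stage canvas done (%.3fs)", time.perf_counter() - t0)

        stage = "project"
        t0 = time.perf_counter()
        layers = {}
        for li, layer in enumerate(cfg.projections):
            name = layer["layer"]
            if name == "shapes":
                sc = viz.proj_shapes(canvas, shapes)
                _write_csv(pd.DataFrame(sc, columns=["x", "y"]),
                           outdir / f"layer{li}_shapes.csv")
                layers[f"{li}:shapes"] = sc
            elif name == "groups":
                col = layer.get("column")
                if table is None or col not in table.columns:
                    raise ValidationError("groups layer needs 'column' in "
                                          "the covariate table")
                sc = viz.proj_shapes(canvas, shapes)
                ovs = viz.proj_groups(canvas, sc, table[col].to_numpy(),
                                      style=layer.get("style", "hull"),
                                      level=float(layer.get("level", 0.95)))
                rows = [{"group": str(ov.label), "x": v[0], "y": v[1]}
                        for ov in ovs.values() for v in ov.vertices]
                _write_csv(pd.DataFrame(rows),
                           outdir / f"layer{li}_groups.csv")
                layers[f"{li}:groups"] = ovs
            elif name == "phylogeny":
                if tree is None:
                    raise ValidationError("phylogeny layer requires "
                                          "input.tree")
                ph = viz.proj_phylogeny(canvas, tree, shapes)
                allsc = ph.all_scores
                _write_csv(pd.DataFrame(
                    {"label": list(ph.tip_labels) + list(ph.node_labels),
                     "x": allsc[:, 0], "y": allsc[:, 1]}),
                    outdir / f"layer{li}_phylo.csv")
                layers[f"{li}:phylogeny"] = ph
            elif name == "landscape":
                col = layer.get("values")
                if table is None or col not in table.columns:
                    raise ValidationError("landscape layer needs 'values' "
                                          "in the covariate table")
                sc = viz.proj_shapes(canvas, shapes)
                land = viz.proj_landscape(canvas, sc,
                                          table[col].to_numpy(dtype=float))
                _write_csv(pd.DataFrame(land.grid_values,
                                        columns=[f"x{c}" for c in
                                                 range(land.grid_x.size)]),
                           outdir / f"layer{li}_landscape.csv")
                layers[f"{li}:landscape"] = land
            elif name == "axis":
                col = layer.get("column")
                if table is None or col not in table.columns:
                    raise ValidationError("axis layer needs 'column' in the "
                                          "covariate table")
                D, names = design_matrix(table, f"~ {col}")
                model = fit_shape_regression(shapes, D, names)
                ap = viz.proj_axis(canvas, model)
                _write_csv(pd.DataFrame(ap.segment, columns=["x", "y"]),
                           outdir / f"layer{li}_axis.csv")
                layers[f"{li}:axis"] = ap
        artifacts["layers"] = layers
        log.info("stage project done (%.3fs)", time.perf_counter() - t0)

        stage = "figure"
        t0 = time.perf_counter()
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        scatter = viz.proj_shapes(canvas, shapes)
        ax = viz.plot_layers(
            canvas, scatter=scatter,
            groups=next((v for k, v in layers.items()
                         if k.endswith(":groups")), None),
            landscape=next((v for k, v in layers.items()
                            if k.endswith(":landscape")), None),
            phylo=next((v for k, v in layers.items()
                        if k.endswith(":phylogeny")), None))
        ax.figure.savefig(outdir / "morphospace.png", dpi=120)
        plt.close(ax.figure)
        log.info("stage figure done (%.3fs)", time.perf_counter() - t0)
    except ValidationError:
        log.removeHandler(handler)
        handler.close()
        raise
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    log.removeHandler(handler)
    handler.close()
    return artifacts
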