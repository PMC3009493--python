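"""Readers and writers for the file formats the pipeline touches.

Expression matrices travel as GCT v1.2, class labels as GenePattern CLS
or two-column TSV, the cancer-miRNA network as a TSV edge table, fitted
models as JSON, and biclusters as one-row-per-bicluster TSV.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Union

import numpy as np

from .datatypes import Bicluster, CancerMirnaNetwork, DIRECTIONS, ExpressionMatrix, UscModel

__all__ = [
    "read_gct",
    "write_gct",
    "read_labels",
    "write_labels",
    "read_network",
    "write_network",
    "read_biclusters",
    "write_biclusters",
    "save_model",
    "load_model",
    "GctParseError",
]

PathLike = Union[str, Path]


class GctParseError(ValueError):
    """Malformed GCT input; the message names the offending line."""


def read_gct(path: PathLike, *, impute_missing: bool = False) -> ExpressionMatrix:
    """Read a GCT v1.2 expression matrix.

    Layout: line 1 ``#1.2``; line 2 ``<nrows>\\t<ncols>``; line 3 header
    ``Name\\tDescription\\t<sample ids...>``; one data row per feature.
    Missing cells ("", "NA", "NaN") are rejected unless
    ``impute_missing`` is set, in which case they are replaced by the
    feature's row mean.

    Raises
    ------
    GctParseError
        On a bad version line, dimension mismatch, duplicate feature IDs
        or a non-numeric cell; the message names the line number.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() not in ("#1.2",):
        raise GctParseError(f"line 1: expected GCT version line '#1.2', got {lines[0]!r}"
                            if lines else "empty file")
    try:
        nrows, ncols = (int(tok) for tok in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise GctParseError(f"line 2: expected '<nrows>\\t<ncols>': {exc}") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0].lower() != "name":
        raise GctParseError("line 3: expected header starting 'Name\\tDescription'")
    sample_ids = header[2:]
    if len(sample_ids) != ncols:
        raise GctParseError(
            f"line 3: dimension mismatch: header lists {len(sample_ids)} samples, "
            f"line 2 declares {ncols}"
        )
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != nrows:
        raise GctParseError(
            f"dimension mismatch: {len(data_lines)} data rows found, "
            f"line 2 declares {nrows}"
        )
    feature_ids: list[str] = []
    meta: dict[str, str] = {}
    values = np.empty((nrows, ncols), dtype=float)
    missing_tokens = {"", "na", "nan"}
    for r, ln in enumerate(data_lines):
        lineno = r + 4
        cells = ln.split("\t")
        if len(cells) != ncols + 2:
            raise GctParseError(
                f"line {lineno}: expected {ncols + 2} columns, found {len(cells)}"
            )
        fid = cells[0]
        feature_ids.append(fid)
        meta[fid] = cells[1]
        row_missing = []
        for c, cell in enumerate(cells[2:]):
            if cell.strip().lower() in missing_tokens:
                row_missing.append(c)
                values[r, c] = np.nan
                continue
            try:
                values[r, c] = float(cell)
            except ValueError:
                raise GctParseError(
                    f"line {lineno}: non-numeric cell {cell!r} in column {c + 3}"
                ) from None
        if row_missing:
            if not impute_missing:
                raise GctParseError(
                    f"line {lineno}: missing value(s) in feature {fid!r} "
                    "(pass impute_missing=True for row-mean imputation)"
                )
            row = values[r]
            fill = np.nanmean(row)
            if math.isnan(fill):
                raise GctParseError(f"line {lineno}: feature {fid!r} entirely missing")
            row[np.isnan(row)] = fill
    if len(set(feature_ids)) != len(feature_ids):
        raise GctParseError("duplicate feature IDs in GCT body")
    return ExpressionMatrix(feature_ids, sample_ids, values, feature_meta=meta)


def write_gct(m: ExpressionMatrix, path: PathLike, *, float_fmt: str = "%.6g") -> None:
    """Write GCT v1.2; the Description column comes from ``feature_meta``."""
    meta = m.feature_meta or {}
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{m.n_features}\t{m.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(m.sample_ids) + "\n")
        for i, fid in enumerate(m.feature_ids):
            row = "\t".join(float_fmt % v for v in m.values[i])
            fh.write(f"{fid}\t{meta.get(fid, 'na')}\t{row}\n")


def read_labels(path: PathLike, format: str = "auto") -> dict[str, str]:
    """Read sample class labels from a CLS file or a two-column TSV.

    CLS dialect: line 1 ``<n> <K> 1``; line 2 ``# <class names>``;
    line 3 space-separated class indices, one per sample. Samples get
    positional IDs only when read from CLS, so CLS labels are matched to
    a matrix by column order via :func:`labels_for_matrix`; the TSV form
    maps sample IDs directly.

    Returns either ``{sample_id: class}`` (TSV) or ``{"@0": class, ...}``
    positional keys (CLS).
    """
    text = Path(path).read_text()
    if format == "auto":
        format = "cls" if text.lstrip().split("\n")[0].split()[:1] and _looks_cls(text) else "tsv"
    if format == "cls":
        return _read_cls(text)
    if format == "tsv":
        out: dict[str, str] = {}
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"label TSV line {ln!r} lacks two columns")
            out[parts[0]] = parts[1]
        if not out:
            raise ValueError("empty label file")
        return out
    raise ValueError(f"unknown label format {format!r}")


def _looks_cls(text: str) -> bool:
    first = text.lstrip().splitlines()[0].split()
    return len(first) == 3 and all(tok.isdigit() for tok in first)


def _read_cls(text: str) -> dict[str, str]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError("CLS file needs 3 lines")
    n, k_declared, _ = (int(t) for t in lines[0].split())
    names = lines[1].lstrip("#").split()
    idx = [int(t) for t in lines[2].split()]
    if len(idx) != n:
        raise ValueError(f"CLS declares {n} samples but lists {len(idx)} indices")
    used = sorted(set(idx))
    if any(i < 0 or i >= len(names) for i in used):
        raise ValueError("CLS class index out of range")
    if len(used) != k_declared:
        warnings.warn(
            f"CLS declares {k_declared} classes but uses {len(used)}; "
            f"inferring K={len(used)}",
            stacklevel=3,
        )
    return {f"@{j}": names[i] for j, i in enumerate(idx)}


def labels_for_matrix(labels: dict[str, str], m: ExpressionMatrix) -> dict[str, str]:
    """Resolve positional CLS labels (``@j`` keys) against matrix columns."""
    if labels and next(iter(labels)).startswith("@"):
        if len(labels) != m.n_samples:
            raise ValueError(
                f"CLS lists {len(labels)} samples, matrix has {m.n_samples}"
            )
        return {sid: labels[f"@{j}"] for j, sid in enumerate(m.sample_ids)}
    return {s: c for s, c in labels.items() if s in set(m.sample_ids)}


def write_labels(labels: dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for sid in labels:
            fh.write(f"{sid}\t{labels[sid]}\n")


def read_network(path: PathLike) -> CancerMirnaNetwork:
    """Read a cancer-miRNA edge table: ``cancer_type<TAB>mirna[<TAB>direction]``.

    Duplicate edges collapse to one; conflicting up/down direction tags
    collapse to ``mixed``; unknown direction tokens are kept as
    ``unknown`` with a warning. A header line starting with
    ``cancer_type`` is skipped.
    """
    net = CancerMirnaNetwork()
    n_rows = 0
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if lineno == 1 and parts[0].strip().lower() in ("cancer_type", "cancer"):
            continue
        if len(parts) < 2:
            raise ValueError(f"network line {lineno}: fewer than two columns")
        direction = parts[2].strip().lower() if len(parts) > 2 and parts[2].strip() else "unknown"
        if direction not in DIRECTIONS:
            warnings.warn(
                f"network line {lineno}: unknown direction {direction!r}, treating as 'unknown'",
                stacklevel=2,
            )
            direction = "unknown"
        net.add_edge(parts[0], parts[1], direction)
        n_rows += 1
    if n_rows == 0:
        raise ValueError("empty network file")
    return net


def write_network(net: CancerMirnaNetwork, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("cancer_type\tmirna\tdirection\n")
        for (u, v), d in sorted(net.edges.items()):
            fh.write(f"{net.display_name(u)}\t{net.display_name(v)}\t{d}\n")


def write_biclusters(biclusters: list[Bicluster], path: PathLike) -> None:
    """One row per bicluster: score, comma-joined features, comma-joined samples."""
    with open(path, "w") as fh:
        fh.write("score\tfeatures\tsamples\n")
        for b in biclusters:
            fh.write(
                "%.10g\t%s\t%s\n"
                % (b.score, ",".join(sorted(b.features)), ",".join(sorted(b.samples)))
            )


def read_biclusters(path: PathLike) -> list[Bicluster]:
    out = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if lineno == 1 and ln.startswith("score"):
            continue
        if not ln.strip():
            continue
        score, feats, samps = ln.split("\t")
        out.append(Bicluster(frozenset(feats.split(",")), frozenset(samps.split(",")), float(score)))
    return out


# -- model (de)serialization --------------------------------------------
#
# JSON schema:
#   {"format": "sfssclass-usc-model", "version": 1,
#    "selected_features": [...], "class_labels": [...],
#    "shrunken_centroids": [[...]],   # features x classes
#    "overall_centroid": [...], "s_i": [...], "s_0": float,
#    "priors": [...], "delta": float, "rho": float,
#    "standardizer": {feature: [mean, sd], ...} | null}


def save_model(model: UscModel, path: PathLike) -> None:
    doc = {
        "format": "sfssclass-usc-model",
        "version": 1,
        "selected_features": model.selected_features,
        "class_labels": model.class_labels,
        "shrunken_centroids": model.shrunken_centroids.tolist(),
        "overall_centroid": model.overall_centroid.tolist(),
        "s_i": model.s_i.tolist(),
        "s_0": model.s_0,
        "priors": model.priors.tolist(),
        "delta": model.delta,
        "rho": model.rho,
        "standardizer": model.standardizer,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: PathLike) -> UscModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "sfssclass-usc-model":
        raise ValueError("not a sfssclass model file")
    return UscModel(
        selected_features=list(doc["selected_features"]),
        class_labels=list(doc["class_labels"]),
        shrunken_centroids=np.array(doc["shrunken_centroids"], dtype=float),
        overall_centroid=np.array(doc["overall_centroid"], dtype=float),
        s_i=np.array(doc["s_i"], dtype=float),
        s_0=float(doc["s_0"]),
        priors=np.array(doc["priors"], dtype=float),
        delta=float(doc["delta"]),
        rho=float(doc["rho"]),
        standardizer=doc.get("standardizer"),
    )
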