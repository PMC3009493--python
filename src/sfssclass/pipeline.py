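"""End-to-end orchestration: preprocess -> standardize -> bicluster ->
network-guided selection -> cross-validate (delta, rho) -> fit -> predict.

A single config dict (usually loaded from YAML) drives the run; one
top-level seed feeds every source of randomness, so re-running a config
reproduces every artifact byte for byte. Artifacts carry the config
hash and seed that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as sio
from . import usc
from .biclustering import build_graph, discretize, find_biclusters
from .datatypes import Bicluster, CancerMirnaNetwork, CvResult, ExpressionMatrix, UscModel
from .model_selection import (
    DEFAULT_DELTA_GRID,
    DEFAULT_RHO_GRID,
    cross_validate,
    select_params,
)
from .network_selection import SelectionReport, build_training_set
from .preprocess import (
    feature_stats,
    filter_min_expression,
    log2_transform,
    min_count_fraction,
    standardize_features,
)
from .synthetic import make_classification_data, make_network

__all__ = ["run_pipeline", "PipelineResult", "PipelineError", "load_config", "config_hash"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    """In-memory view of everything a pipeline run produced."""

    config: dict
    seed: int
    biclusters: list[Bicluster]
    selection_report: SelectionReport
    cv: CvResult
    delta: float
    rho: float
    model: UscModel
    predictions: list[dict] = field(default_factory=list)
    test_accuracy: Optional[float] = None
    training_matrix: Optional[ExpressionMatrix] = None
    artifacts: dict[str, str] = field(default_factory=dict)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _validate(config: dict) -> None:
    has_sim = "simulate" in config
    data = config.get("data", {})
    if not has_sim:
        for key in ("expression", "labels", "network"):
            if key not in data:
                raise PipelineError(
                    f"config error: data.{key} missing and no 'simulate' block given"
                )


@_stage("load")
def _load_inputs(config: dict, seed: int):
    """Return (train matrix on log2 scale, labels, network, test matrix or None)."""
    if "simulate" in config:
        sim = dict(config["simulate"])
        test_n_k = int(sim.pop("test_n_k", 0))
        coverage = float(sim.pop("coverage", 1.0))
        false_rate = float(sim.pop("false_edge_rate", 0.0))
        params = dict(
            K=int(sim.get("K", 5)),
            p=int(sim.get("p", 100)),
            n_k=int(sim.get("n_k", 20)),
            p_info=int(sim.get("p_info", 5)),
            effect=float(sim.get("effect", 3.0)),
        )
        train, labels, truth = make_classification_data(seed=seed, **params)
        net = make_network(
            truth, coverage=coverage, false_edge_rate=false_rate, seed=seed + 1,
            feature_ids=train.feature_ids,
        )
        test = None
        if test_n_k > 0:
            tparams = dict(params, n_k=test_n_k)
            test, tlabels, _ = make_classification_data(seed=seed + 2, **tparams)
            test = ExpressionMatrix(
                test.feature_ids,
                [f"T{s}" for s in test.sample_ids],
                test.values,
                scale=test.scale,
                labels={f"T{s}": c for s, c in tlabels.items()},
            )
        return train, labels, net, test, truth
    data = config["data"]
    m = sio.read_gct(data["expression"])
    raw_labels = sio.read_labels(data["labels"])
    labels = sio.labels_for_matrix(raw_labels, m)
    net = sio.read_network(data["network"])
    if data.get("scale", "raw") == "raw":
        m = log2_transform(m, floor=float(config.get("preprocess", {}).get("log2_floor", 1.0)))
    else:
        m = ExpressionMatrix(m.feature_ids, m.sample_ids, m.values, scale="log2",
                             feature_meta=m.feature_meta)
    m = m.with_labels(labels)
    test = None
    if "test_expression" in data:
        test = sio.read_gct(data["test_expression"])
        if data.get("scale", "raw") == "raw":
            test = log2_transform(
                test, floor=float(config.get("preprocess", {}).get("log2_floor", 1.0))
            )
        if "test_labels" in data:
            tl = sio.labels_for_matrix(sio.read_labels(data["test_labels"]), test)
            test = test.with_labels(tl)
    return m, labels, net, test, None


@_stage("preprocess")
def _preprocess(m: ExpressionMatrix, config: dict) -> ExpressionMatrix:
    pp = config.get("preprocess", {})
    filt = pp.get("filter")
    if filt:
        cutoff = float(filt["cutoff"])
        if "min_fraction" in filt:
            mc = min_count_fraction(m.n_samples, float(filt["min_fraction"]))
        else:
            mc = int(filt.get("min_count", 1))
        m = filter_min_expression(m, cutoff, mc)
    return m


@_stage("bicluster")
def _bicluster(m_std: ExpressionMatrix, config: dict) -> list[Bicluster]:
    bc = config.get("bicluster", {})
    tm = discretize(m_std, t=float(bc.get("t", 1.0)))
    g = build_graph(tm, p_c=float(bc.get("p_c", 0.9)))
    return find_biclusters(
        g,
        d=int(bc.get("d", 30)),
        k=int(bc.get("k", 3)),
        n_keep=int(bc.get("n_keep", 20)),
        max_overlap=float(bc.get("max_overlap", 0.25)),
    )


@_stage("select")
def _select(biclusters, m, net, labels, config):
    sel = config.get("selection", {})
    return build_training_set(
        biclusters, m, net, labels,
        class_anywhere=bool(sel.get("class_anywhere", False)),
    )


@_stage("cv")
def _cv(train: ExpressionMatrix, config: dict, seed: int) -> CvResult:
    cv_cfg = config.get("cv", {})
    clf = config.get("classifier", {})
    return cross_validate(
        train,
        delta_grid=cv_cfg.get("delta_grid", DEFAULT_DELTA_GRID),
        rho_grid=cv_cfg.get("rho_grid", DEFAULT_RHO_GRID),
        repeats=int(cv_cfg.get("repeats", 10)),
        n_folds=int(cv_cfg.get("n_folds", 4)),
        seed=seed,
        prior_mode=clf.get("prior_mode", "empirical"),
        mk_mode=clf.get("mk_mode", "cv"),
    )


@_stage("train")
def _train(train: ExpressionMatrix, delta: float, rho: float, config: dict) -> UscModel:
    clf = config.get("classifier", {})
    means, sds = feature_stats(train)
    std = {f: (float(mu), float(sd)) for f, mu, sd in zip(train.feature_ids, means, sds)}
    train_std = standardize_features(train, stats=(means, np.where(np.isclose(sds, 0), 1, sds)))
    return usc.fit(
        train_std, delta, rho,
        prior_mode=clf.get("prior_mode", "empirical"),
        mk_mode=clf.get("mk_mode", "cv"),
        standardizer=std,
    )


@_stage("predict")
def _predict(test: ExpressionMatrix, model: UscModel):
    labels, scores, ties = usc.predict_matrix(test, model)
    rows = []
    correct = 0
    n_labeled = 0
    for j, sid in enumerate(test.sample_ids):
        true = (test.labels or {}).get(sid)
        if true is not None:
            n_labeled += 1
            correct += int(labels[j] == true)
        rows.append(
            {
                "sample_id": sid,
                "predicted_class": labels[j],
                "true_class": true,
                "tie": bool(ties[j]),
                "scores": {c: float(scores[j, ci]) for ci, c in enumerate(model.class_labels)},
            }
        )
    acc = correct / n_labeled if n_labeled else None
    return rows, acc


def run_pipeline(config: dict, output_dir: Optional[str] = None) -> PipelineResult:
    """Execute the full flow described by a config dict.

    The config needs either a ``data`` block (expression/labels/network
    paths) or a ``simulate`` block; ``seed`` defaults to 0. When
    ``output_dir`` is given all artifacts are written there.
    """
    _validate(config)
    seed = int(config.get("seed", 0))
    m, labels, net, test, _truth = _load_inputs(config, seed)
    m = _preprocess(m, config)
    m_std = standardize_features(m)
    biclusters = _bicluster(m_std, config)
    reduced, report = _select(biclusters, m, net, labels, config)
    cv = _cv(reduced, config, seed)
    delta, rho = select_params(cv)
    model = _train(reduced, delta, rho, config)
    predictions: list[dict] = []
    accuracy = None
    if test is not None:
        predictions, accuracy = _predict(test, model)
    result = PipelineResult(
        config=config,
        seed=seed,
        biclusters=biclusters,
        selection_report=report,
        cv=cv,
        delta=delta,
        rho=rho,
        model=model,
        predictions=predictions,
        test_accuracy=accuracy,
        training_matrix=reduced,
    )
    if output_dir is not None:
        _write_artifacts(result, Path(output_dir))
    return result


def _write_artifacts(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(res.config)
    stamp = {"config_hash": chash, "seed": res.seed}

    sio.write_biclusters(res.biclusters, outdir / "biclusters.tsv")
    with open(outdir / "selection_report.json", "w") as fh:
        json.dump({**stamp, **res.selection_report.to_dict()}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cv_doc = {
        **stamp,
        "delta_grid": res.cv.delta_grid,
        "rho_grid": res.cv.rho_grid,
        "mean_error": res.cv.mean_error.tolist(),
        "failed": res.cv.failed.tolist(),
        "selected_delta": res.delta,
        "selected_rho": res.rho,
    }
    with open(outdir / "cv_result.json", "w") as fh:
        json.dump(cv_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    sio.save_model(res.model, outdir / "model.json")
    if res.predictions:
        with open(outdir / "predictions.tsv", "w") as fh:
            classes = res.model.class_labels
            fh.write("sample_id\tpredicted_class\ttrue_class\ttie\t"
                     + "\t".join(f"score_{c}" for c in classes) + "\n")
            for row in res.predictions:
                fh.write(
                    "\t".join(
                        [
                            row["sample_id"],
                            row["predicted_class"],
                            str(row["true_class"]),
                            str(int(row["tie"])),
                        ]
                        + ["%.10g" % row["scores"][c] for c in classes]
                    )
                    + "\n"
                )
    log = {
        **stamp,
        "stages": {
            "bicluster": {"n_biclusters": len(res.biclusters)},
            "select": res.selection_report.to_dict(),
            "cv": {"selected_delta": res.delta, "selected_rho": res.rho,
                   "min_mean_error": float(np.min(res.cv.mean_error[~res.cv.failed]))},
            "predict": {"n_predictions": len(res.predictions),
                        "test_accuracy": res.test_accuracy},
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    res.artifacts = {p.name: str(p) for p in sorted(outdir.iterdir())}
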