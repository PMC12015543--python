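"""End-to-end orchestration: cohort -> split -> screen -> graphs ->
train (GCN/GAT/GIN) -> evaluate -> agreement.

A single global seed deterministically derives one sub-seed per stage
(cohort generation, split, per-architecture initialisation, training,
bootstrap), so any stage can be re-run in isolation and two runs with
the same configuration are bit-identical.  Every run writes a manifest
recording the resolved configuration, seeds, input checksum and
per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gnn_core import ModelConfig, save_checkpoint
from .patient_graph import (assemble_graph, cosine_similarity_matrix,
                            export_edge_list, export_node_attributes,
                            fit_scaler, graph_summary)
from .synthetic_cohort import (CohortSpec, LABEL_COLUMN, generate_cohort,
                               read_cohort_csv, split_cohort, validate_cohort,
                               write_cohort_csv)
from .train_eval import (TrainConfig, evaluate, model_agreement, train_model,
                         write_report)
from .univariate_screen import (CANDIDATE_FACTOR_PANEL, screen_features,
                                selected_features, write_screen_csv)

log = logging.getLogger("alngraph")

ARCHITECTURES = ("gcn", "gat", "gin")

#: derivation order of per-stage seeds from the global seed
SEED_STAGES = ("cohort", "split", "init_gcn", "init_gat", "init_gin",
               "train", "bootstrap")


class PipelineConfigError(ValueError):
    pass


def derive_stage_seeds(global_seed: int) -> dict:
    """Stable per-stage sub-seeds (all below 2**31)."""
    state = np.random.SeedSequence(global_seed).generate_state(len(SEED_STAGES))
    return {stage: int(s % (2 ** 31)) for stage, s in zip(SEED_STAGES, state)}


@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run.

    `factor_mode` controls candidate-factor selection: "panel" uses the
    fixed ten-factor panel (size, location, eight axillary-US terms) —
    the reproduction default; "screen" re-derives the set from the
    univariate p-values at `alpha`; an explicit list can also be given.
    """

    mode: str = "synthetic"                  # "synthetic" | "csv"
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    csv_path: str | None = None
    split_ratio: float = 0.8
    stratified: bool = True
    alpha: float = 0.05
    factor_mode: str | list = "panel"
    tau: float = 0.95
    architectures: tuple = ARCHITECTURES
    hidden_dim: int = 16
    n_layers: int = 2
    activation: str = "relu"
    dropout: float = 0.0
    epochs: int = 1000
    lr: float = 1e-4
    batch_size: int | None = None
    n_boot: int = 2000
    outdir: str = "alngraph_run"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise PipelineConfigError(f"unknown input mode {self.mode!r}")
        if self.mode == "csv":
            if not self.csv_path:
                raise PipelineConfigError("csv mode requires csv_path")
            if not Path(self.csv_path).exists():
                raise PipelineConfigError(f"cohort file not found: {self.csv_path}")
        unknown = set(self.architectures) - set(ARCHITECTURES)
        if unknown:
            raise PipelineConfigError(f"unknown architectures: {sorted(unknown)}")
        if isinstance(self.factor_mode, str) and self.factor_mode not in ("panel", "screen"):
            raise PipelineConfigError(
                "factor_mode must be 'panel', 'screen', or an explicit feature list")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["architectures"] = list(self.architectures)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cohort_spec" in raw and isinstance(raw["cohort_spec"], dict):
            raw["cohort_spec"] = CohortSpec(**raw["cohort_spec"])
        if "architectures" in raw:
            raw["architectures"] = tuple(raw["architectures"])
        return cls(**raw)


def validate_cohort_csv(path) -> dict:
    """Schema report for a cohort CSV: header, types, binary domains,
    ordinal ranges, patient_id uniqueness."""
    table = pd.read_csv(path)
    issues = validate_cohort(table)
    return {"path": str(path), "n_rows": len(table),
            "passed": not issues, "issues": issues}


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under config.outdir.

    Returns the run manifest (also written as manifest.json).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["architectures"] = list(config.architectures)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "seeds": seeds,
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "complete": False,
    }

    def checkpoint_manifest():
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    checkpoint_manifest()

    # ---- cohort -----------------------------------------------------
    if config.mode == "synthetic":
        spec = dataclasses.replace(config.cohort_spec, seed=seeds["cohort"])
        cohort = generate_cohort(spec)
        cohort_path = outdir / "cohort.csv"
        write_cohort_csv(cohort, cohort_path)
    else:
        cohort_path = Path(config.csv_path)
        cohort = read_cohort_csv(cohort_path)
    manifest["input_checksum"] = _file_sha256(cohort_path)
    manifest["stages"]["cohort"] = {
        "n_patients": len(cohort),
        "n_positive": int(cohort[LABEL_COLUMN].sum()),
    }
    log.info("cohort: %d patients, %d with metastasis", len(cohort),
             int(cohort[LABEL_COLUMN].sum()))

    # ---- split ------------------------------------------------------
    train_tab, test_tab = split_cohort(cohort, ratio=config.split_ratio,
                                       stratified=config.stratified,
                                       seed=seeds["split"])
    write_cohort_csv(train_tab, outdir / "train_cohort.csv")
    write_cohort_csv(test_tab, outdir / "test_cohort.csv")
    manifest["stages"]["split"] = {"n_train": len(train_tab), "n_test": len(test_tab)}
    log.info("split: %d train / %d test", len(train_tab), len(test_tab))

    # ---- univariate screen -----------------------------------------
    include = None
    if config.factor_mode == "panel":
        include = list(CANDIDATE_FACTOR_PANEL)
    elif isinstance(config.factor_mode, (list, tuple)):
        include = list(config.factor_mode)
    screen = screen_features(train_tab, alpha=config.alpha, include=include)
    write_screen_csv(screen, outdir / "screen.csv")
    factors = selected_features(screen)
    # a selected feature can still be constant in the realised training
    # cohort (rare findings at small n); it carries no contrast and is
    # dropped before scaling, as a degenerate screen row would be
    constant = [f for f in factors if train_tab[f].nunique() <= 1]
    factors = [f for f in factors if f not in constant]
    if constant:
        log.warning("dropping zero-variance candidate factor(s): %s", constant)
    if not factors:
        raise PipelineConfigError("screening selected no usable features")
    manifest["stages"]["screen"] = {"n_features": len(screen),
                                    "n_selected": len(factors),
                                    "selected": factors,
                                    "dropped_constant": constant}
    log.info("screen: %d of %d features selected", len(factors), len(screen))

    # ---- graphs -----------------------------------------------------
    scaler = fit_scaler(train_tab[factors].to_numpy(float), factors)
    graphs = {}
    for name, tab in (("train", train_tab), ("test", test_tab)):
        g = assemble_graph(tab, factors, scaler, tau=config.tau)
        S = cosine_similarity_matrix(g.X) if g.n_nodes > 1 else np.ones((1, 1))
        export_edge_list(g, S, outdir / f"{name}_edges.tsv")
        export_node_attributes(g, outdir / f"{name}_nodes.csv")
        summary = graph_summary(g)
        manifest["stages"][f"graph_{name}"] = summary
        log.info("%s graph: %d nodes, %d edges, %d components", name,
                 summary["n_nodes"], summary["n_edges"], summary["n_components"])
        graphs[name] = g

    # ---- train + evaluate per architecture --------------------------
    reports = {}
    for arch in config.architectures:
        mc = ModelConfig(architecture=arch, n_layers=config.n_layers,
                         hidden_dim=config.hidden_dim,
                         activation=config.activation, dropout=config.dropout,
                         init_seed=seeds[f"init_{arch}"])
        tc = TrainConfig(epochs=config.epochs, lr=config.lr,
                         batch_size=config.batch_size, seed=seeds["train"])
        t0 = time.time()
        params, history = train_model(graphs["train"], mc, tc)
        save_checkpoint(outdir / f"{arch}_checkpoint.json", params, mc)
        pd.DataFrame({"epoch": np.arange(len(history)), "loss": history}).to_csv(
            outdir / f"{arch}_loss.csv", index=False)
        report = evaluate(graphs["test"], params, mc, n_boot=config.n_boot,
                          seed=seeds["bootstrap"])
        write_report(report, outdir, f"{arch}_test")
        train_report = evaluate(graphs["train"], params, mc,
                                n_boot=config.n_boot, seed=seeds["bootstrap"])
        write_report(train_report, outdir, f"{arch}_train")
        reports[arch] = report
        manifest["stages"][f"train_{arch}"] = {
            "epochs": len(history),
            "final_loss": float(history[-1]),
            "seconds": round(time.time() - t0, 2),
            "test_auc": round(float(report.auc), 4),
            "test_acc": round(float(report.metrics["acc"]), 4),
        }
        log.info("%s: final loss %.4f, test AUC %.3f, test ACC %.3f", arch,
                 history[-1], report.auc, report.metrics["acc"])

    # ---- combined metrics table and agreement matrix ----------------
    rows = []
    for arch, rep in reports.items():
        rows.append({"model": arch, **{k: round(v, 6) for k, v in rep.metrics.items()},
                     "auc": round(rep.auc, 6), "auc_ci_low": round(rep.auc_ci_low, 6),
                     "auc_ci_high": round(rep.auc_ci_high, 6)})
    pd.DataFrame(rows).to_csv(outdir / "metrics_summary.csv", index=False)

    archs = list(reports)
    agree = pd.DataFrame(np.eye(len(archs)), index=archs, columns=archs)
    for i, a in enumerate(archs):
        for j, b in enumerate(archs):
            if i < j:
                try:
                    phi = model_agreement(reports[a].predictions,
                                          reports[b].predictions)
                except Exception:
                    phi = float("nan")
                agree.loc[a, b] = agree.loc[b, a] = round(phi, 6)
    agree.to_csv(outdir / "agreement_matrix.csv")
    manifest["agreement"] = {f"{a}_{b}": float(agree.loc[a, b])
                             for i, a in enumerate(archs)
                             for j, b in enumerate(archs) if i < j}

    manifest["complete"] = True
    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    checkpoint_manifest()
    return manifest
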