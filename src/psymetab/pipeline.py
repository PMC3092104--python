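"""End-to-end orchestration: simulate -> cluster -> stats -> lmm ->
network -> diagnose, with one master seed, per-stage derived seeds,
stable file contracts and a run manifest.

Per-stage seeds are derived by hashing (master seed, stage name), so
enabling or disabling one stage does not shift another stage's random
stream.  Rerunning with the same config and seed reproduces every output
bit-identically; the manifest records parameters, seeds and output
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, diagnostic, lmm as lmm_mod, network as net_mod, stats as stats_mod
from . import synthetic

log = logging.getLogger("psymetab")

STAGES = ("simulate", "cluster", "stats", "lmm", "network", "diagnose")


def stage_seed(master_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    outdir: str = "psymetab_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # inputs (used when simulate is disabled)
    cohort_path: str | None = None
    lipid_path: str | None = None
    polar_path: str | None = None
    # simulate
    group_sizes: dict | None = None
    # cluster
    kmin: int = 4
    kmax: int = 15
    families: tuple = clustering.DEFAULT_FAMILIES
    n_init: int = 5
    # network
    beta: float = 0.25
    alpha: float = 0.05
    n_subsets_per_q: int = 500
    q_levels: tuple | None = None
    # diagnose
    cv_runs: int = 10_000
    train_frac: float = 2.0 / 3.0
    markers: tuple = diagnostic.DEFAULT_MARKERS
    # lmm
    lmm_alpha: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(raw.get("stages"), dict):
            stages = {s: True for s in STAGES}
            stages.update(raw["stages"])
            cfg.stages = stages
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_features(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the run
    manifest.  A stage failure aborts the run, naming the stage, after
    persisting the partial manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "outputs": {},
                "parameters": {k: v for k, v in asdict(config).items()
                               if k not in ("stages",)}}
    state: dict = {}

    def record(stage: str, outputs: dict[str, Path]):
        manifest["stages"].append(stage)
        for name, path in outputs.items():
            manifest["outputs"][f"{stage}:{name}"] = {
                "path": str(path), "sha256": _sha256(Path(path))}

    def persist():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        seed = stage_seed(config.seed, stage)
        log.info("[%s] starting (seed=%d)", stage, seed)
        try:
            outputs = _STAGE_FUNCS[stage](config, state, seed, outdir)
        except Exception as exc:
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            persist()
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, outputs)
        persist()
    return manifest


def _load_inputs(config: RunConfig, state: dict):
    if "cohort" not in state:
        if config.cohort_path is None:
            raise ValueError("no cohort available: enable simulate or set cohort_path")
        state["cohort"] = pd.read_csv(config.cohort_path)
        state["lipid"] = _read_features(config.lipid_path) if config.lipid_path else None
        state["polar"] = _read_features(config.polar_path) if config.polar_path else None


def _stage_simulate(config: RunConfig, state: dict, seed: int, outdir: Path):
    cc = synthetic.CohortConfig(seed=seed) if config.group_sizes is None else \
        synthetic.CohortConfig(group_sizes=config.group_sizes, seed=seed)
    study = synthetic.generate_study(cc)
    state["study"] = study
    state["cohort"] = study.cohort
    state["lipid"] = study.lipid_features
    state["polar"] = study.polar_features
    return synthetic.write_study(study, outdir)


def _stage_cluster(config: RunConfig, state: dict, seed: int, outdir: Path):
    _load_inputs(config, state)
    outputs = {}
    score_blocks = []
    for platform, prefix in (("lipid", "LC"), ("polar", "MC")):
        feats = state.get(platform)
        if feats is None:
            continue
        scaled = clustering.standardize(feats)
        assignment = clustering.select_model(
            scaled, k_range=range(config.kmin, config.kmax + 1),
            families=config.families, seed=seed, n_init=config.n_init)
        named = assignment.labels.map(lambda l: f"{prefix}{l + 1}")
        scores = clustering.cluster_scores(feats, named)
        state[f"assignment_{platform}"] = assignment
        score_blocks.append(scores.scores)
        a_path = outdir / f"assignment_{platform}.csv"
        named.rename("cluster").rename_axis("feature_id").to_csv(a_path)
        b_path = outdir / f"bic_{platform}.csv"
        assignment.bic_table.to_csv(b_path, index=False)
        outputs[f"assignment_{platform}"] = a_path
        outputs[f"bic_{platform}"] = b_path
    state["scores"] = pd.concat(score_blocks, axis=1)
    s_path = outdir / "scores.csv"
    state["scores"].rename_axis("subject_id").to_csv(s_path)
    outputs["scores"] = s_path
    return outputs


def _require_scores(config: RunConfig, state: dict):
    if "scores" not in state:
        path = Path(config.outdir) / "scores.csv"
        if not path.exists():
            raise ValueError("no cluster scores available: run the cluster stage first")
        state["scores"] = pd.read_csv(path, index_col=0)


def _stage_stats(config: RunConfig, state: dict, seed: int, outdir: Path):
    _load_inputs(config, state)
    _require_scores(config, state)
    table1 = stats_mod.table1_summary(state["cohort"])
    groups = stats_mod.diagnostic_groups(state["cohort"])
    scores = clustering.ClusterScoreMatrix(scores=state["scores"])
    anova = stats_mod.anova_cluster_profiles(scores, groups)
    t_path, a_path = outdir / "table1.csv", outdir / "anova.csv"
    table1.to_csv(t_path)
    anova.to_csv(a_path)
    return {"table1": t_path, "anova": a_path}


def _stage_lmm(config: RunConfig, state: dict, seed: int, outdir: Path):
    _load_inputs(config, state)
    _require_scores(config, state)
    scores = clustering.ClusterScoreMatrix(scores=state["scores"])
    spec = lmm_mod.LmmSpec()
    fits = lmm_mod.fit_all_clusters(state["cohort"], scores, spec)
    full = lmm_mod.lmm_report(fits, alpha=config.lmm_alpha)
    sens = lmm_mod.sensitivity_excluding_t2d(state["cohort"], scores, spec,
                                             alpha=config.lmm_alpha)
    f_path, s_path = outdir / "lmm_full.csv", outdir / "lmm_sensitivity.csv"
    full.to_csv(f_path, index=False)
    sens.to_csv(s_path, index=False)
    return {"full": f_path, "sensitivity": s_path}


def _stage_network(config: RunConfig, state: dict, seed: int, outdir: Path):
    _load_inputs(config, state)
    _require_scores(config, state)
    scores = clustering.ClusterScoreMatrix(scores=state["scores"])
    vars_ = net_mod.assemble_variables(state["cohort"], scores.log_scores)
    reg = net_mod.regulation_directions(state["cohort"], vars_)
    graph = net_mod.build_network(
        vars_, beta=config.beta,
        q_levels=list(config.q_levels) if config.q_levels else None,
        n_subsets_per_q=config.n_subsets_per_q, alpha=config.alpha,
        seed=seed, regulation=reg)
    return graph.write(outdir)


def _stage_diagnose(config: RunConfig, state: dict, seed: int, outdir: Path):
    _load_inputs(config, state)
    labels = diagnostic.pool_psychoses(state["cohort"])
    if "study" in state:
        panel = diagnostic.marker_panel_from_study(state["study"], config.markers)
    else:
        cols = {}
        for m in config.markers:
            for source in (state["cohort"].set_index("subject_id"),
                           state.get("lipid"), state.get("polar")):
                if source is not None and m in source.columns:
                    cols[m] = source[m]
                    break
            else:
                raise ValueError(f"marker {m!r} not found in inputs")
        panel = diagnostic.MarkerPanel(pd.DataFrame(cols))
    panel = diagnostic.MarkerPanel(panel.values.loc[labels.index])
    report = diagnostic.run_cv(panel, labels, n_runs=config.cv_runs,
                               train_frac=config.train_frac, seed=seed)
    r_path = outdir / "cv_report.json"
    r_path.write_text(json.dumps({
        "n_runs": report.n_runs,
        "train_size": report.train_size,
        "test_size": report.test_size,
        "n_resampled": report.n_resampled,
        "header": report.header,
        "selection_frequency": report.selection_frequency.to_dict(),
        "summaries": report.summaries.round(6).to_dict(),
    }, indent=1))
    # ROC points of the modal model refit on the full pooled-psychosis sample
    from sklearn.metrics import roc_curve
    X = diagnostic._prepare_panel(panel, True, True)
    subset = list(report.modal_subset)
    fit = diagnostic.fit_logistic(X[subset].to_numpy() if subset
                                  else np.empty((len(labels), 0)),
                                  labels.to_numpy(), markers=subset)
    probs = fit.predict(X[subset].to_numpy() if subset else np.empty((len(labels), 0)))
    fpr, tpr, thr = roc_curve(labels.to_numpy(), probs)
    roc_path = outdir / "roc_points.csv"
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(roc_path, index=False)
    return {"cv_report": r_path, "roc_points": roc_path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cluster": _stage_cluster,
    "stats": _stage_stats,
    "lmm": _stage_lmm,
    "network": _stage_network,
    "diagnose": _stage_diagnose,
}
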