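"""Cross-validated metabolite diagnostic model for schizophrenia.

Discriminates schizophrenia cases from the pooled other psychoses (ONAP +
affective) with logistic regression over a small candidate marker panel.
Inside each of many repeated random train/test splits (139 -> 93 train /
46 test by default), the marker subset is chosen by bidirectional
stepwise selection on AIC; the selected model is applied to the held-out
test set, recording the subset, ROC AUC, odds ratio and relative risk.
Selection frequencies and mean (5th, 95th percentile) metric summaries
are aggregated over runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

DEFAULT_MARKERS = ("insulin", "tg_18_1_18_0_18_1", "isoleucine", "proline")
SEPARATION_GUARD = 15.0


@dataclass
class MarkerPanel:
    """Per-subject candidate marker values (rows = subjects)."""

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.shape[1] < 1:
            raise ValueError("panel needs at least one marker")

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)


def pool_psychoses(cohort: pd.DataFrame) -> pd.Series:
    """Binary labels over cases only: 1 = schizophrenia, 0 = other
    psychoses (controls excluded); indexed by subject id."""
    cases = cohort[cohort["role"] == "case"]
    for stratum in ("schizophrenia", "onap", "affective"):
        if not (cases["stratum"] == stratum).any():
            raise ValueError(f"no cases in stratum {stratum!r}")
    y = (cases["stratum"] == "schizophrenia").astype(int)
    return pd.Series(y.to_numpy(), index=cases["subject_id"].to_numpy(), name="label")


@dataclass
class LogisticFit:
    markers: list[str]
    params: np.ndarray            # intercept first
    log_likelihood: float
    aic: float
    converged: bool
    separation: bool
    model: object = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.params[0] + X @ self.params[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(X: np.ndarray, y: np.ndarray, markers: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS (tolerance 1e-8,
    at most 100 iterations), with quasi-separation flagged when any
    coefficient magnitude exceeds the guard on standardized inputs."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and X.shape[1] == len(y):
        X = X.T
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    if X.shape[1] and np.any(X.std(axis=0) == 0):
        raise ValueError("all-constant predictor column")
    design = sm.add_constant(X, has_constant="add") if X.shape[1] else np.ones((len(y), 1))
    res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
        maxiter=100, tol=1e-8)
    params = np.asarray(res.params, float)
    sep = bool(np.any(np.abs(params[1:]) > SEPARATION_GUARD)) if len(params) > 1 else False
    ll = float(res.llf)
    k = len(params)
    return LogisticFit(markers=list(markers or []), params=params,
                       log_likelihood=ll, aic=-2.0 * ll + 2.0 * k,
                       converged=bool(res.converged), separation=sep, model=res)


def stepwise_aic(X: pd.DataFrame, y: np.ndarray,
                 candidates: list[str] | None = None) -> tuple[list[str], LogisticFit]:
    """Bidirectional stepwise selection from the intercept-only model.

    At each step the single add/drop move that most decreases AIC is
    applied; selection stops when no move improves.  Ties break by
    marker-name order, so the procedure is deterministic.
    """
    candidates = sorted(candidates if candidates is not None else X.columns)
    if not candidates:
        raise ValueError("need at least one candidate marker")
    current: list[str] = []

    def fit(subset: list[str]) -> LogisticFit:
        return fit_logistic(X[subset].to_numpy() if subset else np.empty((len(y), 0)),
                            y, markers=subset)

    best_fit = fit(current)
    while True:
        moves = []
        for m in candidates:
            if m not in current:
                moves.append(sorted(current + [m]))
        for m in current:
            moves.append([x for x in current if x != m])
        improved = None
        for subset in moves:
            f = fit(subset)
            if f.aic < best_fit.aic - 1e-12:
                if improved is None or f.aic < improved[1].aic - 1e-12:
                    improved = (subset, f)
        if improved is None:
            return current, best_fit
        current, best_fit = improved


def roc_auc(scores, labels) -> float:
    """AUC = (concordant pairs + half the ties) / (n1 * n0)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def or_rr(pred_probs, labels, cutoff: float = 0.5) -> tuple[float, float]:
    """Odds ratio and relative risk of the dichotomized classification.

    Cells are TP/FP/FN/TN at the probability cutoff; the Haldane-Anscombe
    +0.5 correction is applied to every cell whenever any cell is zero.
    """
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(pred_probs, float) >= cutoff
    tp = float(np.sum(pred & labels))
    fp = float(np.sum(pred & ~labels))
    fn = float(np.sum(~pred & labels))
    tn = float(np.sum(~pred & ~labels))
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    odds = (tp * tn) / (fp * fn)
    rr = (tp / (tp + fp)) / (fn / (fn + tn))
    return float(odds), float(rr)


@dataclass
class CvReport:
    n_runs: int
    train_size: int
    test_size: int
    selection_frequency: pd.Series        # "marker + marker" string -> frequency
    runs: pd.DataFrame                    # per-run auc, odds_ratio, relative_risk
    summaries: pd.DataFrame               # mean, p5, p95 per metric
    n_resampled: int
    header: dict = field(default_factory=dict)

    @property
    def modal_subset(self) -> tuple:
        key = self.selection_frequency.index[0]
        return tuple() if key == "(intercept only)" else tuple(key.split(" + "))


def _prepare_panel(panel: MarkerPanel, log_transform: bool, standardize: bool) -> pd.DataFrame:
    X = panel.values.astype(float)
    if log_transform:
        if (X <= 0).any().any():
            raise ValueError("non-positive marker values cannot be log-transformed")
        X = np.log(X)
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0)
    return X


def run_cv(panel: MarkerPanel, labels: pd.Series, n_runs: int = 10_000,
           train_frac: float = 2.0 / 3.0, seed: int = 0,
           log_transform: bool = True, standardize: bool = True,
           cutoff: float = 0.5) -> CvReport:
    """Repeated random-split cross-validation with stepwise-AIC selection.

    Splits are simple random at ``train_frac`` (139 subjects -> 93 train /
    46 test).  A run whose test set lacks a class is resampled (and
    counted).  Deterministic given the seed.
    """
    X = _prepare_panel(panel, log_transform, standardize).loc[labels.index]
    y = labels.to_numpy(int)
    n = len(y)
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("need at least 10 subjects per class")
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    sel_counts: dict[tuple, int] = {}
    rows = []
    n_resampled = 0
    for _ in range(n_runs):
        while True:
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
            n_resampled += 1
        subset, fit = stepwise_aic(X.iloc[tr], y[tr])
        key = " + ".join(subset) if subset else "(intercept only)"
        sel_counts[key] = sel_counts.get(key, 0) + 1
        probs = fit.predict(X.iloc[te][subset].to_numpy() if subset
                            else np.empty((len(te), 0)))
        auc = roc_auc(probs, y[te]) if subset else 0.5
        odds, rr = or_rr(probs, y[te], cutoff=cutoff)
        rows.append({"subset": key, "auc": auc, "odds_ratio": odds,
                     "relative_risk": rr})
    runs = pd.DataFrame(rows)
    freq = (pd.Series(sel_counts, dtype=float) / n_runs).sort_values(ascending=False)
    summaries = pd.DataFrame({
        m: {"mean": runs[m].mean(),
            "p5": runs[m].quantile(0.05),
            "p95": runs[m].quantile(0.95)}
        for m in ("auc", "odds_ratio", "relative_risk")}).T
    if n_resampled:
        log.info("resampled %d degenerate splits", n_resampled)
    return CvReport(
        n_runs=n_runs, train_size=n_train, test_size=n - n_train,
        selection_frequency=freq, runs=runs, summaries=summaries,
        n_resampled=n_resampled,
        header={"stepwise": "bidirectional from intercept-only, AIC",
                "split": "simple random (unstratified)",
                "cutoff": cutoff, "log_transform": log_transform,
                "standardize": standardize, "seed": seed})


def marker_panel_from_study(study, markers=DEFAULT_MARKERS) -> MarkerPanel:
    """Assemble the default panel from a synthetic study: insulin from the
    cohort plus the designated marker features of LC9/MC3/MC5."""
    cohort = study.cohort
    idx = cohort["subject_id"].to_numpy()
    cols = {}
    truth_markers = study.truth.get("markers", {})
    for m in markers:
        if m in cohort.columns:
            cols[m] = cohort.set_index("subject_id")[m].reindex(idx).astype(float)
        elif m in truth_markers:
            fid = truth_markers[m]
            mat = study.lipid_features if fid in getattr(study.lipid_features, "columns", []) \
                else study.polar_features
            cols[m] = mat[fid].reindex(idx).astype(float)
        else:
            raise ValueError(f"marker {m!r} not found in cohort or truth markers")
    return MarkerPanel(values=pd.DataFrame(cols, index=idx))
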