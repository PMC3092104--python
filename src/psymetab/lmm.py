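"""Matched-pair random-intercept linear mixed models per metabolite cluster.

The response is the natural log of a cluster score; fixed effects are the
three diagnosis indicators (against a pooled-control baseline), current
antipsychotic use, metabolic comorbidity, four diet flags and fasting
time; a random intercept per matched pair absorbs the shared environment
of case and control.  Estimation is REML with the variance ratio
theta = sigma2_pair / sigma2_resid profiled out and optimized numerically;
this is exact for the single random-intercept structure because every
pair's covariance block is I + theta * J with closed-form inverse and
determinant.

t statistics use containment-style residual degrees of freedom
n_obs - rank(X) - n_pairs + 1 (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .clustering import ClusterScoreMatrix

log = logging.getLogger(__name__)

DEFAULT_FIXED_EFFECTS = (
    "schizophrenia", "onap", "affective",
    "antipsychotic_current", "metabolic_comorbidity",
    "diet_vegetables", "diet_high_fat_milk", "diet_vegetable_oils",
    "diet_high_fat_cheese", "fasting_time",
)

THETA_MAX = 1e4


@dataclass
class LmmSpec:
    fixed_effects: tuple = DEFAULT_FIXED_EFFECTS
    log_response: bool = True
    df_method: str = "containment"   # or 'residual' (n - rank(X))
    min_pairs: int = 10


@dataclass
class LmmFit:
    effects: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: float
    sigma2_pair: float
    sigma2_resid: float
    theta: float
    reml_loglik: float
    converged: bool
    n_obs: int
    n_pairs: int
    n_dropped: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se, "t": self.t,
                             "p": self.p}, index=self.effects)


def _group_blocks(pair_codes: np.ndarray):
    order = np.argsort(pair_codes, kind="stable")
    codes = pair_codes[order]
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    ends = np.r_[starts[1:], len(codes)]
    return [order[s:e] for s, e in zip(starts, ends)]


def reml_profile(y: np.ndarray, X: np.ndarray, pair_codes: np.ndarray):
    """Return (objective, solve) where objective(theta) is the negative
    profiled REML log-likelihood and solve(theta) the GLS quantities."""
    n, p = X.shape
    blocks = _group_blocks(pair_codes)

    def components(theta: float):
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdetV = 0.0
        for idx in blocks:
            Xg, yg = X[idx], y[idx]
            m = len(idx)
            c = theta / (1.0 + m * theta)
            sx, sy = Xg.sum(axis=0), yg.sum()
            XtWX += Xg.T @ Xg - c * np.outer(sx, sx)
            XtWy += Xg.T @ yg - c * sx * sy
            ytWy += yg @ yg - c * sy * sy
            logdetV += np.log1p(m * theta)
        return XtWX, XtWy, ytWy, logdetV

    def solve(theta: float):
        XtWX, XtWy, ytWy, logdetV = components(theta)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = float(ytWy - beta @ XtWy)  # r' V^-1 r at the GLS solution
        sigma2 = max(rss / (n - p), 1e-300)
        sign, logdetXWX = np.linalg.slogdet(XtWX)
        reml = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                       + logdetV + logdetXWX)
        return beta, sigma2, XtWX, reml

    def objective(theta: float) -> float:
        return -solve(theta)[3]

    return objective, solve


def fit_lmm_arrays(y: np.ndarray, X: np.ndarray, pair_codes: np.ndarray,
                   effects: list[str], df_method: str = "containment",
                   n_dropped: int = 0) -> LmmFit:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        aliased = _aliased_columns(X, effects)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    objective, solve = reml_profile(y, X, pair_codes)
    # optimize theta on a log-ish grid-bracketed bounded search; theta = 0
    # (no pair variance) is a valid boundary solution
    res = optimize.minimize_scalar(lambda u: objective(np.expm1(u)),
                                   bounds=(0.0, np.log1p(THETA_MAX)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    theta = float(np.expm1(res.x))
    if objective(0.0) <= res.fun:
        theta = 0.0
    beta, sigma2, XtWX, reml = solve(theta)
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    n_pairs = len(np.unique(pair_codes))
    df = (n - rank - n_pairs + 1) if df_method == "containment" else (n - rank)
    df = max(df, 1)
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    return LmmFit(effects=effects, beta=beta, se=se, t=t, p=pvals, df=df,
                  sigma2_pair=theta * sigma2, sigma2_resid=sigma2, theta=theta,
                  reml_loglik=reml, converged=bool(res.success),
                  n_obs=n, n_pairs=n_pairs, n_dropped=n_dropped)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            aliased.append(name)
        else:
            kept = cand
    return aliased


def design_matrix(cohort: pd.DataFrame, fixed_effects=DEFAULT_FIXED_EFFECTS):
    """Intercept + fixed-effect columns; diagnosis indicators are 1 for
    cases of the given stratum, 0 otherwise."""
    cols = {"intercept": np.ones(len(cohort))}
    for eff in fixed_effects:
        if eff in ("schizophrenia", "onap", "affective"):
            cols[eff] = ((cohort["stratum"] == eff)
                         & (cohort["role"] == "case")).to_numpy(float)
        elif eff in cohort.columns:
            cols[eff] = pd.to_numeric(cohort[eff], errors="coerce").to_numpy(float)
        else:
            raise ValueError(f"fixed effect {eff!r} not in cohort table")
    return pd.DataFrame(cols, index=cohort["subject_id"].to_numpy())


def fit_lmm(spec: LmmSpec, cohort: pd.DataFrame,
            scores: ClusterScoreMatrix | pd.DataFrame, cluster) -> LmmFit:
    """Fit the matched-pair mixed model for one cluster (complete cases)."""
    score_df = scores.scores if isinstance(scores, ClusterScoreMatrix) else scores
    y = score_df[cluster].reindex(cohort["subject_id"]).to_numpy(float)
    if spec.log_response:
        if np.nanmin(y) <= 0:
            raise ValueError(f"cluster {cluster!r} has non-positive scores; cannot log")
        y = np.log(y)
    Xdf = design_matrix(cohort, spec.fixed_effects)
    X = Xdf.to_numpy(float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("cluster %s: dropped %d incomplete rows", cluster, n_dropped)
    pair_codes = cohort["pair_id"].astype("category").cat.codes.to_numpy()[ok]
    n_complete_pairs = pd.Series(pair_codes).value_counts().ge(2).sum()
    if n_complete_pairs < spec.min_pairs:
        raise ValueError(f"only {n_complete_pairs} complete pairs (< {spec.min_pairs})")
    return fit_lmm_arrays(y[ok], X[ok], pair_codes, list(Xdf.columns),
                          df_method=spec.df_method, n_dropped=n_dropped)


def fit_all_clusters(cohort: pd.DataFrame, scores: ClusterScoreMatrix | pd.DataFrame,
                     spec: LmmSpec | None = None) -> dict:
    spec = spec or LmmSpec()
    score_df = scores.scores if isinstance(scores, ClusterScoreMatrix) else scores
    return {cl: fit_lmm(spec, cohort, scores, cl) for cl in score_df.columns}


def lmm_report(fits: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster significant-predictor table.

    One row per fixed effect with p < alpha (direction = sign of beta);
    clusters with no significant effect get a single 'None' row.
    """
    rows = []
    for cluster, fit in fits.items():
        any_sig = False
        for i, eff in enumerate(fit.effects):
            if eff == "intercept":
                continue
            if fit.p[i] < alpha:
                any_sig = True
                rows.append({"cluster": cluster, "effect": eff,
                             "beta": fit.beta[i], "se": fit.se[i],
                             "t": fit.t[i], "p": fit.p[i],
                             "direction": "up" if fit.beta[i] > 0 else "down"})
        if not any_sig:
            rows.append({"cluster": cluster, "effect": "None", "beta": np.nan,
                         "se": np.nan, "t": np.nan, "p": np.nan, "direction": ""})
    return pd.DataFrame(rows, columns=["cluster", "effect", "beta", "se", "t",
                                       "p", "direction"])


def sensitivity_excluding_t2d(cohort: pd.DataFrame,
                              scores: ClusterScoreMatrix | pd.DataFrame,
                              spec: LmmSpec | None = None,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Refit all clusters after dropping every pair in which either member
    has type 2 diabetes; returns the same report shape (retained pair
    count in ``report.attrs['n_pairs_retained']``)."""
    spec = spec or LmmSpec()
    t2d_pairs = set(cohort.loc[cohort["t2d"].astype(bool), "pair_id"])
    kept = cohort[~cohort["pair_id"].isin(t2d_pairs)].reset_index(drop=True)
    n_pairs = kept["pair_id"].nunique()
    if n_pairs < spec.min_pairs:
        raise ValueError(f"only {n_pairs} pairs remain after T2D exclusion")
    report = lmm_report(fit_all_clusters(kept, scores, spec), alpha=alpha)
    report.attrs["n_pairs_retained"] = int(n_pairs)
    report.attrs["n_pairs_excluded"] = int(cohort["pair_id"].nunique() - n_pairs)
    return report
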