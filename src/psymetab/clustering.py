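"""Model-based clustering of metabolite features.

Features (not subjects) are the observations: each metabolite's
standardized profile across subjects is a point in subject-space, and
finite Gaussian mixtures group metabolites with similar profiles.  Model
selection maximizes BIC = 2*loglik - m*ln(N) over a grid of component
counts and covariance parameterizations.

Because the dimension (number of subjects) typically rivals or exceeds the
number of features, the default covariance families are the four
spherical/diagonal parameterizations (equal or varying across
components); full-covariance families are accepted only when the dimension
is strictly below the observation count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

DEFAULT_FAMILIES = (
    "spherical-equal",     # one variance shared by all components (EII)
    "spherical-varying",   # one variance per component (VII)
    "diagonal-equal",      # one diagonal shared by all components (EEI)
    "diagonal-varying",    # a diagonal per component (VVI)
)
FULL_FAMILIES = ("full-equal", "full-varying")

_LOG2PI = np.log(2.0 * np.pi)
#: relative variance floor: fraction of the data's mean per-dimension
#: variance; prevents singleton components from collapsing to degenerate,
#: likelihood-dominating spikes
_VAR_FLOOR_FRAC = 1e-3


@dataclass
class ScaledMatrix:
    """Features x subjects matrix with per-feature mean 0 / unit variance
    (sample convention, ddof=1), plus the scaling constants for inversion."""

    values: np.ndarray            # (n_features, n_subjects)
    feature_ids: list[str]
    subject_ids: list[str]
    means: np.ndarray
    sds: np.ndarray


def standardize(features: pd.DataFrame) -> ScaledMatrix:
    """Scale each feature's profile across subjects to zero mean and unit
    variance (sample SD, ddof=1, so the profile (2, 4, 6) maps exactly to
    (-1, 0, 1)).

    ``features`` is subjects x features.  Raises on constant features,
    naming the offender.
    """
    if features.shape[0] < 2:
        raise ValueError("need at least 2 subjects to standardize")
    X = features.to_numpy(float).T  # features x subjects
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        bad = [features.columns[i] for i in zero[:5]]
        raise ValueError(f"constant feature(s) cannot be standardized: {bad}")
    return ScaledMatrix(
        values=(X - means[:, None]) / sds[:, None],
        feature_ids=list(features.columns),
        subject_ids=list(features.index),
        means=means,
        sds=sds,
    )


@dataclass
class MixtureFit:
    K: int
    family: str
    weights: np.ndarray
    means: np.ndarray              # (K, d)
    variances: np.ndarray          # (K, d) diagonals, expanded per family
    log_likelihood: float
    n_params: int
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    responsibilities: np.ndarray | None = None

    def labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    def bic(self, n_obs: int) -> float:
        """2*loglik - m*ln(N): higher is better."""
        return 2.0 * self.log_likelihood - self.n_params * np.log(n_obs)


def _n_params(K: int, d: int, family: str) -> int:
    base = (K - 1) + K * d
    return base + {
        "spherical-equal": 1,
        "spherical-varying": K,
        "diagonal-equal": d,
        "diagonal-varying": K * d,
        "full-equal": d * (d + 1) // 2,
        "full-varying": K * d * (d + 1) // 2,
    }[family]


def _m_step(X: np.ndarray, R: np.ndarray, family: str, var_floor: float):
    n, d = X.shape
    Nk = R.sum(axis=0)
    if np.any(Nk < 1e-6):
        raise _EmptyComponent
    w = Nk / n
    mu = (R.T @ X) / Nk[:, None]
    # weighted squared deviations per component/dimension
    sq = np.empty((R.shape[1], d))
    for k in range(R.shape[1]):
        diff = X - mu[k]
        sq[k] = R[:, k] @ (diff * diff)
    if family == "diagonal-varying":
        var = sq / Nk[:, None]
    elif family == "diagonal-equal":
        var = np.tile(sq.sum(axis=0) / n, (len(Nk), 1))
    elif family == "spherical-varying":
        var = np.tile((sq.sum(axis=1) / (Nk * d))[:, None], (1, d))
    elif family == "spherical-equal":
        var = np.full((len(Nk), d), sq.sum() / (n * d))
    else:
        raise ValueError(f"unknown family {family!r}")
    return w, mu, np.maximum(var, var_floor)


def _log_dens_diag(X, w, mu, var):
    n, d = X.shape
    K = len(w)
    out = np.empty((n, K))
    for k in range(K):
        diff = X - mu[k]
        out[:, k] = (np.log(w[k])
                     - 0.5 * (d * _LOG2PI + np.log(var[k]).sum()
                              + (diff * diff / var[k]).sum(axis=1)))
    return out


class _EmptyComponent(Exception):
    pass


def _full_fit(X: np.ndarray, K: int, family: str, seed: int,
              n_init: int, max_iter: int, tol: float, var_floor: float) -> MixtureFit:
    """Full-covariance families via scikit-learn's EM ('tied'/'full')."""
    from sklearn.mixture import GaussianMixture

    n, d = X.shape
    if d >= n:
        raise ValueError(
            f"full-covariance family needs dimension < observations ({d} >= {n})")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="tied" if family == "full-equal" else "full",
        n_init=n_init, max_iter=max_iter, tol=tol, reg_covar=var_floor,
        init_params="k-means++", random_state=seed,
    ).fit(X)
    ll = float(gm.score(X) * n)
    R = gm.predict_proba(X)
    cov = gm.covariances_
    var = (np.tile(np.diag(cov), (K, 1)) if family == "full-equal"
           else np.stack([np.diag(c) for c in cov]))
    return MixtureFit(K=K, family=family, weights=gm.weights_, means=gm.means_,
                      variances=var, log_likelihood=ll,
                      n_params=_n_params(K, d, family), converged=bool(gm.converged_),
                      n_iter=int(gm.n_iter_), loglik_trace=[ll], responsibilities=R)


def fit_gmm(data: ScaledMatrix | np.ndarray, K: int, family: str = "diagonal-varying",
            seed: int = 0, n_init: int = 5, max_iter: int = 500,
            tol: float = 1e-6) -> MixtureFit:
    """Fit a K-component Gaussian mixture by EM.

    Initialization is k-means++ with ``n_init`` seeded restarts; the
    restart with the best final log-likelihood wins.  Convergence:
    relative log-likelihood change below ``tol`` or ``max_iter``
    iterations.  The per-iteration log-likelihood trace is retained (it is
    non-decreasing, an EM guarantee asserted in the test suite).
    """
    X = data.values.astype(float) if isinstance(data, ScaledMatrix) else np.asarray(data, float)
    n, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K:
        raise ValueError(f"need more observations ({n}) than components ({K})")
    var_floor = _VAR_FLOOR_FRAC * float(X.var(axis=0).mean())
    if family in FULL_FAMILIES:
        return _full_fit(X, K, family, seed, n_init, max_iter, tol, var_floor)
    if family not in DEFAULT_FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    attempts = 0
    while attempts < n_init:
        attempts += 1
        try:
            fit = _one_em_run(X, K, family, rng, max_iter, tol, var_floor,
                              init="ward" if attempts == 1 else "kmeans++")
        except _EmptyComponent:
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        # every restart collapsed; fall back to a single flagged fit
        R = np.full((n, K), 1.0 / K)
        w, mu, var = _m_step(X, R, family, var_floor)
        ld = _log_dens_diag(X, w, mu, var)
        ll = float(logsumexp(ld, axis=1).sum())
        best = MixtureFit(K=K, family=family, weights=w, means=mu, variances=var,
                          log_likelihood=ll, n_params=_n_params(K, d, family),
                          converged=False, n_iter=0, loglik_trace=[ll],
                          responsibilities=np.exp(ld - logsumexp(ld, axis=1)[:, None]))
    return best


def _one_em_run(X, K, family, rng, max_iter, tol, var_floor, init="kmeans++") -> MixtureFit:
    n, d = X.shape
    if K == 1:
        R = np.ones((n, 1))
    else:
        if init == "ward":
            # deterministic agglomerative start (good at isolating small
            # tight clusters, in the spirit of hierarchical model-based init)
            from sklearn.cluster import AgglomerativeClustering
            hard = AgglomerativeClustering(n_clusters=K).fit_predict(X)
        else:
            centers, _ = kmeans_plusplus(X, n_clusters=K,
                                         random_state=int(rng.integers(2**31)))
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            hard = np.argmin(d2, axis=1)
        R = np.zeros((n, K))
        R[np.arange(n), hard] = 1.0
        # soften slightly so small clusters don't start degenerate
        R = R * 0.99 + 0.01 / K
    w, mu, var = _m_step(X, R, family, var_floor)
    trace: list[float] = []
    converged = False
    ll = -np.inf
    for it in range(1, max_iter + 1):
        ld = _log_dens_diag(X, w, mu, var)
        row = logsumexp(ld, axis=1)
        new_ll = float(row.sum())
        trace.append(new_ll)
        R = np.exp(ld - row[:, None])
        if it > 1 and new_ll - ll <= tol * abs(new_ll):
            ll = new_ll
            converged = True
            break
        ll = new_ll
        w, mu, var = _m_step(X, R, family, var_floor)
    return MixtureFit(K=K, family=family, weights=w, means=mu, variances=var,
                      log_likelihood=ll, n_params=_n_params(K, d, family),
                      converged=converged, n_iter=len(trace), loglik_trace=trace,
                      responsibilities=R)


@dataclass
class ClusterAssignment:
    """Feature -> cluster partition with the winning model and BIC trace."""

    labels: pd.Series              # feature_id -> integer cluster label
    K: int
    family: str
    bic_table: pd.DataFrame        # columns: K, family, bic, converged
    fit: MixtureFit | None = None

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def cluster_labels(self) -> list[int]:
        return sorted(self.labels.unique())


def select_model(data: ScaledMatrix, k_range: Iterable[int] = range(4, 16),
                 families: Sequence[str] = DEFAULT_FAMILIES, seed: int = 0,
                 n_init: int = 5, max_iter: int = 500,
                 tol: float = 1e-6) -> ClusterAssignment:
    """Fit every (K, family) on the grid and keep the highest-BIC model.

    The assignment is the maximum-responsibility labeling of the winning
    fit; the full BIC table is retained for inspection.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty K range")
    n = data.values.shape[0]
    rows = []
    best_fit, best_bic = None, -np.inf
    for family in families:
        for K in k_range:
            if n <= K:
                continue
            try:
                fit = fit_gmm(data, K, family, seed=seed, n_init=n_init,
                              max_iter=max_iter, tol=tol)
            except ValueError:
                continue
            bic = fit.bic(n)
            rows.append({"K": K, "family": family, "bic": bic,
                         "converged": fit.converged})
            if bic > best_bic:
                best_fit, best_bic = fit, bic
    if best_fit is None:
        raise RuntimeError("all mixture fits failed on the requested grid")
    labels = pd.Series(best_fit.labels(), index=data.feature_ids, name="cluster")
    return ClusterAssignment(labels=labels, K=best_fit.K, family=best_fit.family,
                             bic_table=pd.DataFrame(rows), fit=best_fit)


@dataclass
class ClusterScoreMatrix:
    """Per-subject cluster summaries: the arithmetic mean of member
    features' raw concentrations, and its natural log for modeling."""

    scores: pd.DataFrame           # subjects x clusters

    @property
    def log_scores(self) -> pd.DataFrame:
        if (self.scores <= 0).any().any():
            bad = self.scores.columns[(self.scores <= 0).any()].tolist()
            raise ValueError(f"non-positive cluster score; cannot log: {bad}")
        return np.log(self.scores)


def cluster_scores(features: pd.DataFrame,
                   assignment: ClusterAssignment | pd.Series | dict) -> ClusterScoreMatrix:
    """Average raw member concentrations per cluster and subject.

    ``assignment`` may be a ClusterAssignment, a Series, or a plain
    feature->label mapping (e.g. a generator's ground truth).
    """
    if isinstance(assignment, ClusterAssignment):
        labels = assignment.labels
    elif isinstance(assignment, dict):
        labels = pd.Series(assignment)
    else:
        labels = assignment
    missing = [f for f in features.columns if f not in labels.index]
    if missing:
        raise ValueError(f"assignment does not cover features: {missing[:5]}")
    cols = {}
    for label in pd.unique(labels.loc[features.columns]):
        members = [f for f in features.columns if labels[f] == label]
        if not members:
            raise ValueError(f"cluster {label!r} has no member features")
        cols[label] = features[members].mean(axis=1)
    return ClusterScoreMatrix(scores=pd.DataFrame(cols, index=features.index))


def mean_profiles(data: ScaledMatrix, assignment: ClusterAssignment) -> pd.DataFrame:
    """Mean standardized profile per cluster (for summary plots)."""
    rows = {}
    for label in assignment.cluster_labels:
        idx = [data.feature_ids.index(f) for f in assignment.members(label)]
        rows[label] = data.values[idx].mean(axis=0)
    return pd.DataFrame(rows, index=data.subject_ids)
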