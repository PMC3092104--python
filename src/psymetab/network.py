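"""Dependency-network inference via average non-rejection rates (NRR) of
q-order partial-correlation tests.

For each variable pair, the hypothesis of zero partial correlation is
t-tested repeatedly while conditioning on randomly sampled subsets of q
other variables, over several q levels.  The NRR is the fraction of tests
that fail to reject; a small NRR is strong evidence of a direct
dependence, and edges are drawn where NRR <= beta (default 0.25).

For the canonical 52-variable set (21 metabolite clusters + 4 diagnosis
indicators + 27 phenotype/lifestyle variables) the conditioning orders are
q = 1, 13, 26 and 38 with 500 subsets each.  Binary variables enter the
Gaussian framework as numeric 0/1.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Default phenotype/lifestyle block of the network variable set (27).
DEFAULT_PHENOTYPES = (
    "antipsychotic_current", "antipsychotic_atypical", "daily_smoking",
    "diet_vegetables", "diet_high_fat_milk", "diet_vegetable_oils",
    "diet_high_fat_cheese", "fasting_time", "bmi", "waist", "insulin",
    "glucose", "homa_ir", "triglycerides", "hdl", "ldl", "total_chol",
    "crp", "ggt", "alcohol", "bdi", "cotinine", "systolic_bp",
    "diastolic_bp", "metabolic_syndrome", "obesity", "age",
)


def q_level_grid(p: int, n_levels: int = 4, n_subjects: int | None = None) -> list[int]:
    """Conditioning orders for a p-variable set.

    For p = 52 this is the canonical {1, 13, 26, 38}; otherwise n_levels
    integers spread evenly over [1, p-3], deduplicated, each capped at
    n_subjects - 3 when a sample size is given.
    """
    if p < 3:
        raise ValueError("need at least 3 variables")
    if p == 52 and n_levels == 4:
        qs = [1, 13, 26, 38]
    else:
        hi = max(p - 3, 1)
        qs = sorted({int(round(q)) for q in np.linspace(1, hi, n_levels)})
    if n_subjects is not None:
        qs = [q for q in qs if q <= n_subjects - 3]
    qs = sorted({max(q, 1) for q in qs})
    if not qs:
        raise ValueError("no valid q for this sample size")
    return qs


def partial_correlation(S: np.ndarray, i: int, j: int, Q) -> float:
    """Partial correlation of variables i and j given the set Q, from the
    covariance matrix S.

    r = -P_ij / sqrt(P_ii P_jj) with P the inverse of the covariance
    submatrix over {i, j} union Q (pseudo-inverse if singular).  Returns
    NaN when the submatrix is singular beyond tolerance; with Q empty this
    is the Pearson correlation.
    """
    idx = [i, j, *Q]
    sub = S[np.ix_(idx, idx)]
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        P = np.linalg.pinv(sub, rcond=1e-10)
    denom = P[0, 0] * P[1, 1]
    if not np.isfinite(denom) or denom <= 0:
        return np.nan
    return float(np.clip(-P[0, 1] / np.sqrt(denom), -1.0, 1.0))


def _batched_partial_corr(S: np.ndarray, i: int, j: int, Qs: np.ndarray) -> np.ndarray:
    """Partial correlations for a batch of conditioning sets (B, q) via the
    Schur complement of S_QQ."""
    B, q = Qs.shape
    if q == 0:
        r = S[i, j] / np.sqrt(S[i, i] * S[j, j])
        return np.full(B, np.clip(r, -1, 1))
    SQQ = S[Qs[:, :, None], Qs[:, None, :]]            # (B, q, q)
    SQij = np.stack([S[Qs, i], S[Qs, j]], axis=2)       # (B, q, 2)
    try:
        sol = np.linalg.solve(SQQ, SQij)                # (B, q, 2)
        cii = S[i, i] - np.einsum("bq,bq->b", SQij[:, :, 0], sol[:, :, 0])
        cjj = S[j, j] - np.einsum("bq,bq->b", SQij[:, :, 1], sol[:, :, 1])
        cij = S[i, j] - np.einsum("bq,bq->b", SQij[:, :, 0], sol[:, :, 1])
        denom = cii * cjj
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, cij / np.sqrt(np.maximum(denom, 1e-300)), np.nan)
        return np.clip(r, -1.0, 1.0)
    except np.linalg.LinAlgError:
        return np.array([partial_correlation(S, i, j, Qs[b]) for b in range(B)])


def _nonrejections(r: np.ndarray, n: int, q: int, alpha: float) -> np.ndarray:
    """Boolean non-rejection per test; singular (NaN) correlations count
    as rejections (treated as |r| = 1)."""
    df = n - q - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(r), p, 0.0)
    return p >= alpha


def nrr_pair(data: np.ndarray, i: int, j: int, q_levels=None,
             n_subsets_per_q: int = 500, alpha: float = 0.05,
             seed: int | np.random.Generator = 0,
             S: np.ndarray | None = None,
             candidate_order: np.ndarray | None = None) -> float:
    """Average non-rejection rate for one variable pair.

    For each q level, conditioning sets of size q are drawn uniformly from
    the other variables (exhaustive enumeration replaces sampling whenever
    C(p-2, q) <= n_subsets_per_q); each set yields a t-test of zero
    partial correlation with n - q - 2 degrees of freedom at level alpha.
    """
    data = np.asarray(data, float)
    n, p = data.shape
    if q_levels is None:
        q_levels = q_level_grid(p, n_subjects=n)
    if n - max(q_levels) - 2 < 3:
        raise ValueError("sample too small for the largest q")
    S = np.cov(data, rowvar=False) if S is None else S
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    others = np.array([k for k in (range(p) if candidate_order is None
                                   else candidate_order) if k not in (i, j)])
    nonrej = total = 0
    for q in q_levels:
        if q > len(others):
            raise ValueError(f"q={q} too large for p={p}")
        if comb(len(others), q) <= n_subsets_per_q:
            Qs = np.array(list(itertools.combinations(others, q)), dtype=int)
        else:
            Qs = np.stack([rng.choice(others, size=q, replace=False)
                           for _ in range(n_subsets_per_q)])
        r = _batched_partial_corr(S, i, j, Qs)
        keep = _nonrejections(r, n, q, alpha)
        nonrej += int(keep.sum())
        total += len(keep)
    return nonrej / total


@dataclass
class NetworkVariableSet:
    """Complete-case data matrix for the network variables, with each
    variable's kind (cluster_score | diagnosis_indicator | phenotype)."""

    data: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self):
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 variables")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)


def assemble_variables(cohort: pd.DataFrame, log_scores: pd.DataFrame,
                       phenotypes=DEFAULT_PHENOTYPES) -> NetworkVariableSet:
    """Default network variable set: cluster log-scores + 4 diagnosis
    indicators (three psychosis strata and NIDDM) + phenotype block.

    With the default 21 clusters and 27 phenotypes this is p = 52.
    """
    idx = cohort["subject_id"].to_numpy()
    cols = {}
    kinds = {}
    for cl in log_scores.columns:
        cols[str(cl)] = log_scores[cl].reindex(idx).to_numpy(float)
        kinds[str(cl)] = "cluster_score"
    for stratum in ("schizophrenia", "onap", "affective"):
        cols[stratum] = ((cohort["stratum"] == stratum)
                         & (cohort["role"] == "case")).to_numpy(float)
        kinds[stratum] = "diagnosis_indicator"
    cols["niddm"] = pd.to_numeric(cohort["t2d"]).to_numpy(float)
    kinds["niddm"] = "diagnosis_indicator"
    for ph in phenotypes:
        cols[ph] = pd.to_numeric(cohort[ph], errors="coerce").to_numpy(float)
        kinds[ph] = "phenotype"
    df = pd.DataFrame(cols, index=idx).dropna()
    return NetworkVariableSet(data=df, kinds=kinds)


@dataclass
class NrrGraph:
    nrr: pd.DataFrame             # symmetric, NaN diagonal
    beta: float
    q_levels: list[int]
    n_subsets_per_q: int
    alpha: float
    kinds: dict[str, str] = field(default_factory=dict)
    regulation: dict[str, str] = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        names = list(self.nrr.columns)
        out = []
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                v = self.nrr.iloc[a, b]
                if v <= self.beta:
                    out.append((names[a], names[b], float(v)))
        return out

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph(beta=self.beta, alpha=self.alpha)
        for name in self.nrr.columns:
            g.add_node(name, kind=self.kinds.get(name, ""),
                       regulation=self.regulation.get(name, ""))
        for a, b, v in self.edges:
            g.add_edge(a, b, nrr=v, strength=1.0 - v)
        return g

    def write(self, outdir: str | Path, stem: str = "network") -> dict[str, Path]:
        import networkx as nx
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"matrix": outdir / "nrr_matrix.csv",
                 "graphml": outdir / f"{stem}.graphml",
                 "sif": outdir / f"{stem}.sif"}
        self.nrr.to_csv(paths["matrix"])
        nx.write_graphml(self.to_networkx(), paths["graphml"])
        with open(paths["sif"], "w") as fh:
            for a, b, v in self.edges:
                fh.write(f"{a}\tnrr={v:.4f}\t{b}\n")
        return paths


def _pair_rng(seed: int, name_a: str, name_b: str) -> np.random.Generator:
    """Per-pair generator keyed by the unordered name pair, so results are
    invariant to variable reordering (up to relabeling)."""
    key = "|".join(sorted((str(name_a), str(name_b))))
    h = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def build_network(vars: NetworkVariableSet, beta: float = 0.25, q_levels=None,
                  n_subsets_per_q: int = 500, alpha: float = 0.05,
                  seed: int = 0, regulation: dict[str, str] | None = None) -> NrrGraph:
    """NRR for every variable pair; edges where NRR <= beta."""
    df = vars.data
    names = vars.names
    X = df.to_numpy(float)
    n, p = X.shape
    if q_levels is None:
        q_levels = q_level_grid(p, n_subjects=n)
    S = np.cov(X, rowvar=False)
    sort_idx = sorted(range(p), key=lambda k: str(names[k]))
    M = np.full((p, p), np.nan)
    for a in range(p):
        for b in range(a + 1, p):
            rng = _pair_rng(seed, names[a], names[b])
            M[a, b] = M[b, a] = nrr_pair(
                X, a, b, q_levels=q_levels, n_subsets_per_q=n_subsets_per_q,
                alpha=alpha, seed=rng, S=S, candidate_order=np.array(sort_idx))
    return NrrGraph(nrr=pd.DataFrame(M, index=names, columns=names),
                    beta=beta, q_levels=list(q_levels),
                    n_subsets_per_q=n_subsets_per_q, alpha=alpha,
                    kinds=dict(vars.kinds), regulation=regulation or {})


def regulation_directions(cohort: pd.DataFrame, vars: NetworkVariableSet,
                          stratum: str = "schizophrenia") -> dict[str, str]:
    """Case-vs-control direction per variable (node coloring metadata)."""
    idx = vars.data.index
    coh = cohort.set_index("subject_id").loc[idx]
    case = (coh["stratum"] == stratum) & (coh["role"] == "case")
    ctrl = coh["role"] == "control"
    out = {}
    for name in vars.names:
        if vars.kinds.get(name) == "diagnosis_indicator":
            out[name] = ""
            continue
        x = vars.data[name]
        diff = x[case.to_numpy()].mean() - x[ctrl.to_numpy()].mean()
        out[name] = "up" if diff > 0 else "down"
    return out
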