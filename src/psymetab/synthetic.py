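"""Seeded synthetic cohort and serum-metabolome feature generator.

Emulates the structure of a matched case-control psychosis study: three
diagnostic strata (schizophrenia, other non-affective psychosis, affective
psychosis) with one age/sex-matched control per case, demographic-table
covariate distributions, and two metabolite platforms ("lipid" and
"polar") whose features are organized into latent clusters with planted
group, comorbidity, medication, diet and fasting effects.

Concentrations are log-normal: each feature is ``exp`` of a loading on its
cluster's latent per-subject score plus feature-level noise, so
within-cluster features are correlated while between-cluster features are
(near) independent.  Ground truth (feature->cluster partition, planted
effects, latent scores) is recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STRATA = ("schizophrenia", "onap", "affective")

#: Default per-stratum case counts (matched 1:1 with controls).
DEFAULT_GROUP_SIZES = {"schizophrenia": 45, "onap": 57, "affective": 37}

#: Lipid-platform cluster sizes LC1..LC13 (sum 351) and polar-platform
#: cluster sizes MC1..MC8 (sum 201).
DEFAULT_LIPID_SIZES = [112, 48, 11, 15, 31, 21, 20, 34, 17, 21, 9, 7, 5]
DEFAULT_POLAR_SIZES = [34, 18, 10, 53, 38, 25, 17, 6]

#: Fraction of features flagged as identified per platform (170/360 lipids,
#: 155/201 polar metabolites in the emulated design).
IDENTIFIED_FRACTION = {"lipid": 170 / 360, "polar": 155 / 201}


# --------------------------------------------------------------------------
# covariate distribution specs
# --------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """Distribution of one covariate, per (stratum, role).

    kind: 'normal' (optionally truncated), 'lognormal' (moment-matched to
    the given mean/SD), or 'bernoulli' (params are probabilities).
    params maps (stratum, role) -> (mean, sd) or probability.
    """

    kind: str
    params: Mapping[tuple[str, str], tuple[float, float] | float]
    lower: float | None = None
    upper: float | None = None

    def draw(self, rng: np.random.Generator, stratum: str, role: str, size: int = 1):
        p = self.params[(stratum, role)]
        if self.kind == "bernoulli":
            return rng.random(size) < p
        mean, sd = p
        if self.kind == "normal":
            x = rng.normal(mean, sd, size)
            lo = -np.inf if self.lower is None else self.lower
            hi = np.inf if self.upper is None else self.upper
            # re-draw instead of clip: keeps the distribution continuous
            bad = (x < lo) | (x > hi)
            while bad.any():
                x[bad] = rng.normal(mean, sd, bad.sum())
                bad = (x < lo) | (x > hi)
            return x
        if self.kind == "lognormal":
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size)
        raise ValueError(f"unknown covariate kind {self.kind!r}")


def _sym(case_sch, case_onap, case_aff, ctrl_sch, ctrl_onap, ctrl_aff):
    """Helper building the (stratum, role) -> params mapping."""
    return {
        ("schizophrenia", "case"): case_sch,
        ("onap", "case"): case_onap,
        ("affective", "case"): case_aff,
        ("schizophrenia", "control"): ctrl_sch,
        ("onap", "control"): ctrl_onap,
        ("affective", "control"): ctrl_aff,
    }


def default_covariate_params() -> dict[str, CovariateSpec]:
    """Covariate distributions informed by the emulated study's
    demographic table.

    Skewed biomarkers (insulin, triglycerides, CRP, cotinine, GGT, alcohol)
    are log-normal with moments matched to the reported mean/SD; roughly
    symmetric ones (age, blood pressure, BMI, cholesterol, fasting time,
    BDI) are truncated normal.
    """
    return {
        "age": CovariateSpec("normal", _sym((53.7, 12.9), (54.7, 14.3), (54.7, 14.8),
                                            (53.7, 12.9), (54.7, 14.3), (54.7, 14.8)),
                             lower=30.0, upper=95.0),
        "sex_male": CovariateSpec("bernoulli", _sym(19 / 45, 20 / 57, 23 / 37,
                                                    19 / 45, 20 / 57, 23 / 37)),
        "antipsychotic_current": CovariateSpec(
            "bernoulli", _sym(0.756, 0.421, 0.216, 0.0, 0.0, 0.0)),
        "antipsychotic_atypical": CovariateSpec(
            "bernoulli", _sym(0.170, 0.070, 0.0, 0.0, 0.0, 0.0)),
        "t2d": CovariateSpec("bernoulli", _sym(0.244, 0.140, 0.0, 0.067, 0.070, 0.081)),
        "metabolic_syndrome": CovariateSpec(
            "bernoulli", _sym(0.422, 0.439, 0.270, 0.289, 0.263, 0.297)),
        "daily_smoking": CovariateSpec(
            "bernoulli", _sym(0.444, 0.298, 0.270, 0.267, 0.263, 0.243)),
        "diet_vegetables": CovariateSpec(
            "bernoulli", _sym(0.455, 0.411, 0.514, 0.711, 0.614, 0.541)),
        "diet_high_fat_milk": CovariateSpec(
            "bernoulli", _sym(0.465, 0.375, 0.405, 0.364, 0.286, 0.324)),
        "diet_vegetable_oils": CovariateSpec(
            "bernoulli", _sym(0.628, 0.614, 0.676, 0.689, 0.750, 0.595)),
        "diet_high_fat_cheese": CovariateSpec(
            "bernoulli", _sym(0.191, 0.286, 0.243, 0.333, 0.250, 0.432)),
        "bmi": CovariateSpec("normal", _sym((28.4, 5.8), (28.8, 6.2), (27.5, 3.7),
                                            (26.1, 3.3), (26.6, 3.9), (26.4, 4.1)),
                             lower=15.0, upper=60.0),
        "waist": CovariateSpec("normal", _sym((98.8, 15.1), (97.4, 16.4), (97.4, 12.2),
                                              (89.5, 11.7), (90.8, 12.4), (93.1, 12.6)),
                               lower=55.0),
        "systolic_bp": CovariateSpec(
            "normal", _sym((128.4, 20.1), (131.6, 17.8), (128.1, 18.8),
                           (134.3, 20.7), (140.8, 25.4), (135.4, 20.1)),
            lower=80.0, upper=230.0),
        "diastolic_bp": CovariateSpec(
            "normal", _sym((79.8, 10.7), (82.3, 10.5), (79.9, 10.4),
                           (80.5, 12.0), (82.7, 10.0), (81.5, 9.9)),
            lower=45.0, upper=140.0),
        "glucose": CovariateSpec(
            "normal", _sym((109.9, 31.9), (106.5, 42.5), (97.0, 12.0),
                           (97.2, 12.3), (101.6, 15.0), (100.2, 14.6)),
            lower=55.0),
        "insulin": CovariateSpec(
            "lognormal", _sym((16.6, 19.6), (11.9, 12.4), (9.6, 6.1),
                              (7.6, 5.4), (8.4, 5.8), (9.3, 7.2))),
        "triglycerides": CovariateSpec(
            "lognormal", _sym((197.4, 130.2), (156.5, 112.6), (151.4, 97.2),
                              (120.6, 55.2), (125.9, 81.2), (144.5, 85.0))),
        "hdl": CovariateSpec("normal", _sym((45.3, 13.5), (49.7, 14.3), (45.0, 13.0),
                                            (54.5, 14.5), (51.6, 14.6), (50.5, 16.7)),
                             lower=15.0),
        "total_chol": CovariateSpec(
            "normal", _sym((226.0, 50.0), (232.3, 41.6), (230.0, 40.0),
                           (229.7, 37.9), (224.7, 39.6), (237.1, 37.0)),
            lower=90.0),
        "crp": CovariateSpec("lognormal", _sym((2.5, 2.8), (3.7, 4.9), (1.9, 2.9),
                                               (1.7, 3.3), (2.2, 4.3), (1.0, 1.4))),
        "cotinine": CovariateSpec(
            "lognormal", _sym((216.2, 317.2), (151.4, 249.4), (124.5, 234.2),
                              (96.8, 207.1), (121.2, 253.5), (150.4, 284.6))),
        "fasting_time": CovariateSpec(
            "normal", _sym((6.40, 4.17), (9.29, 5.98), (6.43, 3.98),
                           (7.13, 3.89), (7.87, 4.23), (8.37, 5.06)),
            lower=0.5),
        "bdi": CovariateSpec("normal", _sym((13.5, 10.9), (14.9, 12.3), (11.1, 9.3),
                                            (5.7, 4.4), (6.5, 6.1), (6.0, 5.6)),
                             lower=0.0),
        # not tabulated in the emulated study; population-plausible values
        "ggt": CovariateSpec("lognormal", _sym((40.0, 40.0), (40.0, 40.0), (40.0, 40.0),
                                               (30.0, 25.0), (30.0, 25.0), (30.0, 25.0))),
        "alcohol": CovariateSpec(
            "lognormal", _sym((80.0, 120.0), (80.0, 120.0), (80.0, 120.0),
                              (70.0, 90.0), (70.0, 90.0), (70.0, 90.0))),
    }


#: Covariates every downstream model formula may reference.
REQUIRED_COVARIATES = (
    "age", "sex_male", "antipsychotic_current", "t2d", "metabolic_syndrome",
    "diet_vegetables", "diet_high_fat_milk", "diet_vegetable_oils",
    "diet_high_fat_cheese", "fasting_time", "bmi", "insulin", "glucose",
)


# --------------------------------------------------------------------------
# planted effects and cluster specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A directional shift of one cluster's latent score per unit of a
    predictor (binary predictors: raw 0/1; continuous: z-score), expressed
    in units of the latent residual SD."""

    target_cluster: str
    predictor: str
    direction: str  # 'up' | 'down'
    magnitude: float

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")

    @property
    def signed(self) -> float:
        return self.magnitude if self.direction == "up" else -self.magnitude


def default_effects() -> list[PlantedEffect]:
    """Planted effects with the signs of the emulated study's per-cluster
    mixed-model findings.

    Magnitudes (in latent residual SDs) are chosen so that a matched design
    with 37-57 pairs per stratum detects each diagnosis/comorbidity effect
    with high power while diet/medication/fasting effects remain moderate;
    the strongest reported association (LC9) gets the largest shift.
    """
    E = PlantedEffect
    return [
        # schizophrenia: up in the saturated-TG lipid clusters and the
        # amino-acid polar clusters, down in the ketone-body cluster
        E("LC4", "schizophrenia", "up", 1.0),
        E("LC5", "schizophrenia", "up", 1.0),
        E("LC6", "schizophrenia", "up", 1.0),
        E("LC7", "schizophrenia", "up", 1.0),
        E("LC8", "schizophrenia", "up", 1.0),
        E("LC9", "schizophrenia", "up", 1.2),
        E("MC2", "schizophrenia", "down", 1.0),
        E("MC3", "schizophrenia", "up", 1.0),
        E("MC5", "schizophrenia", "up", 1.2),
        E("MC2", "affective", "down", 1.0),
        # metabolic comorbidity: up across the TG clusters and sugars
        E("LC4", "metabolic_comorbidity", "up", 1.2),
        E("LC5", "metabolic_comorbidity", "up", 0.8),
        E("LC6", "metabolic_comorbidity", "up", 1.0),
        E("LC7", "metabolic_comorbidity", "up", 1.2),
        E("LC8", "metabolic_comorbidity", "up", 1.2),
        E("LC9", "metabolic_comorbidity", "up", 1.2),
        E("LC10", "metabolic_comorbidity", "up", 1.0),
        E("MC1", "metabolic_comorbidity", "up", 0.8),
        E("MC5", "metabolic_comorbidity", "up", 1.0),
        # antipsychotic medication
        E("MC2", "antipsychotic_current", "up", 0.6),
        E("MC4", "antipsychotic_current", "down", 0.6),
        # diet
        E("LC4", "diet_high_fat_cheese", "up", 0.5),
        E("LC6", "diet_high_fat_cheese", "up", 0.5),
        E("LC7", "diet_high_fat_cheese", "up", 0.5),
        E("LC9", "diet_high_fat_cheese", "up", 0.6),
        E("LC11", "diet_vegetable_oils", "down", 0.6),
        E("LC12", "diet_vegetable_oils", "down", 0.5),
        # fasting time (per SD of hours fasted)
        E("LC9", "fasting_time", "down", 0.4),
        E("LC11", "fasting_time", "down", 0.4),
        E("MC1", "fasting_time", "down", 0.5),
        E("MC5", "fasting_time", "down", 0.5),
        # insulin-resistance coupling: the saturated-TG and amino-acid
        # clusters co-vary with fasting insulin (per SD of insulin), which
        # links them to the metabolic phenotype block in the dependency
        # network and makes insulin largely redundant as a diagnostic
        # marker once the cluster markers are in the model
        E("LC9", "insulin", "up", 0.3),
        E("MC5", "insulin", "up", 0.3),
    ]


@dataclass
class ClusterSpec:
    """Latent cluster structure of one platform.

    within_cluster_correlation is the pairwise correlation of member
    features' log concentrations induced by their shared latent score;
    noise_sd is the latent residual SD (the unit of planted magnitudes);
    pair_sd is the SD of a shared per-pair intercept emulating the matching
    variables' common environment.  loading_scale lets designated features
    (e.g. a weakly cluster-representative marker) deviate from the common
    loading.
    """

    platform: str  # 'lipid' | 'polar'
    cluster_sizes: Sequence[int] = None
    within_cluster_correlation: float = 0.8
    noise_sd: float = 1.0
    pair_sd: float = 0.5
    baseline_mean: float = 4.0   # mean log concentration (arbitrary units)
    baseline_sd: float = 0.5
    #: amplitude of the standardized signal on the natural-log scale; 0.35
    #: corresponds to a realistic ~35-40% concentration CV and keeps the
    #: exp() map near-linear, so standardized raw profiles are close to
    #: Gaussian.  Log-scale effect sizes and residuals scale together, so
    #: downstream t statistics are unaffected.
    log_scale: float = 0.35
    loading_scale: Mapping[tuple[str, int], float] = field(default_factory=dict)
    #: per-feature attenuation of the planted (disease/covariate) shift
    #: component of the latent score: a feature can track its cluster's
    #: baseline biological variation while responding only weakly to the
    #: planted effects (not every member of a co-regulated group shifts
    #: equally with disease)
    effect_attenuation: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.platform not in ("lipid", "polar"):
            raise ValueError("platform must be 'lipid' or 'polar'")
        if self.cluster_sizes is None:
            self.cluster_sizes = list(
                DEFAULT_LIPID_SIZES if self.platform == "lipid" else DEFAULT_POLAR_SIZES)
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("all cluster sizes must be >= 1")
        if not 0 <= self.within_cluster_correlation < 1:
            raise ValueError("within_cluster_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def prefix(self) -> str:
        return "LC" if self.platform == "lipid" else "MC"

    @property
    def cluster_names(self) -> list[str]:
        return [f"{self.prefix}{i + 1}" for i in range(len(self.cluster_sizes))]


def default_lipid_spec() -> ClusterSpec:
    # the TG marker analogue is a solid but not dominant representative of
    # its cluster, mirroring the diagnostic hierarchy of the emulated
    # study (the amino-acid marker ranks first)
    return ClusterSpec(platform="lipid", loading_scale={("LC9", 0): 0.8})


def default_polar_spec() -> ClusterSpec:
    # marker-feature loadings emulate how representative each top-ranking
    # metabolite is of its cluster: proline tracks MC5 strongly, while the
    # isoleucine analogue carries only part of MC3's cluster-level shift
    return ClusterSpec(platform="polar",
                       loading_scale={("MC5", 0): 1.2},
                       effect_attenuation={("MC3", 0): 0.15})


#: Feature ids of the designated diagnostic-marker analogues (first member
#: of each marker cluster; see default_polar_spec for the MC3 loading).
MARKER_CLUSTERS = {"LC9": "tg_18_1_18_0_18_1", "MC3": "isoleucine", "MC5": "proline"}


@dataclass
class CohortConfig:
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    controls_per_case: int = 1
    seed: int = 0
    covariate_params: Mapping[str, CovariateSpec] = field(default_factory=default_covariate_params)
    effect_specs: Sequence[PlantedEffect] = field(default_factory=default_effects)
    diet_missing_rate: float = 0.0

    def __post_init__(self):
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.controls_per_case < 0:
            raise ValueError("controls_per_case must be >= 0")
        missing = [c for c in REQUIRED_COVARIATES if c not in self.covariate_params]
        if missing:
            raise ValueError(f"missing covariate specs: {missing}")


@dataclass
class SyntheticStudy:
    """A generated cohort, its two feature matrices (subjects x features),
    and the ground truth used by recovery tests."""

    cohort: pd.DataFrame
    lipid_features: pd.DataFrame | None
    polar_features: pd.DataFrame | None
    truth: dict

    def features(self, platform: str) -> pd.DataFrame:
        return self.lipid_features if platform == "lipid" else self.polar_features


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a matched case-control cohort table.

    One row per subject.  Each case in each diagnostic stratum gets
    ``controls_per_case`` controls sharing its pair id, age and sex.
    Deterministic for a given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    cov = config.covariate_params
    rows: list[dict] = []
    for stratum in STRATA:
        n = int(config.group_sizes.get(stratum, 0))
        for i in range(n):
            pair_id = f"{stratum[:3]}-{i + 1:03d}"
            age = float(cov["age"].draw(rng, stratum, "case")[0])
            male = bool(cov["sex_male"].draw(rng, stratum, "case")[0])
            members = [("case", "case")] + [
                ("control", f"ctl{k + 1}") for k in range(config.controls_per_case)]
            for role, tag in members:
                row = {
                    "subject_id": f"{pair_id}-{tag}",
                    "pair_id": pair_id,
                    "stratum": stratum,
                    "role": role,
                    "sex": "male" if male else "female",
                    "age": age,
                }
                for name, spec in cov.items():
                    if name in ("age", "sex_male"):
                        continue
                    row[name] = spec.draw(rng, stratum, role)[0]
                for flag in ("antipsychotic_current", "antipsychotic_atypical", "t2d",
                             "metabolic_syndrome", "daily_smoking", "diet_vegetables",
                             "diet_high_fat_milk", "diet_vegetable_oils",
                             "diet_high_fat_cheese"):
                    row[flag] = bool(row[flag])
                # atypical use only among current users
                if not row["antipsychotic_current"]:
                    row["antipsychotic_atypical"] = False
                rows.append(row)
    columns = ["subject_id", "pair_id", "stratum", "role", "sex", "age",
               "antipsychotic_current", "antipsychotic_atypical", "t2d",
               "metabolic_syndrome", "daily_smoking", "diet_vegetables",
               "diet_high_fat_milk", "diet_vegetable_oils", "diet_high_fat_cheese",
               "fasting_time", "bmi", "waist", "insulin", "glucose",
               "triglycerides", "hdl", "total_chol", "crp", "ggt", "alcohol",
               "bdi", "cotinine", "systolic_bp", "diastolic_bp"]
    cohort = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    if config.diet_missing_rate > 0 and len(cohort):
        diet_cols = [c for c in columns if c.startswith("diet_")]
        mask = rng.random((len(cohort), len(diet_cols))) < config.diet_missing_rate
        vals = cohort[diet_cols].astype(object).to_numpy()
        vals[mask] = np.nan
        cohort[diet_cols] = vals
    return derive_covariates(cohort)


def derive_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill derived columns: HOMA-IR, LDL, obesity, metabolic comorbidity.

    HOMA-IR = insulin[uIU/ml] * glucose[mg/dl] / 405 (equivalently the
    mmol/l form divided by 22.5).  LDL follows the Friedewald estimate.
    Metabolic comorbidity is the OR-composite of type 2 diabetes, metabolic
    syndrome and obesity (BMI >= 30).
    """
    out = cohort.copy()
    if len(out) == 0:
        for c in ("homa_ir", "ldl", "obesity", "metabolic_comorbidity"):
            out[c] = pd.Series(dtype=float)
        return out
    if (out["insulin"] < 0).any() or (out["glucose"] < 0).any():
        raise ValueError("insulin and glucose must be non-negative")
    out["homa_ir"] = out["insulin"] * out["glucose"] / 405.0
    out["ldl"] = (out["total_chol"] - out["hdl"] - out["triglycerides"] / 5.0).clip(lower=30.0)
    out["obesity"] = out["bmi"] >= 30.0
    out["metabolic_comorbidity"] = out["t2d"] | out["metabolic_syndrome"] | out["obesity"]
    return out


# --------------------------------------------------------------------------
# feature generation
# --------------------------------------------------------------------------

def _predictor_values(cohort: pd.DataFrame, predictor: str) -> np.ndarray:
    """Design values of a planted predictor: diagnosis indicators and
    binary flags as 0/1, continuous covariates z-scored."""
    if predictor in STRATA:
        return ((cohort["stratum"] == predictor) & (cohort["role"] == "case")).to_numpy(float)
    if predictor not in cohort.columns:
        raise ValueError(f"unknown predictor {predictor!r}")
    col = cohort[predictor]
    if col.dtype == bool or set(col.dropna().unique()) <= {0, 1, True, False}:
        return col.to_numpy(float)
    x = col.to_numpy(float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_features(
    cohort: pd.DataFrame,
    spec: ClusterSpec | Sequence[ClusterSpec],
    effects: Sequence[PlantedEffect] | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate log-normal feature matrices with planted cluster structure.

    Per cluster, a latent per-subject score is the sum of a shared pair
    intercept, the planted shifts for that subject's predictor values and
    Gaussian noise.  Each member feature is ``exp(baseline + loading *
    standardized latent + feature noise)`` with the loading chosen so the
    within-cluster log-scale correlation equals the configured value.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    specs = [spec] if isinstance(spec, ClusterSpec) else list(spec)
    effects = list(default_effects() if effects is None else effects)
    all_clusters = {name for s in specs for name in s.cluster_names}
    for e in effects:
        if e.target_cluster not in all_clusters:
            raise ValueError(f"effect targets unknown cluster {e.target_cluster!r}")
        _predictor_values(cohort, e.predictor)  # validates predictor

    rng = np.random.default_rng(seed)
    n = len(cohort)
    pair_codes = cohort["pair_id"].astype("category").cat.codes.to_numpy()

    matrices: dict[str, pd.DataFrame] = {}
    assignment: dict[str, str] = {}
    identified: dict[str, bool] = {}
    latents: dict[str, np.ndarray] = {}
    markers: dict[str, str] = {}

    for s in specs:
        rho = s.within_cluster_correlation
        cols: dict[str, np.ndarray] = {}
        for cname, size in zip(s.cluster_names, s.cluster_sizes):
            u_pair = rng.normal(size=pair_codes.max() + 1)
            shift = np.zeros(n)
            for e in effects:
                if e.target_cluster == cname:
                    shift += e.signed * s.noise_sd * _predictor_values(cohort, e.predictor)
            base = s.pair_sd * u_pair[pair_codes] + s.noise_sd * rng.normal(size=n)
            latent = base + shift
            sd_nominal = np.hypot(s.pair_sd, s.noise_sd)
            latents[cname] = latent
            for j in range(size):
                fid = f"{cname}_f{j:03d}"
                scale = s.loading_scale.get((cname, j), 1.0)
                att = s.effect_attenuation.get((cname, j), 1.0)
                z = (base + att * shift) / sd_nominal
                loading = np.sqrt(rho) * scale
                noise_sd = np.sqrt(1.0 - rho) if rho > 0 else 1.0
                baseline = rng.normal(s.baseline_mean, s.baseline_sd)
                logx = baseline + s.log_scale * (loading * z
                                                 + noise_sd * rng.normal(size=n))
                cols[fid] = np.exp(logx)
                assignment[fid] = cname
                identified[fid] = bool(rng.random() < IDENTIFIED_FRACTION[s.platform])
            if cname in MARKER_CLUSTERS:
                markers[MARKER_CLUSTERS[cname]] = f"{cname}_f000"
        matrices[s.platform] = pd.DataFrame(cols, index=cohort["subject_id"].to_numpy())

    truth = {
        "assignment": assignment,
        "identified": identified,
        "effects": [{"target_cluster": e.target_cluster, "predictor": e.predictor,
                     "direction": e.direction, "magnitude": e.magnitude}
                    for e in effects],
        "latent_scores": pd.DataFrame(latents, index=cohort["subject_id"].to_numpy()),
        "markers": markers,
    }
    return SyntheticStudy(
        cohort=cohort,
        lipid_features=matrices.get("lipid"),
        polar_features=matrices.get("polar"),
        truth=truth,
    )


def generate_study(config: CohortConfig | None = None,
                   lipid_spec: ClusterSpec | None = None,
                   polar_spec: ClusterSpec | None = None) -> SyntheticStudy:
    """Convenience: cohort plus both platforms under one config/seed."""
    config = config or CohortConfig()
    cohort = generate_cohort(config)
    specs = [lipid_spec or default_lipid_spec(), polar_spec or default_polar_spec()]
    return generate_features(cohort, specs, config.effect_specs, seed=config.seed + 1)


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write cohort.csv, lipid.csv, polar.csv (first column subject_id) and
    truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"cohort": outdir / "cohort.csv"}
    study.cohort.to_csv(paths["cohort"], index=False)
    for platform in ("lipid", "polar"):
        m = study.features(platform)
        if m is not None:
            paths[platform] = outdir / f"{platform}.csv"
            m.rename_axis("subject_id").to_csv(paths[platform])
    truth = {k: v for k, v in study.truth.items() if k != "latent_scores"}
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
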