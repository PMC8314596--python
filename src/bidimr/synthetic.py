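"""Synthetic genotype-phenotype cohort generator.

Generates individual-level cohorts with the statistical structure the
bidirectional Mendelian-randomization analysis assumes: Hardy-Weinberg
genotypes at the six instrument SNPs, natural-log-normal 25(OH)D with
additive per-allele effects, a logistic type 2 diabetes model with
additive per-allele log-odds, and age/sex/BMI covariates.  Optional causal
(25(OH)D -> T2D), reverse-causal (T2D -> 25(OH)D) and pleiotropic paths
let simulation scenarios probe each arm of the causal diagram; the two
directed paths are mutually exclusive within a single run so the simulated
causal direction is always unambiguous.

Scenario presets
----------------
``INDEPENDENT``    the analysis' concluded world: each SNP cluster affects
                   only its own trait, no path connects the traits.
``FORWARD_CAUSAL`` adds a causal effect of ln 25(OH)D on T2D log-odds.
``REVERSE_CAUSAL`` adds a shift in ln 25(OH)D among T2D cases.
``NULL``           all genetic effects zero (for type-I-error checks).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Ancestry, Trait
from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "SimulationParams",
    "Cohort",
    "Scenario",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "default_presets",
    "write_cohort",
    "read_cohort",
]

# Published per-allele effects used as generator presets.
VITD_EFFECTS = {
    "rs2282679": -0.091,   # GC, ln-nmol/L per effect allele
    "rs12794714": -0.039,  # CYP2R1
    "rs12785878": -0.042,  # DHCR7
}
T2D_LOG_ORS = {
    "rs1470579": math.log(1.12),  # IGF2BP2
    "rs7903146": math.log(1.25),  # TCF7L2
    "rs2237896": math.log(1.49),  # KCNQ1
}
#: Marginal per-allele T2D odds ratio of the vitamin-D synthesis SNP
#: (DHCR7), the one individual instrument with a disease signal.
DHCR7_T2D_OR = 1.05

# Effect-allele frequencies.  European values sit in the reported
# 0.22-0.32 range; the South Asian set differs only where a
# population-specific frequency was reported (GC, 0.73 in Sikhs).
EUROPEAN_EAF = {
    "rs2282679": 0.28,
    "rs12794714": 0.32,
    "rs12785878": 0.23,
    "rs1470579": 0.30,
    "rs7903146": 0.30,
    "rs2237896": 0.22,
}
SOUTH_ASIAN_EAF = {**EUROPEAN_EAF, "rs2282679": 0.73}

# Covariate distributions (age in years, BMI in kg/m^2), loosely calibrated
# to the combined case-control rows of the participating cohorts.
AGE_MEAN, AGE_SD = 52.0, 13.0
BMI_MEAN, BMI_SD = 26.5, 4.8
SEX_P = 0.5

DEFAULT_COVARIATE_EFFECTS = {
    # slopes on ln 25(OH)D (ln-nmol/L per unit)
    "vitd": {"age": -0.002, "sex": 0.05, "bmi": -0.01},
    # slopes on the T2D logit
    "t2d": {"age": 0.03, "sex": 0.2, "bmi": 0.08},
}

#: Baseline ln 25(OH)D by ancestry: ~55 nmol/L in Europeans, ~36 nmol/L in
#: South Asians, matching the reported separation of cohort means.
BASELINE_LN_VITD = {Ancestry.EUROPEAN: 4.0, Ancestry.SOUTH_ASIAN: 3.58}
VITD_SD = 0.5  # residual SD of ln 25(OH)D, ~50% coefficient of variation

TARGET_PREVALENCE = 0.10


class Scenario(str, enum.Enum):
    NULL = "NULL"
    FORWARD_CAUSAL = "FORWARD_CAUSAL"
    REVERSE_CAUSAL = "REVERSE_CAUSAL"
    INDEPENDENT = "INDEPENDENT"


@dataclass
class UvParams:
    """Optional per-sample UV-index covariate (supplied, not derived)."""

    mean: float = 5.0
    sd: float = 2.0
    effect_on_ln_vitd: float = 0.02


@dataclass
class SimulationParams:
    """Full parameterisation of one synthetic cohort."""

    n: int
    ancestry: Ancestry = Ancestry.EUROPEAN
    maf_by_snp: dict[str, float] = field(default_factory=dict)
    vitd_effects: dict[str, float] = field(default_factory=dict)
    t2d_log_ors: dict[str, float] = field(default_factory=dict)
    baseline_ln_vitd: float = BASELINE_LN_VITD[Ancestry.EUROPEAN]
    vitd_sd: float = VITD_SD
    t2d_intercept: float = math.log(TARGET_PREVALENCE / (1 - TARGET_PREVALENCE))
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    causal_vitd_to_t2d: float = 0.0
    reverse_t2d_to_vitd: float = 0.0
    pleiotropy: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    uv_index: UvParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ParameterError(f"cohort size must be positive, got {self.n}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.vitd_sd <= 0:
            raise ParameterError(f"vitd_sd must be positive, got {self.vitd_sd}")
        for rsid, q in self.maf_by_snp.items():
            if not 0.0 < q < 1.0:
                raise ParameterError(f"{rsid}: frequency {q} outside (0, 1)")
        if self.causal_vitd_to_t2d != 0.0 and self.reverse_t2d_to_vitd != 0.0:
            raise ConfigurationError(
                "causal_vitd_to_t2d and reverse_t2d_to_vitd are mutually exclusive; "
                "the causal direction must be unambiguous within one simulation"
            )


@dataclass
class Cohort:
    """Individual-level data: dosage matrix plus phenotype table.

    ``dosages`` is samples x SNPs with entries 0/1/2 or NaN for missing;
    ``phenotypes`` carries ``age`` (years), ``sex`` (0/1), ``bmi`` (kg/m^2),
    ``t2d`` (0/1), ``vitd_nmol_l`` (> 0) and optionally ``uv_index``.
    Both frames share the sample-id index.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.phenotypes.index):
            raise ParameterError("dosage and phenotype tables must share the same sample index")

    @property
    def ln_vitd(self) -> pd.Series:
        return np.log(self.phenotypes["vitd_nmol_l"])


def simulate_genotypes(
    n: int,
    maf_by_snp: dict[str, float],
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw Hardy-Weinberg dosages for each SNP independently.

    Dosage counts the effect allele, so P(0,1,2) = ((1-q)^2, 2q(1-q), q^2)
    for effect-allele frequency ``q`` -- a Binomial(2, q) draw.  Entries are
    then masked missing (NaN) independently with ``missing_rate``.
    """
    if n <= 0:
        raise ParameterError(f"cohort size must be positive, got {n}")
    if not 0.0 <= missing_rate < 1.0:
        raise ParameterError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = pd.Index([f"S{i + 1:06d}" for i in range(n)], name="sample_id")
    data = {}
    for rsid, q in maf_by_snp.items():
        if not 0.0 < q < 1.0:
            raise ParameterError(f"{rsid}: frequency {q} outside (0, 1)")
        g = rng.binomial(2, q, size=n).astype(float)
        if missing_rate > 0.0:
            g[rng.random(n) < missing_rate] = np.nan
        data[rsid] = g
    return pd.DataFrame(data, index=index)


def _genetic_lp(dosages: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    """Sum of per-allele effects; missing dosages contribute zero."""
    lp = np.zeros(len(dosages))
    for rsid, beta in effects.items():
        if beta == 0.0 or rsid not in dosages.columns:
            continue
        lp += beta * np.nan_to_num(dosages[rsid].to_numpy(), nan=0.0)
    return lp


def simulate_phenotypes(
    dosages: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Generate covariates and both outcomes on top of a dosage matrix.

    ln 25(OH)D = baseline + sum_j beta_j g_j + covariate terms
                 [+ reverse shift x T2D] + Normal(0, vitd_sd);
    logit P(T2D) = intercept + sum_j lnOR_j g_j + pleiotropy terms
                 + covariate terms [+ causal slope x ln 25(OH)D].

    T2D is drawn before 25(OH)D when the reverse path is active and after
    it when the causal path is active.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(dosages)
    age = rng.normal(AGE_MEAN, AGE_SD, n)
    sex = rng.binomial(1, SEX_P, n).astype(float)
    bmi = rng.normal(BMI_MEAN, BMI_SD, n)
    uv = rng.normal(params.uv_index.mean, params.uv_index.sd, n) if params.uv_index else None

    cov_v = params.covariate_effects.get("vitd", {})
    cov_t = params.covariate_effects.get("t2d", {})
    lp_vitd = (
        params.baseline_ln_vitd
        + _genetic_lp(dosages, params.vitd_effects)
        + cov_v.get("age", 0.0) * age
        + cov_v.get("sex", 0.0) * sex
        + cov_v.get("bmi", 0.0) * bmi
    )
    if uv is not None:
        lp_vitd = lp_vitd + params.uv_index.effect_on_ln_vitd * uv
    lp_t2d = (
        params.t2d_intercept
        + _genetic_lp(dosages, params.t2d_log_ors)
        + _genetic_lp(dosages, params.pleiotropy)
        + cov_t.get("age", 0.0) * age
        + cov_t.get("sex", 0.0) * sex
        + cov_t.get("bmi", 0.0) * bmi
    )

    noise = rng.normal(0.0, params.vitd_sd, n)
    if params.causal_vitd_to_t2d != 0.0:
        ln_vitd = lp_vitd + noise
        prob = 1.0 / (1.0 + np.exp(-(lp_t2d + params.causal_vitd_to_t2d * ln_vitd)))
        t2d = rng.binomial(1, prob).astype(int)
    else:
        prob = 1.0 / (1.0 + np.exp(-lp_t2d))
        t2d = rng.binomial(1, prob).astype(int)
        ln_vitd = lp_vitd + params.reverse_t2d_to_vitd * t2d + noise

    phen = pd.DataFrame(
        {
            "age": age,
            "sex": sex.astype(int),
            "bmi": bmi,
            "t2d": t2d,
            "vitd_nmol_l": np.exp(ln_vitd),
        },
        index=dosages.index,
    )
    if uv is not None:
        phen["uv_index"] = uv
    return Cohort(dosages=dosages, phenotypes=phen)


def simulate_cohort(params: SimulationParams) -> Cohort:
    """Generate a full cohort from a single seeded random stream."""
    rng = np.random.default_rng(params.seed)
    dosages = simulate_genotypes(params.n, params.maf_by_snp, params.missing_rate, rng)
    return simulate_phenotypes(dosages, params, rng)


def _expected_ln_vitd(params: SimulationParams) -> float:
    mean = params.baseline_ln_vitd
    for rsid, beta in params.vitd_effects.items():
        mean += beta * 2.0 * params.maf_by_snp.get(rsid, 0.0)
    cov = params.covariate_effects.get("vitd", {})
    mean += cov.get("age", 0.0) * AGE_MEAN + cov.get("sex", 0.0) * SEX_P + cov.get("bmi", 0.0) * BMI_MEAN
    if params.uv_index:
        mean += params.uv_index.effect_on_ln_vitd * params.uv_index.mean
    return mean


def calibrate_t2d_intercept(params: SimulationParams, prevalence: float = TARGET_PREVALENCE) -> float:
    """Intercept placing the logit at logit(prevalence) for a mean individual.

    Closed-form mean-covariate calibration; the realised case fraction sits
    close to (slightly above) the target because of the logistic
    non-collapsibility over covariate variation.
    """
    mean_lp = 0.0
    for rsid, lor in {**params.t2d_log_ors}.items():
        mean_lp += lor * 2.0 * params.maf_by_snp.get(rsid, 0.0)
    for rsid, lor in params.pleiotropy.items():
        mean_lp += lor * 2.0 * params.maf_by_snp.get(rsid, 0.0)
    cov = params.covariate_effects.get("t2d", {})
    mean_lp += cov.get("age", 0.0) * AGE_MEAN + cov.get("sex", 0.0) * SEX_P + cov.get("bmi", 0.0) * BMI_MEAN
    mean_lp += params.causal_vitd_to_t2d * _expected_ln_vitd(params)
    return math.log(prevalence / (1.0 - prevalence)) - mean_lp


#: Causal slope used by the FORWARD_CAUSAL preset (ln-OR of T2D per
#: ln-nmol/L of 25(OH)D; negative, i.e. lower vitamin D raises risk).
FORWARD_CAUSAL_SLOPE = -0.5
#: Case shift used by the REVERSE_CAUSAL preset (ln-nmol/L in T2D cases).
REVERSE_CAUSAL_SHIFT = -0.10


def default_presets(
    scenario: Scenario | str,
    n: int = 50_000,
    ancestry: Ancestry | str = Ancestry.EUROPEAN,
    seed: int = 0,
    missing_rate: float = 0.0,
    uv_index: UvParams | None = None,
) -> SimulationParams:
    """Preset parameters for the four study scenarios.

    ``INDEPENDENT`` installs the six published per-allele effects with no
    path between the traits; ``FORWARD_CAUSAL``/``REVERSE_CAUSAL`` switch
    on exactly one directed path on top of it; ``NULL`` zeroes every
    genetic effect.  The T2D intercept is calibrated so the case fraction
    is ~10% in each scenario.
    """
    scenario = Scenario(scenario)
    ancestry = Ancestry(ancestry)
    maf = dict(SOUTH_ASIAN_EAF if ancestry is Ancestry.SOUTH_ASIAN else EUROPEAN_EAF)
    params = SimulationParams(
        n=n,
        ancestry=ancestry,
        maf_by_snp=maf,
        vitd_effects={} if scenario is Scenario.NULL else dict(VITD_EFFECTS),
        t2d_log_ors={} if scenario is Scenario.NULL else dict(T2D_LOG_ORS),
        baseline_ln_vitd=BASELINE_LN_VITD[ancestry],
        missing_rate=missing_rate,
        uv_index=uv_index,
        seed=seed,
    )
    if scenario is Scenario.FORWARD_CAUSAL:
        params.causal_vitd_to_t2d = FORWARD_CAUSAL_SLOPE
    elif scenario is Scenario.REVERSE_CAUSAL:
        params.reverse_t2d_to_vitd = REVERSE_CAUSAL_SHIFT
    params.t2d_intercept = calibrate_t2d_intercept(params)
    return params


# ---------------------------------------------------------------------------
# Plain-text cohort files
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.dosages.tsv`` and ``<prefix>.phenotypes.tsv``."""
    prefix = Path(out_prefix)
    dosage_path = Path(str(prefix) + ".dosages.tsv")
    pheno_path = Path(str(prefix) + ".phenotypes.tsv")
    dosages = cohort.dosages.copy()
    # integral dosages print as 0/1/2, missing as NA
    formatted = dosages.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    formatted.to_csv(dosage_path, sep="\t")
    cohort.phenotypes.to_csv(pheno_path, sep="\t", na_rep="NA", float_format="%.10g")
    return dosage_path, pheno_path


def read_cohort(prefix: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    dosages = pd.read_csv(str(prefix) + ".dosages.tsv", sep="\t", index_col="sample_id", na_values="NA")
    phen = pd.read_csv(str(prefix) + ".phenotypes.tsv", sep="\t", index_col="sample_id", na_values="NA")
    return Cohort(dosages=dosages.astype(float), phenotypes=phen)
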