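"""Per-SNP and per-score additive association fits.

Thin wrappers around statsmodels OLS (ln 25(OH)D outcome) and Logit (T2D
outcome) that enforce the pipeline's conventions: complete-case analysis
(missing outcome or missing dosage drops the sample -- dosages are never
mean-imputed), additive 0/1/2 coding of the effect allele, Wald normal
z and two-sided p so that estimate, Z, p and direction are mutually
consistent, and explicit error signalling for degenerate designs and
perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .core import Scale, Trait, Z_95, sign_direction
from .exceptions import DegenerateDesignError, NonConvergenceError, SeparationError
from .io_tables import CohortSummary
from .meta import p_from_z
from .synthetic import Cohort

__all__ = ["AssociationResult", "fit_linear_vitd", "fit_logistic_t2d", "to_cohort_summary"]

#: design condition number above which a collinearity warning is recorded
_COND_WARN = 1e8


@dataclass
class AssociationResult:
    """Estimate/SE/Z/p from one additive regression fit.

    ``estimate`` is a slope on ln 25(OH)D for the VITD outcome and a ln-OR
    per effect allele for the T2D outcome.  ``z = estimate/se`` and ``p``
    is the two-sided normal tail, so ``direction == sign(z)`` always.
    """

    term: str
    outcome: Trait
    n: int
    estimate: float
    se: float
    z: float
    p: float
    direction: str
    eaf: float | None = None
    covariates_used: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _term_series(dosage_or_score, cohort: Cohort) -> tuple[pd.Series, str]:
    if isinstance(dosage_or_score, str):
        if dosage_or_score not in cohort.dosages.columns:
            raise LookupError(f"term {dosage_or_score!r} is not a dosage column")
        return cohort.dosages[dosage_or_score].astype(float), dosage_or_score
    series = pd.Series(np.asarray(dosage_or_score, dtype=float), index=cohort.phenotypes.index)
    name = getattr(dosage_or_score, "name", None)
    return series, str(name) if name else "term"


def _build_design(
    cohort: Cohort, dosage_or_score, covariates: list[str], outcome: pd.Series
) -> tuple[pd.Series, pd.DataFrame, str, float | None, list[str]]:
    term, name = _term_series(dosage_or_score, cohort)
    frame = pd.DataFrame({"__y": outcome, name: term})
    for cov in covariates:
        if cov not in cohort.phenotypes.columns:
            raise LookupError(f"covariate {cov!r} missing from phenotype table")
        frame[cov] = cohort.phenotypes[cov].astype(float)
    frame = frame.dropna()
    y = frame.pop("__y")
    if len(frame) < 30:
        raise DegenerateDesignError(f"only {len(frame)} complete cases; need at least 30")
    if frame[name].nunique() < 2:
        raise DegenerateDesignError(f"term {name!r} is constant over complete cases")
    X = sm.add_constant(frame, has_constant="add")

    warnings: list[str] = []
    cond = np.linalg.cond(np.asarray(X, dtype=float))
    if cond > _COND_WARN:
        warnings.append(f"ill-conditioned design (condition number {cond:.3g})")

    term_vals = frame[name]
    eaf = None
    if term_vals.min() >= 0.0 and term_vals.max() <= 2.0:
        eaf = float(term_vals.mean() / 2.0)  # dosage-like term
    return y, X, name, eaf, warnings


def _package(name, outcome, n, estimate, se, eaf, covariates, warnings) -> AssociationResult:
    z = estimate / se
    return AssociationResult(
        term=name,
        outcome=outcome,
        n=n,
        estimate=float(estimate),
        se=float(se),
        z=float(z),
        p=p_from_z(z),
        direction=sign_direction(z),
        eaf=eaf,
        covariates_used=list(covariates),
        warnings=warnings,
    )


def fit_linear_vitd(dosage_or_score, cohort: Cohort, covariates: list[str] | None = None) -> AssociationResult:
    """OLS of ln 25(OH)D on a dosage or score term plus covariates.

    Samples with missing 25(OH)D or a missing term value are excluded;
    ``n`` counts analysed samples only.
    """
    covariates = list(covariates or [])
    vitd = cohort.phenotypes["vitd_nmol_l"].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_vitd = np.log(vitd.where(vitd > 0))
    y, X, name, eaf, warn = _build_design(cohort, dosage_or_score, covariates, ln_vitd)
    fit = sm.OLS(y, X).fit()
    return _package(name, Trait.VITD, int(fit.nobs), fit.params[name], fit.bse[name], eaf, covariates, warn)


def fit_logistic_t2d(dosage_or_score, cohort: Cohort, covariates: list[str] | None = None) -> AssociationResult:
    """Maximum-likelihood logistic fit of T2D on a dosage or score term.

    The estimate is the ln-OR per effect allele (or per score unit).
    Newton iterations converge on relative log-likelihood change < 1e-8
    within 50 iterations; perfect separation raises :class:`SeparationError`.
    """
    covariates = list(covariates or [])
    t2d = cohort.phenotypes["t2d"].astype(float)
    y, X, name, eaf, warn = _build_design(cohort, dosage_or_score, covariates, t2d)
    if y.nunique() < 2:
        raise DegenerateDesignError("both outcome classes must be present")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=50, tol=1e-8)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"perfect separation: effect not estimable ({exc})") from exc
    if not fit.mle_retvals.get("converged", True):
        raise NonConvergenceError(f"logistic fit did not converge: {fit.mle_retvals}")
    se = fit.bse[name]
    if not np.isfinite(se) or se > 1e3:
        raise SeparationError(f"effect for {name!r} is not estimable (SE={se:.3g})")
    return _package(name, Trait.T2D, int(fit.nobs), fit.params[name], se, eaf, covariates, warn)


def to_cohort_summary(result: AssociationResult, cohort_label: str, ancestry=None) -> CohortSummary:
    """Map an association result to a cohort-level summary row.

    For the T2D outcome the CI is expressed on the OR scale,
    exp(estimate +/- 1.959964 * SE), matching the published table layout.
    """
    lo = result.estimate - Z_95 * result.se
    hi = result.estimate + Z_95 * result.se
    if result.outcome is Trait.T2D:
        scale, ci_low, ci_high = Scale.LN_OR, float(np.exp(lo)), float(np.exp(hi))
    else:
        scale, ci_low, ci_high = Scale.BETA, lo, hi
    return CohortSummary(
        cohort=cohort_label,
        ancestry=ancestry,
        n=result.n,
        outcome=result.outcome,
        scale=scale,
        estimate=result.estimate,
        se=result.se,
        ci_low=ci_low,
        ci_high=ci_high,
        p=result.p,
        direction=result.direction,
        z=result.z,
    )
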