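"""Bidirectional causal inference from instrument-trait associations.

The forward arm asks whether genetically lowered 25(OH)D raises T2D risk
(vitamin-D-pathway instruments); the reverse arm asks whether genetic T2D
liability shifts 25(OH)D (T2D instruments).  Each arm pairs the
instrument-exposure association with the instrument-outcome association;
the Wald ratio beta_outcome / beta_exposure with a first-order delta-method
SE turns the pair into a causal estimate, and a Bonferroni-corrected
threshold (0.05 / 8 tested variables = 0.0063) gates the verdicts.

The verdict rule per direction:

* ``SUPPORTED``      -- instrument-exposure p < alpha AND instrument-outcome
                        p < alpha (a quantifiable, significant causal path).
* ``NOT_SUPPORTED``  -- the instrument is valid (exposure p < alpha) but the
                        outcome association is null.
* ``INCONCLUSIVE``   -- the instrument fails on its own exposure, so the
                        direction cannot be tested.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

from .exceptions import ParameterError, WeakInstrumentError
from .meta import p_from_z

__all__ = [
    "MrEstimate",
    "MrReport",
    "Verdict",
    "DEFAULT_ALPHA",
    "wald_ratio",
    "bidirectional_report",
    "headline_scale",
]

#: Bonferroni threshold: 0.05 over the 8 tested variables (six instrument
#: SNPs plus the two traits); prints as 0.0063 at 2 significant figures.
DEFAULT_ALPHA = 0.05 / 8


class Verdict(str, enum.Enum):
    SUPPORTED = "SUPPORTED"
    NOT_SUPPORTED = "NOT_SUPPORTED"
    INCONCLUSIVE = "INCONCLUSIVE"


def _est_se_p(assoc) -> tuple[float, float, float]:
    """(estimate, se, p) from an AssociationResult, MetaResult, CohortSummary or tuple."""
    if isinstance(assoc, tuple):
        b, se = float(assoc[0]), float(assoc[1])
        p = float(assoc[2]) if len(assoc) > 2 else p_from_z(b / se)
        return b, se, p
    if hasattr(assoc, "estimate_additive"):  # CohortSummary
        return assoc.estimate_additive(), assoc.se_additive(), assoc.p
    return float(assoc.estimate), float(assoc.se), float(assoc.p)


@dataclass
class MrEstimate:
    """Wald-ratio causal estimate for one instrument (or the composite).

    ``beta_iv`` is on the outcome's additive scale per unit of exposure;
    for the forward arm here, ln-OR of T2D per ln-nmol/L of 25(OH)D.
    """

    instrument: str
    beta_iv: float
    se_iv: float
    z: float
    p: float
    exposure_assoc: object = None
    outcome_assoc: object = None


def wald_ratio(exposure, outcome, instrument: str = "composite") -> MrEstimate:
    """IV ratio estimate beta_GY / beta_GX with delta-method SE.

    ``se_iv = |beta_iv| * sqrt(SE_GY^2/beta_GY^2 + SE_GX^2/beta_GX^2)``,
    falling back to ``SE_GY / |beta_GX|`` when beta_GY = 0.
    """
    b_gx, se_gx, _ = _est_se_p(exposure)
    b_gy, se_gy, _ = _est_se_p(outcome)
    if b_gx == 0.0:
        raise WeakInstrumentError(f"{instrument}: exposure effect is zero; Wald ratio undefined")
    if se_gx <= 0 or se_gy <= 0:
        raise ParameterError("both standard errors must be positive")
    beta_iv = b_gy / b_gx
    if b_gy == 0.0:
        se_iv = se_gy / abs(b_gx)
    else:
        se_iv = abs(beta_iv) * math.sqrt((se_gy / b_gy) ** 2 + (se_gx / b_gx) ** 2)
    z = beta_iv / se_iv
    return MrEstimate(
        instrument=instrument,
        beta_iv=beta_iv,
        se_iv=se_iv,
        z=z,
        p=p_from_z(z),
        exposure_assoc=exposure,
        outcome_assoc=outcome,
    )


@dataclass
class MrReport:
    """Assembled bidirectional report."""

    forward: list[MrEstimate]
    reverse: list[MrEstimate]
    alpha: float
    verdicts: dict[str, Verdict]
    notes: list[str] = field(default_factory=list)


def _direction_verdict(
    label: str,
    exposure_by_instrument: Mapping[str, object],
    outcome_by_instrument: Mapping[str, object],
    alpha: float,
    notes: list[str],
) -> tuple[list[MrEstimate], Verdict]:
    if set(exposure_by_instrument) != set(outcome_by_instrument):
        raise ParameterError(
            f"{label}: exposure and outcome analyses must cover the same instruments "
            f"({sorted(exposure_by_instrument)} vs {sorted(outcome_by_instrument)})"
        )
    estimates: list[MrEstimate] = []
    passing: list[str] = []
    for name in exposure_by_instrument:
        exp, out = exposure_by_instrument[name], outcome_by_instrument[name]
        est = wald_ratio(exp, out, instrument=name)
        estimates.append(est)
        _, _, p_exp = _est_se_p(exp)
        _, _, p_out = _est_se_p(out)
        if p_exp < alpha and p_out < alpha:
            passing.append(name)
            notes.append(f"{label}/{name}: exposure p={p_exp:.3g} and outcome p={p_out:.3g} both below alpha")
    # the composite instrument decides the direction; individual
    # instruments are reported alongside (the per-instrument pattern can
    # differ, e.g. a single synthesis-pathway SNP carrying the signal)
    key = "composite" if "composite" in exposure_by_instrument else sorted(exposure_by_instrument)[0]
    _, _, p_exp = _est_se_p(exposure_by_instrument[key])
    _, _, p_out = _est_se_p(outcome_by_instrument[key])
    if p_exp >= alpha:
        verdict = Verdict.INCONCLUSIVE
        notes.append(f"{label}: composite instrument not associated with its exposure (p={p_exp:.3g})")
    elif p_out < alpha:
        verdict = Verdict.SUPPORTED
    else:
        verdict = Verdict.NOT_SUPPORTED
    return estimates, verdict


def bidirectional_report(
    forward_exposure: Mapping[str, object],
    forward_outcome: Mapping[str, object],
    reverse_exposure: Mapping[str, object],
    reverse_outcome: Mapping[str, object],
    alpha: float = DEFAULT_ALPHA,
) -> MrReport:
    """Assemble per-direction Wald ratios and verdicts.

    Each mapping is keyed by instrument label (use ``"composite"`` for the
    allele score) and valued by an association/meta result.  Within each
    direction the exposure and outcome mappings must cover the same
    instruments.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    notes: list[str] = []
    forward, fwd_verdict = _direction_verdict("forward", forward_exposure, forward_outcome, alpha, notes)
    reverse, rev_verdict = _direction_verdict("reverse", reverse_exposure, reverse_outcome, alpha, notes)
    return MrReport(
        forward=forward,
        reverse=reverse,
        alpha=alpha,
        verdicts={"forward": fwd_verdict, "reverse": rev_verdict},
        notes=notes,
    )


class HeadlineScale(NamedTuple):
    """Reporting-convention conversions of an ln-scale beta."""

    per_hundred: float      # 100 * beta, the convention used for "nmol/L" figures
    percent_change: float   # exact percent change, 100 * (exp(beta) - 1)


def headline_scale(beta_ln: float) -> HeadlineScale:
    """Express an ln-nmol/L effect the way the headline figures print it.

    Published headline effects multiply the ln-scale beta by 100 and label
    it nmol/L (e.g. -0.042 -> "-4.2 nmol/L"); the exact percent change
    100*(exp(beta)-1) is returned alongside.
    """
    return HeadlineScale(per_hundred=100.0 * beta_ln, percent_change=100.0 * (math.exp(beta_ln) - 1.0))
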