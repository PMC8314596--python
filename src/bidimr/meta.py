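"""Cross-cohort combination of summary statistics.

Three schemes:

* ``ivw_fixed`` -- fixed-effect inverse-variance weighting on the additive
  scale (beta or ln-OR), the scheme behind the pooled estimate columns of
  the published tables.
* ``stouffer_unweighted`` -- Z = sum(z_i)/sqrt(k) from per-cohort signed Z
  values.  This is the scheme that reproduces every printed combined Z in
  the source tables.
* ``stouffer_sample_weighted`` -- Z = sum(sqrt(n_i) z_i)/sqrt(sum n_i),
  provided for comparison (it does not reproduce the printed values).

The p <-> Z transforms are tail-safe: Z from p uses the inverse-normal
quantile (accurate down to p ~ 1e-300) and p from Z uses the complementary
error function, never 1 - CDF, so nothing underflows before |Z| ~ 38.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import direction_sign
from .exceptions import ValidationError
from .io_tables import CohortSummary

__all__ = [
    "MetaResult",
    "MetaScheme",
    "z_from_p",
    "p_from_z",
    "ivw_fixed",
    "stouffer_unweighted",
    "stouffer_sample_weighted",
    "heterogeneity",
    "forest_data",
    "render_forest",
]


class MetaScheme(str, enum.Enum):
    IVW = "IVW"
    STOUFFER = "STOUFFER"
    SAMPLE_WEIGHTED_Z = "SAMPLE_WEIGHTED_Z"


@dataclass
class MetaResult:
    """Combined result across cohorts.

    ``estimate``/``se`` are populated for the IVW scheme only; the Z
    schemes produce no pooled effect size.  ``direction_string``
    concatenates per-cohort direction marks in input order, as in the
    published tables.  Heterogeneity fields are NaN when k < 2.
    """

    k: int
    n_total: int
    z: float
    p: float
    scheme: MetaScheme
    direction_string: str
    estimate: float | None = None
    se: float | None = None
    q_stat: float = math.nan
    i2: float = math.nan
    p_het: float = math.nan


def z_from_p(p: float, direction: str | int) -> float:
    """Signed Z from a two-sided p: sign * Phi^-1(1 - p/2)."""
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"p={p} outside (0, 1]")
    sign = direction if isinstance(direction, (int, float)) else direction_sign(direction)
    return float(np.sign(sign) * stats.norm.isf(p / 2.0))


def p_from_z(z: float) -> float:
    """Two-sided p from Z via erfc; safe far into the tail."""
    p = float(special.erfc(abs(z) / math.sqrt(2.0)))
    return max(p, 5e-324)  # keep p in (0, 1] even when erfc underflows


def _cohort_rows(rows: Sequence[CohortSummary], include_subtotals: bool) -> list[CohortSummary]:
    kept = [r for r in rows if include_subtotals or not r.subtotal]
    if not kept:
        raise ValidationError("no cohort rows to combine")
    return kept


def heterogeneity(rows: Sequence[CohortSummary], include_subtotals: bool = False):
    """Cochran's Q, I^2 and the chi-square heterogeneity p across cohorts.

    Returns ``(nan, nan, nan)`` for fewer than two rows, where the
    statistics are undefined.
    """
    rows = _cohort_rows(rows, include_subtotals)
    if len(rows) < 2:
        return math.nan, math.nan, math.nan
    b = np.array([r.estimate_additive() for r in rows])
    w = np.array([1.0 / r.se_additive() ** 2 for r in rows])
    pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    i2 = max(0.0, (q - (len(rows) - 1)) / q) if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, len(rows) - 1))
    return q, i2, max(p_het, 5e-324)


def ivw_fixed(rows: Sequence[CohortSummary], include_subtotals: bool = False) -> MetaResult:
    """Fixed-effect inverse-variance pooling on the additive scale.

    Weights are 1/SE^2 with SEs reconstructed from 95% CIs where absent.
    Q, I^2 and the heterogeneity p are always reported (NaN for k = 1).
    """
    rows = _cohort_rows(rows, include_subtotals)
    b = np.array([r.estimate_additive() for r in rows])
    se = np.array([r.se_additive() for r in rows])
    if np.any(se <= 0):
        raise ValidationError("all SEs must be positive")
    w = 1.0 / se**2
    estimate = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = estimate / pooled_se
    q, i2, p_het = heterogeneity(rows, include_subtotals=True) if len(rows) > 1 else (math.nan,) * 3
    return MetaResult(
        k=len(rows),
        n_total=int(sum(r.n for r in rows)),
        estimate=estimate,
        se=pooled_se,
        z=float(z),
        p=p_from_z(z),
        scheme=MetaScheme.IVW,
        direction_string="".join(r.direction for r in rows),
        q_stat=q,
        i2=i2,
        p_het=p_het,
    )


def stouffer_unweighted(rows: Sequence[CohortSummary], include_subtotals: bool = False) -> MetaResult:
    """Unweighted Stouffer combination: Z = sum(z_i) / sqrt(k)."""
    rows = _cohort_rows(rows, include_subtotals)
    zs = [z_from_p(r.p, r.direction) for r in rows]
    z = float(np.sum(zs) / math.sqrt(len(zs)))
    return MetaResult(
        k=len(rows),
        n_total=int(sum(r.n for r in rows)),
        z=z,
        p=p_from_z(z),
        scheme=MetaScheme.STOUFFER,
        direction_string="".join(r.direction for r in rows),
    )


def stouffer_sample_weighted(rows: Sequence[CohortSummary], include_subtotals: bool = False) -> MetaResult:
    """Sample-size-weighted Stouffer: Z = sum(sqrt(n_i) z_i) / sqrt(sum n_i)."""
    rows = _cohort_rows(rows, include_subtotals)
    for r in rows:
        if r.n is None or r.n <= 0:
            raise ValidationError(f"{r.cohort}: sample size required for the weighted scheme")
    zs = np.array([z_from_p(r.p, r.direction) for r in rows])
    ns = np.array([r.n for r in rows], dtype=float)
    z = float(np.sum(np.sqrt(ns) * zs) / math.sqrt(np.sum(ns)))
    return MetaResult(
        k=len(rows),
        n_total=int(ns.sum()),
        z=z,
        p=p_from_z(z),
        scheme=MetaScheme.SAMPLE_WEIGHTED_Z,
        direction_string="".join(r.direction for r in rows),
    )


# ---------------------------------------------------------------------------
# Forest output
# ---------------------------------------------------------------------------

def forest_data(rows: Sequence[CohortSummary], meta: MetaResult | None = None) -> pd.DataFrame:
    """Per-cohort estimates, CIs and IVW weight percentages for plotting.

    Rows appear in input order; the pooled row, when supplied, comes last
    with weight 100.  Columns: ``label estimate ci_low ci_high weight_pct``.
    """
    rows = _cohort_rows(rows, include_subtotals=False)
    b = [r.estimate_additive() for r in rows]
    se = np.array([r.se_additive() for r in rows])
    w = 1.0 / se**2
    weight_pct = 100.0 * w / w.sum()
    from .core import Z_95

    records = [
        {
            "label": r.cohort,
            "estimate": bi,
            "ci_low": bi - Z_95 * si,
            "ci_high": bi + Z_95 * si,
            "weight_pct": wp,
        }
        for r, bi, si, wp in zip(rows, b, se, weight_pct)
    ]
    if meta is not None and meta.estimate is not None:
        records.append(
            {
                "label": f"META ({meta.scheme.value})",
                "estimate": meta.estimate,
                "ci_low": meta.estimate - Z_95 * meta.se,
                "ci_high": meta.estimate + Z_95 * meta.se,
                "weight_pct": 100.0,
            }
        )
    return pd.DataFrame.from_records(records, columns=["label", "estimate", "ci_low", "ci_high", "weight_pct"])


def render_forest(data: pd.DataFrame, width: int = 50) -> str:
    """Minimal plain-text forest rendering of :func:`forest_data` output."""
    lo, hi = data["ci_low"].min(), data["ci_high"].max()
    span = (hi - lo) or 1.0
    pos = lambda x: int(round((x - lo) / span * (width - 1)))
    lines = []
    label_w = max(len(l) for l in data["label"])
    for _, row in data.iterrows():
        bar = [" "] * width
        for i in range(pos(row["ci_low"]), pos(row["ci_high"]) + 1):
            bar[i] = "-"
        bar[pos(row["estimate"])] = "x"
        lines.append(
            f"{row['label']:<{label_w}} |{''.join(bar)}| "
            f"{row['estimate']: .4f} [{row['ci_low']: .4f}, {row['ci_high']: .4f}] {row['weight_pct']:5.1f}%"
        )
    return "\n".join(lines)
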