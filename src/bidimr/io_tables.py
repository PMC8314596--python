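"""Reading and writing instrument definitions and cohort-level summary statistics.

Two plain-text tab-delimited formats are supported:

* **Summary TSV** -- one cohort-level association result per row, columns
  ``cohort ancestry n outcome scale estimate se ci_low ci_high p direction
  subtotal`` (an optional ``z`` column carries printed combined Z values on
  subtotal/meta rows).  Odds ratios are converted to the ln-OR scale on
  ingest, with a provenance flag, so that every downstream combination
  operates on an additive scale.

* **Instrument TSV** -- one SNP instrument per row, columns
  ``rsid gene effect_allele other_allele eaf weight exposure``.

The per-cohort rows of the published score-association tables (the T2D
score on T2D and on 25(OH)D; the vitamin-D score on 25(OH)D and on T2D)
ship as packaged fixtures and are exposed through :func:`load_fixture`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .core import Ancestry, Scale, Trait, Z_95, direction_sign
from .exceptions import FormatError, ValidationError

__all__ = [
    "SnpInstrument",
    "CohortSummary",
    "FixtureTable",
    "TableId",
    "se_from_ci",
    "read_summaries",
    "write_summaries",
    "read_instruments",
    "write_instruments",
    "load_fixture",
]

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SnpInstrument:
    """One instrument SNP: identity, effect allele, and per-allele weight.

    ``weight`` is the per-allele effect on the exposure's additive scale:
    ln-OR when the exposure is T2D, ln-nmol/L slope when the exposure is
    25(OH)D.  Dosages downstream count copies of ``effect_allele``.
    """

    rsid: str
    gene: str
    effect_allele: str
    other_allele: str
    eaf: float
    weight: float
    exposure: Trait

    def __post_init__(self) -> None:
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise ValidationError(
                f"{self.rsid}: alleles must be single nucleotide codes, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not 0.0 < self.eaf < 1.0:
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside (0, 1)")


@dataclass
class CohortSummary:
    """One cohort's association result for one term and one outcome.

    Exactly one of ``se`` or the ``(ci_low, ci_high)`` pair is required on
    ingest; computed summaries may carry both.  ``z`` is optional and only
    populated for printed subtotal/meta rows transcribed from the source
    tables.  ``from_or`` flags rows whose estimate was converted from a
    printed odds ratio to the ln-OR scale (their CI bounds remain on the OR
    scale as printed).
    """

    cohort: str
    ancestry: Ancestry | None
    n: int
    outcome: Trait
    scale: Scale
    estimate: float | None
    se: float | None
    ci_low: float | None
    ci_high: float | None
    p: float
    direction: str
    subtotal: bool = False
    z: float | None = None
    from_or: bool = False

    def validate(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.cohort}: p={self.p} outside (0, 1]")
        if self.se is None and (self.ci_low is None or self.ci_high is None):
            raise ValidationError(f"{self.cohort}: neither SE nor CI present")
        if self.se is not None and self.se <= 0:
            raise ValidationError(f"{self.cohort}: SE must be positive, got {self.se}")
        if self.n <= 0:
            raise ValidationError(f"{self.cohort}: n must be positive, got {self.n}")
        direction_sign(self.direction)

    # -- additive-scale accessors ------------------------------------------

    def estimate_additive(self) -> float:
        """Effect estimate on the additive scale (BETA or ln-OR)."""
        if self.estimate is None:
            raise ValidationError(f"{self.cohort}: no estimate present")
        if self.scale is Scale.OR:
            return math.log(self.estimate)
        return self.estimate

    def se_additive(self) -> float:
        """SE on the additive scale, reconstructed from the CI if absent.

        CI bounds on rows converted from printed odds ratios are still on
        the OR scale, so reconstruction logs them first.
        """
        if self.se is not None:
            return self.se
        ci_scale = Scale.LN_OR if (self.from_or or self.scale in (Scale.OR, Scale.LN_OR)) else Scale.BETA
        return se_from_ci(self.ci_low, self.ci_high, ci_scale)


class TableId(str, enum.Enum):
    """The four published score-association tables."""

    T2D_SCORE_ON_T2D = "T2D_SCORE_ON_T2D"
    T2D_SCORE_ON_VITD = "T2D_SCORE_ON_VITD"
    VITD_SCORE_ON_VITD = "VITD_SCORE_ON_VITD"
    VITD_SCORE_ON_T2D = "VITD_SCORE_ON_T2D"


_FIXTURE_FILES = {
    TableId.T2D_SCORE_ON_T2D: "t2d_score_on_t2d.tsv",
    TableId.T2D_SCORE_ON_VITD: "t2d_score_on_vitd.tsv",
    TableId.VITD_SCORE_ON_VITD: "vitd_score_on_vitd.tsv",
    TableId.VITD_SCORE_ON_T2D: "vitd_score_on_t2d.tsv",
}

#: Cohort label used by the fixtures' printed all-cohort meta row.
META_LABEL = "Meta-Analysis"


@dataclass
class FixtureTable:
    """A transcribed score-association table.

    ``rows`` holds the per-cohort records only; ancestry subtotal rows and
    the table's printed meta row are stored separately so that combination
    operations never mix pooled rows into an all-cohort combination.
    """

    table_id: TableId
    rows: list[CohortSummary]
    subtotals: list[CohortSummary] = field(default_factory=list)
    printed_meta: CohortSummary | None = None


def se_from_ci(ci_low: float, ci_high: float, scale: Scale | str) -> float:
    """Reconstruct a standard error from a 95% confidence interval.

    Returns ``(t(ci_high) - t(ci_low)) / (2 * 1.959964)`` where ``t`` is the
    natural log for the ln-OR scale and the identity for the beta scale.
    """
    scale = Scale(scale)
    if ci_low is None or ci_high is None:
        raise ValidationError("CI bounds required")
    if ci_high <= ci_low:
        raise ValidationError(f"ci_high ({ci_high}) must exceed ci_low ({ci_low})")
    if scale in (Scale.LN_OR, Scale.OR):
        if ci_low <= 0 or ci_high <= 0:
            raise ValidationError("OR-scale CI bounds must be positive")
        return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return (ci_high - ci_low) / (2.0 * Z_95)


# ---------------------------------------------------------------------------
# Summary TSV
# ---------------------------------------------------------------------------

_MANDATORY = ["cohort", "n", "outcome", "scale", "p", "direction"]
_COLUMNS = [
    "cohort", "ancestry", "n", "outcome", "scale", "estimate", "se",
    "ci_low", "ci_high", "p", "direction", "subtotal", "z",
]


def _opt_float(value: str) -> float | None:
    value = value.strip()
    return float(value) if value not in ("", "NA", "nan") else None


def read_summaries(path) -> list[CohortSummary]:
    """Read a Summary TSV into a list of :class:`CohortSummary`.

    Printed odds ratios (``scale`` = OR) are converted to the ln-OR scale
    (``estimate := ln OR``) with ``from_or=True``; row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    out: list[CohortSummary] = []
    for idx, row in df.iterrows():
        try:
            p = float(row["p"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx}: unparsable p {row['p']!r}") from exc
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"{path}: row {idx}: p={p} outside (0, 1]")
        scale = Scale(row["scale"])
        estimate = _opt_float(row.get("estimate", ""))
        from_or = False
        if scale is Scale.OR and estimate is not None:
            estimate = math.log(estimate)
            scale = Scale.LN_OR
            from_or = True
        ancestry_raw = row.get("ancestry", "").strip()
        summary = CohortSummary(
            cohort=row["cohort"],
            ancestry=Ancestry(ancestry_raw) if ancestry_raw else None,
            n=int(row["n"].replace(",", "")),
            outcome=Trait(row["outcome"]),
            scale=scale,
            estimate=estimate,
            se=_opt_float(row.get("se", "")),
            ci_low=_opt_float(row.get("ci_low", "")),
            ci_high=_opt_float(row.get("ci_high", "")),
            p=p,
            direction=row["direction"].strip(),
            subtotal=row.get("subtotal", "0").strip() in ("1", "true", "True"),
            z=_opt_float(row.get("z", "")),
            from_or=from_or,
        )
        summary.validate()
        out.append(summary)
    return out


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.12g}"
    return str(value)


def write_summaries(summaries: Iterable[CohortSummary], path) -> None:
    """Write summaries back to the Summary TSV format.

    Rows ingested from printed odds ratios are written back on the OR scale
    so a read/write cycle reproduces the numeric fields of the input.
    """
    records = []
    for s in summaries:
        estimate, scale = s.estimate, s.scale
        if s.from_or and estimate is not None:
            estimate, scale = math.exp(estimate), Scale.OR
        records.append({
            "cohort": s.cohort,
            "ancestry": s.ancestry.value if s.ancestry else "",
            "n": s.n,
            "outcome": s.outcome.value,
            "scale": scale.value,
            "estimate": _fmt(estimate),
            "se": _fmt(s.se),
            "ci_low": _fmt(s.ci_low),
            "ci_high": _fmt(s.ci_high),
            "p": _fmt(s.p),
            "direction": s.direction,
            "subtotal": int(s.subtotal),
            "z": _fmt(s.z),
        })
    pd.DataFrame.from_records(records, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Instrument TSV
# ---------------------------------------------------------------------------

_INSTRUMENT_COLUMNS = ["rsid", "gene", "effect_allele", "other_allele", "eaf", "weight", "exposure"]


def read_instruments(path) -> list[SnpInstrument]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _INSTRUMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return [
        SnpInstrument(
            rsid=row["rsid"],
            gene=row["gene"],
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]),
            weight=float(row["weight"]),
            exposure=Trait(row["exposure"]),
        )
        for _, row in df.iterrows()
    ]


def write_instruments(instruments: Sequence[SnpInstrument], path) -> None:
    pd.DataFrame.from_records(
        [
            {
                "rsid": i.rsid,
                "gene": i.gene,
                "effect_allele": i.effect_allele,
                "other_allele": i.other_allele,
                "eaf": _fmt(i.eaf),
                "weight": _fmt(i.weight),
                "exposure": i.exposure.value,
            }
            for i in instruments
        ],
        columns=_INSTRUMENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def load_fixture(table_id: TableId | str) -> FixtureTable:
    """Load one of the four packaged score-association tables.

    Per-cohort rows, ancestry subtotal rows, and the printed meta row are
    returned in separate slots of the :class:`FixtureTable`.
    """
    try:
        table_id = TableId(table_id)
    except ValueError as exc:
        raise LookupError(f"unknown table id: {table_id!r}") from exc
    ref = resources.files("bidimr.data").joinpath(_FIXTURE_FILES[table_id])
    with resources.as_file(ref) as fp:
        summaries = read_summaries(fp)
    rows = [s for s in summaries if not s.subtotal]
    subtotals = [s for s in summaries if s.subtotal and s.cohort != META_LABEL]
    printed = [s for s in summaries if s.cohort == META_LABEL]
    return FixtureTable(
        table_id=table_id,
        rows=rows,
        subtotals=subtotals,
        printed_meta=printed[0] if printed else None,
    )


def packaged_instruments(exposure: Trait | str) -> list[SnpInstrument]:
    """The six published instruments, filtered to one exposure trait."""
    exposure = Trait(exposure)
    ref = resources.files("bidimr.data").joinpath("instruments.tsv")
    with resources.as_file(ref) as fp:
        instruments = read_instruments(fp)
    return [i for i in instruments if i.exposure is exposure]
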