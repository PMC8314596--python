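"""Weighted composite allele-score construction.

The score is the composite instrument of the analysis: per sample,
sum_j weight_j * dosage_j over the instrument SNPs, with PLINK
``--score``-compatible missing-data semantics.  Under no-mean-imputation
(the default, matching the published construction) a missing genotype
contributes zero; the alternative replaces it with its frequency-expected
dosage 2*eaf.  Scores are normalised to mean 0, SD 1 before regression, so
score-on-outcome effects read as per-SD-of-score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Trait
from .exceptions import ConfigurationError, DegenerateDesignError
from .io_tables import SnpInstrument

__all__ = ["ScoreSpec", "ScoreMode", "build_score", "standardize", "score_weights_from_results"]


class ScoreMode(str, enum.Enum):
    SUM = "SUM"
    AVERAGE = "AVERAGE"


@dataclass
class ScoreSpec:
    """Specification of one composite allele score."""

    name: str
    instruments: list[SnpInstrument]
    mode: ScoreMode = ScoreMode.SUM
    no_mean_imputation: bool = True
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.instruments:
            raise ConfigurationError("a score needs at least one instrument")
        exposures = {i.exposure for i in self.instruments}
        if len(exposures) > 1:
            raise ConfigurationError(
                f"all instruments must share one exposure trait, got {sorted(e.value for e in exposures)}"
            )

    @property
    def exposure(self) -> Trait:
        return self.instruments[0].exposure


def build_score(dosages: pd.DataFrame, spec: ScoreSpec) -> pd.Series:
    """Per-sample raw (and optionally standardised) weighted allele score.

    SUM mode: sum_j w_j g_j over non-missing j (missing contributes 0
    under no-mean-imputation, else g_j is replaced by 2*eaf_j).  AVERAGE
    mode divides by the number of non-missing alleles (2 x non-missing SNP
    count).  Samples with every instrument SNP missing get a missing score.
    """
    rsids = [i.rsid for i in spec.instruments]
    absent = [r for r in rsids if r not in dosages.columns]
    if absent:
        raise LookupError(f"instrument SNP(s) missing from dosage columns: {', '.join(absent)}")
    G = dosages[rsids].to_numpy(dtype=float)
    w = np.array([i.weight for i in spec.instruments])
    missing = np.isnan(G)
    if spec.no_mean_imputation:
        filled = np.where(missing, 0.0, G)
    else:
        expected = 2.0 * np.array([i.eaf for i in spec.instruments])
        filled = np.where(missing, expected[None, :], G)
    raw = filled @ w
    if spec.mode is ScoreMode.AVERAGE:
        n_alleles = 2.0 * (~missing if spec.no_mean_imputation else np.ones_like(missing, dtype=bool)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(n_alleles > 0, raw / n_alleles, np.nan)
    raw = np.where(missing.all(axis=1), np.nan, raw)
    score = pd.Series(raw, index=dosages.index, name=spec.name)
    return standardize(score) if spec.standardize else score


def standardize(score: pd.Series) -> pd.Series:
    """Centre and scale to sample SD 1 over non-missing entries."""
    values = score.dropna()
    if values.nunique() < 2:
        raise DegenerateDesignError(f"score {score.name!r} is constant; cannot standardise")
    out = (score - values.mean()) / values.std(ddof=1)
    out.name = score.name
    return out


def score_weights_from_results(results: Sequence, instruments: Sequence[SnpInstrument] | None = None) -> list[SnpInstrument]:
    """Instrument weights taken from per-SNP association estimates.

    All results must share one outcome; each estimate (ln-OR for T2D,
    ln-scale beta for 25(OH)D) becomes the weight of the matching
    instrument, preserving effect-allele orientation.  ``instruments``
    supplies allele/gene metadata matched by rsid; without it, minimal
    placeholder instruments are synthesised from the results alone.
    """
    outcomes = {r.outcome for r in results}
    if len(outcomes) != 1:
        raise ConfigurationError(f"mixed outcomes in weight source: {sorted(o.value for o in outcomes)}")
    outcome = outcomes.pop()
    by_rsid = {i.rsid: i for i in instruments or []}
    out = []
    for r in results:
        if r.term in by_rsid:
            out.append(replace(by_rsid[r.term], weight=float(r.estimate), exposure=outcome))
        else:
            out.append(
                SnpInstrument(
                    rsid=r.term,
                    gene=r.term,
                    effect_allele="A",
                    other_allele="C",
                    eaf=r.eaf if r.eaf is not None else 0.5,
                    weight=float(r.estimate),
                    exposure=outcome,
                )
            )
    return out
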