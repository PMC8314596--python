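"""Allele-score semantics: missing-data rules, normalization, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

import bidimr
from bidimr.core import Trait
from bidimr.exceptions import ConfigurationError, DegenerateDesignError
from bidimr.gene_score import ScoreMode


def _instruments(weights, eafs=(0.3, 0.25, 0.4), exposure=Trait.T2D):
    alleles = [("A", "G"), ("C", "T"), ("G", "A")]
    return [
        bidimr.SnpInstrument(f"rs{i}", f"G{i}", a, b, q, w, exposure)
        for i, ((a, b), q, w) in enumerate(zip(alleles, eafs, weights))
    ]


def _dosages(rows):
    idx = pd.Index([f"S{i}" for i in range(len(rows))], name="sample_id")
    return pd.DataFrame(np.array(rows, dtype=float), index=idx, columns=["rs0", "rs1", "rs2"])


class TestBuildScore:
    @pytest.mark.parametrize(
        "row,no_mean_imputation,expected",
        [
            ([2, 1, 0], True, 0.4),                  # plain weighted sum
            ([2, np.nan, 0], True, 0.2),             # missing contributes 0
            ([2, np.nan, 0], False, 0.2 + 0.2 * 0.5),  # imputed as 2*eaf=0.5
        ],
    )
    def test_sum_mode_missing_semantics(self, row, no_mean_imputation, expected):
        spec = bidimr.ScoreSpec(
            "s", _instruments([0.1, 0.2, 0.3], eafs=(0.3, 0.25, 0.4)),
            no_mean_imputation=no_mean_imputation, standardize=False,
        )
        score = bidimr.build_score(_dosages([row, [0, 0, 1]]), spec)
        assert score.iloc[0] == pytest.approx(expected)

    def test_average_divides_by_nonmissing_alleles(self):
        spec = bidimr.ScoreSpec(
            "s", _instruments([0.1, 0.2, 0.3]), mode=ScoreMode.AVERAGE, standardize=False
        )
        score = bidimr.build_score(_dosages([[2, np.nan, 0], [1, 1, 1]]), spec)
        assert score.iloc[0] == pytest.approx(0.2 / 4)   # two non-missing SNPs -> 4 alleles
        assert score.iloc[1] == pytest.approx(0.6 / 6)

    def test_all_missing_sample_gets_missing_score(self):
        spec = bidimr.ScoreSpec("s", _instruments([0.1, 0.2, 0.3]), standardize=False)
        score = bidimr.build_score(_dosages([[np.nan] * 3, [1, 1, 1]]), spec)
        assert np.isnan(score.iloc[0]) and not np.isnan(score.iloc[1])

    def test_unknown_rsid_listed(self):
        spec = bidimr.ScoreSpec("s", _instruments([0.1, 0.2, 0.3]), standardize=False)
        dosages = _dosages([[1, 1, 1]]).drop(columns=["rs2"])
        with pytest.raises(LookupError, match="rs2"):
            bidimr.build_score(dosages, spec)

    def test_complete_data_equals_matrix_product_and_column_order_invariant(self, independent_cohort, t2d_instruments):
        spec = bidimr.ScoreSpec("t2d_score", t2d_instruments, standardize=False)
        score = bidimr.build_score(independent_cohort.dosages, spec)
        rsids = [i.rsid for i in t2d_instruments]
        w = np.array([i.weight for i in t2d_instruments])
        direct = independent_cohort.dosages[rsids].to_numpy() @ w
        assert np.allclose(score.to_numpy(), direct, atol=1e-12)
        shuffled = independent_cohort.dosages[list(reversed(independent_cohort.dosages.columns))]
        assert np.allclose(bidimr.build_score(shuffled, spec).to_numpy(), direct, atol=1e-12)

    def test_mixed_exposures_rejected(self):
        instruments = _instruments([0.1, 0.2, 0.3])
        flipped = bidimr.SnpInstrument("rs9", "G9", "A", "G", 0.2, 0.1, Trait.VITD)
        with pytest.raises(ConfigurationError):
            bidimr.ScoreSpec("s", instruments + [flipped])


class TestStandardize:
    def test_three_point(self):
        out = bidimr.standardize(pd.Series([1.0, 2.0, 3.0]))
        assert np.allclose(out, [-1, 0, 1])

    def test_two_point_with_missing(self):
        out = bidimr.standardize(pd.Series([5.0, np.nan, 7.0]))
        assert out.iloc[0] == pytest.approx(-math.sqrt(0.5))
        assert np.isnan(out.iloc[1])
        assert out.iloc[2] == pytest.approx(math.sqrt(0.5))

    def test_moments(self, independent_cohort, vitd_instruments):
        spec = bidimr.ScoreSpec("vitd_score", vitd_instruments)
        score = bidimr.build_score(independent_cohort.dosages, spec)
        assert score.mean() == pytest.approx(0.0, abs=1e-12)
        assert score.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_score_rejected(self):
        with pytest.raises(DegenerateDesignError):
            bidimr.standardize(pd.Series([2.0, 2.0, 2.0]))


class TestWeightsFromResults:
    def test_published_or_weights(self):
        results = [
            bidimr.AssociationResult(f"rs{i}", Trait.T2D, 1000, math.log(orr), 0.02,
                                     math.log(orr) / 0.02, 1e-4, "+", eaf=0.3)
            for i, orr in enumerate((1.12, 1.25, 1.49))
        ]
        instruments = bidimr.score_weights_from_results(results)
        assert [i.weight for i in instruments] == pytest.approx([math.log(1.12), math.log(1.25), math.log(1.49)])
        assert all(i.exposure is Trait.T2D for i in instruments)

    def test_template_metadata_preserved(self, vitd_instruments):
        results = [
            bidimr.AssociationResult(i.rsid, Trait.VITD, 1000, b, 0.005, b / 0.005, 1e-4,
                                     "-", eaf=i.eaf)
            for i, b in zip(vitd_instruments, (-0.091, -0.039, -0.042))
        ]
        out = bidimr.score_weights_from_results(results, vitd_instruments)
        assert [i.gene for i in out] == [i.gene for i in vitd_instruments]
        assert [i.weight for i in out] == pytest.approx([-0.091, -0.039, -0.042])

    def test_mixed_outcomes_rejected(self):
        a = bidimr.AssociationResult("rs1", Trait.T2D, 10, 0.1, 0.1, 1.0, 0.3, "+")
        b = bidimr.AssociationResult("rs2", Trait.VITD, 10, 0.1, 0.1, 1.0, 0.3, "+")
        with pytest.raises(ConfigurationError):
            bidimr.score_weights_from_results([a, b])


class TestScoreRegressionsInvariances:
    def test_allele_flip_leaves_abs_z_unchanged(self, independent_cohort, t2d_instruments):
        from dataclasses import replace

        spec = bidimr.ScoreSpec("t2d_score", t2d_instruments)
        score = bidimr.build_score(independent_cohort.dosages, spec)
        z_orig = bidimr.fit_logistic_t2d(score, independent_cohort, ["age", "sex", "bmi"]).z

        flipped_dosages = independent_cohort.dosages.copy()
        target = t2d_instruments[0]
        flipped_dosages[target.rsid] = 2.0 - flipped_dosages[target.rsid]
        flipped_instruments = [
            replace(i, effect_allele=i.other_allele, other_allele=i.effect_allele,
                    eaf=1 - i.eaf, weight=-i.weight) if i.rsid == target.rsid else i
            for i in t2d_instruments
        ]
        flipped_cohort = bidimr.Cohort(dosages=flipped_dosages, phenotypes=independent_cohort.phenotypes)
        flipped_score = bidimr.build_score(flipped_dosages, bidimr.ScoreSpec("t2d_score", flipped_instruments))
        z_flip = bidimr.fit_logistic_t2d(flipped_score, flipped_cohort, ["age", "sex", "bmi"]).z
        assert abs(z_flip) == pytest.approx(abs(z_orig), rel=1e-6)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_t2d_score_hits_t2d_not_vitd(self, seed, t2d_instruments):
        """The disease score is a strong disease instrument and a 25(OH)D null."""
        params = bidimr.default_presets("INDEPENDENT", n=50_000, seed=seed)
        cohort = bidimr.simulate_cohort(params)
        score = bidimr.build_score(cohort.dosages, bidimr.ScoreSpec("t2d_score", t2d_instruments))
        assert bidimr.fit_logistic_t2d(score, cohort, ["age", "sex", "bmi"]).p < 1e-10
        assert bidimr.fit_linear_vitd(score, cohort, ["age", "sex", "bmi", "t2d"]).p > 0.01
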