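"""Polygenic risk scores: orientation, weighting, scaling, quintiles, ORs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancprs import (
    GenotypeMatrix,
    PrsConfig,
    PrsModel,
    SimConfig,
    Subject,
    quintile_assign,
    risk_allele_dosage,
    scale_score,
    simulate_cohort,
    unweighted_score,
    weighted_score,
)
from pancprs.prs import PrsError, quintile_cutpoints


class TestRiskAlleleOrientation:
    def test_risk_allele_is_minor_when_or_above_one(self):
        assert risk_allele_dosage(2, 1.5) == 2

    def test_protective_minor_flips_to_major_risk_allele(self):
        assert risk_allele_dosage(0, 0.8) == 2
        assert risk_allele_dosage(2, 0.8) == 0

    def test_missing_propagates(self):
        assert math.isnan(risk_allele_dosage(float("nan"), 1.5))


class TestScores:
    def test_unweighted_bounds_on_23_snp_panel(self):
        assert unweighted_score(np.zeros(23)) == (0.0, 23)
        assert unweighted_score(np.full(23, 2.0)) == (46.0, 23)

    def test_missing_calls_excluded_from_sum_and_count(self):
        raw, n = unweighted_score(np.array([2.0, 1.0, 0.0, np.nan]))
        assert (raw, n) == (3.0, 3)

    def test_weighted_contributions_are_a_times_ln_or(self):
        raw, n = weighted_score(np.array([2.0]), np.array([math.log(2.0)]))
        assert raw == pytest.approx(2 * math.log(2.0))
        # protective SNP: heterozygote carries one major-allele risk copy
        a = risk_allele_dosage(1, 0.5)
        raw, _ = weighted_score(np.array([a]), np.array([abs(math.log(0.5))]))
        assert raw == pytest.approx(math.log(2.0))
        raw, _ = weighted_score(np.array([2.0]), np.array([abs(math.log(1.0))]))
        assert raw == 0.0

    def test_unweighted_equals_weighted_with_unit_weights(self):
        rng = np.random.default_rng(8)
        a = rng.choice([0.0, 1.0, 2.0, np.nan], size=40)
        # gwas_or = e for every SNP gives X = 1, so the sums must coincide
        assert weighted_score(a, np.ones(40))[0] == pytest.approx(unweighted_score(a)[0])

    @given(st.floats(0.1, 50), st.integers(1, 30), st.integers(1, 30))
    @settings(max_examples=100, deadline=None)
    def test_scaling_is_homogeneous(self, raw, m, g):
        if g > m:
            g = m
        assert scale_score(3 * raw, m, g) == pytest.approx(3 * scale_score(raw, m, g))

    @pytest.mark.parametrize("raw,m,g,expected", [(10, 23, 23, 10), (10, 23, 20, 11.5), (0, 23, 7, 0)])
    def test_scaling_examples(self, raw, m, g, expected):
        assert scale_score(raw, m, g) == pytest.approx(expected)

    def test_zero_genotyped_is_undefined(self):
        with pytest.raises(PrsError, match="no genotyped"):
            scale_score(5.0, 23, 0)


class TestQuintiles:
    def test_nearest_rank_cutpoints_and_assignment(self):
        controls = np.arange(1.0, 11.0)
        assert quintile_cutpoints(controls).tolist() == [2, 4, 6, 8]
        assert quintile_assign(np.array([7.0]), controls)[0] == 4

    def test_boundary_scores_fall_in_lower_bin(self):
        controls = np.arange(1.0, 11.0)
        assert quintile_assign(np.array([4.0]), controls)[0] == 2
        assert quintile_assign(np.array([2.0]), controls)[0] == 1
        assert quintile_assign(np.array([8.1]), controls)[0] == 5

    def test_control_quintiles_hold_a_fifth_each(self):
        rng = np.random.default_rng(123)
        controls = rng.random(10_000)
        q = quintile_assign(controls, controls)
        frac = np.bincount(q, minlength=6)[1:] / controls.size
        assert np.all(np.abs(frac - 0.2) <= 0.01)

    def test_degenerate_control_distribution_rejected(self):
        with pytest.raises(PrsError, match="degenerate"):
            quintile_cutpoints(np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0]))


class TestPrsConfig:
    def test_survival_only_snps_never_enter_the_default_subset(self, panel):
        cfg = PrsConfig.from_panel(panel)
        assert "rs684559" not in cfg.snp_subset and "rs353630" not in cfg.snp_subset
        assert all(w >= 0 and math.isfinite(w) for w in cfg.weights.values())

    def test_explicit_survival_snp_rejected(self, panel):
        with pytest.raises(PrsError, match="survival-only"):
            PrsConfig.from_panel(panel, snp_subset=["rs684559"])


def _qc_cohort(study_cohort):
    from pancprs import run_qc

    matrix, subjects, _ = study_cohort
    kept, kept_subjects, _ = run_qc(matrix, subjects)
    return kept, kept_subjects


class TestPrsModel:
    def test_scaled_equals_raw_at_full_call_rate(self, panel, study_cohort):
        matrix, subjects = _qc_cohort(study_cohort)
        table = PrsModel(matrix, subjects, panel).score_table()
        m = len(PrsConfig.from_panel(panel, [r for r in matrix.rsids
                                             if r not in ("rs684559", "rs353630")]).snp_subset)
        full = table[table["n_genotyped"] == m]
        assert not full.empty
        assert np.allclose(full["unweighted_raw"], full["unweighted_scaled"])
        assert np.allclose(full["weighted_raw"], full["weighted_scaled"])

    def test_full_call_rate_analysis_uses_a_subset_of_the_cohort(self, panel, study_cohort):
        matrix, subjects = _qc_cohort(study_cohort)
        results = PrsModel(matrix, subjects, panel).fit()
        full = results["unweighted_full_call_rate"]
        scaled = results["unweighted_scaled_all"]
        assert full.n_cases + full.n_controls < scaled.n_cases + scaled.n_controls

    def test_summary_has_four_blocks_of_six_rows(self, panel, study_cohort):
        matrix, subjects = _qc_cohort(study_cohort)
        summary = PrsModel(matrix, subjects, panel).fit().summary()
        assert len(summary) == 24
        counts = summary.groupby("variant").size()
        assert set(counts) == {6}
        q1 = summary[summary["term"] == "quintile_1"]
        assert (q1["or"] == 1.0).all()

    def test_nine_snp_subset_produces_same_schema(self, panel, study_cohort):
        matrix, subjects = _qc_cohort(study_cohort)
        replicated = ["rs3790844", "rs17688601", "rs9854771", "rs7310409", "rs2941471",
                      "rs401681", "rs13303010", "rs9543325", "rs4795218"]
        results = PrsModel(matrix, subjects, panel, snp_subset=replicated).fit()
        summary = results.summary()
        assert len(summary) == 24
        assert results.model.config.m_total == 9

    def test_null_scores_give_continuous_or_near_one(self):
        rng = np.random.default_rng(31)
        n = 5000
        rsids = [f"rs{i}" for i in range(8)]
        from pancprs.panel import SnpDef
        from pancprs.simulate import hwe_genotype_probs

        pan = [SnpDef(r, "G", "A", "C", 1.3) for r in rsids]
        dosage = pd.DataFrame(
            {r: rng.choice(3, 2 * n, p=hwe_genotype_probs(0.3)).astype(float) for r in rsids},
            index=[f"S{i}" for i in range(2 * n)],
        )
        subjects = [
            Subject(f"S{i}", "case" if i < n else "control",
                    age=float(rng.normal(60, 10)),
                    sex="male" if rng.random() < 0.42 else "female")
            for i in range(2 * n)
        ]
        results = PrsModel(GenotypeMatrix(dosage), subjects, pan).fit()
        cont = results["weighted_scaled_all"].continuous
        assert 0.95 < cont.odds_ratio < 1.05

    def test_aggregate_risk_yields_increasing_quintile_ors(self, panel):
        # a cohort generated with the study's own per-SNP effects should put
        # the top control-quintile at clearly elevated odds
        cfg = SimConfig.from_panel(panel, n_cases=800, n_controls=800, seed=17,
                                   missing_rate=0.0, low_callrate_fraction=0.0,
                                   duplicate_fraction=0.0)
        matrix, subjects = simulate_cohort(cfg)
        results = PrsModel(matrix, subjects, panel).fit()
        a = results["weighted_full_call_rate"]
        top = a.quintile_ors[5]
        assert top is not None and top.odds_ratio > 1.5 and top.p < 0.01
        assert a.continuous.odds_ratio > 1.0
        assert top.odds_ratio > a.continuous.odds_ratio
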