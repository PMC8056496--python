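"""Logistic association machinery: IRLS fits, inheritance codings, trend test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pancprs import (
    GenotypeMatrix,
    SnpAssociationModel,
    Subject,
    assign_reference_allele,
    associate_snp,
    encode_model,
    logistic_fit,
    trend_test,
)
from pancprs.association import AssociationError
from pancprs.panel import SnpDef
from pancprs.simulate import case_genotype_probs, hwe_genotype_probs


def expand_2x2(a, b, c, d):
    """Per-subject (x, y) data for a 2×2 exposure × status table."""
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    return x, y


class TestLogisticFit:
    def test_single_binary_covariate_matches_closed_form(self):
        x, y = expand_2x2(39, 37, 84, 176)
        fit = logistic_fit(x[:, None], y, names=["tobacco"])
        assert fit.converged
        assert fit.coefficients["tobacco"] == pytest.approx(math.log(39 * 176 / (37 * 84)), abs=1e-10)
        assert fit.standard_errors["tobacco"] == pytest.approx(
            math.sqrt(1 / 39 + 1 / 37 + 1 / 84 + 1 / 176), abs=1e-10
        )

    def test_closed_form_agreement_on_100_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = rng.integers(5, 120, size=4)
            x, y = expand_2x2(a, b, c, d)
            fit = logistic_fit(x[:, None], y, names=["x"])
            beta = math.log(a * d / (b * c))
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert fit.coefficients["x"] == pytest.approx(beta, abs=1e-10)
            assert fit.standard_errors["x"] == pytest.approx(se, abs=1e-10)

    def test_intercept_only_recovers_log_case_fraction(self):
        y = np.r_[np.ones(78), np.zeros(256)]
        fit = logistic_fit(np.empty((334, 0)), y, names=[])
        assert fit.coefficients["intercept"] == pytest.approx(math.log(78 / 256), abs=1e-10)

    def test_matches_statsmodels_on_multivariate_design(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 600
        X = np.column_stack([rng.integers(0, 3, n), rng.normal(60, 10, n), rng.random(n) < 0.4])
        eta = -1.0 + 0.4 * X[:, 0] + 0.01 * X[:, 1] + 0.3 * X[:, 2]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        fit = logistic_fit(X, y.astype(float), names=["g", "age", "male"])
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(list(fit.coefficients.values()), ref.params, atol=1e-6)
        assert np.allclose(list(fit.standard_errors.values()), ref.bse, atol=1e-6)

    def test_null_covariate_coefficient_is_small_at_large_n(self):
        rng = np.random.default_rng(12345)
        n = 10_000
        g = rng.integers(0, 3, n).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        fit = logistic_fit(g[:, None], y, names=["g"])
        assert abs(fit.coefficients["g"]) < 0.1

    def test_single_class_outcome_rejected(self):
        with pytest.raises(AssociationError, match="single class"):
            logistic_fit(np.ones((5, 1)), np.ones(5))

    def test_collinear_design_names_offending_column(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(AssociationError, match="'b'"):
            logistic_fit(X, y)

    def test_separation_is_flagged(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.copy()
        fit = logistic_fit(x[:, None], y, names=["x"])
        assert fit.separation_flag


class TestReferenceAllele:
    def test_minor_allele_frequency_from_control_dosages(self):
        maf, flipped = assign_reference_allele(np.array([0.0, 0.0, 1.0, 2.0]))
        assert maf == pytest.approx(0.375) and not flipped

    def test_majority_allele_triggers_flip(self):
        maf, flipped = assign_reference_allele(np.array([2.0, 2.0, 2.0, 1.0]))
        assert maf == pytest.approx(0.125) and flipped

    def test_tie_keeps_panel_orientation(self):
        maf, flipped = assign_reference_allele(np.array([1.0, 1.0, 1.0]))
        assert maf == 0.5 and not flipped

    def test_all_missing_controls_rejected(self):
        with pytest.raises(AssociationError):
            assign_reference_allele(np.array([np.nan, np.nan]))


class TestModelCoding:
    @pytest.mark.parametrize(
        "dosage,allelic,codominant,dominant",
        [(0, [0], [0, 0], [0]), (1, [1], [1, 0], [1]), (2, [2], [0, 1], [1])],
    )
    def test_inheritance_codings(self, dosage, allelic, codominant, dominant):
        d = np.array([float(dosage)])
        assert encode_model(d, "allelic")[0].tolist() == allelic
        assert encode_model(d, "codominant")[0].tolist() == codominant
        assert encode_model(d, "dominant")[0].tolist() == dominant


def trend_oracle(table):
    """Independently coded Cochran–Armitage score statistic (two-sided p)."""
    t = np.asarray(table, float)
    n = t.sum()
    weights = np.array([0.0, 1.0, 2.0])
    p_case = t[0].sum() / n
    num = (weights * (t[0] - t.sum(axis=0) * p_case)).sum()
    col = t.sum(axis=0)
    var = p_case * (1 - p_case) * (
        (weights**2 * col).sum() - (weights * col).sum() ** 2 / n
    ) * n / (n - 1)
    z = num / math.sqrt(var)
    return 2 * stats.norm.sf(abs(z))


class TestTrend:
    def test_equal_distributions_give_p_one(self):
        assert trend_test([[10, 20, 10], [10, 20, 10]]) == pytest.approx(1.0)

    def test_matches_score_test_oracle(self):
        table = [[10, 20, 30], [30, 20, 10]]
        assert trend_test(table) == pytest.approx(trend_oracle(table), abs=1e-10)

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(99)
        probs = hwe_genotype_probs(0.3)
        reps = 3000
        cases = rng.multinomial(150, probs, reps)
        ctrls = rng.multinomial(300, probs, reps)
        rej = sum(
            trend_test(np.vstack([ca, co])) < 0.05 for ca, co in zip(cases, ctrls)
        )
        assert 0.035 <= rej / reps <= 0.065

    def test_degenerate_margin_rejected(self):
        with pytest.raises(AssociationError):
            trend_test([[0, 0, 0], [1, 2, 3]])


def _snp_cohort(case_dosages, control_dosages, rsid="rs_test", seed=0):
    rng = np.random.default_rng(seed)
    dosages = np.concatenate([case_dosages, control_dosages]).astype(float)
    ids = [f"S{i}" for i in range(len(dosages))]
    matrix = GenotypeMatrix(pd.DataFrame({rsid: dosages}, index=ids))
    subjects = [
        Subject(sid, "case" if i < len(case_dosages) else "control",
                age=float(rng.normal(60, 10)),
                sex="male" if rng.random() < 0.42 else "female")
        for i, sid in enumerate(ids)
    ]
    return matrix, subjects


class TestAssociateSnp:
    SNP = SnpDef("rs_test", "GENE", "A", "C", 1.2)

    def test_null_snp_or_near_one(self):
        rng = np.random.default_rng(2024)
        probs = hwe_genotype_probs(0.3)
        matrix, subjects = _snp_cohort(
            rng.choice(3, 5000, p=probs), rng.choice(3, 5000, p=probs)
        )
        res = associate_snp(matrix, subjects, self.SNP)
        assert 0.9 < res.allelic.odds_ratio < 1.1

    def test_recovers_twofold_risk(self):
        rng = np.random.default_rng(77)
        matrix, subjects = _snp_cohort(
            rng.choice(3, 5000, p=case_genotype_probs(0.3, 2.0)),
            rng.choice(3, 5000, p=hwe_genotype_probs(0.3)),
        )
        res = associate_snp(matrix, subjects, self.SNP)
        assert 1.85 < res.allelic.odds_ratio < 2.15
        assert res.allelic.ci_low <= res.allelic.odds_ratio <= res.allelic.ci_high
        assert res.p_trend < 1e-6

    def test_missing_rare_homozygotes_leave_contrast_undefined(self):
        rng = np.random.default_rng(5)
        case_d = np.r_[np.zeros(60), np.ones(20)]
        ctrl_d = np.r_[np.zeros(200), np.ones(50), np.full(6, 2.0)]
        matrix, subjects = _snp_cohort(case_d, ctrl_d)
        res = associate_snp(matrix, subjects, self.SNP)
        assert res.codominant_hom is None and res.dominant is None
        assert res.codominant_het is not None and res.allelic is not None

    def test_insufficient_cohort_is_marked(self):
        matrix, subjects = _snp_cohort(np.array([0, 1, 2]), np.array([0, 1, 2, 1]))
        res = associate_snp(matrix, subjects, self.SNP)
        assert res.status == "insufficient_data"


class TestSnpAssociationModel:
    def test_fit_reports_one_row_per_analyzed_snp(self, panel, study_cohort):
        matrix, subjects, _ = study_cohort
        results = SnpAssociationModel(matrix, subjects, panel).fit()
        summary = results.summary()
        assert len(summary) == 25  # 26-SNP panel minus the monomorphic locus
        assert "rs35226131" not in set(summary["rsid"])
        assert (summary["maf_controls"] <= 0.5 + 1e-12).all()
        ok = summary[summary["status"] == "ok"]
        assert (ok["allelic_ci_low"] <= ok["allelic_or"]).all()
        assert (ok["allelic_or"] <= ok["allelic_ci_high"]).all()

    def test_wald_interval_reproduces_contrast(self, panel, study_cohort):
        matrix, subjects, _ = study_cohort
        results = SnpAssociationModel(matrix, subjects, panel).fit()
        res = results["rs13303010"]
        fit = res.fits["allelic"]
        beta, se = fit.coefficients["dosage"], fit.standard_errors["dosage"]
        assert res.allelic.ci_low == pytest.approx(math.exp(beta - 1.959963984540054 * se))
        assert res.allelic.ci_high == pytest.approx(math.exp(beta + 1.959963984540054 * se))
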