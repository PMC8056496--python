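"""Polygenic risk scores with control-based quintiles and quintile odds ratios.

Four score variants are computed, matching the published analysis layout:
unweighted and ln(OR)-weighted sums of risk-allele counts, each either
restricted to subjects with a 100% call rate over the score SNPs or computed
for all subjects with the score rescaled by (total SNPs)/(genotyped SNPs).
Quintile cutpoints always come from the control distribution; association
with disease is a logistic regression adjusted for age and sex, once with
quintile indicator contrasts against the bottom quintile and once with the
quintile index as a continuous covariate (unit = one quintile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationError, Contrast, logistic_fit
from .panel import GenotypeMatrix, SnpDef, Subject, SURVIVAL_ONLY_SNPS


class PrsError(ValueError):
    pass


@dataclass
class PrsConfig:
    """Which SNPs enter the score and with what weights.

    ``weights`` maps rsid → X = |ln(gwas_or)| on the risk-allele scale; the
    survival-only loci are never allowed into the subset.
    """

    snp_subset: list[str]
    weights: dict[str, float]
    gwas_ors: dict[str, float]

    def __post_init__(self) -> None:
        bad = SURVIVAL_ONLY_SNPS & set(self.snp_subset)
        if bad:
            raise PrsError(f"survival-only SNPs cannot enter the PRS: {sorted(bad)}")
        for rsid in self.snp_subset:
            if rsid not in self.weights:
                raise PrsError(f"missing weight for {rsid}")
            if not math.isfinite(self.weights[rsid]) or self.weights[rsid] < 0:
                raise PrsError(f"weight for {rsid} must be finite and ≥ 0")

    @classmethod
    def from_panel(cls, panel: list[SnpDef], snp_subset: list[str] | None = None) -> "PrsConfig":
        eligible = [s.rsid for s in panel if s.in_prs]
        subset = list(snp_subset) if snp_subset is not None else eligible
        by_rsid = {s.rsid: s for s in panel}
        missing = [r for r in subset if r not in by_rsid]
        if missing:
            raise PrsError(f"subset rsIDs not in panel: {missing}")
        return cls(
            snp_subset=subset,
            weights={r: abs(math.log(by_rsid[r].gwas_or)) for r in subset},
            gwas_ors={r: by_rsid[r].gwas_or for r in subset},
        )

    @property
    def m_total(self) -> int:
        return len(self.snp_subset)


def risk_allele_dosage(minor_dosage: float, gwas_or: float) -> float:
    """Risk-allele count from a minor-allele dosage.

    The risk allele is the minor allele when the published OR ≥ 1 and the
    major allele otherwise (protective minor allele), so a protective
    homozygous-major genotype carries two risk alleles.  Missing propagates.
    """
    if not gwas_or > 0:
        raise PrsError(f"gwas_or must be positive, got {gwas_or}")
    if minor_dosage is None or (isinstance(minor_dosage, float) and math.isnan(minor_dosage)):
        return math.nan
    return float(minor_dosage) if gwas_or >= 1 else 2.0 - float(minor_dosage)


def unweighted_score(risk_dosages: np.ndarray) -> tuple[float, int]:
    """Sum of non-missing risk-allele counts and the number genotyped."""
    a = np.asarray(risk_dosages, dtype=float)
    if a.size == 0:
        raise PrsError("empty risk-dosage vector")
    called = a[~np.isnan(a)]
    return float(called.sum()), int(called.size)


def weighted_score(risk_dosages: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Σ a·X over non-missing risk-allele counts, X = |ln(OR)| per SNP."""
    a = np.asarray(risk_dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.shape != w.shape:
        raise PrsError("risk dosages and weights must align")
    if np.isnan(w).any():
        raise PrsError("missing weight")
    called = ~np.isnan(a)
    return float((a[called] * w[called]).sum()), int(called.sum())


def scale_score(raw: float, m_total: int, n_genotyped: int) -> float:
    """Rescale a score to the full panel: raw × m_total / n_genotyped."""
    if n_genotyped == 0:
        raise PrsError("no genotyped PRS SNPs: scaled score undefined")
    return raw * m_total / n_genotyped


def quintile_cutpoints(control_scores: np.ndarray) -> np.ndarray:
    """Nearest-rank 20/40/60/80th percentiles of the control scores."""
    c = np.sort(np.asarray(control_scores, dtype=float))
    if np.unique(c).size < 5:
        raise PrsError("degenerate control distribution: fewer than 5 distinct scores")
    n = c.size
    return np.array([c[math.ceil(q * n) - 1] for q in (0.2, 0.4, 0.6, 0.8)])


def quintile_assign(scores: np.ndarray, control_scores: np.ndarray) -> np.ndarray:
    """Quintile (1–5) per subject from the control distribution.

    Bins are left-open/right-closed: quintile k covers (c_{k−1}, c_k], with
    quintile 1 = (−∞, c1] and quintile 5 = (c4, ∞).
    """
    cuts = quintile_cutpoints(control_scores)
    s = np.asarray(scores, dtype=float)
    return (np.searchsorted(cuts, s, side="left") + 1).astype(int)


@dataclass
class PrsAnalysis:
    """Quintile and continuous logistic results for one score variant."""

    variant: str
    n_cases: int
    n_controls: int
    quintile_ors: dict[int, Contrast | None]  # quintiles 2..5 vs 1
    continuous: Contrast | None
    cutpoints: np.ndarray
    scores: pd.DataFrame  # subject_id, status, raw, n_genotyped, score, quintile


def _prs_logistic(quintiles, subjects_df, *, continuous: bool):
    y = subjects_df["is_case"].to_numpy(float)
    age = subjects_df["age"].to_numpy(float)
    male = subjects_df["male"].to_numpy(float)
    if continuous:
        X = pd.DataFrame({"quintile": quintiles.astype(float), "age": age, "male": male})
        fit = logistic_fit(X, y)
        return fit.contrast("quintile")
    cols = {f"q{k}": (quintiles == k).astype(float) for k in (2, 3, 4, 5)}
    present = {}
    for k in (2, 3, 4, 5):
        in_q = quintiles == k
        present[k] = (y[in_q].sum() > 0) and ((1 - y[in_q]).sum() > 0)
    X = pd.DataFrame({name: col for name, col in cols.items()} | {"age": age, "male": male})
    drop = [f"q{k}" for k in (2, 3, 4, 5) if not np.any(quintiles == k)]
    X = X.drop(columns=drop)
    fit = logistic_fit(X, y)
    out: dict[int, Contrast | None] = {}
    for k in (2, 3, 4, 5):
        out[k] = fit.contrast(f"q{k}") if f"q{k}" in fit.coefficients and present[k] else None
    return out


class PrsModel:
    """Polygenic-risk-score model over a QC'd cohort.

    ``fit()`` computes the four published score variants and their
    quintile/continuous disease associations.  The SNP subset defaults to
    every score-eligible panel SNP present in the matrix (the survival-only
    loci are excluded by construction); pass ``snp_subset`` to score, e.g.,
    only the replicated loci.
    """

    VARIANTS = (
        "unweighted_full_call_rate",
        "unweighted_scaled_all",
        "weighted_full_call_rate",
        "weighted_scaled_all",
    )

    def __init__(
        self,
        matrix: GenotypeMatrix,
        subjects: list[Subject],
        panel: list[SnpDef],
        *,
        snp_subset: list[str] | None = None,
    ):
        self.matrix = matrix
        self.subjects = [s for s in subjects if s.subject_id in set(matrix.subject_ids)]
        self.panel = panel
        if snp_subset is None:
            eligible = {s.rsid for s in panel if s.in_prs}
            snp_subset = [r for r in matrix.rsids if r in eligible]
        self.config = PrsConfig.from_panel(panel, snp_subset)

    def _risk_dosage_matrix(self) -> pd.DataFrame:
        """Subjects × subset-SNPs risk-allele counts (NaN = missing)."""
        cols = {}
        for rsid in self.config.snp_subset:
            gor = self.config.gwas_ors[rsid]
            minor = self.matrix.column(rsid)
            cols[rsid] = np.where(np.isnan(minor), np.nan,
                                  minor if gor >= 1 else 2.0 - minor)
        return pd.DataFrame(cols, index=self.matrix.subject_ids)

    def score_table(self) -> pd.DataFrame:
        """Per-subject raw/scaled scores for both weighting schemes."""
        risk = self._risk_dosage_matrix()
        w = np.array([self.config.weights[r] for r in self.config.snp_subset])
        m = self.config.m_total
        rows = []
        meta = {s.subject_id: s for s in self.subjects}
        for sid, a in zip(risk.index, risk.to_numpy()):
            raw_u, n_gt = unweighted_score(a)
            raw_w, _ = weighted_score(a, w)
            s = meta.get(sid)
            rows.append({
                "subject_id": sid,
                "status": s.status if s else "unknown",
                "is_case": 1.0 if (s and s.is_case) else 0.0,
                "age": s.age if s else None,
                "male": None if s is None or s.sex is None else float(s.sex == "male"),
                "n_genotyped": n_gt,
                "unweighted_raw": raw_u if n_gt else math.nan,
                "weighted_raw": raw_w if n_gt else math.nan,
                "unweighted_scaled": scale_score(raw_u, m, n_gt) if n_gt else math.nan,
                "weighted_scaled": scale_score(raw_w, m, n_gt) if n_gt else math.nan,
            })
        return pd.DataFrame(rows)

    def fit(self) -> "PrsResults":
        table = self.score_table()
        m = self.config.m_total
        analyses: dict[str, PrsAnalysis] = {}
        for variant in self.VARIANTS:
            weighting = "unweighted" if variant.startswith("unweighted") else "weighted"
            if variant.endswith("full_call_rate"):
                subset = table[table["n_genotyped"] == m].copy()
                col = f"{weighting}_raw"
            else:
                subset = table[table["n_genotyped"] > 0].copy()
                col = f"{weighting}_scaled"
            subset = subset.dropna(subset=[col, "age", "male"])
            if subset.empty or subset["is_case"].nunique() < 2:
                raise PrsError(f"{variant}: cohort lacks both outcome classes")
            ctrl_scores = subset.loc[subset["is_case"] == 0, col].to_numpy()
            cuts = quintile_cutpoints(ctrl_scores)
            quintiles = quintile_assign(subset[col].to_numpy(), ctrl_scores)
            subset["score"] = subset[col]
            subset["quintile"] = quintiles
            try:
                q_ors = _prs_logistic(quintiles, subset, continuous=False)
            except AssociationError:
                q_ors = {k: None for k in (2, 3, 4, 5)}
            try:
                cont = _prs_logistic(quintiles, subset, continuous=True)
            except AssociationError:
                cont = None
            analyses[variant] = PrsAnalysis(
                variant=variant,
                n_cases=int(subset["is_case"].sum()),
                n_controls=int((1 - subset["is_case"]).sum()),
                quintile_ors=q_ors,
                continuous=cont,
                cutpoints=cuts,
                scores=subset[["subject_id", "status", "n_genotyped", "score", "quintile"]],
            )
        return PrsResults(self, table, analyses)


class PrsResults:
    """Fitted PRS variants with a published-style quintile OR table."""

    def __init__(self, model: PrsModel, score_table: pd.DataFrame,
                 analyses: dict[str, PrsAnalysis]):
        self.model = model
        self.score_table = score_table
        self.analyses = analyses

    def __getitem__(self, variant: str) -> PrsAnalysis:
        return self.analyses[variant]

    def summary(self) -> pd.DataFrame:
        """Four blocks × (5 quintile rows + 1 continuous row)."""
        rows = []
        for variant, a in self.analyses.items():
            rows.append({"variant": variant, "term": "quintile_1", "or": 1.0,
                         "ci_low": math.nan, "ci_high": math.nan, "p": math.nan})
            for k in (2, 3, 4, 5):
                c = a.quintile_ors.get(k)
                rows.append({
                    "variant": variant, "term": f"quintile_{k}",
                    "or": c.odds_ratio if c else math.nan,
                    "ci_low": c.ci_low if c else math.nan,
                    "ci_high": c.ci_high if c else math.nan,
                    "p": c.p if c else math.nan,
                })
            c = a.continuous
            rows.append({
                "variant": variant, "term": "continuous",
                "or": c.odds_ratio if c else math.nan,
                "ci_low": c.ci_low if c else math.nan,
                "ci_high": c.ci_high if c else math.nan,
                "p": c.p if c else math.nan,
            })
        return pd.DataFrame(rows)
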