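"""Per-SNP case–control association under three inheritance models.

For each locus the more common allele in controls is taken as the reference;
unconditional logistic regression adjusted for age and sex is then fitted
under the allelic (per-allele additive), codominant (separate heterozygote
and rare-homozygote contrasts) and dominant (carrier vs non-carrier) codings,
alongside a Cochran–Armitage trend test on the genotype counts.

The maximum-likelihood fit is iteratively reweighted least squares with Wald
standard errors from the inverse observed information; convergence is
declared when the largest absolute score component falls below 1e-8 (at most
50 iterations), and quasi-complete separation is flagged when a coefficient
drifts beyond ±15 on the log-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypeMatrix, SnpDef, Subject
from .qc import genotype_counts, run_qc

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class Contrast:
    """One fitted odds-ratio contrast with its Wald 95% CI and p-value."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float

    @classmethod
    def from_beta(cls, beta: float, se: float) -> "Contrast":
        z = beta / se
        return cls(
            odds_ratio=math.exp(beta),
            ci_low=math.exp(beta - Z_95 * se),
            ci_high=math.exp(beta + Z_95 * se),
            p=2 * stats.norm.sf(abs(z)),
        )


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    n_iterations: int
    separation_flag: bool
    n_obs: int

    def contrast(self, name: str) -> Contrast:
        return Contrast.from_beta(self.coefficients[name], self.standard_errors[name])


def logistic_fit(
    design: np.ndarray | pd.DataFrame,
    outcome: np.ndarray,
    names: list[str] | None = None,
    *,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``design`` holds the covariate columns (complete cases only); the outcome
    is 0/1.  Raises on a single-class outcome or an exactly collinear design,
    naming the offending column.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise AssociationError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise AssociationError("outcome has a single class; logistic fit undefined")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + list(names)

    # exact collinearity check, naming the first dependent column
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise AssociationError(f"collinear design: column {names[j - 1]!r}")

    from scipy.special import expit

    beta = np.zeros(X.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        converged = bool(np.max(np.abs(score)) < tol)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # dampen absurd steps so separation drifts rather than overflows
        step = np.clip(step, -10, 10)
        beta = beta + step
        # the converging iteration's Newton step is still applied: quadratic
        # convergence then squares the residual score error away
        if converged:
            break

    # (quasi-)separated fits drift to huge coefficients; under separation the
    # score also vanishes numerically, so flag on magnitude, not convergence
    separation = bool(np.max(np.abs(beta)) > 15)
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return LogisticFit(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        converged=converged,
        n_iterations=n_iter,
        separation_flag=separation,
        n_obs=len(y),
    )


def assign_reference_allele(control_dosages: np.ndarray) -> tuple[float, bool]:
    """Orient dosages so the reference allele is the more common in controls.

    Returns ``(control MAF, flipped)``; a frequency of exactly 0.5 keeps the
    panel orientation.  Callers complement dosages (2 − d) when flipped.
    """
    d = np.asarray(control_dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise AssociationError("no non-missing control genotypes")
    freq = d.sum() / (2 * d.size)
    if freq > 0.5:
        return 1.0 - freq, True
    return float(freq), False


def encode_model(dosage: np.ndarray, model: str) -> np.ndarray:
    """Covariate column(s) for one inheritance model from a dosage vector."""
    d = np.asarray(dosage, dtype=float)
    if model == "allelic":
        return d[:, None]
    if model == "codominant":
        return np.column_stack([(d == 1).astype(float), (d == 2).astype(float)])
    if model == "dominant":
        return (d >= 1).astype(float)[:, None]
    raise AssociationError(f"unknown inheritance model {model!r}")


def trend_test(table_2x3: np.ndarray) -> float:
    """Two-sided Cochran–Armitage trend test with scores (0, 1, 2).

    ``table_2x3`` rows are status (case, control), columns genotype counts
    (ref-hom, het, alt-hom).
    """
    t = np.asarray(table_2x3, dtype=float)
    if t.shape != (2, 3) or (t < 0).any():
        raise AssociationError("trend test needs a 2×3 non-negative count table")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or n == 0 or np.count_nonzero(col) < 2:
        raise AssociationError("degenerate margins for trend test")
    scores = np.array([0.0, 1.0, 2.0])
    r1 = row[0]
    obs = scores @ t[0]
    mean = r1 * (scores @ col) / n
    var = (
        r1 * (n - r1) / (n * (n - 1))
        * ((scores**2) @ col - (scores @ col) ** 2 / n)
    )
    if var <= 0:
        raise AssociationError("zero trend variance")
    z = (obs - mean) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class AssocResult:
    """One SNP's association summary (one output-table row)."""

    rsid: str
    nearest_gene: str = ""
    maf_controls: float = math.nan
    maf_cases: float = math.nan
    flipped: bool = False
    allelic: Contrast | None = None
    codominant_het: Contrast | None = None
    codominant_hom: Contrast | None = None
    dominant: Contrast | None = None
    p_trend: float = math.nan
    allele_count_or: float = math.nan  # unadjusted 2×2 allele-count OR (cross-check)
    n_complete: int = 0
    status: str = "ok"  # ok | insufficient_data
    fits: dict[str, LogisticFit] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        ps = [c.p for c in (self.allelic, self.codominant_het, self.codominant_hom, self.dominant)
              if c is not None]
        return bool(ps) and min(ps) < 0.05


def _complete_cases(dosage, subjects):
    rows = []
    for d, s in zip(dosage, subjects):
        if np.isnan(d) or s.age is None or s.sex is None:
            continue
        rows.append((d, float(s.age), 1.0 if s.sex == "male" else 0.0, 1.0 if s.is_case else 0.0))
    if not rows:
        return (np.empty(0),) * 4
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


def associate_snp(
    matrix: GenotypeMatrix,
    subjects: list[Subject],
    snp: SnpDef,
    *,
    min_per_group: int = 10,
) -> AssocResult:
    """Full association analysis of one panel SNP, adjusted for age and sex.

    Contrasts whose genotype cell is empty in either status group are left
    undefined (``None``), mirroring dash entries in published tables.
    Cohorts below ``min_per_group`` complete cases in either group yield an
    ``insufficient_data`` result.
    """
    order = {sid: i for i, sid in enumerate(matrix.subject_ids)}
    subjects = [s for s in subjects if s.subject_id in order]
    subjects.sort(key=lambda s: order[s.subject_id])
    raw = matrix.column(snp.rsid)[[order[s.subject_id] for s in subjects]]

    ctrl = np.array([d for d, s in zip(raw, subjects) if not s.is_case])
    maf_controls, flipped = assign_reference_allele(ctrl)
    dosage = 2.0 - raw if flipped else raw

    case_d = np.array([d for d, s in zip(raw, subjects) if s.is_case])
    case_d = case_d[~np.isnan(case_d)]
    maf_cases = float(case_d.sum() / (2 * case_d.size)) if case_d.size else math.nan
    if flipped and case_d.size:
        maf_cases = 1.0 - maf_cases

    result = AssocResult(
        rsid=snp.rsid, nearest_gene=snp.nearest_gene,
        maf_controls=maf_controls, maf_cases=maf_cases, flipped=flipped,
    )

    d, age, male, y = _complete_cases(dosage, subjects)
    result.n_complete = len(y)
    n_case, n_ctrl = int(y.sum()), int(len(y) - y.sum())
    if min(n_case, n_ctrl) < min_per_group:
        result.status = "insufficient_data"
        return result

    counts_case = genotype_counts(d[y == 1])
    counts_ctrl = genotype_counts(d[y == 0])
    table = np.array([counts_case, counts_ctrl], dtype=float)
    try:
        result.p_trend = trend_test(table)
    except AssociationError:
        result.p_trend = math.nan

    # unadjusted allele-count OR for cross-checks against printed MAFs
    a_case = (counts_case[1] + 2 * counts_case[2], 2 * sum(counts_case) - counts_case[1] - 2 * counts_case[2])
    a_ctrl = (counts_ctrl[1] + 2 * counts_ctrl[2], 2 * sum(counts_ctrl) - counts_ctrl[1] - 2 * counts_ctrl[2])
    if min(*a_case, *a_ctrl) > 0:
        result.allele_count_or = (a_case[0] * a_ctrl[1]) / (a_case[1] * a_ctrl[0])

    covars = np.column_stack([age, male])
    covar_names = ["age", "male"]

    def fit_contrasts(model, columns, col_names):
        X = pd.DataFrame(np.column_stack([columns, covars]), columns=col_names + covar_names)
        fit = logistic_fit(X, y)
        result.fits[model] = fit
        return fit

    het_ok = counts_case[1] > 0 and counts_ctrl[1] > 0
    hom_ok = counts_case[2] > 0 and counts_ctrl[2] > 0

    if het_ok or hom_ok:
        fit = fit_contrasts("allelic", encode_model(d, "allelic"), ["dosage"])
        result.allelic = fit.contrast("dosage")
    if het_ok and hom_ok:
        fit = fit_contrasts("codominant", encode_model(d, "codominant"), ["het", "hom"])
        result.codominant_het = fit.contrast("het")
        result.codominant_hom = fit.contrast("hom")
        fit = fit_contrasts("dominant", encode_model(d, "dominant"), ["carrier"])
        result.dominant = fit.contrast("carrier")
    elif het_ok:
        # no rare homozygotes anywhere in one group: het contrast only
        fit = fit_contrasts("codominant", encode_model(d, "codominant")[:, :1], ["het"])
        result.codominant_het = fit.contrast("het")
    return result


class SnpAssociationModel:
    """Case–control association model over a genotyped SNP panel.

    Parameters
    ----------
    matrix, subjects, panel
        Genotype dosages, participant metadata and panel definitions.
    qc
        Run the full QC chain (duplicates, call rate, monomorphic, HWE)
        before fitting; on by default.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        subjects: list[Subject],
        panel: list[SnpDef],
        *,
        qc: bool = True,
        call_rate_min: float = 0.75,
        hwe_alpha: float = 0.05,
        min_per_group: int = 10,
    ):
        self.matrix = matrix
        self.subjects = subjects
        self.panel = panel
        self.qc = qc
        self.call_rate_min = call_rate_min
        self.hwe_alpha = hwe_alpha
        self.min_per_group = min_per_group

    @classmethod
    def from_files(cls, genotypes_path, subjects_path, panel_path=None, **kwargs):
        from . import panel as pio

        pan = pio.load_panel(panel_path) if panel_path else pio.default_panel()
        return cls(
            pio.read_genotypes(genotypes_path, pan),
            pio.read_subjects(subjects_path),
            pan,
            **kwargs,
        )

    def fit(self) -> "SnpAssociationResults":
        if self.qc:
            matrix, subjects, report = run_qc(
                self.matrix, self.subjects,
                call_rate_min=self.call_rate_min, hwe_alpha=self.hwe_alpha,
            )
        else:
            matrix, subjects, report = self.matrix, self.subjects, None
        by_rsid = {s.rsid: s for s in self.panel}
        results = [
            associate_snp(matrix, subjects, by_rsid[rsid], min_per_group=self.min_per_group)
            for rsid in matrix.rsids
        ]
        return SnpAssociationResults(self, results, report)


class SnpAssociationResults:
    """Fitted per-SNP association results with a rendered summary table."""

    def __init__(self, model, results: list[AssocResult], qc_report):
        self.model = model
        self.results = results
        self.qc_report = qc_report
        self._by_rsid = {r.rsid: r for r in results}

    def __getitem__(self, rsid: str) -> AssocResult:
        return self._by_rsid[rsid]

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.results]

    @property
    def significant_rsids(self) -> list[str]:
        return [r.rsid for r in self.results if r.significant]

    def summary(self) -> pd.DataFrame:
        """One row per analyzed SNP, mirroring the published layout."""

        def fmt(c: Contrast | None, what: str):
            if c is None:
                return math.nan
            return {"or": c.odds_ratio, "lo": c.ci_low, "hi": c.ci_high, "p": c.p}[what]

        rows = []
        for r in self.results:
            rows.append({
                "rsid": r.rsid,
                "gene": r.nearest_gene,
                "maf_controls": r.maf_controls,
                "maf_cases": r.maf_cases,
                "allelic_or": fmt(r.allelic, "or"),
                "allelic_ci_low": fmt(r.allelic, "lo"),
                "allelic_ci_high": fmt(r.allelic, "hi"),
                "allelic_p": fmt(r.allelic, "p"),
                "het_or": fmt(r.codominant_het, "or"),
                "het_p": fmt(r.codominant_het, "p"),
                "hom_or": fmt(r.codominant_hom, "or"),
                "hom_p": fmt(r.codominant_hom, "p"),
                "p_trend": r.p_trend,
                "dominant_or": fmt(r.dominant, "or"),
                "dominant_p": fmt(r.dominant, "p"),
                "n_complete": r.n_complete,
                "significant": r.significant,
                "status": r.status,
            })
        return pd.DataFrame(rows)
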