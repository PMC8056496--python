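"""Sample- and SNP-level genotype quality control.

Filters applied, in a fixed order: duplicate pairs are resolved (the member
with the higher call rate is kept for analysis), subjects with a call rate
below 75% are discarded, and on the survivors monomorphic SNPs are dropped
and Hardy–Weinberg equilibrium is tested in controls with an exact test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, Subject


class QcError(ValueError):
    pass


@dataclass
class QcReport:
    call_rates: dict[str, float] = field(default_factory=dict)
    excluded_subjects: list[tuple[str, str]] = field(default_factory=list)
    duplicate_pairs: list[dict] = field(default_factory=list)
    hwe_p_controls: dict[str, float] = field(default_factory=dict)
    monomorphic_snps: list[str] = field(default_factory=list)
    excluded_snps: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_subject_ids(self) -> set[str]:
        return {sid for sid, _ in self.excluded_subjects}

    @property
    def excluded_snp_ids(self) -> set[str]:
        return {rsid for rsid, _ in self.excluded_snps}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    def to_frame(self) -> pd.DataFrame:
        """Human-readable exclusion table (one row per excluded entity)."""
        rows = [{"entity": "subject", "id": sid, "reason": r} for sid, r in self.excluded_subjects]
        rows += [{"entity": "snp", "id": rsid, "reason": r} for rsid, r in self.excluded_snps]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])


def call_rate(row: np.ndarray) -> float:
    """Fraction of panel SNPs with a successful genotype call for one subject."""
    row = np.asarray(row, dtype=float)
    if row.size == 0:
        raise QcError("call rate undefined for a zero-length dosage row")
    return float(np.count_nonzero(~np.isnan(row)) / row.size)


def duplicate_concordance(row_a: np.ndarray, row_b: np.ndarray) -> tuple[float | None, int]:
    """Genotype agreement between a duplicate pair.

    Returns ``(concordance, n_compared)`` over positions non-missing in both
    rows; concordance is None when no position is jointly genotyped.
    """
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape:
        raise QcError("duplicate rows have different lengths")
    both = ~np.isnan(a) & ~np.isnan(b)
    n = int(both.sum())
    if n == 0:
        return None, 0
    return float(np.count_nonzero(a[both] == b[both]) / n), n


def hwe_exact_p(n_mm_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy–Weinberg test for one biallelic locus.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (the Wigginton/Cutler/Abecasis construction).  Counts are
    genotype counts among controls: (hom-major, het, hom-minor).
    """
    for c in (n_mm_hom_major, n_het, n_hom_minor):
        if c < 0 or c != int(c):
            raise QcError(f"genotype counts must be non-negative integers, got {c}")
    n = n_mm_hom_major + n_het + n_hom_minor
    if n == 0:
        raise QcError("no genotyped controls: HWE test undefined")
    n_minor = n_het + 2 * n_hom_minor  # rare-allele copies (may exceed n; symmetric below)
    n_minor = min(n_minor, 2 * n - n_minor)
    obs_het = n_het

    # P(het = h | allele counts) ∝ n! / (n_hom_maj! h! n_hom_min!) · 2^h,
    # computed over the support h ≡ n_minor (mod 2), 0 ≤ h ≤ n_minor.
    support = range(n_minor % 2, n_minor + 1, 2)
    log_probs = {}
    for h in support:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        log_probs[h] = (
            h * math.log(2)
            - math.lgamma(hom_major + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_minor + 1)
        )
    log_norm = max(log_probs.values())
    weights = {h: math.exp(lp - log_norm) for h, lp in log_probs.items()}
    total = sum(weights.values())
    p_obs = weights[obs_het] / total
    p = sum(w for w in weights.values() if w / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def detect_monomorphic(matrix: GenotypeMatrix) -> list[str]:
    """rsIDs with zero observed copies of one allele across all subjects."""
    out = []
    for rsid in matrix.rsids:
        col = matrix.column(rsid)
        called = col[~np.isnan(col)]
        if called.size == 0:
            out.append(rsid)
            continue
        minor_copies = called.sum()
        if minor_copies == 0 or minor_copies == 2 * called.size:
            out.append(rsid)
    return out


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts from a dosage vector, ignoring NaN."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return (
        int(np.count_nonzero(d == 0)),
        int(np.count_nonzero(d == 1)),
        int(np.count_nonzero(d == 2)),
    )


def run_qc(
    matrix: GenotypeMatrix,
    subjects: list[Subject],
    *,
    call_rate_min: float = 0.75,
    concordance_min: float = 0.99,
    hwe_alpha: float = 0.05,
    exclude_hwe_failures: bool = True,
) -> tuple[GenotypeMatrix, list[Subject], QcReport]:
    """Run the full QC chain and return the filtered matrix, subjects, report.

    Duplicates declared via ``Subject.duplicate_of`` are used for concordance
    checking only; the pair member with the higher call rate stays in the
    analysis set.  HWE failures (exact p ≤ ``hwe_alpha`` in controls) are
    excluded by default; set ``exclude_hwe_failures=False`` to only flag them.
    """
    report = QcReport()
    by_id = {s.subject_id: s for s in subjects}
    for sid in matrix.subject_ids:
        report.call_rates[sid] = call_rate(matrix.row(sid))

    # 1. duplicate pairs: record concordance, drop the lower-call-rate member
    for s in subjects:
        if s.duplicate_of is None:
            continue
        if s.duplicate_of not in by_id or s.subject_id not in report.call_rates:
            continue
        conc, n_comp = duplicate_concordance(matrix.row(s.subject_id), matrix.row(s.duplicate_of))
        entry = {
            "id_a": s.subject_id,
            "id_b": s.duplicate_of,
            "concordance": conc,
            "n_compared": n_comp,
            "flag": None,
        }
        if conc is None:
            entry["flag"] = "no_overlap"
        elif conc < concordance_min:
            entry["flag"] = "low_concordance"
        report.duplicate_pairs.append(entry)
        drop = (
            s.subject_id
            if report.call_rates[s.subject_id] <= report.call_rates[s.duplicate_of]
            else s.duplicate_of
        )
        if drop not in report.excluded_subject_ids:
            report.excluded_subjects.append((drop, "duplicate"))

    # 2. per-sample call-rate filter
    for sid, cr in report.call_rates.items():
        if cr < call_rate_min and sid not in report.excluded_subject_ids:
            report.excluded_subjects.append((sid, "low_call_rate"))

    keep_ids = [sid for sid in matrix.subject_ids if sid not in report.excluded_subject_ids]
    kept_matrix = matrix.subset(subject_ids=keep_ids)
    kept_subjects = [by_id[sid] for sid in keep_ids if sid in by_id]

    # 3. SNP-level checks on survivors
    report.monomorphic_snps = detect_monomorphic(kept_matrix)
    for rsid in report.monomorphic_snps:
        report.excluded_snps.append((rsid, "monomorphic"))

    control_ids = [s.subject_id for s in kept_subjects if not s.is_case]
    control_matrix = kept_matrix.subset(subject_ids=control_ids)
    for rsid in kept_matrix.rsids:
        if rsid in report.excluded_snp_ids:
            continue
        counts = genotype_counts(control_matrix.column(rsid))
        if sum(counts) == 0:
            report.excluded_snps.append((rsid, "no_genotyped_controls"))
            continue
        p = hwe_exact_p(*counts)
        report.hwe_p_controls[rsid] = p
        if p <= hwe_alpha and exclude_hwe_failures:
            report.excluded_snps.append((rsid, "hwe_fail"))

    keep_snps = [r for r in kept_matrix.rsids if r not in report.excluded_snp_ids]
    return kept_matrix.subset(rsids=keep_snps), kept_subjects, report
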