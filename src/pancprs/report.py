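"""Pipeline orchestration and rendering of the four study-style output tables."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import panel as pio
from .association import SnpAssociationModel
from .prs import PrsModel
from .tabstats import allele_count_test, comparisons_frame, epidemiology_comparisons

log = logging.getLogger("pancprs")


@dataclass
class RunConfig:
    panel_path: str | None = None
    genotypes_path: str | None = None
    subjects_path: str | None = None
    out_dir: str = "pancprs-out"
    call_rate_min: float = 0.75
    concordance_min: float = 0.99
    alpha: float = 0.05
    hwe_alpha: float = 0.05
    prs_subset: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "concordance_min", "alpha", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def _fmt(v, digits=3):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "–"
    return f"{v:.{digits}g}" if isinstance(v, float) else str(v)


def render_table(results, style: str) -> pd.DataFrame:
    """Render a stage's results in the corresponding published-table layout.

    ``style`` is one of table1 (epidemiology), table2 (per-SNP association),
    table3 (ancestry MAF comparison), table4 (PRS quintile ORs).  Undefined
    contrasts appear as "–".
    """
    if style == "table1":
        return comparisons_frame(results)
    if style == "table2":
        df = results.summary()
        out = pd.DataFrame({
            "SNP": df["rsid"],
            "Nearest gene": df["gene"],
            "MAF controls": df["maf_controls"].round(3),
            "MAF cases": df["maf_cases"].round(3),
            "Allelic OR (95% CI)": [
                f"{_fmt(o)} ({_fmt(l)}–{_fmt(h)})" if not math.isnan(o) else "–"
                for o, l, h in zip(df["allelic_or"], df["allelic_ci_low"], df["allelic_ci_high"])
            ],
            "Allelic p": df["allelic_p"].map(_fmt),
            "Het OR": df["het_or"].map(_fmt),
            "Het p": df["het_p"].map(_fmt),
            "Hom OR": df["hom_or"].map(_fmt),
            "Hom p": df["hom_p"].map(_fmt),
            "p trend": df["p_trend"].map(_fmt),
            "Dominant OR": df["dominant_or"].map(_fmt),
            "Dominant p": df["dominant_p"].map(_fmt),
            "Significant": df["significant"],
        })
        return out
    if style == "table3":
        return results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
    if style == "table4":
        df = results.summary()
        df["or"] = df["or"].map(_fmt)
        df["ci"] = [
            f"{_fmt(l)}–{_fmt(h)}" if _fmt(l) != "–" else "–"
            for l, h in zip(df["ci_low"], df["ci_high"])
        ]
        df["p"] = df["p"].map(_fmt)
        return df[["variant", "term", "or", "ci", "p"]]
    raise ValueError(f"unknown table style {style!r}")


def ancestry_maf_comparison(matrix, subjects, panel, alpha: float = 0.05) -> pd.DataFrame:
    """Per-ancestry case-vs-control and control-vs-reference MAF comparisons.

    Minor-allele frequencies are computed from the cohort within each
    self-reported ancestry and compared by allele-count chi-square (Fisher
    when any expected cell is small); reference comparisons use the panel's
    per-ancestry ``ref_mafs``.
    """
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for snp in panel:
        if snp.rsid not in matrix.rsids:
            continue
        col = matrix.dosage[snp.rsid]
        for ancestry in ("African", "European", "Asian"):
            def maf_of(group):
                vals = [
                    col[sid] for sid in matrix.subject_ids
                    if sid in by_id and by_id[sid].ancestry == ancestry
                    and (by_id[sid].status == group) and not math.isnan(col[sid])
                ]
                if not vals:
                    return math.nan, 0
                return sum(vals) / (2 * len(vals)), len(vals)

            maf_ca, n_ca = maf_of("case")
            maf_co, n_co = maf_of("control")
            row = {
                "rsid": snp.rsid, "ancestry": ancestry,
                "maf_cases": maf_ca, "n_cases": n_ca,
                "maf_controls": maf_co, "n_controls": n_co,
                "p_case_vs_control": math.nan, "p_control_vs_reference": math.nan,
            }
            if n_ca > 0 and n_co > 0 and not (math.isnan(maf_ca) or math.isnan(maf_co)):
                method = "fisher" if min(n_ca, n_co) < 15 else "chisq"
                try:
                    _, row["p_case_vs_control"] = allele_count_test(
                        maf_ca, n_ca, maf_co, n_co, method=method)
                except ValueError:
                    pass
            ref = snp.ref_mafs.get(ancestry) or snp.ref_mafs.get(ancestry.lower())
            if ref and n_co > 0 and not math.isnan(maf_co):
                try:
                    _, row["p_control_vs_reference"] = allele_count_test(
                        maf_co, n_co, ref[0], ref[1], method="chisq")
                except ValueError:
                    pass
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["sig_case_vs_control"] = df["p_case_vs_control"] < alpha
        df["sig_control_vs_reference"] = df["p_control_vs_reference"] < alpha
    return df


def run_all(config: RunConfig):
    """QC → epidemiology → association → ancestry MAFs → PRS, writing all tables.

    Returns a dict with every stage's results; writes TSVs plus a JSON bundle
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = pio.load_panel(config.panel_path) if config.panel_path else pio.default_panel()
    if config.genotypes_path is None or config.subjects_path is None:
        raise FileNotFoundError("run_all needs genotype and subject paths")
    for path in (config.genotypes_path, config.subjects_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    matrix = pio.read_genotypes(config.genotypes_path, panel)
    subjects = pio.read_subjects(config.subjects_path)
    log.info("loaded %d subjects × %d SNPs", *matrix.shape)

    model = SnpAssociationModel(
        matrix, subjects, panel,
        call_rate_min=config.call_rate_min, hwe_alpha=config.hwe_alpha,
    )
    assoc = model.fit()
    qc = assoc.qc_report
    for sid, reason in qc.excluded_subjects:
        log.info("excluded subject %s: %s", sid, reason)
    for rsid, reason in qc.excluded_snps:
        log.info("excluded SNP %s: %s", rsid, reason)

    kept_subject_ids = set(matrix.subject_ids) - qc.excluded_subject_ids
    kept_subjects = [s for s in subjects if s.subject_id in kept_subject_ids]
    kept_rsids = [r for r in matrix.rsids if r not in qc.excluded_snp_ids]
    kept_matrix = matrix.subset(subject_ids=[s.subject_id for s in kept_subjects],
                                rsids=kept_rsids)

    epi = epidemiology_comparisons(kept_subjects)
    maf_table = ancestry_maf_comparison(kept_matrix, kept_subjects, panel, alpha=config.alpha)
    prs = PrsModel(kept_matrix, kept_subjects, panel, snp_subset=config.prs_subset).fit()

    tables = {
        "table1": render_table(epi, "table1"),
        "table2": render_table(assoc, "table2"),
        "table3": render_table(maf_table, "table3"),
        "table4": render_table(prs, "table4"),
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    qc.to_frame().to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    qc.to_json(out / "qc_report.json")
    prs.score_table.to_csv(out / "prs_scores.tsv", sep="\t", index=False)

    bundle = {
        "n_subjects_input": len(subjects),
        "n_subjects_analyzed": len(kept_subjects),
        "n_snps_analyzed": len(kept_rsids),
        "significant_snps": assoc.significant_rsids,
        "excluded_subjects": qc.excluded_subjects,
        "excluded_snps": qc.excluded_snps,
    }
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2))
    return {"qc": qc, "epidemiology": epi, "association": assoc,
            "ancestry_mafs": maf_table, "prs": prs, "tables": tables}
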