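"""Synthetic case–control cohort generator.

Emulates the statistical structure the analysis assumes: control genotypes
drawn from exact Hardy–Weinberg proportions at per-SNP control minor-allele
frequencies, case genotypes from the case–control tilted distribution
P(g | case) ∝ HWE(g)·OR^g implied by an additive logistic disease model,
group-specific age/sex/ancestry/exposure distributions, uniform genotype
missingness with a low-call-rate tail, and duplicated samples for
concordance checks.  SNPs are simulated independently (no linkage
disequilibrium).  A locus with control MAF 0 is emitted as monomorphic, so
the default panel reproduces a monomorphic-SNP exclusion at QC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    GenotypeMatrix,
    SnpDef,
    Subject,
    default_panel,
    reported_epidemiology,
    write_genotypes,
    write_subjects,
)


class SimulationError(ValueError):
    pass


def _default_exposure_rates() -> dict[str, tuple[float, float]]:
    # published exposure percentages per group; family history is not printed,
    # so a realistic default is fixed here
    table1 = reported_epidemiology()
    yes = table1[table1["level"] == "yes"].set_index("variable")
    rates = {
        var: (yes.loc[var, "pct_cases"] / 100, yes.loc[var, "pct_controls"] / 100)
        for var in yes.index
    }
    rates["family_history"] = (0.08, 0.05)
    return rates


@dataclass
class SimConfig:
    """Cohort-generation settings; defaults mirror the study conditions.

    78 cases / 256 controls, control MAFs and per-allele odds ratios from the
    shipped panel, group age means 62.46 / 56.62 (SD 26), 41% / 43% male,
    self-reported ancestry at the published proportions, 5% duplicates, and a
    3% tail of low-call-rate samples to exercise the 75% filter.
    """

    n_cases: int = 78
    n_controls: int = 256
    control_mafs: dict[str, float] = field(default_factory=dict)  # rsid -> MAF in [0,1)
    true_ors: dict[str, float] = field(default_factory=dict)  # rsid -> per-risk-allele OR
    age_mean_case: float = 62.46
    age_mean_control: float = 56.62
    age_sd: float = 26.0  # implied by the reported group means and age p-value
    male_frac_case: float = 0.41
    male_frac_control: float = 0.43
    ancestry_probs_case: tuple[float, float, float] = (0.32, 0.667, 0.013)  # Af, Eu, As
    ancestry_probs_control: tuple[float, float, float] = (0.175, 0.813, 0.012)
    exposure_rates: dict[str, tuple[float, float]] = field(default_factory=_default_exposure_rates)
    missing_rate: float = 0.01
    low_callrate_fraction: float = 0.03
    low_callrate_missing_rate: float = 0.4
    duplicate_fraction: float = 0.05
    age_effect_per_year: float = 0.0  # optional genotype-independent age effect knob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise SimulationError("group sizes must be positive")
        for rsid, maf in self.control_mafs.items():
            if not 0.0 <= maf < 1.0:
                raise SimulationError(f"{rsid}: control MAF {maf} outside [0, 1)")
        for rsid, orr in self.true_ors.items():
            if not orr > 0:
                raise SimulationError(f"{rsid}: true OR must be positive")
        for probs in (self.ancestry_probs_case, self.ancestry_probs_control):
            if min(probs) < 0 or sum(probs) > 1 + 1e-9:
                raise SimulationError(f"ancestry probabilities invalid: {probs}")
        for rate in (self.missing_rate, self.low_callrate_fraction, self.duplicate_fraction):
            if not 0.0 <= rate < 1.0:
                raise SimulationError(f"rate {rate} outside [0, 1)")

    @classmethod
    def from_panel(cls, panel: list[SnpDef] | None = None, **kwargs) -> "SimConfig":
        """Study-condition defaults: panel control MAFs and panel ORs as truth."""
        panel = panel if panel is not None else default_panel()
        mafs = {s.rsid: s.ref_mafs.get("controls", (0.0, 1))[0] for s in panel}
        ors = {s.rsid: s.gwas_or for s in panel}
        return cls(control_mafs=mafs, true_ors=ors, **kwargs)


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """(P(g=0), P(g=1), P(g=2)) under Hardy–Weinberg at minor-allele freq maf."""
    q = maf
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def case_genotype_probs(maf: float, odds_ratio: float) -> np.ndarray:
    """Genotype distribution among cases under the additive logistic model.

    With a rare-ish disease sampled case–control, P(g | case) ∝ HWE(g)·OR^g;
    this is the exact tilted distribution, no rejection sampling needed.
    """
    base = hwe_genotype_probs(maf)
    tilt = base * odds_ratio ** np.arange(3)
    return tilt / tilt.sum()


def expected_case_maf(maf: float, odds_ratio: float) -> float:
    """Closed-form case minor-allele frequency implied by the tilted model."""
    probs = case_genotype_probs(maf, odds_ratio)
    return float((probs @ np.arange(3)) / 2.0)


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, list[Subject]]:
    """Draw a full cohort (genotypes + subject metadata) from ``config``.

    Deterministic given (config, seed): all randomness flows from one
    ``numpy.random.Generator`` seeded by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rsids = list(config.control_mafs)
    if not rsids:
        raise SimulationError("no SNPs configured")
    n_ca, n_co = config.n_cases, config.n_controls
    n = n_ca + n_co
    status = np.array(["case"] * n_ca + ["control"] * n_co)

    dosage = np.empty((n, len(rsids)))
    for j, rsid in enumerate(rsids):
        maf = config.control_mafs[rsid]
        orr = config.true_ors.get(rsid, 1.0)
        if maf == 0.0:
            dosage[:, j] = 0.0
            continue
        dosage[:n_ca, j] = rng.choice(3, size=n_ca, p=case_genotype_probs(maf, orr))
        dosage[n_ca:, j] = rng.choice(3, size=n_co, p=hwe_genotype_probs(maf))

    age = np.where(
        status == "case",
        rng.normal(config.age_mean_case, config.age_sd, n),
        rng.normal(config.age_mean_control, config.age_sd, n),
    ).clip(18, 100)
    if config.age_effect_per_year:
        # optional confounding knob: re-draw case ages with an extra shift
        age[:n_ca] += config.age_effect_per_year
    male = np.where(
        status == "case",
        rng.random(n) < config.male_frac_case,
        rng.random(n) < config.male_frac_control,
    )
    labels = np.array(["African", "European", "Asian", "unknown"])

    def draw_ancestry(probs, size):
        p = np.array(list(probs) + [max(0.0, 1.0 - sum(probs))])
        return labels[rng.choice(4, size=size, p=p / p.sum())]

    ancestry = np.concatenate([
        draw_ancestry(config.ancestry_probs_case, n_ca),
        draw_ancestry(config.ancestry_probs_control, n_co),
    ])

    exposures = {}
    for exp, (rate_ca, rate_co) in config.exposure_rates.items():
        draws = rng.random(n) < np.where(status == "case", rate_ca, rate_co)
        exposures[exp] = np.where(draws, "yes", "no")

    # missingness: uniform base rate, with a tail of low-call-rate subjects
    low = rng.random(n) < config.low_callrate_fraction
    per_subject_rate = np.where(low, config.low_callrate_missing_rate, config.missing_rate)
    mono = np.array([config.control_mafs[r] == 0.0 for r in rsids])
    miss = rng.random(dosage.shape) < per_subject_rate[:, None]
    miss[:, mono] = False  # keep intentionally monomorphic columns fully called
    dosage[miss] = np.nan

    ids = [f"S{i + 1:04d}" for i in range(n)]
    subjects = [
        Subject(
            subject_id=ids[i],
            status=str(status[i]),
            age=round(float(age[i]), 1),
            sex="male" if male[i] else "female",
            ancestry=str(ancestry[i]),
            exposures={exp: str(vals[i]) for exp, vals in exposures.items()},
        )
        for i in range(n)
    ]

    # duplicates: re-genotype a sample of subjects under fresh missingness
    n_dup = int(np.ceil(config.duplicate_fraction * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        dup_rows = dosage[dup_idx].copy()
        redraw = rng.random(dup_rows.shape) < config.missing_rate
        dup_rows[redraw] = np.nan
        for k, i in enumerate(dup_idx):
            src = subjects[i]
            subjects.append(
                Subject(
                    subject_id=f"{src.subject_id}-dup",
                    status=src.status,
                    age=src.age,
                    sex=src.sex,
                    ancestry=src.ancestry,
                    exposures=dict(src.exposures),
                    duplicate_of=src.subject_id,
                )
            )
        dosage = np.vstack([dosage, dup_rows])
        ids = ids + [f"{ids[i]}-dup" for i in dup_idx]

    matrix = GenotypeMatrix(pd.DataFrame(dosage, index=pd.Index(ids, name="subject_id"),
                                         columns=rsids))
    return matrix, subjects


def simulate_exposures(config: SimConfig, subjects: list[Subject], seed: int | None = None):
    """Independent Bernoulli exposure draws at the group-specific rates."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for s in subjects:
        flags = {}
        for exp, (rate_ca, rate_co) in config.exposure_rates.items():
            rate = rate_ca if s.is_case else rate_co
            flags[exp] = "yes" if rng.random() < rate else "no"
        out.append(flags)
    return out


def write_fixture(matrix: GenotypeMatrix, subjects: list[Subject],
                  directory: str | Path, panel: list[SnpDef] | None = None,
                  config: SimConfig | None = None) -> dict[str, Path]:
    """Write genotype/subject (and panel, provenance) TSVs for the pipeline."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.tsv",
        "subjects": directory / "subjects.tsv",
    }
    write_genotypes(matrix, paths["genotypes"])
    write_subjects(subjects, paths["subjects"])
    if panel is not None:
        paths["panel"] = directory / "panel.tsv"
        _write_panel(panel, paths["panel"])
    if config is not None:
        paths["provenance"] = directory / "provenance.json"
        blob = asdict(config)
        paths["provenance"].write_text(json.dumps(blob, indent=2, default=str))
    return paths


def _write_panel(panel: list[SnpDef], path: Path) -> None:
    labels = sorted({lbl for s in panel for lbl in s.ref_mafs})
    rows = []
    for s in panel:
        row = {
            "rsid": s.rsid, "gene": s.nearest_gene, "major": s.major_allele,
            "minor": s.minor_allele, "gwas_or": s.gwas_or,
            "in_prs": "true" if s.in_prs else "false",
        }
        for lbl in labels:
            maf_n = s.ref_mafs.get(lbl)
            row[f"ref_maf_{lbl}"] = maf_n[0] if maf_n else "NA"
            row[f"ref_n_{lbl}"] = maf_n[1] if maf_n else "NA"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
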