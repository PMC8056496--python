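"""Domain types and readers/writers for the SNP panel, genotype and subject tables.

The panel is rsID-keyed: loci are identified by their dbSNP rsID, never by
genomic coordinates.  Genotypes are stored as minor-allele dosage — the count
(0/1/2) of copies of the panel's minor allele — with NaN marking a failed call.
Risk-allele orientation (for scoring) and reference-allele orientation (for
association) are applied downstream, so ingest keeps a single convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
#: rsIDs reported only for patient survival, never entered into risk scores.
SURVIVAL_ONLY_SNPS = frozenset({"rs684559", "rs353630"})

ANCESTRIES = ("African", "European", "Asian", "unknown")
EXPOSURES = ("tobacco", "alcohol", "diabetes", "pancreatitis", "family_history")


class PanelError(ValueError):
    """Malformed panel, genotype or subject input."""


@dataclass(frozen=True)
class SnpDef:
    """One panel locus: alleles, external GWAS weight and reference frequencies.

    ``ref_mafs`` maps an ancestry label (or ``"controls"`` for the study's own
    control group) to a ``(maf, n)`` pair, where ``n`` is the sample size the
    frequency was estimated from.
    """

    rsid: str
    nearest_gene: str
    major_allele: str
    minor_allele: str
    gwas_or: float
    in_prs: bool = True
    ref_mafs: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.major_allele not in VALID_BASES or self.minor_allele not in VALID_BASES:
            raise PanelError(
                f"{self.rsid}: alleles must be one of A/C/G/T, "
                f"got {self.major_allele!r}/{self.minor_allele!r}"
            )
        if self.major_allele == self.minor_allele:
            raise PanelError(f"{self.rsid}: major and minor allele are identical")
        if not self.gwas_or > 0:
            raise PanelError(f"{self.rsid}: gwas_or must be positive, got {self.gwas_or}")
        if self.rsid in SURVIVAL_ONLY_SNPS and self.in_prs:
            raise PanelError(f"{self.rsid} is survival-only and cannot enter the PRS")
        for label, (maf, n) in self.ref_mafs.items():
            if not 0.0 <= maf <= 1.0:
                raise PanelError(f"{self.rsid}: reference MAF for {label} outside [0,1]")
            if n <= 0:
                raise PanelError(f"{self.rsid}: reference n for {label} must be positive")


@dataclass(frozen=True)
class Subject:
    """One participant: disease status, demographics, and exposure flags."""

    subject_id: str
    status: str  # "case" | "control"
    age: float | None = None
    sex: str | None = None  # "male" | "female"
    ancestry: str = "unknown"
    exposures: dict[str, str] = field(default_factory=dict)  # value: yes/no/missing
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise PanelError(
                f"subject {self.subject_id}: status must be 'case' or 'control', "
                f"got {self.status!r}"
            )
        if self.age is not None and not 0 <= self.age <= 120:
            raise PanelError(f"subject {self.subject_id}: age {self.age} outside [0, 120]")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise PanelError(f"subject {self.subject_id}: sex {self.sex!r} invalid")
        if self.ancestry not in ANCESTRIES:
            raise PanelError(f"subject {self.subject_id}: ancestry {self.ancestry!r} invalid")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


class GenotypeMatrix:
    """Subjects × SNPs minor-allele dosages with missingness.

    Thin wrapper around a float DataFrame (rows = subjects, columns = rsIDs);
    cells are 0.0/1.0/2.0 or NaN for a failed call.
    """

    def __init__(self, dosage: pd.DataFrame):
        values = dosage.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise PanelError(
                f"invalid dosage {values[i, j]!r} for subject "
                f"{dosage.index[i]!r} at {dosage.columns[j]!r}"
            )
        if dosage.index.duplicated().any():
            dup = dosage.index[dosage.index.duplicated()][0]
            raise PanelError(f"duplicate subject_id {dup!r} in genotype matrix")
        if dosage.columns.duplicated().any():
            dup = dosage.columns[dosage.columns.duplicated()][0]
            raise PanelError(f"duplicate rsid {dup!r} in genotype matrix")
        self._df = dosage.astype(float)

    @property
    def subject_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def rsids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def dosage(self) -> pd.DataFrame:
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def row(self, subject_id: str) -> np.ndarray:
        return self._df.loc[subject_id].to_numpy()

    def column(self, rsid: str) -> np.ndarray:
        return self._df[rsid].to_numpy()

    def subset(self, subject_ids=None, rsids=None) -> "GenotypeMatrix":
        df = self._df
        if subject_ids is not None:
            df = df.loc[list(subject_ids)]
        if rsids is not None:
            df = df[list(rsids)]
        return GenotypeMatrix(df.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenotypeMatrix) and self._df.equals(other._df)


def _parse_bool(raw: str, where: str) -> bool:
    low = str(raw).strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise PanelError(f"{where}: cannot parse boolean {raw!r}")


def load_panel(path: str | Path) -> list[SnpDef]:
    """Parse a panel TSV into :class:`SnpDef` records.

    Required columns: rsid, gene, major, minor, gwas_or, in_prs.  Any column
    pair ``ref_maf_<label>`` / ``ref_n_<label>`` populates ``ref_mafs``.
    Duplicate rsIDs are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise PanelError(f"no panel rows in {path}")
    required = {"rsid", "gene", "major", "minor", "gwas_or", "in_prs"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel {path} missing columns: {sorted(missing)}")
    maf_labels = [c[len("ref_maf_"):] for c in df.columns if c.startswith("ref_maf_")]

    snps: list[SnpDef] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rsid = str(row["rsid"]).strip()
        if rsid in seen:
            raise PanelError(f"duplicate rsid {rsid!r} at panel row {i + 1}")
        seen.add(rsid)
        try:
            gwas_or = float(row["gwas_or"])
        except (TypeError, ValueError):
            raise PanelError(f"panel row {i + 1} ({rsid}): bad gwas_or {row['gwas_or']!r}")
        ref_mafs: dict[str, tuple[float, int]] = {}
        for label in maf_labels:
            maf_raw = row.get(f"ref_maf_{label}")
            n_raw = row.get(f"ref_n_{label}")
            if pd.isna(maf_raw) or str(maf_raw).strip() in ("", "NA"):
                continue
            n = int(float(n_raw)) if not pd.isna(n_raw) and str(n_raw).strip() not in ("", "NA") else 1
            ref_mafs[label] = (float(maf_raw), n)
        try:
            snps.append(
                SnpDef(
                    rsid=rsid,
                    nearest_gene=str(row["gene"]).strip(),
                    major_allele=str(row["major"]).strip().upper(),
                    minor_allele=str(row["minor"]).strip().upper(),
                    gwas_or=gwas_or,
                    in_prs=_parse_bool(row["in_prs"], f"panel row {i + 1} ({rsid})"),
                    ref_mafs=ref_mafs,
                )
            )
        except PanelError as exc:
            raise PanelError(f"panel row {i + 1}: {exc}") from exc
    return snps


def default_panel() -> list[SnpDef]:
    """The shipped 26-SNP pancreatic-adenocarcinoma panel.

    Weights (``gwas_or``) default to the study's own per-SNP allelic odds
    ratios as documented placeholders; substitute the original GWAS estimates
    for production scoring.  Reference MAFs carry the study control
    frequencies plus dbSNP per-ancestry values where available.
    """
    with resources.as_file(resources.files("pancprs.data") / "default_panel.tsv") as p:
        return load_panel(p)


def _data_table(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("pancprs.data") / name) as p:
        return pd.read_csv(p, sep="\t")


def reported_associations() -> pd.DataFrame:
    """Published per-SNP association summary (printed MAFs, allelic OR, flag)."""
    df = _data_table("reported_associations.tsv")
    df["significant"] = df["significant"].astype(str).str.lower().eq("true")
    return df


def reported_ancestry_mafs() -> pd.DataFrame:
    """Published per-ancestry minor-allele frequencies for the nine flagged SNPs."""
    return _data_table("reported_ancestry_mafs.tsv")


def reported_epidemiology() -> pd.DataFrame:
    """Published exposure percentages by case/control group."""
    return _data_table("reported_epidemiology.tsv")


_MISSING_TOKENS = ("", "NA", "nan")


def read_genotypes(path: str | Path, panel: list[SnpDef]) -> GenotypeMatrix:
    """Read a wide genotype TSV (subject_id + one column per rsID).

    Cells must be 0, 1, 2 or NA/blank.  Columns not in the panel are dropped
    with a warning; a cell outside the domain is an error naming its
    coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("subject_id")
    panel_ids = [s.rsid for s in panel]
    unknown = [c for c in df.columns if c not in panel_ids]
    if unknown:
        warnings.warn(f"ignoring non-panel genotype columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    out = pd.DataFrame(index=df.index, dtype=float)
    for col in df.columns:
        parsed = []
        for sid, raw in df[col].items():
            token = "" if pd.isna(raw) else str(raw).strip()
            if token in _MISSING_TOKENS:
                parsed.append(np.nan)
            elif token in ("0", "1", "2"):
                parsed.append(float(token))
            else:
                raise PanelError(
                    f"invalid dosage {raw!r} for subject {sid!r} at {col!r} in {path}"
                )
        out[col] = parsed
    return GenotypeMatrix(out)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as the wide TSV ``read_genotypes`` reads."""
    df = matrix.dosage.copy()
    out = df.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


def read_vcf_genotypes(path: str | Path, panel: list[SnpDef]) -> GenotypeMatrix:
    """Read genotypes from a VCF, matching sites to the panel by rsID only.

    Diploid GT fields are converted to panel-minor-allele dosage.  If the VCF
    REF/ALT orientation is flipped relative to the panel (REF = panel minor),
    the ALT dosage is complemented (2 − dosage) and the flip logged as a
    warning.  Half-calls and ``./.`` become missing.  Panel rsIDs absent from
    the VCF yield an all-missing column with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_rsid = {s.rsid: s for s in panel}
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in by_rsid:
            continue
        snp = by_rsid[rsid]
        if len(variant.ALT) > 1:
            raise PanelError(f"{rsid}: multi-allelic VCF site not supported for panel loci")
        alt = variant.ALT[0] if variant.ALT else None
        ref = variant.REF
        if ref == snp.major_allele and alt == snp.minor_allele:
            flip = False
        elif ref == snp.minor_allele and alt == snp.major_allele:
            flip = True
            warnings.warn(f"{rsid}: VCF REF/ALT flipped relative to panel; complementing dosage",
                          stacklevel=2)
        else:
            raise PanelError(
                f"{rsid}: VCF alleles {ref}/{alt} do not match panel "
                f"{snp.major_allele}/{snp.minor_allele}"
            )
        col = np.full(len(samples), np.nan)
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown; half-calls map to unknown
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) != 2:
                continue
            alt_dosage = sum(alleles)
            col[i] = 2 - alt_dosage if flip else alt_dosage
        columns[rsid] = col
    out = pd.DataFrame(index=pd.Index(samples, name="subject_id"), dtype=float)
    for snp in panel:
        if snp.rsid in columns:
            out[snp.rsid] = columns[snp.rsid]
        else:
            warnings.warn(f"{snp.rsid} absent from VCF; column set to missing", stacklevel=2)
            out[snp.rsid] = np.nan
    return GenotypeMatrix(out)


def read_subjects(path: str | Path) -> list[Subject]:
    """Read the subject metadata TSV.

    Columns: subject_id, status, age, sex, ancestry, tobacco, alcohol,
    diabetes, pancreatitis, family_history, duplicate_of.  Status outside
    {case, control} is a hard error; other fields may be missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    subjects = []
    for i, row in df.iterrows():
        def cell(name):
            raw = row.get(name)
            if pd.isna(raw) or str(raw).strip() in _MISSING_TOKENS:
                return None
            return str(raw).strip()

        status = cell("status")
        if status is None:
            raise PanelError(f"subject row {i + 1}: missing status")
        age_raw = cell("age")
        exposures = {}
        for exp in EXPOSURES:
            val = cell(exp)
            exposures[exp] = val if val in ("yes", "no") else "missing"
        subjects.append(
            Subject(
                subject_id=cell("subject_id"),
                status=status,
                age=float(age_raw) if age_raw is not None else None,
                sex=cell("sex"),
                ancestry=cell("ancestry") or "unknown",
                exposures=exposures,
                duplicate_of=cell("duplicate_of"),
            )
        )
    return subjects


def write_subjects(subjects: list[Subject], path: str | Path) -> None:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "status": s.status,
            "age": "" if s.age is None else f"{s.age:g}",
            "sex": s.sex or "",
            "ancestry": s.ancestry,
        }
        for exp in EXPOSURES:
            val = s.exposures.get(exp, "missing")
            row[exp] = "" if val == "missing" else val
        row["duplicate_of"] = s.duplicate_of or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
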