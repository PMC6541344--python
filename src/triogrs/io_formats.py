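"""Readers and writers for the package's file formats.

Four kinds of files flow through the pipeline:

* **weight tables** — one row per scored SNP with its risk (effect) allele,
  the other allele, a positive per-allele weight and the condition the SNP
  belongs to (``HTN``, ``OBESITY`` or ``T2D``).  TSV/CSV with a header.
* **trio pedigrees** — one row per case-parent trio with sample ids, cohort
  label and the categorical phenotype fields used by subgroup filters.
* **genotype dosages** — effect-allele dosages in ``[0, 2]`` for the scored
  SNPs, either as a VCF (``GT`` hard calls or a ``DS`` dosage field, read
  and written through :mod:`pysam`) or as a tabular grid.
* **association p-values** — per-SNP p-values consumed by the screening
  step (the upstream trio GWAS is outside this package).

The tabular dosage dialect is a TSV whose first column is ``sample_id`` and
whose remaining column names encode the variant as
``<snp_id>:<counted_allele>:<other_allele>``; missing genotypes are the
literal string ``NA``.  This keeps the allele bookkeeping needed for
orientation inside a single self-describing text file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

CONDITIONS = ("HTN", "OBESITY", "T2D")

#: canonical CTD subtypes; anything unrecognized maps to "other"
CTD_SUBTYPES = (
    "ToF",
    "D-TGA",
    "L-TGA",
    "DORV",
    "VSD",
    "IAA",
    "truncus",
    "aortic_arch_anomaly",
    "complex",
    "other",
)

YES_NO_FIELDS = (
    "extracardiac",
    "maternal_preeclampsia",
    "maternal_htn_medication",
    "maternal_pregestational_diabetes",
    "maternal_gestational_diabetes",
)

BAND_FIELDS = ("maternal_age_band", "paternal_age_band", "maternal_bmi_band")

TRIO_REQUIRED = ("family_id", "mother_id", "father_id", "child_id", "cohort")

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# weight tables
# ---------------------------------------------------------------------------

def read_weight_table(path, condition_filter: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a per-condition SNP weight table.

    Parameters
    ----------
    path
        TSV or CSV file with a header naming at least ``snp_id``,
        ``effect_allele``, ``other_allele``, ``weight`` and ``condition``.
        ``chrom``/``pos`` columns are carried through when present.
    condition_filter
        Optional subset of conditions to keep.

    Returns
    -------
    pandas.DataFrame
        Validated weight table, one row per SNP, input order preserved.
    """
    df = _read_delimited(path)
    required = ("snp_id", "effect_allele", "other_allele", "weight", "condition")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: weight table missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: weight table is empty (header only)", path)
        df = df.assign(weight=pd.Series(dtype=float))
        return df.reset_index(drop=True)

    weights = pd.to_numeric(df["weight"], errors="coerce")
    bad = weights.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: malformed weight on line {line}: {df['weight'][bad.idxmax()]!r}")
    df = df.assign(weight=weights.astype(float), condition=df["condition"].str.upper())

    if (df["weight"] <= 0).any():
        snp = df.loc[df["weight"] <= 0, "snp_id"].iloc[0]
        raise ValidationError(f"{path}: non-positive weight for {snp}; weights must be oriented to the risk allele")
    unknown = set(df["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValidationError(f"{path}: unknown condition(s) {sorted(unknown)}")
    for col in ("effect_allele", "other_allele"):
        bad_allele = ~df[col].astype(str).isin(_VALID_BASES)
        if bad_allele.any():
            snp = df.loc[bad_allele, "snp_id"].iloc[0]
            raise ValidationError(f"{path}: {col} for {snp} is not a single base")
    if (df["effect_allele"] == df["other_allele"]).any():
        snp = df.loc[df["effect_allele"] == df["other_allele"], "snp_id"].iloc[0]
        raise ValidationError(f"{path}: effect and other allele identical for {snp}")

    dup_within = df.duplicated(subset=["condition", "snp_id"])
    if dup_within.any():
        snp = df.loc[dup_within, "snp_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate snp_id {snp} within a condition")
    counts_per_snp = df.groupby("snp_id")["condition"].nunique()
    cross = counts_per_snp[counts_per_snp > 1]
    if not cross.empty:
        raise ValidationError(
            f"{path}: snp_id(s) {list(cross.index)} appear in more than one condition; "
            "score panels must not overlap"
        )

    if condition_filter is not None:
        keep = {c.upper() for c in condition_filter}
        df = df[df["condition"].isin(keep)]

    for cond, n in df["condition"].value_counts().items():
        logger.info("weight table %s: %d SNPs for %s", path, n, cond)
    return df.reset_index(drop=True)


def write_weight_table(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trio pedigrees
# ---------------------------------------------------------------------------

def read_trios(path) -> pd.DataFrame:
    """Read a trio pedigree table (one row per case-parent trio).

    Unknown or missing values in the enumerated phenotype fields are mapped
    to ``"unknown"``; unrecognized CTD subtypes map to ``"other"``.
    """
    df = _read_delimited(path)
    missing = [c for c in TRIO_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: pedigree missing required column(s) {missing}")

    dup = df.duplicated(subset="family_id")
    if dup.any():
        raise ValidationError(f"{path}: duplicate family_id {df.loc[dup, 'family_id'].iloc[0]}")
    ids = df[["mother_id", "father_id", "child_id"]].astype(str)
    distinct = ids.nunique(axis=1)
    if (distinct < 3).any():
        fam = df.loc[distinct < 3, "family_id"].iloc[0]
        raise ValidationError(f"{path}: mother/father/child ids not distinct in family {fam}")

    df = df.copy()
    df["cohort"] = df["cohort"].astype(str).str.upper()
    bad_cohort = ~df["cohort"].isin(("CHOP", "PCGC"))
    if bad_cohort.any():
        raise ValidationError(f"{path}: cohort must be CHOP or PCGC, got {df.loc[bad_cohort, 'cohort'].iloc[0]!r}")

    subtype_lut = {s.lower(): s for s in CTD_SUBTYPES}
    if "ctd_subtype" not in df.columns:
        df["ctd_subtype"] = "other"
    df["ctd_subtype"] = (
        df["ctd_subtype"].astype(str).str.strip().str.lower().map(subtype_lut).fillna("other")
    )

    if "child_sex" not in df.columns:
        df["child_sex"] = "unknown"
    df["child_sex"] = df["child_sex"].astype(str).str.lower().where(
        df["child_sex"].astype(str).str.lower().isin(("male", "female")), "unknown"
    )

    for col in YES_NO_FIELDS:
        if col not in df.columns:
            df[col] = "unknown"
        vals = df[col].astype(str).str.lower()
        df[col] = vals.where(vals.isin(("yes", "no")), "unknown")
    for col in BAND_FIELDS:
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].astype(str).replace({"nan": "unknown", "": "unknown"})
    return df.reset_index(drop=True)


def write_trios(trios: pd.DataFrame, path) -> None:
    trios.to_csv(path, sep="\t", index=False)


def parent_roles(trios: pd.DataFrame) -> pd.DataFrame:
    """Map parental sample ids to their role and cohort.

    Returns a frame with columns ``sample_id``, ``role`` (``mother`` /
    ``father``), ``family_id`` and ``cohort`` — the bookkeeping the GRS
    engine needs for role-stratified imputation and the contrast step.
    """
    mothers = trios[["mother_id", "family_id", "cohort"]].rename(columns={"mother_id": "sample_id"})
    mothers["role"] = "mother"
    fathers = trios[["father_id", "family_id", "cohort"]].rename(columns={"father_id": "sample_id"})
    fathers["role"] = "father"
    out = pd.concat([mothers, fathers], ignore_index=True)
    return out[["sample_id", "role", "family_id", "cohort"]]


# ---------------------------------------------------------------------------
# dosage matrices
# ---------------------------------------------------------------------------

@dataclass
class DosageMatrix:
    """Samples x SNPs effect-allele dosages with allele bookkeeping.

    ``dosage`` is a float matrix with entries in ``[0, 2]`` or ``NaN`` for
    missing genotypes.  ``counted_allele[j]`` is the allele whose copies
    column ``j`` counts; ``oriented[j]`` is True once that allele is known
    to be the weight table's effect allele (see
    :func:`triogrs.grs_engine.align_alleles`).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    counted_allele: list[str]
    other_allele: list[str]
    oriented: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(self.counted_allele) != len(self.snp_ids) or len(self.other_allele) != len(self.snp_ids):
            raise ValidationError("allele lists must have one entry per SNP")
        with np.errstate(invalid="ignore"):
            out_of_range = (self.dosage < 0) | (self.dosage > 2)
        if np.any(out_of_range):
            i, j = np.argwhere(out_of_range)[0]
            raise ValidationError(
                f"dosage {self.dosage[i, j]} for sample {self.sample_ids[i]} at "
                f"{self.snp_ids[j]} outside [0, 2]"
            )
        if self.oriented is None:
            self.oriented = np.zeros(len(self.snp_ids), dtype=bool)
        else:
            self.oriented = np.asarray(self.oriented, dtype=bool)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in dosage matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_samples(self, keep: Sequence[str]) -> "DosageMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise ValidationError(f"samples absent from dosage matrix: {missing[:5]}")
        rows = [index[s] for s in keep]
        return replace(self, sample_ids=list(keep), dosage=self.dosage[rows, :])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}:{c}:{o}" for s, c, o in zip(self.snp_ids, self.counted_allele, self.other_allele)]
        return pd.DataFrame(self.dosage, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols)


def read_dosages(path, weights: pd.DataFrame, format: str | None = None) -> DosageMatrix:
    """Read genotype dosages for the SNPs in ``weights``.

    ``format`` is ``"vcf"`` or ``"tabular"``; inferred from the file
    extension when omitted.  SNPs in the file that are absent from the
    weight table are skipped (logged); allele orientation is recorded but
    flipping is deferred to :func:`triogrs.grs_engine.align_alleles`.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "tabular"
    if format == "vcf":
        dm = _read_vcf(path, weights)
    elif format == "tabular":
        dm = _read_tabular(path, weights)
    else:
        raise ValueError(f"unknown dosage format {format!r}")
    effect = dict(zip(weights["snp_id"], weights["effect_allele"]))
    dm.oriented = np.array([effect.get(s) == c for s, c in zip(dm.snp_ids, dm.counted_allele)], dtype=bool)
    return dm


def _read_tabular(path, weights: pd.DataFrame) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column of a tabular dosage grid must be sample_id")
    samples = df["sample_id"].tolist()
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path}: sample listed twice in dosage grid")
    known = set(weights["snp_id"])
    snp_ids, counted, other, cols = [], [], [], []
    for col in df.columns[1:]:
        parts = col.split(":")
        if len(parts) != 3:
            raise ParseError(f"{path}: dosage column {col!r} is not <snp_id>:<counted>:<other>")
        snp, c_allele, o_allele = parts
        if snp not in known:
            logger.info("%s: skipping %s (not in weight table)", path, snp)
            continue
        snp_ids.append(snp)
        counted.append(c_allele)
        other.append(o_allele)
        cols.append(col)
    values = df[cols].replace("NA", np.nan).astype(float).to_numpy() if cols else np.empty((len(samples), 0))
    return DosageMatrix(samples, snp_ids, values, counted, other)


def _read_vcf(path, weights: pd.DataFrame) -> DosageMatrix:
    known = set(weights["snp_id"])
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise ValidationError(f"{path}: sample listed twice in VCF header")
        snp_ids, counted, other, rows = [], [], [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValidationError(
                    f"{path}: multi-allelic or ALT-less record at {rec.chrom}:{rec.pos} ({rec.id}); "
                    "the scored panel is biallelic SNPs"
                )
            if rec.id not in known:
                logger.info("%s: skipping %s (not in weight table)", path, rec.id)
                continue
            row = np.full(len(samples), np.nan)
            for i, name in enumerate(samples):
                call = rec.samples[name]
                ds = call.get("DS") if "DS" in call else None
                if ds is not None:
                    row[i] = float(ds if np.isscalar(ds) else ds[0])
                else:
                    gt = call.get("GT")
                    if gt is not None and None not in gt:
                        row[i] = float(sum(gt))
            snp_ids.append(rec.id)
            counted.append(rec.alts[0])  # dosages count ALT copies
            other.append(rec.ref)
            rows.append(row)
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return DosageMatrix(samples, snp_ids, dosage, counted, other)


def write_dosages(dm: DosageMatrix, path) -> None:
    """Write the tabular dosage dialect (``NA`` for missing)."""
    frame = dm.to_frame()
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def write_vcf(dm: DosageMatrix, path, weights: pd.DataFrame | None = None) -> None:
    """Write dosages as an uncompressed VCF.

    ``DS`` always carries the dosage; ``GT`` is additionally written when
    the dosage is a hard call (integral).  Chromosome/position come from the
    weight table when available, else synthetic coordinates are used.
    """
    coords: Mapping[str, tuple[str, int]] = {}
    if weights is not None and "chrom" in weights.columns and "pos" in weights.columns:
        coords = {
            r.snp_id: (str(r.chrom), int(r.pos))
            for r in weights.itertuples()
            if pd.notna(r.pos)
        }
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">')
    chroms = []
    for j, snp in enumerate(dm.snp_ids):
        chrom = coords.get(snp, ("1", j + 1))[0]
        if chrom not in chroms:
            chroms.append(chrom)
    for chrom in chroms or ["1"]:
        header.add_line(f"##contig=<ID={chrom}>")
    for s in dm.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, snp in enumerate(dm.snp_ids):
            chrom, pos = coords.get(snp, ("1", j + 1))
            rec = out.new_record(
                contig=chrom,
                start=pos - 1,
                alleles=(dm.other_allele[j], dm.counted_allele[j]),
                id=snp,
            )
            for i, name in enumerate(dm.sample_ids):
                val = dm.dosage[i, j]
                if np.isnan(val):
                    rec.samples[name]["GT"] = (None, None)
                else:
                    rec.samples[name]["DS"] = float(val)
                    if float(val).is_integer():
                        g = int(val)
                        rec.samples[name]["GT"] = ((0, 0), (0, 1), (1, 1))[g]
                    else:
                        rec.samples[name]["GT"] = (None, None)
            out.write(rec)


# ---------------------------------------------------------------------------
# association p-values (screen input)
# ---------------------------------------------------------------------------

def read_associations(path) -> pd.DataFrame:
    """Read per-SNP association p-values for the screening step.

    Expects columns ``snp_id``, ``condition``, ``p_value``; optional
    ``nearest_gene`` and ``location`` are carried through.
    """
    df = _read_delimited(path)
    required = ("snp_id", "condition", "p_value")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: association table missing column(s) {missing}")
    p = pd.to_numeric(df["p_value"], errors="coerce")
    if p.isna().any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError(f"{path}: p_value must be in (0, 1]")
    df = df.assign(p_value=p.astype(float), condition=df["condition"].str.upper())
    unknown = set(df["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValidationError(f"{path}: unknown condition(s) {sorted(unknown)}")
    return df.reset_index(drop=True)


def _read_delimited(path) -> pd.DataFrame:
    """Read a TSV/CSV with a header, delimiter sniffed."""
    try:
        return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
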