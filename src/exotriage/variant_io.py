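"""Readers/writers for the formats the triage pipeline touches, and cohort
allele counting.

Formats handled
---------------
* VCF 4.x (via :mod:`cyvcf2`): only the GT field is consumed; phased and
  unphased separators are treated identically because every downstream
  statistic uses allele counts only. Multi-allelic sites are split into one
  record per alternate allele; in a split record the two allele slots of a
  sample are coded ``0`` (reference or *another* alternate), ``1`` (this
  record's alternate) or ``-1`` (missing), so that summing per-alt counts
  over a split site recovers the site's total alt-slot count.
* Annotation table: TSV with one row per (chrom, pos, ref, alt) after
  splitting; missing values are empty strings on disk and NaN/None in
  memory. See :data:`ANNOTATION_COLUMNS`.
* Gene panel: one symbol per line, ``#`` comments, matched case-sensitively
  after trimming whitespace.
* GMT gene sets: ``term_id TAB description TAB gene ...``.
* Protein domain table: TSV ``transcript, domain, aa_start, aa_end``
  (1-based inclusive amino-acid coordinates).

Coordinates are 1-based throughout (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .prioritizer import TOOL_ROSTER

logger = logging.getLogger(__name__)

MISSING = -1  # allele-slot code for an uncalled allele

#: columns of the annotation TSV, in file order; the 18 predictor columns
#: follow, named after the tools in :data:`exotriage.prioritizer.TOOL_ROSTER`.
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "effect", "impact",
    "hgvs_c", "hgvs_p", "transcript", "af_gnomad", "af_1kg", "cadd",
    "clinical_sig",
]

IMPACT_CLASSES = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})


class VcfParseError(ValueError):
    """A structurally malformed VCF body line (reported with line number)."""


class UnknownSampleError(KeyError):
    """A VCF sample has no case/control assignment."""


@dataclass(frozen=True)
class Cohort:
    """Sample names and their case/control assignment, in VCF column order."""

    samples: tuple[str, ...]
    groups: tuple[str, ...]  # parallel to samples, each "case" or "control"

    def __post_init__(self) -> None:
        bad = set(self.groups) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def mask(self, group: str) -> np.ndarray:
        if group not in set(self.groups):
            raise ValueError(f"empty or unknown group {group!r}")
        return np.array([g == group for g in self.groups])

    def n(self, group: str) -> int:
        return int(self.mask(group).sum())


@dataclass
class VariantRecord:
    """One site + single alternate allele with per-sample diploid calls.

    ``genotypes`` has shape (n_samples, 2); entries are 0 (ref/other-alt),
    1 (this alt) or -1 (missing).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValueError("genotypes must have shape (n_samples, 2)")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class AlleleCount:
    """Ref/alt/missing allele-slot counts for one site within one group."""

    n_ref: int
    n_alt: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ref, self.n_alt, self.n_missing) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_ref + self.n_alt + self.n_missing


@dataclass(frozen=True)
class GenePanel:
    genes: frozenset[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        if any(not g or g != g.strip() for g in self.genes):
            raise ValueError("panel symbols must be non-empty and trimmed")

    def __contains__(self, gene: object) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes within set {self.term_id}")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    category: str = "uncategorized"

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# VCF

def _prescan_vcf(path: str | Path) -> int:
    """Structural check of the VCF body; returns the expected sample count.

    htslib does not report line numbers on parse failure, so column counts
    are validated here first and errors carry the 1-based line number.
    """
    n_fixed = 9  # CHROM..FORMAT
    n_samples = None
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < n_fixed:
                    raise VcfParseError(
                        f"line {lineno}: header has {len(fields)} columns, "
                        f"expected at least {n_fixed}"
                    )
                n_samples = len(fields) - n_fixed
                continue
            if n_samples is None:
                raise VcfParseError(f"line {lineno}: data before #CHROM header")
            if len(fields) != n_fixed + n_samples:
                raise VcfParseError(
                    f"line {lineno}: {len(fields)} columns, expected "
                    f"{n_fixed + n_samples}"
                )
            if len(fields) > 1 and not fields[1].isdigit():
                raise VcfParseError(f"line {lineno}: POS {fields[1]!r} not an integer")
    if n_samples is None:
        raise VcfParseError("no #CHROM header line found")
    return n_samples


def read_vcf(
    path: str | Path,
    sample_groups: Mapping[str, str],
) -> tuple[list[VariantRecord], Cohort]:
    """Read a VCF into split, sorted variant records plus cohort labels.

    Every sample in the file must appear in ``sample_groups`` with value
    "case" or "control". Records are returned sorted by (chrom, pos, alt).
    """
    _prescan_vcf(path)
    vcf = VCF(str(path), gts012=False)
    samples = tuple(vcf.samples)
    missing = [s for s in samples if s not in sample_groups]
    if missing:
        raise UnknownSampleError(
            f"samples without a case/control assignment: {missing}"
        )
    cohort = Cohort(samples, tuple(sample_groups[s] for s in samples))

    records: list[VariantRecord] = []
    for v in vcf:
        # genotypes: per sample [allele0, allele1, phased]; -1 = missing
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        for ai, alt in enumerate(v.ALT, start=1):
            slots = np.where(gts == MISSING, MISSING, (gts == ai).astype(np.int16))
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    id=None if v.ID in (None, ".") else v.ID,
                    genotypes=slots.astype(np.int8),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return records, cohort


def write_vcf(
    path: str | Path,
    records: Sequence[VariantRecord],
    cohort: Cohort,
) -> None:
    """Write biallelic records as a minimal GT-only VCF 4.2 file."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exotriage\n")
        for chrom in sorted({r.chrom for r in records}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples) + "\n"
        )
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            if r.genotypes.shape[0] != len(cohort.samples):
                raise ValueError(
                    f"{r.key_str}: {r.genotypes.shape[0]} genotype rows for "
                    f"{len(cohort.samples)} samples"
                )
            gts = "\t".join(
                "/".join("." if a == MISSING else str(a) for a in pair)
                for pair in r.genotypes
            )
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id or '.'}\t{r.ref}\t{r.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def site_allele_counts(record: VariantRecord, cohort: Cohort, group: str) -> AlleleCount:
    """Count ref/alt/missing allele slots of one record within one group.

    The conservation invariant ``n_ref + n_alt + n_missing == 2 * n_group``
    holds by construction.
    """
    slots = record.genotypes[cohort.mask(group)]
    if slots.size == 0:
        raise ValueError(f"group {group!r} contains no samples")
    n_missing = int((slots == MISSING).sum())
    n_alt = int((slots == 1).sum())
    n_ref = int(slots.size - n_alt - n_missing)
    return AlleleCount(n_ref=n_ref, n_alt=n_alt, n_missing=n_missing)


# ---------------------------------------------------------------------------
# Annotation table

def _predictor_columns() -> list[str]:
    return list(TOOL_ROSTER)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation-table contract; returns the frame unchanged.

    Enforced: required columns present, impact one of the four classes when
    present, population frequencies within [0, 1], CADD non-negative.
    """
    required = set(ANNOTATION_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    impacts = set(df["impact"].dropna()) - IMPACT_CLASSES
    if impacts:
        raise ValueError(f"unknown impact classes: {sorted(impacts)}")
    for col in ("af_gnomad", "af_1kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    cadd = pd.to_numeric(df["cadd"], errors="coerce").dropna()
    if (cadd < 0).any():
        raise ValueError("cadd must be >= 0")
    return df


def variant_key_column(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str)
        + ":" + df["ref"] + ":" + df["alt"]
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV; empty strings become missing values."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    for col in ("af_gnomad", "af_1kg", "cadd"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype(int)
    for col in _predictor_columns():
        if col not in df.columns:
            df[col] = np.nan
    return validate_annotations(df)


def write_annotations(path: str | Path, df: pd.DataFrame) -> None:
    validate_annotations(df)
    cols = ANNOTATION_COLUMNS + _predictor_columns()
    out = df.reindex(columns=cols)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_panel(path: str | Path, name: str | None = None) -> GenePanel:
    genes = []
    with open(path, "rt") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                genes.append(sym)
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        logger.warning("panel %s: dropping duplicate symbols %s", path, sorted(dupes))
    return GenePanel(frozenset(genes), name=name or Path(path).stem)


def write_panel(path: str | Path, panel: GenePanel) -> None:
    with open(path, "wt") as fh:
        fh.write(f"# gene panel: {panel.name} ({len(panel)} genes)\n")
        for g in sorted(panel.genes):
            fh.write(g + "\n")


def read_gene_sets(path: str | Path, category: str = "uncategorized") -> GeneSetCollection:
    """Read a GMT file. Duplicate genes within a set are deduplicated with a
    warning; a line with fewer than 3 fields is an error naming the line."""
    sets: list[GeneSet] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields, expected >= 3"
                )
            term_id, description, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "GMT %s line %d (%s): deduplicated %d repeated gene(s)",
                    path, lineno, term_id, len(genes) - len(deduped),
                )
            sets.append(GeneSet(term_id, description, tuple(deduped)))
    return GeneSetCollection(sets, category=category)


def write_gene_sets(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "wt") as fh:
        for s in collection:
            fh.write("\t".join((s.term_id, s.description, *s.genes)) + "\n")


# ---------------------------------------------------------------------------
# Protein domain table

def read_domains(path: str | Path) -> pd.DataFrame:
    """Read a domain TSV: transcript, domain, aa_start, aa_end (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript": str, "domain": str})
    required = {"transcript", "domain", "aa_start", "aa_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    if (df["aa_start"] < 1).any() or (df["aa_end"] < df["aa_start"]).any():
        raise ValueError("domain coordinates must satisfy 1 <= aa_start <= aa_end")
    return df
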