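"""Core domain types and readers/writers for the external formats the
framework consumes.

Coordinate conventions are enforced at the boundaries: variants are 1-based
(VCF convention), intervals are 0-based half-open (BED convention).  A
variant at 1-based position ``p`` overlaps an interval ``[s, e)`` iff
``s <= p - 1 < e``.  Conversion happens only inside overlap queries.

Multi-allelic VCF records are split into biallelic records at load time;
every downstream definition is per-(ref, alt) pair.  INDELs follow the VCF
anchored-base convention (the first base of REF and ALT is the shared
anchor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import motifs as bio_motifs

__all__ = [
    "ANNOTATION_CLASSES",
    "MARKER_CLASSES",
    "Variant",
    "PeakInterval",
    "Pfm",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "CovariateTable",
    "SchemaError",
    "VariantParseError",
    "read_variants",
    "write_variants_vcf",
    "filter_common",
    "read_pfms",
    "write_pfms",
    "read_peaks",
    "write_peaks",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_genotypes",
    "read_expression",
    "read_covariates",
]

ANNOTATION_CLASSES = frozenset(
    {
        "intergenic",
        "intronic",
        "exonic",
        "utr3",
        "utr5",
        "tts",
        "ncRNA",
        "promoter",
        "unknown",
    }
)

#: Consensus regulatory-region marker labels.
MARKER_CLASSES = frozenset({"promoter", "enhancer", "active_enhancer"})


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class VariantParseError(ValueError):
    """A variant record could not be parsed; carries the line number."""


@dataclass(frozen=True)
class Variant:
    """One common biallelic variant.

    ``pos`` is 1-based.  ``maf`` is the minor-allele frequency as a fraction
    (``None`` when the source file does not report it).  ``annotation`` is a
    coarse genic-context class.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float | None = None
    annotation: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref == alt ({self.ref})")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")
        if self.annotation not in ANNOTATION_CLASSES:
            raise ValueError(f"variant {self.id}: unknown annotation {self.annotation!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)


@dataclass(frozen=True)
class PeakInterval:
    """A ChIP-seq peak interval, 0-based half-open, with experiment metadata."""

    chrom: str
    start: int
    end: int
    experiment_id: str
    replicate_id: str
    factor: str
    cell_or_tissue: str
    peak_kind: str = "narrow"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.peak_kind not in ("narrow", "broad"):
            raise ValueError(f"unknown peak_kind {self.peak_kind!r}")

    def contains_pos(self, pos_1based: int) -> bool:
        """True iff the 1-based variant position falls inside the interval."""
        return self.start <= pos_1based - 1 < self.end


@dataclass
class Pfm:
    """A position frequency matrix, rows fixed in A, C, G, T order."""

    motif_id: str
    factor: str
    counts: np.ndarray  # shape (4, L), nonnegative
    source: str = ""
    motif_kind: str = "tfbs"  # "tfbs" or "rbp"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: empty matrix")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if self.motif_kind not in ("tfbs", "rbp"):
            raise ValueError(f"unknown motif_kind {self.motif_kind!r}")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    def probabilities(self, pseudocount: float = 0.01) -> np.ndarray:
        """Column-normalized probabilities after adding a per-cell pseudocount."""
        c = self.counts + pseudocount
        total = c.sum(axis=0)
        if (total <= 0).any():
            raise ValueError(f"motif {self.motif_id}: column with nonpositive total")
        return c / total

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "Pfm":
        return Pfm(
            motif_id=self.motif_id,
            factor=self.factor,
            counts=self.counts[::-1, ::-1].copy(),
            source=self.source,
            motif_kind=self.motif_kind,
        )


@dataclass
class GenotypeMatrix:
    """Samples x variants allele dosages of the alternative allele.

    ``codes`` is a float array with values in {0, 1, 2} and NaN for missing
    genotypes.  Missing values are excluded per-test downstream, never
    imputed.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("genotype codes shape inconsistent with ids")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype codes must be 0/1/2 or missing")

    def dosages(self, variant_id: str) -> np.ndarray:
        return self.codes[:, self.variant_ids.index(variant_id)]


@dataclass
class ExpressionMatrix:
    """Samples x genes normalized transcript levels."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("expression values shape inconsistent with ids")


@dataclass
class CovariateTable:
    """Per-sample covariates: age, sex (0/1), and three ancestry PCs."""

    table: pd.DataFrame  # index sample_id; columns age, sex, pc1, pc2, pc3

    REQUIRED = ("age", "sex", "pc1", "pc2", "pc3")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"covariate table missing columns: {missing}")
        sex = self.table["sex"].dropna()
        if not sex.isin([0, 1]).all():
            raise ValueError("sex must be coded 0/1")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in covariate table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def design_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Covariate block (age, sex, pc1..pc3) aligned to ``sample_ids``."""
        return self.table.loc[list(sample_ids), list(self.REQUIRED)].to_numpy(float)


# ---------------------------------------------------------------------------
# Variants


def _variant_from_fields(
    chrom: str, pos: int, vid: str, ref: str, alt: str, maf: float | None,
    annotation: str = "unknown",
) -> Variant:
    if maf is not None:
        # allele frequency above 0.5 refers to the major allele; fold it
        maf = min(float(maf), 1.0 - float(maf))
        maf = round(maf, 6)
    return Variant(id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt, maf=maf,
                   annotation=annotation)


def _read_variants_vcf(path: Path) -> list[Variant]:
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            afs = rec.info.get("AF") if "AF" in rec.info else None
            for i, alt in enumerate(alts):
                maf = None
                if afs is not None:
                    maf = float(afs[i]) if i < len(afs) else float(afs[0])
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                if len(alts) > 1:
                    vid = f"{vid}:{alt}" if rec.id else vid
                out.append(
                    _variant_from_fields(rec.chrom, rec.pos, vid, rec.ref, alt, maf)
                )
    return out


_TSV_REQUIRED = ("chrom", "pos", "ref", "alt", "id")


def _read_variants_tsv(path: Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        maf = getattr(row, "maf", None)
        if maf is not None and (isinstance(maf, float) and math.isnan(maf)):
            maf = None
        annotation = getattr(row, "annotation", "unknown")
        out.append(
            _variant_from_fields(
                str(row.chrom), int(row.pos), str(row.id), str(row.ref),
                str(row.alt), maf, str(annotation),
            )
        )
    return out


def read_variants(path: str | Path, format: str = "vcf") -> list[Variant]:
    """Read variants from VCF or minimal TSV, splitting multi-allelic sites.

    The TSV schema is ``chrom, pos, ref, alt, id`` with optional ``maf`` and
    ``annotation`` columns.  Returns variants in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_variants_vcf(path)
    if format == "tsv":
        return _read_variants_tsv(path)
    raise ValueError(f"unknown variant format {format!r}")


def write_variants_vcf(variants: Iterable[Variant], path: str | Path) -> None:
    """Write a minimal VCF (CHROM POS ID REF ALT with INFO/AF)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        info = f"AF={v.maf:g}" if v.maf is not None else "."
        lines.append(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def filter_common(variants: Sequence[Variant], maf_min: float = 0.01) -> list[Variant]:
    """Keep variants with MAF >= ``maf_min`` (inclusive), preserving order."""
    missing = [v.id for v in variants if v.maf is None]
    if missing:
        raise ValueError(f"variants lacking MAF: {missing}")
    return [v for v in variants if v.maf >= maf_min]


# ---------------------------------------------------------------------------
# Position frequency matrices


def read_pfms(path: str | Path, dialect: str = "jaspar") -> list[Pfm]:
    """Read PFMs from a JASPAR- or TRANSFAC-style text file.

    Counts are returned with row order fixed as A, C, G, T regardless of the
    dialect.  The record name is used as the associated factor symbol.
    """
    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unknown PFM dialect {dialect!r}")
    with open(path) as fh:
        records = bio_motifs.parse(fh, dialect)
    out = []
    for m in records:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        if (counts < 0).any():
            raise ValueError(f"motif {m.name}: negative counts")
        motif_id = getattr(m, "matrix_id", None) or m.name
        out.append(Pfm(motif_id=str(motif_id), factor=str(m.name), counts=counts,
                       source=dialect))
    return out


def write_pfms(pfms: Sequence[Pfm], path: str | Path) -> None:
    """Write PFMs in JASPAR plain-text format."""
    chunks = []
    for p in pfms:
        rows = [f">{p.motif_id} {p.factor}"]
        for i, base in enumerate("ACGT"):
            vals = " ".join(f"{x:g}" for x in p.counts[i])
            rows.append(f"{base} [ {vals} ]")
        chunks.append("\n".join(rows))
    Path(path).write_text("\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# Peaks (BED + sidecar metadata TSV)

_META_REQUIRED = ("experiment_id", "replicate_id", "factor", "cell_or_tissue",
                  "peak_kind")


def read_peaks(bed_path: str | Path, meta_path: str | Path) -> list[PeakInterval]:
    """Read peaks from BED plus a sidecar metadata TSV.

    The BED name column (4th) keys into the metadata table's
    ``replicate_id``; metadata carries experiment, factor, cell/tissue and
    peak kind for each replicate track.
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise SchemaError(f"{meta_path}: missing metadata columns {missing}")
    meta = meta.set_index("replicate_id", drop=False)
    if meta.index.has_duplicates:
        raise SchemaError(f"{meta_path}: duplicate replicate_id entries")
    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise VariantParseError(f"{bed_path}:{lineno}: BED needs >= 4 columns")
            chrom, start, end, name = fields[:4]
            if name not in meta.index:
                raise SchemaError(
                    f"{bed_path}:{lineno}: replicate {name!r} absent from metadata"
                )
            row = meta.loc[name]
            out.append(
                PeakInterval(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    experiment_id=row["experiment_id"],
                    replicate_id=name,
                    factor=row["factor"],
                    cell_or_tissue=row["cell_or_tissue"],
                    peak_kind=row["peak_kind"],
                )
            )
    return out


def write_peaks(peaks: Sequence[PeakInterval], bed_path: str | Path,
                meta_path: str | Path) -> None:
    """Write peaks as BED4 plus sidecar metadata TSV (inverse of read_peaks)."""
    bed_lines = []
    meta_rows: dict[str, tuple] = {}
    for p in peaks:
        bed_lines.append(f"{p.chrom}\t{p.start}\t{p.end}\t{p.replicate_id}")
        meta_rows[p.replicate_id] = (
            p.experiment_id, p.replicate_id, p.factor, p.cell_or_tissue, p.peak_kind
        )
    Path(bed_path).write_text("\n".join(bed_lines) + "\n")
    meta = pd.DataFrame(list(meta_rows.values()), columns=list(_META_REQUIRED))
    meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSV matrices (header row of ids, first column of sample ids)


def read_matrix_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)


def write_matrix_tsv(path: str | Path, sample_ids: Sequence[str],
                     col_ids: Sequence[str], values: np.ndarray,
                     float_format: str = "%.10g") -> None:
    df = pd.DataFrame(values, index=list(sample_ids), columns=list(col_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    samples, variants, values = read_matrix_tsv(path)
    return GenotypeMatrix(samples, variants, values)


def read_expression(path: str | Path) -> ExpressionMatrix:
    samples, genes, values = read_matrix_tsv(path)
    return ExpressionMatrix(samples, genes, values)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return CovariateTable(df)
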