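"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  GFF3 (1-based, inclusive) and
the variant TSV (1-based positions) are converted at the read/write boundary.
BED is 0-based half-open on disk and in memory.

All readers validate and reject malformed records rather than coercing them.
"""

from __future__ import annotations

import logging
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
VARIANT_TYPES = frozenset({"SNP", "INS", "DEL"})

VARIANT_COLUMNS = ["hap_a", "hap_b", "chromA", "posA", "chromB", "posB", "type", "ref", "alt"]
EXPRESSION_COLUMNS = ["gene_id", "haplotype", "tissue", "tpm"]
ANCHOR_COLUMNS = ["gene_a", "gene_b", "similarity"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequenceSet:
    """One haplotype's chromosome sequences, keyed by chromosome id."""

    haplotype: str
    records: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.records.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"record {cid!r}: illegal characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.records.items()}

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its CDS segments. Coordinates 0-based half-open."""

    gene_id: str
    haplotype: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...] = ()
    pathway_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand {self.strand!r}")
        prev_end = None
        total = 0
        for s, e in self.cds:
            if s < self.start or e > self.end or s >= e:
                raise ValidationError(
                    f"gene {self.gene_id}: CDS segment [{s}, {e}) outside gene body"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping CDS segments")
            prev_end = e
            total += e - s
        if self.cds and total % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: summed CDS length {total} not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass(frozen=True)
class TEInterval:
    """A transposable-element interval, 0-based half-open."""

    haplotype: str
    chromosome: str
    start: int
    end: int
    te_class: str = "TE"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"TE interval [{self.start}, {self.end}) on {self.chromosome} is empty/invalid"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A variant between two haplotypes; position 0-based internally."""

    hap_a: str
    hap_b: str
    chromosome: str
    position: int
    vtype: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.vtype not in VARIANT_TYPES:
            raise ValidationError(f"unknown variant type {self.vtype!r}")
        if self.vtype == "SNP" and not (
            len(self.ref) == 1 and len(self.alt) == 1 and self.ref != self.alt
        ):
            raise ValidationError(
                f"SNP at {self.chromosome}:{self.position + 1} must have two distinct "
                f"single-base alleles, got {self.ref!r}>{self.alt!r}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.hap_a, self.hap_b)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, haplotype: str | None = None) -> GenomeSequenceSet:
    """Read a FASTA file into a :class:`GenomeSequenceSet`.

    Soft-masked (lowercase) bases are folded to uppercase.  Duplicate record
    ids and characters outside ``{A,C,G,T,N}`` raise :class:`FormatError`
    naming the offending record.
    """
    from Bio import SeqIO

    path = Path(path)
    label = haplotype if haplotype is not None else path.stem
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        log.warning("%s: empty FASTA, returning empty sequence set", path)
    return GenomeSequenceSet(haplotype=label, records=records)


def write_fasta(genome: GenomeSequenceSet, path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for cid, seq in genome.records.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "tetradiv") -> None:
    """Write gene/mRNA/CDS features, converting to 1-based inclusive."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};haplotype={g.haplotype}"
            if g.pathway_tags:
                attrs += ";pathway=" + ",".join(sorted(g.pathway_tags))
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for s, e in g.cds:
                fh.write(
                    f"{g.chromosome}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds;Parent={mrna_id}\n"
                )


def read_gff3(path: str | Path, haplotype: str | None = None) -> list[GeneModel]:
    """Read gene models (gene + CDS children) from a GFF3 file.

    Positions are converted from 1-based inclusive to the internal 0-based
    half-open convention.  A gene whose summed CDS length is not a multiple
    of 3 raises :class:`ValidationError` naming the gene id.
    """
    import gffutils

    path = Path(path)
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            sort_attribute_values=True,
        )
        genes: list[GeneModel] = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            cds = tuple(
                sorted(
                    (c.start - 1, c.end)
                    for c in db.children(feat, featuretype="CDS", order_by="start")
                )
            )
            hap = feat.attributes.get("haplotype", [haplotype or "?"])[0]
            tags = frozenset(
                t for v in feat.attributes.get("pathway", []) for t in v.split(",") if t
            )
            try:
                genes.append(
                    GeneModel(
                        gene_id=feat.id,
                        haplotype=hap,
                        chromosome=feat.seqid,
                        start=feat.start - 1,
                        end=feat.end,
                        strand=feat.strand,
                        cds=cds,
                        pathway_tags=tags,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: {exc}") from exc
    return genes


# ---------------------------------------------------------------------------
# BED (TEs)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, haplotype: str | None = None) -> list[TEInterval]:
    """Read TE intervals from BED (0-based half-open, no header)."""
    path = Path(path)
    label = haplotype if haplotype is not None else path.stem
    out: list[TEInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{ln}: invalid BED interval {chrom}:{start}-{end}"
                )
            te_class = parts[3] if len(parts) > 3 else "TE"
            out.append(TEInterval(label, chrom, start, end, te_class))
    return out


def write_bed(tes: Iterable[TEInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tes:
            fh.write(f"{t.chromosome}\t{t.start}\t{t.end}\t{t.te_class}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty table") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read the variant TSV (1-based positions on disk)."""
    df = _read_tsv(path, ["hap_a", "hap_b", "chromA", "posA", "type", "ref", "alt"])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantRecord(
                hap_a=str(row.hap_a),
                hap_b=str(row.hap_b),
                chromosome=str(row.chromA),
                position=int(row.posA) - 1,
                vtype=str(row.type),
                ref=str(row.ref),
                alt=str(row.alt),
            )
        )
    return out


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        (
            v.hap_a,
            v.hap_b,
            v.chromosome,
            v.position + 1,
            v.chromosome,
            v.position + 1,
            v.vtype,
            v.ref,
            v.alt,
        )
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Convert records to the internal DataFrame layout used by analyses."""
    return pd.DataFrame(
        [
            (v.hap_a, v.hap_b, v.chromosome, v.position, v.vtype, v.ref, v.alt)
            for v in variants
        ],
        columns=["hap_a", "hap_b", "chromosome", "position", "type", "ref", "alt"],
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read the long-format per-allele expression table."""
    df = _read_tsv(path, EXPRESSION_COLUMNS)
    if (df["tpm"] < 0).any():
        bad = df.loc[df["tpm"] < 0, "gene_id"].iloc[0]
        raise ValidationError(f"{path}: negative TPM for gene {bad}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_anchors(
    path: str | Path,
    known_a: set[str] | None = None,
    known_b: set[str] | None = None,
) -> pd.DataFrame:
    """Read the homolog anchor-pair table (gene_a, gene_b, similarity).

    When *known_a*/*known_b* gene-id sets are provided every referenced id is
    checked and an unknown id raises :class:`ValidationError` naming it.
    """
    df = _read_tsv(path, ANCHOR_COLUMNS)
    for col, known in (("gene_a", known_a), ("gene_b", known_b)):
        if known is not None:
            unknown = set(df[col].astype(str)) - known
            if unknown:
                raise ValidationError(
                    f"{path}: unknown gene id(s) in {col}: {sorted(unknown)[:5]}"
                )
    return df


def write_anchors(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
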