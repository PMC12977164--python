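"""Synteny-block chaining, gap-rule consolidation and gene-retention statistics.

Anchors (homologous gene pairs between a diploid reference genome A and one
polyploid haplotype genome B) are chained into maximal collinear runs, then
runs are consolidated into larger blocks whenever the separating gap is small
(< `max_gene_gap` genes or < `max_bp_gap` bp).  Gene retention is the ratio
of distinct polyploid syntenic genes to (distinct diploid syntenic genes x
ploidy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AnalysisError, ConfigurationError, UndefinedStatisticError
from .io import GeneModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorPair:
    """One homologous gene pair with gene-order ranks on both chromosomes.

    Ranks index *all annotated genes* along the chromosome (not just
    anchors), so rank gaps count intervening genes.
    """

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    similarity: float = 1.0


@dataclass
class SyntenyBlock:
    """A run of anchors collinear in both genomes."""

    anchors: list[AnchorPair]
    orientation: str = "same"  # or "inverted"

    @property
    def chrom_a(self) -> str:
        return self.anchors[0].chrom_a

    @property
    def chrom_b(self) -> str:
        return self.anchors[0].chrom_b

    @property
    def rank_range_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return (min(ranks), max(ranks))

    @property
    def rank_range_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return (min(ranks), max(ranks))

    @property
    def span_a(self) -> tuple[int, int]:
        return (min(a.start_a for a in self.anchors), max(a.end_a for a in self.anchors))

    @property
    def span_b(self) -> tuple[int, int]:
        return (min(a.start_b for a in self.anchors), max(a.end_b for a in self.anchors))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class RetentionReport:
    """Gene-retention statistic over consolidated synteny blocks."""

    polyploid_syntenic_genes: int
    diploid_syntenic_genes: int
    ploidy: int
    retention_rate: float
    per_set_rates: dict[str, float | None] = field(default_factory=dict)

    @property
    def percent(self) -> float:
        return round(100.0 * self.retention_rate, 1)


# ---------------------------------------------------------------------------
# Anchor construction and filtering
# ---------------------------------------------------------------------------

def rank_genes(genes: Sequence[GeneModel]) -> dict[str, tuple[str, int, int, int]]:
    """Map gene id -> (chromosome, rank, start, end), ranks by position."""
    out: dict[str, tuple[str, int, int, int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(gs):
            out[g.gene_id] = (chrom, rank, g.start, g.end)
    return out


def build_anchors(
    table: pd.DataFrame,
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
) -> list[AnchorPair]:
    """Join an anchor table (gene_a, gene_b, similarity) against gene models."""
    ranks_a = rank_genes(genes_a)
    ranks_b = rank_genes(genes_b)
    anchors = []
    for row in table.itertuples(index=False):
        ga, gb = str(row.gene_a), str(row.gene_b)
        if ga not in ranks_a:
            raise AnalysisError(f"anchor references unknown gene id {ga!r} in genome A")
        if gb not in ranks_b:
            raise AnalysisError(f"anchor references unknown gene id {gb!r} in genome B")
        ca, ra, sa, ea = ranks_a[ga]
        cb, rb, sb, eb = ranks_b[gb]
        anchors.append(
            AnchorPair(ga, gb, ca, cb, ra, rb, sa, ea, sb, eb,
                       float(getattr(row, "similarity", 1.0)))
        )
    return anchors


def best_hit_filter(anchors: Iterable[AnchorPair]) -> list[AnchorPair]:
    """Reduce anchors to one-to-one pairs by highest similarity.

    Ties are broken by smallest (gene_a, gene_b) lexicographic order so the
    result is deterministic.
    """
    ordered = sorted(anchors, key=lambda a: (-a.similarity, a.gene_a, a.gene_b))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out = []
    for a in ordered:
        if a.gene_a in used_a or a.gene_b in used_b:
            continue
        used_a.add(a.gene_a)
        used_b.add(a.gene_b)
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def chain_anchors(anchors: Sequence[AnchorPair]) -> list[SyntenyBlock]:
    """Chain anchors into maximal runs consecutive in rank on both genomes.

    Anchors must be one-to-one (use :func:`best_hit_filter` first); a gene
    appearing in more than one anchor raises :class:`AnalysisError`.  Within a
    run, genome-A ranks increase by exactly 1 per step and genome-B ranks move
    by exactly +1 (``same`` orientation) or -1 (``inverted``).  Every anchor
    lands in exactly one run; single anchors form size-1 blocks of ``same``
    orientation by convention.
    """
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for a in anchors:
        if a.gene_a in seen_a or a.gene_b in seen_b:
            raise AnalysisError(
                f"anchor gene used more than once ({a.gene_a}/{a.gene_b}); "
                "pre-filter to best one-to-one pairs"
            )
        seen_a.add(a.gene_a)
        seen_b.add(a.gene_b)

    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda a: a.rank_a)
        run: list[AnchorPair] = [group[0]]
        direction = 0  # 0 undecided, +1 same, -1 inverted
        for nxt in group[1:]:
            prev = run[-1]
            step_b = nxt.rank_b - prev.rank_b
            contiguous = nxt.rank_a == prev.rank_a + 1 and abs(step_b) == 1
            if contiguous and (direction == 0 or step_b == direction):
                run.append(nxt)
                direction = step_b
            else:
                blocks.append(_close_run(run, direction))
                run = [nxt]
                direction = 0
        blocks.append(_close_run(run, direction))
    return blocks


def _close_run(run: list[AnchorPair], direction: int) -> SyntenyBlock:
    return SyntenyBlock(anchors=list(run), orientation="inverted" if direction < 0 else "same")


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def _gap_between(lo: tuple[int, int], hi: tuple[int, int]) -> int:
    """Genes strictly between two disjoint rank ranges."""
    return hi[0] - lo[1] - 1


@dataclass(frozen=True)
class _BlockSummary:
    key: tuple[str, str, str]
    ra: tuple[int, int]
    rb: tuple[int, int]
    sa: tuple[int, int]
    sb: tuple[int, int]
    orientation: str


def _summarize(b: SyntenyBlock) -> _BlockSummary:
    return _BlockSummary(
        key=(b.chrom_a, b.chrom_b, b.orientation),
        ra=b.rank_range_a,
        rb=b.rank_range_b,
        sa=b.span_a,
        sb=b.span_b,
        orientation=b.orientation,
    )


def _mergeable_s(
    s1: _BlockSummary,
    s2: _BlockSummary,
    max_gene_gap: int,
    max_bp_gap: int,
    mode: str,
) -> bool:
    if s1.key != s2.key:
        return False
    left, right = (s1, s2) if s1.ra[0] <= s2.ra[0] else (s2, s1)
    if right.ra[0] <= left.ra[1]:
        return False  # overlapping in genome A
    if s1.orientation == "same":
        if right.rb[0] <= left.rb[1]:
            return False
        gap_genes_b = _gap_between(left.rb, right.rb)
        bp_gap_b = max(0, right.sb[0] - left.sb[1])
    else:
        if left.rb[0] <= right.rb[1]:
            return False
        gap_genes_b = _gap_between(right.rb, left.rb)
        bp_gap_b = max(0, left.sb[0] - right.sb[1])
    gap_genes_a = _gap_between(left.ra, right.ra)
    bp_gap_a = max(0, right.sa[0] - left.sa[1])

    ok_a = gap_genes_a < max_gene_gap or bp_gap_a < max_bp_gap
    ok_b = gap_genes_b < max_gene_gap or bp_gap_b < max_bp_gap
    return (ok_a and ok_b) if mode == "both" else (ok_a or ok_b)


def mergeable(
    b1: SyntenyBlock,
    b2: SyntenyBlock,
    max_gene_gap: int,
    max_bp_gap: int,
    mode: str = "both",
) -> bool:
    """Pairwise merge predicate for two blocks.

    Blocks qualify only on the same chromosome pair with the same
    orientation, rank-disjoint in both genomes, and ordered consistently with
    the orientation.  The gap condition ``gene_gap < max_gene_gap OR
    bp_gap < max_bp_gap`` (strict) must then hold in both genomes
    (``mode="both"``, the default) or in at least one (``mode="either"``).
    """
    return _mergeable_s(_summarize(b1), _summarize(b2), max_gene_gap, max_bp_gap, mode)


def _merge_round(
    blocks: list[SyntenyBlock], max_gene_gap: int, max_bp_gap: int, mode: str
) -> tuple[list[SyntenyBlock], bool]:
    """One transitive-closure round over the pairwise predicate (union-find)."""
    n = len(blocks)
    parent = list(range(n))
    summaries = [_summarize(b) for b in blocks]

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    changed = False
    for i in range(n):
        for j in range(i + 1, n):
            if _mergeable_s(summaries[i], summaries[j], max_gene_gap, max_bp_gap, mode):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
                    changed = True
    if not changed:
        return blocks, False
    components: dict[int, list[SyntenyBlock]] = {}
    for i, b in enumerate(blocks):
        components.setdefault(find(i), []).append(b)
    merged = []
    for members in components.values():
        anchors = sorted(
            (a for b in members for a in b.anchors), key=lambda a: a.rank_a
        )
        orientation = members[0].orientation
        if len(members) > 1 and all(b.n_anchors == 1 for b in members):
            # size-1 runs carry no orientation; infer from merged order
            rb = [a.rank_b for a in anchors]
            orientation = "inverted" if rb[0] > rb[-1] else "same"
        merged.append(SyntenyBlock(anchors=anchors, orientation=orientation))
    return merged, True


def consolidate_blocks(
    blocks: Sequence[SyntenyBlock],
    max_gene_gap: int = 50,
    max_bp_gap: int = 300_000,
    mode: str = "both",
) -> list[SyntenyBlock]:
    """Consolidate collinear runs separated by small gaps.

    Merging is the transitive closure of :func:`mergeable`, iterated to a
    fixpoint so the operation is idempotent.  Output blocks are sorted by
    genome-A position.
    """
    if max_gene_gap < 0 or max_bp_gap < 0:
        raise ConfigurationError("gap thresholds must be non-negative")
    if mode not in ("both", "either"):
        raise ConfigurationError(f"mode must be both|either, got {mode!r}")
    out = list(blocks)
    changed = True
    while changed:
        out, changed = _merge_round(out, max_gene_gap, max_bp_gap, mode)
    out.sort(key=lambda b: (b.chrom_a, b.span_a[0], b.chrom_b, b.span_b[0]))
    return out


# ---------------------------------------------------------------------------
# Retention statistics
# ---------------------------------------------------------------------------

def retention_rate(
    polyploid_syntenic: int, diploid_syntenic: int, ploidy: int
) -> float:
    """``polyploid_syntenic / (diploid_syntenic * ploidy)``, exact."""
    if ploidy < 1:
        raise ConfigurationError(f"ploidy must be >= 1, got {ploidy}")
    if diploid_syntenic == 0:
        raise UndefinedStatisticError("retention undefined: zero diploid syntenic genes")
    if polyploid_syntenic < 0 or diploid_syntenic < 0:
        raise AnalysisError("gene counts must be non-negative")
    return polyploid_syntenic / (diploid_syntenic * ploidy)


def pathway_retention(
    blocks: Sequence[SyntenyBlock],
    gene_sets: Mapping[str, set[str]],
    ploidy: int,
) -> RetentionReport:
    """Retention rates overall and per tagged gene set.

    Gene sets are defined on diploid (genome A) gene ids; the numerator for a
    set counts the distinct polyploid partners of its syntenic members.  A
    set with no syntenic member yields an undefined (``None``) rate with a
    warning, never zero.
    """
    pairs = {(a.gene_a, a.gene_b) for b in blocks for a in b.anchors}
    dip = {ga for ga, _ in pairs}
    poly = {gb for _, gb in pairs}
    rate = retention_rate(len(poly), len(dip), ploidy)
    per_set: dict[str, float | None] = {}
    for label, ids in gene_sets.items():
        dip_set = dip & ids
        if not dip_set:
            log.warning("gene set %r has no syntenic member; rate undefined", label)
            per_set[label] = None
            continue
        poly_set = {gb for ga, gb in pairs if ga in dip_set}
        per_set[label] = retention_rate(len(poly_set), len(dip_set), ploidy)
    return RetentionReport(
        polyploid_syntenic_genes=len(poly),
        diploid_syntenic_genes=len(dip),
        ploidy=ploidy,
        retention_rate=rate,
        per_set_rates=per_set,
    )


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """Flat TSV-ready summary of consolidated blocks."""
    rows = []
    for i, b in enumerate(blocks):
        sa, sb = b.span_a, b.span_b
        rows.append(
            (i, b.chrom_a, sa[0], sa[1], b.chrom_b, sb[0], sb[1], b.orientation, b.n_anchors)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "chrom_a", "start_a", "end_a",
            "chrom_b", "start_b", "end_b", "orientation", "n_anchors",
        ],
    )
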