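"""Pairwise haplotype variant densities, divergence matrices, and
distance-based lineage pairing (UPGMA).

Windows are 0-based half-open ``[i*step, i*step + window)``; the last partial
window is dropped, so a chromosome of length ``L >= window`` yields
``floor((L - window)/step) + 1`` windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .io import VariantRecord

log = logging.getLogger(__name__)


@dataclass
class WindowDensityTrack:
    """Per-window feature counts along one chromosome for one haplotype pair."""

    pair: tuple[str, str]
    chromosome: str
    window_size: int
    step: int
    values: np.ndarray

    @property
    def per_bp(self) -> np.ndarray:
        return self.values / float(self.window_size)


def n_windows(length: int, window_size: int, step: int) -> int:
    """Closed-form window count for the half-open drop-tail scheme."""
    if window_size > length:
        return 0
    return (length - window_size) // step + 1


def window_density(
    positions: Sequence[int] | np.ndarray,
    chrom_length: int,
    window_size: int,
    step: int,
    pair: tuple[str, str] = ("", ""),
    chromosome: str = "",
) -> WindowDensityTrack:
    """Count features per sliding window.

    Each window ``[i*step, i*step + window_size)`` counts the features whose
    position falls inside it; the last partial window is dropped.
    """
    if window_size <= 0 or step <= 0:
        raise AnalysisError("window_size and step must be > 0")
    if window_size > chrom_length:
        raise AnalysisError(
            f"window_size {window_size} exceeds chromosome length {chrom_length}"
        )
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    nw = n_windows(chrom_length, window_size, step)
    starts = np.arange(nw, dtype=np.int64) * step
    counts = np.searchsorted(pos, starts + window_size) - np.searchsorted(pos, starts)
    return WindowDensityTrack(
        pair=pair,
        chromosome=chromosome,
        window_size=window_size,
        step=step,
        values=counts.astype(np.int64),
    )


@dataclass
class DivergenceMatrix:
    """Symmetric SNP/InDel totals between haplotypes."""

    labels: tuple[str, ...]
    snp_counts: np.ndarray
    indel_counts: np.ndarray

    def total(self) -> np.ndarray:
        return self.snp_counts + self.indel_counts

    def to_frame(self, kind: str = "snp") -> pd.DataFrame:
        mat = {"snp": self.snp_counts, "indel": self.indel_counts, "total": self.total()}[kind]
        return pd.DataFrame(mat, index=list(self.labels), columns=list(self.labels))


def divergence_matrix(
    variants: pd.DataFrame | Iterable[VariantRecord],
    haplotypes: Sequence[str],
) -> DivergenceMatrix:
    """Totals of SNPs and InDels per haplotype pair.

    InDels count as single events regardless of length.  Unknown haplotype
    labels in the variant table raise :class:`AnalysisError`.
    """
    labels = tuple(haplotypes)
    index = {h: i for i, h in enumerate(labels)}
    snp = np.zeros((len(labels), len(labels)), dtype=np.int64)
    indel = np.zeros_like(snp)
    if not isinstance(variants, pd.DataFrame):
        from .io import variants_to_frame

        variants = variants_to_frame(list(variants))
    if len(variants):
        grouped = variants.groupby(["hap_a", "hap_b", "type"]).size()
        for (ha, hb, vtype), count in grouped.items():
            if ha not in index or hb not in index:
                raise AnalysisError(f"unknown haplotype label in variants: {ha!r}/{hb!r}")
            i, j = index[ha], index[hb]
            target = snp if vtype == "SNP" else indel
            target[i, j] += count
            target[j, i] += count
    return DivergenceMatrix(labels=labels, snp_counts=snp, indel_counts=indel)


# ---------------------------------------------------------------------------
# UPGMA lineage clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    partition: frozenset[frozenset[str]]
    newick: str
    merges: list[tuple[frozenset[str], frozenset[str], float]]
    warnings: list[str] = field(default_factory=list)


def cluster_haplotypes(
    matrix: DivergenceMatrix,
    method: str = "UPGMA",
    normalize_by: dict[tuple[str, str], float] | None = None,
) -> ClusterResult:
    """UPGMA clustering of haplotypes on variant-count distances.

    Distance between two haplotypes is SNP count + InDel count, optionally
    normalized by an aligned length per pair.  Ties among merge candidates
    are broken by lexicographic label order (deterministic) and logged.  For
    four leaves the two children of the root define the lineage partition.
    """
    if method.upper() != "UPGMA":
        raise ConfigurationError(f"unsupported clustering method {method!r}")
    labels = matrix.labels
    if len(labels) < 3:
        raise AnalysisError("clustering needs >= 3 haplotypes")
    total = matrix.total().astype(float)
    if normalize_by:
        for (a, b), length in normalize_by.items():
            i, j = labels.index(a), labels.index(b)
            total[i, j] /= length
            total[j, i] /= length
    if not np.all(np.isfinite(total)):
        raise AnalysisError("distances must be finite")

    # Cluster state: distances on frozensets, UPGMA average linkage.
    clusters: list[frozenset[str]] = [frozenset({l}) for l in labels]
    sizes = {c: 1 for c in clusters}
    heights = {c: 0.0 for c in clusters}
    newick_of = {c: next(iter(c)) for c in clusters}
    dist: dict[frozenset[str], dict[frozenset[str], float]] = {
        c: {} for c in clusters
    }
    for i, a in enumerate(clusters):
        for j, b in enumerate(clusters):
            if i < j:
                d = total[i, j]
                dist[a][b] = d
                dist[b][a] = d

    warnings: list[str] = []
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []

    def sort_key(c: frozenset[str]) -> tuple[str, ...]:
        return tuple(sorted(c))

    while len(clusters) > 1:
        candidates = [
            (dist[a][b], sort_key(a), sort_key(b), a, b)
            for i, a in enumerate(clusters)
            for b in clusters[i + 1 :]
        ]
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        best_d = candidates[0][0]
        if len(candidates) > 1 and candidates[1][0] == best_d:
            msg = f"tie at distance {best_d}; broken by lexicographic label order"
            warnings.append(msg)
            log.warning(msg)
        _, _, _, a, b = candidates[0]
        merged = a | b
        h = best_d / 2.0
        newick_of[merged] = (
            f"({newick_of[a]}:{h - heights[a]:.6g},{newick_of[b]}:{h - heights[b]:.6g})"
        )
        heights[merged] = h
        sizes[merged] = sizes[a] + sizes[b]
        merges.append((a, b, best_d))
        dist[merged] = {}
        for c in clusters:
            if c is a or c is b:
                continue
            d = (dist[a][c] * sizes[a] + dist[b][c] * sizes[b]) / sizes[merged]
            dist[merged][c] = d
            dist[c][merged] = d
        clusters = [c for c in clusters if c is not a and c is not b] + [merged]

    root_children = merges[-1][:2]
    partition = frozenset(root_children)
    newick = newick_of[clusters[0]] + ";"
    return ClusterResult(partition=partition, newick=newick, merges=merges, warnings=warnings)
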