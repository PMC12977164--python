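"""TE-density profiles over gene flanks.

For each gene, the 5-kb regions upstream (5' of the gene's strand) and
downstream are tiled with 100-bp windows at a 10-bp step; per window the
TE-covered base fraction is computed against merged (union) TE intervals.
Window vectors are indexed by distance from the gene edge: index 0 is the
window adjacent to the gene, the last index is the farthest.  Windows
truncated by a chromosome end carry reduced effective lengths and averaging
weights windows by effective length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError
from .io import GeneModel, TEInterval

log = logging.getLogger(__name__)


@dataclass
class TEProfile:
    """Windowed TE-coverage vectors over the two flanks of a gene (set)."""

    label: str
    flank: int
    window: int
    step: int
    upstream: np.ndarray          # TE fraction per window, nan if no effective bases
    downstream: np.ndarray
    upstream_covered: np.ndarray  # summed TE-covered bases per window
    downstream_covered: np.ndarray
    upstream_effective: np.ndarray  # summed effective (in-chromosome) bases
    downstream_effective: np.ndarray
    n_genes: int = 1

    @property
    def n_windows(self) -> int:
        return (self.flank - self.window) // self.step + 1

    def odds(self, side: str = "upstream") -> np.ndarray:
        """TE : non-TE odds per window; inf where the window is all TE."""
        cov = getattr(self, f"{side}_covered").astype(float)
        eff = getattr(self, f"{side}_effective").astype(float)
        non_te = eff - cov
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(non_te > 0, cov / non_te, np.where(cov > 0, np.inf, np.nan))

    def geometry(self) -> tuple[int, int, int]:
        return (self.flank, self.window, self.step)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _coverage_mask(
    merged: Sequence[tuple[int, int]], region_start: int, region_end: int
) -> np.ndarray:
    mask = np.zeros(region_end - region_start, dtype=bool)
    for s, e in merged:
        lo = max(s, region_start)
        hi = min(e, region_end)
        if lo < hi:
            mask[lo - region_start : hi - region_start] = True
    return mask


def _window_sums(values: np.ndarray, window: int, step: int) -> np.ndarray:
    csum = np.concatenate(([0], np.cumsum(values)))
    n = (values.size - window) // step + 1
    starts = np.arange(n) * step
    return csum[starts + window] - csum[starts]


def flank_te_profile(
    gene: GeneModel,
    tes: Sequence[TEInterval],
    chrom_length: int,
    flank: int = 5000,
    window: int = 100,
    step: int = 10,
) -> TEProfile:
    """TE-fraction profile of one gene's upstream/downstream flanks.

    Overlapping TE annotations are merged by union before coverage, so no
    base is double counted.  Flanks are oriented by strand (upstream = 5'
    side) and truncated at chromosome ends via per-window effective lengths.
    """
    if window > flank:
        raise AnalysisError(f"window {window} exceeds flank {flank}")
    if window <= 0 or step <= 0:
        raise AnalysisError("window and step must be > 0")
    if gene.start < 0 or gene.end > chrom_length:
        raise AnalysisError(f"gene {gene.gene_id} outside chromosome bounds")

    merged = merge_intervals(
        [(t.start, t.end) for t in tes if t.chromosome == gene.chromosome]
    )

    def flank_arrays(region_start: int, region_end: int, reverse: bool):
        """Coverage and validity arrays oriented away from the gene."""
        cov = np.zeros(flank, dtype=np.int64)
        valid = np.zeros(flank, dtype=np.int64)
        lo = max(region_start, 0)
        hi = min(region_end, chrom_length)
        if lo < hi:
            mask = _coverage_mask(merged, lo, hi)
            seg_cov = mask.astype(np.int64)
            seg_valid = np.ones(hi - lo, dtype=np.int64)
            off = lo - region_start
            cov[off : off + (hi - lo)] = seg_cov
            valid[off : off + (hi - lo)] = seg_valid
        if reverse:
            cov = cov[::-1]
            valid = valid[::-1]
        return cov, valid

    # 5' flank lies before the start on '+' genes, after the end on '-' genes.
    if gene.strand == "+":
        up_cov, up_valid = flank_arrays(gene.start - flank, gene.start, reverse=True)
        dn_cov, dn_valid = flank_arrays(gene.end, gene.end + flank, reverse=False)
    else:
        up_cov, up_valid = flank_arrays(gene.end, gene.end + flank, reverse=False)
        dn_cov, dn_valid = flank_arrays(gene.start - flank, gene.start, reverse=True)

    up_c = _window_sums(up_cov, window, step)
    up_e = _window_sums(up_valid, window, step)
    dn_c = _window_sums(dn_cov, window, step)
    dn_e = _window_sums(dn_valid, window, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        up_f = np.where(up_e > 0, up_c / np.maximum(up_e, 1), np.nan)
        dn_f = np.where(dn_e > 0, dn_c / np.maximum(dn_e, 1), np.nan)

    return TEProfile(
        label=gene.gene_id,
        flank=flank,
        window=window,
        step=step,
        upstream=up_f,
        downstream=dn_f,
        upstream_covered=up_c,
        downstream_covered=dn_c,
        upstream_effective=up_e,
        downstream_effective=dn_e,
        n_genes=1,
    )


def average_profiles(profiles: Sequence[TEProfile], label: str = "mean") -> TEProfile:
    """Mean profile of a gene set, weighting windows by effective length."""
    if not profiles:
        raise AnalysisError("need >= 1 profile to average")
    geom = profiles[0].geometry()
    if any(p.geometry() != geom for p in profiles):
        raise AnalysisError("profiles have mixed window geometries")
    up_c = np.sum([p.upstream_covered for p in profiles], axis=0)
    up_e = np.sum([p.upstream_effective for p in profiles], axis=0)
    dn_c = np.sum([p.downstream_covered for p in profiles], axis=0)
    dn_e = np.sum([p.downstream_effective for p in profiles], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        up_f = np.where(up_e > 0, up_c / np.maximum(up_e, 1), np.nan)
        dn_f = np.where(dn_e > 0, dn_c / np.maximum(dn_e, 1), np.nan)
    flank, window, step = geom
    return TEProfile(
        label=label,
        flank=flank,
        window=window,
        step=step,
        upstream=up_f,
        downstream=dn_f,
        upstream_covered=up_c,
        downstream_covered=dn_c,
        upstream_effective=up_e,
        downstream_effective=dn_e,
        n_genes=sum(p.n_genes for p in profiles),
    )


def profile_frame(profile: TEProfile) -> "pd.DataFrame":
    """TSV-ready long table: (side, offset_bp, mean_fraction, n_genes)."""
    import pandas as pd

    rows = []
    for side in ("upstream", "downstream"):
        frac = getattr(profile, side)
        for i, f in enumerate(frac):
            rows.append((side, i * profile.step, float(f), profile.n_genes))
    return pd.DataFrame(rows, columns=["side", "offset_bp", "mean_fraction", "n_genes"])
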