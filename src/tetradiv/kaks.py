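"""Nei–Gojobori (1986) Ka/Ks estimation, Ks distributions, WGD peak detection
and molecular dating via T = Ks / (2 mu).

The NG86 method counts synonymous/nonsynonymous *sites* by enumerating all
nine single-nucleotide mutants of each codon, and synonymous/nonsynonymous
*differences* by averaging step classifications over all orderings of the
substitutions separating two codons.  Proportions are Jukes–Cantor corrected:
``K = -(3/4) ln(1 - (4/3) p)``, undefined for ``p >= 3/4``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError, ConfigurationError

log = logging.getLogger(__name__)

_BASES = "ACGT"


def _standard_code() -> tuple[dict[str, str], frozenset[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    return dict(table.forward_table), frozenset(table.stop_codons)


_AA, STOP_CODONS = _standard_code()
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_AA))


def is_sense_codon(codon: str) -> bool:
    return codon in _AA


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous and nonsynonymous site counts of one codon.

    Each of the nine single-nucleotide mutants is classified against the
    standard genetic code; mutants producing a stop codon count as
    nonsynonymous.  Returns ``(syn_sites, nonsyn_sites)`` with
    ``syn_sites + nonsyn_sites == 3`` exactly.
    """
    if codon not in _AA:
        raise AnalysisError(f"{codon!r} is not a sense codon")
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut in _AA and _AA[mut] == _AA[codon]:
                syn += 1
    s = syn / 3.0
    return (s, 3.0 - s)


@lru_cache(maxsize=None)
def ng86_differences(
    codon_a: str, codon_b: str, stop_paths: str = "exclude"
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    For codons differing at ``k`` positions, every one of the ``k!`` orderings
    of the substitutions is a mutational pathway.  With
    ``stop_paths="exclude"`` (the dominant convention) pathways passing
    through a stop codon are dropped from the average when at least one
    stop-free pathway exists; otherwise — and always with
    ``stop_paths="include"`` — all pathways contribute, with steps into or
    out of a stop codon counted as nonsynonymous.
    """
    for c in (codon_a, codon_b):
        if c not in _AA:
            raise AnalysisError(f"{c!r} is not a sense codon")
    if stop_paths not in ("exclude", "include"):
        raise ConfigurationError(f"stop_paths must be exclude|include, got {stop_paths!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                nd += 1.0
                if nxt in STOP_CODONS and nxt != codon_b:
                    blocked = True
            elif _AA[cur] == _AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, blocked

    paths = [walk(order) for order in permutations(diff)]
    open_paths = [p for p in paths if not p[2]]
    use = open_paths if (stop_paths == "exclude" and open_paths) else paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return (sd, nd)


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; ``None`` outside its domain (p >= 3/4)."""
    if p < 0:
        raise AnalysisError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class KaKsResult:
    """NG86 estimates for one aligned coding-sequence pair."""

    pair_id: str = ""
    n_codons: int = 0
    s_sites: float = 0.0
    n_sites: float = 0.0
    sd: float = 0.0
    nd: float = 0.0
    ps: float = 0.0
    pn: float = 0.0
    ks: float | None = None
    ka: float | None = None
    ratio: float | None = None
    flags: list[str] = field(default_factory=list)


GAPLIKE = frozenset("-N")


def _iter_codon_pairs(seq_a: str, seq_b: str):
    for i in range(0, len(seq_a), 3):
        yield seq_a[i : i + 3], seq_b[i : i + 3]


def kaks_pair(
    seq_a: str,
    seq_b: str,
    pair_id: str = "",
    min_codons: int = 10,
    stop_paths: str = "exclude",
) -> KaKsResult:
    """Estimate Ka/Ks for one codon-aligned pair by the NG86 method.

    Codons containing gaps, ambiguous bases, or a stop in either sequence are
    skipped pairwise.  Site counts are averaged over the two sequences;
    ``pS = Sd/S`` and ``pN = Nd/N`` are Jukes–Cantor corrected into Ks/Ka.
    Values outside the correction domain are left undefined (``None``) with a
    reason recorded in ``flags`` — never fabricated.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise AnalysisError("aligned sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise AnalysisError(f"alignment length {len(seq_a)} not a multiple of 3")

    res = KaKsResult(pair_id=pair_id)
    sa = na = sb = nb = 0.0
    for ca, cb in _iter_codon_pairs(seq_a, seq_b):
        if any(ch in GAPLIKE for ch in ca + cb) or ca not in _AA or cb not in _AA:
            continue
        s1, n1 = ng86_sites(ca)
        s2, n2 = ng86_sites(cb)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        dsd, dnd = ng86_differences(ca, cb, stop_paths)
        res.sd += dsd
        res.nd += dnd
        res.n_codons += 1

    if res.n_codons < min_codons:
        raise AnalysisError(
            f"only {res.n_codons} comparable codons (< {min_codons}) in pair {pair_id!r}"
        )

    res.s_sites = (sa + sb) / 2.0
    res.n_sites = (na + nb) / 2.0
    if res.s_sites > 0:
        res.ps = res.sd / res.s_sites
        res.ks = jukes_cantor(res.ps)
        if res.ks is None:
            res.flags.append("Ks undefined: JC correction domain (pS >= 3/4)")
    else:
        res.flags.append("Ks undefined: zero synonymous sites")
    if res.n_sites > 0:
        res.pn = res.nd / res.n_sites
        res.ka = jukes_cantor(res.pn)
        if res.ka is None:
            res.flags.append("Ka undefined: JC correction domain (pN >= 3/4)")
    else:
        res.flags.append("Ka undefined: zero nonsynonymous sites")

    if res.ka is not None and res.ks is not None:
        if res.ks > 0:
            res.ratio = res.ka / res.ks
        else:
            res.flags.append("ratio undefined: Ks = 0")
    return res


# ---------------------------------------------------------------------------
# Ks distribution and WGD peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KsPeak:
    location: float
    density: float
    prominence: float


@dataclass
class KsDistribution:
    """Pooled finite Ks values with a saturation cutoff for peak detection."""

    values: list[float]
    cutoff: float = 3.0
    n_undefined: int = 0
    peaks: list[KsPeak] = field(default_factory=list)

    @property
    def peak_values(self) -> list[float]:
        return [v for v in self.values if v <= self.cutoff]


def ks_distribution(
    results: Iterable[KaKsResult | float], cutoff: float = 3.0
) -> KsDistribution:
    """Pool defined, finite Ks values from per-pair results.

    Values above *cutoff* are retained in the record but excluded from peak
    detection (saturation).  Raises if no pair has a defined Ks.
    """
    values: list[float] = []
    n_undef = 0
    for r in results:
        ks = r.ks if isinstance(r, KaKsResult) else float(r)
        if ks is None or not math.isfinite(ks):
            n_undef += 1
        else:
            values.append(float(ks))
    if not values:
        raise AnalysisError("no defined Ks values in input")
    return KsDistribution(values=values, cutoff=cutoff, n_undefined=n_undef)


def detect_ks_peaks(
    dist: KsDistribution,
    bandwidth: str | float = "silverman",
    min_prominence: float = 0.05,
    grid_step: float = 0.005,
    min_values: int = 30,
) -> list[KsPeak]:
    """Detect WGD peaks as local maxima of a Gaussian KDE of the Ks values.

    The density is evaluated on a fixed grid over ``[0, cutoff]`` and peaks
    must reach a prominence of ``min_prominence`` times the maximum density.
    Returns peaks sorted by location; also stored on ``dist.peaks``.
    """
    from scipy.signal import find_peaks
    from scipy.stats import gaussian_kde

    if isinstance(bandwidth, (int, float)) and bandwidth <= 0:
        raise AnalysisError(f"bandwidth must be > 0, got {bandwidth}")
    vals = np.asarray(dist.peak_values, dtype=float)
    if vals.size < min_values:
        raise AnalysisError(
            f"peak detection needs >= {min_values} Ks values, got {vals.size}"
        )
    if np.ptp(vals) == 0.0:
        # Degenerate distribution: all mass at one value.
        peak = KsPeak(location=float(vals[0]), density=math.inf, prominence=math.inf)
        dist.peaks = [peak]
        return dist.peaks

    kde = gaussian_kde(vals, bw_method=bandwidth)
    # Pad the grid below zero so peaks near the origin keep their full
    # prominence; only peaks at locations >= 0 are reported.
    bw = float(kde.factor * np.std(vals))
    pad = grid_step * math.ceil(max(0.1, 4.0 * bw) / grid_step)
    grid = np.arange(-pad, dist.cutoff + grid_step / 2.0, grid_step)
    density = kde(grid)
    # Prominence is measured within a window of a few bandwidths so that a
    # broad plateau (e.g. near-uniform Ks values) does not register as a peak
    # merely by towering over the far-away tails.
    wlen = max(31, int(math.ceil(6.0 * bw / grid_step)))
    idx, props = find_peaks(
        density, prominence=min_prominence * density.max(), wlen=wlen
    )
    peaks = [
        KsPeak(
            location=float(grid[i]),
            density=float(density[i]),
            prominence=float(p),
        )
        for i, p in zip(idx, props["prominences"])
        if grid[i] >= 0.0
    ]
    peaks.sort(key=lambda p: p.location)
    if not peaks:
        log.warning("no Ks peak passes prominence threshold %.3g", min_prominence)
    dist.peaks = peaks
    return peaks


@dataclass(frozen=True)
class DatingParams:
    """Parameters of the dating equation Ks = 2 * mu * T."""

    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ConfigurationError(f"mu must be > 0, got {self.mu}")


def date_event(ks: float, params: DatingParams) -> float:
    """Divergence time in years: ``T = Ks / (2 mu)``."""
    if ks < 0:
        raise AnalysisError(f"Ks must be >= 0, got {ks}")
    return ks / (2.0 * params.mu)
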