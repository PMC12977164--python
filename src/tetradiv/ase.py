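"""Allele-specific expression: TPM normalization, the four-category
threshold classifier, cross-tissue intersections, Ka/Ks-by-class comparison,
and a minimal IUPAC motif scanner.

Classification rules (thresholds configurable, defaults TPM > 2 and 2-fold):

* both alleles <= threshold            -> ``not_expressed``
* both > threshold, fold < 2           -> ``biallelic``
* both > threshold, fold >= 2          -> ``higher_one_allele``
* exactly one allele > threshold       -> ``hap1_dominant`` / ``hap3_dominant``

Fold is max/min of the two TPMs; a fold of exactly 2 counts as imbalanced so
the two printed rules partition the space.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError

log = logging.getLogger(__name__)

ASE_CLASSES = ("biallelic", "higher_one_allele", "hap1_dominant", "hap3_dominant")
NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class ASECall:
    pair_id: str
    tissue: str
    ase_class: str
    fold: float | None


def tpm_from_counts(
    counts: Sequence[float] | np.ndarray, lengths: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Transcripts-per-million from read counts and effective lengths.

    ``TPM_i = 1e6 * (counts_i / lengths_i) / sum_j(counts_j / lengths_j)``.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise AnalysisError("counts and lengths must have equal shape")
    if np.any(lengths <= 0):
        raise AnalysisError("effective lengths must be > 0")
    if np.any(counts < 0):
        raise AnalysisError("counts must be >= 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise AnalysisError("all counts are zero; TPM undefined")
    return 1e6 * rate / total


def classify_ase(
    hap1_tpm: float,
    hap3_tpm: float,
    expr_threshold: float = 2.0,
    fold_threshold: float = 2.0,
) -> tuple[str, float | None]:
    """Classify one TPM pair; returns ``(class, fold)``.

    Fold (max/min) is defined only when both TPMs are positive.
    """
    if hap1_tpm < 0 or hap3_tpm < 0:
        raise AnalysisError("TPM values must be >= 0")
    on1 = hap1_tpm > expr_threshold
    on3 = hap3_tpm > expr_threshold
    fold = None
    if hap1_tpm > 0 and hap3_tpm > 0:
        fold = max(hap1_tpm, hap3_tpm) / min(hap1_tpm, hap3_tpm)
    if not on1 and not on3:
        return NOT_EXPRESSED, fold
    if on1 and on3:
        return ("biallelic" if fold < fold_threshold else "higher_one_allele"), fold
    return ("hap1_dominant" if on1 else "hap3_dominant"), fold


def classify_matrix(
    table: pd.DataFrame,
    expr_threshold: float = 2.0,
    fold_threshold: float = 2.0,
    hap_labels: tuple[str, str] | None = None,
) -> tuple[list[ASECall], pd.DataFrame]:
    """Classify every (gene, tissue) row of a long-format expression table.

    *table* must have columns (gene_id, haplotype, tissue, tpm) covering
    exactly two haplotypes per gene/tissue.  Returns the per-row calls and a
    per-tissue summary of class fractions over *expressed* rows (class !=
    ``not_expressed``), with denominators reported.
    """
    if table.empty:
        raise AnalysisError("empty expression table")
    wide = table.pivot_table(
        index=["gene_id", "tissue"], columns="haplotype", values="tpm"
    )
    haps = hap_labels if hap_labels is not None else tuple(sorted(wide.columns))
    if len(haps) != 2 or any(h not in wide.columns for h in haps):
        raise AnalysisError(f"expected exactly two haplotypes, got {tuple(wide.columns)}")
    calls: list[ASECall] = []
    for (gene_id, tissue), row in wide.sort_index().iterrows():
        cls, fold = classify_ase(
            float(row[haps[0]]), float(row[haps[1]]), expr_threshold, fold_threshold
        )
        calls.append(ASECall(pair_id=gene_id, tissue=tissue, ase_class=cls, fold=fold))

    rows = []
    by_tissue: dict[str, list[ASECall]] = {}
    for c in calls:
        by_tissue.setdefault(c.tissue, []).append(c)
    for tissue in sorted(by_tissue):
        group = by_tissue[tissue]
        expressed = [c for c in group if c.ase_class != NOT_EXPRESSED]
        n = len(expressed)
        if n == 0:
            log.warning("tissue %r: no expressed gene; fractions undefined", tissue)
        for cls in ASE_CLASSES:
            count = sum(1 for c in expressed if c.ase_class == cls)
            rows.append((tissue, cls, count, n, count / n if n else np.nan))
        rows.append(
            (tissue, NOT_EXPRESSED, len(group) - n, n, np.nan)
        )
    summary = pd.DataFrame(
        rows, columns=["tissue", "ase_class", "count", "n_expressed", "fraction"]
    )
    return calls, summary


def intersect_ase_sets(
    calls_by_tissue: Mapping[str, Iterable[ASECall]],
    classes_of_interest: set[str],
) -> dict[frozenset[str], int]:
    """Exclusive Venn-region counts of gene ids across tissues.

    Gene ids are restricted to calls whose class is in *classes_of_interest*;
    each id in the union is assigned to exactly one region (the set of
    tissues containing it), so region counts sum to the union size.
    """
    tissues = sorted(calls_by_tissue)
    if len(tissues) < 2:
        raise AnalysisError("intersection needs >= 2 tissues")
    sets = {
        t: {c.pair_id for c in calls_by_tissue[t] if c.ase_class in classes_of_interest}
        for t in tissues
    }
    regions: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for k in range(1, len(tissues) + 1)
        for combo in combinations(tissues, k)
    }
    union = set().union(*sets.values())
    for gid in union:
        signature = frozenset(t for t in tissues if gid in sets[t])
        regions[signature] += 1
    return regions


def compare_kaks_by_class(
    kaks_by_pair: Mapping[str, float | None],
    calls: Iterable[ASECall],
    class_a: str,
    class_b: str,
) -> dict:
    """Welch two-sample t-test of Ka/Ks ratios between two ASE classes.

    Pairs with undefined ratios are excluded (counts reported).  Raises when
    either group has fewer than 3 defined ratios.
    """
    from scipy import stats

    groups: dict[str, list[float]] = {class_a: [], class_b: []}
    excluded = 0
    seen: set[tuple[str, str]] = set()
    for c in calls:
        if c.ase_class not in groups:
            continue
        key = (c.pair_id, c.ase_class)
        if key in seen:
            continue
        seen.add(key)
        ratio = kaks_by_pair.get(c.pair_id)
        if ratio is None or not np.isfinite(ratio):
            excluded += 1
            continue
        groups[c.ase_class].append(float(ratio))
    a, b = groups[class_a], groups[class_b]
    if len(a) < 3 or len(b) < 3:
        raise AnalysisError(
            f"need >= 3 defined ratios per group, got {len(a)}/{len(b)}"
        )
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    return {
        "class_a": class_a,
        "class_b": class_b,
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "t": float(t_stat),
        "p": float(p_value),
        "n_excluded_undefined": excluded,
    }


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    position: int
    strand: str
    motif: str


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise AnalysisError(f"invalid IUPAC symbol {ch!r} in motif {motif!r}")
        parts.append(f"[{IUPAC[ch]}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_motif(
    sequence: str,
    motif: str = "ACGTG",
    sequence_id: str = "",
    both_strands: bool = False,
) -> list[MotifHit]:
    """Find all (possibly overlapping) motif matches, 0-based positions.

    With *both_strands* the reverse-complement of the motif is scanned on the
    forward sequence and hits are reported against forward coordinates with
    strand ``-``.
    """
    sequence = sequence.upper()
    hits = [
        MotifHit(sequence_id, m.start(), "+", motif)
        for m in _iupac_regex(motif).finditer(sequence)
    ]
    if both_strands:
        rc = reverse_complement(motif)
        hits += [
            MotifHit(sequence_id, m.start(), "-", motif)
            for m in _iupac_regex(rc).finditer(sequence)
        ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
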