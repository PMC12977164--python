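"""Small shared helpers and worked-example arithmetic."""

from __future__ import annotations

from .errors import AnalysisError, UndefinedStatisticError


def annotation_rate(n_annotated: int, n_total: int, ndigits: int = 1) -> float:
    """Percentage of gene models with a functional annotation.

    Parameters
    ----------
    n_annotated : int
        Number of gene models that received an annotation.
    n_total : int
        Total number of predicted gene models.
    ndigits : int
        Decimal places for the rounded percentage.

    Returns
    -------
    float
        ``100 * n_annotated / n_total`` rounded to *ndigits* places.
    """
    if n_total <= 0:
        raise UndefinedStatisticError("annotation rate undefined for n_total <= 0")
    if n_annotated < 0 or n_annotated > n_total:
        raise AnalysisError(
            f"annotated count {n_annotated} outside [0, {n_total}]"
        )
    return round(100.0 * n_annotated / n_total, ndigits)


def orf_aa_count(orf_length_bp: int, includes_stop: bool = True) -> int:
    """Number of amino acids encoded by an open reading frame.

    An ORF of ``L`` bp comprises ``L/3`` codons; when the terminal stop codon
    is part of the ORF it is untranslated, so the protein has ``L/3 - 1``
    residues.
    """
    if orf_length_bp <= 0 or orf_length_bp % 3 != 0:
        raise AnalysisError(
            f"ORF length must be a positive multiple of 3, got {orf_length_bp}"
        )
    n = orf_length_bp // 3
    return n - 1 if includes_stop else n


def check_fraction(name: str, value: float) -> float:
    """Validate that *value* lies in [0, 1]; returns it unchanged."""
    from .errors import ConfigurationError

    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
    return value
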