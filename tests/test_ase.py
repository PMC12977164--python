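import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetradiv.ase import (
    ASECall,
    classify_ase,
    classify_matrix,
    compare_kaks_by_class,
    intersect_ase_sets,
    scan_motif,
    tpm_from_counts,
)
from tetradiv.errors import AnalysisError

# The 40-nt probe used for the motif worked example (an input sequence).
PROBE = "TTGTGCACACGTGTCGTGACAGGTCTCACACGTGGCAAGT"


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def test_tpm_equal_counts_equal_lengths():
    tpm = tpm_from_counts([10, 10, 10, 10], [500, 500, 500, 500])
    assert np.allclose(tpm, 250_000)


def test_tpm_zero_count_gene():
    tpm = tpm_from_counts([0, 5], [100, 100])
    assert tpm[0] == 0.0


def test_tpm_sums_to_million(rng):
    counts = rng.integers(0, 1000, size=50)
    counts[0] = 5  # ensure at least one positive
    lengths = rng.integers(200, 5000, size=50)
    assert tpm_from_counts(counts, lengths).sum() == pytest.approx(1e6, rel=1e-9)


def test_tpm_all_zero_counts_error():
    with pytest.raises(AnalysisError):
        tpm_from_counts([0, 0], [100, 100])


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "h1,h3,expected",
    [
        (10, 8, "biallelic"),       # fold 1.25
        (10, 1, "hap1_dominant"),
        (1, 10, "hap3_dominant"),
        (10, 4, "higher_one_allele"),  # fold 2.5
        (2, 2, "not_expressed"),    # threshold is strict > 2
        (10, 5, "higher_one_allele"),  # fold exactly 2 counts as imbalanced
        (0, 0, "not_expressed"),
    ],
)
def test_classify_rules(h1, h3, expected):
    cls, _ = classify_ase(h1, h3)
    assert cls == expected


def test_classifier_rejects_negative():
    with pytest.raises(AnalysisError):
        classify_ase(-1, 5)


@given(st.floats(min_value=0, max_value=1e5), st.floats(min_value=0, max_value=1e5))
@settings(max_examples=200, deadline=None)
def test_classifier_total_function(h1, h3):
    cls, _ = classify_ase(h1, h3)
    assert cls in {
        "biallelic", "higher_one_allele", "hap1_dominant", "hap3_dominant",
        "not_expressed",
    }


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "haplotype", "tissue", "tpm"])


def test_classify_matrix_fractions_sum_to_one():
    rows = []
    for i, (a, b) in enumerate([(10, 8), (10, 4), (10, 1), (1, 10), (0, 0)]):
        rows.append((f"g{i}", "H1", "stem", a))
        rows.append((f"g{i}", "H3", "stem", b))
    calls, summary = classify_matrix(_table(rows), hap_labels=("H1", "H3"))
    expressed = summary[summary["ase_class"] != "not_expressed"]
    assert expressed["fraction"].sum() == pytest.approx(1.0)
    assert expressed["n_expressed"].iloc[0] == 4


def test_classify_matrix_all_silent_warns(caplog):
    rows = [("g1", "H1", "stem", 0.0), ("g1", "H3", "stem", 0.0)]
    with caplog.at_level("WARNING"):
        calls, summary = classify_matrix(_table(rows), hap_labels=("H1", "H3"))
    assert calls[0].ase_class == "not_expressed"
    assert summary["fraction"].dropna().empty


def test_classify_matrix_order_invariant():
    rows = [("g1", "H1", "stem", 10), ("g1", "H3", "stem", 8),
            ("g2", "H1", "stem", 10), ("g2", "H3", "stem", 1)]
    _, s1 = classify_matrix(_table(rows), hap_labels=("H1", "H3"))
    _, s2 = classify_matrix(_table(rows[::-1]), hap_labels=("H1", "H3"))
    pd.testing.assert_frame_equal(s1, s2)


def test_classify_matrix_empty_errors():
    with pytest.raises(AnalysisError):
        classify_matrix(_table([]))


# ---------------------------------------------------------------------------
# Venn intersections
# ---------------------------------------------------------------------------

def _calls(tissue, ids):
    return [ASECall(i, tissue, "hap1_dominant", None) for i in ids]


def test_disjoint_sets():
    regions = intersect_ase_sets(
        {"stem": _calls("stem", ["a", "b"]), "root": _calls("root", ["c"])},
        {"hap1_dominant"},
    )
    assert regions[frozenset({"stem"})] == 2
    assert regions[frozenset({"root"})] == 1
    assert regions[frozenset({"stem", "root"})] == 0


def test_identical_sets_all_in_full_region():
    ids = [f"g{i}" for i in range(10)]
    tissues = ["stem", "root", "peel", "flesh"]
    regions = intersect_ase_sets(
        {t: _calls(t, ids) for t in tissues}, {"hap1_dominant"}
    )
    assert regions[frozenset(tissues)] == 10
    assert sum(regions.values()) == 10


def test_regions_sum_to_union(rng):
    pool = [f"g{i}" for i in range(200)]
    sets = {
        t: list(rng.choice(pool, size=50, replace=False))
        for t in ("stem", "root", "peel", "flesh")
    }
    regions = intersect_ase_sets(
        {t: _calls(t, ids) for t, ids in sets.items()}, {"hap1_dominant"}
    )
    union = set().union(*(set(v) for v in sets.values()))
    assert sum(regions.values()) == len(union)


def test_venn_matches_set_algebra_oracle(rng):
    from itertools import combinations

    tissues = ("stem", "root", "peel", "flesh")
    pool = [f"g{i}" for i in range(200)]
    sets = {t: set(rng.choice(pool, size=50, replace=False)) for t in tissues}
    regions = intersect_ase_sets(
        {t: _calls(t, ids) for t, ids in sets.items()}, {"hap1_dominant"}
    )
    # oracle: exclusive region = intersection of members minus union of rest
    for k in range(1, 5):
        for combo in combinations(tissues, k):
            inside = set.intersection(*(sets[t] for t in combo))
            outside = set.union(*(sets[t] for t in tissues if t not in combo), set())
            assert regions[frozenset(combo)] == len(inside - outside)


def test_venn_needs_two_tissues():
    with pytest.raises(AnalysisError):
        intersect_ase_sets({"stem": []}, {"hap1_dominant"})


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def _welch_oracle(a, b):
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as t_dist

    p = 2 * t_dist.sf(abs(t), df)
    return t, p


def _ratio_calls(pairs):
    return [ASECall(pid, "stem", cls, None) for pid, cls in pairs]


def test_welch_identical_groups():
    kaks = {f"a{i}": float(v) for i, v in enumerate([1, 2, 3])}
    kaks.update({f"b{i}": float(v) for i, v in enumerate([1, 2, 3])})
    calls = _ratio_calls(
        [(f"a{i}", "biallelic") for i in range(3)]
        + [(f"b{i}", "hap1_dominant") for i in range(3)]
    )
    res = compare_kaks_by_class(kaks, calls, "biallelic", "hap1_dominant")
    assert res["t"] == pytest.approx(0.0)
    assert res["p"] == pytest.approx(1.0)


def test_welch_matches_closed_form_oracle():
    a, b = [1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 3.0, 4.0, 5.0, 6.0]
    kaks = {f"a{i}": v for i, v in enumerate(a)}
    kaks.update({f"b{i}": v for i, v in enumerate(b)})
    calls = _ratio_calls(
        [(f"a{i}", "biallelic") for i in range(5)]
        + [(f"b{i}", "hap1_dominant") for i in range(5)]
    )
    res = compare_kaks_by_class(kaks, calls, "biallelic", "hap1_dominant")
    t, p = _welch_oracle(a, b)
    assert res["t"] == pytest.approx(t, abs=1e-10)
    assert res["p"] == pytest.approx(p, abs=1e-10)


def test_welch_separated_groups_significant(rng):
    a = rng.normal(0.2, 0.1, 100)
    b = rng.normal(0.5, 0.1, 100)
    kaks = {f"a{i}": v for i, v in enumerate(a)}
    kaks.update({f"b{i}": v for i, v in enumerate(b)})
    calls = _ratio_calls(
        [(f"a{i}", "biallelic") for i in range(100)]
        + [(f"b{i}", "hap1_dominant") for i in range(100)]
    )
    res = compare_kaks_by_class(kaks, calls, "biallelic", "hap1_dominant")
    assert res["p"] < 1e-6


def test_welch_small_group_errors():
    kaks = {"a0": 0.2, "b0": 0.5}
    calls = _ratio_calls([("a0", "biallelic"), ("b0", "hap1_dominant")])
    with pytest.raises(AnalysisError):
        compare_kaks_by_class(kaks, calls, "biallelic", "hap1_dominant")


def test_welch_undefined_ratios_excluded():
    kaks = {f"a{i}": 0.1 * (i + 1) for i in range(4)}
    kaks["a3"] = None
    kaks.update({f"b{i}": 0.2 * (i + 1) for i in range(3)})
    calls = _ratio_calls(
        [(f"a{i}", "biallelic") for i in range(4)]
        + [(f"b{i}", "hap1_dominant") for i in range(3)]
    )
    res = compare_kaks_by_class(kaks, calls, "biallelic", "hap1_dominant")
    assert res["n_a"] == 3 and res["n_excluded_undefined"] == 1


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def test_probe_has_two_forward_hits():
    # brute-force oracle over the probe
    expected = [i for i in range(len(PROBE) - 4) if PROBE[i : i + 5] == "ACGTG"]
    hits = scan_motif(PROBE, "ACGTG")
    assert [h.position for h in hits] == expected
    assert len(hits) == 2


def test_empty_sequence_no_hits():
    assert scan_motif("", "ACGTG") == []


def test_iupac_wildcard():
    hits = scan_motif("AAA", "ANA")
    assert len(hits) == 1 and hits[0].position == 0


def test_overlapping_hits_reported():
    hits = scan_motif("AAAA", "AA")
    assert [h.position for h in hits] == [0, 1, 2]


def test_both_strands():
    # CACGT is the reverse complement of ACGTG
    hits = scan_motif("CACGT", "ACGTG", both_strands=True)
    assert [(h.position, h.strand) for h in hits] == [(0, "-")]


def test_invalid_iupac_symbol():
    with pytest.raises(AnalysisError):
        scan_motif("ACGT", "AXA")
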