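import numpy as np
import pytest

from tetradiv.errors import AnalysisError, ConfigurationError, UndefinedStatisticError
from tetradiv.synteny import (
    AnchorPair,
    SyntenyBlock,
    best_hit_filter,
    chain_anchors,
    consolidate_blocks,
    mergeable,
    pathway_retention,
    retention_rate,
)


def anchor(i, ra, rb, chrom_a="c1", chrom_b="c1", bp_a=1000, bp_b=1000):
    return AnchorPair(
        f"a{i}", f"b{i}", chrom_a, chrom_b, ra, rb,
        ra * bp_a, ra * bp_a + bp_a // 2, rb * bp_b, rb * bp_b + bp_b // 2,
    )


def make_run(tag, ra0, rb0, size, orientation="same", bp_a=1000, bp_b=1000):
    anchors = []
    for k in range(size):
        rb = rb0 + k if orientation == "same" else rb0 - k
        anchors.append(anchor(f"{tag}_{k}", ra0 + k, rb, bp_a=bp_a, bp_b=bp_b))
    return SyntenyBlock(anchors=anchors, orientation=orientation)


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def test_chain_single_run():
    blocks = chain_anchors([anchor(i, i, i) for i in range(1, 6)])
    assert len(blocks) == 1
    assert blocks[0].orientation == "same"
    assert blocks[0].n_anchors == 5


def test_chain_with_inverted_run():
    anchors = [anchor(0, 1, 1), anchor(1, 2, 2), anchor(2, 3, 3),
               anchor(3, 4, 7), anchor(4, 5, 6)]
    blocks = chain_anchors(anchors)
    assert [(b.n_anchors, b.orientation) for b in blocks] == [(3, "same"), (2, "inverted")]


def test_chain_single_anchor():
    blocks = chain_anchors([anchor(0, 3, 9)])
    assert len(blocks) == 1 and blocks[0].n_anchors == 1
    assert blocks[0].orientation == "same"


def test_chain_rejects_duplicate_genes():
    a1 = anchor(0, 1, 1)
    a2 = AnchorPair("a0", "bZ", "c1", "c1", 2, 2, 2000, 2500, 2000, 2500)
    with pytest.raises(AnalysisError):
        chain_anchors([a1, a2])


def test_best_hit_filter_deterministic():
    rows = [
        AnchorPair("a1", "b1", "c1", "c1", 0, 0, 0, 1, 0, 1, similarity=0.9),
        AnchorPair("a1", "b2", "c1", "c1", 0, 1, 0, 1, 10, 11, similarity=0.9),
        AnchorPair("a2", "b2", "c1", "c1", 1, 1, 5, 6, 10, 11, similarity=0.8),
    ]
    kept = best_hit_filter(rows)
    # a1 ties between b1/b2 at 0.9 -> lexicographically smallest partner b1;
    # b2 then remains free for a2
    assert {(a.gene_a, a.gene_b) for a in kept} == {("a1", "b1"), ("a2", "b2")}


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def test_merge_on_gene_gap_despite_large_bp_gap():
    # 49 intervening genes, 500 kb apart in both genomes: gene condition holds
    left = make_run("L", 0, 0, 3, bp_a=10_000, bp_b=10_000)
    right = make_run("R", 52, 52, 3, bp_a=10_000, bp_b=10_000)
    merged = consolidate_blocks([left, right])
    assert len(merged) == 1 and merged[0].n_anchors == 6


def test_no_merge_at_exact_thresholds():
    # exactly 50 intervening genes; max_bp_gap set to the exact bp gap so
    # both strict < conditions fail in both genomes
    left = make_run("L", 0, 0, 2, bp_a=6000, bp_b=6000)
    right = make_run("R", 52, 52, 2, bp_a=6000, bp_b=6000)
    gap_genes = right.rank_range_a[0] - left.rank_range_a[1] - 1
    assert gap_genes == 50
    bp_gap = right.span_a[0] - left.span_a[1]
    assert not mergeable(left, right, 50, bp_gap, mode="both")
    merged = consolidate_blocks([left, right], max_gene_gap=50, max_bp_gap=bp_gap)
    assert len(merged) == 2


def test_negative_thresholds_rejected():
    with pytest.raises(ConfigurationError):
        consolidate_blocks([], max_gene_gap=-1)


def test_only_same_orientation_merged():
    left = make_run("L", 0, 0, 3)
    right = make_run("R", 10, 20, 3, orientation="inverted")
    assert len(consolidate_blocks([left, right])) == 2


def test_idempotence_random_instances():
    for seed in range(20):
        blocks = _random_instance(np.random.default_rng(seed))
        once = consolidate_blocks(blocks)
        twice = consolidate_blocks(once)
        assert _partition(once) == _partition(twice)


def test_matches_bruteforce_oracle_random_instances():
    for seed in range(40):
        blocks = _random_instance(np.random.default_rng(seed))
        got = _partition(consolidate_blocks(blocks))
        want = _partition(_oracle_consolidate(blocks, 50, 300_000, "both"))
        assert got == want, f"seed {seed}"


# --- instance generator and independent oracle -----------------------------

def _random_instance(rng, max_runs=12):
    n_runs = int(rng.integers(2, max_runs + 1))
    bp_a = int(rng.choice([500, 2000, 8000]))
    bp_b = int(rng.choice([500, 2000, 8000]))
    blocks = []
    ra = 0
    used_b = []
    for r in range(n_runs):
        size = int(rng.integers(1, 5))
        ra += int(rng.integers(1, 80))
        rb0 = int(rng.integers(0, 400))
        orientation = "same" if rng.random() < 0.8 else "inverted"
        if orientation == "inverted":
            rb0 += size
        blocks.append(
            make_run(f"s{r}", ra, rb0, size, orientation, bp_a=bp_a, bp_b=bp_b)
        )
        ra += size
    return blocks


def _partition(blocks):
    return frozenset(frozenset(a.gene_a for a in b.anchors) for b in blocks)


def _oracle_consolidate(blocks, max_gene_gap, max_bp_gap, mode):
    """Brute-force transitive closure of the pairwise merge predicate,
    merging whole connected components per round (order-independent) and
    iterating to a fixpoint."""
    blocks = [SyntenyBlock(anchors=list(b.anchors), orientation=b.orientation)
              for b in blocks]
    while True:
        n = len(blocks)
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                if mergeable(blocks[i], blocks[j], max_gene_gap, max_bp_gap, mode):
                    adj[i].add(j)
                    adj[j].add(i)
        if not any(adj.values()):
            return blocks
        # connected components by BFS
        seen, components = set(), []
        for i in range(n):
            if i in seen:
                continue
            queue, comp = [i], set()
            while queue:
                k = queue.pop()
                if k in comp:
                    continue
                comp.add(k)
                queue.extend(adj[k] - comp)
            seen |= comp
            components.append(sorted(comp))
        new_blocks = []
        for comp in components:
            anchors = sorted(
                (a for k in comp for a in blocks[k].anchors), key=lambda a: a.rank_a
            )
            orientation = blocks[comp[0]].orientation
            if len(comp) > 1 and all(blocks[k].n_anchors == 1 for k in comp):
                rb = [a.rank_b for a in anchors]
                orientation = "inverted" if rb[0] > rb[-1] else "same"
            new_blocks.append(SyntenyBlock(anchors=anchors, orientation=orientation))
        blocks = new_blocks


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

def test_retention_rate_arithmetic():
    assert retention_rate(400, 100, 4) == 1.0
    assert retention_rate(365, 100, 4) == 0.9125


def test_retention_rate_zero_denominator():
    with pytest.raises(UndefinedStatisticError):
        retention_rate(10, 0, 4)


def test_pathway_retention_all_retained():
    blocks = [make_run("x", 0, 0, 10)]
    ids = {a.gene_a for a in blocks[0].anchors}
    report = pathway_retention(blocks, {"set1": ids}, ploidy=1)
    assert report.retention_rate == 1.0
    assert report.per_set_rates["set1"] == 1.0


def test_pathway_retention_disjoint_set_undefined(caplog):
    blocks = [make_run("x", 0, 0, 5)]
    with caplog.at_level("WARNING"):
        report = pathway_retention(blocks, {"ghost": {"zzz"}}, ploidy=4)
    assert report.per_set_rates["ghost"] is None
    assert any("ghost" in r.message for r in caplog.records)


def test_retention_percent_rounding():
    r = pathway_retention([make_run("x", 0, 0, 73)], {}, ploidy=1)
    assert r.percent == 100.0
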