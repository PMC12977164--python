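import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tetradiv.errors import ConfigurationError, SimulationError
from tetradiv.kaks import STOP_CODONS
from tetradiv.simulate import (
    SimulationConfig,
    _random_cds,
    assign_retention,
    evolve_cds_pair,
    simulate_expression,
    simulate_tetraploid,
    write_dataset,
)


def test_structure_counts():
    cfg = SimulationConfig(seed=1, n_chromosomes=2, chrom_length=50_000,
                           n_genes_per_chrom=5)
    ds = simulate_tetraploid(cfg)
    assert set(ds.genomes) == {"H1", "H2", "H3", "H4"}
    assert sum(len(g) for g in ds.genomes.values()) == 8
    assert ds.truth_lineages == frozenset(
        {frozenset({"H1", "H2"}), frozenset({"H3", "H4"})}
    )


def test_variant_counts_match_poisson_expectation():
    cfg = SimulationConfig(
        seed=3, n_chromosomes=1, chrom_length=100_000, n_genes_per_chrom=5,
        within_lineage_snp_rate=1e-3, between_lineage_snp_rate=1e-2,
        indel_fraction=0.0,
    )
    ds = simulate_tetraploid(cfg)
    counts = ds.truth_variants.groupby(["hap_a", "hap_b"]).size()
    within = counts[("H1", "H2")]
    between = counts[("H1", "H3")]
    assert abs(within - 100) <= 3 * np.sqrt(100)
    assert abs(between - 1000) <= 3 * np.sqrt(1000)


def test_determinism_byte_identical(tmp_path):
    cfg = dict(seed=9, n_chromosomes=1, chrom_length=30_000, n_genes_per_chrom=4)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_dataset(simulate_tetraploid(SimulationConfig(**cfg)), d1)
    write_dataset(simulate_tetraploid(SimulationConfig(**cfg)), d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
    assert mismatch == [] and errors == []


def test_sequences_over_valid_alphabet(small_dataset):
    for genome in small_dataset.genomes.values():
        for seq in genome.records.values():
            assert set(seq) <= set("ACGTN")


def test_gene_intervals_inside_chromosomes(small_dataset):
    lengths = {h: g.lengths for h, g in small_dataset.genomes.items()}
    for hap, genes in small_dataset.gene_models.items():
        for g in genes:
            assert 0 <= g.start < g.end <= lengths[hap][g.chromosome]


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(ploidy=1)
    with pytest.raises(ConfigurationError):
        SimulationConfig(within_lineage_snp_rate=0.5, between_lineage_snp_rate=0.1)
    with pytest.raises(ConfigurationError):
        SimulationConfig(te_fraction=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(
            ase_design={t: {"biallelic": 0.5, "higher_one_allele": 0.1,
                            "hap1_dominant": 0.1, "hap3_dominant": 0.1}
                        for t in ("stem", "root", "tuber_peel", "tuber_flesh")}
        )


# ---------------------------------------------------------------------------
# evolve_cds_pair
# ---------------------------------------------------------------------------

def test_evolve_zero_targets_is_identity(rng):
    cds = _random_cds(rng, 50)
    mut, n_syn, n_nonsyn, events = evolve_cds_pair(cds, 0.0, 0.0, 1)
    assert mut == cds and n_syn == 0 and n_nonsyn == 0 and events == []


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_evolve_never_creates_stop(seed):
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, 100)
    mut, *_ = evolve_cds_pair(cds, 0.3, 0.1, rng)
    codons = {mut[i : i + 3] for i in range(0, len(mut), 3)}
    assert not codons & STOP_CODONS


def test_evolve_realized_counts_match_diff_when_single_hit(rng):
    # small targets: every event hits a distinct position, so the event log
    # must coincide exactly with the positional diff of the two sequences
    cds = _random_cds(rng, 200)
    mut, n_syn, n_nonsyn, events = evolve_cds_pair(cds, 0.02, 0.01, 7)
    positions = [e[0] for e in events]
    if len(set(positions)) == len(positions):  # single-hit regime
        diff = [i for i in range(len(cds)) if cds[i] != mut[i]]
        assert sorted(positions) == diff
        assert n_syn == sum(1 for e in events if e[3] == "syn")
        assert n_nonsyn == sum(1 for e in events if e[3] == "nonsyn")


def test_evolve_impossible_target_errors():
    # ATG (Met) and TGG (Trp) have zero synonymous sites
    with pytest.raises(SimulationError):
        evolve_cds_pair("ATGTGG" * 10, 0.5, 0.0, 1)


def test_evolve_rejects_internal_stop():
    with pytest.raises(SimulationError):
        evolve_cds_pair("ATGTAAATG", 0.1, 0.1, 1)


# ---------------------------------------------------------------------------
# assign_retention
# ---------------------------------------------------------------------------

def test_retention_extremes():
    copies = [(f"g{i}", h) for i in range(50) for h in ("H1", "H2", "H3", "H4")]
    all_on = assign_retention(copies, set(), 1.0, 1.0, 1)
    assert all_on["retained"].all()
    all_off = assign_retention(copies, set(), 0.0, 0.0, 1)
    assert not all_off["retained"].any()


def test_retention_binomial_check():
    copies = [(f"g{i}", h) for i in range(1000) for h in ("H1", "H2", "H3", "H4")]
    flags = assign_retention(copies, set(), 0.9, 0.98, 42)
    frac = flags["retained"].mean()
    sd = np.sqrt(0.9 * 0.1 / len(copies))
    assert abs(frac - 0.9) <= 3 * sd


def test_retention_invalid_probability():
    with pytest.raises(ConfigurationError):
        assign_retention([("g", "H1")], set(), 1.2, 0.9, 1)


# ---------------------------------------------------------------------------
# simulate_expression
# ---------------------------------------------------------------------------

def _design(props):
    classes = ("biallelic", "higher_one_allele", "hap1_dominant", "hap3_dominant")
    return {"stem": dict(zip(classes, props))}


def test_expression_all_biallelic_closed_loop():
    from tetradiv.ase import classify_matrix

    expr, labels = simulate_expression(_design((1.0, 0, 0, 0)), [f"g{i}" for i in range(20)], 5)
    calls, summary = classify_matrix(expr, hap_labels=("H1", "H3"))
    assert all(c.ase_class == "biallelic" for c in calls)


def test_expression_dominant_construction():
    expr, labels = simulate_expression(_design((0, 0, 1.0, 0)), ["g1", "g2"], 3)
    wide = expr.pivot_table(index="gene_id", columns="haplotype", values="tpm")
    assert (wide["H1"] > 2).all() and (wide["H3"] <= 2).all()


def test_expression_deterministic():
    genes = [f"g{i}" for i in range(10)]
    e1, l1 = simulate_expression(_design((0.5, 0.3, 0.1, 0.1)), genes, 8)
    e2, l2 = simulate_expression(_design((0.5, 0.3, 0.1, 0.1)), genes, 8)
    pd.testing.assert_frame_equal(e1, e2)
    pd.testing.assert_frame_equal(l1, l2)


def test_expression_empty_gene_list_errors():
    with pytest.raises(ConfigurationError):
        simulate_expression(_design((1, 0, 0, 0)), [], 1)


def test_margin_keeps_values_off_boundaries():
    expr, _ = simulate_expression(
        _design((0.25, 0.25, 0.25, 0.25)), [f"g{i}" for i in range(40)], 13
    )
    tpm = expr["tpm"].to_numpy()
    assert not np.any(np.isclose(tpm, 2.0, rtol=0.05))
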