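"""Synthetic autotetraploid dataset generator.

Produces desk-scale datasets with known truth so every downstream analysis
stage (synteny/retention, divergence/lineage clustering, Ka/Ks, ASE, TE
profiles) can be tested without external data.

Model
-----
A single ancestral genome gives rise to lineage ancestors, which in turn give
rise to haplotypes.  SNPs are placed in-place (position-preserving) along
each branch: lineage branches carry rate ``(between - within)/2`` and leaf
branches ``within/2`` so that the *pairwise* densities match the configured
within/between-lineage rates.  InDel events are recorded in the truth tables
but, by design, not applied to coordinates.  Coding-sequence divergence is a
separate, explicitly controlled channel (`evolve_cds_pair`) so NG86 recovery
is exact and stop-free.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError
from .io import (
    GeneModel,
    GenomeSequenceSet,
    TEInterval,
    write_anchors,
    write_bed,
    write_expression,
    write_fasta,
    write_gff3,
)
from . import kaks as _kaks

log = logging.getLogger(__name__)

ASE_CLASSES = ("biallelic", "higher_one_allele", "hap1_dominant", "hap3_dominant")
DEFAULT_TISSUES = ("stem", "root", "tuber_peel", "tuber_flesh")
DEFAULT_ASE_DESIGN = {"biallelic": 0.90, "higher_one_allele": 0.05,
                      "hap1_dominant": 0.03, "hap3_dominant": 0.02}

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_PATHWAY_TAG = "dioscin"


def default_lineage_pairs(ploidy: int) -> tuple[tuple[str, ...], ...]:
    """Partition H1..Hn into consecutive pairs (last group may be a singleton)."""
    labels = [f"H{i + 1}" for i in range(ploidy)]
    return tuple(tuple(labels[i : i + 2]) for i in range(0, ploidy, 2))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tetraploid generator."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    ploidy: int = 4
    lineage_pairs: tuple[tuple[str, ...], ...] | None = None
    within_lineage_snp_rate: float = 1e-3
    between_lineage_snp_rate: float = 1e-2
    indel_fraction: float = 0.1
    n_genes_per_chrom: int = 40
    retention_background: float = 0.9
    retention_pathway: float = 0.98
    pathway_gene_fraction: float = 0.1
    target_ds: float = 0.05
    target_dn: float = 0.01
    te_fraction: float = 0.2
    ase_design: Mapping[str, Mapping[str, float]] | None = None
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    min_gene_codons: int = 40
    max_gene_codons: int = 120

    def __post_init__(self) -> None:
        if self.lineage_pairs is None:
            self.lineage_pairs = default_lineage_pairs(self.ploidy)
        else:
            self.lineage_pairs = tuple(tuple(g) for g in self.lineage_pairs)
        if self.ase_design is None:
            self.ase_design = {t: dict(DEFAULT_ASE_DESIGN) for t in self.tissues}
        self.validate()

    @property
    def haplotypes(self) -> tuple[str, ...]:
        return tuple(h for group in self.lineage_pairs for h in group)

    def validate(self) -> None:
        if self.ploidy < 2:
            raise ConfigurationError(f"ploidy must be >= 2, got {self.ploidy}")
        labels = self.haplotypes
        if len(labels) != self.ploidy or len(set(labels)) != self.ploidy:
            raise ConfigurationError(
                "lineage_pairs must partition exactly `ploidy` distinct labels"
            )
        for name in (
            "within_lineage_snp_rate",
            "between_lineage_snp_rate",
            "indel_fraction",
            "retention_background",
            "retention_pathway",
            "pathway_gene_fraction",
            "te_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if len(self.lineage_pairs) > 1 and not (
            self.within_lineage_snp_rate < self.between_lineage_snp_rate
        ):
            raise ConfigurationError(
                "within_lineage_snp_rate must be < between_lineage_snp_rate "
                "when lineage structure is requested"
            )
        if self.target_ds < 0 or self.target_dn < 0:
            raise ConfigurationError("target_ds/target_dn must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length < 1000:
            raise ConfigurationError("need >= 1 chromosome of >= 1000 bp")
        if self.n_genes_per_chrom < 1:
            raise ConfigurationError("n_genes_per_chrom must be >= 1")
        for tissue, design in self.ase_design.items():
            if set(design) != set(ASE_CLASSES):
                raise ConfigurationError(
                    f"ase_design[{tissue!r}] must cover exactly {ASE_CLASSES}"
                )
            total = sum(design.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"ase_design[{tissue!r}] sums to {total}, expected 1"
                )
        slot = self.chrom_length // self.n_genes_per_chrom
        if slot < 3 * self.max_gene_codons + 200:
            raise ConfigurationError(
                "chromosome too short for the requested gene count/length"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class CdsPair:
    """An aligned CDS pair with the realized substitution event counts."""

    gene_id: str
    seq_a: str
    seq_b: str
    n_syn: int
    n_nonsyn: int


@dataclass
class SimulatedDataset:
    """Ground-truth bundle emitted by :func:`simulate_tetraploid`."""

    config: SimulationConfig
    genomes: dict[str, GenomeSequenceSet]
    gene_models: dict[str, list[GeneModel]]
    reference_genes: list[GeneModel]
    te_intervals: list[TEInterval]
    truth_variants: pd.DataFrame
    truth_cds_pairs: list[CdsPair]
    expression: pd.DataFrame
    truth_ase_labels: pd.DataFrame
    truth_retention: pd.DataFrame
    truth_lineages: frozenset[frozenset[str]]

    @property
    def lineage_representatives(self) -> tuple[str, str]:
        """First haplotype of each of the first two lineages (e.g. H1, H3)."""
        groups = self.config.lineage_pairs
        if len(groups) < 2:
            raise SimulationError("need >= 2 lineages for representative pairing")
        return (groups[0][0], groups[1][0])


# ---------------------------------------------------------------------------
# CDS evolution
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(_kaks.SENSE_CODONS), size=n_codons)
    return "".join(_kaks.SENSE_CODONS[i] for i in codons)


def evolve_cds_pair(
    cds: str,
    target_ds: float,
    target_dn: float,
    seed: int | np.random.Generator,
) -> tuple[str, int, int, list[tuple[int, str, str, str]]]:
    """Mutate *cds* to realized synonymous/nonsynonymous substitution targets.

    Targets are interpreted as substitutions per site of each class; the
    integer event counts are ``round(target * sites)`` against the NG86 site
    counts of the input sequence.  Events are placed by proposing uniform
    single-nucleotide changes (position and new base), classifying each
    against the *current* codon, rejecting changes that would create a stop
    codon, until both targets are met.  Positions may be hit more than once,
    which is what makes the downstream Jukes–Cantor correction appropriate.

    Returns ``(mutant, n_syn_applied, n_nonsyn_applied, events)`` where each
    event is ``(position, old_base, new_base, "syn"|"nonsyn")``.
    """
    if len(cds) % 3 != 0:
        raise SimulationError(f"CDS length {len(cds)} not a multiple of 3")
    cds = cds.upper()
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] in _kaks.STOP_CODONS:
            raise SimulationError(f"input CDS has internal stop at codon {i // 3}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    s_sites = n_sites = 0.0
    for i in range(0, len(cds), 3):
        s, n = _kaks.ng86_sites(cds[i : i + 3])
        s_sites += s
        n_sites += n
    n_syn_target = int(round(target_ds * s_sites))
    n_nonsyn_target = int(round(target_dn * n_sites))
    if target_ds > 0 and s_sites == 0:
        raise SimulationError("target_ds > 0 but the CDS has zero synonymous sites")
    if target_dn > 0 and n_sites == 0:
        raise SimulationError("target_dn > 0 but the CDS has zero nonsynonymous sites")

    seq = list(cds)
    events: list[tuple[int, str, str, str]] = []
    n_syn = n_nonsyn = 0
    budget = 1000 + 500 * (n_syn_target + n_nonsyn_target)
    proposals = 0
    while n_syn < n_syn_target or n_nonsyn < n_nonsyn_target:
        proposals += 1
        if proposals > budget:
            raise SimulationError(
                f"could not reach targets (dS={target_ds}, dN={target_dn}) "
                f"after {budget} proposals"
            )
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        alt = _BASES_EXCEPT[old][int(rng.integers(3))]
        c0 = pos - pos % 3
        codon = "".join(seq[c0 : c0 + 3])
        mut = codon[: pos - c0] + alt + codon[pos - c0 + 1 :]
        if mut in _kaks.STOP_CODONS:
            continue
        syn = _kaks._AA[mut] == _kaks._AA[codon]
        if syn and n_syn < n_syn_target:
            n_syn += 1
        elif not syn and n_nonsyn < n_nonsyn_target:
            n_nonsyn += 1
        else:
            continue
        seq[pos] = alt
        events.append((pos, old, alt, "syn" if syn else "nonsyn"))
    return "".join(seq), n_syn, n_nonsyn, events


_BASES_EXCEPT = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


# ---------------------------------------------------------------------------
# Retention and expression
# ---------------------------------------------------------------------------

def assign_retention(
    gene_copies: Sequence[tuple[str, str]],
    pathway_genes: set[str],
    p_background: float,
    p_pathway: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Independently retain each (gene, haplotype) copy.

    Copies of genes in *pathway_genes* are retained with probability
    *p_pathway*, all others with *p_background*.
    """
    for name, p in (("p_background", p_background), ("p_pathway", p_pathway)):
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for gene_id, hap in gene_copies:
        pathway = gene_id in pathway_genes
        p = p_pathway if pathway else p_background
        rows.append((gene_id, hap, pathway, bool(rng.random() < p)))
    return pd.DataFrame(rows, columns=["gene_id", "haplotype", "pathway", "retained"])


def _apportion(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items to proportions."""
    quotas = [p * n for p in proportions]
    counts = [int(np.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (counts[i] - quotas[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_expression(
    design: Mapping[str, Mapping[str, float]],
    gene_ids: Sequence[str],
    seed: int | np.random.Generator,
    expr_threshold: float = 2.0,
    fold_threshold: float = 2.0,
    margin: float = 0.1,
    hap_labels: tuple[str, str] = ("H1", "H3"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-allele TPM values realizing designed ASE class proportions.

    Class counts per tissue are apportioned exactly (largest remainder) and
    TPM values keep a relative *margin* away from every threshold boundary so
    the downstream classifier recovers the designed labels exactly.

    Returns ``(expression, labels)``: a long-format TPM table with columns
    (gene_id, haplotype, tissue, tpm) and a truth-label table with columns
    (gene_id, tissue, label).
    """
    if not gene_ids:
        raise ConfigurationError("empty gene list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo_on = expr_threshold * (1.0 + margin)        # safely expressed
    hi_off = expr_threshold * (1.0 - margin)       # safely not expressed
    fold_lo = fold_threshold * (1.0 - margin)      # biallelic fold stays below
    fold_hi = fold_threshold * (1.0 + margin)      # imbalanced fold stays above

    expr_rows: list[tuple[str, str, str, float]] = []
    label_rows: list[tuple[str, str, str]] = []
    hap_a, hap_b = hap_labels
    for tissue, props in design.items():
        counts = _apportion(len(gene_ids), [props[c] for c in ASE_CLASSES])
        labels = np.repeat(np.arange(len(ASE_CLASSES)), counts)
        labels = labels[rng.permutation(len(labels))]
        for gid, lab_idx in zip(gene_ids, labels):
            cls = ASE_CLASSES[lab_idx]
            if cls == "biallelic":
                low = float(rng.uniform(lo_on, 10 * lo_on))
                fold = float(rng.uniform(1.0, fold_lo))
                a, b = (low * fold, low) if rng.random() < 0.5 else (low, low * fold)
            elif cls == "higher_one_allele":
                low = float(rng.uniform(lo_on, 10 * lo_on))
                fold = float(rng.uniform(fold_hi, 4 * fold_hi))
                a, b = (low * fold, low) if rng.random() < 0.5 else (low, low * fold)
            elif cls == "hap1_dominant":
                a = float(rng.uniform(lo_on, 20 * lo_on))
                b = float(rng.uniform(0.0, hi_off))
            else:  # hap3_dominant
                a = float(rng.uniform(0.0, hi_off))
                b = float(rng.uniform(lo_on, 20 * lo_on))
            expr_rows.append((gid, hap_a, tissue, round(a, 6)))
            expr_rows.append((gid, hap_b, tissue, round(b, 6)))
            label_rows.append((gid, tissue, cls))

    expression = pd.DataFrame(expr_rows, columns=["gene_id", "haplotype", "tissue", "tpm"])
    labels_df = pd.DataFrame(label_rows, columns=["gene_id", "tissue", "label"])
    return expression, labels_df


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------

def _mutate_branch(
    rng: np.random.Generator,
    seqs: dict[str, np.ndarray],
    rate: float,
    indel_fraction: float,
) -> pd.DataFrame:
    """Apply SNPs in place per chromosome; return recorded InDel events."""
    indel_rows = []
    for chrom, arr in seqs.items():
        n_events = rng.poisson(rate * arr.size)
        if n_events == 0:
            continue
        n_events = min(n_events, arr.size)
        pos = rng.choice(arr.size, size=n_events, replace=False)
        is_indel = rng.random(n_events) < indel_fraction
        snp_pos = pos[~is_indel]
        # shift by 1..3 within the 4-letter alphabet: always a real change
        shift = rng.integers(1, 4, size=snp_pos.size).astype(np.uint8)
        codes = _base_codes(arr[snp_pos])
        arr[snp_pos] = _BASE_ARR[(codes + shift) % 4]
        for p in pos[is_indel]:
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                ref, alt, t = "N", "N" * (length + 1), "INS"
            else:
                ref, alt, t = "N" * (length + 1), "N", "DEL"
            indel_rows.append((chrom, int(p), t, ref, alt))
    return pd.DataFrame(indel_rows, columns=["chromosome", "position", "type", "ref", "alt"])


_CODE_LOOKUP = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LOOKUP[_b] = _i


def _base_codes(arr: np.ndarray) -> np.ndarray:
    return _CODE_LOOKUP[arr]


def simulate_tetraploid(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic tetraploid dataset with truth tables.

    The same configuration (including seed) always yields a byte-identical
    dataset.
    """
    config.validate()
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    (ss_anc, ss_genes, ss_mut, ss_ret, ss_te, ss_expr, ss_cds) = root.spawn(7)
    rng_anc = np.random.default_rng(ss_anc)
    rng_genes = np.random.default_rng(ss_genes)
    rng_mut = np.random.default_rng(ss_mut)
    rng_te = np.random.default_rng(ss_te)
    rng_cds = np.random.default_rng(ss_cds)

    haps = cfg.haplotypes
    chroms = [f"chr{c + 1:02d}" for c in range(cfg.n_chromosomes)]

    # --- ancestral genome -------------------------------------------------
    ancestor: dict[str, np.ndarray] = {
        chrom: _BASE_ARR[rng_anc.integers(0, 4, size=cfg.chrom_length)]
        for chrom in chroms
    }

    # --- gene placement on the ancestor -----------------------------------
    ref_genes: list[GeneModel] = []
    anc_cds: dict[str, str] = {}
    slot = cfg.chrom_length // cfg.n_genes_per_chrom
    for ci, chrom in enumerate(chroms):
        for gi in range(cfg.n_genes_per_chrom):
            n_codons = int(rng_genes.integers(cfg.min_gene_codons, cfg.max_gene_codons + 1))
            length = 3 * n_codons
            lo = gi * slot + 50
            hi = (gi + 1) * slot - length - 50
            start = int(rng_genes.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng_genes.random() < 0.5 else "-"
            gid = f"g{ci + 1:02d}{gi + 1:04d}"
            cds_seq = _random_cds(rng_genes, n_codons)
            anc_cds[gid] = cds_seq
            ancestor[chrom][start : start + length] = np.frombuffer(
                cds_seq.encode(), dtype=np.uint8
            )
            ref_genes.append(
                GeneModel(
                    gene_id=gid,
                    haplotype="REF",
                    chromosome=chrom,
                    start=start,
                    end=start + length,
                    strand=strand,
                    cds=((start, start + length),),
                )
            )

    # --- pathway tagging ---------------------------------------------------
    all_gene_ids = [g.gene_id for g in ref_genes]
    n_pathway = int(round(cfg.pathway_gene_fraction * len(all_gene_ids)))
    pathway_genes = set(
        np.array(all_gene_ids)[rng_genes.permutation(len(all_gene_ids))[:n_pathway]]
    )
    ref_genes = [
        GeneModel(
            gene_id=g.gene_id,
            haplotype=g.haplotype,
            chromosome=g.chromosome,
            start=g.start,
            end=g.end,
            strand=g.strand,
            cds=g.cds,
            pathway_tags=frozenset({_PATHWAY_TAG}) if g.gene_id in pathway_genes else frozenset(),
        )
        for g in ref_genes
    ]

    # --- branch mutation ---------------------------------------------------
    within = cfg.within_lineage_snp_rate
    between = cfg.between_lineage_snp_rate
    lineage_rate = max(between - within, 0.0) / 2.0 if len(cfg.lineage_pairs) > 1 else 0.0
    leaf_rate = within / 2.0

    hap_seqs: dict[str, dict[str, np.ndarray]] = {}
    branch_indels: dict[str, pd.DataFrame] = {}
    hap_lineage: dict[str, int] = {}
    for li, group in enumerate(cfg.lineage_pairs):
        lin_seqs = {c: a.copy() for c, a in ancestor.items()}
        branch_indels[f"lineage{li}"] = _mutate_branch(
            rng_mut, lin_seqs, lineage_rate, cfg.indel_fraction
        )
        for hap in group:
            leaf = {c: a.copy() for c, a in lin_seqs.items()}
            branch_indels[hap] = _mutate_branch(
                rng_mut, leaf, leaf_rate, cfg.indel_fraction
            )
            hap_seqs[hap] = leaf
            hap_lineage[hap] = li

    # --- truth variants (pairwise) ----------------------------------------
    var_frames = []
    for i, ha in enumerate(haps):
        for hb in haps[i + 1 :]:
            for chrom in chroms:
                a, b = hap_seqs[ha][chrom], hap_seqs[hb][chrom]
                pos = np.nonzero(a != b)[0]
                if pos.size:
                    var_frames.append(
                        pd.DataFrame(
                            {
                                "hap_a": ha,
                                "hap_b": hb,
                                "chromosome": chrom,
                                "position": pos,
                                "type": "SNP",
                                "ref": [chr(x) for x in a[pos]],
                                "alt": [chr(x) for x in b[pos]],
                            }
                        )
                    )
            path = [ha, hb]
            if hap_lineage[ha] != hap_lineage[hb]:
                path += [f"lineage{hap_lineage[ha]}", f"lineage{hap_lineage[hb]}"]
            for br in path:
                ind = branch_indels[br]
                if len(ind):
                    ind = ind.copy()
                    ind.insert(0, "hap_b", hb)
                    ind.insert(0, "hap_a", ha)
                    var_frames.append(ind)
    if var_frames:
        truth_variants = pd.concat(var_frames, ignore_index=True)
        truth_variants = truth_variants.sort_values(
            ["hap_a", "hap_b", "chromosome", "position", "type"]
        ).reset_index(drop=True)
    else:
        truth_variants = pd.DataFrame(
            columns=["hap_a", "hap_b", "chromosome", "position", "type", "ref", "alt"]
        )

    # --- retention ---------------------------------------------------------
    copies = [(gid, hap) for gid in all_gene_ids for hap in haps]
    truth_retention = assign_retention(
        copies, pathway_genes, cfg.retention_background, cfg.retention_pathway,
        np.random.default_rng(ss_ret),
    )
    retained = {
        (r.gene_id, r.haplotype) for r in truth_retention.itertuples() if r.retained
    }

    gene_models: dict[str, list[GeneModel]] = {h: [] for h in haps}
    ref_by_id = {g.gene_id: g for g in ref_genes}
    for gid, hap in copies:
        if (gid, hap) not in retained:
            continue
        g = ref_by_id[gid]
        gene_models[hap].append(
            GeneModel(
                gene_id=f"{hap}_{gid}",
                haplotype=hap,
                chromosome=g.chromosome,
                start=g.start,
                end=g.end,
                strand=g.strand,
                cds=g.cds,
                pathway_tags=g.pathway_tags,
            )
        )

    # --- CDS pairs between the lineage representatives ---------------------
    rep_a = cfg.lineage_pairs[0][0]
    rep_b = cfg.lineage_pairs[1][0] if len(cfg.lineage_pairs) > 1 else cfg.lineage_pairs[0][-1]
    truth_cds_pairs: list[CdsPair] = []
    for gid in all_gene_ids:
        if (gid, rep_a) in retained and (gid, rep_b) in retained:
            mutant, n_syn, n_nonsyn, _events = evolve_cds_pair(
                anc_cds[gid], cfg.target_ds, cfg.target_dn, rng_cds
            )
            truth_cds_pairs.append(
                CdsPair(gene_id=gid, seq_a=anc_cds[gid], seq_b=mutant,
                        n_syn=n_syn, n_nonsyn=n_nonsyn)
            )

    # --- TE intervals -------------------------------------------------------
    te_classes = ("LTR/Gypsy", "LTR/Copia", "DNA", "LINE")
    te_intervals: list[TEInterval] = []
    for hap in haps:
        for chrom in chroms:
            target = cfg.te_fraction * cfg.chrom_length
            covered = 0.0
            while covered < target:
                length = int(rng_te.integers(200, 2000))
                start = int(rng_te.integers(0, cfg.chrom_length - length))
                cls = te_classes[int(rng_te.integers(len(te_classes)))]
                te_intervals.append(TEInterval(hap, chrom, start, start + length, cls))
                covered += length

    # --- expression ---------------------------------------------------------
    pair_gene_ids = [p.gene_id for p in truth_cds_pairs]
    if pair_gene_ids:
        expression, truth_ase = simulate_expression(
            cfg.ase_design,
            pair_gene_ids,
            np.random.default_rng(ss_expr),
            hap_labels=(rep_a, rep_b),
        )
    else:
        expression = pd.DataFrame(columns=["gene_id", "haplotype", "tissue", "tpm"])
        truth_ase = pd.DataFrame(columns=["gene_id", "tissue", "label"])

    genomes = {
        hap: GenomeSequenceSet(
            haplotype=hap,
            records={c: hap_seqs[hap][c].tobytes().decode() for c in chroms},
        )
        for hap in haps
    }
    truth_lineages = frozenset(frozenset(g) for g in cfg.lineage_pairs)

    return SimulatedDataset(
        config=cfg,
        genomes=genomes,
        gene_models=gene_models,
        reference_genes=ref_genes,
        te_intervals=te_intervals,
        truth_variants=truth_variants,
        truth_cds_pairs=truth_cds_pairs,
        expression=expression,
        truth_ase_labels=truth_ase,
        truth_retention=truth_retention,
        truth_lineages=truth_lineages,
    )


def anchor_table(dataset: SimulatedDataset, haplotype: str) -> pd.DataFrame:
    """Homolog anchor pairs between the diploid reference and one haplotype."""
    rows = [
        (g.gene_id.split("_", 1)[1], g.gene_id, 1.0)
        for g in dataset.gene_models[haplotype]
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the dataset to *out_dir* as plain-text standard formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for hap, genome in dataset.genomes.items():
        write_fasta(genome, out / f"{hap}.fa")
        write_gff3(dataset.gene_models[hap], out / f"{hap}.gff3")
        write_bed(
            [t for t in dataset.te_intervals if t.haplotype == hap],
            out / f"{hap}.te.bed",
        )
    write_gff3(dataset.reference_genes, out / "reference.gff3")

    vt = dataset.truth_variants
    disk = pd.DataFrame(
        {
            "hap_a": vt["hap_a"],
            "hap_b": vt["hap_b"],
            "chromA": vt["chromosome"],
            "posA": vt["position"] + 1,
            "chromB": vt["chromosome"],
            "posB": vt["position"] + 1,
            "type": vt["type"],
            "ref": vt["ref"],
            "alt": vt["alt"],
        }
    )
    disk.to_csv(out / "variants.tsv", sep="\t", index=False)
    write_expression(dataset.expression, out / "expression.tsv")
    for hap in dataset.genomes:
        write_anchors(anchor_table(dataset, hap), out / f"anchors_{hap}.tsv")

    with open(out / "cds_pairs.fa", "w") as fh:
        for p in dataset.truth_cds_pairs:
            fh.write(f">{p.gene_id}|A\n{p.seq_a}\n>{p.gene_id}|B\n{p.seq_b}\n")

    truth = {
        "lineages": sorted(sorted(g) for g in dataset.truth_lineages),
        "retention": dataset.truth_retention.to_dict(orient="list"),
        "ase_labels": dataset.truth_ase_labels.to_dict(orient="list"),
        "cds_pair_counts": {
            p.gene_id: {"n_syn": p.n_syn, "n_nonsyn": p.n_nonsyn}
            for p in dataset.truth_cds_pairs
        },
        "config": _config_to_jsonable(dataset.config),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def _config_to_jsonable(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["lineage_pairs"] = [list(g) for g in cfg.lineage_pairs]
    d["ase_design"] = {t: dict(v) for t, v in cfg.ase_design.items()}
    d["tissues"] = list(cfg.tissues)
    return d
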