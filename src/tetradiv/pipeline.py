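"""End-to-end orchestration: simulate -> synteny -> divergence -> kaks ->
ase -> teprofile, with a machine-readable JSON report.

All randomness lives in the simulator (one global seed in the config);
analytical stages are deterministic given their inputs, so rerunning the same
config reproduces all deterministic report fields byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .errors import AnalysisError, ConfigurationError
from . import ase as ase_mod
from . import divergence as div_mod
from . import kaks as kaks_mod
from . import synteny as syn_mod
from . import teprofile as te_mod
from .simulate import SimulationConfig, anchor_table, simulate_tetraploid, write_dataset

log = logging.getLogger(__name__)

DEFAULT_ANALYSIS = {
    "window": 300_000,
    "step": 300_000,
    "max_gene_gap": 50,
    "max_bp_gap": 300_000,
    "gap_mode": "both",
    "ks_cutoff": 3.0,
    "ks_min_prominence": 0.05,
    "mu": None,
    "expr_threshold": 2.0,
    "fold_threshold": 2.0,
    "te_flank": 5000,
    "te_window": 100,
    "te_step": 10,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline config."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def _split_config(config: Mapping[str, Any]) -> tuple[SimulationConfig, dict]:
    sim_part = dict(config.get("simulation", {}))
    analysis = dict(DEFAULT_ANALYSIS)
    extra = {
        k: v for k, v in config.get("analysis", {}).items()
    }
    unknown = set(extra) - set(analysis)
    if unknown:
        raise ConfigurationError(f"unknown analysis config keys: {sorted(unknown)}")
    analysis.update(extra)
    return SimulationConfig.from_dict(sim_part), analysis


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Run every stage on a simulated dataset and write ``report.json``."""
    sim_cfg, analysis = _split_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "tool": "tetradiv",
        "version": __version__,
        "seed": sim_cfg.seed,
        "config": {"simulation": json.loads(json.dumps(_jsonable(sim_cfg))),
                   "analysis": analysis},
        "stages": {},
        "warnings": [],
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _T()

    # --- simulate ----------------------------------------------------------
    with stage("simulate"):
        dataset = simulate_tetraploid(sim_cfg)
        write_dataset(dataset, out / "dataset")
    report["stages"]["simulate"] = {
        "haplotypes": list(sim_cfg.haplotypes),
        "n_chromosomes": sim_cfg.n_chromosomes,
        "n_sequence_records": sum(len(g) for g in dataset.genomes.values()),
        "n_variants": int(len(dataset.truth_variants)),
        "n_cds_pairs": len(dataset.truth_cds_pairs),
    }

    # --- synteny / retention ----------------------------------------------
    with stage("synteny"):
        all_blocks: list[syn_mod.SyntenyBlock] = []
        for hap in sim_cfg.haplotypes:
            anchors = syn_mod.build_anchors(
                anchor_table(dataset, hap),
                dataset.reference_genes,
                dataset.gene_models[hap],
            )
            anchors = syn_mod.best_hit_filter(anchors)
            blocks = syn_mod.chain_anchors(anchors)
            all_blocks.extend(
                syn_mod.consolidate_blocks(
                    blocks,
                    analysis["max_gene_gap"],
                    analysis["max_bp_gap"],
                    analysis["gap_mode"],
                )
            )
        pathway_ids = {
            g.gene_id for g in dataset.reference_genes if g.pathway_tags
        }
        retention = syn_mod.pathway_retention(
            all_blocks, {"dioscin": pathway_ids}, sim_cfg.ploidy
        )
        syn_mod.blocks_to_frame(all_blocks).to_csv(
            out / "synteny_blocks.tsv", sep="\t", index=False
        )
    report["stages"]["synteny"] = {
        "n_blocks": len(all_blocks),
        "polyploid_syntenic_genes": retention.polyploid_syntenic_genes,
        "diploid_syntenic_genes": retention.diploid_syntenic_genes,
        "retention_rate": retention.retention_rate,
        "retention_percent": retention.percent,
        "per_set_rates": retention.per_set_rates,
    }

    # --- divergence / lineages --------------------------------------------
    with stage("divergence"):
        matrix = div_mod.divergence_matrix(dataset.truth_variants, sim_cfg.haplotypes)
        clustering = div_mod.cluster_haplotypes(matrix)
        matrix.to_frame("snp").to_csv(out / "divergence_snp.tsv", sep="\t")
        matrix.to_frame("indel").to_csv(out / "divergence_indel.tsv", sep="\t")
        (out / "lineages.nwk").write_text(clustering.newick + "\n")
        density_rows = []
        window, step = analysis["window"], analysis["step"]
        if window <= sim_cfg.chrom_length:
            snps = dataset.truth_variants
            snps = snps[snps["type"] == "SNP"]
            for (ha, hb, chrom), grp in snps.groupby(["hap_a", "hap_b", "chromosome"]):
                track = div_mod.window_density(
                    grp["position"].to_numpy(), sim_cfg.chrom_length, window, step,
                    pair=(ha, hb), chromosome=chrom,
                )
                for i, v in enumerate(track.values):
                    density_rows.append((ha, hb, chrom, i * step, int(v)))
        import pandas as pd

        pd.DataFrame(
            density_rows,
            columns=["hap_a", "hap_b", "chromosome", "window_start", "snp_count"],
        ).to_csv(out / "variant_density.tsv", sep="\t", index=False)
    truth_partition = sorted(sorted(g) for g in dataset.truth_lineages)
    found_partition = sorted(sorted(g) for g in clustering.partition)
    report["stages"]["divergence"] = {
        "lineage_partition": found_partition,
        "truth_partition": truth_partition,
        "partition_correct": found_partition == truth_partition,
        "newick": clustering.newick,
    }
    report["warnings"] += clustering.warnings

    # --- Ka/Ks and WGD peaks ----------------------------------------------
    with stage("kaks"):
        results = [
            kaks_mod.kaks_pair(p.seq_a, p.seq_b, pair_id=p.gene_id)
            for p in dataset.truth_cds_pairs
        ]
        dist = kaks_mod.ks_distribution(results, cutoff=analysis["ks_cutoff"])
        peaks_info: list[dict] = []
        try:
            peaks = kaks_mod.detect_ks_peaks(
                dist, min_prominence=analysis["ks_min_prominence"]
            )
            for p in peaks:
                entry = {"ks": p.location, "density": p.density}
                if analysis["mu"]:
                    entry["age_years"] = kaks_mod.date_event(
                        p.location, kaks_mod.DatingParams(mu=analysis["mu"])
                    )
                peaks_info.append(entry)
        except AnalysisError as exc:
            report["warnings"].append(f"ks peaks: {exc}")
        import pandas as pd

        pd.DataFrame(
            [
                (r.pair_id, r.n_codons, r.s_sites, r.n_sites, r.sd, r.nd,
                 r.ks, r.ka, r.ratio, ";".join(r.flags))
                for r in results
            ],
            columns=["pair_id", "n_codons", "s_sites", "n_sites", "sd", "nd",
                     "ks", "ka", "ratio", "flags"],
        ).to_csv(out / "kaks.tsv", sep="\t", index=False)
    defined_ks = [r.ks for r in results if r.ks is not None]
    report["stages"]["kaks"] = {
        "n_pairs": len(results),
        "n_defined_ks": len(defined_ks),
        "median_ks": float(np.median(defined_ks)) if defined_ks else None,
        "peaks": peaks_info,
    }

    # --- ASE ----------------------------------------------------------------
    with stage("ase"):
        if len(dataset.expression):
            calls, summary = ase_mod.classify_matrix(
                dataset.expression,
                expr_threshold=analysis["expr_threshold"],
                fold_threshold=analysis["fold_threshold"],
                hap_labels=dataset.lineage_representatives,
            )
            summary.to_csv(out / "ase_summary.tsv", sep="\t", index=False)
            by_tissue: dict[str, list] = {}
            for c in calls:
                by_tissue.setdefault(c.tissue, []).append(c)
            venn = ase_mod.intersect_ase_sets(
                by_tissue,
                {"hap1_dominant", "hap3_dominant", "higher_one_allele"},
            ) if len(by_tissue) >= 2 else {}
            fractions = {
                (row.tissue, row.ase_class): row.fraction
                for row in summary.itertuples()
                if row.ase_class != ase_mod.NOT_EXPRESSED
            }
            report["stages"]["ase"] = {
                "n_calls": len(calls),
                "fractions": {f"{t}:{c}": (None if np.isnan(f) else f)
                              for (t, c), f in fractions.items()},
                "venn": {"+".join(sorted(k)): v for k, v in venn.items()},
            }
        else:
            report["stages"]["ase"] = {"n_calls": 0}
            report["warnings"].append("ase: no expression rows simulated")

    # --- TE profile ---------------------------------------------------------
    with stage("teprofile"):
        te_by_hap: dict[str, list] = {}
        for t in dataset.te_intervals:
            te_by_hap.setdefault(t.haplotype, []).append(t)
        te_report = {}
        for hap in dataset.lineage_representatives:
            profiles = [
                te_mod.flank_te_profile(
                    g, te_by_hap.get(hap, []), sim_cfg.chrom_length,
                    analysis["te_flank"], analysis["te_window"], analysis["te_step"],
                )
                for g in dataset.gene_models[hap]
            ]
            if profiles:
                mean = te_mod.average_profiles(profiles, label=hap)
                te_mod.profile_frame(mean).to_csv(
                    out / f"te_profile_{hap}.tsv", sep="\t", index=False
                )
                te_report[hap] = {
                    "n_genes": mean.n_genes,
                    "n_windows": mean.n_windows,
                    "mean_upstream_fraction": float(np.nanmean(mean.upstream)),
                    "mean_downstream_fraction": float(np.nanmean(mean.downstream)),
                }
    report["stages"]["teprofile"] = te_report

    report["timings_s"] = timings
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report


def _jsonable(cfg: SimulationConfig) -> dict:
    from .simulate import _config_to_jsonable

    return _config_to_jsonable(cfg)


def deterministic_view(report: Mapping[str, Any]) -> dict:
    """The report minus timings, for reproducibility comparisons."""
    view = dict(report)
    view.pop("timings_s", None)
    return view
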