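# tetradiv

Haplotype-divergence analytics for autotetraploid genomes, driven by a
synthetic tetraploid data generator with known ground truth.

The package implements, as a tested reusable pipeline:

- **`tetradiv.simulate`** — a desk-scale autotetraploid simulator: four
  haplotypes in two lineages (within-lineage variant density ≪
  between-lineage), per-copy gene retention with a background rate and an
  elevated rate for a tagged pathway gene set, coding sequences diverged to
  configurable dS/dN targets, TE intervals at configurable density, and
  per-allele per-tissue expression realizing designed allele-specific
  expression (ASE) class proportions. Identical seed ⇒ byte-identical output.
- **`tetradiv.io`** — strict readers/writers for FASTA, GFF3 (1-based
  inclusive), BED (0-based half-open), and the variant/expression/anchor TSV
  dialects. Internal coordinates are 0-based half-open everywhere.
- **`tetradiv.synteny`** — homolog-anchor chaining into collinear blocks,
  consolidation of blocks separated by < 50 genes or < 300 kb (strict,
  required in both genomes by default), and gene-retention statistics:
  `retention = polyploid syntenic genes / (diploid syntenic genes × ploidy)`.
- **`tetradiv.divergence`** — sliding-window variant densities (default
  300-kb windows), symmetric SNP/InDel divergence matrices over the six
  haplotype pairs, and deterministic UPGMA clustering that recovers the
  haplotype lineage partition (Newick output).
- **`tetradiv.kaks`** — Nei–Gojobori (1986) Ka/Ks: single-mutant site
  counting, pathway-averaged difference counting with stop-path exclusion,
  Jukes–Cantor correction (undefined values flagged, never fabricated), Ks
  distributions with a saturation cutoff, KDE-based WGD peak detection, and
  dating via `T = Ks / (2μ)`.
- **`tetradiv.ase`** — TPM normalization, the four-category ASE classifier
  (TPM > 2 / 2-fold rules), exclusive Venn-region intersection across
  tissues, Welch t-tests of Ka/Ks by ASE class, and an IUPAC motif scanner
  (default `ACGTG`).
- **`tetradiv.teprofile`** — TE-density profiles in 100-bp windows (10-bp
  step) over 5-kb gene flanks, strand-oriented, union-merged intervals,
  effective-length-weighted averaging over gene sets.
- **`tetradiv.pipeline` / `tetradiv.cli`** — end-to-end orchestration with a
  reproducible JSON report.

## CLI

```bash
# end-to-end demo run on simulated data
cat > demo.yaml <<'YAML'
simulation:
  seed: 7
  n_chromosomes: 2
  chrom_length: 200000
  n_genes_per_chrom: 40
YAML
tetradiv run --config demo.yaml --out out/

# individual stages
tetradiv simulate --config demo.yaml --out sim/
tetradiv synteny --anchors sim/anchors_H1.tsv --gff-a sim/reference.gff3 \
    --gff-b sim/H1.gff3 --max-gene-gap 50 --max-bp-gap 300000 --out blocks.tsv
tetradiv divergence --variants sim/variants.tsv --window 300000 \
    --step 300000 --chrom-length 200000 --out div/
tetradiv kaks --cds sim/cds_pairs.fa --ks-peaks --mu 7e-9 --out kaks.tsv
tetradiv ase --expr sim/expression.tsv --expr-threshold 2 --fold-threshold 2 --out ase/
tetradiv teprofile --gff sim/H1.gff3 --te sim/H1.te.bed --fasta sim/H1.fa \
    --flank 5000 --window 100 --step 10 --out te.tsv
tetradiv motif --fasta sim/H1.fa --motif ACGTG
```

`out/report.json` echoes the config and seed and contains the retention
report, divergence matrix and lineage partition, Ks peaks (with ages when μ
is given), ASE summary and Venn regions, TE profiles, and stage timings.
Rerunning the same config reproduces all deterministic fields byte-identically.

## Conventions

- GFF3 positions are 1-based inclusive and BED 0-based half-open on disk;
  everything is 0-based half-open in memory.
- Sliding windows are half-open `[i·step, i·step + window)`; the last
  partial window is dropped.
- TPM exactly 2 counts as not expressed; a fold change of exactly 2 counts
  as imbalanced, so the two threshold rules partition the space.
- Gap thresholds in block consolidation are strict (`< 50` genes,
  `< 300000` bp).
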