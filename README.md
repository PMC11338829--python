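# hapweave

Reusable building blocks for turning a large inbred-crop resequencing panel
(a landrace diversity collection plus modern cultivars, wheat-scale) into a
haplotype map and breeding-genetics results:

* **Site QC** — heterozygosity-excess filtering for selfing species via the
  per-site inbreeding coefficient *F* = 1 − H<sub>obs</sub>/H<sub>exp</sub>
  against a per-chromosome ceiling
  H<sub>obs,max</sub> = 10 (1 − F<sub>median</sub>) H<sub>exp</sub>, then
  missingness (> 20%) / MAF (< 1%) filtering.
* **LD haplotype map** — D, D′ and r² from phased haplotypes; two-step
  windowed pruning (10 kb, then 50 SNPs; r² > 0.8); Gabriel-style haploblocks
  from D′ confidence intervals; merging of adjacent blocks when the lower
  quartile of inter-block |D′| exceeds 0.98; haplogroup clustering and
  landrace/modern sharing classes.
* **k-mer IBS painting** — canonical 31-mer sets, per-50-kb-window variation
  scores (zero ⇔ identical by state), affinity-propagation haplotype labels
  per 1-Mb window, minimum-tiling-path reconstruction of a cultivar as donor
  segments (longest matched-haplotype-window rule), donor contributions and a
  greedy minimum donor cover.
* **Gene CNV from read depth** — collapse of recently duplicated genes
  (CDS alignments with < 5 gaps and < 5 mismatches), per-accession depth
  normalization, GC-bias correction from a 1,000-bp-window profile, and
  copy-number bins [0–0.25), [0.25–0.75), [0.75–1.25), ….
* **Population structure support** — per-window genetic vs geographic
  (haversine) distance correlation with the r < 0.07 introgression-exclusion
  rule, pairwise IBS distance, windowed π and SNP counts, 4DTv site
  extraction.
* **NAM imputation** — projection of parental SNPs onto A/B/H/− RIL skeleton
  markers (nearest marker, haploblock-aware), population merging, pruning and
  percentage-of-environmental-mean trait standardization.
* **NIL allele effects** — per-environment BLUEs from fixed-effects trial
  models, an `AMMI` model whose `fit()` returns an `AMMIResults` object
  (main effects, SVD interaction terms, AMMI means, stability, `summary()`),
  allele-class ANOVA with environment control, trait trade-off classes, and
  the BC2 crossing-scheme background expectation (> 87.5% recurrent parent).

A `simulate` module generates the synthetic study conditions all of this is
tested against: seven Balding–Nichols ancestral groups (two founding a
"modern" mosaic panel), RILs by single-seed descent, BC2F2 NIL families,
GC-biased gene depths and multi-environment trait trials — fully
deterministic under a seed, with machine-readable truth.

## Worked example

```python
import numpy as np
from hapweave import simulate, qc, ammi

# a structured landrace panel and its modern mosaics
cfg = simulate.SimConfig(n_chrom=1, chrom_len_bp=2_000_000, n_sites=300,
                         n_groups=3, group_sizes=(10, 10, 10),
                         group_fst=0.3, seed=11)
panel = simulate.sim_group_panel(cfg)
filtered, report = qc.qc_pipeline(panel.genotypes)
print(filtered.n_sites, "of", panel.genotypes.n_sites, "sites pass QC")

# BC2F2 NIL derivations: recurrent-parent background
fams = simulate.sim_bc_nils(n_chrom=21, n_families=200, seed=1)
print("recurrent background: %.1f%%" %
      (100 * ammi.bc2_background(fams)["mean"]))
```

prints

```
282 of 300 sites pass QC
recurrent background: 89.8%
```

The synthetic panel is free of paralog artifacts, so the
heterozygosity-excess ladder removes nothing; the 18 dropped sites are
rare-allele sites caught by the MAF < 0.01 rule (group-structured
frequencies occasionally drift near fixation).  The BC2F2 families retain
~90% recurrent-parent genome outside the selected target interval, above
the 87.5% pedigree expectation because each derivation starts from the
donor-carrying RIL with the most recurrent background.

An `hapweave` command-line tool exposes the pipeline stages
(`simdata`, `qc`, `cnv`, `hapmap`, `nil`, `standardize`); each subcommand is
a thin wrapper over one library call.

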