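# Methods

This note documents the models and procedures hapweave implements, the
choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish about real data.

## Data model

Genotypes are diploid bi-allelic SNP codes (0 hom-ref, 1 het, 2 hom-alt,
−9 missing) in a sites × accessions matrix with chromosome, 1-based
position and REF/ALT per site, and an optional panel label per accession
(`landrace` / `modern` by default; labels are free strings).  Phase lives
in a separate container holding two 0/1 haplotypes per accession; windows
and block spans are 0-based half-open.  VCF I/O is GT-only VCF 4.2; all
tables are TSV with a header and a named schema.

## Site quality control

Selfing crops should be almost fully homozygous; a site with many
heterozygous calls is usually a collapsed paralogue.  The per-site
inbreeding coefficient is F = 1 − H_obs/H_exp with H_exp = 2p(1−p) over
non-missing calls (heterozygotes contribute one allele of each kind to p).
Per chromosome, F_median is the median F over sites with F > 0 and
MAF > 0.05 (even counts: mean of the two middle order statistics).  A site
is removed when H_obs > 10 (1 − F_median) H_exp, where H_exp is the site's
own expected heterozygosity — the formula juxtaposes a chromosome-level
F_median with a per-site H_exp, and the per-site reading is the one under
which the rule has its intended behaviour (a site-specific ceiling
proportional to the site's information).  Monomorphic sites carry no
heterozygosity excess and are kept.  Missingness/MAF filtering uses strict
inequalities (drop iff missing rate > 0.20 or MAF < 0.01), so boundary
sites survive.  An upstream keep-list hook accepts hard-filter decisions
made outside the package (caller-quality filters are not re-implemented).

## LD haplotype map

D, D′ and r² are computed from direct phased haplotype counts; D′ uses
Dmax = min(pA·pb, pa·pB) for D > 0 and min(pA·pB, pa·pb) for D < 0.
Pruning r² is the squared Pearson correlation of genotype dosages over
shared calls (the convention of standard genotype-based pruners);
monomorphic or data-free pairs count as r² = 0.  Greedy pruning keeps the
earlier site of an offending pair, which makes the procedure idempotent;
the two-step schedule is a 10-kb window followed by a 50-SNP window, both
with step one SNP and r² > 0.8.

Block detection follows the Gabriel confidence-interval recipe because the
upstream tool's defaults are themselves Gabriel rules: the |D′| posterior
under a flat prior on a 0.01 grid at observed allele frequencies gives a
90% interval; a pair is strong LD when CI_low ≥ 0.70 and CI_high ≥ 0.98,
recombinant when CI_high < 0.90, otherwise uninformative.  A block is a
candidate span whose endpoint pair is strong and in which ≥ 95% of
informative pairs are strong; candidates are ranked by bp length and
accepted greedily without overlap; sites are pre-filtered at MAF ≥ 0.05
and missingness ≤ 0.10 and no block exceeds 1,000 kb.  All thresholds are
keyword arguments.

Adjacent blocks merge when the lower quartile of inter-block |D′| (over
inter-block SNP pairs only; computing over the union is a flag away)
exceeds 0.98.  Q1 uses type-7 linear interpolation — the quantile
convention matters near a 0.98 cut, so it is the explicit, documented
default.  Merge passes run left-to-right to a fixpoint; termination is
guaranteed because each merge reduces the block count.

Haplogroups within a block are identity classes of complete genotype
strings, labelled by descending carrier count; strings with missing data
join the nearest class by normalized Hamming distance over jointly
observed sites (ties to the lower label); all-missing accessions stay
unlabelled.  Sharing classes between two panels: unique (zero carriers in
the other panel), enriched (carrier-frequency ratio ≥ 3 — the ratio is a
configuration value with no empirical anchor, documented as such), else
shared.

## k-mer IBS painting

Canonical 31-mers (lexicographic minimum of a k-mer and its reverse
complement; k odd so the two never coincide) are held as sorted 62-bit
integer codes.  A window's variation score counts maximal runs of
reference k-mer start positions absent from the query — one substitution
knocks out ≤ k consecutive k-mers, i.e. one run — so the score is zero iff
the window is identical by state.  This is a deliberate simplification of
the published variation statistic with the same zero/IBS semantics, and it
is documented as such rather than as a re-derivation.

Per 1-Mb window (20 consecutive 50-kb scores) accessions are clustered by
affinity propagation (damping 0.9, preference = median similarity,
negative squared Euclidean similarity, fixed random state).  Exact
duplicate vectors are collapsed first — identical accessions can never be
split — and a deterministic average-linkage fallback with
silhouette-chosen k (2..5) handles non-convergence.  Pooling syntenic
windows of multiple reference assemblies is out of scope; clustering uses
the single reference's vectors.

A query genome is reconstructed per chromosome by scanning windows
left-to-right: among donors sharing the query's label at the first
uncovered window, the donor whose matched-haplotype-window run extends
furthest wins (ties to the smallest accession id); the scan resumes after
the segment, which discards overlapping candidate runs and yields the
minimum tiling path.  Windows with no matching donor become `none` gaps.
Donor contributions are window fractions of the whole genome; the minimum
donor cover is greedy maximum coverage over (query, window) cells, which
the tests show equal to the exhaustive optimum on all panels with ≤ 10
donors.

The window-variation matrix can also be computed directly from genotypes
(count of non-reference alleles per 50-kb window), which has the same
zero-on-IBS property; the painting and cover tests run on that route at 60
one-Mb windows per chromosome — running the k-mer stage at that genome
size would add cost without changing what the tests measure, and the k-mer
route itself is verified on smaller sequences against direct enumeration.

## Gene CNV

Union–find over CDS alignment pairs with gaps < 5 and mismatches < 5
(strict, as printed) partitions genes into recent-duplicate groups whose
depths are summed onto the smallest-id representative; alignment itself is
an input table, not re-implemented.  RDV = summed depth / accession mean
coverage.  GC correction divides by factor(gc bin) = mean 1,000-bp-window
depth in the bin / mean over observed bins; empty bins borrow the nearest
observed bin.  Copy-number bins extend the printed half-open grid
[0–0.25), [0.25–0.75), [0.75–1.25) upward in 0.5 steps indefinitely.  A
non-reference bin carried in exactly one panel is that panel's unique CNV.
The depth generator uses lognormal multiplicative noise (sd 0.1 by
default) and splits a duplicate group's total depth evenly between
members, mimicking reads that cannot be assigned within the group.

## Population structure support

Genetic distance is the p-distance (mean over shared sites of
|code difference|/2) in 5-Mb tiles by default (the companion filter acts
per window; tiles rather than sliding steps, step configurable);
geographic distance is the haversine with Earth radius 6371.0088 km.  Per
window, a plain Pearson correlation over condensed pair vectors is
compared with the 0.07 cut: windows with r < 0.07 (strict) or undefined r
lose their SNPs.  The synthetic introgression windows draw every
accession's genotypes from a randomly chosen group irrespective of its own
group, which removes all geographic signal there — the mechanism the
filter targets.  Windowed diversity uses the unbiased per-site estimator
2p(1−p)·n/(n−1) summed and divided by window length; 4DTv sites are codon
third positions whose two-base prefix determines the amino acid,
strand-aware with minus-strand positions mapped back to forward
coordinates.

## NAM imputation

Skeleton markers (A/B/H/−) are validated against the parental sequence
calls (unmapped, parent-not-homozygous, monomorphic and allele-inconsistent
markers drop with reasons).  Each parental SNP site is governed by the
nearest in-block skeleton marker when its haploblock has one, else the
nearest on the chromosome; equidistant ties go to the lower coordinate,
and a RIL missing at the governing marker falls back to the next-nearest
non-missing marker in the same scope.  A governs parent 1's genotype, B
parent 2's, H the heterozygous combination of two homozygous parents (a
het parent makes inheritance ambiguous → missing).  Imputing a parent
against an all-A skeleton reproduces it exactly.

Accuracy at sites ≥ 1 cM from true breakpoints is limited by markers lying
across a breakpoint from the site they govern, i.e. by half the marker
spacing: at array-like density (1 marker / 2 cM, a desk-scale down-sample
of a 35k array on a ~3,500-cM map) recovery is ≥ 99%, while at 1 marker /
10 cM the same pipeline measures ~96% — both are pinned by tests, and the
junction density of the RIL simulator matches the Haldane–Waddington
expectation (≈1.75 junctions per Morgan per haplotype at F4).

Trait standardization divides each value by its environment's
post-exclusion mean (× 100) after removing controls and, by default,
values more than 5 MAD from the within-environment median — the outlier
rule is configurable because the original exclusion rule is not
operationally specified.

## NIL allele effects

BLUEs come from a per-environment fixed-effects line + block model
(ordinary least squares, adjusted line means averaged over blocks; a
disconnected line/block incidence graph is an error naming the
components).  `AMMI` double-centres the BLUE matrix, decomposes the
interaction residual by SVD and reports line/environment main effects,
AMMI means (grand mean + line effect), per-line stability (sum of squared
scores on the retained axes, default 2) and exact reconstruction at full
rank; missing cells are mean-imputed (row + column − grand) and flagged.

The allele-class test regresses AMMI-BLUE cells on class + environment and
F-tests the class term: the environment main effect cancels in the allelic
contrast but would inflate the error term of a plain one-way ANOVA, making
it conservative; with the environment controlled the null p-values are
uniform (verified over 500 simulated null families).  Effects are the
adjusted donor-minus-recurrent difference, also as a percentage of the
recurrent-class mean; significance is raw p < 0.05 per family.  Trade-off
classes for a trait pair: antagonistic (both significant, opposite
signs), synergistic (both significant, same sign), neutral-A/B (one
significant — the significant-improvement-with-neutral-partner case is the
antagonism-breaking pattern), both-neutral.

## BC2 crossing scheme

`sim_bc_nils` reproduces the NIL derivation: F4 RILs (three selfings under
the Haldane model, Poisson crossovers, no interference) are screened for
homozygosity of the donor allele at a target locus, and the candidate with
the most recurrent-parent alleles outside the target interval is selected
from a pool (default 24, the donor-homozygous fraction of a ~96-line
population); two backcrosses with marker-assisted donor retention and one
selfing follow, keeping a homozygous-donor sib.  The marker-selected
target interval defaults to 20 cM centred on the locus (the order of a QTL
confidence interval in such populations).  The genome is a marker grid
(151 loci per 150-cM chromosome, 21 chromosomes by default).  Without
background selection the unlinked genome sits exactly at the 87.5%
pedigree expectation while linkage drag pulls the excluding-interval mean
to ~86.7%; with it the mean is ~89.6%, above the expectation — which is
why the breeding scheme includes that selection.  Simulations run
vectorized over families (batched gametes); 1,000 derivations take well
under a minute on one CPU.

## What the synthetic conditions do not show

The generators produce idealized structure: Balding–Nichols groups have no
isolation-by-distance within groups, mosaics have exact IBS segments with
no mutation since divergence, depths have purely multiplicative lognormal
noise, k-mer tests use error-free assemblies, and trials are balanced with
Gaussian noise.  Passing tests therefore demonstrate correctness of the
procedures under their stated models — not robustness to reference bias,
mapping artifacts, segregation distortion or heteroscedastic field data.
Problem sizes throughout (hundreds of sites, dozens of accessions, tens of
Mb) are chosen so the full suite runs in about a minute; every stage is
O(data) or better in the dimensions that grow at population scale, except
the quadratic-in-sites block finder, which is windowed by the 1,000-kb
span cap.
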