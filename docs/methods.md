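# Methods

## The analysis model

All analysis operates on fixed-size genomic bins (10 kb by default)
tiling a genome whose chromosomes are classed as autosome or chrX; the
terminal bin of each chromosome is truncated and kept, with downstream
informative-site rules deciding its fate. Coordinates are 0-based
half-open everywhere internally; 1-based conventions are handled only by
reader flags.

### WGBS

Replicate CpG call sets are merged by summing counts per CpG before any
filtering, so the coverage filter applies to merged coverage. A CpG is
informative when its total coverage lies in [4, 100] reads (both ends
inclusive); a bin reports a methylation level only when it holds at
least six informative CpGs. The bin level is the pooled, read-weighted
estimator `100·Σm/Σt`, not the mean of per-site levels: the two
estimators genuinely differ when coverage is heterogeneous, and pooling
is the declared convention so tests can be exact. Category boundaries
are HMR at level ≥ 80, LMR at level < 20, MMR the remainder [20, 80);
the two explicit inequalities force the resolution of the ambiguous
middle band at both ends. Global means are unweighted means over
non-missing bins (the statistic marked on bin-distribution violin
plots); whether a CpG-weighted mean would be preferable is unknowable
from bin data alone and bin-averaging is declared. The affected /
unaffected region criteria use strict and non-strict inequalities
exactly as stated in their definitions (affected: Δ < −20 **and**
control > 40; unaffected: −10 ≤ Δ < 10 **and** control ≥ 40); the two
sets are disjoint by construction.

### ChIP / DamID enrichment

Within-sample enrichment is RPKM(treatment)/RPKM(control) per bin, with
`RPKM = count·10⁹/(bin_length·track_total)`; bins with zero control
count are missing rather than pseudocounted, since a ratio there is
meaningless and explicit missingness is testable. Because each track is
normalized by its own total, this ratio is invariant to sequencing
depth — which also means it cannot compare levels *across* samples.
Cross-genotype comparisons therefore rescale raw ChIP counts by
spike-in factors `spike_total(reference)/spike_total(sample)` first,
with the control sample as reference. These are two deliberately
distinct normalizations and only the second uses the spike-in.
Antibody specificity is the fraction of K36-methyl-state spike reads on
the target state. Gene-body enrichment pools reads over all bins
overlapping the gene interval (interval length cancels in the ratio);
the loss call requires control ratio > 1 and mutant/control < 0.67,
both ratios present. Occupancy at a threshold is computed over
non-missing bins per chromosome class with an inclusive ≥.

### Clustering

The five-cluster classification runs k-means (25 restarts, fixed seed)
on (log2 me2, log2 me3) over bins where both control ratios exist;
missing bins are excluded, not imputed. Two determinism measures are
built in: the model is fitted on a lexicographically sorted copy of the
feature matrix and then predicts the original rows, so shuffling bin
order can never change a label; and labels are renamed canonically
(cluster 1 = highest mean log2 me3, descending, ties broken by
ascending me2). No claim is made that cluster identities match any
particular published figure — the clustering algorithm behind such
figures is generally unspecified, so cluster *identities* are not an
acceptance surface, only the determinism and summary machinery.

### Allelic assignment

After excluding SNPs shared with the third strain, a read's bases at
its overlapped SNPs are tallied against the maternal and paternal
alleles; matches to neither allele (including N) are treated as
sequencing error and ignored rather than counted as conflicts, the
standard behavior of SNP-splitting tools. maternal/paternal require
purity; both-allele reads are conflicting and are excluded from the
allelic tallies but reported, so per-gene counts conserve read totals.

## The synthetic cohort

The generator emulates the study conditions on a miniature genome of
three 30 Mb autosomes plus a 17 Mb X (107 Mb, ~10,700 bins at 10 kb),
keeping a roughly realistic X:autosome length ratio at desk-scale
runtime.

**Domain structure.** Transcribed genes (lognormal lengths, mean 60 kb,
genic fraction 0.245 of sequence) define me3-genic bins; H3K36me2
domains are contiguous segments (geometric lengths, mean 25 bins)
placed in the non-genic complement until the per-class bin occupancy
hits its target — 45% of X bins, 10% of autosomal bins — within one
bin. The two marks occupy disjoint bins, reflecting their reciprocal
enrichment pattern. The genic fraction is chosen so that the solved
me3-dependent methylation component puts genic bins at ~88% baseline,
i.e. the H3K36me3 bins coincide with HMRs.

**Methylation truth.** Each bin's baseline methylation decomposes as
`preexisting + denovo_me2 + denovo_me3`: a DNMT3A-independent residue
present in nongrowing oocytes, a component deposited on me2 domains,
and a component deposited on me3 genic bins. Component means are solved
in closed form from the configured genotype global means (control 36.4,
K36M 31.0, DM 7.5, Dnmt3a-KO 6.5, all %) and the *realized* domain bin
fractions f₂, f₃:

```
preexisting = mean(DM)
m₂ = (mean(control) − mean(K36M)) / f₂        (per me2-domain bin)
m₃ = (mean(control) − preexisting − f₂·m₂) / f₃   (per genic bin)
```

Per-bin values jitter around these means but are exactly recentred, so
truth-level calibration is exact and every observed deviation in the
pipeline output is attributable to the read model. Genotypes act
component-wise: K36M removes denovo_me2 (and scales me2 enrichment by
0.2); Setd2-KO removes denovo_me3, zeroes me3 enrichment, and adds a
+15-point gain inside me2 domains (no printed effect size exists for
this gain; 15 points is a package default, not a reproduced value); DM
removes both de novo components, leaving exactly the preexisting
residue per bin; Dnmt3a-KO retains 6.5/7.5 of the residue, sitting
slightly below DM as configured.

**Read models.** CpG positions have exponential spacing (mean 100 bp);
coverage is negative binomial (mean 15, var = mean + 0.3·mean²); site
methylation probabilities draw from a Beta around the bin truth
(concentration 50 — realistic within-bin heterogeneity without
destroying bin means); methylated counts are binomial. ChIP and input
bin counts are Poisson with per-sample lognormal library-depth factors
(σ = 0.4) so that spike-in normalization is genuinely needed; the ChIP
rate is `background + ratio·scale` with a 1% nonspecific background, so
a genotype whose mark scale is zero produces flat, input-like counts.
True enrichment ratios are constructed with length-weighted mean
exactly 1 (domain draws above the call threshold with a floor at 1.6
for me2 / 1.7 for me3, background solved to balance), because an
RPKM/RPKM ratio self-normalizes by the genome-mean enrichment — without
this constraint no generator could make observed ratios agree with
truth ratios. Spike-in totals scale with the library factor and split
multinomially over the barcode panel with on-target fraction 0.95.
Allelic reads place 100 bp reads uniformly in genes, draw a maternal
allele per read and corrupt bases at 0.5% into a uniform random base.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: bisulfite conversion failure and
non-CG methylation; mappability, GC and copy-number biases; correlated
coverage along reads (sites are independent given the bin);
fragment-size and peak-shape effects in ChIP; PCR duplicates; imprinted
or ICR-specific behavior; and real gene/SNP annotation. Recovery of the
calibrated statistics demonstrates the correctness of the filters,
estimators and normalizations, not robustness to these artifacts.

## Numerical and design choices

* Random streams are `numpy` PCG64 generators keyed by (seed, stage
  tag, sample tag), so every simulated object is independently
  reproducible and genotypes never share a stream.
* Component jitter is recentred exactly and, after non-negativity
  clipping, rescaled multiplicatively, keeping calibration exact; the
  build fails if any bin's baseline would exceed 100%.
* On genomes so small that the realized genic bin fraction makes the
  solved m₃ infeasible (genic baseline above ~97%), the build raises
  rather than silently clipping; tiny test genomes pass a larger
  genic fraction instead.
* Degenerate inputs: zero occupancy targets yield zero domains (the
  associated genotype means are then unreachable by design); clustering
  refuses fewer distinct points than clusters; summaries refuse
  all-missing methylomes and warn when one chromosome class is empty.
* The acceptance script runs the default-scale cohort (~1.07 M CpGs per
  genotype, four WGBS genotypes and one ChIP pair) in a few seconds;
  the heavier test fixtures use a 5 Mb genome, sizes chosen so the
  statistical assertions retain power.

## Known limitations

The five-cluster identities are algorithm-dependent and not comparable
across tools. The Dnmt3a-KO model is a phenomenological rescaling of
the preexisting residue, not a mechanism. Gene-level enrichment uses a
bin-overlap surrogate rather than exact read-interval intersection, a
~1-bin edge effect for short genes. Real-data mode expects pre-computed
per-CpG call tables and per-bin count tables; alignment, deduplication
and MAPQ filtering are upstream concerns.
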