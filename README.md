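# oometh

Binned analysis of the oocyte epigenome: how the histone marks H3K36me2
and H3K36me3 partition the genome of fully grown mouse oocytes (FGOs)
into chromatin territories that guide DNMT3A-dependent de novo CG
methylation — and what happens to the methylome when either or both
marks are removed.

The package is aimed at epigenomics analysts working with whole-genome
bisulfite sequencing (WGBS), spike-in-normalized ChIP-seq/CUT&RUN, and
allele-resolved RNA-seq of scarce material such as oocytes. It
implements the complete bin-level analysis stack plus a calibrated
synthetic-cohort generator, so every stage is testable end-to-end
without any sequencing download.

## What it computes

**WGBS methylome (10 kb bins).** CG sites with merged coverage of 4–100
reads are *informative*; a bin reports a level only with more than five
informative CpGs, as the pooled (read-weighted) estimator

```
level(bin) = 100 · Σ meth_count / Σ total_count   over informative CpGs
```

Bins are categorized as HMR (≥ 80%), MMR (20–80%) or LMR (< 20%);
per-genotype tracks are compared through ΔCGme = mutant − control, and
regions are called *affected* (ΔCGme < −20 and control > 40) or
*unaffected* (−10 ≤ ΔCGme < 10 and control ≥ 40).

**Histone-mark enrichment.** Per-bin ChIP/input enrichment is the ratio
of RPKM-normalized tracks (`RPKM = count · 10⁹ / (bin_length · total)`);
cross-genotype level comparisons first rescale counts by spike-in
factors `spike_total(reference) / spike_total(sample)` from a barcoded
nucleosome panel, which also yields antibody specificity
(`target / Σ K36-methyl states`). Occupancy is the per-chromosome-class
fraction of bins with ratio ≥ 1.4 (me2) or ≥ 1.5 (me3); genes lose
H3K36me2 when control ChIP/input > 1 and mutant/control < 0.67. The
same ratio machinery serves DamID lamina tracks.

**Chromatin clusters.** Bins are grouped into five clusters by k-means
on (log2 me2, log2 me3) in the control sample, with canonical,
permutation-invariant labels, and summarized per cluster.

**Allelic expression.** Reads are classified maternal / paternal /
unassigned / conflicting from their base calls at strain-specific SNPs
(SNPs shared with the third strain in the cross are excluded first).

**Synthetic cohorts.** A miniature genome (3 × 30 Mb autosomes + 17 Mb
X) carries broad H3K36me2 domains (45% of X bins, 10% of autosomal
bins), H3K36me3-high transcribed genes, and a three-component truth
methylome calibrated in closed form so that the control, K36M,
double-mutant and Dnmt3a-KO genotypes have global means of 36.4%,
31.0%, 7.5% and 6.5%.

## Worked example

```python
import oometh as om

cfg = om.SimulationConfig(seed=42)
cohort = om.generate_cohort(cfg, genotypes=("control", "K36M"),
                            chip_experiments=(("me2", "control"),))

for g in ("control", "K36M"):
    calls = om.filter_informative_calls(cohort.wgbs[g])
    bm = om.compute_bin_methylation(calls, cohort.grid)
    s = om.methylome_summary(bm)
    print(f"{g:8s} global mean = {s.global_mean:5.1f}%  HMR/MMR/LMR = "
          + "/".join(f"{s.category_fractions[c]:.2f}" for c in ("HMR", "MMR", "LMR")))

exp = cohort.chip[("me2", "control")]
track = om.bin_enrichment_ratio(exp.chip, exp.input, mark="me2")
occ = om.enriched_occupancy(track, cohort.grid.layout, 1.4)
print(f"H3K36me2 occupancy (ratio >= 1.4): chrX {100*occ['chrX']:.1f}%, "
      f"autosomes {100*occ['autosome']:.1f}%")
print(f"anti-H3K36me2 specificity: "
      f"{om.antibody_specificity(exp.spike_in, 'K36me2'):.3f}")
```

prints

```
control  global mean =  36.4%  HMR/MMR/LMR = 0.29/0.16/0.55
K36M     global mean =  31.0%  HMR/MMR/LMR = 0.29/0.00/0.71
H3K36me2 occupancy (ratio >= 1.4): chrX 44.9%, autosomes 10.0%
anti-H3K36me2 specificity: 0.950
```

Reading: the control methylome averages 36.4% with a large
moderately-methylated compartment; expressing the K36M onco-histone
removes the H3K36me2-dependent methylation, dropping the global mean to
31.0% and emptying the MMR class into LMRs (the X chromosome, where me2
domains cover ~45% of bins versus ~10% on autosomes, is hit hardest).
The spike-in panel confirms the me2 antibody reads 95% on-target.

A CLI mirrors the stages:

```sh
oometh wgbs --seed 42          # per-genotype methylome summaries
oometh chip --seed 42          # occupancies, specificity, gene-loss count
oometh run-all --seed 42 --out rundir   # full pipeline + track files
```

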