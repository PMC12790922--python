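# mitocohort

Cohort-scale analysis of the human mitochondrial genome from deep
whole-genome sequencing: high-quality mtDNA variant curation with
heteroplasmy classification, discovery of non-reference NUMTs (nuclear
mitochondrial DNA segments) from paired-end alignment evidence,
breakpoint enrichment statistics, extraction of invariable mtDNA
intervals, and association scans between mtDNA heteroplasmic levels and
nuclear genotypes. Every stage is exercisable end to end on synthetic
cohorts with planted truth, so the whole pipeline is testable without
access-restricted human data.

It is aimed at population and mitochondrial geneticists who have
per-sample mtDNA variant calls (VCF with AD/DP), alignment-derived
discordant/split-read evidence, and genotype dosage matrices, and want
a tested, scriptable reimplementation of the standard cohort analyses.

## The models and statistics

**Heteroplasmy.** For a call with alt depth AD and total depth DP, the
variant allele fraction is VAF = AD/DP. Retained calls require
FILTER = PASS, DP > 100, VAF ≥ 0.1, and a position outside known WGS
artifact/low-complexity sites (66–71, 301, 302, 310, 316, 3107,
12418–12425, 16182–16194 on rCRS). Calls with VAF ≥ 0.95 are
homoplasmic, 0.10 ≤ VAF < 0.95 heteroplasmic. Samples are dropped for
nDNA contamination > 2%, a phylogeny-based mtDNA contamination flag, or
mtDNA copy number = 2 × (mean mtDNA depth / mean autosomal depth) < 50.
Distinct variants aggregate carriers into frequency classes: common
(F ≥ 1%), rare (0.1% ≤ F < 1%), ultra-rare (F < 0.1%), private (one
carrier). Regional over-representation uses a one-tailed hypergeometric
test against the 16,569 bp genome as background.

**NUMT detection.** Read pairs with exactly one mate on chrM are
single-linkage clustered per sample on the nuclear axis (max gap
500 bp); clusters with < 5 pairs are discarded; clusters within
1000 bp across samples form one event; split reads within 500 bp
flanks refine breakpoints, requiring ≥ 2 reads in exact agreement on a
(nuclear, mitochondrial) junction. Insertion size is the arc length
between the two mitochondrial breakpoints on the circular genome
(identical breakpoints mean a full-circle insertion of 16,568 bp).
Events overlapping a published NUMT set padded by ±500 bp are flagged
known.

**Breakpoint enrichment.** Nuclear insertion windows (±100 bp) are
compared against annotation tracks with a permutation test: 10,000
resampled sets of uniform random positions, upper tail,
p = (#{null ≥ observed} + 1)/(n_perm + 1).

**Invariable intervals.** A position is variable when an SNV hits it or
a deletion removes it (left-anchored VCF convention); insertions break
interval continuity at their anchor without consuming bases. Maximal
invariable runs satisfy the identity |variable| + |invariable| = 16,569
by construction, and interval sets from multiple cohorts intersect
positionwise.

**mtDNA–nDNA association.** Heteroplasmic levels of common mtDNA
variants (carrier frequency ≥ 5%, non-carriers at 0) are regressed on
nuclear dosages that pass call-rate > 0.9, MAF > 5% and exact
Hardy–Weinberg p ≥ 1e-6 filters, with the top genotype PCs and sex as
covariates. Significance uses BH q < 0.05/n_mt (primary) and
p < 5×10⁻⁸/n_mt (stringent); with n_mt = 93 these are 5.4×10⁻⁴ and
5.4×10⁻¹⁰.

## Worked example

Plant eight NUMT insertions (plus four sub-threshold decoys) in a
synthetic 20-sample cohort and call them back:

```python
from mitocohort.synthetic_data import gen_numt_reads
from mitocohort.numt_detect import call_numts, per_sample_numt_stats

records, truth = gen_numt_reads(n_samples=20, n_insertions=8, n_decoys=4, seed=7)
events = call_numts(records, n_cohort=20)
print(f"{len(events)} NUMT events called from {len(records)} alignment records")
for ev in events[:3]:
    print(f"  {ev.event_id}  {ev.nuclear_chrom}:{ev.nuclear_bp_left}-{ev.nuclear_bp_right}"
          f"  arc chrM:{ev.mito_bp_a}->{ev.mito_bp_b}  size={ev.size_bp} bp"
          f"  carriers={ev.n_samples}  class={ev.freq_category}  refined={ev.refined}")
counts, mean, sd = per_sample_numt_stats(events, truth.extras["samples"])
print(f"per-sample NUMT count: mean={mean:.2f}, SD={sd:.2f}")
```

prints

```
8 NUMT events called from 577 alignment records
  NUMT_00001  chr1:1126316-1126317  arc chrM:9446->9603  size=157 bp  carriers=4  class=common  refined=True
  NUMT_00002  chr1:2891382-2891383  arc chrM:14352->14404  size=52 bp  carriers=3  class=common  refined=True
  NUMT_00003  chr1:3125349-3125350  arc chrM:8967->9292  size=325 bp  carriers=3  class=common  refined=True
per-sample NUMT count: mean=1.15, SD=0.93
```

All eight planted insertions are recovered with breakpoint-exact
refinement (`refined=True` means both junctions were confirmed by ≥ 2
split reads each), the four decoys are absent, and each event carries a
population-frequency class computed over the 20-sample cohort. The same
flow is available from the shell:

```bash
mitocohort simulate numt-reads --seed 7 --out sim/
mitocohort numt-call --alignments sim/alignments.tsv --n-cohort 20 --out events.tsv
mitocohort run --out run/ --seed 7   # full multi-stage pipeline
```

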