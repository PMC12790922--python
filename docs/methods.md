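# Methods

This note documents the models, parameter choices and numerical
conventions behind `mitocohort`, and what the synthetic-data tests do
and do not demonstrate about real cohorts.

## Coordinates and reference

All mtDNA positions are 1-based inclusive on rCRS (NC_012920.1,
16,569 bp, circular); BED I/O is 0-based half-open, converted only at
the I/O boundary; mitochondrial contig names (`MT`, `chrM`, `chrMT`,
`M`) unify internally to `chrM`. The bundled region table flattens the
canonical rCRS gene annotation into a complete non-overlapping tiling;
where features overlap (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, abutting
tRNAs) precedence is tRNA > rRNA > protein-coding > D-loop >
intergenic, ties going to the earlier-starting feature. This single
deterministic label per position is what variant and breakpoint
annotation report; users needing overlapping annotations should query
`RCRS_REGIONS` directly.

Circular arc arithmetic is centralized in `mitocohort.circular` and
shared between the NUMT caller and the read simulator. A forward arc
from a to b spans (b − a) mod 16,569 bases; identical breakpoints
denote a full-circle insertion of 16,568 bases, because the junction
base is not duplicated. When no orientation evidence exists the
shorter arc is reported.

## mtDNA variant curation

Tunable parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `max_contamination` | 0.02 | nDNA-based contamination fraction above which a sample is dropped (strict >) |
| `min_copy_number` | 50 | mtDNA copies/cell, 2 × mean mtDNA depth / mean autosomal depth; drop below (strict <) |
| `min_insert_size` | 250 bp | NUMT-mode sample filter; exactly 250 is kept |
| `min_dp` | 100× | per-call depth; a call at exactly 100 is dropped (strict >) |
| `min_vaf` | 0.1 | high-quality VAF floor (inclusive ≥) |
| homoplasmy bound | 0.95 | VAF ≥ 0.95 homoplasmic; [0.10, 0.95) heteroplasmic |

Boundary semantics follow the definitions of each filter as stated
above and are asserted in tests. The artifact/low-complexity exclusion
set is hard-coded in `io_formats.ARTIFACT_POSITIONS`; records at these
sites are read and flagged rather than silently dropped, so drop
reasons stay auditable. The nDNA:mtDNA depth-ratio 0.04 check is a
per-sample diagnostic report (`depth_ratio_diagnostic`), not a variant
filter — its role is to justify the 0.1 VAF floor, not to remove
calls. Multi-allelic records are split per ALT using the per-allele AD;
a VCF lacking per-allele AD is a hard error rather than a proportional
guess.

Frequency classes use exact rational arithmetic (`fractions.Fraction`)
so bin boundaries (F = 1%, F = 0.1%) classify exactly; `private` is
checked before the frequency bins. MitoTIP scores falling exactly on a
published bin boundary (16.25, 12.66, 8.44) go to the lower bin; the
published ranges are ambiguous at the boundary, and the lower-bin rule
is stated in the classifier docstring.

Substitution classes are reported on both strands: VCF alleles sit on
the reference (light) strand under the rCRS convention, and the
heavy-strand class is the complement pair.

## NUMT detection

"Within 500 bp" clustering is implemented as single-linkage chaining
of sorted nuclear positions with a maximum successive gap of 500 bp —
equivalent to connected components of the ≤ 500 bp adjacency graph,
which the tests verify against a brute-force all-pairs oracle. Cluster
span is therefore uncapped; supporting evidence from a long insertion
is not split arbitrarily. Cross-sample grouping anchors on cluster
span midpoints with a 1000 bp single-linkage cap.

Breakpoint refinement requires *exact* junction agreement between at
least two split reads, separately for the left junction (nuclear
breakpoint joined to the arc start) and the right junction (joined to
the arc end); an event is `refined` only when both junctions are
confirmed. Events failing refinement are retained unrefined so
frequency accounting over all events is unaffected. More than two
confirmed junctions is the signature of a concatenated or complex
insertion; such events are left unrefined rather than given arbitrary
breakpoints.

The split aligner is a pluggable callable. The default,
`segment_junction_aligner`, consumes the two-locus segment coordinates
already carried by split records (the form emitted by
samblaster-style preprocessing and by the read simulator); any
sequence-level realigner can be substituted as long as it maps a
clipped read to a (nuclear, mito) junction. Aligner failure on a
single read is logged and skipped, never fatal to the event.

`min_mapq` for discordant mates defaults to 20. Per-sample summary
statistics use the sample standard deviation (ddof = 1).

## Breakpoint enrichment

The permutation test draws each null set uniformly over the genome
defined by `chrom_sizes` (a per-chromosome option exists for users who
prefer matched-chromosome nulls); windows extending past a chromosome
end are truncated, not discarded; no gap or blacklist masking is
applied by default, though a masked track can simply be supplied as
the genome. The p-value uses the add-one convention
(null ≥ observed + 1)/(n_perm + 1): it can never be zero, its floor at
1/(n_perm + 1) matches the granularity of permutation testing, and
fixing the seed fixes p exactly. The test is upper-tailed (enrichment
only). Null calibration — the fraction of p ≤ 0.05 under a uniform
event model staying inside binomial 99% bounds — is asserted over
hundreds of replicate synthetic genomes.

Region-normalised mitochondrial breakpoint counts flag regions shorter
than `min_region_len` (default 200 bp) as excluded: a density over a
70 bp tRNA is dominated by sampling noise.

## Invariable intervals

Deletion footprints exclude the left-anchored VCF anchor base
(REF=ACT ALT=A at p marks p+1, p+2 variable). An insertion splits the
interval at its anchor gap without marking any base variable, so the
conservation identity |variable| + |invariable| = 16,569 holds exactly
for every cohort and is asserted on every pipeline run. The
16,569 → 1 adjacency is not joined; intervals are linear. Length-1
runs are included in output with a length column so "> 1 nt" and
"> 10 nt" summaries are derivable downstream. Cross-cohort sharing is
a positionwise intersection re-segmented into maximal runs, filtered
to length strictly greater than `min_len` (default 10). Conservation
score comparison (phastCons/phyloP) is supported as a user-supplied
per-base score track joined by a one-tailed rank-sum test; the package
computes no conservation scores itself.

## Association scan

The scan residualizes the covariates (intercept, top genotype PCs,
sex) out of both phenotype and dosages by QR decomposition, then takes
per-variant slopes; this is algebraically identical to full-design OLS
(verified against statsmodels to 1e-8 relative) at a fraction of the
cost, with df = n − n_covariates − 2. Missing dosages are mean-imputed
per variant for the scan and the PCA only; the call-rate filter runs
first, samples before variants. MAF uses non-missing dosages. The HWE
filter is the exact conditional test on heterozygote counts (no mid-p),
computed in log-gamma space and cross-checked against exact rational
enumeration at small n; a chi-square alternative was deliberately not
made the default, matching standard GWAS practice.

The primary significance rule is `q_BH < alpha/n_mt` exactly as the
divisor-based rule is conventionally stated for this analysis, even
though dividing a BH q-value threshold by the phenotype count mixes
two correction styles; a `bonferroni_on_p` switch provides the
conventional alternative. mtDNA phenotype selection uses minor-allele
carrier frequency ≥ 5% (a major-allele > 5% rule would be vacuous), and
non-carriers receive phenotype 0.0 — required for homoplasmic common
variants to vary at all. Constant or covariate-collinear dosages yield
NaN-flagged results rather than silent drops. PCA signs are fixed by
making each component's largest-magnitude loading positive, so scores
are reproducible across runs.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all recovery tests:

* **mtDNA cohort** — site depth ~3000× (Normal, 10% CV), ~36 variants
  per sample, 97.8%/2.2% homoplasmic/heteroplasmic call mix. True
  heteroplasmic VAFs are uniform on [0.15, 0.90] and homoplasmic on
  [0.97, 1.0] — inside the classification bins, far enough from the
  0.95/0.10 boundaries that binomial depth sampling at 3000× cannot
  flip a class; in `noiseless` mode AD = round(VAF × DP) and class
  recovery must be exact. Spurious calls are injected at artifact
  sites, below the VAF floor, below the depth floor and with non-PASS
  filters to exercise every filter arm.
* **NUMT reads** — insertions at mutually separated nuclear junctions
  (≥ 5 kb, so grouping never merges distinct truths), arcs log-uniform
  on 50–2000 bp (short-insertion dominance at the ~119 bp median
  scale), 5–12 discordant pairs per carrier, 3 junction-exact split
  reads per side, insert size 500 bp / reads 150 bp, plus concordant,
  nuclear-nuclear and chrM-internal background noise. Decoys are
  planted with 1–4 pairs and must never be called.
* **Association** — binomial(2, p) genotypes, optional two-population
  allele-frequency shift driving PC1 with an optional phenotype
  confound, planted effects β on a [0, 1]-clipped phenotype whose
  baseline (0.4) keeps clipping inactive at the default effect and
  noise sizes (σ = 0.05).
* **Tracks** — equal-length non-overlapping intervals at an exactly
  realized coverage fraction via a uniform gap composition.

Passing these tests shows the algorithms are correct under their own
evidence model. They do not demonstrate robustness to alignment
artifacts around real NUMT junctions, reference-NUMT cross-mapping,
index hopping, LD structure, relatedness, or depth heterogeneity along
the mitochondrial genome — real-data features the generators
deliberately do not model. Sample QC inputs (contamination fractions,
phylogeny flags) are consumed as precomputed fields, mirroring their
origin in external tools.

## Problem sizes and determinism

The default test and acceptance runs use 40–50-sample mtDNA cohorts,
50 planted NUMTs with 50 decoys over a 5 Mb nuclear segment, 500
clustering-oracle instances of ≤ 200 pairs, 500 permutation-calibration
replicates at 1000 permutations, association at n = 2000 (recovery) and
1200 null SNPs (calibration), and 1000 brute-force interval oracles —
sizes at which every oracle comparison is exhaustive while the whole
suite completes in well under a minute. One global seed fans out per
stage via `numpy.random.SeedSequence.spawn` (kept below 2³¹); reruns
with the same config and seed are byte-identical, which the pipeline
tests assert on the output files themselves.

## Known limitations

* The NUMT caller does not genotype homozygosity, assemble inserted
  sequence, or mask reference (assembly-fixed) NUMTs.
* Only simple two-junction insertions receive refined breakpoints;
  concatenated/complex events are retained unrefined.
* The association module fits OLS only — no mixed models, kinship
  correction or LD pruning (PCA-input pruning is left to the user).
* Haplogroup assignment, pathogenicity prediction and external
  annotation (VEP-class tools) are consumed as inputs, never computed.
* Enrichment nulls are uniform; GC- or length-matched permutation
  schemes are out of scope.
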