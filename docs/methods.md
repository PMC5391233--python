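# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `epidrift`, in the order data flows through the
package.

## Competitive quantification model

Each amplicon is co-amplified from mouse cDNA and from rat genomic DNA added
as a fixed competitive standard. Because both templates share the same primer
sites and differ only at inter-species variant (ISV) positions, amplification
efficiency largely cancels in the ratio of mouse to rat reads (M/R), which is
therefore used as the abundance measure. Assumptions: the rat spike-in is
constant per reaction and independent of the sample's expression state;
species assignment errors are negligible (enforced by the exact-identity
rule); residual amplicon-specific ratio bias is multiplicative and stable, so
a single known-mixture control can remove it.

### Reference construction

* The provisional reference stores both species' co-aligned sequences per
  amplicon; putative ISVs are their mismatch positions. Pairs with zero
  mismatches are flagged — they can never discriminate species.
* Calibration reads (pure mouse, pure rat) are attributed to amplicons by
  ungapped identity against the whole panel, best match wins. Matching is
  exhaustive rather than heuristic: at a few hundred amplicons of ~150 bp,
  exact scoring has the same selectivity as a seeded aligner with none of the
  external-binary dependency. Ties between amplicons set the read aside
  (never split); reads under 90 % identity to every amplicon are set aside.
* Consensus rule: at each aligned position, alleles carried by at least 25 %
  of the reads covering that position are retained; frequencies are computed
  over covering reads (not total reads) to tolerate length-trimmed reads.
  The consensus *set* is the set of read-supported full-length haplotypes
  whose every base is a retained allele, plus the per-position majority
  consensus (ties broken alphabetically for determinism). Applying the
  threshold per position and then filtering haplotypes coincides with a pure
  per-haplotype reading whenever at most two positions vary, which covers the
  default panels; the positional reading is the one implemented.
* Pileups with fewer than 10 reads are excluded (`insufficient_reads`)
  rather than risking a noise consensus; the floor is configurable.
* An amplicon is discarded when any mouse consensus sequence equals any rat
  consensus sequence (`identical_consensus`) or when either species lacks a
  usable consensus. Retention soundness (every retained cross-species pair
  differs somewhere) is asserted exhaustively after every build.

### Read processing and assignment

* Pair merging is an in-repo overlap merger: the best offset maximizes
  matches − 4 × mismatches over overlaps ≥ 20 bp with mismatch fraction
  ≤ 0.1; ties prefer the larger overlap. Overlap disagreements take the
  higher-quality base; quality ties keep R1. Merged reads containing an
  ambiguous base (N) are rejected.
* Assignment: a read is counted for (amplicon, species) only if it equals a
  consensus sequence — or a terminal (prefix/suffix) span of one — with
  100 % identity over at least 90 % of that reference's length. Internal-gap
  or mismatched alignments never count; reads matching two amplicons are
  discarded as ambiguous. This makes substitution errors self-censoring:
  an erroneous read is far more likely to match nothing than to match the
  other species (measured cross-species flip rate < 10⁻³ at 0.5 % per-base
  error with 2 ISVs).
* Ratios: M/R = mouse/rat per amplicon. The default keeps the arithmetic
  exact — an amplicon with zero rat reads is flagged missing rather than
  imputed; a pseudocount (0.5 on both numerator and denominator) is available
  for workflows that prefer finite ratios.
* Bias correction: corrected = raw ÷ (control observed / control expected),
  with expected 1.0 for an equimolar control. The stage is isolated behind
  one operation and is the identity when no control is supplied.
* Normalization divides each sample's corrected ratios by their mean over
  non-missing amplicons, making the mean relative abundance exactly 1
  (enforced to 1e-9). This is compositional: a planted k-fold change on a
  subset of amplicons appears as less than k-fold after normalization
  because the mean shifts too; contrasts meant to recover planted absolute
  shifts should use the corrected (un-normalized) ratios.

## Expression statistics

* DETS: Welch t-test on log₂ RA per amplicon with Benjamini–Hochberg FDR
  across all tested amplicons in the run; an amplicon passes at
  |log₂FC| > 1 and FDR < 0.01. Count-model frameworks (DESeq2-style
  negative-binomial shrinkage) are the common alternative for this task; the
  Welch-on-log-ratios choice is deliberate — the verification surface here is
  recovery of planted truth, not equality with a particular count model —
  and a negative-binomial Wald variant on raw mouse counts is available
  behind `method="nb_wald"`.
  Zero-variance amplicons are dropped from testing with a log entry.
* Paired tests pair **amplicons** across conditions (the only unit shared
  between the compared groups): category-level age effects use a one-sample
  t on per-amplicon log₂ fold changes vs 0 within genotype, and a paired t
  of each amplicon's HD fold change against its wt fold change for the
  genotype contrast. Exactly-zero difference vectors return p = 1 (perfectly
  consistent with the null); constant nonzero vectors return p = 0.
* PCA operates on log₂-transformed, per-amplicon-centered profiles with a
  full SVD (deterministic up to sign). Pearson correlations are computed on
  the RA columns; zero-variance samples get NaN rows/columns.
* The amplicon bipartition z-scores log₂ profiles per amplicon and runs
  2-means with a fixed seed and 10 restarts (a Ward-linkage cut is available
  behind `method="ward"`); the cluster with the higher mean over the aged
  samples is labeled `aged_high`.

## DNase accessibility

* TSS convention: BED interval start on '+', end − 1 on '−'; duplicates
  collapse. Windows are half-open [TSS − 2000, TSS + 2000) split into
  40 × 100 bp bins, bin order flipped on '−' so upstream is always left.
* A fragment contributes to the single bin containing its midpoint
  ((start + end) // 2). The midpoint rule avoids double-counting 50–100 bp
  fragments across bins. Consequence: profile reflection symmetry (mirror
  the genome, flip all strands) is exact except for even-length fragments
  (integer midpoint shifts by one cell under reflection) and midpoints
  sitting exactly on a bin boundary; the property test states the invariant
  on odd-length, off-boundary fragments.
* Depth normalization scales each group to counts per million fragments.
  The 2-fold differential classification uses (HD + 1)/(wt + 1) on per-TSS
  window totals — the unit pseudo-floor keeps empty promoters finite.
* Clustering: k-means (k = 2, fixed seed, 10 restarts) on the per-TSS
  concatenation of the HD and wt binned profiles after log1p; the cluster
  with the higher mean signal is labeled cluster 1 (the dense minority).
  Per-cluster contrasts report the HD/wt ratio of mean ±300 bp core density
  with a two-sided Wilcoxon rank-sum across TSSs (chosen for robustness to
  the heavy-tailed per-TSS counts; Welch t behind a flag).
* Parameter-recovery runs contrast the **raw** count matrices: the simulator
  plants per-TSS HD/wt fold effects under equal per-fragment sampling, and
  per-million scaling would rescale the two groups by their different totals
  and shift every recovered fold by that global ratio (~7 % at the default
  effect sizes). CPM remains the default pipeline step for real groups of
  unequal sequencing depth, where that global factor is exactly the nuisance
  to remove.
* Gene-set accessibility reports each resolvable gene's cluster and whether
  HD core density exceeds wt; exact ties are neutral and excluded from the
  summary proportion.

## Synthetic-data generators

All generators are pure functions of (spec, seed) — regeneration is
byte-identical — and every planted quantity is recorded in a truth object so
downstream operations can be scored by parameter recovery alone.

* **Panel**: i.i.d. bases at a configurable GC fraction; exactly
  `n_isv_per_amplicon` planted substitutions distinguish the rat sequence
  (default 2 — the regime the assay targets: as few variants as possible
  while remaining discriminable). Default amplicon length 150 bp, read
  length 100 bp, so error-free pairs overlap by 50 bp and merge exactly.
  Categories are assigned round-robin from the epi-driver vocabulary so
  every study category is populated.
* **Reads**: per amplicon, mouse-origin pair counts are
  Binomial(depth, mouse fraction) (or pinned exactly); substitution errors
  are independent per base and per mate at a configurable rate (default
  0.1 %, a typical short-read substitution scale; the platform's true error
  profile is not modeled — no indels, no quality-dependent errors, constant
  Phred strings). Indels are deliberately excluded: under the exact-identity
  assignment rule they are indistinguishable from substitution failures at
  this scale.
* **Study**: 2×2 genotype-by-age design, 4 replicates per group by default.
  Mouse counts are negative-binomial with mean baseline × 2^(planted log₂FC)
  and dispersion 0.05 (variance = m + 0.05 m², a moderate bulk-RNA
  overdispersion); rat counts are Poisson around a constant spike mean set
  by the spike-in fraction (default 0.5, i.e. competitor ≈ baseline),
  independent of expression. Default planted effect signs follow the
  study-level directions: senescence up with age in both genotypes,
  acetylation down in both, lysine-(de)methylation up in aged HD but down in
  aged wt, Polycomb complex down and its targets strongly up in aged HD
  (+3 log₂) and weakly in wt, maintenance DNA methylation down in aged HD.
* **DNase fragments**: the first ⌈0.136 · n⌉ TSSs form the dense cluster
  (deterministic so cluster sizes are exact; Bernoulli assignment is an
  option). Per-TSS fragment counts are Poisson with cluster means 400
  (dense) and 40 (shallow) in wt — a ten-fold signal separation that makes
  the two-cluster structure unambiguous — multiplied in HD by the planted
  per-cluster folds (defaults 0.704 and 1.287: a mild depletion of the dense
  cluster and a ~30 % enrichment of the shallow one, simulation parameters
  rather than claims about any dataset). Fragment midpoints follow a
  Gaussian (σ = 300 bp) truncated to the ±2 kb window, so window totals
  equal the truth exactly; lengths are uniform on 50–100 bp, the
  size-selected digestion range. Synthetic TSSs are spaced 10 kb apart so
  windows never overlap — real promoters can share fragments between
  overlapping windows, which the conservation tally handles but the
  generator does not exercise.

What passing tests therefore show: the pipeline's rules are implemented
exactly (oracle equivalence), planted parameters are recovered at realistic
depths, and the statistics are calibrated under the generator's noise model.
What they do not show: robustness to PCR chimeras, indels, quality-dependent
error profiles, primer-pool structure, batch effects, or annotation quirks
of real genomes — none of which the generator emulates.

## Verification design notes

* The consensus caller is checked against a brute-force enumeration over all
  read-supported haplotypes on pileups of ≤ 8 reads × ≤ 12 positions, and
  the assignment rule against an exhaustive restatement of the
  identity/coverage conditions; the BH adjustment against a from-definition
  step-up on ≤ 12 p-values.
* Quantification linearity is verified through the full FASTQ path at depth
  1000 per amplicon with planted ratios spanning 10⁻²–10². The log-log slope
  recovers 1 within 0.05 and normalization is exactly mean-1. A per-amplicon
  10 % recovery bound at these settings is **not attainable for the extreme
  ratios**: with ~10 reads on the minority side, the binomial loss imposed
  by the exact-identity rule (~15 % of reads carry an error and are
  correctly censored) contributes a ~13 % standard deviation by itself; the
  corresponding acceptance check documents this and is expected to fail at
  its strict tolerance while the slope and mean-1 checks pass.
* The bias-correction oracle plants ×0.5–×2 per-amplicon ratio bias on
  deterministic expected counts, isolating the systematic component the
  control calibration exists to remove (exact recovery), and separately
  checks on binomially sampled counts that correction shrinks deviations
  far below the planted bias. Conflating the two would test counting noise,
  not the correction.
* Problem sizes in the test-suite and acceptance script (24–100 amplicons,
  depth 1000–2000, 2,000 TSSs, 20–200 simulation replicates) are chosen so
  every Monte-Carlo margin is comfortable at desk scale; they are package
  choices, not statements about the original assay's scale.

## Known limitations

* No gapped alignment anywhere; structural differences between orthologs
  beyond substitutions are out of scope.
* The correction stage assumes a single equimolar control with a purely
  multiplicative, stable ratio bias; it is isolated behind one operation and
  can be disabled when no control is available.
* The DNase track consumes mapped fragment intervals; genome alignment,
  peak calling and replicate-level modeling are out of scope.
* Category-level paired tests could in principle pair samples instead of
  amplicons; this package pairs amplicons, because the category summaries
  aggregate per-amplicon fold changes and the amplicon is the only unit
  shared across the compared conditions.
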