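# Methods

## The module and its coordinate conventions

An S–X–Y module is three short DNA elements (defaults: S 7 bp, X 14 bp,
Y 10 bp) in fixed order and tightly constrained spacing on one strand.
All coordinates are 0-based half-open internally; browser-style
`chr:start-end` strings are treated as 1-based inclusive and converted on
parse. Inter-motif *spacing* is defined as the gap in base pairs between
the end of the upstream motif and the start of the downstream one. The
60/100-bp flank search windows are measured from the **center** of the
X box on the outer side; on the inner side they stop at the X-box edge so
a flank motif can never overlap the anchor.

## Unique gene models and promoters

For each `gene_id` the exons of all isoforms are merged into a single
set of disjoint intervals (per-base union). The TSS is the minimum exon
start on the + strand and the maximum exon end − 1 on the − strand. The
promoter is the window from 500 bp upstream to 50 bp downstream of the
TSS; on the − strand "upstream" means higher coordinates, so for a TSS
*t* the window is `[t − 500, t + 50)` on + and `[t − 49, t + 501)` on −
(both contain the TSS, both are 550 bp before clipping at contig
bounds). A peak is assigned to every promoter window it overlaps by at
least one base; a peak overlapping the promoters of a divergent gene
pair yields two assignments, and no deduplication is applied — gene
counts and peak counts are reported separately.

## PWM scoring and the 95% threshold rule

A PWM stores per-position nucleotide probabilities (estimated from
weighted counts plus a 0.01 per-cell pseudocount, so all entries are
positive). Windows are scored by the log-probability sum, min–max
normalized to [0, 1] using the per-position extremes of the matrix:
consensus scores 1, the worst possible window 0. This scale makes the
"95% of the minimum training score" threshold rule monotone and
well-defined — on a raw log-odds scale the rule flips meaning with the
sign of the score, which is why thresholding is defined on the
normalized scale throughout. Windows containing non-ACGT characters are
skipped (NaN).

## Anchored discovery (ZOOPS EM)

The anchor (X) is discovered on both strands under a
zero-or-one-occurrence-per-sequence model: each sequence contributes its
N-free windows on both strands as candidates; EM alternates posterior
assignment (including a "no occurrence" cell with prior 1 − γ) with
weighted-count matrix updates. Numerical/algorithmic choices:

* **Seeding.** A uniformly random restart almost never lands on a motif
  instance, so restarts converge to off-register local optima. Instead,
  a large sample of data windows (10 × `n_starts`, at least 50) is
  ranked by the one-pass likelihood of a matrix centred on each
  (0.6 on the seed base, rest uniform), and only the top `n_starts`
  seeds are refined by full EM.
* **Column-shift refinement.** The winning matrix is re-run from copies
  shifted by ±1 column (vacated rows uniform) until no improvement, the
  standard escape from off-by-one register optima.
* **Monotonicity.** Because the pseudocount makes the M-step a MAP
  update, the monotone quantity is the penalized log-likelihood (data
  term plus Dirichlet prior term); it is asserted non-decreasing at
  every iteration. Convergence: relative change < 1e-8, max 300
  iterations; γ is clipped to [1e-4, 1 − 1e-4].
* **Occurrence filtering.** A sequence contributes a training occurrence
  only if its fitted posterior probability of containing the motif is
  ≥ 0.5; its occurrence is then the best-scoring window (ties: smaller
  offset, then forward strand).
* **Strand of the module.** A de-novo motif is defined only up to
  reverse complement. When a reference X-box consensus is supplied, the
  discovered matrix is compared with it at the best ungapped alignment
  in both orientations and flipped if the reverse complement agrees
  better — the in-package form of recognizing the discovered anchor as
  the known X box before orienting peaks.

Peaks are then reverse-complemented as needed so all X occurrences lie
on the forward strand, and S (upstream) and Y (downstream) are
discovered by the same EM restricted to the windowed subsequences,
forward strand only.

The module model records the three PWMs, thresholds at 95% of the
per-motif minimum training score, spacing ranges = observed [min, max]
gaps widened by 5 nt per side and floored at 0, the window width, and
the full training provenance. By construction every training instance
satisfies the model — asserted as a pipeline self-consistency test.

## Genome scanning

All three PWMs are scored at every offset of both strands (vectorized
over sliding windows). For each X placement above threshold, the
best-scoring admissible S and best-scoring admissible Y are chosen
independently (which maximizes the triple's total score); spacing ranges
are inclusive at both ends. Matches sharing an X interval are collapsed
keeping the higher X score, which also removes palindromic double
counts across strands. Relaxing thresholds or widening spacings can only
grow the match set; this monotonicity is tested, and is the reason a
stringent-geometry module yields far fewer genome-wide matches than a
spacing-relaxed one.

## ChIP-seq QC

* **Cross-correlation**: Pearson correlation between per-base 5'-tag
  coverage of the two strands as the reverse strand is shifted by
  0…`max_shift` (default 400), pooled over contigs. Fragment length =
  argmax outside a ±10 bp guard band around the read length. Background
  = median correlation over the largest 10% of shifts. NSC =
  cc(fragment)/cc(background); RSC = (cc(fragment) − cc(background)) /
  (cc(read length) − cc(background)), clamped at 0. Denominators are
  floored at 1/√L (the sampling noise of a null correlation over L
  positions) so a background at or below zero yields a large but
  finite, interpretable ratio rather than an arbitrary one.
* **FRiP**: fraction of tag 5' positions inside the merged peak
  intervals (binary-search membership).
* **Pseudo-replicates**: a seeded permutation split into k disjoint
  equal-size tag sets.
* **IDR**: the semiparametric Gaussian copula mixture. Ranks are mapped
  to pseudo-data through the inverse marginal CDF of the current
  mixture — a correlated bivariate normal "reproducible" component
  (mean μ > 0, variance σ², correlation ρ ≥ 0) against independent
  standard-normal noise — and one EM update is applied per mapping;
  the alternation runs to parameter stability (max change < 1e-3,
  up to 1500 iterations; start values π 0.7, μ 2.6, σ² 1.69, ρ 0.8).
  Local idr = posterior of the noise component; peaks are counted
  reproducible by the cumulative (global) IDR at the chosen threshold
  (0.01 by default). Two degeneracy rules: if ρ collapses to 0 the
  remaining parameters drift along a non-identifiable ridge, so ten
  consecutive collapsed iterations end the fit; and if the final ρ is
  below 0.2 the mixture carries no evidence of reproducibility (any
  split of independent data fits equally well) and all local idr values
  are reported as 1.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis relies
on: i.i.d. background sequence at a set GC fraction; planted module
instances at controlled spacings (defaults: S–X gap 16, X–Y gaps
20/21/22, optional "H2-T-like" class at 48), strands and per-base
mutation rates, with a serialized truth table; multi-isoform gene
annotations with overlapping exons; and stranded tag pileups with three
components — fragment-end signal around peak summits (Gaussian jitter,
sd 15 bp), block-wise non-uniform background (Gamma-distributed rate
per 5-kb block, shape 0.5, shared between strands — the coverage bias
that gives real profiles their positive baseline correlation), and a
2% both-strand "phantom" artifact at shared hotspots offset by the read
length, which is what gives the RSC denominator its peak. The
`enrichment` parameter sets the signal fraction to 1 − 1/enrichment.

Not emulated: read-level sequencing errors, mappability structure,
duplicate-read statistics, dinucleotide or repeat sequence composition,
and real TSS/peak geometry beyond the planted layout. Passing tests
therefore demonstrate the correctness and calibration of the
algorithms under the stated generative assumptions, not performance on
real libraries.

A box-swap utility builds hybrid promoter constructs from annotated
S/X/Y box intervals; the default fixtures are the H2-K and H2-E reporter
inserts reconstructed by overlap-merging each printed primer pair
(both overlap by exactly 10 bp) and trimming the 10-bp restriction-site
extensions.

## Problem sizes and defaults

Analyses, tests and the acceptance script use desk-scale study sizes
chosen as the package's own defaults: 24 planted modules (two H2-T-like)
on a 200-kb genome at 5% per-base mutation for discovery and scanning;
50-kb genomes for scanner-versus-oracle comparisons; 60 k tags over
300 kb (20 peaks, enrichment 10) for fragment-length recovery; 150 k
tags over 1 Mb (11 small peaks, enrichment 1.005) for the low-FRiP
regime; n = 1000 peak pairs (reproducible fraction 0.6, ρ 0.9) for IDR
parameter recovery. EM discovery uses 10–20 restarts.

## Known limitations

* Motif widths are configuration (defaults S 7, X 14, Y 10 from the MHC
  promoter literature); the discovery does not infer widths.
* The EM is single-motif-per-stage (anchor, then each flank); the three
  motifs are not optimized jointly.
* PWM score thresholds are the 95%-of-minimum rule, not calibrated
  p-values; scores between models are comparable only via the
  normalized scale.
* On sequences whose true flank instance is heavily mutated, the
  best-scoring window in the flank search may be a background window,
  which can widen the fitted spacing range beyond the planted ±5 —
  visible in the training provenance.
* NSC/RSC on synthetic data are advisory: their absolute values depend
  on the background-block and artifact parameters, although their
  qualitative regimes (≈1 without enrichment, elevated with it) match
  expectations.
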