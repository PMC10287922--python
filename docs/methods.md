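# Methods

## Signal model

A lead-induced cleavage of the phosphodiester bond between positions *p* and
*p*+1 produces a 5′ fragment ending at *p* with a 2′,3′-cyclic phosphate and
a 3′ fragment starting at *p*+1 with a 5′-OH. Both libraries are mapped onto
the shared cleavage coordinate *p*: cP fragments increment the count at
their last nucleotide, OH fragments at `start − 1`. An OH fragment starting
at position 1 carries the native transcript 5′ end rather than a cleavage
and is skipped with a warning. Position *L* is never a cleavage site.

With a 12-nt minimum mappable fragment length, cP fragments produced by
cleavages at sites 1–11 are lost, so the first 11 positions of every
transcript carry no cP signal; symmetrically the OH library is blind for the
last 12 positions. The two blind ends never coincide, which is the point of
capturing both cleavage products.

### Normalization

Raw counts are normalized per transcript by the mean of the 90th–98th
percentile band, implemented as an outlier-trimmed top band: sort the
counts, discard the largest `ceil(0.02·L)` values, and average the next
`max(1, round(0.08·L))` values. This avoids the ambiguity of interpolated
percentile definitions while matching the intent of treating the top 2% as
outliers. Zeros are included in the band computation by default
(configurable; the band sits near the top of the distribution, so this
rarely matters). Normalized values are capped at 7 *before* replicate
averaging; replicate means skip NaN replicates at a position rather than
propagating them (strict propagation is available).

Two coverage criteria gate detailed structural analysis: at least 75% of
positions covered by reads and at least 2.5 read starts per position on
average. Both thresholds are parameters.

## Calibration of unpaired probability

On a calibration set with reference structures, positions are pooled into
signal bins and the unpaired fraction n_u/n per bin estimates
P(unpaired | S). Sigmoids

    p(S)           = 1/(1 + exp(−a·S + b)) + c
    p(S_cP, S_OH)  = 1/(1 + exp(−a1·S_cP − a2·S_OH + b)) + c

are fitted to the (bin representative, unpaired fraction) points by
nonlinear least squares (`scipy.optimize.curve_fit`, initial guesses
a = a1 = a2 = 1, b = 1, c = 0.1).

Numerical choices:

* **Bin edges.** 1D default `{0, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5, 2.5,
  4.0, 7.0}` — denser near 0 where most of the signal mass lies; the 2D
  grid is the Cartesian product of the coarser `{0, 0.1, 0.4, 1.0, 2.5, 7}`.
  Both are configurable (dense uniform grids are preferable for
  high-depth parameter-recovery studies, where wide bins introduce
  curvature bias).
* **Bin representative.** The mean signal of the bin's members, not the
  interval midpoint — reduces binning bias in skewed bins.
* **min_bin_count = 20.** Bins with fewer members get an undefined unpaired
  fraction and are excluded from fitting. At least 4 usable bins (1D) or 6
  cells (2D) are required.
* **Bounded fits.** Slopes are constrained non-negative (a, a1, a2 ∈
  [0, 100]) and offsets to sane ranges (|b| ≤ 50, |c| ≤ 1). More cleavage
  can only make a position more likely to be unpaired; without the bound,
  least squares on sparse, nearly collinear 2D bin grids can settle on
  sign-flipped degenerate optima that invert one library's response.
* **Clipping.** Predicted probabilities are clipped to [0, 1]: the additive
  offset c can push the raw sigmoid outside the unit interval.
* Fits are unweighted by default; weighting bins by membership is optional.

### CA dinucleotide class

Cleavage sites falling in CA dinucleotides (position *i* = C, *i*+1 = A) are
strongly over-represented in cP libraries for reasons unrelated to
structure, so CA sites get separate fits everywhere (1D and 2D). UA shows a
much weaker bias and is not special-cased. When a CA-class fusion fit is
impossible (small calibration sets rarely have enough CA sites per signal
cell), CA sites do **not** fall back to the non-CA fusion model — that model
would misread the inflated cP signal as unpaired evidence. Instead the
bias-affected cP signal is dropped at those sites and the OH 1D model is
used. For 1D fits the fallback is the pooled non-CA model of the same
library.

### Per-position probability

For each position, q_i comes from the 2D fusion model when both signals are
defined, from the OH 1D model inside the cP blind end, from the cP 1D model
inside the OH blind end, and is NaN (source "none") when neither signal
exists. The prior p0 is the unpaired fraction of the calibration set over
positions with at least one defined signal.

### Shuffled-label control

Shuffling the pairing labels within each transcript and refitting must
produce a flat response curve; the flatness statistic is the range
(max − min) of the fitted curve over the observed signal range. A
structured signal yields flatness well above 0.2, a shuffled one below
0.05 at calibration-scale sample sizes.

## Pseudo-energies and folding

The probability q_i is converted into a free-energy bonus for the unpaired
state,

    dG_i = −R·T·c·( ln(q_i/(1−q_i)) − ln(p0/(1−p0)) ),

a log-likelihood ratio against the prior. Defaults: c = 1.2 (trust in the
probing data), p0 = 0.42, T = 310.15 K (37 °C growth and folding
temperature), R = 0.0019872 kcal/(mol·K); all configurable. q is clipped to
[1e−6, 1−1e−6] before the log-odds. Because low signal cannot be
distinguished from missing data, constraints are applied only where
q_i > p0 (strict), where dG < 0 stabilizes the open state; dG(p0) = 0
exactly.

Folding goes through a pluggable engine contract — (sequence, per-position
unpaired-state energies, temperature) → (MFE dot-bracket, energy) — with a
ViennaRNA adapter (`fc.sc_add_up`) as the reference implementation.
Energies attach to the unpaired state only; no term is placed on paired
states, which is sufficient up to a constant shift of the energy landscape.

## Evaluation

Predicted and reference base pairs are compared exactly (no slippage credit
by default; a ±1 option exists). PPV = TP/(TP+FP), SEN = TP/(TP+FN),
MCC = √(PPV·SEN) — the standard form in RNA benchmarking; an exact
contingency MCC counting true negatives over candidate pairs {(i,j): j−i ≥
4} is available. Degenerate conventions: empty prediction against a
non-empty reference gives SEN = 0, PPV = NA, MCC = 0. Benchmark summaries
are unweighted NA-skipping means over transcripts.

## mRNA metaprofiles

Eligible mRNAs have a 50-nt window upstream of the AUG free of other
annotated genes and pass the coverage filter. Tracks are aligned at the
start codon; the meta-coordinate runs −48…180 with no position 0 (position
1 = A of AUG). Blind-end positions are NaN in the normalized tracks and
thereby excluded from per-position means. Region means cover the 5′-UTR
(−48…−1), CDS 1–60 and CDS 61–180; two-sided Welch t-tests compare regions
on per-position profile means by default (a per-transcript pooling option
exists — which unit the tests should use is genuinely open, so both are
offered). Codon-position means group CDS meta-positions by ((m−1) mod 3)+1;
the UTR gets an arbitrary pseudo-frame as a no-periodicity control.
Only plus-strand annotations are supported for meta-alignment.

## The simulator

The generator is a test harness emulating the empirical features of
double-end probing data, not a mechanistic claim:

* Cleavage events per internal site are Poisson with rate
  depth · (λ_bg + λ_str·unpairedness(site)); defaults λ_bg = 0.5,
  λ_str = 5 per site per replicate, depth = 5. The unpairedness input may
  be a binary indicator (from a reference structure) or a probability.
* Every event emits both fragments (1…s and s+1…L), so pre-censoring
  per-site counts of the two libraries are identical when biases are off —
  the dual-end conservation property.
* CA sites get a cP-channel capture multiplier (default 3) emulating the
  observed dinucleotide bias; it appears in the cP library only.
* Three lognormal noise sources (all mean-1): per-replicate depth
  (sd 0.2), per-site cleavage propensity shared across libraries and
  replicates (sd 0.5), and per-site/library/replicate capture efficiency
  (sd 0.3). The site and capture magnitudes were chosen so the simulated
  data reproduce the reproducibility observed in real dual-library probing
  (replicate Pearson ≈ 0.8) and an overlapping signal distribution between
  paired and unpaired positions; with them, benchmark transcripts pass the
  coverage filter at the default depth. With capture noise and CA bias
  disabled, the per-library counts equal the shared event stream exactly.
* Fragments shorter than 12 nt are censored, producing the 11-nt/12-nt
  blind ends with no special-casing.
* Benchmark references are seeded Boltzmann samples from the ViennaRNA
  ensemble (`uniq_ML = 1`, `RNA.init_rand`). A sample, unlike the MFE
  structure, differs from the unconstrained prediction, so the probing
  signal has room to demonstrate improvement. Driving cleavage rates by
  ensemble unpairedness instead was tried and rejected: constraints pulled
  predictions toward the ensemble mean and away from the sampled reference.
* The mRNA generator draws per-position unpaired indicators with region
  probabilities (UTR 0.40, CDS codons 1–20 0.50, rest 0.35) and boosts the
  cleavage rate of third codon positions (×1.4), emulating the observed
  region contrast and CDS periodicity.

What passing tests show — and do not show. The simulator's cleavage
chemistry is idealized: no ligation sequence preferences beyond CA, no
PCR/UMI artifacts, no multi-mapping, no ensemble heterogeneity of the true
structure, and references that are (up to Boltzmann sampling) internally
consistent with the folding engine's energy model. Passing the end-to-end
benchmark therefore demonstrates that the pipeline's inference chain is
correct and self-consistent, not that real libraries reach the same
accuracy.

## Problem sizes

The default verification study uses a 20-transcript benchmark (70–300 nt,
two replicates), 1e5 labeled positions for calibration recovery, and a
30-mRNA metaprofile set — sizes at which every statistical check is
well-powered while the whole suite runs in well under a minute of compute.
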