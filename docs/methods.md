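# Methods

## Overview

`ldne` asks a single question with simulated data: when natural
selection and recombination-rate heterogeneity shape a genome, which
estimators of effective population size (Ne) still report the
demographic quantity?  Three estimator families are implemented and run
against the same forward simulations:

* **Ne_LD** — from linkage disequilibrium.  Pairwise squared allelic
  correlation r² between SNPs is binned by recombination fraction c;
  each bin is inverted through the drift expectation
  E(r²) = 1/(α + 4 Ne c) + sampling correction, and dated to
  t = 1/(2c) generations in the past (LD at distance c turns over at
  rate ≈ 2c per generation, so it integrates drift over roughly that
  horizon).
* **Ne_π** — from nucleotide diversity, π/(4μ), valid at mutation–drift
  equilibrium for neutral variation.
* **Ne_Vk** — from the variance of family (gamete) sizes: the realized
  (4N−2)/(Vk+2) under random mating, and the closed form N/(1+α) with
  α = β/(2−β) under partial self-fertilization with selfed fraction β.

The working hypothesis the package reproduces: Ne_LD tracks demography
and is nearly blind to selection, while Ne_π collapses wherever linked
selection depresses diversity, most strongly at low recombination.

## Forward simulator

Diploid Wright–Fisher, discrete generations, one linear chromosome.

* **State.** 2N haplotypes × S segregating sites (binary, infinite
  sites).  Fixed and lost columns are pruned every generation; fixation
  counts are retained.
* **Reproduction.** Parents are drawn with probability proportional to
  fitness (fecundity selection).  With probability β an offspring is
  selfed: one fitness-weighted parent supplies both gametes
  (independent meioses).  Fitness is multiplicative over loci with
  genotype values 1, 1+sh, 1+s, floored at zero.
* **Recombination.** Each gamete receives Poisson(total map length in
  Morgans) crossovers placed uniformly on the Morgan scale — i.e. no
  interference, which makes the Haldane function
  c = (1 − e^(−2d))/2 the exact map-distance-to-recombination-fraction
  conversion for simulated data.
* **Mutation.** Poisson(μL) new mutations per gamete at uniform bp
  positions; position collisions are redrawn so every site stays
  biallelic.  Effects come from the configured DFE: neutral;
  background selection (fraction p deleterious, |s| ~ Gamma(shape 0.2,
  mean 0.02), h = 0.5); sweeps (same gamma, positive sign);
  overdominance (s = 0.02, h = 1.5).  Gamma draws with |s| ≥ 1 are
  resampled (the shape-0.2 tail makes them possible; 1+s ≤ 0 is
  meaningless).
* **Initialization.** `equilibrium_init` seeds the population at
  neutral mutation–drift equilibrium: Poisson(θL·H_{2N−1}) segregating
  sites, frequencies ∝ 1/i over copy classes, alleles assigned to
  haplotypes independently (linkage equilibrium), all initial sites
  neutral.  A forward burn-in then builds up LD and (under selection
  models) the selected standing variation.  Because LD at distance c
  equilibrates on the 1/(2c) timescale, ≥ 3/(2·c_min) generations of
  burn-in suffice for estimates that only use pairs with c ≥ c_min;
  the constant-size scenarios use 600 generations for c_min = 0.0025.
  This replaces multi-thousand-generation cold starts and is what makes
  desk-scale recovery experiments possible.
* **Rescaling.** `rescale_config` applies the standard Q-rescaling
  (N/Q, generations/Q, μ·Q, map·Q, s·Q), preserving Nμ, N·map-length
  and N·s.

## Ne_LD estimator choices

* Phased haplotypes: r² is the squared Pearson correlation of allelic
  indicators (equal to D²/(p_A p_a p_B p_b)); inversion constant α = 1
  and additive sampling correction 1/n_h.
* Unphased genotypes: squared correlation of dosages (Burrows-style
  composite), α = 2, correction 1/n diploids.  This mirrors analyses of
  genotype data with unknown phase, and is the default for the genome
  scan.
* Bins: 30 logarithmic bins over c ∈ [0.001, 0.5], ≥ 100 pairs per
  bin.  A single summary Ne_LD averages the bin estimates with mean c
  in [0.0025, 0.0250], weighted by pair count.  The weighting is an
  inverse-variance choice with a measured payoff: the sparse lowest-c
  bins carry the largest inversion bias (≈ +20% at 4Nc ≈ 10) and an
  unweighted average lets them dominate.  Corrected mean r² ≤ 0 flags
  the bin invalid (NaN) rather than raising.
* The MAF ≥ 0.05 pair filter is not cosmetic: rare variants have
  frequency-bounded r² and, unfiltered, drag mean r² far below the
  drift expectation (recovery errors of 2–3×).
* The Sved-form inversion is a calibration choice validated by
  parameter recovery, not a finite-sample-exact formula.  Its known
  small-ρ (ρ = 4Nc) bias is visible in the package's own outputs: bins
  with ρ ≲ 10 overestimate Ne by tens of percent, and window-level
  regional estimates at n = 50, ~10³ effective pairs carry an upward
  Jensen-type bias (the tight-linkage and genome-scan checks are
  therefore designed as ratio/correlation contrasts against a matched
  neutral control, where these biases cancel).

## Genome scan

Windows of exactly 2 cM are laid consecutively from the start of each
chromosome's map; the trailing (telomeric) remainder shorter than 2 cM
is dropped.  Per window: π (denominator = window bp length; monomorphic
sites contribute zero), proportion of polymorphic sites P, mean SNP
MAF, mean recombination rate (map span / bp span), annotation-track
aggregates, and a regional constant-size Ne_LD from the pooled pairs
with c ∈ [1/100, 1/50] Morgans.  Windows are excluded when the pair
count is not above the configured minimum (250,000 at human scale; 500
in the desk-scale synthetic runs, whose windows hold ~10²–10³ SNPs
rather than ~10⁴) or when Ne_LD is non-positive, non-finite, or above
100,000 (10,000 desk scale); exclusions are tallied per rule.
Correlations are Spearman with average ranks; two-sided p-values use
the t approximation on n−2 degrees of freedom (adequate at hundreds of
windows; a permutation option was considered unnecessary at this n).
Genes and variant-count intervals are assigned to the window containing
their midpoint; value tracks (the B statistic) use overlap-weighted
means.

## Synthetic human-like data

The scan needs inputs resembling a human whole-genome panel.  The
generator produces, at desk scale:

* **Maps** — each chromosome split into equal-bp regions with i.i.d.
  rates from a log-normal (mean 1 cM/Mb, CV 1, truncated to
  [0.01, 5] cM/Mb — a parametric stand-in for the empirical
  distribution of human 2 cM-window rates), scaled by Q.
* **Genotypes** — one background-selection forward run per chromosome
  (56 chromosomes × 2 Mb, census 200 = Q·5 rescale of 1000, sample 50
  diploids, 500 generations).  The neutral per-bp mutation rate
  (3.6×10⁻⁷) sets the SNP budget so that even the narrowest
  (high-recombination) windows retain enough pairs; the deleterious
  rate (1×10⁻⁷ per bp, gamma mean |s| = 0.1 = Q·0.02) sets the
  strength of linked selection.  The deleterious share is deliberately
  higher than the 5% used in the chromosome-scale scenarios: shrinking
  a chromosome to 2 Mb while keeping a human-like per-bp deleterious
  density would make background selection invisible, so the per-Morgan
  deleterious input, which is what diversity responds to, is kept at a
  level where the diversity–recombination coupling is detectable over
  a few hundred windows.  The positive π–RR correlation in the scan is
  therefore an emergent property of linked selection in the simulator,
  not wired into any track.
* **Annotation tracks** — Gaussian copula on window ranks: gene density
  (Poisson), LoF and missense counts (Poisson, positively coupled to
  gene density), B statistic (Beta with mean 0.78, in (0,1],
  decreasing in gene density, increasing in recombination rate).  Rank
  couplings reproduce the observed sign structure; magnitudes are
  targets (default ±0.6/0.5) realized within ±0.15 over ≥ 200 windows.
  An infeasible target combination (non-PSD latent correlation) raises.

## Desk-scale study conditions

Full-scale runs (N up to 10⁴, 100 Mb, 10⁴ generations, 100 replicates)
are not desk-reproducible; the package's canonical scenarios are:

| scenario | census | sequence | map | μ (bp) | generations | replicates |
|---|---|---|---|---|---|---|
| constant-size neutral | 1000 | 2 Mb | 1.25 cM/Mb | 2×10⁻⁸ | 600 | 20–32 |
| constant-size BS / SS | 1000 | 2 Mb | 1 cM/Mb | 2×10⁻⁸ | 600 | 20–32 |
| tight linkage (Q=5) | 200 | 1 Mb | 5 cM/Mb (≡ 1 cM genome) | 5.5×10⁻⁷ total | 1600 | 12 pooled |
| step change 1000→250 | 1000/250 | 2 Mb | 10 cM/Mb | 2×10⁻⁸ | 630 | 8–10 |
| human-like scan | 200 | 56 × 2 Mb | lognormal ×5 | 4.6×10⁻⁷ total | 500 | 1 |

The tight-linkage pair keeps the per-gamete deleterious input (0.25)
and total map (5 cM, the Q-scaled 1 cM genome) of the extreme
low-recombination scenario while shrinking the sequence; both models
share the same total μ so π/(4μ) is comparable, the neutral model
simply making every mutation neutral.  Because the information content
of a 5 cM genome is low, SNP pairs are pooled across replicates before
inversion (per-replicate estimates at this map length are dominated by
a handful of genealogies), and the runs last 4×2N generations: linked
selection equilibrates slowly at this map length, and at half that
length the background-selection arm is still measurably in transit.

## Numerical and degenerate-input choices

* All randomness flows from one `numpy.random.Generator` per run;
  seeded runs are bit-reproducible.
* Coordinates are 0-based half-open bp internally; VCF output is
  1-based; map positions are Morgans.
* Zero-rate map segments are legal; pairs at zero map distance have
  c = 0 and are excluded from LD by the c > 0 filter.  The inverse map
  (Morgans → bp) returns the left edge of flat stretches.
* Monomorphic sites reaching the r² kernel raise (an upstream filtering
  bug); invalid bin inversions flag NaN instead.
* MAF filter for LD pairs: 0.05 by default, configurable.
* Pair subsampling above 5×10⁶ pairs is uniform and seeded.

## What passing does and does not show

The synthetic data generator emulates the features the estimators are
sensitive to — SNP density, map heterogeneity, linked selection, rank
structure of annotations.  It does not emulate human chromosome counts,
hotspot fine structure, gene clustering, demographic history, phasing
or genotyping error, or ascertainment bias.  Recovery and invariance
results here validate the estimators' logic under the stated models;
they do not by themselves calibrate accuracy on real human panels.
Known limitations: the Sved-family inversion is biased at small 4Nc
(absolute regional Ne_LD levels run high at desk scale; contrasts are
the reliable output); at the 1 cM-genome extreme the background-
selection arm's pooled Ne_LD sits some 10–25% below the neutral
control depending on replicate draw — small next to the ~70% collapse
of Ne_π, but not zero; no gene conversion, no overlapping generations,
no population structure; and the overdominance model is implemented
but not part of the canonical desk scenarios.
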