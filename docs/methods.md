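# Methods

This note documents the statistical models implemented in `hidra-kit`, the
choices made where the design was genuinely open, the synthetic-data
conditions under which the package validates itself, and known limitations.

## Data model and conventions

All intervals are BED-style 0-based half-open; conversion to 1-based
coordinates happens only at the VCF boundary. A fragment's identity is the
(chrom, start, end, barcode) quadruple — the random 4-nt PCR barcode
disambiguates fragments whose alignment coordinates coincide, which matters
for allele assignment. Strand is carried through unmodified and never
interpreted: the reporter construct is episomal and orientation is not
modeled. The length filter (100–600 nt) is inclusive at both bounds.
Blacklist removal defaults to any-overlap (≥1 bp), with a `full`-containment
mode available; mapping-quality filtering is an upstream (alignment-stage)
concern and is not re-applied here.

## Activity calling

Counts for fragment group g in sample j are modeled as
NB(mean = s_j·exp(η_{g,cond(j)}), dispersion α_g), where s_j are
median-of-ratios size factors normalized to geometric mean 1. With only a
condition effect and offsets, the NB score equation per condition is
one-dimensional; it is solved by a vectorized Newton iteration and the Wald
statistic uses the Fisher information of the log-mean. With α = 0 the fit
reduces exactly to a Poisson GLM (verified against statsmodels in the test
suite); p-values are two-sided, and the activity call additionally requires
log2FC > 0, implementing an "up-regulated only" definition.

Dispersions are method-of-moments estimates from within-condition variance
(requiring ≥2 replicates), shrunk 50/50 toward a mean-dependent trend — the
median raw dispersion in 20 baseMean quantile slices, linearly interpolated —
and floored at 10⁻⁸. This replaces a full empirical-Bayes treatment; the
acceptance surface is *calibration* (the realized active fraction under a
complete null stays below the nominal FDR level), not replication of any
specific differential-expression package's numerics. Outlier handling
(Cook's-distance-style) and fold-change shrinkage are deliberately out of
scope.

Benjamini–Hochberg runs strictly within 100-nt length bins
(bin = floor(length/100)) to absorb length-dependent transfection bias; no
cross-bin correction is applied. Groups with zero totals in either condition
are flagged untestable (p = 1, log2FC = 0) rather than fitted: the log-scale
fold change is unidentified there. Signal tracks use
a = (RNA_rpm − DNA_rpm′)/DNA_rpm′ with 0.1 added to both RPM means so that
inactive fragments score exactly 0; per-base values are the mean over
covering fragments (max available via a flag), rounded to 4 decimals.

## Per-nucleotide score inference

Within a tiled region (≥10 unique fragments), each unique fragment endpoint
pattern contributes one observation: its activity (RPM-based log2 RNA/DNA
ratio with the 0.1 pseudocount, fragments with identical endpoints collapsed
by summing counts) is modeled as the *length-scaled average* of a latent
per-position score plus noise. The prior is zero-mean iid Gaussian per
position; the posterior mean and variance are computed through the M×M
system (M = number of rows), never T×T, with a 10⁻¹⁰ jitter guard.
Activities are standardized per region so that (τ², σ²) are comparable
across regions.

**Design rows are endpoint patterns, not 75%-overlap groups.** Reciprocal-
overlap grouping quantizes endpoint offsets to roughly a quarter of the
fragment length (~80 nt), which destroys precisely the information the
deconvolution exploits; empirically it capped attainable resolution far
above the tens-of-nucleotides scale and halved end-to-end driver recovery.
Activity calling, whose unit is read coverage rather than breakpoints,
continues to use fragment groups.

**Variance fitting.** (τ², σ²) maximize the Gaussian marginal likelihood
y ~ N(0, τ²AAᵀ + σ²I) by bounded L-BFGS-B in log space, bounds [10⁻⁴, 10²],
deterministic start τ² = σ² = var(y)/2, with an even moment split as the
non-convergence fallback. The upper bound on τ² is deliberately tight: a row
averaging L positions contributes only τ²/L signal variance, so the cap
limits how much broad between-row variance the prior may claim and pushes
the excess into σ². This regularizes the Monte-Carlo null toward flatter
draws; without it, called elements collapse to the single sharpest peak
position and sparsely tiled regions (10–20 fragments) yield no calls at all,
contradicting the observed behavior of real libraries. A single fitted τ² is
used (no two-variance prior interpolation); one-sided (activation) scanning
is the default, with |z| available.

**Regional FWER.** The driver threshold c_α is the empirical (1−α) quantile
of max_i z*_i over n_mc = 2000 draws y* ~ N(0, τ²AAᵀ + σ²I) pushed through
the same posterior operator; element p-values are exceedance fractions with
+1 smoothing (minimum attainable p = 1/(n_mc+1)); n_mc < 100 is refused as
too unstable. Driver elements are maximal runs of z ≥ c_α with no gap
merging and min_len = 1 by default. Because the null is the *fitted* model,
the guarantee is per-region FWER control under the no-signal null —
empirically the realized rate is conservative (≈0.2–1% at α = 5%).

**Shuffle enrichment.** Each of 1000 shuffles relocates every element,
length-preserved, to a uniform position in a uniformly chosen universe
interval large enough to contain it; significance is a two-sided normal
p-value from the shuffle mean and SD, with a degenerate (SD 0) null reported
as p = 1.

## Allelic imbalance

Fragments are assigned alleles via a genotype map keyed by the fragment
identity triple; records naming a variant outside the fragment raise a
consistency error, and ungenotyped or ambiguous fragments are dropped and
tallied. Three filters guard against positional confounding: (i) within
each SNP, fragments are greedily retained (highest coverage first) so every
kept pair of fragments has ≥90% reciprocal overlap; (ii) fragments with
either end strictly closer than 25 nt to a driver element are removed;
(iii) both alleles must exceed 20 reads in both the DNA and the RNA
libraries (the read filter is applied to both libraries — the stricter
reading of "both").

The test: under the null, the RNA reference count is
BetaBinomial(n = RNA total, mean = DNA reference proportion, ρ), with ρ = 0
reducing to the exact binomial. Two-sided p-values aggregate all outcomes
whose density does not exceed the observed one (minimum-likelihood ordering,
exact rather than a normal approximation, since filtered totals can be
small). The shared overdispersion ρ is a method-of-moments estimate across
SNPs that subtracts *both* libraries' binomial sampling variance (the DNA
proportion is itself estimated), clipped to [0, 0.5] and requiring ≥20
pairs. Multiplicity: BH across tested SNPs, with a nominal tier (p < 0.05)
and a corrected tier (FDR < 0.1).

## Simulator: what it emulates, and what it does not

Per region (default 2000 nt), accessibility is a mixture of 1–3 Gaussian
peaks; one transposase cut is drawn from this profile and the fragment
extends a mixture-distributed length in a random direction, resampled until
it fits the region. Fragment lengths are a two-component Normal mixture with
means 230 and 377 nt (147 nt apart — nucleosomal spacing), SDs 35/45 nt,
truncated to the 150–500 nt size-selection window; the emulated library has
median length ~310 nt. Plasmid-DNA means are proportional to accessibility
at the fragment midpoint (mean depth 200 per replicate); counts are NB with
dispersion 0.01 per replicate — reflecting the high replicate concordance of
plasmid-library reporter assays (~0.95 Pearson between RNA replicates)
rather than the larger dispersions typical of biological bulk RNA-seq. RNA
means scale the DNA mean by 2^(mean latent score over the fragment); default
ground truth embeds one 50-nt driver of effect +2 (log2) per region, placed
near an accessibility peak (where regulatory elements live, and where
coverage is guaranteed). Allelic simulation assigns ref/alt at ½ per
fragment overlapping a het SNP and multiplies alt RNA means by 2^δ; phase
labels are cosmetic. All three stages are deterministic under the seed.

Not modeled: sequence content (no FASTQ, motifs, or GC bias), length-
dependent transfection bias beyond what binning absorbs, chromosomal context
effects, and mapping artifacts. Passing tests on simulated data therefore
demonstrate the statistical machinery's calibration and resolution under the
stated generative model — not robustness to alignment or sequence-level
artifacts in real libraries.

**Calibration-study noise.** The activity-scale recovery and resolution
studies simulate row activities directly as length-scaled score averages
plus N(0, 0.05²) noise on the standardized scale. This level was calibrated
against the assay's published operating regime: it is the noise at which
regions tiled by 10–20 fragments yield driver elements of ~50–70 nt while
regions tiled by 40+ fragments sharpen to ~20–40 nt, matching the reported
coverage–resolution relationship. It corresponds to well-covered endpoint
patterns whose counts pool several fragments across five replicates.

## Problem sizes

The self-validation suite uses: 500 null regions × 20 fragments (FWER
calibration), 10,000 groups × 50 seeds (activity null), 20 random instances
with T ≤ 300, M ≤ 50 (ridge-oracle equivalence), 50 seeded runs of a 30-nt
+2 driver under 100 fragments (recovery), matched 10- vs 40-fragment
simulations of 60 regions (resolution), 2000 simulated SNPs (allelic null),
and a 20-true + 50-null region end-to-end run at the simulator defaults.
These sizes give Monte-Carlo standard errors comfortably below the margins
tested while keeping the whole suite under a minute of compute.

## Known limitations

- The FWER guarantee is conditional on the fitted Gaussian null; heavy-
  tailed activity noise would make the realized rate drift from nominal
  (conservatively, in our simulations).
- The iid prior ignores spatial smoothness of true regulatory scores;
  elements shorter than ~10 nt should not be over-interpreted.
- τ²/σ² are per-region; no information is shared across regions.
- The beta-binomial null conditions on the observed DNA proportion rather
  than modeling its sampling error inside the test (it is accounted for in
  the ρ estimator); at the >20-read filter this bias is small.
- `estimate_dispersion` assumes exchangeable replicates within condition;
  batch structure is not modeled.
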