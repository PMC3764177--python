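# Methods

This note documents the statistical models implemented in `finescale`,
their assumptions, the tunable parameters that matter, and the choices made
where the design was genuinely open.

## Data model

Individuals are diploid, georeferenced (metres, arbitrary local Cartesian
frame — plot extents of interest are well under 2 ha, so no geodesy), and
genotyped at L codominant loci. Allele codes are opaque positive integers;
identity is all any statistic here uses, so fragment sizes and repeat
motifs carry no semantics. Missing data are coded 0 and a locus genotype is
either fully typed or fully missing; a half-missing pair on input is
normalized to missing. This matches the SPAGeDi/GenAlEx conventions, and a
SPAGeDi text export (zero-padded concatenated allele pairs, plot label as
category) is provided for cross-checking against that ecosystem.

## Pairwise relatedness

**Loiselle kinship.** For individuals i, j,

    F_ij = Σ_l Σ_a [ (p_ila − p̄_la)(p_jla − p̄_la) + p̄_la(1 − p̄_la)/(n_l − 1) ]
           / Σ_l Σ_a p̄_la (1 − p̄_la)

with p_ila the allele-a dosage/2 of individual i at locus l, p̄_la the
reference frequency and n_l the number of typed individuals in the
reference set. The second numerator term is the small-sample bias
correction; it makes the estimator average ≈ 0 over pairs drawn from the
reference population (verified to |mean| < 0.005 at n = 200 in the tests).
The reference frequency set defaults to the analysed individuals
themselves, computed per plot, because each plot is analysed as its own
population. Loiselle's estimator is the default kinship because it is
well-behaved with the rare alleles that 25–41-allele SSR profiles
inevitably contain; the module structure admits other estimators.

**Smouse–Peakall covariance.** Squared single-locus genotypic distances
follow the codominant table (0 identical; 1 hom↔het or het↔het sharing an
allele; 2 het↔het disjoint; 3 hom↔het disjoint; 4 different homozygotes),
are summed over pairwise-complete loci, rescaled by L/L_shared so pairs
typed at fewer loci stay on the full-locus scale, and double-centred
(c = −½(d² − row − col + grand)). The per-class autocorrelation is
r_k = Σ_{ij∈k} c_ij / Σ_{i∈k} c_ii, the denominator summing the
self-covariances of the individuals involved in class-k pairs.

Missing data are handled pairwise-complete in both estimators; pairs with
no shared typed locus are masked, and downstream statistics skip masked
pairs. The rescaling choice biases nothing when missingness is random but
is documented because it inflates the variance of poorly typed pairs.

## Correlograms, Sp, heterogeneity

Distance classes are either even-width (20 m default — the scale at which
SGS in temperate broadleaves typically lives) or even-count (7 classes of
near-equal pair numbers, rank-split with stable ties). The first interval
is closed at 0; all others are left-open/right-closed.

The no-structure null shuffles individual locations among individuals
(1000 permutations), which preserves the multiset of genetic values and
re-bins them through the permuted geometry; the 2.5/97.5 percentiles per
class form the envelope. Bootstrap CIs resample pairwise comparisons within
each class (1000 draws); for the ratio statistic r the numerator is
resampled with the normalization held at its observed value.

Sp = −b_F/(1 − F_1). b_F regresses F_ij on ln(distance) by default — the
two-dimensional isolation-by-distance expectation decays with log distance,
and this is the definition under which Sp values are comparable across
studies — with a linear-distance option. Zero-distance pairs are excluded
from the regression (count logged). SEs come from a delete-one-locus
jackknife; tests are one-sided (F_1 > 0, b_F < 0) because the SGS
hypothesis is directional. Permutation p-values are always
(1 + #{perm ≥ obs})/(R + 1).

The between-plot heterogeneity test compares two correlograms class by
class: t²_k = (r_Ak − r_Bk)²/(v_Ak + v_Bk), with v from the within-class
pair bootstrap, and ω = Σ_k t². The null pools the genotypes of the two
plots and redistributes them at random over the fixed location scaffolds of
each plot (a re-split at the original sizes); class estimates are
recomputed each resample against the observed variances. Classes empty in
either plot are skipped and noted. Default 9999 resamples.

## Bayesian clustering

A no-admixture finite mixture: cluster allele frequencies have symmetric
Dirichlet(1) priors per locus; mixing weights have a sparse symmetric
Dirichlet(α/K_max) prior with total mass α = 0.1. Labels are updated
sequentially with the frequencies integrated out (Dirichlet-multinomial
posterior predictive). The collapsed update is the load-bearing choice:
with sampled frequencies the chain sticks in overfit modes, because a
spurious cluster's sampled frequencies adapt to its members; the collapsed
predictive carries the marginal-likelihood penalty that lets superfluous
clusters evaporate. The total weight mass α = 0.1 was calibrated on the
generator's no-structure and planted-partition oracles: with α near 1 the
weight prior alone supports several occupied components at n ≈ 120 even
without signal, while α = 0.1 concentrates the prior on few occupied
clusters yet leaves genuine structure (θ_ST ≈ 0.10 with four polymorphic
loci) easily recovered.

K is selected by the repetition rule used with spatial Bayesian clustering
in the field: each of `reps` (default 10) independent runs of the
overfitted mixture at K_max (default 20) reports the median number of
occupied clusters over its retained sweeps; the chosen K is the highest of
those medians, and the final labels come from the repetition and sweep
attaining it with the best likelihood. This keeps the selection rule of the
original workflow while replacing its reversible-jump tessellation model —
whose internals the downstream statistics do not need (they consume only
labels and K) — with a documented, testable sampler. The uncorrelated
Dirichlet(1) frequency prior (rather than a correlated-frequencies model)
is the main fidelity gap and tends to be conservative about K.

Options: a Potts interaction (β = 0.6) on a 10-nearest-neighbour graph for
spatial smoothing, and a per-cluster, per-locus null-allele frequency with
uniform prior, Metropolis-updated, folded into the genotype likelihood
(apparent homozygote = true homozygote or null heterozygote; missing =
null homozygote). Sweeps auto-scale with n (150–600, half burn-in,
thinning 2). A label-entropy comparison between trace halves flags (never
fails) suspected non-mixing.

## F-statistics

**θ_ST.** Weir–Cockerham (1984) per-allele variance components (a, b, c)
from group allele frequencies, heterozygote frequencies and sample sizes,
pooled ratio-of-sums over alleles and loci (Σa/Σ(a+b+c)) — the
Fstat/hierfstat convention. Negative components are retained. Monomorphic
loci contribute zero to both sums. Significance: genotypes randomized among
groups, sizes kept.

**Hierarchical F.** A four-level unbalanced nested ANOVA of allele
indicators (gene copy ⊂ individual ⊂ cluster ⊂ plot), solved by equating
observed between-stratum sums of squares to their expectations (Searle's
coefficients); this generic solver reproduces the WC84 closed form to
10⁻¹² on two-level designs (tested). F ratios come from pooled components,
so the multiplicative identity
(1−F_IndTotal) = (1−F_IndClu)(1−F_CluPlot)(1−F_PlotTotal) holds to
rounding. Each level is tested by permuting the units one level below:
whole clusters among plots, individuals among clusters within plots, gene
copies among individuals within clusters. A degenerate (single) plot level
fixes the plot component at zero, reducing F_CluPlot to the two-level θ
among clusters. Plots with one cluster are flagged; they still contribute
to plot-level components.

**Null alleles and ENA.** Per locus × group, an EM estimator treats each
apparent homozygote as a possible visible/null heterozygote (posterior
weight 2q/(p_a + 2q)) and each missing genotype as a null homozygote,
iterating to Δ < 10⁻⁸ (cap 1000 iterations; non-convergence flagged).
Groups under 5 typed individuals are flagged. The ENA-corrected θ treats
the estimated null as an additional allele excluded from the sums: visible
EM frequencies are renormalized over the visible alleles, EM-inferred
visible/null heterozygotes are removed from the visible-visible sample
size, and the WC84 components are computed over visible alleles only. With
q̂ = 0 this reduces to the uncorrected θ exactly. A practical finding,
reproduced by the tests: null alleles do not distort *relative* visible
allele frequencies, so θ itself is nearly unbiased even at 25% nulls — the
correction's value is insurance (and it is close to the null-free truth
whenever q̂ is accurate); estimates with q̂ ≥ 0.5 are flagged unreliable.

## The complexity statistic N̄c

For every focal individual farther than 23 m from each edge of the plot
rectangle (bounding box of the coordinates unless a boundary is supplied),
the number of distinct cluster labels inside a closed axis-aligned square
window of 0.21 ha (side ≈ 45.8 m, half-side 23 m — hence the margin)
centred on the focal is counted; N̄c is the mean over focal windows and the
CI a percentile bootstrap (1000 draws) over focal individuals. A window
that would overhang the plot is shifted to stay inside the rectangle, so in
the limit where the window equals the plot every count equals K. N̄c is
label-permutation and translation invariant, monotone in window area, and
never increased by deleting a cluster (all tested). The statistic
standardizes cluster counts across plots of different areas; intermingled
small clusters raise it relative to spatially blocked clusters of the same
K and n.

## The dispersal simulator

A constant-density, overlapping-generations life cycle on a rectangular
torus arena:

1. a uniform-random fraction 1 − overlap (default 50%) of adults dies;
2. every vacated site is refilled by one recruit at that exact site
   (density stays constant by construction);
3. parents are drawn from the surviving adults — so reproducing adults
   coexist with recruits, emulating overlapping cohorts — and the recruit
   inherits one random gene copy per parent per locus. No mutation (64
   generations is short on SSR mutation timescales), no selfing,
   hermaphroditic monoecy.

Two kernel modes:

- **`gene` (default).** Both parents are drawn with probability
  proportional to a bivariate Gaussian of axial sd σ_g centred on the
  site, father ≠ mother. Every inherited copy then moves ~ Gaussian(σ_g),
  matching the single-parameter "axial gene-dispersal sd" description of
  the simulation lineage this design follows. Under this mode SGS strength
  tracks the neighbourhood size Nb = 4πDσ_g²: the reference scenarios
  (σ_g, D) = (12, 20), (12, 35), (29, 50), (72, 145) span Nb ≈ 3.6 to
  ≈ 940 and produce generation-64 first-class kinship from ≈ 0.5 down to
  below 0.01, in the intended strong-to-absent order.
- **`seed_pollen`.** A two-stage cycle: mother from a seed kernel (axial
  σ_seed) centred on the site, father from a pollen kernel (axial σ_pollen)
  centred on the mother, with σ_g² = σ_seed² + σ_pollen²/2 and a
  configurable σ_seed:σ_pollen ratio (default 1:10, within the range
  reported for beech). This mode is more mechanistic but its short-range
  kinship is dominated by the narrow seed kernel (σ_g/√51 at ratio 1:10):
  maternal-sib clumping keeps F_1 near 0.03 *regardless of σ_g*, so a
  "low-SGS" parameterization cannot reach F_1 < 0.01 under it. That is why
  it is not the default for scenario studies; it remains available for
  mechanism exploration.

Torus boundaries avoid edge artefacts in power studies (a recruit site
near the arena edge sees a full complement of potential parents); parent
sampling uses log-kernel weights (Gumbel-max), so distant-parent weights
never underflow. Arena area defaults to max(2·sample_n/D, 150/D) ha —
twice the sampling window, never fewer than ~150 adults; this reproduces a
9-ha arena for the lowest-density scenario. Initial genotypes are two
independent copies per locus drawn from supplied allele frequencies, or
from symmetric Dirichlet(1) profiles over the configured allele counts
(default 25/41/26/31, the four-locus SSR panel); the 20-locus power mode
tiles that panel five times.

**Measurement.** At checkpoints (default generations 1, 2, 4, 8, 16, 32,
48, 64), `sample_n` (default 90) individuals are taken from a centred
square window whose area gives an expected count of `sample_n` at the
scenario density (padded with nearest individuals if underfull) — a
compact-stand sampling scheme applied consistently across densities, since
a fixed 1.32-ha window cannot contain 90 trees at 20 trees/ha — and F_1,
b_F, Sp are computed with the 20 m first class.

**Null-allele injection** replaces each gene copy by a null with per-locus
probability q; null/null becomes missing, null/visible an apparent visible
homozygote, so the missing rate is q² in expectation.

**Drift.** Each turnover funnels the recruits' genes through the N/2
survivors, so heterozygosity decays faster than an ideal Wright–Fisher
population of size N. At N ≈ 580 near-panmictic adults the expected-
heterozygosity decline over 64 turnovers is ≈ 7% (within the 10% Wright
bound used as a sanity check); at N ≈ 180 it is ≈ 20%, and restricted
dispersal raises it further — an expected property of the model, not a
defect, and the reason the drift check in the tests runs at the larger
arena.

## What the generator does and does not emulate

The synthetic data reproduce the features the statistics consume: multiloc
us codominant genotypes with realistic allele richness, spatial kinship
decay governed by dispersal and density, genotype clusters of controlled
differentiation (Balding–Nichols island and hierarchical-island
generators), null alleles, and missing data. They do not emulate
microsatellite mutation, selection, phenology, uneven stand age structure,
colonization fronts, or real plot geometries — so green tests demonstrate
estimator correctness and power under the stated models, not robustness to
every field complication.

## Numerical and reproducibility choices

Permutation p-values are never 0 (always (1+k)/(R+1)). Allele bookkeeping
uses exact integer counts; frequency sums are validated to 10⁻⁹. All
randomness flows from explicit seeds (`numpy` Generators; per-stage seeds
derived from the global seed via `SeedSequence` with a CRC tag of the
stage name), making pipeline reports byte-identical for identical configs;
stage wall-times go to the logger, not the report. Test and default
problem sizes (20 simulator replicates, 150–600 Gibbs sweeps, 10 × 5 × 20
hierarchy recovery) were chosen as the smallest sizes at which the checked
quantities are stable.

## Known limitations

- The clustering model is not the correlated-frequencies tessellation
  model it stands in for; K estimates are exchangeable in downstream use
  but not numerically identical to that model's.
- The ENA correction is an independent implementation from the method's
  published description, not a port of the original program.
- Individual inbreeding (F_IS) estimation under null alleles is out of
  scope; the EM null-frequency estimator covers the confound for the
  statistics computed here.
- Sp-based dispersal inference (estimating σ or Nb from Sp) is not
  provided.
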