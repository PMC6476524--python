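# Methods

## The experiment being modelled

A short protein segment carries a handful of variable sites; at each site a
set of amino-acid states observed in orthologues ("extant" states, the first
listed being the wildtype) is encoded by a single IUPAC-degenerate codon.
Degeneracy has three side effects that the whole analysis leans on: each
amino-acid genotype is encoded by several synonymous nucleotide variants
(an internal replication used for quality control), position-wise mixing of
codons creates non-extant byproduct amino acids, and some codons are
premature stops — nonsense variants that anchor the lethal end of the
fitness scale.  The pooled library grows in selective medium; abundance is
read out by sequencing at t0, t1 and t14 (time in units of the first growth
interval), in two biological replicates with two technical replicates each.

## Growth model and fitness estimator

Cell numbers grow exponentially, n_x(t) = n_x(0)·exp(s_x·t), so genotype
frequencies obey f_x(t) = f_x(0)·exp[(s_x − s̄_0t)·t], with s̄_0t the mean
growth offset of the pool.  By convention s̄_01 = 0 and t1 = 1; that leaves
two segment-wide nuisance parameters, the offset s̄_02 and the effective
time ratio k = t2/t1, which in practice deviates from its nominal value of
14.  They are fitted by exhaustive grid search (s̄_02 ∈ [0, 1.2] step 0.01,
k ∈ [1, 14] step 0.1) over genotypes with t0 frequency above 25·10⁻⁶,
minimising the summed per-genotype objective; ties resolve to the lowest
s̄_02, then the lowest k.  When more genotypes qualify than needed, the 300
most frequent are used — the calibration is segment-wide, and beyond a few
hundred high-coverage trajectories additional genotypes only rescale the
objective.

Per genotype, (s, f0) minimise Σ_t (f_t − f0·exp[(s − s̄_0t)·t])²/σ²(f_t).
For fixed s the problem is quadratic in f0, so f0 is profiled out in closed
form and the minimisation is one-dimensional.  Numerically this profile has
a deceptive shape: the t2 term carries the factor k ≈ 14 in its exponent,
so at percent-level relative noise the objective valley in s is orders of
magnitude narrower than any practical scan step.  The minimiser therefore
works in three stages — a coarse grid (step 0.1 over [−16, 3] for final
fits; step 0.2 over [−10, 2] inside the calibration loop, where only summed
objectives are compared), a dense local grid around the coarse argmin, and
either a vectorised ternary search (final fits; converges to ~10⁻⁹) or a
parabolic step (calibration loop, where one extra evaluation per grid point
keeps the 121×131-point search affordable).  Standard errors come from the
local curvature of the profiled objective, s_std = sqrt(2/∂²obj/∂s²),
evaluated by central differences with step 10⁻³.

Dropout genotypes (present at t0, zero reads afterwards) cannot be fitted;
they receive the upper bound s_boundary = log(1/max_i N_i^t1) and carry no
standard error.

## Noise model

Variance is estimated empirically as a function of frequency.  For each
replicate pair and time point, genotypes are sorted by mean frequency and
binned (5,000 per bin at library scale; simulated segments use 100–500 so
that a few thousand genotypes still give several bins); per bin the mean
frequency and mean squared difference give a piecewise-linear curve
s²ᵢⱼ(f), anchored at f = 0 by ½((0.5/Nᵢ)² + (0.5/Nⱼ)²) with per-timepoint
total read numbers.  A final partial bin is merged into its predecessor and
the curves continue as constants beyond the last bin centre.  Because
biological drift is shared within a biological replicate, within-pair
curves see technical noise only and

σ²(f) = 1/16·((s²₁₃ + s²₁₄ + s²₂₃ + s²₂₄) − (s²₁₂ + s²₃₄)),

which equals v/4 under pure technical noise of variance v and b/2 under
pure biological noise b.  Sampling noise can make the combination negative;
it is clamped from below at its own f = 0 value (and never allowed to reach
zero), which only affects the emptiest frequency ranges.

## Filtering and rescaling conventions

Genotypes are kept only if every replicate holds ≥ 10 reads summed over the
three time points.  The consensus frequency is the mean over four replicate
frequencies, replaced by the median when |mean − median| exceeds the
median.  After synonymous merging (frequencies and variances summed),
amino-acid genotypes with the appearance patterns (0,0,>0), (0,>0,0) or
(>0,0,>0) are discarded as artefacts; the dropout pattern (>0,0,0) is kept
for the boundary estimate.  Fitness is rescaled affinely so that the 95th
percentile of the nonsense distribution maps to 0 (placing 95% of nonsense
genotypes at 0 after clipping) and the mode of the extant distribution maps
to 1.  The mode is taken from a 0.01-wide histogram restricted to extant
values above the nonsense anchor: on strongly deleterious landscapes the
lethal extant pile would otherwise beat the neutral peak, and the neutral
anchor is by construction the upper local maximum.

## Synonymous false-discovery rates

For n = 1..10, every amino-acid genotype with more than n synonymous
variants contributes one random n-subset whose summed frequencies and
variances are refitted; the rescaled difference from the full amino-acid
fitness is thresholded at ±0.4 with strict inequalities.  Per-n rates are
combined with weights equal to the fraction of genotypes having exactly n
synonyms.

## Epistasis classification

A replacement's effect profile is the vector of fitness differences over
all genetic backgrounds (full amino-acid context at the other sites) in
which both states were measured.  The neutral fraction is the overlap
coefficient Σ min(p, q) between the profile and the synonymous-difference
null, on shared 0.05-wide bins; fractions beyond ±0.4 count as strong and
are flagged significant only above the corresponding FDR.  Sign epistasis:
backgrounds are split into large increases (> +0.4) and large decreases
(< −0.4); for every secondary site and state pair, a 2×2 table (secondary
state × effect sign) is tested with the two-sided conditional-probability
Fisher exact test, Bonferroni-corrected over all secondary replacements
tested for that focal replacement, at level 0.05.  A site is under sign
epistasis when one of its replacements has at least one significant
secondary (the focal, source side of an edge); reciprocal sign epistasis
requires significance in both directions.

## Fitness-potential network

Genotypes are one-hot encoded (site-major columns, states alphabetical).
The network has n sigmoid units in the first layer — each computing a
fitness potential p_j = c_jᵀx + b_j — then 20 sigmoid units, then one
sigmoid output; all three layers are sigmoidal.  Training: MSE loss,
RMSProp (learning rate 0.01, decay 0.9, batch 64), at most 100 epochs with
early stopping after 10 epochs without test-MSE improvement, a random 90/10
train/test split and Xavier-normal initialisation; each model is built from
ten independent restarts and the best-test-r² model is kept along with the
per-restart r² list.  The learning rate was set to 0.01 because at 0.001
the optimiser does not reach the realizable optimum within the 100-epoch
budget on datasets of a few thousand genotypes; all other optimiser
constants are conventional defaults.  Fitness is squashed into (0.01, 0.99)
before the sigmoid-output fit and mapped back on prediction.

Dimensionality: the scan reports test r² per n over the restarts.  The
gain from n to n+1 is the difference of restart medians, compared against
the restart scatter of the *larger* model: on genuinely multidimensional
data the n = 1 fits are multimodal — different restarts track different
potentials — so their spread measures misspecification, not optimisation
noise.  The scatter used for the "exceeds" contrast is the top-half
(converged-basin) spread, because with ten restarts one occasionally lands
in a distant local minimum — the very failure mode restarting guards
against — and a stray failed restart of the larger model should not mask
an order-of-magnitude improvement; the full spread is still reported as
the reproducibility figure (well under 2 percentage points on the planted
unidimensional data).  Conversely, gains below half a percentage point of
r² always count as "no improvement": differences at that scale sit far
inside the protocol's own reproducibility tolerance.

The planted two-potential landscape gives the two potentials disjoint site
support (sites 1-5 vs 6-10, penalties cycling 0.4/0.8/1.2 with a small
seeded jitter) under the product of two cliffs at threshold 1.6: fitness
is the AND of two independent threshold constraints, which no single
linear potential can order regardless of the jitter draw, while a single
potential still reaches r² ≈ 0.89 by merging the two constraints — the
planted analysis probes exactly that residual.

## Landscape topology

Between parents at Hamming distance d, the 2^d − 2 intermediates live on a
d-hypercube; only measured genotypes are vertices (missing genotypes break
paths rather than counting as fit or unfit) and shortest (length-d) paths
are counted by dynamic programming over BFS layers — each vertex's path
count is the sum over its present lower neighbours — which is exact and
avoids enumerating up to d! orderings.  "Unfit" means rescaled fitness
exactly 0; "fit" parents require fitness ≥ 0.6 (configurable — the
fitness bands of the quality-control analyses motivate 0.6 as the lower
edge of clearly-fit).  Null models redraw the observed number of unfit
intermediates uniformly (1,000 draws).  Connectivity uses the 1-replacement
graph degree, computed by bucketing genotypes on site-masked keys; random
same-size subsets are averaged over 1,000 draws.  Intra- vs inter-segmental
epistasis compares the unfit fraction among intermediates of fit pairs
(curve A, by pair distance; all pairs up to a 2,000-pair cap, uniformly
sampled beyond it) with the unfit fraction by distance from a reference
genotype (curve B); bins under 10 observations are suppressed and the
per-distance ratio B/A is reported.

## What the simulator does and does not emulate

The generator reproduces the statistical structure the estimators assume:
equal initial abundances passed through a founder bottleneck, exponential
growth, genetic drift as a Brownian perturbation of per-genotype log
frequency shared within each biological replicate (one increment for the
pre-competition growth plus one per elapsed interval, so drift variance
accumulates linearly in time — the serial-dilution competition accumulates
drift at every bottleneck, and this is what lets later time points be
noisier than sampling alone implies; the default increment sd is 0.05 per
unit time, and the drift law itself is not documented for the real
experiment), multinomial
read sampling at fixed depth, a single uniform per-nucleotide substitution
rate (10⁻³ by default; at most one error per read, no quality-score
structure, no indels), and template switching that recombines the two
variable halves at rate 10⁻⁴ with a frequency-weighted partner.  It does
not model PCR cycle chemistry, amplification jackpots, depth variation
between replicates, or contamination.  Passing recovery tests on these
simulations therefore demonstrates correctness of the estimators under the
stated noise structure, not robustness to artefacts outside it.

Planted landscapes map a linear potential (per-state penalties, wildtype 0)
through a cliff: fitness = plateau·σ((threshold − p)/steepness), i.e.
truncation selection; nonsense genotypes are forced to 0.  Pairwise terms
plant sign epistasis; additional independent, signed coefficient vectors
(the product of two cliffs) create genuinely multidimensional landscapes —
with all-positive coefficients the product of two cliffs is almost
unidimensional, which is itself a useful negative control.

## Study sizes and run times

The standard simulated segment has 8 variable sites → 12,288 nucleotide /
6,144 amino-acid variants at 10⁶ reads per replicate × time point; full
pipeline recovery of the planted landscape runs in ~2 minutes on one CPU,
dominated by the calibration grid.  The potential-model analyses use a
10-site vocabulary (3,456 genotypes), the sign-epistasis analyses the same
vocabulary, and the synonymous-FDR analyses a 5-site, synonym-rich segment
(5,184 nucleotide / 1,024 amino-acid variants; four L/V/M sites give most
genotypes 4-16 synonyms) at 10⁵ reads with drift sd 0.5 — conditions under
which a single nucleotide variant's fit has a rescaled standard error of
roughly 0.25, the regime where the ±0.4 thresholds are actually exercised.
A noteworthy property of the three-time-point design: as long as a variant
retains reads at t14, its fitness is pinned to within (relative noise)/14
by the final point, so false fitness calls are driven almost entirely by
variants that drop out of t14 and by accumulated drift, not by sampling
depth at t0/t1.

## Known limitations

* The abundance-greedy clustering is a behavioural stand-in for
  message-passing error correction: it conserves counts and recovers
  planted errors, but is O(n·parents) and is not bit-compatible with
  Starcode; at library scale the ≥ 10-read filter removes error variants
  anyway, so the pipeline does not depend on it.
* The calibration surface has a genuine (s̄_02, k) ridge when the fitness
  distribution is strongly bimodal (cliff landscapes): dropout-bound
  genotypes accept any sufficiently negative exponent and neutral genotypes
  cluster at one potential, so k is weakly identified from such data.  The
  affine rescaling absorbs the resulting shift — recovery correlations are
  unaffected — and the nuisance parameters themselves are recovered to one
  grid step on data with a spread of informative trajectories.
* Fisher tests are skipped for contingency tables with an empty margin;
  the Bonferroni family is the set of tests actually performed.
* The insertion-sharing template-switch estimator flags both members of a
  sharing pair; with one-member flagging the bound would be tighter, so the
  reported percentage is conservative.
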