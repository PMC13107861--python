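# Methods

## Input model and binarization

The unit of modelling is the *bead*: one fixed-size genomic bin (e.g.
1 Mbp or 500 Kbp), so a chromosome is a chain of beads and the genome a
sequence of chains (each haplotype copy of a diploid chromosome is an
independent chain). Raw contacts are binned by
`bead = offset + floor(pos / resolution)` with half-open 0-based bins, and
any multiplicity collapses to a 0/1 value per bead pair. This binarization
is deliberate: at single-cell depth the information carried by counts
above 1 is negligible, and committing to the binary regime is what lets
the method run where count-based tools fail. Same-bead pairs are dropped;
contacts on chromosomes absent from the binning are dropped with a logged
count rather than raised, since real files routinely carry scaffolds the
user did not ask to model.

## Theta imputation

The loss consumes a *theta matrix*: per-pair contact probabilities with
`theta = 1` on the observed support and imputed values elsewhere.

**Gaussian kernel.** For an unobserved pair, theta is the maximum Gaussian
response `exp(-((i-u)^2 + (j-v)^2) / (2 sigma^2))` over observed contacts
`(u, v)` within a Chebyshev window of `window` bins in matrix-index space.
Maximum (not sum) combination keeps theta <= 1 without renormalization.
Defaults `sigma = 1` bin, `window = 5` bins: imputed values then never
reach the 0.7 regime boundary (the nearest off-support value is
`exp(-1/2) ~ 0.607`), so under Gaussian imputation regime 1 of the loss is
exactly the observed contacts and the kernel's effect is confined to
sub-threshold smoothing. Both constants are exposed and are honest knobs:
larger sigma populates regime 2.

**Graph autoencoder.** The binary matrix is treated as an unweighted
graph; adjacency with self-loops is symmetrically normalized
(`D^-1/2 (A+I) D^-1/2`), a two-layer GCN encodes nodes into F = 128
dimensional embeddings, and a logistic inner-product decoder scores pairs.
Node features are the per-partner interaction-frequency vectors, i.e. the
rows of the binary matrix. A single scalar degree feature was rejected on
rank grounds: with one input feature every hidden activation is
proportional to the same vector, the embedding matrix has rank 1, and
inner products cannot order pairs beyond a degree product. Training is
full-batch cross-entropy on observed edges vs an equal number of non-edges
resampled each epoch, optimized with Adam (implemented in numpy along with
the backpropagation; the model is small enough that a deep-learning
framework would add nothing). Hidden width 32 follows the original GAE
convention; learning rate 0.01 with 300 epochs — of the classical grid
{0.1, 0.001, 0.0001}, 0.1 diverges under Adam here and 0.001 needs about
twice the epochs for the same held-out score. Early stopping triggers on a
relative loss plateau (< 1e-4 over 10 epochs).

Decoded output is sparsified rather than densely materialized (the dense
decode is quadratic in bead count, which is exactly what makes
genome-scale GAE imputation infeasible at very high resolution): decoded
probabilities are kept for intra-chromosomal pairs within 200 bins at
theta >= 0.5 and inter-chromosomal pairs at theta >= 0.9; probabilities
>= 0.99 are promoted to theta = 1 (entering the strictest loss regime);
observed pairs are always forced to 1.

**Link-prediction benchmark.** Imputation quality is measured by holding
out 10% of observed edges, retraining, and ranking held-out edges against
an equal number of sampled non-edges (AUC and average precision). The
benchmark instance is the geometric contact graph of two simulated
chromosome territories (edges = bead pairs within the capture radius, 10%
dropout). A pure two-block stochastic block model was considered and
rejected: with block membership as the only signal, within-block non-edges
are statistically exchangeable with held-out edges and a Bayes-optimal
scorer caps near AUC 0.7, so no method could demonstrate useful imputation
there. The geometric graph has Bayes AUC ~0.99 and is the regime the
imputer actually faces; the GAE reaches AUC/AP ~0.95-0.98 on it.

## The objective

Pair terms by imputed probability (distances in lattice units):
regime 1 (`theta = 1`): `w1 * max(0, d - d_target)^2`;
regime 2 (`0.7 <= theta < 1`): `w2 * theta * max(0, d - d_target)^2`;
regime 3 (`theta < 0.7`): `w3 * max(0, d_target - d)^2`, a weak repulsion
that keeps non-contacting pairs from collapsing. All pairs additionally
feel excluded volume `w1 * max(0, d_repel - d)^2`. The quadratic hinge
forms are this package's concretization of the three-regime design: they
vanish at the target distance, reproduce the stringency ordering
(regime 1 most stringent, regime 3 loosest), and are isolated behind
`pair_loss` so alternative functional forms can be swapped in. Defaults:
`d_target = 8`, `theta_threshold = 0.7`, `w1 = 1.0 >= w2 = 0.5 >= w3 =
0.1`, `d_repel = 1`, backbone weight `w_bb = w1` with the same target
distance (consecutive beads are trivially in contact).

Intra-chromosomal pair terms are weighted by
`C_ratio = 1 / (floor(count1 / count2) + 1)` and inter-chromosomal terms
by `1 - C_ratio`, with count1/count2 the intra/inter contact counts of the
*binary observed* matrix (not the imputed one). The formula is implemented
literally, including its odd corner: whenever `count1 < count2` it yields
`C_ratio = 1` and the inter weight vanishes — harmless in practice since
real single-cell maps always have intra >> inter, and the degenerate
`count2 = 0` case (single chromosome) returns 1 by definition.

Confinement to the `(5l)^3` box is enforced by rejecting moves that leave
it, not by a finite penalty, so loss values stay comparable across runs;
`total_loss` reports infinity for a structure outside the box.

**Evaluation cost.** The full pair sum is evaluated as a short-ranged
background (regime 3 + excluded volume vanish beyond `d_target`) plus
explicit corrections for the pairs with `theta >= 0.7` — algebraically
identical to the naive double loop (tested to 1e-9 relative against a
brute-force oracle) but O(l + degree) per single-bead move.
`partitioned_loss` evaluates the same sum as contiguous bead-block partial
sums (each pair charged to its lower index) and matches the serial result
to summation-order accuracy; this determinism contract is what makes
parallel evaluation safe, though execution here is serial — on the
problem sizes this package targets the compiled kernel is not the
bottleneck.

## Annealing

Initialization is a self-avoiding unit-step lattice walk for the whole
chain, chromosome after chromosome, from a random in-box site. Moves pick
a bead uniformly and displace it by one of the 26 unit lattice offsets
(scaled by a step size, 1.0 by default); Metropolis acceptance is
`min(1, exp(-dE/T))`. Cooling is geometric, `T_c = T0 * alpha^c` with
`T0 = 10`; each temperature runs to equilibrium (10 accepted moves per
bead on average, or 100 attempts per bead). Three variants:

- `standard` (`alpha = 0.9`): stops at a temperature floor of 1e-3 — the
  per-temperature equilibrium rule needs a global stop, and by T ~ 1e-3
  acceptance of any uphill move is numerically dead — or earlier on a
  zero-accept round;
- `coarse` (`alpha = 0.9`): stops after three consecutive rounds with no
  accepted moves ("round" = one full equilibrium cycle at one
  temperature); because zero-cost plateau moves are always accepted, this
  rule can in principle never fire, so a 200-round safety bound applies;
- `fast` (`alpha = 0.6`): stops when the temperature reaches `T_min =
  0.1` (exactly 10 cooling steps from `T0 = 10`).

Coordinates become continuous after the stage-1 scaling (the 1.2x lattice
is no longer integral); stage-2 proposals use the same 26-direction
kernel. Self-avoidance is soft — the excluded-volume term, not hard site
exclusion — which keeps acceptance well-defined off-lattice. Runs are
fully deterministic for a fixed (inputs, parameters, seed): per-round RNG
streams derive from the master seed.

## Two-step coarse-to-fine

Stage 1 bins, imputes and anneals at the low resolution (e.g. 10 Mbp);
coordinates are scaled by `0.12 * (low/high)` and recentered into the
high-resolution box (side `5 * l_high`); `low/high - 1` equidistant beads
are interpolated into each within-chromosome segment (never across
chromosome boundaries — cross-boundary interpolation would fabricate
inter-chromosomal tethers); stage 2 anneals at the high resolution from
that start. Chromosome-end remainders extend along the last segment
direction at the established spacing. Non-integer resolution ratios are
rejected with guidance. Schedule pairing: targets at or above 0.5 Mbp use
identical standard schedules in both stages; below that, coarse stage-1 +
fast stage-2 (open-ended cooling is prohibitive at those bead counts).
The value of the framework is measurable: the interpolated start enters
stage 2 at a lower loss than a random initialization (tested as a median
over seeds).

## Structure assessment

All metrics consume pairwise Euclidean distances only, so they are
invariant to rigid motion and reflection and need no superposition
(Kabsch) step — in particular, run-to-run reproducibility and
truth-vs-reconstruction concordance are Pearson correlations of
upper-triangle distance-matrix entries, restricted to intra- or
inter-chromosomal pairs as requested.

Contact/non-contact group statistics report means, medians and a
one-sided Mann–Whitney rank-sum test (contact distances smaller), per
20 Mbp genomic-distance band and overall.

`P(s)` is the fraction of intra-chromosomal pairs at genomic separation
`s` whose spatial distance is below the contact threshold (the loss target
distance, 8, by default), in log-spaced bins (20 per decade), with a
log-log slope fitted for comparison against the fractal-globule (`s^-1`)
and ideal-chain (`s^-3/2`) references. The slope is fitted over the bins
with `P` in (0.002, 0.3): the closed-form ideal-chain curve (Maxwell CDF
of the threshold at scale `sqrt(s/3)`) shows that any window touching the
`P ~ 1` shoulder biases the apparent exponent shallow — over a
(0.01, 0.9) window the true ideal-chain slope reads -1.18, over the
dilute window -1.37 at chain length 2000 (asymptotically -1.5) — so the
default window measures the scaling regime, not the crossover. For
ensemble benchmarks, `pool_ps_curves` sums contact counts across
independent realizations before fitting: a single conformation does not
self-average at large s (all its large-separation pairs share one global
fold), so per-realization slopes scatter several times more widely than
the pooled fit.

Radial positioning is the distance to the nuclear center of mass (mean
bead coordinate), per bead and aggregated per chromosome; the
annotation-based radial test compares two per-bead label groups (e.g.
A/B-compartment proxies) by a one-sided rank-sum test.

## Synthetic ground truth

The generator makes the study conditions explicit. Each chromosome grows
as a unit-step random walk with soft overlap rejection (0.7 lattice units
minimum separation, 60 retries per step) inside its own *territory*
sphere, whose center is drawn inside the nucleus with a one-territory
margin; spherical confinement (rather than the reconstruction's cubic
box) guarantees that radial structure and territories exist to recover.
Contacts: every pair within `capture_radius` is emitted with probability
`capture_rate`, plus `noise_rate` x (emitted) uniformly random spurious
pairs; positions are bin midpoints, counts 1. `target_pair_density`, when
set, solves for the capture rate that yields a requested contact density.

The reference instance is 3 chromosomes x 200 beads (l = 600) at 1 Mbp,
nucleus radius 25, territory radius 10, capture radius 3, density target
1%, noise 2% — small enough that a full two-step build takes seconds,
sparse enough to exercise the binary regime, and with intra contacts
outnumbering inter roughly 6:1, exercising the balancing coefficient
(`C_ratio ~ 0.14`). On it, the two-step build recovers intra-chromosomal
distance matrices at Pearson ~0.6-0.75 (median over 5 replicates),
contact pairs sit ~4x closer than non-contact pairs (rank-sum p
underflows to 0), and 10 annealing seeds agree at mean pairwise Pearson
~0.7-0.8 with sd < 0.1.

What the generator does *not* emulate: genomic-distance-dependent contact
decay beyond what territory geometry induces, cell-cycle conformations
(mitotic rods, lobed nuclei), haplotype-phasing errors, and mapping noise
beyond uniform spurious pairs. Passing the recovery benchmarks therefore
shows the estimator recovers geometry from sparsity and noise of the
assumed kind; it does not certify accuracy on real cells, which is why
the assessment suite (contact/non-contact separation, P(s) scaling,
radial tests, reproducibility) is shipped as a first-class module for use
on real reconstructions.

## Numerical choices and degenerate inputs

- Positions on bin boundaries belong to the higher bin (half-open bins);
  positions at or past the chromosome end are dropped.
- `downsample_contacts` takes exactly `floor(fraction * n)` records,
  uniformly without replacement, preserving input order.
- Theta entries below the regime threshold never enter the attraction
  terms, so kernel-underflow entries (tiny sigma) are dropped rather than
  stored as zeros.
- Structure files round-trip coordinates at 6 decimals; box side and
  resolution travel in header comments.
- The annealing loop seeds each temperature round from a SeedSequence
  spawn of the master seed; identical seeds give bit-identical structures.
- Test and benchmark problem sizes (600-bead reference instance, 200-node
  link-prediction graph, 4 x 2000-bead ideal chains) were chosen as the
  smallest instances on which the respective effects are comfortably
  resolvable.

## Known limitations

- The exact functional forms behind the three regimes are this package's
  own (hinge-quadratic) choice; published variants of the three-regime
  design differ in detail. They are isolated behind `pair_loss`.
- GAE imputation is quadratic in bead count at decode time even with
  banding; it is intended for resolutions around 1 Mbp, not 20-50 Kbp.
- No nuclear-envelope or lamina prior: radial organization emerges (or
  not) from the contacts alone.
- Haplotype assignment of diploid contacts is assumed done upstream; the
  parser only consumes pre-tagged labels.
- `C_ratio` follows the floor formula literally, including the
  inter-weight-zero corner described above.
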