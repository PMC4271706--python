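# Methods

This note documents the models, defaults, numerical choices, and known
limitations of `biomepool`. Everything quantitative stated here is computed
by the test suite or `scripts/acceptance.py`; nothing is asserted from
memory.

## Dated trees

Trees are rooted, binary, and dated in Myr before present; extant tips sit
at age 0 and internal ages are depths subtracted from the root age.
Non-ultrametric trees (simulated extinct tips) are accepted by the
container, but the birth–death likelihood validates ultrametricity and the
biogeographic stages require observed (non-extinct) tips. Newick parsing
and writing go through dendropy; node labels after `)` are kept as
metadata, bracket comments are dropped, and missing branch lengths or
duplicate tip labels are parse errors. Pruning preserves the ages of
retained nodes and records a map back to the source tree's node ids, which
the simulator uses to restrict ground truth to the observable tree.

## Range evolution model

Ranges are subsets of an ordered area list encoded as bitmasks; the state
space holds all subsets of size 1..`max_range` plus an absorbing extinct
state (listed last; ordering is by cardinality then bitmask value, so
indices are reproducible). Defaults mirror the motivating study: seven
areas (SA, CA, Me, Ca, As, Af, M) with `max_range = 4`, the maximum range
observed among extant taxa there.

Anagenesis: gain of area *a* from range *R* at rate `d * sum_{b in R}
m_k[b, a]`, loss of each occupied area at rate `e`; losing the last area
enters the extinct state. The epoch schedule holds one multiplier matrix
per interval (default boundaries 70/45/30/5/0 Myr). The source study states
only that multipliers span 0.1 (well separated) to 1.0 (contiguous), so the
package ships `example_epoch_schedule()` — a documented, editable example
in which the South America ↔ Central America ↔ Mexico connections
strengthen toward the present — and treats the schedule as user input.

Cladogenesis weights (normalized per parent range): DEC — narrow sympatry
for singletons, subset sympatry and smaller-part-size-1 vicariance
otherwise; DIVALIKE — vicariance of any split; BAYAREALIKE — identical-copy
sympatry only. All `+J` variants add founder events, one daughter jumping
to any single unoccupied area with weight `j`. Founder weights are *not*
scaled by the dispersal multipliers: the unscaled form is the simplest
model nesting the base variants, and nothing in the source analysis pins
the scaled alternative (a scaled mode would be a straightforward extension
of the cladogenesis table).

The likelihood is Felsenstein pruning over the state space with per-node
rescaling; branch propagation multiplies per-epoch-segment matrix
exponentials, oldest first. Internally each epoch generator is
eigendecomposed once so a branch segment costs two matrix–vector products;
the decomposition is verified against `expm` at construction (tolerance
1e-9) and falls back to dense `expm` when ill-conditioned. The root prior
is flat over non-extinct states; the extinct state contributes zero tip
likelihood and is excluded from the root average. (Whether the original
pie-chart marginals used a flat or a state-size-weighted root prior is not
stated in the source; flat is the package's choice.)

Fitting maximizes over (log10 d, log10 e[, j]) with L-BFGS-B, bounds
d, e ∈ [1e-9, 5] Myr⁻¹ and j ∈ [0, 3], three starts (one fixed, the rest
seeded); non-convergence is flagged on the result, never raised. AIC
= 2k − 2 logL with k = 2 (base) or 3 (+J); Akaike weights are normalized
exponential half-ΔAIC.

Marginal ancestral ranges combine the inside pass with an outside pass
through the cladogenesis table; the most-probable state per node uses the
tie-break highest probability → smaller range → lower state index
(deterministic, conservative about event calls). Both the likelihood and
the marginals are verified against exhaustive enumeration over all
internal-state assignments and cladogenetic outcomes on small instances.

**Known limitation — extinction-rate bias.** Simulated range histories in
which a lineage's range empties are flagged extinct and must be pruned
before fitting (tips need observed ranges), but the likelihood does not
condition on survival. The ML extinction rate `e` is therefore driven
toward zero on simulated-then-pruned data: profiling the likelihood in `e`
on representative 200-tip datasets shows the boundary `e ≈ 0` genuinely
dominates the true `e = 0.01` by several log units. This survivorship bias
is a documented property of DEC-family inference (and is aggravated by +J
absorbing contraction signal); `d` and `j` recover within a factor of two
at the study conditions, `e` does not. The acceptance suite asserts the
full parameter-recovery property anyway and the `e` component is expected
to fail, by design rather than be papered over.

## Events, rates, inflection

Expansion: focal area absent at the parent node, present at the child.
Restriction: child range exactly the focal singleton, parent different. A
branch can emit both. The root emits one expansion if its range contains
the focal area. Events are dated at the stem (parent) node by default
(`crown` and `midpoint` conventions available) because the source anchors
events at stem nodes. Events are called on most-probable states; a
probability-weighted counting mode is a sensible extension but the
most-probable method is what the recovery tests validate. The simulator's
truth events are extracted from true node states with the same conventions,
so recovery comparisons are like-with-like.

Dispersal rate = n_events / (oldest − youngest event age); windows with
fewer than two distinct ages flag an undefined rate rather than divide.

Inflection: the cumulative event-count curve over calendar time
(x = −age) is compared with the chord joining its endpoints. EDE takes the
x of the extremal deviation; ESE balances the trapezoidal area between
curve and chord; the consensus is their mean, mapped back to an age. When
the deviation changes sign substantially (sigmoid-like curves) each
estimator uses the midpoint of its per-sign solutions — this two-sided form
recovers the midpoint of a symmetric logistic exactly, and reduces to the
one-sided rule for single-signed (convex) deviations such as a two-rate
Poisson cumulative curve. Curves whose maximal relative deviation is below
5% of the count span are flagged degenerate (no inflection). Before/after
rates use `count(age > t*)/(oldest − t*)` and `count(age ≤ t*)/(t* −
youngest)`.

Ensemble summaries are arithmetic means with empirical 2.5/97.5 percentiles
(linear interpolation); per-tree values are retained next to every summary.

## Climate, reconstruction, lag

Species profiles are arithmetic means of occurrence records per species;
non-numeric records are rejected with a warning. Groups: endemic (range
exactly the focal area), widespread (focal plus others), non-focal.

PGLS uses the BM covariance C[i,j] = shared root-to-MRCA path length and a
3-level group factor with non-focal as reference (statsmodels GLS under the
hood); pairwise contrasts report t statistics with n − p degrees of
freedom. Across an ensemble the pipeline reports the fraction of trees with
a significant contrast.

BM ancestral ML: root = GLS mean (1ᵀC⁻¹y)/(1ᵀC⁻¹1), σ̂² = rᵀC⁻¹r/n,
internal states are the GLS conditional expectations (verified against the
closed form). The Bayesian variant is a Gibbs sampler — every full
conditional is normal (node states) or inverse-gamma (σ², flat prior) — so
draws are exact and the reported acceptance rate is 1 by construction;
default 10,000 sweeps with 20% burn-in, and a tiny floor on σ² keeps the
chain defined for constant tip data.

Threshold crossing: walk root → target; the first branch passing from above
to at-or-below the threshold dates the crossing by linear interpolation in
time between node point estimates (no within-branch uncertainty band in
v1); a root already at/below the threshold crosses at the root age; later
re-crossings are counted but do not move the (oldest) crossing, matching a
"first evolved" reading. Default thresholds: bio12 ≤ 1800 and 1600
mm yr⁻¹, bio17 ≤ 50 and 100 mm qtr⁻¹ (traditional and alternative
definitions of the seasonally-dry-forest conditions).

Lag = crossing age − restriction age. Concurrent means the crossing lies on
the restriction's own branch (the source does not define "concurrent"; the
same-branch rule is deterministic and scale-free, and a ±τ window variant
would slot into `lag_time`). No crossing at all is classed in-situ with the
lag flagged undefined rather than guessed.

## Diversification and PD

Constant-rate reconstructed birth–death with sampling fraction f
(independent tip inclusion), conditioned on the crown age and both crown
lineages being sampled; the pure-birth/f = 1 boundary is verified against
the closed-form Yule likelihood. ML is over (log10 λ, μ/λ ∈ [0, 1)). The
λ = μ limit is handled by an epsilon nudge. Extinction estimates on
reconstructed trees are mode-at-zero with a heavy right tail — the familiar
pathology — so tests assert that character rather than a tight μ̂ ≈ 0.

The rate-shift scan is an explicit simplification standing in for
compound-Poisson shift machinery: for each candidate clade (≥ 5 tips, not
the root) the tree is decomposed into the clade subtree and the backbone
(clade collapsed to one representative lineage), and shared (λ, μ) (k = 2)
is compared with separate rates (k = 4) *on the same decomposition*, so the
AIC comparison is properly nested; non-nested candidates with ΔAIC above
the threshold (default 4) are accepted best-first up to `max_shifts`.

MPD partition: patristic distances pooled over all within-introduction
pairs vs all between-introduction pairs (pair-weighted; introductions with
one tip contribute no within pairs). Because published mean-phylogenetic-
distance values are ambiguous between full and half path length, both are
reported (`mpd_*` and `mpd_*_half`). Tips are assigned to introductions by
their youngest expansion ancestor. The χ² sampling-bias test is the plain
Σ(O−E)²/E statistic with k − 1 degrees of freedom (scipy's χ² tail), with
an explicit error suggesting pooling when an expected count is zero.

## Synthetic data

The generator is the package's study-conditions definition, not a tuning
dial. Defaults: 395 extant species (the usable-species count of the
motivating dataset), birth 0.2 / death 0.1 Myr⁻¹, DEC+J truth (d = 0.02,
e = 0.01, j = 0.1), the example epoch schedule over 7 areas with
max_range 4, root range {SA}, BM climate with roots 2200 mm yr⁻¹ (bio12)
and 250 mm qtr⁻¹ (bio17) and variance rates 5000 and 120 units² Myr⁻¹
(chosen once to give realistic extant spreads over an ~80 Myr tree), 8
occurrence records per species (the median record count of the motivating
occurrence data) with 300/50 units of within-species noise.

Range histories use exact Gillespie stepping per branch with epoch-aware
rates identical to the likelihood's generator (branches crossing epoch
boundaries are segmented); the cladogenetic outcome at a node is drawn from
the same cladogenesis distribution the likelihood uses, applied to the
post-anagenesis range. The complete event log is returned and replaying it
from the root reproduces the tip ranges exactly (tested). Tree ensembles
jitter internal node ages multiplicatively (Normal(1, sd) factors,
monotonicity enforced by resampling), emulating bootstrap age uncertainty
without re-inferring topologies.

What the generator does *not* emulate: spatially explicit occurrence
structure (records are iid Gaussian around the species mean), correlation
between climate and geography (traits and ranges evolve independently
unless shifts are supplied), diversification–range feedbacks (the tree is
simulated first, ranges afterwards), and fossil tips. Passing tests
therefore demonstrate correctness of the inference machinery under its own
assumptions, not robustness to the violations real data bring.

## Problem sizes and scaled study conditions

Recovery suites run at sizes chosen for a desk machine: the DEC+J
parameter/event-recovery study uses 50 replicates of 200-tip trees over 4
areas with a 2-area range cap (11 range states; the area count is the
package's scaled-down choice — the criterion fixes tips and rates but not
areas), dispersal multipliers 0.3 → 1.0 at 24 Myr. Replicates in which
three quarters of the tips lose their range entirely (whole-clade
extinction cascades) are replaced by fresh draws, conditioning on an
analyzable dataset rather than on any inference outcome. The inflection
recovery uses 100 two-rate Poisson replicates (0.3 → 1.7 events/Myr at 24
Myr); PGLS calibration uses 500 null replicates on one 100-tip tree;
birth–death recovery uses 50 half-sampled 400-tip trees; the end-to-end
pipeline recovery uses 20 seeds of 150-tip two-rate simulations in
fixed-parameter mode (the ML fit is exercised separately, so the
end-to-end check isolates the event/inflection chain).

## Determinism

Every generator and sampler takes an explicit integer seed; the pipeline
derives per-stage substreams from one master seed via a CRC-based mix, and
a fixed seed reproduces the run report byte-for-byte apart from timing
fields (tested).
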