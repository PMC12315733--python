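# Methods

`sfcoupling` implements, at desk scale, a complete analysis of
structure–function coupling in brain networks: predicting functional
connectivity (FC) from structural connectivity (SC) with a graph
neural network, decomposing coupling into group-common and
individual-specific effects, and testing the cortical-axis
organization of those effects against topology-randomizing and
spatial-rotation null models.  Because the empirical datasets this
kind of study uses (multi-subject diffusion + resting-state MRI) are
access-restricted and far beyond desk scale, the package ships a
synthetic cohort generator with *known* group and individual
structure, so every estimator can be validated by parameter recovery
rather than by smoke tests.

## The estimand: group vs individual coupling

Structure–function coupling for a (source, target) subject pair is the
Pearson correlation between a structural profile of the source subject
and the empirical FC profile of the target subject, over unique edges
(globally) or over one region's row profile (regionally).  Two
structural profiles are supported:

* **correlation approach** — the SC edge weights themselves,
  restricted to edges with nonzero SC in the source subject (direct
  connections only);
* **GNN approach** — the model-predicted FC of the source subject,
  over all unmasked unique edges, so indirect (polysynaptic)
  communication contributes.

Computing coupling for every ordered subject pair of a test set of N
subjects gives an N×N asymmetric coupling matrix `cp`.  Its diagonal
("matched" coupling) reflects everything shared plus subject identity;
its off-diagonal ("mismatched") entries reflect only what transfers
between subjects.  The decomposition is

    total      = mean_i cp[i,i]
    group      = mean_{i≠j} cp[i,j]
    individual = total − group,

with per-subject mismatched coupling
`(1/(2(N−1))) Σ_{j≠i}(cp[i,j]+cp[j,i])` and a two-sided paired t-test
of matched vs mismatched across subjects (closed form,
`t = mean(d)/(sd(d)/√N)`, df = N−1) for the significance of the
individual effect.  `total = group + individual` holds exactly by
construction; the test suite asserts it against an independent
double-loop implementation at 1e−12.

## The predictive model

A two-layer graph convolutional encoder over the SC adjacency with
self-loops,

    H^{l+1} = PReLU( D̂^{−1/2} (A + I) D̂^{−1/2} H^l W^l ),    H^0 = I_K,

(one trainable PReLU slope per layer, initialized at 0.25), followed by
an edge decoder `pFC_ij = W2·ReLU(W1·[h_i; h_j] + b1) + b2`.  The loss
is the mean squared error over ordered off-diagonal pairs,
`(1/N_b) Σ_subjects (1/(K(K−1))) Σ_{i≠j} (pFC_ij − eFC_ij)² + λ‖W_MLP‖²`,
with the L2 penalty on the MLP weight matrices only (no biases, no GCN
weights).  Training uses Adam (0.9/0.999, eps 1e−8) on batches of 2
subjects; predictions are symmetrized as `(pFC_ij + pFC_ji)/2` with
zero diagonal only at prediction time.

Defaults at desk scale (K=60): GCN dims K×64×64, MLP 128×64×1,
learning rate 7e−3, λ=1e−4, 250 epochs.  For an empirical 400-node
parcellation the natural settings would be 400×256×256, 512×64×1,
lr 1e−3, 400 epochs; the higher desk-scale learning rate compensates
for the much smaller problem and epoch budget (at 1e−3/200 epochs the
small model is still far from converged).  The MLP hidden width is 64
because width 32 demonstrably underfits even the group-stable part of
the target (the decoder must effectively encode a region-pair table
plus topology terms from one-hot-derived embeddings).

The forward and backward passes are written directly in NumPy.  The
model is small (tens of thousands of parameters), every run is exactly
reproducible from its seed, and the analytic gradients are verified
against central finite differences at 1e−4 relative error in the test
suite.  Training cost is roughly 50 s for the default cohort on one
CPU core.

## The synthetic cohort generator

The generator emulates the features of a real cohort that matter for
this analysis, with every component scale a parameter:

* **Backbone.** A stochastic block model over 4 contiguous modules
  (within/between edge probabilities 0.45/0.10) plus hub nodes (10% of
  regions, extra edge probability 0.3), i.i.d. lognormal(0, 0.5) edge
  weights, resampled (bounded) until connected.  Default density ≈
  0.25 at K=60.
* **Region metadata.** Quasi-uniform unit-sphere coordinates per
  hemisphere (Fibonacci lattice, right hemisphere mirrored), lognormal
  volumes, and a sensorimotor→association-like axis: regions are
  ranked by a spatially smooth random field on the sphere (sum of
  Gaussian bumps, mirrored across hemispheres), so the axis is
  spatially autocorrelated — the property the spin test requires.
* **Subject SC.** Biological jitter multiplies each backbone edge
  weight by exp(N(0, τ=0.1)); this jittered SC is what generates the
  subject's FC.  The *observed* SC additionally carries measurement
  noise (lognormal sd 0.2) and random edge flips (rate 0.02) that do
  **not** propagate into FC — emulating tractography noise.  Without
  this split, the correlation approach trivially "recovers" its own
  measurement noise and its individual effect dwarfs the GNN's, the
  opposite of what happens in real data where streamline counts are
  noisy.
* **FC forward model.**

      FC = standardize(0.5·Ā + 0.5·Ā²) + γ_g·G
           + √(σ_u σ_v)·I_i + N(0, ε),

  with Ā the degree-normalized biological SC, standardization to zero
  mean/unit variance off-diagonal (so all component scales are
  interpretable), G a shared rank-3 standardized symmetric component
  (γ_g=1) emulating functional-system structure that is tied to region
  identity but not to SC, and ε=0.2 observation noise.  The individual
  component I_i mixes (a) the subject's standardized *two-hop* latent
  deviation from the backbone (standardize(Ā_i² − Ā_backbone²)) —
  individual variation that is predictable from the subject's own SC
  but rides on indirect communication that direct edgewise correlation
  largely misses — and (b) fresh i.i.d. symmetric noise with no
  structural counterpart.  Two properties of the mix vary along the
  axis: the regional scale σ(r) = γ_i·(1 + s·(rank_r−1)/(K−1))
  (γ_i=0.5, s=3), and the *structurally coupled share* of the mix,
  rising from 0.3 at the sensorimotor-like pole to 0.9 at the
  association-like pole (edge (u, v) weights the structural part by
  √(w_u w_v) and the noise part by √((1−w_u)(1−w_v))).  The share
  gradient matters because the estimated regional individual effect is
  a correlation-scale quantity: scaling only the individual *variance*
  along the axis inflates the regional FC variance (the denominator)
  in step with the signal (the numerator), largely cancelling the
  regional contrast; letting the capturable share grow instead raises
  the numerator without extra denominator growth, so association-like
  regions carry not just more individual variance but more
  structurally coupled — hence recoverable — individual variance, as
  the empirical literature on association-cortex individual
  variability suggests.

The design makes the qualitative empirical regime reproducible from
first principles: the shared low-rank component G is learnable by the
GNN (through node-identity embeddings) but invisible to direct SC–FC
correlation, so GNN coupling far exceeds correlation coupling; the
two-hop individual component is captured by the two-layer GCN but not
by direct correlation, so the GNN detects larger individual effects;
and rewiring the training SC destroys both the multi-hop latent and
the embedding–identity correspondence, collapsing coupling.

Quantities the generator deliberately does **not** emulate: BOLD
hemodynamics, autocorrelated time series (FC matrices are generated
directly on the Fisher-z scale), realistic cortical geometry or
geodesic distances, tractography length biases, and site/age
structure.  Passing tests therefore show estimator correctness and
recoverability under a faithful generative analog — not performance on
real MRI data.

## Preprocessing rules

* FC from time series: Fisher-z of Pearson correlation, |r| clipped at
  1−1e−7 before atanh, zero diagonal.
* SC normalization: streamline counts divided by the mean volume of
  the two regions, then log-transformed.  `log1p` is the default
  (zeros stay zero and weights stay nonnegative even when volume
  normalization pushes them below 1); `log_nonzero` is available as a
  config option.
* Group-consistency thresholding: for every edge present in at least
  one subject, the across-subject coefficient of variation (sample
  SD/mean, zeros counted as 0-weight observations, penalizing
  inconsistent presence); edges above the 75th percentile of the CV
  distribution (linear-interpolation quantiles) are removed, as are
  edges absent everywhere.  The mask is computed on training subjects
  only and applied cohort-wide, preventing test-set leakage; a config
  flag allows whole-cohort computation.  CV is computed on pre-log
  weights (CV is scale-invariant, so this matters only through zero
  handling).
* Motion QC, in fixed order: (1) drop runs with >25% of frames above
  0.2 mm framewise displacement; (2) pool mean FD of surviving runs
  across subjects and drop runs above Q3 + 1.5·IQR of that
  distribution; (3) exclude subjects with fewer than 4 surviving runs.

## Null models

**Rewiring.** Maslov–Sneppen double-edge swaps (10 successful swaps
per edge, bounded attempts) randomize binary topology while exactly
preserving every node's degree; the original weight multiset is then
reassigned to the new edges by rank-matching weights to the sum of
endpoint strengths, approximately preserving nodal strengths (exact
joint degree+strength preservation is NP-hard; this mirrors the
standard toolbox behavior).  A graph with no valid swap (e.g.
complete) is returned unchanged with a warning.  Only training SC is
rewired; the test SC stays intact, so the comparison isolates what the
model learned from topology.  Reported as per-subject coupling for
both models and the drop in variance accounted for,
`mean(r_emp²) − mean(r_null²)`.

**Spin test.** Each rotation draws a uniform random 3D rotation
(applied to the left hemisphere, mirror-conjugated for the right) and
reassigns rotated regions to original regions by greedy
nearest-neighbor matching without replacement, yielding a true
permutation (value multisets are preserved exactly, unlike
projection-based variants that can duplicate assignments).  The
p-value is the fraction of null correlations at least as extreme as
the empirical one in the direction of its sign (no +1 smoothing; a
reported 0 means < 1/n_rotations); a two-sided option compares |rho|.
Calibration: when the tested map is itself drawn from the rotation
ensemble, empirical and null statistics are exchangeable and the
two-sided p is uniform (verified by KS test).  For a fixed map that
was not generated by rotation, parcel-level spinning at K≈40–60 is
only approximately calibrated — rotating one map explores its
orientation orbit, not map-shape variability — which is the standard
caveat of parcel-level spin tests and is why the calibration test uses
the exchangeable construction.

## Axis alignment

Regional effect maps are compared with axis ranks by Spearman rank
correlation (average ranks for ties).  Outliers beyond mean ± 3·SD of
the map (sample SD) are excluded; the mask is recomputed per map, and
each spin permutation is applied to the full-length map before the
same mask is applied, so empirical and null correlations see identical
exclusions.  Missing regions (degenerate profiles) are dropped
pairwise.

## Pipeline and reproducibility

`pipeline.run_study` chains generate/load → motion QC → 50/50 split →
consistency mask → train → predict → global and regional coupling for
both approaches → decomposition with paired t → rewired null → axis
alignment, and emits one JSON report.  All stage seeds derive from a
single master seed via `SeedSequence([master_seed, stage_tag])`, so a
rerun is byte-identical.  `pipeline.run_repeated_cv` repeats the
two-fold split with role reversal (every subject tested exactly once
per repeat) and aggregates coupling, individual fraction, and
alignment rhos across folds.

Problem sizes used throughout (N=80 subjects, K=60 regions, 250
epochs, 1,000 spin rotations, seeds 0..4 for replication) are the
package's desk-scale defaults: large enough that the coupling matrix,
regional maps, and null distributions are informative, small enough
that the full study runs in about two minutes per seed on one CPU
core.

## Known limitations

* The GNN captures only part of the generated individual signal
  (capture efficiency depends on capacity and epochs), so estimated
  individual effects are attenuated relative to their generative
  scale; recovery tests assert ordering and significance, not absolute
  magnitudes.
* The correlation approach's individual effect *decreases* with the
  individual-component scale here, because that component is two-hop
  by design; in datasets where individual variation rides on direct
  edges the ordering could differ.
* Regional coupling estimates at K=60 use 59-edge profiles and are
  correspondingly noisy; axis-alignment correlations are moderate by
  design, not estimates of any empirical effect size.
* The paired t-test assumes approximately normal matched−mismatched
  differences across subjects; with N_test=40 this is adequate for the
  simulated data but is not a substitute for the permutation
  alternatives one might prefer on real data.
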