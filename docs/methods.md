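# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `leakmend`, and what the simulation-based tests do and
do not establish about real data.

## Symmetric orthogonalisation

**Model.** Leakage is assumed to be a purely linear, zero-temporal-lag
mixing of otherwise-uncorrelated channel time-courses. Under that
assumption, removing all zero-lag correlations removes the artefact
exactly; any surviving envelope correlation is attributed to genuine
coupling. The cost is that *true* zero-lag dependence is removed along
with the artefact — the method cannot distinguish the two.

**Algorithm.** `symmetric_orthogonalise` minimises `ε = ‖Z − OD‖²_F`
over orthonormal `O` and positive diagonal `D` by alternating the two
closed-form updates (polar factor of `ZD`; `d = diag(ZᵀO)`). With the
optimal `d` in hand, ε is evaluated as `‖Z‖²_F − Σ dᵢ²`, which is exact
and cheap. Convergence is monotone but only to a local minimum in
general; the iteration is deterministic, so results are reproducible
bit-for-bit.

* **Stopping rule** (tunable): `|ε_k − ε_{k−1}| / ‖Z‖²_F < 1e−10`, cap
  50 iterations. The rule is scale-free; the cap is generous relative to
  the typical ≤ 20 iterations observed on correlated data. Hitting the
  cap flags `converged=False` rather than raising, so batch experiments
  continue.
* **Rank tolerance:** inputs with `σ_min/σ_max < 1e−10` are rejected as
  degenerate — the closest-orthonormal problem has no unique solution at
  rank deficiency, and this matches the double-precision SVD noise
  floor. Correcting more nodes than the data's rank is out of scope for
  the same reason.
* The number of tandem iterations is counted as the number of (O, d)
  update pairs; convergence is declared on the first iteration whose ε
  matches its predecessor to tolerance, so an already-orthogonal input
  reports 2 iterations.

The pair-wise correction (`pairwise_orthogonalise`) regresses one series
of a pair from the other and is retained purely for method comparison;
it is seed-dependent, and downstream code averages edge estimates over
the two seed choices. Pairs with |cosine| above `1 − 1e−10` are treated
as collinear and reported as missing edges rather than fitted.

## Envelopes

All filters are 4th-order Butterworth designs applied forward-backward
(`sosfiltfilt`), i.e. zero-phase: any phase distortion would re-introduce
lag structure and undermine the zero-lag correction. The instantaneous
amplitude is the magnitude of the FFT-based analytic signal, computed at
the next fast FFT length and cropped. One second is trimmed from each
end of the envelope before decimation to absorb the bounded edge
transient of the analytic transform and filters; envelope length is
therefore exactly `floor(duration × out_rate) − 2·trim·out_rate`
samples. Defaults: 0.5 Hz envelope low-pass, 1 Hz output rate, 1 s trim.

`roi_timecourse` collapses a multi-voxel region to the scores of the
first principal component of the weight-scaled voxel series, after
normalising the weight map to a positive peak of one. The component sign
is aligned with the weighted mean time-course, which makes the output
deterministic.

## Network inference

Envelope columns are standardised before the covariance is formed, so
the "covariance" is a correlation matrix and penalty strengths are
comparable across datasets.

**Graphical lasso.** The precision estimate maximises
`log det Ω − tr(SΩ) − λ‖Ω‖₁` with the L1 norm taken over the *whole*
matrix, diagonal included; `penalize_diagonal=False` switches to the
more common off-diagonal-only convention for interoperability. The
solver is ADMM: the Ω-subproblem is solved exactly by eigendecomposition
and the penalty subproblem by soft-thresholding, stopping when primal
and dual residuals fall below `1e−8` (scaled by dimension), with a
2000-sweep cap that raises a solver error carrying the residuals. The
soft-thresholded iterate is returned so that exact zeros encode the
support; in the rare case it is not positive definite the (PD)
Ω-iterate is returned instead. At `λ = 0` the estimate is the explicit
inverse covariance, which requires a well-conditioned input.

**Choosing λ.** Ten-fold cross-validation on *contiguous temporal
blocks* — envelopes are strongly autocorrelated, and random folds would
leak information between train and validation. For each candidate λ the
model is fitted on the training blocks and the Gaussian log-likelihood
of the held-out block is accumulated; the score is

    AICc = −2·loglik_heldout + 2k + 2k(k+1)/(m − k − 1),

with `k` = n diagonal parameters plus the union of nonzero
upper-triangle entries across fold fits, and `m` the pooled held-out
sample count. (An earlier variant applied the correction per fold with
the fold's own sample count; with 38 nodes and ~60-sample folds that
declares every support beyond ~20 edges infeasible and collapses the
selection to the empty graph, so the pooled form is used.) The search
starts from 16 geometric points on `[1e−4, 1]` and zooms the grid around
the incumbent three times, each zoom shrinking the log-width by a factor
of four.

**Calibration.** Sample correlations of smooth series are far more
variable than the `1/√m` intuition suggests, so raw Fisher z-scores are
not comparable across datasets. Each edge's `arctanh`-transformed value
is divided by the standard deviation of an empirical null: 50 synthetic
datasets of independent Gaussian AR(1) series matched to the envelopes
in node count, length and lag-1 autocorrelation, pushed through the same
correlation (or unregularised partial-correlation) computation. The
surrogates are matched to the *envelopes* rather than to the raw
time-courses: envelope smoothness is dominated by the slow amplitude
dynamics, and matching at the raw scale was measured to under-estimate
the null spread by roughly 40% in simulation, inflating false-positive
rates three-fold. Regularised partial correlations are scaled by the
unregularised-partial null, which makes their calibrated scores
conservative by construction — regularisation can only shrink them.

Group inference is fixed effects, `z_group = Σᵢ zᵢ / √S`: standard
normal under the null, testing the group-mean effect, with no attempt to
model between-subject variability. FDR control is one-sided
Benjamini–Hochberg on the positive tail, reporting both the surviving
edge mask and the implied z-threshold.

## Simulator

The simulator is the validation instrument, and its defaults are the
reference study conditions rather than free dials: 600 s recordings;
activities from `ȧ = A a + u + e` with diagonal −1, edge weights
N(0.6, 0.1²); binary burst drive of strength 0.4 with exponential on/off
durations of means 2 s and 7 s (an alternating renewal process, started
from its stationary distribution — on-probability 2/9); Gaussian input
`e` of variance 0.02; carriers assigned evenly spaced across 8–26 Hz;
unit (or 0.4) signal-to-noise power ratio. The reference network is a
fixed 6-edge DAG over 5 nodes embedded among 38 otherwise independent
nodes.

Numerical choices:

* **Integration** is RK4 at `dt = 1/sampling_rate`. Because the system
  is linear and inputs are held constant within a step, each step is the
  exact affine recurrence `a ← M a + N (u + e)` with `M` the 4th-order
  Taylor polynomial of `exp(dt·A)` — no per-step ODE evaluations.
* **Noise interpretation:** the activity equation is treated as an ODE
  with a noise input redrawn each step and held constant within it, not
  as a formal SDE. The per-step variance is fixed at 0.02, so the
  integrated noise contribution scales with `dt` (an Euler–Maruyama
  reading would scale it as `0.02/dt`); at `dt = 0.01 s` the activities
  are therefore dominated by the burst drive. Both readings are
  consistent with the printed equation; this one is the literal one.
* **Leakage** is an explicit row-stochastic mixing matrix with Gaussian
  profile `exp(−d²/2σ²)` over a 1-D node ordering (`spread` = σ in units
  of node spacing; 0 gives identity). It stands in for the spatial
  point-spread of a source-reconstruction operator, which is exactly a
  zero-lag linear map. Sensor noise is added to the sources *before*
  mixing: physically, noise enters at the sensors and is projected by
  the same inverse operator that spreads the signal. This matters — if
  independent noise were added after mixing, no zero-lag correction
  could demix the observations, and measured false partial correlations
  between neighbouring nodes reach ≈0.5 regardless of correction. The
  default `spread = 1.0` mixes each node appreciably with ±2 neighbours,
  a deliberately severe leakage level.
* The 38-node default assigns carriers in spatial order ≈0.49 Hz apart;
  with the pre-mixing noise model the correction demixes the channels
  and no beat-frequency artefact survives it.

**What the simulator does not emulate:** sensor-array geometry, forward
fields and beamformer reconstruction (the mixing matrix is a 1-D
caricature of their point spread); non-sinusoidal or frequency-varying
oscillations; non-Gaussian sensor noise; inter-subject variability.
Passing the validation suite therefore shows the pipeline behaves
correctly *given* leakage that is linear and zero-lag — it does not
certify performance under reconstruction errors with lagged structure.

## Experiments and evaluation

`run_experiment` derives per-repeat seeds from the config seed, so a
manifest (config + seeds) regenerates every artefact byte-identically.
The directed ground truth is scored as undirected, since correlation
methods carry no direction. FPR curves threshold calibrated z at the
standard-normal upper-α critical value and count false detections among
true-null edges, reporting the median and central 95% band over repeats.

Scale choices for the shipped validation runs (the package's own desk
scale): network-recovery uses the printed 15 repeats of 600 s at 38
nodes; the random-placement FPR comparison uses 20 repeats of 400 s at
12 nodes, because the pair-wise comparison method costs
O(n²) envelope computations per repeat (it is two orders of magnitude
slower than the symmetric correction, consistent with its reputation).
Full-size runs are a config change.

Single-repeat recovery is information-limited: with 600 s of envelopes
(~10² effective samples given their smoothness) unconnected node pairs
show sample correlations up to ≈0.3 while the weakest true partial
correlation is ≈0.15, so no correction can perfectly separate true from
false edges in every repeat. Group-level fixed-effects z over 15
repeats averages this sampling noise down by √15 and is the level at
which perfect thresholdable recovery holds (and is asserted in the
acceptance suite); individual regularised repeats separate perfectly in
a majority of seeds.

## Known limitations

* The tandem iteration is only locally optimal; no restart strategy is
  attempted (none was needed in any tested instance).
* The correction consumes true zero-lag connectivity together with the
  artefact, and degrades gracefully but imperfectly when two nodes share
  one underlying signal (near rank deficiency).
* AR(1) is a first-order proxy for envelope smoothness; heavier-tailed
  or longer-memory envelope dynamics would make the calibration mildly
  anti-conservative.
* The pair-wise path supports only unregularised partial correlations;
  a penalised pair-wise variant is deliberately not provided.
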