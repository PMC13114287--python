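# Methods

This note documents the statistical procedures, the synthetic-colony
generator, parameter defaults and the numerical choices behind
`anthazard`, in the order data flows through the pipeline.

## Units and calibration

All spatial quantities are held internally in body lengths (BL); pixel and
millimetre conversions happen only at I/O boundaries through `ArenaSpec`
(defaults: 0.083 mm/pixel, 30 pixels per BL, 10 frames/s). One BL ≈ 2.5 mm.

A note on the speed threshold: the conventional description of the
classification threshold as "0.25 mm/s (3 pixels/frame at 10 fps)" is
internally inconsistent — 3 px/frame at 10 fps and 0.083 mm/px is
≈ 2.49 mm/s, and a resting-speed mean of 0.26 mm/s would itself exceed
0.25 mm/s. The package defaults to the pixel figure (3 px/frame) and
exposes the threshold, the minimum durations and all unit conversions as
configuration; no attempt is made to guess which figure was intended.

## State segmentation

Instantaneous speed is the backward one-frame Euclidean displacement, with
no smoothing; the downstream lag-k convention already buffers the
covariates against frame-level noise. Speed is undefined at an ant's first
observed frame and across tracking gaps, and unknown frames never
contribute to bouts (dwell resets after a gap).

Frames are classified moving iff speed > threshold, then minimum bout
durations (defaults 1.0 s resting, 0.5 s moving) are enforced by a greedy
filter: repeatedly find the shortest bout below its state's minimum (ties →
earliest), relabel it to the state of its longer flanking bout (ties → the
previous bout's state), merge, and iterate until stable. The rule is
deterministic, idempotent, and is verified in the tests against an
exhaustive enumeration of all merge orders on short sequences. A contiguous
run that collapses to a single sub-minimum bout is left as-is — there is
nothing to merge it into.

Dwell is 0 at the bout's entry frame (an ant that began resting at frame
100 has dwell 50 at frame 150). Stop events are emitted at the last frame
of a moving bout immediately followed by a resting bout, and vice versa for
starts; bout pairs separated by unknown frames emit no event.

An important consequence of duration filtering, measured on the simulator:
even for a memoryless colony the *start*-transition design acquires genuine
short-dwell structure, because no surviving resting bout can end before the
1.0 s minimum while ants are at-risk from dwell k = 3 frames. The
stop-transition design is unaffected (the 0.5 s moving minimum sits almost
entirely inside the lag exclusion), which is why calibration checks at
chance level use the stop model, and why permutation-calibration tests on
memoryless data use the simulator's ground-truth states.

## Design matrix

For transition type `stop` (`start`), a row is *at-risk* at frame `t` when
the ant is moving (resting) at `t`, its dwell satisfies `d(t) ≥ k` so the
lagged frame lies inside the same bout, and the state at `t+1` is observed;
the label is 1 iff the state changes between `t` and `t+1`. All covariates
are evaluated at `t − k` (default `k = 3` frames); the dwell covariate is
lagged like the others, `log(d(t) − k + 1)` (natural log; a config switch
evaluates it unlagged at `t`). Nothing except the label uses information
after `t − k`; the tests verify this by perturbing all later frames.

Neighbourhoods are closed balls of radius 1.5 BL, centre-to-centre, focal
excluded; density is count / πR². Headings are displacement directions over
a 3-frame window, undefined below 0.1 BL of displacement; heading
dispersion is the circular standard deviation `√(−2 ln R̄)` of
neighbour-minus-focal heading differences, capped at 4.0 rad. Isolated
ants receive neutral fills (fraction resting 0.5, speed difference 0,
dispersion cap/2) plus an `isolated_flag` column, rather than being
dropped — dropping would condition the risk set on a covariate. The
canonical neighbours *model*, however, consists of exactly the four
continuous covariates; the flag is carried in the design matrix for
diagnostics and can be added as an explicit feature. (Including it in the
model by default would also let the feature-jitter control leak signal,
since the jitter perturbs the four covariates.)

## Pheromone field

The arrestant field is reconstructed on a square grid of 0.25 BL cells
(equal to the deposition kernel radius; finer grids change sampled values
by less than the interpolation error at this kernel width). Per frame, in
a fixed order: each observed ant deposits mass `dt/τ` through a Gaussian
kernel (σ = 0.25 BL, truncated at 3σ and renormalised so the deposited
mass is exact); the field is convolved with a Gaussian of variance
`2·D·dt`, `D = ℓ²/τ`; the field decays by `exp(−dt/τ)`. Any operator
order differs at O(dt); this one is fixed for determinism. Diffusion uses
a mirrored (zero-flux, Neumann) boundary on the bounding square, which
conserves mass exactly; the circular wall is not specially handled. With
deposition and decay both at rate 1/τ, each stationary ant carries unit
integrated mass at steady state — a property the tests verify to 1%.

The grid stores *concentration* (mass per BL²), so sampled values are
independent of the grid resolution; `total_mass()` integrates concentration
over cell areas. Sampling is bilinear, with nearest-cell values outside
the grid. Deposition defaults to all observed ants (moving and resting);
a mask restricts it if desired. The τ → ∞ limit degenerates to pure
accumulation (no calibrated pure-accumulation model is provided).

Because resting clusters make the field collinear with crowding, the phi
covariate is residualised against local density by OLS before entering any
model; the regression is fitted on training rows only and applied to
held-out rows within each cross-validation fold. The (τ, ℓ) grid search
scores each candidate field by the percent reduction in out-of-fold
binomial deviance of {neighbours + phi_resid} relative to the nested
{neighbours} baseline, per transition type, on identical folds and sampled
rows; the nested baseline (rather than a null model) isolates what the
field adds beyond instantaneous social context. Default grids:
τ ∈ {60, 180, 300, 600, 900, 3600} s, ℓ ∈ {0.5, 1.0, 1.5, 2.0, 2.5} BL.

## Hazard fitting and evaluation

Transitions occur in well under 2% of at-risk frames, so training sets are
built by incidence-density sampling: every case row is kept, and for each
frame with `c` cases, `c × 10` control rows are drawn uniformly without
replacement from that frame's non-transitioning same-state rows (all are
taken, with a logged shortfall, when fewer are eligible). Sampling is
deterministic under its seed, and the tests confirm that AUC is invariant
to the ratio (10:1 vs 50:1 agree within 0.01). Evaluation uses the sampled
out-of-fold rows.

`PenalisedHazardModel` is a scikit-learn estimator: features are
standardised with training statistics, the logistic hazard is fitted with
an elastic-net penalty (SAGA solver), and the mixing parameter and penalty
strength are chosen by an inner ant-grouped cross-validation maximising
AUC. Default grids: l1_ratio ∈ {0.1, 0.5, 0.9}, 10 strengths log-spaced
over 10⁻⁴…10¹ on the standardised scale (sklearn `C = 1/strength`). Outer
evaluation uses 5 folds grouped by ant identity — ants are shuffled under
the seed and dealt round-robin, so fold sizes differ by at most one ant —
and the reported AUC is the mean of per-fold out-of-fold AUCs with
SE = sd/√folds. Folds with single-class labels are skipped with a warning.
Model-variant comparisons reuse the same sampled rows and the same fold
assignment, so differences between variants are paired.

Cross-colony transfer reports a train × test AUC matrix: diagonal entries
are within-colony grouped-CV means; off-diagonal entries come from a model
fitted on the full training colony (hyperparameters by inner grouped CV)
and evaluated on the full sampled design of the test colony. The gap is
mean(diagonal) − mean(off-diagonal).

Empirical hazard curves report, per dwell bin, (bouts ending in the bin) /
(bout-frames at risk in the bin) with binomial standard errors; a censored
bout contributes no at-risk frame for its final, unobserved transition
trial. Default bins are 0.1 s wide to 2 s, then log-spaced to 60 s.

## Negative controls

All three controls refit with the observed fit's per-fold hyperparameters
and fold assignment (no inner search per iteration — the hyperparameters
are not the quantity under test, and the refit of unperturbed data
reproduces the observed AUC exactly). One master seed spawns per-iteration
seeds. The p-value is plus-one smoothed, `(1 + #{null ≥ observed}) /
(B + 1)`, with minimum `1/(B+1)` (0.003 at the default B = 300).

- **Identity shuffle** — within each frame the assignment of identities to
  positions is permuted among ants observed in that frame; each identity
  keeps its own state/dwell/label history and its own speed and heading
  channels, and the four neighbourhood covariates are recomputed from the
  permuted configuration before refitting the neighbours-only model.
- **Feature jitter** — independent Gaussian noise with sd = multiplier ×
  each feature's sd (default multiplier 1.0) is added to the four
  neighbourhood covariates only.
- **Dwell shuffle** — dwell values are permuted among at-risk rows of the
  same frame (rows of one design share a state, so the permutation is
  state-restricted by construction) and the dwell-only model is refitted;
  per-frame dwell multisets are preserved exactly.

## The synthetic colony generator

The simulator provides ground truth, not a calibrated replica of any real
colony: no generative movement model is available for the study system, so
motion parameters are plausible rather than fitted. Agents live in a
circular arena (radius 20 BL ≈ the 10 cm arena) with a reflective wall
(positions folded radially, headings reflected about the wall tangent).
Moving ants follow a correlated random walk — wrapped-normal heading
increments (sd 0.4 rad/frame) and lognormal per-frame speeds with mean
2.08 BL/s (≈ 5.2 mm/s) and sd 0.6 BL/s — while resting ants jitter
isotropically around their stopping point with sd 0.006 BL, giving
apparent resting speeds of ≈ 0.1 BL/s (≈ 0.26 mm/s). This reproduces the
bimodal speed structure of tracked colonies with modes well separated by
the 3 px/frame threshold. Tracking gaps are i.i.d. per (ant, frame).

Per frame the update order is: record position → read covariates → draw
the transition with probability `σ(β₀ + β_dwell log(d+1) + β_social f_R +
β_phi φ)` → move, so the transition conditions on the pre-move context
exactly as the inference assumes. The social covariate is the fraction of
resting ants within 1.5 BL (0.5 when isolated); φ is sampled from a
pheromone field evolved alongside the agents by the same
deposit–diffuse–decay dynamics used for reconstruction.

Preset ground-truth coefficients (per-frame logit scale):

| preset      | stop β₀            | start β₀           | β_dwell | β_social | β_phi | field (τ, ℓ) |
|-------------|--------------------|--------------------|---------|----------|-------|--------------|
| memoryless  | logit(0.01)        | logit(0.02)        | 0       | 0        | 0     | —            |
| inertia     | −3.0               | −3.5               | −0.45   | 0        | 0     | —            |
| imitation   | logit(0.01)        | logit(0.02)        | 0       | +3 / −3  | 0     | —            |
| stigmergy   | logit(0.01)        | logit(0.02)        | 0       | 0        | +6 / −6 | (300 s, 1 BL) |
| full        | −3.2               | −3.0               | −0.25   | +1.5 / −1.5 | +0.5 / −0.5 | (300 s, 1 BL) |

(signs: first for stops, second for starts — ants stop more and start less
where neighbours rest or pheromone accumulates). The rates are chosen so
every preset produces hundreds of transitions at the default desk scale
(40 ants × 6000 frames = 10 min of colony time), bout durations comfortably
clear the minimum-duration filter (the inertia preset yields ≈ 33%
activity, like the most active real colony), and each preset's designed-in
mechanism is the dominant predictable signal. The stigmergy coupling is
deliberately strong because aggregation must nucleate within a 10-minute
run — 1/24 of the 4 h recordings it emulates.

What the generator does *not* emulate: collision mechanics or excluded
volume, 3-D stacking, brood/food objects, individual heterogeneity
(frailty), autocorrelated tracking noise, and systematic (non-i.i.d.)
detection failures. Passing ground-truth recovery tests therefore shows
that the pipeline identifies generating mechanisms of this model class —
not that real colonies obey any particular mechanism.

## Problem sizes and tolerances

Tests and the acceptance script run at reduced but statistically adequate
scales (e.g. 20–40 ants × 6–8 k frames; hundreds to thousands of events),
chosen so that AUC Monte-Carlo error stays well inside the asserted
margins. Chance-level checks use ±0.03; permutation-null centring uses
±0.05 on the median; the cross-colony gap bound is |gap| < 0.02 with ≈ 8 k
frames per colony. Out-of-fold probabilities are clipped at 10⁻¹² in
deviance computations; Rbar is clipped away from 0 before the circular-sd
log; the SAGA solver runs with tol 10⁻³ and max_iter 300 on standardised
features, with a fixed random_state per fold so every fit is reproducible.

## Known limitations

- The simulator's motion model is an artifact construct; its parameters
  are not calibrated to tracked colonies beyond the speed scales above.
- The hazard is linear on the logit scale in `log(d+1)`; strongly
  non-monotone hazards (beyond the filter-induced early censoring) would
  need spline or binned dwell terms.
- Duration filtering induces genuine short-dwell structure in start
  designs (see above); analyses comparing dwell models across different
  minimum-duration settings should account for it.
- The pheromone reconstruction assumes accumulation with exponential
  decay; contact-mediated transfer and chemically distinct signals are out
  of scope, and the pure-accumulation limit (τ → ∞) is available but not
  calibrated.
- Fold skipping under single-class labels biases the fold-AUC mean when
  events are extremely rare; at the documented problem sizes it never
  triggers.
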