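# anthazard

**Discrete-time hazard models for behavioural state transitions in ant
colonies.**

Resting ants aggregate into dense clusters, and at least three microscopic
mechanisms could drive the individual stop/start decisions behind that
pattern: *local imitation* (react to the states of nearby ants),
*stigmergy* (react to an arrestant pheromone field that accumulates where
ants spend time), and *internal state* (the tendency to remain in a state
the longer it has been occupied — behavioural inertia). Matching a
simulation to colony-level patterns cannot distinguish these; predicting
*individual* transitions can. `anthazard` implements that predictive test
as a reusable pipeline, together with a seeded agent-based colony simulator
whose generating mechanisms are known exactly, so every stage can be
validated against ground truth.

## The model

Each ant `i` occupies a binary state per video frame, `S_i(t) ∈ {moving,
resting}`. The per-frame hazard of leaving the current state is modelled
with logistic regression:

```
λ_i(t) = P(S_i(t+1) ≠ S_i(t) | S_i(t), X_{i,t-k}) = σ(β₀ + βᵀ X_{i,t-k})
```

where `σ` is the logistic function and the covariates `X` are read at a lag
of `k = 3` frames before the candidate transition so that the predictors
cannot already reflect the transition itself. Covariate families:

- **neighbours** — local density (ants/BL², radius 1.5 body lengths),
  fraction of resting neighbours, focal-minus-mean-neighbour speed, and
  circular heading dispersion `√(−2 ln R̄)`;
- **dwell** — `log(d+1)` with `d` the frames spent in the current state,
  a proxy for internal state;
- **phi** — a reconstructed pheromone concentration: every ant deposits
  mass `dt/τ` per frame through a 0.25 BL Gaussian kernel, the field
  diffuses with `D = ℓ²/τ` and decays as `exp(−dt/τ)` (unit mass per
  stationary ant at steady state), sampled at the ant's lagged position
  and residualised against local density inside each training fold.

Because transitions are rare, models are fitted on incidence-density
samples (all transition events plus 10 same-frame, same-state controls per
event) with elastic-net regularisation, and compared by out-of-fold AUC
under cross-validation grouped by ant identity — a model is only ever
scored on ants it never saw. Three permutation negative controls (identity
shuffle, feature jitter, dwell shuffle) provide plus-one-smoothed p-values
`(1 + #{null ≥ observed}) / (B + 1)`, and cross-colony transfer
(train on one colony, test on another) probes whether the learned hazard
relationships are colony-specific.

## Worked example

Simulate a colony whose transitions are driven purely by behavioural
inertia (a negative dwell coefficient), segment it, and ask which covariate
family predicts its stop transitions:

```python
import anthazard as ah

cfg = ah.preset("inertia", n_ants=30, n_frames=6000, seed=7)
traj, truth = ah.simulate_colony(cfg)
states, bouts, events = ah.segment(traj)

design = ah.assemble_design(states, traj, "stop")
sampled = ah.incidence_density_sample(design, ratio=10, seed=7)

spec = ah.ModelSpec(transition_type="stop", seed=7)
table, _ = ah.compare_models(sampled, spec,
                             {"dwell_only": ("dwell",),
                              "neighbours_only": ("neighbours",),
                              "neighbours_dwell": ("neighbours", "dwell")})
print(table)

nd = ah.dwell_shuffle(sampled, spec, B=100, seed=7)
print(f"dwell shuffle: observed AUC {nd.observed_auc:.3f}, "
      f"null median {nd.null_median:.3f}, p = {nd.p_value:.3f}")
```

Output:

```
         variant transition_type  auc_mean   auc_se
      dwell_only            stop  0.654436 0.013832
 neighbours_only            stop  0.509170 0.005515
neighbours_dwell            stop  0.650304 0.015006
dwell shuffle: observed AUC 0.654, null median 0.508, p = 0.010
```

The dwell-only model discriminates held-out ants' stops (AUC 0.65) while
the neighbours-only model sits at chance — exactly the generating
mechanism. Shuffling dwell times across ants within each frame collapses
the AUC to chance (null median 0.51), and the observed AUC exceeds all 100
shuffled refits, giving the smoothed minimum p-value 1/101 ≈ 0.010.

A command-line interface mirrors the library
(`anthazard simulate | segment | features | pheromone | fit | crosscolony |
run-all`); `anthazard run-all --out results/` performs an end-to-end run
from a YAML pipeline configuration.

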