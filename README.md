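# nafc

Sequential Bayesian decision making between `n` alternatives, modeled as a
particle diffusing on the belief simplex with parameterized nonlinear
decision boundaries.  The package provides:

- **belief_geometry** — simplex-vertex layouts, the probability/log-odds
  transform, and the triplet-subspace combinatorics behind the boundary
  parameterization.
- **accumulator** — equidistant Gaussian hypothesis models, evidence
  sampling, and log-domain sequential Bayes updating (with the two-choice
  SPRT recursion as an equivalent reference path).
- **boundaries** — the general boundary function
  `F(P) = θ·[1 + α/C(n,3) · Σ_j f(Δmax P_j; β)·Π P_j]` with four shape
  families (`flat`, `curve`, `power`, `oscil`) and the strict crossing rule
  `P_i > F(P)`.
- **trial_engine** — scalar and vectorized decision-episode simulation,
  rewards `r = −W·e − c·T`, and Monte-Carlo reward estimates.
- **landscape** — grid-search reward landscapes per cost ratio `c/W`,
  δ-acceptance ("effectively optimal") sets
  `mean_reward ≥ r_max − δ·σ`, and Gaussian-process-smoothed sections.
- **analytics** — speed-accuracy trade-off points and mean SAT curve,
  implicit threshold dynamics (increasing / collapsing / static), Hick's-law
  fits, and closed-form normalization identities for adding an option.
- **cli/config** — YAML-configured command-line workflows with
  reproducibility manifests.

## CLI

```sh
nafc simulate|landscape|accept|sat|implicit|hicks|analytics \
    --config cfg.yaml --out outdir [--seed INT] [--trials INT]
```

Minimal config:

```yaml
model:    {n: 3, delta_mu: 1.0, sigma: 1.0}
boundary: {family: curve, theta: 0.7, alpha: 10.0}
costs:    {cost_ratios: [0.001, 0.04, 0.1]}
mc:       {n_trials: 5000, master_seed: 0}
analysis: {delta: 0.02}
```

Each subcommand writes plain CSV/JSON plus a `manifest.json` (config hash,
seed, version); rerunning with the same config and seed reproduces every
table byte for byte.

Defaults are desk-scale: 5,000 trials per landscape cell and the three
headline cost ratios.  Increase `mc.n_trials` (up to the 100,000 used for
the original landscapes) and the `costs.cost_ratios` list via config for
higher-fidelity sweeps.

## Notes on scales

The mean separation `delta_mu` of the evidence distributions sets the task
difficulty and is a free knob (`model.delta_mu`).  Absolute decision-time
and error scales depend on it; the packaged tests assert the qualitative
structure (threshold sweeps with cost ratio, boundary-shape/dynamics
correlations, log-linear choice-count scaling) rather than absolute values.
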