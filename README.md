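# satlba

A neurally constrained linear ballistic accumulator (LBA) analysis of the
speed–accuracy tradeoff in two-choice decisions, with Bayesian fitting by
differential-evolution MCMC.

The model treats each decision as a race between two ballistic
accumulators (target / distractor). Two neural-style constraints are
built in: the speed-emphasis decision threshold is exactly 1.2× the
accuracy-emphasis threshold, and the speed-setting drift-rate standard
deviation is fixed to 1 (the scaling constraint). Speed- and
neutral-emphasis conditions share identical predictions, and
accuracy-emphasis trials are a cue-neglect mixture: with probability `p`
a trial behaves as a speed-setting trial. This leaves 7 core free
parameters plus `p`.

## Layout

| module | contents |
| --- | --- |
| `satlba.lba` | closed-form first-passage densities (incl. exact A→0 limit), defective race densities, choice probabilities, trial and trajectory simulation |
| `satlba.model` | `SatParameters`, per-setting race construction, mixture likelihood, trial-table I/O, over-constrained variant |
| `satlba.sampler` | DE-MCMC (`run_demc`), priors, Gelman–Rubin `rhat`, posterior summaries, `fit_sat_model` |
| `satlba.synth` | seeded synthetic trial tables with per-trial neglect sidecar |
| `satlba.ppc` | posterior predictive distributions over RT × choice, discrepancy reports, aligned trajectory panels |
| `satlba.cli` | `satlba simulate / fit / ppc / recover` |

## CLI

Each subcommand takes `--config <yaml>`, `--seed <int>` and `--out <dir>`
and is a pure function of those; the resolved config is written to the
output directory. Example end-to-end recovery:

```yaml
# recover.yaml
params: {t0: 0.10, p: 0.08, b_acc: 0.24, v_t_acc: 0.66, v_d_acc: 0.40,
         v_t_spd: 2.30, v_d_spd: 1.41, s_acc: 0.10}
n_iter: 5000
burn_in: 2500
```

```bash
satlba recover --config recover.yaml --seed 1 --out runs/recovery
satlba ppc --config ppc.yaml --seed 2 --out runs/ppc   # needs samples: path
```

`fit` and `recover` accept `--strict` to fail when any R-hat exceeds the
configured threshold.

## Notes

- Start-point variability `A` defaults to 0 (the exact analytic limit);
  any `0 ≤ A < b` is supported.
- Race densities are renormalized by the race's finish probability and
  the simulator redraws non-terminating trials, so analytic densities
  and simulation describe the same process.
- The decision-time distribution has a `1/t²` tail (near-zero sampled
  drifts); quadratures and predictive grids account for this.
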