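# painchain

A two-state hidden Markov model of pain perception. Hidden pain states are
inferred from noxious/harmless sensory observations by exact sum-product
message passing; beliefs over every model parameter (prior, transition
table, likelihood table) are categorical distributions carrying sufficient
statistics `lam` and a pseudocount precision `nu`, and learning absorbs each
trial's expected counts into those pseudocounts in a single batch update.
A one-parameter "stationary family" of transition tables — the null space of
the stationarity constraint for a target marginal p(pain) — models
treatment-resistant chronic pain: no matter where the prior starts, the
inferred pain marginal relaxes back to the target within a few steps.

## Layout

| Module | Contents |
| --- | --- |
| `painchain.beliefs` | `PseudocountDistribution`, `ConditionalTable`; mean and geometric (digamma) message parameterizations; count absorption |
| `painchain.chain_model` | `ChainModel`, `ObservationSchedule`, the `healthy` / `chronic` observer presets, a seeded generative sampler, YAML config loading |
| `painchain.inference` | `propagate` (forward-backward), `brute_force_posterior` (2^N enumeration oracle), `free_energy` |
| `painchain.learning` | expected counts, batch updates, `run_learning` across trials |
| `painchain.null_space` | `stationary_family`, `sample_transition`, stationarity residuals, convergence times |
| `painchain.scenarios` | the named simulations (`mixed`, `prolonged_noxious`, `prolonged_harmless`, `treatment_resistance`, `therapy_ambiguous`, `therapy_accurate`), CSV/JSON writers, CLI backend |

## CLI

```bash
paincli mixed --observer chronic --trials 40 --seed 7 --out run.csv
paincli treatment_resistance --seed 3 --out tr.json --format json
paincli therapy_accurate --seed 3 --out therapy.csv
```

Output is a tidy table (`scenario, trial, time_step, q_pain, free_energy`);
JSON output additionally stores provenance and the final learned parameters,
and `painchain.rerun_from_provenance` reproduces a run bit-for-bit from that
block. `--config file.yaml` overrides preset parameters (keys `prior`,
`transition`, `likelihood`, each with `lam`/`nu`); `--parameterization`
switches the message parameterization between `mean` (default) and
`geometric`. Unknown scenarios/observers exit with status 2.

## Library example

```python
import painchain as pc

model = pc.preset_observer("healthy")
schedule = pc.observation_schedule("mixed", 20)
run = pc.run_learning(model, [schedule] * 40)
print(run.trajectories.shape)        # (40, 20) marginal q(pain)
print(run.final_model.prior.lam)     # learned prior

family = pc.stationary_family(0.7)
transition = pc.sample_transition(family, seed=0, max_second_eigenvalue=0.8)
print(pc.convergence_time(transition, (0.05, 0.95), target=0.7, tolerance=0.01))
```

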