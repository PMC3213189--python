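# sporedyn

Population dynamics of the *Bacillus subtilis* sporulation decision under
fluctuating stress, plus the single-cell reporter-trace analyses that
motivate the model — with a synthetic trace generator so the entire
pipeline runs and validates without any external data.

Starving *B. subtilis* cells differentiate into dormant spores. Single-cell
time-lapse measurements show that the early steps of this program are noisy
and reversible — spontaneous bursts of P<sub>spo0A</sub>/P<sub>spo0F</sub>
activity, transient SpoIIE septal localization in ~2% of cells — while the
final commitment (P<sub>spoIIR</sub> activation) is switch-like and
irreversible, with a tightly timed interval to spore appearance
(CV ≈ 0.2, about 15% of the median cell-cycle duration). `sporedyn` is for
quantitative/systems biologists who want to (a) compare decision-making
architectures as population models under randomly alternating stress and
(b) run the standard trace analyses (alignment, activation calling,
commitment timing, burst and localization event calling) on tidy
single-cell CSV data.

## The model

Three decision schemes take cells from the vegetative state V to the
absorbing spore state S:

| scheme | chain |
|---|---|
| irreversible-only | V → D → S |
| reversible-only | V ⇌ I₁ ⇌ I₂ ⇌ D → S |
| hybrid (the measured architecture) | V ⇌ I₁ ⇌ I₂ → D → S |

Cell counts per state evolve by a linear ODE, **dN/dt = M(σ(t)) N**, where
the generator M is piecewise constant over a two-level (dichotomic) stress
signal σ(t) ∈ {high, low}. Off-diagonal entries of M are the transition
rates (Metzler structure, so populations stay nonnegative); column *j*
sums to the net growth rate g(j, σ) — the only non-conservative term.
Forward rates rise under stress, backward rates rise in the rich phase,
and non-spore cells die faster than they grow under stress (g < 0).
Because the system is piecewise linear it is solved exactly with per-phase
matrix exponentials; an adaptive ODE integrator is kept as an independent
test oracle only.

Relative fitness of two schemes is the ratio of their total populations
(summed over all states) after exposure to the *identical* stress
schedule. The stress schedule is a random telegraph process parameterized
by the high-stress fraction f and the mean cycle duration (6 h default),
integrated over 30 h.

## Worked example

```python
import numpy as np
from sporedyn import (sweep_high_stress_fraction, random_environment_average,
                      GeneratorConfig, generate_cohort, commitment_intervals,
                      transient_localization_fraction)

curve = sweep_high_stress_fraction(n_f=100, n_realizations=25, seed=0)
for target in (0.1, 0.5, 0.9):
    i = np.argmin(abs(curve.fractions - target))
    print(f"f={curve.fractions[i]:.2f}  hyb/irr={curve.ratio_hyb_irr[i]:.3f}"
          f"  hyb/rev={curve.ratio_hyb_rev[i]:.3f}")

res = random_environment_average(100, 30.0, 6.0, seed=0)
print(f"mean hyb/irr = {res.mean_ratio_hyb_irr:.3f}  bars {res.var_irr[0]:.3f}-{res.var_irr[1]:.3f}")
print(f"mean hyb/rev = {res.mean_ratio_hyb_rev:.3f}  bars {res.var_rev[0]:.3f}-{res.var_rev[1]:.3f}")
```

prints

```
f=0.10  hyb/irr=2.655  hyb/rev=0.980
f=0.50  hyb/irr=0.989  hyb/rev=1.033
f=0.90  hyb/irr=0.290  hyb/rev=1.042
mean hyb/irr = 1.405  bars 1.148-1.812
mean hyb/rev = 1.015  bars 0.988-1.037
```

Reading: when high stress is brief (f = 0.1) the hybrid outgrows the
irreversible-only scheme 2.7-fold — the latter is driven irreversibly into
non-growing spores by every short stress pulse — while performing on par
with the reversible-only scheme. When stress dominates (f = 0.9) the
ranking flips against the irreversible-only scheme (spores are the safe
state and the hybrid commits later), but the hybrid now beats the
reversible-only scheme, which is pulled back out of the decided state by
every brief rich interlude. Averaged over uniformly random f, the hybrid
beats both alternatives (both means > 1); the bars are the maximum
variation under simultaneous ±20% perturbation of all non-zero baseline
rates.

The trace side, on a synthetic cohort emulating the measured statistics:

```python
cohort = generate_cohort(GeneratorConfig(n_cells=31, p_sporulate=1.0,
                                         p_burst_only=0.0,
                                         p_transient_localization=0.0, seed=1))
stats = commitment_intervals(cohort.traces, threshold_frac=0.6)
print(f"CV={stats.cv:.3f}  mean={stats.mean_h:.3f} h  "
      f"ratio={100*stats.median_interval_over_median_cycle:.1f}%")

big = generate_cohort(GeneratorConfig(n_cells=1000, seed=1))
frac, sem, k, n = transient_localization_fraction(big.traces)
print(f"transient localization: {100*frac:.1f}% +/- {100*sem:.1f}% ({k}/{n})")
```

prints

```
CV=0.185  mean=1.033 h  ratio=16.3%
transient localization: 2.1% +/- 0.5% (21/1000)
```

i.e. the pipeline recovers the commitment-interval CV (target 0.2), the
interval-to-cell-cycle ratio (target 15%) and the transient-localization
fraction (target 2 ± 1%) from generated cohorts at the study's sample
sizes.

## Command line

A thin CLI wraps the library; every run writes its outputs plus a
`manifest.json` recording the configuration, its hash and all seeds:

```bash
sporedyn sweep --n-f 100 --n-realizations 25 --seed 0 --out-dir out_sweep
sporedyn random-env --seed 0 --out-dir out_env
sporedyn sensitivity --n-draws 100 --seed 0 --out-dir out_sens
sporedyn synth --n-cells 200 --seed 1 --out-dir out_synth
sporedyn traces --traces out_synth/traces.csv \
                --annotations out_synth/annotations.csv --out-dir out_traces
sporedyn simulate --model hybrid --fraction 0.4 --out-dir out_sim
```

Trace input is tidy CSV (`cell_id, time_h, channel, value`) with an
optional annotation CSV (`cell_id, event_type, time_h`; event types
`spore`, `division`, `localization_start`, `localization_end`).

## Layout

- `sporedyn.models` — topologies, stress-coupled rates, generator matrices
- `sporedyn.environment` — periodic and random telegraph stress schedules
- `sporedyn.propagation` — exact matrix-exponential propagation, trajectories
- `sporedyn.fitness` — fitness ratios, f-sweeps, sensitivity envelopes,
  random-environment averages
- `sporedyn.traces` — single-cell trace operations and CSV dialects
- `sporedyn.synth` — annotated synthetic cohort generator + recovery report
- `sporedyn.cli` — command-line entry points and run manifests

See `docs/methods.md` for modeling assumptions, parameter choices and
known limitations.
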