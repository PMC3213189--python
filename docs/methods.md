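# Methods

## Population models

Each decision scheme is a continuous-time linear population model
dN/dt = M(σ) N on its state set, with the spore state S strictly
absorbing: spores neither grow, die, nor germinate (no return edge, zero
net growth in both phases). The decided state D shares the common
non-spore net growth rate; the model distinguishes only non-spore cells
(which grow or die with the environment) from spores (which are inert).

The generator for phase σ has M[i, j] equal to the j→i transition rate,
and M[j, j] = g(j, σ) − (total outflow from j). Two structural facts are
load-bearing and are tested as invariants:

* **Metzler structure** (off-diagonals ≥ 0) guarantees nonnegative
  populations stay nonnegative for any schedule.
* **Column sums equal net growth**, so with g ≡ 0 the total population is
  exactly conserved; this is the conservation oracle used in the tests.

### Stress coupling and baseline rates

The environment is strictly two-level. Rates couple to it directionally:
forward (toward-spore) rates are at least their rich-phase value under
stress, backward rates at least their stressed value in the rich phase,
and non-spore net growth is positive in the rich phase and negative under
stress. `validate_parameters` reports violations of these rules.

Baseline values (per hour, overridable in YAML config and as keyword
arguments of `default_parameters`):

| parameter | high stress | low stress |
|---|---|---|
| forward step rate (V→I₁, I₁→I₂, I₂→D) | 0.3 | 0.1 |
| backward step rate | 0.05 | 1.0 |
| D → S conversion | 1.0 | 1.0 |
| net growth, non-spore states | −0.5 | +0.5 |

The irreversible-only scheme's single V→D step uses the rate whose mean
first-passage time matches the three-step chain under sustained stress of
the same phase (0.1/h high, 0.0333/h low) — a fairness convention so the
schemes differ in architecture, not in raw speed. An optional distinct
commitment-step (I₂→D) rate exists for asymmetric chains; the defaults
keep the chain uniform.

These baselines are this package's reference parameterization, chosen
once (by a coarse grid search over the coupling-respecting region) so the
model comparison exhibits the qualitative regime structure the
architecture argument predicts: the hybrid beats the irreversible-only
scheme for small high-stress fractions and loses to it as f → 1, tracks
the reversible-only scheme closely at small f and beats it at large f,
and wins on average over uniformly random f. The sensitivity analysis
(±20% coherent perturbation of all non-zero baseline rates) quantifies
how far that picture moves under parameter changes; the quantitative
ratio magnitudes themselves are not claims.

### Environment

The random dichotomic environment is a telegraph process: alternating
high/low phases with independent exponentially distributed durations of
means f·T and (1−f)·T (T = 6 h default, several switches per 30 h run); a
uniform-duration variant (on [0, 2·mean]) is available behind a keyword.
Schedules start with the phase of longer expected duration, are truncated
at the 30 h horizon, and are fully reproducible from their seed.
Degenerate f ∈ {0, 1} yields a single phase.

### Propagation and numerics

Within a phase the solution is exp(M·dt)·N. `propagate_phase` uses
`scipy.linalg.expm`; the sweep machinery (`PhasePropagators`) instead
diagonalizes each of the two per-phase generators once and applies
exp(M·dt) as three small matrix-vector products, falling back to `expm`
whenever the eigenbasis condition number exceeds 1e8 (defective or nearly
defective generators). Both paths are the exact solution; they agree with
an adaptive LSODA integration to better than 1e−6 relative error over
random parameter draws (tested). Tiny negative counts from roundoff
(≲1e−16) are clipped to zero.

The default initial condition is one unit of vegetative cells; by
linearity all fitness ratios are invariant to this choice (tested).

### Fitness experiments

* **f-sweep**: 100 evenly spaced fractions in (0, 1), 25 telegraph
  realizations per fraction, identical profiles applied to all three
  models, mean of per-profile ratios. Averaging over realizations (rather
  than one draw) trades a single-realization look for a smooth,
  seed-reported curve; single-realization mode is `n_realizations=1`.
* **Ratios are endpoint totals** at 30 h, not time averages.
* **Sensitivity envelopes**: the three models share one baseline rate
  table, so a perturbation draw multiplies every non-zero scalar of that
  table (per phase) by an independent factor uniform in [1−p, 1+p] and
  rebuilds all three models from the same perturbed table — one draw per
  envelope sample, applied across all fractions, with the environment
  realizations held identical to the baseline sweep so the envelope
  isolates parameter sensitivity. Perturbing each model's rates
  independently instead lets the models' growth rates diverge by up to
  40%, which compounds to ~e^(0.2·30) ≈ 400× over the horizon and says
  nothing about architecture; the coherent draw is the meaningful
  experiment. Envelopes are pointwise min/max over draws together with
  the baseline, hence always bracket it. 100 draws by default.
* **Random-environment average**: 100 fractions uniform on [0, 1], one
  telegraph profile each, 30 h, means over fractions; max-variation bars
  re-run the whole protocol per coherent perturbation draw.

## Trace analysis

All event calling is fractional-of-own-signal: thresholds are fractions
of a cell's dynamic range above its per-trace minimum, which makes every
call invariant under positive affine rescaling of fluorescence (arbitrary
units, arbitrary offsets). Consequences worth knowing:

* `detect_activation` returns the first sample strictly above the
  threshold; on a constant series there is no event.
* A channel containing only noise still has a dynamic range, so
  fractional thresholds will fire on it. `detect_bursts` therefore
  accepts a `min_range` floor (absolute units) for silent-channel data;
  the default is off because the synthetic cohorts are analyzed
  fate-conditionally.
* Burst calling is hysteretic (on at 50%, off at 20% of range, both
  configurable): an excursion must fall back below the off threshold to
  count, so a committed ramp is never a burst and noise cannot
  double-count a single excursion. The operationalization (thresholds and
  merging) is this package's; the source observations show bursts but do
  not formalize them.
* "No late-reporter activation" for burst eligibility is implemented via
  the spore annotation (activation of the commitment reporter is always
  followed by a spore, in the data as in the generator); a
  fractional-threshold test alone cannot distinguish a silent channel
  from an active one.

Alignment shifts each cell so its reference activation (70% threshold by
default) sits at t = 0, normalizes per cell, and averages per relative
timestamp over whatever cells are present there (ragged alignment — the
movies have unequal lengths); SDs are sample (n−1) throughout, matching
the small cohort sizes (n ≈ 28–33). Commitment statistics use the 60%
threshold, per-cell interval = spore time − activation time, CV =
sample SD / mean, and compare the median interval to the median
cell-cycle duration measured from division annotations in the same cells.
A single-interval cohort is flagged degenerate (CV 0). Transient
localization is counted per cell: any septal-localization interval whose
end is not followed (at or after it) by a spore, with binomial SEM.

## Synthetic cohorts

The generator emulates the statistical structure of the reporter movies,
not their biochemistry: channel kinetics are piecewise exponential ramps
and pulses, with additive Gaussian noise (SD 0.05 of the nominal dynamic
range) on every channel.

Defaults and what they encode (all configurable):

* 20-min sampling over 16 h; fates sporulating/burst-only/transient-
  localization/quiescent with probabilities 0.5 / 0.3 / 0.02 / 0.18. The
  2% transient-localization probability is the reported fraction; the
  others set a majority-sporulating cohort with a sizable bursting
  subpopulation.
* Sporulating cells: staged onsets P_spo0A → +0.5 h P_spo0F → +1.5 h
  SpoIIE → +3 h P_spoIIR after a start time uniform in 6.5–8.5 h; slow
  rises for the early reporters (τ = 0.5–1 h) and a sub-frame (τ = 0.01 h)
  switch-like rise for P_spoIIR. The commitment interval is log-normal
  (median 1 h, CV 0.2); the cell-cycle distribution is log-normal with
  median 6.67 h so the median interval is 15% of the median cycle. The
  absolute scales are free choices (the source reports only the CV and
  the ratio); they were fixed once to fit inside the observation window.
* The spore annotation is placed at (first noiseless grid crossing of the
  60% threshold) + interval, so the *measured* interval carries the
  configured distribution; anchoring to the continuous crossing instead
  would add a ±1-frame quantization offset that is an artifact of the
  grid, not of the modeled timing. The trace ends at the frame where the
  spore appears. Sporulating cells also carry a septal-localization
  interval ending at the spore (a completed, non-transient event),
  exercising the transient/completed distinction.
* Burst-only cells: 1 + Poisson(rate − 1) excursions (so the per-cell
  mean equals the configured rate of 2.0 while every such cell bursts at
  least once), placed in disjoint slots so excursions never merge, with
  amplitudes uniform in 0.7–1.0 of range in both early channels and no
  late-reporter activation. Counts are capped at the number of slots that
  fit the observation window (4 at defaults; mean distortion < 0.01).
* Transient-localization cells: one SpoIIE pulse with a matching
  annotation interval and no spore.

`recovery_report` closes the loop: it re-estimates the commitment CV, the
interval/cycle ratio, the localization fraction, the per-cell burst count
and the onset ordering from the generated traces and compares them to the
generator's truth (bootstrap 95% intervals for the two interval
statistics — resampling cells jointly for intervals and cycles — 3 SEM /
3 SE for the two counts, exact ordering for the hierarchy). A
shuffled-label control must fail.

**What passing does and does not show.** Passing recovery demonstrates
that the estimators are unbiased at the study's sample sizes under the
generator's assumptions: clean staged ramps, stationary Gaussian noise,
annotation-grade event times, no photobleaching, no segmentation or
tracking errors, no lineage structure, and fate classes that are mutually
exclusive. Real movies violate all of these to some degree; in
particular, absolute-scale drift would stress the fractional thresholds,
and cycle durations correlated with sporulation timing would bias the
interval/cycle ratio. Those effects are out of scope here.

## Known limitations

* The population models are deterministic means; no finite-population
  (Gillespie) noise, by design.
* The commitment-interval CV at n = 31 has an intrinsic sampling SD of
  ≈ 0.03; single-cohort estimates in roughly 0.15–0.27 are expected and
  the bootstrap interval, not the point estimate, is the meaningful
  check.
* No image analysis: spore appearance, divisions and localization
  intervals are consumed as annotations.
* Fig-style smoothing is not replicated; a centered moving average is
  provided but off by default.
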