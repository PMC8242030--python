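# Methods

## Model

### Chemical programs

A program is a rectangular antiphase rhythm: IAA is ON during
`[kT, kT + w)` for period `T` and pulse width `w`, SA is ON exactly when IAA
is OFF (or shares the IAA window when `antiphase=False`, used with one
amplitude at zero for single-receptor pulse experiments).  Waveforms are
sampled on `[0, duration)`; a sampling step that does not divide the period
is rejected rather than rounded, because silent rounding would shift every
cycle onset used downstream as the phase reference.  Defaults mimic the
recordings the pipeline is built for: 10-min sampling, records up to 72 h,
amplitudes 500 µM SA and 1 µM IAA.

### Drive mapping

The two receptor occupancies are collapsed into one effective drive

    u_raw = Hill(c_IAA; EC50_IAA, n) − Hill(c_SA; EC50_SA, m) ∈ [−1, 1],

relaxed through `du/dt = (u_raw − u)/τ_u` with `u(0) = u_raw(0)`.  The
relaxation uses the exact exponential update for piecewise-constant input,
so the discrete solution carries no step-size error.  `τ_u = 1.5 h` is the
single kinetic constant of sensing; it was chosen so that (i) burst decay
lags the chemical OFF edge by hours, and (ii) the single-receptor 5-h-pulse
response stays below 80 % precision (see *Calibration*).  EC50 defaults are
the published receptor midpoints (0.13 µM IAA, 407.3 µM SA); Hill
coefficients default to 2.

### Hysteretic switch

The promoter is a two-state Schmitt trigger: ON when `u + η > θ_on`, OFF
when `u + η < θ_off`, strict inequalities (a sample landing exactly on a
threshold does not flip).  η is Ornstein–Uhlenbeck noise with stationary
standard deviation `noise_sigma = 0.1` and correlation time
`noise_tau = 0.5 h`, integrated by Euler–Maruyama at `dt = 0.5 min` and
initialized from the exact stationary distribution of the discrete
recursion, so trajectories carry no warm-up transient.  The hysteresis
width is rate dependent:

    h(T) = h0 (1 + κ T_ref / T),   θ_on/off = mid ± h(T)/2,

with `T_ref = 10 h`, `κ = 1.25`.  A discrete two-state switch was chosen
over a continuous double-well because every downstream metric then has an
exact meaning (transition times are well defined) and the noiseless case
has a trivial pen-and-paper oracle.  The sampled Schmitt trigger is
implemented as a forward fill over decisive excursions, which is exactly
equivalent to the sequential update and vectorizes.

### Calibration of mid and h0

`mid = 0.2` and `h0 = 0.1` were derived jointly from the behavioral
constraints the model must satisfy, given the drive mapping above (steady
drive extremes at a 4-h antiphase program are +0.65/−0.27, at 10 h
+0.93/−0.55):

* the deterministic drive must clear both thresholds at 4-h and 10-h
  rhythms (one burst per cycle without noise): `θ_on(4) = 0.41`,
  `θ_off(4) = −0.006` leave ≥ 0.25 margin;
* at fast driving the OFF threshold must sit below zero drive
  (`θ_off(2) = −0.16`), so an IAA-only rhythm — which can only push the
  drive toward 0, never negative — cannot release the switch: fixing one
  chemical destroys the oscillation;
* at slow driving the OFF threshold must stay positive
  (`θ_off(10) = 0.09`, `θ_off(20) = 0.12`), so an isolated pulse does
  switch off, but late: this produces the hour-scale deactivation lag and
  the sub-80 % pulse precision.

No parameter set with a larger base width satisfies all three at once with
this drive mapping.

### Reporter

    dG/dt = α_eff (basal + (1 − basal) P) − γ G,   γ = ln2 / t_half + µ,

Euler-integrated at 0.5 min and sampled at the imaging cadence (10 min).
Defaults: `α = 1 a.u./h`, `basal = 0.02`, `t_half = 2.5 h` (destabilized
GFP), growth dilution `µ = 0.1 /h`.  `G(0)` is the pre-stimulus basal
steady state (computed by fixed-point iteration under feedback), so records
start on the baseline rather than at zero.  Feedback modes rescale the
production rate phenomenologically with `G_ref = α t_half / ln 2`:
`α_eff = α / (1 + g G/G_ref)` (NFL) and
`α_eff = α (1 + g G/G_ref)/(1 + G/G_ref)` (PFL).  These reproduce the
qualitative speed-up of closed-loop circuits; their quantitative effect
sizes are not a validation target.

### Ensembles and seeding

Communities are mutually uncoupled.  Extrinsic heterogeneity is a
mean-preserving lognormal draw (CV 0.1 by default) applied to the
*expression amplitudes* (`α`, mCherry level) only: community-to-community
variation of this kind behaves like copy-number variation and leaves burst
timing untouched, so the timing dispersion measured by the drift metric is
attributable to switch noise alone.  The mCherry channel additionally
carries multiplicative lognormal measurement noise (CV 0.05); dEGFP
stochasticity comes entirely through the switch.  Per-community streams are
`SeedSequence(entropy=seed, spawn_key=(i,))`, so enlarging an ensemble
never perturbs existing communities; the killer strain uses a length-two
spawn key that cannot collide with any community key.

### Consortium and toxin action

The killer strain is one extra switch (no reporter) driven by the same
program; its ON state sources a shared field `dX/dt = r P_killer − δ X`.
Sensitive communities accumulate stress while they are themselves active,

    ds/dt = X · P − s        (1-h relaxation),

and a community whose stress exceeds the threshold at a cycle onset is held
OFF for `refractory_cycles` cycles, then re-evaluated.  Gating the uptake
by the community's own activity is the modelling choice that produces clean
alternation: an active cycle charges the stress above threshold, the skipped
cycle discharges it (e^{−4} ≈ 0.02 of it remains after a 4-h cycle), the
next cycle is active again — period doubling with ratio 2.  A stress that
integrated the field unconditionally would, after its transient, be
cycle-periodic and independent of the community's own history, which can
only yield all-or-nothing skipping, never alternation.  With `r = 0` the
consortium path reduces *exactly* (stream for stream) to the plain ensemble
because both run the same core routine.  Toxin defaults (`r = 1 a.u./h`,
`δ = 0.5 /h`, threshold 0.3 a.u., one refractory cycle) put the default
consortium near the doubling boundary; the doubling demonstrations use
`r = 5` so the alternation is unambiguous.

## Quantification pipeline

Order: `normalize_growth → detrend_linear → smooth_savgol → rescale01`,
column-wise per community.

* `normalize_growth = dEGFP/(dEGFP + mCherry)`; 0/0 is defined as 0 (a dead
  or empty ROI reads as no signal).
* Detrending subtracts the least-squares line (scipy.signal.detrend); the
  choice of a linear rather than constant detrend follows the default of
  the routine the original analysis names.
* Savitzky–Golay smoothing: length 15, polynomial order 3 (the order is not
  documented in the original analysis; 3 preserves burst apexes), boundary
  handling by polynomial fit on the leading/trailing window (`mode=interp`)
  so edge bursts do not alias.
* `rescale01` maps each community onto [0, 1]; constant traces raise.

### Peaks

Index `i` is a burst apex iff preceded by ≥ nups non-decreasing steps with
the step into the apex strictly rising, followed by ≥ ndowns non-increasing
steps with the step off the apex strictly falling, and prominence ≥
`min_prominence` (default 0.1 on the rescaled scale in the pipeline).
Defaults nups = ndowns = 6.  FWHP is measured at `peak − prominence/2` by
linear interpolation (scipy `peak_widths`, `rel_height = 0.5`).  A known
consequence of the strict run rule at 10-min sampling: smoothed measurement
noise occasionally breaks the monotone run near a flat apex, so at default
noise roughly 5–10 % of true bursts go undetected.  The drift and doubling
metrics are robust to such misses (they use assigned or median statistics);
the sync fraction counts them against a community, which is the intended
strictness.

### Metrics

* **Periods**: first differences of peak times (hours).
* **Precision**: `1 − |w_out − w_in|/(w_out + w_in)` with the burst FWHP as
  output width and the pulse ON duration as input width; the absolute value
  keeps the index ≤ 1 when the output is narrower than the input.  Per
  community, the median FWHP over its bursts is used.
* **Phase drift**: per cycle, each community contributes its peak nearest
  the cycle onset (within ±T/2); drift of a cycle is the SD of those times
  across communities as % of T; the report is the mean over cycles with ≥ 2
  assignments.  SD across communities was chosen over range- or
  pairwise-based dispersion as the standard ensemble statistic; the metric
  is invariant to a common offset, so the systematic response lag does not
  register as drift.
* **Sync fraction**: the cycle reference is the onset shifted by the
  ensemble median peak lag; only windows fully inside the record are
  scored (a lag-shifted window protruding past the record start would
  otherwise penalize every community in its first cycle).  A community is
  locked if ≥ 90 % of scored windows contain exactly one peak and the mean
  deviation from the reference is < T/4.  Both thresholds are exposed
  parameters.
* **Cumulative ACF**: per-community biased autocorrelation (statsmodels,
  `adjusted=False`, so the sequence is positive semidefinite), averaged
  across communities; default maximum lag = half the record.
* **PSD**: periodogram of the ensemble-mean trace, no window, zero-padded
  to 4× length; power normalized so its sum equals the trace variance
  (Parseval); the dominant period excludes the zero bin.
* **Doubling ratios**: per community, median response period over the input
  period; snapped to the nearest of {1, 2, 4, 8} when within 25 % relative
  distance, otherwise flagged unsnapped (NaN); raw values retained.

### Dose–response

Four-parameter Hill fit by least squares with the EC50 parametrized on the
log scale (positivity and clean standard-error transformation); zero
concentrations enter the untransformed model.  Initialization from the
data: bottom = min, top = max, EC50 = geometric middle of the positive
range, n = 1.  A fitted dynamic range below three residual standard
deviations, or flat data, raises a fit failure instead of returning a
silent result.  The 95 % EC50 interval is a log-scale Wald interval; over
200 simulated fits at 5 % noise its empirical coverage lies in [90 %, 99 %]
and the EC50 bias is below 5 % (tested).

## Operating point and what the tests show

With all defaults, a 46-community ensemble under the 4-h rhythm shows a
phase drift of ≈ 5.3 % of the period (frozen regression band 3.5–6.5 %),
sync fraction ≈ 0.96, and a dominant PSD period equal to the driving
period; the isolated 5-h pulse gives precision ≈ 75.6 %.  The timing jitter
is first-passage noise of the OU process across the OFF threshold
(≈ σ/|du/dt| ≈ 0.2 h), which is what the drive geometry admits at
`σ = 0.1`; the drift printed for the real fast-rhythm recordings (2 %) is
therefore validated through metric-recovery on constructed ensembles with
engineered jitter, not through the simulator.  The generator emulates the
statistical structure of the recordings — burst shape, lags, jitter,
heterogeneity, period doubling — but not image-level artifacts, growth-rate
drift, trap-to-trap focus variation, or coupling through shared media, so
passing tests demonstrate correctness of the methods and metrics, not
biological fidelity of any particular parameter value.

## Numerical choices

* Internal integration step 0.5 min (Euler for the reporter,
  Euler–Maruyama for the OU noise), outputs sampled at 10 min.
* Exact exponential updates for the two linear relaxations (drive low-pass;
  stationary OU initialization).
* Switching-rate convergence in the step size is slow (the discretely
  sampled path misses threshold excursions at a √dt rate); the refinement
  check is run at a 1/960-h base step and a threshold gap of 2/3 the noise
  SD, where the residual bias is ≈ 5 %, inside the 10 % agreement band.
* Ties on thresholds never flip the state; the initial state is the
  indicator `u(0) > mid`.
* Degenerate inputs raise typed errors (constant trace in `rescale01` and
  `power_spectrum`, empty drives, ragged time grids, missing channels).

## Known limitations

* The 46-community simulator drift at 4 h (≈ 5 %) exceeds the 2 % printed
  for the recordings; matching it would require either weaker switch noise
  or steeper drive crossings than the stated defaults provide.
* Hysteresis width enters through the driving period, not instantaneously
  through du/dt; programs with mixed rates within one record would need the
  instantaneous formulation.
* The toxin mechanism is one of several consistent with the observed
  doubling; it is phenomenological (cycle-skipping refractory), not a
  kinetic model of K1 toxin action.
* `find_peaks` with the strict 6-up/6-down rule under-detects flat apexes
  at high measurement noise (see above).
* Feedback modes are production-rate scalings; amplitude effect sizes of
  closed-loop circuits are out of the validated surface.
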