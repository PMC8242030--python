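# chemsync

Chemically driven synchronization of gene expression across isolated yeast
communities: a simulator for rate-dependent hysteretic stochastic switching
under antiphase chemical rhythms, and the complete quantification pipeline
for the resulting fluorescence time series.

## The problem

Spatially isolated *S. cerevisiae* colonies carrying a dual bacterial-receptor
circuit (an IacR module activated by auxin/IAA, a MarR module repressed by
salicylic acid/SA) express a destabilized GFP reporter (dEGFP) in near-perfect
synchrony when the two chemicals are pulsed in antiphase — despite the absence
of any intercellular coupling or intrinsic oscillator.  The proposed mechanism
is a bistable switch whose hysteresis region widens with the rate of the
chemical rhythm, so fast rhythms gate out molecular noise.  This package is
for computational biologists who want to simulate that mechanism, test
synchrony metrics against engineered ground truth, and analyze tidy CSV
recordings of per-community fluorescence.

## The model

The chemical program delivers rectangular antiphase waveforms c_IAA(t),
c_SA(t).  They are collapsed into an effective drive

    u_raw(t) = c_IAA^n / (c_IAA^n + EC50_IAA^n) − c_SA^m / (c_SA^m + EC50_SA^m),
    du/dt    = (u_raw − u) / τ_u,                       u ∈ [−1, 1],

with EC50_IAA = 0.13 µM and EC50_SA = 407.3 µM (the fitted receptor
midpoints).  The promoter is a two-state Schmitt trigger with
Ornstein–Uhlenbeck noise η(t) added to the drive: it switches ON when
u + η > θ_on and OFF when u + η < θ_off, where the threshold separation is
rate dependent,

    h(T) = h0 (1 + κ · T_ref / T),     θ_on/off = mid ± h(T)/2,

so a 2-h rhythm sees a much wider (noise-rejecting) hysteresis loop than a
10-h rhythm.  The promoter state P(t) drives the short-lived reporter

    dG/dt = α_eff (basal + (1 − basal) P) − (ln 2 / t_half + µ) G,

with optional phenomenological negative or positive production feedback
(α_eff scaled by G/G_ref).  A consortium mode adds a killer strain whose
promoter ON state sources a shared toxin field X; sensitive communities
accumulate stress while active (ds/dt = X·P − s) and skip a refractory cycle
whenever stress exceeds a threshold at a cycle onset — which doubles the
response period under strong pulsatile toxin stress.

The analysis pipeline mirrors the experimental one: growth normalization
dEGFP/(dEGFP + mCherry), linear detrending, Savitzky–Golay smoothing
(filter length 15), 0–1 rescaling, burst detection with the nups/ndowns = 6
rule, periods as successive peak distances, response precision
1 − |w_out − w_in| / (w_out + w_in), inter-community phase drift (SD of
burst times across communities, % of the period), a synchronization
fraction, cumulative ACF, FFT power spectra with dominant period, and
period-doubling ratios.  Four-parameter Hill fitting with EC50 standard
errors handles dose–response tables.

## Worked example

```bash
python examples/synchronized_ensemble.py
```

```
communities:        46
median period:      4.00 h (input 4 h)
dominant period:    4.00 h (from the ensemble PSD)
phase drift:        5.22 % of the period
sync fraction:      0.96
median precision:   0.98
```

46 uncoupled communities entrain to the 4-h rhythm: the ensemble power
spectrum peaks exactly at the driving period, burst timing disperses by only
~5 % of the period across communities, and 96 % of communities place exactly
one burst per cycle near the ensemble reference.  The single-pulse
experiment shows the hysteretic lag instead:

```bash
python examples/pulse_response_lag.py
```

```
input pulse width:  300 min
burst FWHP:         494 min
response precision: 75.6 %  (below the 80 % bound)
```

The reporter burst outlasts the 5-h pulse by more than three hours because
the switch releases only when the slowly relaxing drive crosses the OFF
threshold — the precision index therefore stays below 80 %.  Other examples
cover dose–response fitting (`dose_response_fit.py`), the noise × period
sync sweep (`noise_rate_sweep.py`) and toxin-driven period doubling
(`consortium_period_doubling.py`).

A thin CLI wraps the same functions:

```bash
chemsync simulate --config run.cfg --outdir out/
chemsync analyze --traces traces.csv --program prog.cfg --outdir out/
chemsync sweep --noise-grid 0,0.1,0.3 --period-grid 2,4,10 --seed 1 --outdir out/
chemsync fit-hill --input dose.csv
```

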