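# dyadsync

Analysis pipeline for **dyadic fNIRS hyperscanning** studies of interbrain
synchrony: does a shared behavior (here: laughter in a 2 × 2 Laughter ×
Social-context design) raise the coherence of two interacting people's
cortical hemodynamics, and does that synchrony in turn carry effects on
social outcomes such as liking, prosociality and bonding?

The package implements the full chain a hyperscanning analyst needs:

1. **Synthetic cohorts** (`dyadsync.simulate`) — two-participant, 16-channel
   hemodynamic recordings at 7.81 Hz with a tunable cross-brain coupling κ in
   a configurable period band, 1/f background, cardiac/respiratory/Mayer
   nuisance sinusoids, laughter annotation tracks calibrated to published
   per-condition totals, and questionnaire outcomes generated by a linear
   treatment → mediator → outcome structural model. Everything is seeded and
   bitwise reproducible.
2. **Preprocessing** (`dyadsync.preprocess`) — raw two-wavelength intensity →
   optical density, motion detection, spline correction, wavelet despiking,
   zero-phase band-pass, and the modified Beer–Lambert law (MBLL) to ΔHbO /
   ΔHbR, plus channel/ROI/dyad quality bookkeeping.
3. **Wavelet transform coherence** (`dyadsync.wtc`) — analytic Morlet CWT,
   the standard time-and-scale smoothed squared coherence

   R²(s,t) = |S(s⁻¹ W_xy)|² / ( S(s⁻¹|W_x|²) · S(s⁻¹|W_y|²) ),

   an adaptive period band from 8 s up to a quarter of the segment duration,
   cone-of-influence exclusion, and reduction to one scalar per dyad × ROI
   pair × phase × interval over the 10 canonical pairs of bilateral IFG and
   TPJ.
4. **Pseudo-dyad surrogates** (`dyadsync.surrogate`) — each participant paired
   with random non-partners, coherence matrices averaged, and a Bayesian
   group comparison of real vs chance-level synchrony.
5. **Bayesian inference** (`dyadsync.bayes`) — Gaussian hierarchical linear
   models `y ~ A*B*… + (1|dyad)` with ±0.5 effect coding, an in-package MCMC
   sampler (conjugate Gibbs blocks, slice-sampled scales), rank-normalised
   split R-hat and bulk ESS, prior/posterior predictive checks, Bayes factors
   (Rao-Blackwellised Savage–Dickey for nested comparisons, bridge sampling
   otherwise), and the sequential BF stopping rule (stop at BF > 5 or
   BF < 0.20).
6. **Bayesian mediation** (`dyadsync.mediation`) — dyad-level two-equation
   mediation with per-draw ACME = a·b, ADE = c′, total = c′ + a·b (exact
   identity), proportion mediated, and 95 % equal-tailed intervals.

A thin CLI (`dyadsync simulate|preprocess|synchrony|surrogate|behavior|
outcomes|models|mediate|run|validate`) orchestrates the stages over plain
CSV/JSON artifacts with a checksummed run manifest.

## Worked example

```python
import pandas as pd
from dyadsync import (SimulationConfig, generate_dyad_timeseries,
                      dyad_synchrony, fit_mediation)
import numpy as np

cfg = SimulationConfig(n_dyads_per_condition=1,
                       phase_plan=(("manipulation", 300.0, 0.0),), seed=3)

for kappa in (0.0, 0.9):
    vals = []
    for d in range(6):
        rec = generate_dyad_timeseries(cfg, d, kappa)
        t = dyad_synchrony(rec, pairs=["IFGl_IFGl"], n_intervals=1)
        vals.extend(t["wtc_value"].dropna())
    print(f"kappa={kappa:.1f}  mean band-averaged WTC = {np.mean(vals):.3f}")

rng = np.random.default_rng(0)
T = rng.integers(0, 2, 500).astype(float)
M = 0.5 * T + 0.1 * rng.standard_normal(500)
Y = 0.3 * T + 0.4 * M + 0.1 * rng.standard_normal(500)
res = fit_mediation(pd.DataFrame({"T": T, "M": M, "Y": Y}), "T", "M", "Y",
                    seed=1, chains=2)
print(res.summary().round(3))
```

prints

```
kappa=0.0  mean band-averaged WTC = 0.472
kappa=0.9  mean band-averaged WTC = 0.728
                   mean  eti_low  eti_high
effect
ACME              0.182    0.140     0.221
ADE               0.310    0.267     0.357
total             0.492    0.474     0.510
prop_mediated     0.370    0.285     0.452
a (T->M)          0.483    0.466     0.501
b (M->Y)          0.377    0.290     0.459
c' (T->Y direct)  0.310    0.267     0.357
```

Coherence at zero coupling is not zero — the smoothing that makes wavelet
coherence well-defined also gives independent signals a positive bias level
(~0.43 under these settings), which is exactly why the pseudo-dyad surrogate
null exists: chance-level synchrony is estimated empirically and real dyads
are compared against it. The mediation model recovers the planted paths
(ACME 0.5·0.4 = 0.20, total 0.50) with 95 % ETIs.

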