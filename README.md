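# selt1

Selective inversion-recovery T1 analysis and SOFAST recovery-delay planning
for in-cell NMR of nucleic acids.

## The problem

In-cell NMR of DNA/RNA in human cells works at painfully low signal-to-noise:
transfectable concentrations are a few micromolar and the sample dies over
hours. Band-selective fast-pulsing (SOFAST-style) experiments recover much of
the lost sensitivity, but only if the recovery delay is tuned to the
*selective* longitudinal relaxation time selT1 of the observed protons — and
selT1 inside cells is several-fold shorter than in buffer. This package
implements the quantitative machinery for that workflow on 1D imino-proton
spectra (10–15 ppm):

1. **Measure selT1** by selective inversion recovery. The peak intensity at
   recovery delay τ follows

       I(τ) = A + D·exp(−τ / selT1)

   with A the equilibrium intensity and D the (imperfect-)inversion
   coefficient. Fits are weighted nonlinear least squares; replicates can
   share a single selT1 (global fit) while keeping per-series A and D.
   Interleaved repeats of a 0.32 ms reference delay track sample
   deterioration; a linear fit through them gives a multiplicative
   correction applied before fitting.

2. **Plan the acquisition.** The steady-state sensitivity per unit time of a
   120° fast-pulsing experiment as a function of the total recovery time
   T_rec is

       S(T_rec) = sin(π/3)·(1 − E) / ((1 − E·cos(π/3))·√(T_rec + t_ov)),
       E = exp(−T_rec / selT1),

   with t_ov the per-scan pulse/gradient overhead. The planner maximizes S,
   propagates the selT1 standard error into bounds, and clamps the result
   against instrument floors (minimum D1, acquisition time, disk-write
   time). It also covers the quantitative (5×T1) regime and gain
   comparisons between settings.

3. **Control the sample.** Closed-form calculators for the supporting
   quantifications: spherical cell/nuclear volumes from microscopy
   diameters, the nuclear share of volume and signal, the interstitial
   medium fraction of a cell pellet, sequential-wash carryover dilution, and
   denaturing-PAGE standard-curve concentration estimates.

Because raw spectrometer data are not bundled, a first-class synthetic-data
module generates complex FIDs and complete recovery experiments with the
statistical structure the analysis assumes (Lorentzian imino resonances,
white complex noise at in-cell SNR ≈ 8–12, linear sample deterioration, the
published nine-delay schedules), so every stage is testable end to end.

## Worked example

Three simulated technical replicates at in-cell noise (SNR 10) with 10%
signal decay over 4 h, drift-corrected, globally fitted, then used to plan
the acquisition:

```python
import numpy as np, selt1
from selt1.recovery import (RecoverySeries, fit_recovery_global,
                            correct_deterioration)
from selt1.sofast import (SensitivityParams, InstrumentConstraints,
                          optimal_trec, apply_constraints)

rng = np.random.default_rng(42)
peak = selt1.ResonanceSpec("T4/T22/T18", 13.40, 25.0, A=3.0, selt1=84.0)
schedule = selt1.delay_schedule_preset("short9")
drift = selt1.DriftModel(relative_slope=-0.10 / 240)   # −10% per 4 h

series = []
for i in range(3):
    tau, I, err, t0, ref = selt1.simulate_recovery_points(
        peak, schedule, snr=10, drift=drift, rng=rng)
    s = RecoverySeries.from_arrays("T4/T22/T18", tau, I, err, t0, ref,
                                   replicate_id=("bio1", f"tech{i+1}"))
    series.append(correct_deterioration(s))

res = fit_recovery_global(series)
print(res.summary())

p = SensitivityParams(selt1=res.selt1, selt1_se=res.selt1_se, overhead=11.0)
opt = optimal_trec(p)
ach = apply_constraints(opt, InstrumentConstraints(), p)
print(f"optimal recovery time: {opt.trec_opt:.1f} ms")
print(f"achievable on the instrument: {ach.trec_opt:.1f} ms (D1 = {ach.d1_opt:.0f} ms)")
```

prints

```
Global inversion recovery fit (shared selT1)
peak: T4/T22/T18   series: 3   weighted=True
status: ok (converged)   red. chi2 = 1.162
----------------------------------------------------------
shared selT1 = 83.4 +/- 3.3 ms
replicate_id        A     A_se         D     D_se
  bio1/tech1 2.778398 0.104071 -5.634738 0.130793
  bio1/tech2 3.254401 0.114853 -6.446949 0.144600
  bio1/tech3 2.898207 0.106055 -5.770186 0.133395

optimal recovery time: 65.2 ms
achievable on the instrument: 137.0 ms (D1 = 30 ms)
```

The shared fit recovers the generating selT1 of 84 ms within its standard
error; the drift correction has absorbed the injected decay (reduced χ² near
1). The unconstrained sensitivity optimum for selT1 ≈ 83 ms sits near 65 ms,
but the spectrometer's minimum D1 of 30 ms plus 77 ms acquisition and 30 ms
disk write floor the achievable recovery time at 137 ms — so the planner
recommends running at the floor with D1 = 30 ms.

The same pipeline is scriptable from the shell (`selt1 simulate`, `process`,
`extract`, `fit`, `plan`, `cellcalc`); see `selt1 --help`.

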