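# centraljnd

A computational model of auditory **intensity change detection** built
on time-varying loudness.  Loudness grows over a ~100-dB dynamic range,
yet intensity discrimination hardly improves above moderate levels —
the psychoacoustic face of the *dynamic range problem*.  `centraljnd`
resolves the two with a central stage: neurons adapt to the prevailing
(mean) sound level, so the loudness signal available centrally is
partially renormalized toward a fixed central dynamic range, and what is
detected is not a loudness *difference* but the maximum **rate of
change** of central loudness.

The package is for psychoacousticians and auditory modelers who want to
predict intensity just-noticeable differences (JNDs) for continuous and
pseudo-continuous pedestal paradigms, fit the central constants to their
own data, or simulate adaptive listening procedures with a model
observer.

## Model in brief

1. **Peripheral loudness** `L(t)`: excitation-pattern loudness on a 1-ms
   grid — middle-ear filtering, level-dependent auditory filters on the
   ERB scale, compressive specific loudness, then cascaded asymmetric
   integrators: short-term (attack 25 ms / release 50 ms) and long-term
   (100 / 100 ms) loudness.
2. **Central adaptation**: with L̄ the pedestal's mean loudness and
   `T_CA` the central threshold,

       L_Cen(t) = L(t) · (T_CA + (1 − α)(L̄ − T_CA)) / L̄   for L̄ > T_CA

   (identity otherwise).  Defaults: `T_CA = 0.215` sones, `α = 0.95`.
3. **Detection**: a change is detectable when

       max ΔL_Cen/Δt |_target  −  max ΔL_Cen/Δt |_pedestal  ≥  5.5·10⁻⁵ sones/ms

   on matched analysis windows of the same frozen carrier.  Thresholds
   are reported as the max pedestal-to-target level difference (dB) and
   as the Weber fraction ΔI/I.

Seven classic paradigms ship as declarative conditions: continuous
1-kHz tones with 200-ms increments, continuous band-limited noise with
1.5-s square increments, gated 4-kHz tones (increments and decrements,
in quiet and in masking noise), brief linear ramps in spectrum-level
noise, gated 477-Hz tones, linear up-down ramps (5 ms – 50 s half-ramps)
in 33-dB SPL noise, and 1-kHz two-tone beats.

## Worked example

```python
from centraljnd import CentralParams, condition_registry, solve_jnd

params = CentralParams()            # T_CA=0.215 sones, alpha=0.95
for h in [5, 10, 100, 1000]:        # half-ramp duration, ms
    cond = condition_registry("supplementary_ramps", half_ramps_ms=[h])[0]
    res = solve_jnd(cond, params)
    print(f"half-ramp {h:>5} ms  threshold {res.increment_db:5.2f} dB")
```

prints

```
half-ramp     5 ms  threshold  3.59 dB
half-ramp    10 ms  threshold  2.06 dB
half-ramp   100 ms  threshold  0.59 dB
half-ramp  1000 ms  threshold  1.37 dB
```

— the U-shaped duration tuning of ramped-increment detection: very fast
ramps are smoothed away by temporal integration, very slow ramps never
produce a large loudness slope, and detection is best near the 100-ms
integration scale.  The `examples/` directory has narrative scripts for
loudness traces, JND curves, staircase simulation and parameter
fitting.

Empirical datasets for fitting are user-supplied CSV tables
(`study,x_value,x_units,jnd_value,jnd_units,notes`); no historical data
ship with the package.

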