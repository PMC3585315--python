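# Methods

## The model

`centraljnd` implements a two-stage account of auditory intensity change
detection.  The **peripheral stage** is a time-varying excitation-pattern
loudness model: the calibrated waveform is passed through a tabulated
middle-ear transfer function, analysed spectrally on a 1-ms hop, spread
across cochlear place by level-dependent rounded-exponential (roex)
auditory filters on the ERB-number (Cam) scale, transformed to specific
loudness compressively and integrated across place to give instantaneous
loudness in sones.  Two cascaded asymmetric exponential integrators
produce short-term loudness (STL; attack 25 ms, release 50 ms, the
asymmetry capturing greater forward than backward masking) and long-term
loudness (LTL; attack 100 ms, release 100 ms).  The 100-ms LTL release —
rather than the 2-s value used for loudness-persistence modeling — makes
the long-term window symmetric; the original value remains available via
`ModelConfig.ltl_release_ms`.

The **central stage** models static adaptation to the prevailing (mean)
loudness of a continuous pedestal.  With mean peripheral loudness L̄ and
central adaptation threshold `T_CA`, central loudness is a conditional
partial normalization

    L_Cen(t) = L(t) · (T_CA + (1 − α)(L̄ − T_CA)) / L̄   if L̄ > T_CA
    L_Cen(t) = L(t)                                      otherwise

so the mean central loudness moves a fraction α of the way from L̄ back
to `T_CA`.  α = 0 is the unadapted peripheral model; α = 1 pins the mean
central loudness at `T_CA` for any input.  No adaptation time constant
is modeled: for continuous pedestals the mean level is stationary, and
no data exist to constrain a time constant.  Adaptation acts on the
scalar loudness trace, not per cochlear channel.

**Detection** operates on the maximum rate of change of central
loudness on a 1-ms grid.  For a frozen carrier, the decision statistic
is the difference between the maximum 1-ms first difference of the
pedestal-plus-change trace and that of the matched pedestal trace, and a
change is detectable when this statistic reaches the rate criterion
`(ΔL/Δt)_jnd = 5.5e-5` sones/ms.  For decrements the maximum absolute
first difference is used in both terms.  The threshold solver adjusts
the change size (dB) by bisection over a verified-monotone bracket
(default 0.01–30 dB, ≤ 60 model evaluations) until the statistic equals
the criterion; the solution is reported as the maximum pedestal-to-
target level difference `increment_db`, the Weber fraction
ΔI/I = 10^(increment_db/10) − 1, and its log form 10·log10(ΔI/I).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `T_CA` | 0.215 sones | central adaptation threshold (≈ 25 dB SPL for a 1-kHz tone) |
| `alpha` | 0.95 | normalization amount (95 % adaptation) |
| `rate_jnd` | 5.5e-5 sones/ms | rate-of-change criterion |
| STL attack/release | 25 / 50 ms | short-term integrator |
| LTL attack/release | 100 / 100 ms | long-term integrator |
| threshold criterion | 0.003 sones | LTL plateau at absolute threshold |
| full-scale reference | 100 dB SPL | calibration of amplitude 1.0 sinusoid |

## Numerical choices

* **Internal analysis rate.**  Stimuli are synthesized at 44.1 kHz; the
  loudness front end resamples to 32 kHz internally so the 1-ms hop is
  exactly 32 samples.  Content above 16 kHz is dropped; the middle-ear
  transfer attenuates that region by 30–50 dB, so its loudness
  contribution is negligible even for broadband (0–20 kHz) noise.
* **Multi-resolution spectra.**  Six parallel Hann-windowed FFTs (64 ms
  down to 2 ms) supply the spectral components for six frequency bands
  (20–80, 80–500, 500–1250, 1250–2540, 2540–4050, 4050–15500 Hz),
  trading frequency resolution at low frequencies against time
  resolution at high frequencies.
* **Excitation.**  Roex filter weights `(1 + pg)e^{−pg}` with fixed
  upper slope `p51 = 4f/ERB(f)` and a lower slope reduced by
  0.35·(p51/p51(1 kHz)) dB-for-dB above a 51-dB component level
  (clamped to [0.1, 2]·p51).  Places span 1.8–39 Cam in 0.5-Cam steps.
* **Specific loudness.**  `N' = C[(G·E + A)^0.2 − A^0.2]` with
  C = 0.047, A = 4.62505 and a low-frequency gain term G that equalizes
  the excitation at threshold across centre frequencies; a square-root
  regime takes over above E = 1e10.  This form is exactly zero in
  silence and rises smoothly through threshold.  The published
  below-threshold attenuation factor `(2E/(E+E_THRQ))^1.5` is *not*
  applied: it suppresses sub-threshold channel contributions so strongly
  that a broadband noise could not reach the 0.003-sone criterion until
  far above its empirical detection threshold, which would break the
  model's noise-threshold anchor (see Anchors).  Dropping it is within
  the variant freedom the peripheral stage is allowed, and the two
  anchors below are the acceptance test of that choice.
* **Diotic calibration.**  All modeled experiments are diotic.  The
  binaural convention is absorbed into one scalar
  (`ModelConfig.diotic_calibration` = 1.0474) fixed so that a steady
  1-kHz tone at 25 dB SPL has an LTL plateau of exactly 0.215 sones.
* **Anchors.**  Two fixed points tie the front end to the published
  behavior it replaces: (i) 1-kHz tone at 25 dB SPL → 0.215 sones;
  (ii) the band-limited (150–7000 Hz, 12 dB/oct skirts) noise reaches
  the 0.003-sone criterion near 4 dB SPL (the model computes ≈ 5.9 dB,
  within the ±2 dB the anchor allows).
* **Analysis windows.**  Rate statistics are evaluated over the change
  span plus a 50-ms lead and 250-ms lag, clipped to the settled portion
  of the pedestal (gates + 250-ms margin excluded at both ends; the
  margin shrinks automatically for pedestals shorter than ~0.6 s).
  Gating transients are common to both 2IFC intervals and carry no
  information, so they are excluded from both max-rate terms.
* **Pseudo-continuous pedestals.**  The gated 4-kHz paradigm presented
  500-ms intervals, but the model's continuity approximation (adaptation
  to the stationary mean level, detection against a settled carrier)
  evaluates the documented increment envelopes on a longer internal
  pedestal (1.5 s).  With the literal 500-ms carrier the long-term
  integrator's onset transient (settling ≈ 0.7 s) would overlap every
  increment window and dominate the matched max-rate terms.
* **Mean loudness L̄.**  Computed once per condition from the
  increment-free pedestal: the settled plateau for tonal pedestals, the
  mean over the full settled span for noise pedestals (smoothing the
  carrier's inherent loudness fluctuations).  For masked conditions the
  masker + tone sum is one signal, and L̄ is taken from that sum.
* **Long stimuli.**  Conditions with half-ramps ≥ 10 s run on a
  decimated analysis hop (8 or 16 ms) with traces interpolated back to
  the 1-ms grid; at those ramp rates the loudness trajectory is
  low-bandwidth and the full-rate and decimated paths agree to well
  under 0.2 dB on the 100-ms and 1000-ms conditions.
* **Solver tolerances.**  1e-7 sones/ms on the criterion or 1e-3 dB on
  the bracket, whichever is reached first.
* **Square-increment noise paradigm.**  The historical procedure
  repeated 1.5-s increments every 4.5 s; one cycle is simulated (a
  4.5-s pedestal with one centred 1.5-s increment) — the detector
  reacts to each onset identically, so a periodic train adds nothing
  under a static adaptation state.
* **Tone-study level grid.**  The continuous 1-kHz paradigm spans
  "threshold to 85 dB SPL"; the default grid starts ~5 dB above the
  model's own 1-kHz threshold (≈ 1 dB SPL) and rises in 10-dB steps.

## The fitted parameters

`fitting.fit_central_params` minimizes the mean over datasets of the
per-dataset rms error, in dB on the 10·log10(ΔI/I) scale, between
predicted and observed thresholds, with `rate_jnd` held fixed.  A
12 × 11 coarse grid (T_CA ∈ [0.05, 0.6] sones, α ∈ [0.5, 1.0]) brackets
both slopes of each parameter's minimum; coordinate-wise golden-section
sweeps refine it.  Because the peripheral stage is independent of the
central parameters and the central stage is an exact scalar gain on the
detection statistic, the peripheral statistic is sampled once per
condition on a change-size grid and thresholds for any (T_CA, α) are
obtained by inverting that curve — the optimizer never re-runs the
loudness model.  The per-point error term is a dB difference (a linear
ratio alternative would change only `fitting._rms_error_db`).

An optional per-study additive dB offset (off by default) can absorb
differences in the psychometric criterion of the historical studies
(50 % vs 70.7 % vs 79.4 % correct); when used it is recorded in the fit
output.

## What the synthetic data generator emulates — and what it does not

The stimulus module reproduces the documented conditions of the modeled
studies: carrier types and frequencies, pedestal durations and gating,
envelope shapes (square, gated-plateau, symmetric linear up-down ramps,
two-tone beats), level conventions (SPL, SL + 4 dB for the band-limited
noise study, model-referenced SL for the beats study) and frozen-noise
carriers with per-study seeds.  Synthetic JND "observations" for the
recovery studies are generated by the model itself at the default
central parameters and perturbed with 0.2-dB Gaussian noise on the log
threshold scale.

Passing the recovery and property tests therefore shows that the
pipeline is self-consistent, identifiable and deterministic — not that
the model fits human data; that comparison requires digitized historical
JND tables, which are not redistributable and must be supplied by the
user through `fitting.load_dataset_csv` (schema
`study,x_value,x_units,jnd_value,jnd_units,notes`).  Known features of
real data that are deliberately not emulated: listener lapses and
learning, trace-memory limits for ramps longer than ~4 s, transducer
transfer functions, and the psychometric-slope differences between
studies.

## The simulated adaptive procedure

The 3-down 1-up 2IFC staircase uses the administered constants: start
20 dB, 5-dB steps halved after the fourth reversal, 12 reversals,
threshold = mean of the last 10.  The stochastic observer adds
independent zero-mean Gaussian noise (sd a free calibration constant,
default `rate_jnd / (z_79.4 · √2)`) to each interval's max-rate
statistic and picks the larger, which places the 79.4 % point of the
resulting psychometric function exactly at the analytic criterion.  The
staircase validation runs on the 5-ms half-ramp condition, whose
threshold (≈ 3.6 dB) is commensurate with the procedure's final 2.5-dB
step; conditions with sub-dB thresholds are quantization-limited by the
step geometry and are validated against the analytic solver instead.
Interval order and observer noise use separate named seed streams.

## Scale of the shipped computations

Tests and the acceptance script run the model at the study geometries
but on reduced grids: 4-s noise pedestals for the ramp paradigm
(half-ramps 5–1000 ms), a 9-point beat-rate grid, 60 staircase tracks,
and the full level grids of the two continuous-pedestal studies for the
recovery study (one peripheral curve of 10 change sizes per condition).
The 24-s and 104-s pedestals of the longest ramp conditions are
supported through the decimated-hop path but are not exercised in the
default test run.

## Known limitations

* The peripheral stage is a streamlined variant of the published
  excitation-pattern family; absolute loudness away from the two anchors
  (very low frequencies, very high levels) is approximate.
* Gated (pseudo-continuous) pedestals are handled through the
  continuity approximation (settled internal carrier); onset and offset
  effects of the listening intervals themselves are outside the model.
* In quiet, predicted thresholds stop improving once the increment
  outlasts the temporal integrator (~100 ms): the duration effect
  saturates rather than continuing to fall.
* Beat thresholds above ~6 dB modulation cannot be expressed (two-tone
  envelope minima reach zero at equal amplitudes); the solver reports
  such conditions as undetectable at the bracket ceiling.
* Eq.-domain transforms of historical data require the user's own
  digitized tables; the package ships only the loader and schema.
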