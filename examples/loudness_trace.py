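"""Compute time-varying loudness for a tone and a noise pedestal.

Synthesizes two calibrated stimuli, runs the peripheral cascade
(instantaneous -> short-term -> long-term loudness) and prints the
plateau loudness of each, plus the model's absolute threshold for a
1-kHz tone (the level at which long-term loudness reaches the 0.003-sone
criterion).
"""

from centraljnd import (make_tone, make_noise, NoiseSpec, loudness_cascade,
                        plateau_loudness)
from centraljnd.experiments import model_tone_threshold_spl

tone = make_tone(1000.0, 25.0, 2.0, gate_ms=10.0)
casc = loudness_cascade(tone)
print(f"1 kHz tone at 25 dB SPL -> LTL plateau "
      f"{casc.ltl.plateau(1.0, 1.8):.3f} sones "
      "(the central adaptation threshold T_CA sits at this loudness)")

noise = make_noise(NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0,
                             seed=42), 33.0, 2.0, gate_ms=10.0)
print(f"broadband noise at 33 dB SPL -> plateau "
      f"{plateau_loudness(noise):.3f} sones "
      "(above T_CA: the central stage adapts on this pedestal)")

thr = model_tone_threshold_spl(1000.0)
print(f"model 1-kHz absolute threshold: {thr:.1f} dB SPL "
      "(where loudness reaches the 0.003-sone criterion)")
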