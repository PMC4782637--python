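"""Simulate an irregular rat heart and a ventilator, then detect TTL triggers.

Builds one minute of ECG R peaks with beat-to-beat jitter and a ventilated
respiration schedule with a 7 s end-expiratory breath hold, samples an
impulse waveform, and runs the rising-edge comparator over it.
"""

import numpy as np

import cinegate as cg

ecg = cg.simulate_ecg(duration=60.0, mean_rr=0.143, rr_jitter_sd=0.008, seed=1)
print(f"R peaks in 60 s: {len(ecg.r_peak_times)} "
      f"(mean RR {np.mean(ecg.rr_intervals)*1000:.1f} ms, "
      f"sd {np.std(ecg.rr_intervals)*1000:.1f} ms)")

resp = cg.simulate_ventilated_respiration(
    duration=60.0, rate=60.0, insp_fraction=0.4, breath_holds=((10.0, 17.0),)
)
inside = (resp.cycle_times > 10.0) & (resp.cycle_times < 17.0)
print(f"breaths: {len(resp.cycle_times)}; breaths starting inside the "
      f"10-17 s hold: {inside.sum()} (ventilator suspended at end expiration)")

# comparator: impulse waveform at the R-peak times -> TTL trigger train
times, values = cg.impulse_train(ecg.r_peak_times + 0.001, 60.1)
train = cg.detect_triggers(times, values, threshold=0.5, refractory=0.05)
print(f"comparator events: {len(train)} of {len(ecg.r_peak_times)} peaks "
      f"recovered at 1 kHz sampling")
# Every R peak maps to one TTL pulse; the 50 ms refractory window would
# suppress double-triggering on noisy upstrokes.
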