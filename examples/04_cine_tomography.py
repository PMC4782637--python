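"""Cine micro-CT of a beating phantom via retrospective gating and FBP.

Acquires 5 continuous rotations at 10 frames/s, sorts exposures into 10
cardiac bins, reconstructs each bin with angular-spacing-weighted FBP, and
checks that the reconstructed blood-pool radius traces the programmed
contraction.
"""

import numpy as np

import cinegate as cg
from cinegate.phantom import bin_reconstructions, estimate_chamber_radius

ecg = cg.simulate_ecg(200.0, 0.143, 0.008, seed=3)
resp = cg.simulate_ventilated_respiration(200.0, 60.0, 0.4)
cardiac = ecg.trigger_train()

cfg = cg.GatingConfig(n_rotations=5, frame_rate=10.0)
log = cg.sort_phases(
    cg.retrospective_acquire(cardiac, resp, cfg, rotation_duration=36.0),
    cardiac, resp, cfg,
)
phantom = cg.DynamicPhantom(resp_amp=0.0)
sino = cg.acquire(phantom, log, cardiac, resp, n_detectors=128, grid=128, cfg=cfg)
print(f"acquired {len(sino)} projections over 5 rotations")

recons = bin_reconstructions(sino, n_bins=10, grid=128)
est = np.array([estimate_chamber_radius(recons[b], phantom) for b in range(10)])
true = np.array([phantom.inner_radius((b + 0.5) / 10) for b in range(10)])

print("bin  projections  programmed r  reconstructed r")
counts = sino.labels["cardiac_bin"].value_counts()
for b in range(10):
    print(f"{b:3d}  {counts[b]:11d}  {true[b]:12.3f}  {est[b]:15.3f}")
print(f"correlation programmed vs reconstructed: "
      f"{np.corrcoef(est, true)[0, 1]:.4f}")
# The radius shrinks into systole (bins 4-5) and re-expands: the per-bin
# reconstructions resolve the cardiac cycle despite irregular angles.
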