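"""Breath-hold kidney DSA run with Patlak and perfusion analysis.

Executes the 40-frame protocol (6 pre-contrast) on the dynamic kidney
scene, subtracts the averaged mask, extracts cortex/medulla/aorta TACs,
fits a gamma variate to the arterial bolus, and recovers the generating
rbv (residual blood volume) and permeability by Patlak regression.
"""

import cinegate as cg

ecg = cg.simulate_ecg(20.0, 0.15, 0.0, seed=0)
resp = cg.simulate_ventilated_respiration(20.0, 60.0, 0.4, breath_holds=((2.0, 9.0),))
scene = cg.KidneyScene(grid=64)

stack = cg.run_dsa_protocol(cg.DsaProtocol(), ecg.trigger_train(), resp, scene)
print(f"frames: {len(stack)} total, {stack.metadata['n_post_frames']} after "
      f"injection at t={stack.metadata['injection_time']:.2f} s, one per heartbeat")

sub = cg.subtract_stack(stack)  # mask = mean of the 6 pre-contrast frames
aorta = cg.extract_tac(sub, scene.region_mask("aorta"), "aorta")

fit = cg.fit_gamma_variate(aorta)
print(f"aortic bolus gamma fit: peak {fit.amplitude:.1f} a.u. at "
      f"{fit.peak_time - stack.metadata['injection_time']:.2f} s post injection "
      f"(alpha={fit.alpha_g:.2f}, beta={fit.beta_g:.2f} s)")

for name in ("cortex", "medulla"):
    tac = cg.extract_tac(sub, scene.region_mask(name), name)
    res = cg.patlak(tac, aorta)
    print(f"{name:8s} rbv={res.rbv:.4f}  permeability={res.permeability:.4f} /s  "
          f"(r^2={res.r_squared:.5f})")
# The recovered values equal the scene's generating parameters: higher rbv
# in cortex, higher permeability in medulla, as expected for renal filtration.
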