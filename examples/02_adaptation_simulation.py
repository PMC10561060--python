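"""Step response of the adaptation ODE with tethered-CheR kinetics.

Simulates attractant addition and removal for a Tar-only receptor whose
methylation rate follows the translated-Gaussian CheR density, and prints
the hallmarks of imprecise adaptation.
"""

import numpy as np

from cheradapt import kinetics, mwc, synth

truth = synth.default_tar_truth()
modifier = synth.make_tpm_modifier(truth)
m_pre = synth.steady_state_m(truth, 0.0)
a0 = mwc.activity(m_pre, 0.0, truth.mwc)

traj = kinetics.simulate_adaptation(
    [(0.0, 0.0), (200.0, 0.025), (1100.0, 0.0)],
    truth.mwc, truth.kin, m_init=m_pre, t_end=1400.0,
    rate_modifier=modifier)

a_star = np.mean(traj.a[(traj.t > 1000) & (traj.t < 1100)])
a_peak = np.max(traj.a[traj.t > 1100])
print(f"pre-stimulus activity a0      = {a0:.3f} (m = {m_pre:.2f})")
print(f"adapted activity a* (25 uM)   = {a_star:.3f}")
print(f"post-removal overshoot peak   = {a_peak:.3f}")
print(f"methylation range traversed   = {traj.m.min():.2f} .. "
      f"{traj.m.max():.2f}")
print("a* stays below a0 (imprecise adaptation): the tether suppresses "
      "kR as methylation moves the active sites away from the CheR peak.")
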