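"""Finite-absorption-time dosing: assimilation and clearance phases.

600 mg every 5 h, but each dose is only absorbable for 2 h (the finite
absorption time); afterwards the depot is depleted and the concentration
decays by elimination alone, producing a kink at every cutoff.
"""

import numpy as np

from multidose import PBFTPKRegimen, PKParameters, pbftpk_profile, pbftpk_state

params = PKParameters(ka=0.42, ke=0.4, gamma=0.00449)
regimen = PBFTPKRegimen.equidose(d=600, tau=5, sigma=2, n_doses=6)

for t in (0.0, 1.0, 2.0, 4.0, 5.0, 7.0):
    x, y, phase = pbftpk_state(params, regimen, t)
    print(f"t={t:4.1f} h  x={x:.4f} mg/mL  depot y={y:7.2f} mg  [{phase}]")

prof = pbftpk_profile(params, regimen, np.linspace(0, 30, 301))
frac = np.mean(prof.phase == "clearance")
print(f"\nfraction of time in the clearance phase: {frac:.0%}")
print(f"peak concentration over the schedule: {prof.x.max():.4f} mg/mL")

# During clearance the depot is exactly zero and x is log-linear with slope
# -ke; continuity holds at every dose instant and every cutoff.
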