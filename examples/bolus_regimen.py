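"""Repeated IV bolus dosing: equi-dose vs an irregular schedule.

Doses are concentration increments (mg/mL) delivered directly into the
central compartment, so the concentration jumps at every administration and
decays mono-exponentially (ke=0.3838/h) in between.
"""

import math

from multidose import DoseRegimen, bolus_concentration, make_equidose

ke = 0.3838
equi = make_equidose(600, 6, 6)
irregular = DoseRegimen((4, 4, 8, 4, 6, 4), (600, 600, 700, 500, 400, 300))

print("equi-dose 600 mg/mL every 6 h:")
for t in (0.0, 5.999, 6.0, 15.0):
    print(f"  x({t:6.3f} h) = {bolus_concentration(ke, equi, t):8.2f} mg/mL")

beta = math.exp(-ke * 6)
print(f"  trough limit delta*beta/(1-beta) = {600 * beta / (1 - beta):.2f} mg/mL")

print("irregular schedule (doses 600,600,700,500,400,300 at varying gaps):")
for t in (8.0, 16.0, 20.0, 30.0):
    print(f"  x({t:6.3f} h) = {bolus_concentration(ke, irregular, t):8.2f} mg/mL")

# The jump at each dose instant equals that dose; between doses log(x) falls
# linearly with slope -ke.
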