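"""Kinetic curves: GM vs WM difference signal and where it peaks.

Builds the single-compartment QUIPSS2 difference-signal model for
gray-matter-like and white-matter-like 7T parameters and prints the signal
at a few acquisition times plus the peak TI2.
"""

import numpy as np

from ossasl import KineticParams, delta_m, peak_ti2

gm = KineticParams(f=50.7, delta_t=0.70, tau=0.7, t1_tissue=1.9,
                   m0_blood=110.0)
wm = KineticParams(f=16.3, delta_t=0.89, tau=0.7, t1_tissue=1.4,
                   m0_blood=110.0)

times = np.array([0.8, 1.1, 1.4, 1.7, 2.0, 2.3])
print("TI2 (s)   dM_GM     dM_WM     ratio")
for t in times:
    a, b = delta_m(t, gm), delta_m(t, wm)
    print(f"{t:5.2f}  {a:8.4f}  {b:8.4f}  {a / b if b else float('nan'):6.2f}")

pg, pw = peak_ti2(gm, (0.8, 2.55)), peak_ti2(wm, (0.8, 2.55))
print(f"\npeak TI2: GM {pg:.2f} s, WM {pw:.2f} s")
print("The WM curve peaks later (longer arterial transit time) and is "
      "~3-4x weaker at its peak — the reason WM perfusion is hard to "
      "measure and benefits from tissue-specific sampling times.")
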