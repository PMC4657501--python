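"""The adaptive sampling loop: how the TI2 schedule evolves per tissue.

Runs a 4-block feedback loop for the GM and the (WM-GM) mask on the same
phantom and prints each block's schedule.  The first block is always the
evenly spaced default; later blocks are information-optimal for the pooled
CBF/ATT estimate of the masked voxels.
"""

import numpy as np

from ossasl import AcquisitionConfig, FitConfig, PhantomSpec, \
    make_phantom, run_feedback_loop, simulate_masks

acq, fit = AcquisitionConfig(), FitConfig()
phantom = make_phantom(PhantomSpec(), acq, fit)
masks = simulate_masks(phantom)

for name, t1_tissue in (("gm", fit.t1_gm), ("wm-gm", fit.t1_wm)):
    _, history = run_feedback_loop(
        phantom, masks[name], acq, fit, t1_tissue=t1_tissue,
        m0_blood=phantom.spec.m0_blood, n_blocks=4, seed=1)
    print(f"\n{name}-weighted loop:")
    for sched in history:
        print("  block %d: %s  (mean %.2f s)" %
              (sched.block_index, np.round(sched.ti2_values, 2),
               sched.ti2_values.mean()))

print("\nThe (WM-GM) schedules settle on later TI2 values than the GM "
      "ones: labelled blood arrives later in white matter, so the "
      "informative sampling window shifts right.")
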