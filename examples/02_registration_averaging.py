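"""Traditional enhancement: register, exclude poor fixation, average.

Runs the full Avg-k pipeline on a stack with real inter-frame motion and one
decorrelated (fixation-loss) frame, and reports image quality before/after.
"""

import numpy as np

from octenhance import acquire_frames, enhance_by_averaging, make_phantom, psnr, ssim

truth = make_phantom(128, 256, seed=3)
stack = acquire_frames(truth, n_frames=8, motion_scale=(4.0, 1.0),
                       p_fixation_loss=0.15, seed=5)

avg5, reg = enhance_by_averaging(stack, k=5)
single = stack.frames[reg.reference_index]

print(f"reference frame: {reg.reference_index} (strongest SNR)")
print(f"excluded frames: {sorted(reg.excluded)} "
      f"(true fixation losses: {sorted(truth.fixation_loss_frames)})")
print("per-frame NCC vs reference:",
      [f"{c:.2f}" for c in reg.correlations])
print(f"single frame : SSIM {ssim(single, truth.clean):.3f}  "
      f"PSNR {psnr(single, truth.clean):.2f} dB")
print(f"Avg-5        : SSIM {ssim(avg5, truth.clean):.3f}  "
      f"PSNR {psnr(avg5, truth.clean):.2f} dB")
print("Registration + averaging suppresses speckle roughly as 1/sqrt(k); "
      "the 70% correlation rule removed the decorrelated frame.")
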