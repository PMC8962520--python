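"""Image quality versus number of averaged frames.

Reproduces the qualitative frame-count relationship: SSIM/PSNR rise with k,
steepest below k = 5, with diminishing returns after.
"""

from octenhance.experiments import SweepConfig, run_sweep, sweep_to_frame

results = run_sweep(
    k_values=[1, 2, 3, 5, 8, 12],
    n_phantoms=8,
    methods=("averaging",),
    config=SweepConfig(n_frames=12),
    seed=0,
)
frame = sweep_to_frame(results)
print(frame[["method", "k", "mean_ssim", "sd_ssim", "mean_psnr", "sd_psnr"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("Most of the quality gain arrives in the first five frames — the "
      "reason the clinical comparison focuses on k = 5.")
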