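"""Train a small landmark-detection network on synthetic cephalograms.

Uses a single-stack, width-32 hourglass on 32 px images so it runs in
about a minute on a laptop CPU. Prints the per-epoch validation metrics:
the localization error (px), keypoint AP and the A/N ratio error, which
fall as training progresses.
"""

import numpy as np

from adenoceph import (LossConfig, ModelConfig, SynthConfig, TrainConfig,
                       build_model, generate_dataset, train)

scfg = SynthConfig.scaled(32, seed=0)
train_set = generate_dataset(scfg, 60, rng=np.random.default_rng(0))
val_set = generate_dataset(scfg, 20, rng=np.random.default_rng(1))

model = build_model(ModelConfig(input_size=32, heatmap_size=8, n_stacks=1,
                                hourglass_depth=1, width=32), seed=0)
tcfg = TrainConfig(epochs=5, warmup_lr=0.02, warmup_epochs=2, seed=0)

result = train(model, train_set, val_set, tcfg, LossConfig(),
               log_fn=lambda h: print(
                   f"epoch {h['epoch']}: loss={h['train_loss']:.3f} "
                   f"val_loc={h['val_localization']:.2f}px "
                   f"val_AP={h['val_ap']:.3f} "
                   f"val_AN_err={h['val_an_error']:.3f}"))
print(f"best epoch by validation A/N error: {result.best_epoch}")
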