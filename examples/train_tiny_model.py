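"""Overfit a tiny network on 8 synthetic angiograms (desk-scale training).

Runs the full training loop — snake-convolution U-net, Dice-Focal loss,
Adam — on 128x128 synthetic images until the training-set Dice reaches
0.85 or 200 optimizer steps have been spent (several minutes on a CPU).
"""

from snakeseg import NetworkConfig
from snakeseg.pipeline import TrainConfig, save_checkpoint, train
from snakeseg.synthetic import generate_dataset, scaled_specs

tree, rend = scaled_specs(128)
data = [s.as_sample(f"s{i}") for i, s in enumerate(
    generate_dataset(8, seed=7, tree_spec=tree, render_spec=rend))]

cfg = TrainConfig(epochs=100, early_stop_patience=100, batch_size=4, crop=128,
                  seed=3, max_steps=200, val_interval=5, target_val_dice=0.85)
result = train(data, data, cfg, NetworkConfig(base_width=8))

print(f"epochs run: {len(result.history)}")
print(f"best training-set Dice: {result.best_val_dice:.4f}")
save_checkpoint(result.model, "scratch/tiny_model.npz")
print("Dice near 1 means the model reproduces its training masks almost")
print("pixel-perfectly - the expected outcome of a deliberate overfit, which")
print("verifies that every part of the architecture can learn.")
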