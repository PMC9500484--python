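"""Render the standard figures after a short learning run.

Writes four PNGs to ./figures: the recognition bar chart, the weight mosaic
(each tile is one neuron's input weights: its 'memory content'), the label
map, and the activation heatmaps for one stimulus.
"""
from pathlib import Path

from ca1sim import CA1Model, gen_digit_like, run_catastrophic_forgetting, scaled_params
from ca1sim.reporting import (
    activation_heatmaps, label_map, recognition_bars, weight_mosaic,
)

out = Path("figures")
out.mkdir(exist_ok=True)
params = scaled_params(side=20, i_side=7)
stimuli = gen_digit_like(seed=11, classes=4, per_class=2, size=20)

model = CA1Model(params, seed=0)
for task in stimuli.tasks:
    for image in task:
        model.learn(image.values, task_id=image.task_id, image_id=image.id)

result = run_catastrophic_forgetting(params, stimuli, permutations=2, seed=5)
recognition_bars(result, out / "recognition.png", title="per-task recognition")
weight_mosaic(model, out / "weight_mosaic.png")
label_map(model, out / "label_map.png")
activation_heatmaps(model, stimuli.tasks[0][0].values, out / "activations.png")
print(f"wrote 4 figures to {out}/")
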