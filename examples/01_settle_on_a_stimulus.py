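"""Build a small CA1 network, present one image, and inspect the response.

The network is a self-organizing map of rate neurons: presenting a stimulus
drives a localized population of pyramidal cells; the most active cell (the
peak neuron) is the stimulus's map position.  Dopamine (da) = 1 signals that
nothing on the map is familiar yet.
"""
import numpy as np

from ca1sim import CA1Model, gen_digit_like, scaled_params

params = scaled_params(side=20, i_side=7)   # 400 pyramidal cells, 49 interneurons
stimuli = gen_digit_like(seed=1, classes=3, per_class=2, size=20)
model = CA1Model(params, seed=0)

image = stimuli.tasks[0][0]
report = model.settle(image.values)
row, col = divmod(report.peak_neuron, params.geometry.p_cols)

print(f"stimulus {image.id}: peak neuron {report.peak_neuron} at map position ({row}, {col})")
print(f"peak activation {report.peak_activation:.3f}, dopamine {report.da}, "
      f"{report.steps} settling steps")
print("dopamine 1 = the network saw nothing familiar: the image is novel")
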