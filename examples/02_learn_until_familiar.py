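"""One learning episode: novelty-gated plasticity until dopamine stops it.

A novel image keeps dopamine on, which lets the winning population's input
weights move toward the image (Hebbian, Oja-style).  As the weights align,
the winners' activation grows; when the strongest cell crosses the subiculum
threshold, the novelty circuit shuts dopamine off and learning stops: the
image has become familiar.
"""
from ca1sim import CA1Model, gen_digit_like, scaled_params

params = scaled_params(side=20, i_side=7)
stimuli = gen_digit_like(seed=1, classes=1, per_class=1, size=20)
model = CA1Model(params, seed=0)
image = stimuli.tasks[0][0]

episode = model.learn(image.values, task_id=0, image_id=image.id)
print(f"first presentation: {episode.steps} plasticity steps, "
      f"{episode.n_updated} neurons updated, ended familiar: {episode.learned}")

again = model.learn(image.values, task_id=0, image_id=image.id)
print(f"re-presentation:    {again.steps} steps, {again.n_updated} updated, "
      f"dopamine at onset {again.da_at_presentation}")
print("zero updates on re-presentation = the dopamine gate now blocks plasticity")
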