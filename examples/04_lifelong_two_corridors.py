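"""The lifelong two-corridor experiment.

An agent alternates between two corridors of textured images, repeating each
corridor until a full pass raises no novelty signal (an epoch), then moving
to the other.  Learning effort is measured in episodes per epoch; map quality
in how many distinct neurons encode the images and how stable corridor 1's
winners are when the agent returns to it.
"""
from ca1sim import GeometryParams, gen_corridor_pair, lifelong_protocol_params, run_lifelong

params = lifelong_protocol_params(GeometryParams(
    p_rows=20, p_cols=20, i_rows=7, i_cols=7, input_rows=20, input_cols=20))
pair = gen_corridor_pair(seed=27, n=8, size=20,
                         luminances=(-0.20, -0.22), contrasts=(0.40, 0.38))

result = run_lifelong(params, pair.tasks[0], pair.tasks[1], seed=7, max_epochs=12)
print("episodes per epoch:", result.episodes_per_epoch)
print(f"terminated novelty-free: {result.terminal_novelty_free}")
print(f"distinct winner neurons over all {sum(len(t) for t in pair.tasks)} images: "
      f"{result.distinct_peaks}")
print(f"corridor-1 winners unchanged at first revisit: {result.stability_count()}")
print("a trailing pair of zero-episode epochs means both corridors are fully recognized")
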