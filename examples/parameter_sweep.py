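"""How the dynamic parameters shape sampling behavior.

Replays a fixed stimulus set while moving one parameter at a time:
a more negative last-trial carryover (beta_last_draw) damps inter-trial
variation in sample counts, and more uniform evidence weighting
(alpha_decay -> 1) lowers sample counts where evidence accumulates
freely (zero cost, high evidence).
"""

from beadtask import default_group_level, get_model, sweep_parameter

model = get_model("cost_evidence")
base = dict(default_group_level("NT").means)
base["alpha_decay"] = 0.9

sweep = sweep_parameter(base, model, "beta_last_draw", [-0.4, -0.2, 0.0],
                        n_trials_per_condition=300, seed=2)
print("beta_last_draw vs inter-trial sampling variation (mean over conditions):")
print(sweep.groupby("value")["sampling_variation"].mean().round(3))

sweep = sweep_parameter(base, model, "alpha_decay", [0.1, 0.5, 0.95],
                        n_trials_per_condition=300, seed=2)
cell = sweep[(sweep.cost_level == "zero") & (sweep.evidence_level == "high")]
print("\nalpha_decay vs mean samples (zero cost, high evidence):")
print(cell.set_index("value")["mean_samples"].round(2))
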