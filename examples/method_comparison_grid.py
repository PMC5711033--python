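"""A scaled-down method-comparison experiment.

Runs both direction-inference methods over a small grid of exposure
measurement-error levels (causal model, n = 5000) and prints the rate of
correct-direction calls, wrong-direction calls and no-calls per cell,
together with the population d statistic that stratifies the full study.
"""

import causaldir as cd

cells = [
    cd.SimulationConfig(n=5000, var_gx=0.1, var_xy=0.8, sigma2_mx=s2)
    for s2 in (0.0, 0.4, 1.0)
]
summary = cd.run_grid(cells, reps=20, methods=("mr_steiger", "cit"), seed=3,
                      n_null=300)

cols = ["method", "sigma2_mx", "d_population", "rate_correct", "rate_wrong",
        "rate_no_call"]
print(summary[cols].round(3).to_string(index=False))
print()
print("Rows with d < 0 are the regime where enough exposure noise makes the")
print("wrong direction look genetically proximal; both methods then start")
print("calling the reverse model, and larger samples only add confidence.")
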