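"""One-sample analysis: MR + Steiger versus the mediation-based CIT.

Simulates individual-level data where an exposure causes an outcome, first
with clean measurements and then with heavy noise on the exposure, and runs
both direction-inference procedures on each dataset.  The mediation-based
test flips to the wrong direction under exposure noise; the MR Steiger call
is more resilient until the population d statistic goes negative.
"""

import numpy as np

import causaldir as cd


def analyse(label, ds):
    obs = cd.correlations_from_individual(ds.g, ds.x_o, ds.y_o)
    steiger = cd.steiger_one_sample(obs)
    mr = cd.tsls(ds.g, ds.x_o, ds.y_o)
    call = cd.infer_direction(mr.p_mr, steiger, alpha=0.05)
    cit = cd.cit_bidirectional(ds.g, ds.x_o, ds.y_o, alpha=0.05, n_null=500,
                               seed=1)
    d = cd.population_d(ds.config)
    print(f"--- {label} (population d = {d:+.3f}) ---")
    print(f"MR Steiger: Z = {steiger.z_stat:+.2f}, p_MR = {mr.p_mr:.2g} "
          f"-> {call.outcome}")
    print(f"CIT: p(x->y) = {cit.p_forward:.3g}, p(y->x) = {cit.p_reverse:.3g} "
          f"-> {cit.outcome_code}")


rng = np.random.default_rng(42)
clean = cd.simulate_causal(
    cd.SimulationConfig(n=10000, var_gx=0.1, var_xy=0.8), rng
)
noisy = cd.simulate_causal(
    cd.SimulationConfig(n=10000, var_gx=0.1, var_xy=0.8, sigma2_mx=1.0), rng
)
analyse("clean measurements", clean)
analyse("noisy exposure (sigma2_mx = 1)", noisy)
print()
print("The true model is exposure -> outcome in both cases; only the")
print("measurement quality differs.  Negative d marks the regime where")
print("direction inference from observed correlations becomes unreliable.")
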