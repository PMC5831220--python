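"""How P_DEG depends on the number of replicates while AS does not.

Simulates a 20%-DEG dataset with 12 replicates per group, then bootstraps
n_rep = 3 and 6 replicates per group (10 iterations each, sampling
without replacement) and prints the per-level means. P_DEG and AUC climb
with replicates — more power — while AS, which measures the data's group
separation rather than the test's power, stays flat.
"""

from groupsil import (
    SimulationConfig,
    SweepConfig,
    run_sweep,
    simulate_counts,
    slope_as_vs_nrep,
)

ds = simulate_counts(SimulationConfig(n_genes=1500, p_deg=0.20,
                                      n_rep_A=12, n_rep_B=12, seed=3))
res = run_sweep(ds, SweepConfig(n_rep_grid=[3, 6], n_iterations=10,
                                fdr=0.10, seed=5))
print(res.summary().to_string(index=False))
print(f"AS-vs-n_rep slope = {slope_as_vs_nrep(res):+.5f} per replicate "
      "(near zero: AS does not depend on replication)")
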