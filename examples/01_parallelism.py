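"""Cross-line expression parallelism against an exact combinatorial null.

Simulates a fold-change/q-value table for 11 evolved lines in which half of
each line's ~270 true DEGs come from a shared pool, calls DEGs at q <= 0.01,
and asks whether genes are significant in the same direction in more lines
than expected if every line hit random genes.
"""

import evoexpr as ev
from evoexpr.simulate import SimConfig, simulate_fold_change_table

cfg = SimConfig(n_genes=4131, n_lines=11, deg_per_line=270, shared_fraction=0.5, seed=42)
fc, truth = simulate_fold_change_table(cfg)

deg = ev.call_degs(fc, q_threshold=0.01)
profile = ev.observed_parallelism(fc, deg, method="sinib_independent")
test = ev.parallelism_ks_test(profile, rng=42)

print("up/down DEG counts per line:")
for line in deg.lines[:3]:
    print(f"  {line}: u={deg.u(line)}, d={deg.d(line)}")
print("  ...")

print("\ngenes significant in the same direction in x lines (observed vs expected):")
print(profile.to_frame().to_string(index=False))

print(f"\nKS test observed vs expected: D={test['statistic']:.3f}, p={test['pvalue']:.2g}")
print(
    "A small p-value means genes repeat across lines far more often than the\n"
    "null (independent per-line hits with the observed up/down rates) allows."
)
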