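"""Demographic backdrop of an expansion: betaST, Weir-Cockerham FST, the
FST-based population tree, and regressions of diversity on distance.
"""

import numpy as np

from surfload import popgen_stats
from surfload.pipeline import bundle_from_simulation
from surfload.simulate import ExpansionConfig, simulate_expansion
from surfload.spatial_models import fit_linear

ds = simulate_expansion(ExpansionConfig(seed=5))
b = bundle_from_simulation(ds)

beta = popgen_stats.beta_st(b.gm, b.popmap).sort_index()
print("betaST per deme (negative = closest to the ancestral gene pool):")
print(beta.round(3).to_string())
print(f"-> inferred source: {beta.idxmin()}")

fst = popgen_stats.wc_fst(b.gm, b.popmap)
print(f"\nmax pairwise Weir-Cockerham FST: {np.nanmax(fst.to_numpy()):.3f}")

tree = popgen_stats.fst_tree(fst, beta=beta)
print("root-to-tip distances (expansion order should rank them):")
print(tree.root_distance.sort_index().round(3).to_string())

metrics = b.popmap.covariates.copy()
metrics["ho"] = popgen_stats.observed_heterozygosity(b.gm, b.popmap)
r = fit_linear(metrics, "ho", "distance_south")
print(f"\nHo ~ distance: slope {r.slope:.2e} per km, "
      f"adjusted R^2 = {r.r_squared_adj:.2f}, p = {r.p_value:.2e}")
print("A negative slope quantifies the loss of diversity along the expansion.")
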