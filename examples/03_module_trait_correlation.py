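"""Correlate module eigengenes with diel physiology traits.

Builds the WW network, then correlates each module eigengene with the
per-timepoint means of net CO2 assimilation (A), stomatal conductance
(g_s), PSII efficiency (Fv'/Fm') and non-structural carbohydrates (NSC),
and checks the gene-significance vs module-membership coupling that marks
physiologically relevant hub genes.
"""

import dielnet as dn

config = dn.SimulationConfig(seed=3)
ww, drought, traits, truth = dn.simulate_experiment(config)

filtered, _ = dn.filter_low_expression(ww)
logged = dn.log_transform(filtered)
tom = dn.topological_overlap(dn.signed_adjacency(logged))
modules, _ = dn.detect_modules(tom)
merged = dn.merge_close_modules(logged, modules)
eigengenes = dn.module_eigengenes(logged, merged)

traits_ww = [t for t in traits if t.condition == "WW"]
r, p = dn.module_trait_correlation(eigengenes, traits_ww)
print("module x trait Pearson r:")
print(r.round(2))
print("\nmodule x trait p-values:")
print(p.round(4))

# WUE = A / g_s per replicate record
a = next(t for t in traits_ww if t.trait == "A")
gs = next(t for t in traits_ww if t.trait == "gs")
wue = dn.compute_wue(a, gs)
print(f"\nWUE per-ZT means (A/g_s):\n{wue.summary()['mean'].round(4)}")

# GS vs MM for the module most correlated with g_s
best = r["gs"].abs().idxmax()
mm, _ = dn.module_membership(logged, eigengenes)
gs_vec = dn.gene_significance(logged, gs)
r_gm, p_gm = dn.gs_mm_correlation(gs_vec, mm, best, merged)
print(f"\nGS-MM correlation in module {best} (vs g_s): r={r_gm:.2f}, p={p_gm:.2g}")

# Interpretation: a module whose eigengene tracks a trait (|r| near 1) is a
# candidate regulator of that physiology; a positive GS-MM correlation says
# the module's hub genes are also the genes most correlated with the trait.
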