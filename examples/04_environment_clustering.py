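"""Cluster trial environments by correlated line performance.

Builds the line x environment mean table, runs the GGE decomposition
(SVD of the environment-centered table) and groups environments by
average-linkage clustering on 1 - r.  Groups can feed subset_trials to
estimate genetic values per mega-environment.
"""

from gsfoundry import envclust, pheno, simulate

cfg = simulate.trait_config("YLD", n_lines=200, n_markers=100, n_qtl=40,
                            n_locations=6, n_years=2, reps_range=(1, 2),
                            presence_fraction=0.6, seed=4)
_, truth = simulate.simulate_genotypes(cfg)
trial = simulate.simulate_trial(cfg, truth)

tw = envclust.build_two_way(trial, "YLD")
gge = envclust.gge_decompose(tw)
clusters = envclust.cluster_environments(gge, n_groups=3)

print(f"environments: {len(tw.environments)}, "
      f"masked cells: {tw.n_masked}")
print("GGE axes 1-2 explain "
      f"{100 * gge.explained_fraction[:2].sum():.0f}% of G+GE variance")
for g, members in clusters.groups.items():
    print(f"  group {g}: {members}")

sub = pheno.subset_trials(trial, clusters.groups[1])
print(f"group 1 subset: {len(sub)} records -> per-group genetic values")
# Environments in one group rank lines similarly; fitting genetic values
# per group targets predictions to that mega-environment.
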