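"""Generate a synthetic breeding program: genotypes, trials, gene calls.

Builds a 200-line desk-scale program (3 locations x 2 years, 1-2 reps,
two major genes) and prints what the generator produced.  The printed
heritability inputs are the plot-level variance components the trial
model will later try to recover.
"""

from gsfoundry import simulate

cfg = simulate.demo_config(seed=1)
geno, truth = simulate.simulate_genotypes(cfg)
trial = simulate.simulate_trial(cfg, truth)
calls, trial = simulate.simulate_major_genes(cfg, trial)

print(f"lines: {geno.n_lines}, markers: {geno.n_markers}")
print(f"mean marker heterozygosity: {geno.het_rate().mean():.3f} "
      "(advanced inbred lines)")
print(f"trial records: {len(trial)} across "
      f"{trial['env'].nunique()} location-years")
print(f"true breeding-value sd: {truth.true_breeding_values.std():.0f} kg/ha "
      f"(configured var_G = {cfg.var_G:.0f})")
print("gene-call states:",
      calls.groupby('gene')['call'].value_counts().to_dict())
# Each line's phenotype = mu + its QTL-derived breeding value + environment,
# replicate, GxE and plot noise; the calls table intentionally contains
# heterozygous/null/failed entries to exercise downstream filtering.
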