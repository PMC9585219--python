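import numpy as np
import pandas as pd
import pytest

from gsfoundry import simulate, genotype


def make_oneway_trial(n_lines=6, n_reps=4, var_G=4.0, var_e=1.0, mu=10.0,
                      seed=0, trait="YLD"):
    """Balanced one-way design: g lines x n reps in a single environment."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(var_G), n_lines)
    rows = []
    for i in range(n_lines):
        for k in range(n_reps):
            rows.append({
                "line_id": f"L{i:02d}", "location": "X", "year": "2020",
                "rep": k + 1, "trait": trait,
                "value": mu + g[i] + rng.normal(0, np.sqrt(var_e)),
            })
    return pd.DataFrame(rows)


def anova_oneway(trial, trait="YLD"):
    """Closed-form balanced one-way ANOVA variance-component estimators."""
    d = trial[trial["trait"] == trait]
    means = d.groupby("line_id")["value"].mean()
    n = d.groupby("line_id").size().iloc[0]
    g = len(means)
    grand = d["value"].mean()
    ms_g = n * ((means - grand) ** 2).sum() / (g - 1)
    ss_e = ((d["value"] - means.reindex(d["line_id"]).to_numpy()) ** 2).sum()
    ms_e = ss_e / (g * (n - 1))
    return max(0.0, (ms_g - ms_e) / n), ms_e


@pytest.fixture(scope="session")
def small_panel():
    """120-line, 300-marker genotype panel with structure, imputed."""
    cfg = simulate.SimulationConfig(
        n_lines=120, n_markers=300, n_qtl=40, n_locations=3, n_years=2,
        reps_range=(1, 2), presence_fraction=0.8, seed=42,
    )
    m, truth = simulate.simulate_genotypes(cfg)
    m, _ = genotype.filter_markers(m)      # drop monomorphic markers
    return genotype.impute_missing(m), truth, cfg


@pytest.fixture(scope="session")
def small_trial(small_panel):
    m, truth, cfg = small_panel
    return simulate.simulate_trial(cfg, truth)
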