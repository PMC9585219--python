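"""Synthetic breeding-program data generator.

Emulates the statistical structure of a historical multi-institutional
small-grains testing network: ~10^3 advanced lines evaluated across many
location-year environments with 1-3 replicates and severe unbalance, ~10^4
biallelic SNPs with mild two-subpopulation structure, an additive polygenic
trait architecture, genotype-by-environment variance, and major
presence/absence genes whose yield effect depends on the testing region.

Trait observations are generated from the same model the analysis fits,

    Y_ijk = mu + g_i + E_j + R_k(j) + GE_ij + e_ijk,

with g_i a genomic (QTL-derived) breeding value and all other effects drawn
from centered normals at configured variances.  The generator therefore
doubles as the ground truth for parameter-recovery and heritability tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gsfoundry.genotype import MarkerMatrix

__all__ = [
    "MajorGene",
    "SimulationConfig",
    "TruthRecord",
    "TRAIT_PRESETS",
    "simulate_genotypes",
    "simulate_trial",
    "simulate_major_genes",
    "trait_config",
    "demo_config",
]

# Trait-level presets on their customary scales.  Broad-sense line-mean
# heritabilities follow the winter-wheat regime this package targets
# (yield 0.56, test weight 0.74, heading date 0.85, plant height 0.83);
# the G:GE variance ratio shrinks as heritability rises, reflecting that
# phenology and stature traits show far less genotype-by-environment
# interaction than yield.
TRAIT_PRESETS: dict[str, dict] = {
    "YLD": dict(mu=4500.0, var_G=62_500.0, var_E=360_000.0,
                var_R=10_000.0, var_GE=62_500.0, target_h2=0.56),
    "TW": dict(mu=74.0, var_G=1.0, var_E=4.0, var_R=0.1, var_GE=0.5,
               target_h2=0.74),                       # kg/hl
    "HD": dict(mu=102.0, var_G=9.0, var_E=25.0, var_R=0.5, var_GE=1.2,
               target_h2=0.85),                       # Julian days
    "PH": dict(mu=86.0, var_G=16.0, var_E=36.0, var_R=1.0, var_GE=3.0,
               target_h2=0.83),                       # cm
}

# Divergence (Balding-Nichols F) calibrated so that at 1,000 lines x 5,000
# markers with near-complete inbreeding, PC1 of the centered genotype
# matrix explains about 10% of the variance, emulating a two-subpopulation
# panel split by a major translocation.  See docs/methods.md.
DEFAULT_DIVERGENCE = 0.18


@dataclass
class MajorGene:
    """A presence/absence locus with a region-dependent additive effect."""

    name: str
    carrier_frequency: float
    region_effects: dict[str, float]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic breeding program.

    Defaults mirror a yield-like trait (kg/ha) in a cooperative testing
    network: ~1,000 lines, 19 locations x 14 years, 1-3 replicates, each
    line observed in a small fraction of location-years.
    """

    n_lines: int = 1000
    n_markers: int = 10_000
    n_qtl: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 2
    subpop_divergence: float = DEFAULT_DIVERGENCE
    inbreeding: float = 0.95     # advanced selfed lines are near-homozygous
    n_locations: int = 19
    n_years: int = 14
    reps_range: tuple[int, int] = (1, 3)
    presence_fraction: float = 0.035
    mu: float = 4500.0
    var_G: float = 62_500.0      # sd 250 kg/ha among line genetic values
    var_E: float = 360_000.0     # environments dominate (sd 600)
    var_R: float = 10_000.0
    var_GE: float = 62_500.0
    var_eps: float = 160_000.0
    target_h2: float | None = None
    major_genes: list[MajorGene] = field(default_factory=list)
    region_map: dict[str, str] = field(default_factory=dict)
    call_noise_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0 <= self.subpop_divergence < 1):
            raise ValueError("subpop_divergence must be in [0, 1)")
        if not (0 <= self.inbreeding <= 1):
            raise ValueError("inbreeding must be in [0, 1]")
        for v in (self.var_G, self.var_E, self.var_R, self.var_GE, self.var_eps):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        if not (0 < self.presence_fraction <= 1):
            raise ValueError("presence_fraction must be in (0, 1]")
        lo, hi = self.reps_range
        if not (1 <= lo <= hi <= 3):
            raise ValueError("reps_range must be an integer pair within [1, 3]")
        if self.target_h2 is not None and not (0 < self.target_h2 < 1):
            raise ValueError("target_h2 must be in (0, 1)")

    @property
    def locations(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_locations)]

    @property
    def years(self) -> list[str]:
        return [f"{2008 + i}" for i in range(self.n_years)]

    @property
    def line_ids(self) -> list[str]:
        return [f"LN{i + 1:04d}" for i in range(self.n_lines)]

    def residual_variance(self) -> float:
        """var_eps, derived from ``target_h2`` when that is set.

        ``target_h2`` is a line-mean heritability for the balanced reference
        design (every line in every environment, mean replicate count K):

            h2 = var_G / (var_G + var_GE / J + var_eps / (J K))

        with J = n_locations * n_years environments, so

            var_eps = J K var_G (1 - h2) / h2  -  K var_GE.
        """
        if self.target_h2 is None:
            return self.var_eps
        J = self.n_locations * self.n_years
        K = float(np.mean(self.reps_range))
        v = J * K * self.var_G * (1 - self.target_h2) / self.target_h2 \
            - K * self.var_GE
        if v < 0:
            raise ValueError(
                f"target_h2={self.target_h2} unreachable: genotype-by-"
                "environment variance alone already exceeds the implied "
                "line-mean error variance; lower var_GE or target_h2"
            )
        return v


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel, for parameter-recovery tests."""

    true_breeding_values: pd.Series      # line_id -> genetic value
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    subpop_labels: pd.Series             # line_id -> subpopulation index


def simulate_genotypes(config: SimulationConfig) -> tuple[MarkerMatrix, TruthRecord]:
    """Draw a biallelic SNP panel with mild subpopulation structure.

    Per-marker ancestral frequencies are uniform on ``maf_range``;
    subpopulation frequencies follow a Balding-Nichols beta around the
    ancestral frequency with divergence parameter F =
    ``subpop_divergence``.  Within subpopulation, genotypes follow
    inbreeding-adjusted Hardy-Weinberg proportions: with probability
    ``inbreeding`` a locus is autozygous (homozygous draw at the allele
    frequency), otherwise a standard HW draw — matching advanced selfed
    breeding lines whose residual heterozygosity is a few percent.  True
    breeding values come from ``n_qtl`` randomly chosen markers with
    normal effects rescaled so the realized variance of breeding values
    equals ``var_G`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_lines, config.n_markers
    lo, hi = config.maf_range
    p0 = rng.uniform(lo, hi, p)
    F = config.subpop_divergence
    subpop = np.arange(n) % config.n_subpops
    if F > 0:
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        freqs = rng.beta(a[None, :], b[None, :],
                         size=(config.n_subpops, p))
    else:
        freqs = np.tile(p0, (config.n_subpops, 1))
    pf = freqs[subpop, :]
    autozygous = rng.random((n, p)) < config.inbreeding
    hom_draw = 2.0 * rng.binomial(1, pf)
    hw_draw = rng.binomial(2, pf).astype(float)
    codes = np.where(autozygous, hom_draw, hw_draw)

    line_ids = np.array(config.line_ids)
    marker_ids = np.array([f"S{j + 1:05d}" for j in range(p)])
    chrom = np.array([f"{1 + (j % 21)}" for j in range(p)])
    pos = np.arange(1, p + 1) * 1000
    letters = np.array(["A", "C", "G", "T"])
    pair = rng.integers(0, 4, size=(p, 2))
    pair[:, 1] = (pair[:, 0] + 1 + pair[:, 1] % 3) % 4
    alleles = np.stack([letters[pair[:, 0]], letters[pair[:, 1]]], axis=1)

    m = MarkerMatrix(
        line_ids=line_ids,
        marker_ids=marker_ids,
        codes=codes,
        chrom=chrom,
        pos=pos,
        alleles=alleles,
    )

    n_qtl = min(config.n_qtl, p)
    qtl_idx = np.sort(rng.choice(p, size=n_qtl, replace=False))
    eff = rng.normal(0, 1, n_qtl)
    Wq = codes[:, qtl_idx] - codes[:, qtl_idx].mean(axis=0)
    tbv = Wq @ eff
    sd = tbv.std()
    if config.var_G > 0 and sd > 0:
        scale = np.sqrt(config.var_G) / sd
    else:
        scale = 0.0
    eff *= scale
    tbv = Wq @ eff
    truth = TruthRecord(
        true_breeding_values=pd.Series(tbv, index=line_ids),
        qtl_indices=qtl_idx,
        qtl_effects=eff,
        subpop_labels=pd.Series(subpop, index=line_ids),
    )
    return m, truth


def simulate_trial(
    config: SimulationConfig,
    truth: TruthRecord,
    trait: str = "YLD",
) -> pd.DataFrame:
    """Generate a long-format multi-environment trial table.

    Columns: line_id, location, year, env, rep, trait, value.  Each
    line x location-year cell is observed with probability
    ``presence_fraction`` (completely at random); replicate counts are
    drawn per location-year from ``reps_range``.
    """
    if config.presence_fraction * config.n_locations * config.n_years < 2:
        warnings.warn(
            "fewer than 2 expected observations per line; genetic values "
            "will be poorly estimable",
            UserWarning,
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    locs, years = config.locations, config.years
    envs = [(l, y) for l in locs for y in years]
    J = len(envs)
    n = config.n_lines
    line_ids = np.array(config.line_ids)
    tbv = truth.true_breeding_values.reindex(line_ids).to_numpy()

    var_eps = config.residual_variance()
    E = rng.normal(0, np.sqrt(config.var_E), J)
    reps_per_env = rng.integers(config.reps_range[0],
                                config.reps_range[1] + 1, J)
    GE = rng.normal(0, np.sqrt(config.var_GE), (n, J))
    present = rng.random((n, J)) < config.presence_fraction

    rows_line, rows_env, rows_rep, values = [], [], [], []
    for j, (loc, yr) in enumerate(envs):
        li = np.flatnonzero(present[:, j])
        if li.size == 0:
            continue
        K = int(reps_per_env[j])
        R = rng.normal(0, np.sqrt(config.var_R), K)
        for k in range(K):
            eps = rng.normal(0, np.sqrt(var_eps), li.size)
            values.append(config.mu + tbv[li] + E[j] + R[k]
                          + GE[li, j] + eps)
            rows_line.append(li)
            rows_env.append(np.full(li.size, j))
            rows_rep.append(np.full(li.size, k + 1))

    if not values:
        raise ValueError("no observations generated; raise presence_fraction")
    li = np.concatenate(rows_line)
    ej = np.concatenate(rows_env)
    rk = np.concatenate(rows_rep)
    vals = np.concatenate(values)
    loc_arr = np.array([envs[j][0] for j in ej])
    yr_arr = np.array([envs[j][1] for j in ej])
    t = pd.DataFrame({
        "line_id": line_ids[li],
        "location": loc_arr,
        "year": yr_arr,
        "env": [f"{a}_{b}" for a, b in zip(loc_arr, yr_arr)],
        "rep": rk,
        "trait": trait,
        "value": vals,
    })
    unseen = sorted(set(line_ids) - set(t["line_id"]))
    if unseen:
        warnings.warn(
            f"{len(unseen)} line(s) drew zero observations: "
            f"{unseen[:10]}{'...' if len(unseen) > 10 else ''}",
            UserWarning,
        )
    return t


def simulate_major_genes(
    config: SimulationConfig,
    trial: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign major-gene carriers and add their region-dependent effects.

    Returns ``(gene_calls, modified_trial)``.  ``gene_calls`` is long
    format (line_id, gene, call) where a fraction ``call_noise_fraction``
    of true present/absent states is masked as heterozygous/null/failed to
    exercise downstream call filtering.  Carrier observations get the
    gene's additive effect for the region of the observation's location.
    """
    if not config.major_genes:
        return pd.DataFrame(columns=["line_id", "gene", "call"]), trial.copy()
    regions = config.region_map
    for g in config.major_genes:
        missing = set(g.region_effects) - set(regions.values())
        if missing:
            raise ValueError(
                f"gene {g.name}: effect given for unknown region(s) {sorted(missing)}"
            )
    if not set(trial["location"]) <= set(regions):
        unmapped = sorted(set(trial["location"]) - set(regions))
        raise ValueError(f"locations without a region: {unmapped}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    line_ids = np.array(config.line_ids)
    trial = trial.copy()
    obs_region = trial["location"].map(regions)
    line_pos = pd.Series(np.arange(len(line_ids)), index=line_ids)
    obs_line = line_pos.reindex(trial["line_id"]).to_numpy()

    calls_rows = []
    for g in config.major_genes:
        carrier = rng.random(len(line_ids)) < g.carrier_frequency
        effect = obs_region.map(
            lambda r: g.region_effects.get(r, 0.0)
        ).to_numpy(dtype=float)
        trial["value"] = trial["value"] + np.where(
            carrier[obs_line], effect, 0.0
        )
        call = np.where(carrier, "present", "absent").astype(object)
        noisy = rng.random(len(line_ids)) < config.call_noise_fraction
        call[noisy] = rng.choice(
            ["heterozygous", "null", "failed"], size=int(noisy.sum())
        )
        calls_rows.append(pd.DataFrame({
            "line_id": line_ids, "gene": g.name, "call": call,
        }))
    calls = pd.concat(calls_rows, ignore_index=True)
    return calls, trial


def trait_config(trait: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Config preset for one of the four standard traits (YLD/TW/HD/PH)."""
    if trait not in TRAIT_PRESETS:
        raise KeyError(f"no preset for trait {trait!r}; "
                       f"choose from {sorted(TRAIT_PRESETS)}")
    kwargs = dict(TRAIT_PRESETS[trait])
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A desk-scale configuration: 200 lines, 1,000 markers, 6 environments."""
    region_map = {"L01": "1", "L02": "2", "L03": "3"}
    defaults = dict(
        n_lines=200,
        n_markers=1000,
        n_qtl=50,
        n_locations=3,
        n_years=2,
        reps_range=(1, 2),
        presence_fraction=0.7,
        major_genes=[
            MajorGene("GeneA", 0.25, {"1": 0.0, "2": 0.0, "3": -300.0}),
            MajorGene("GeneB", 0.5, {"1": 150.0, "2": 150.0, "3": 150.0}),
        ],
        region_map=region_map,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
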