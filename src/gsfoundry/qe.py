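"""Major-gene by region interaction analysis.

For each presence/absence gene, the multi-environment model is extended
with a fixed allele-by-region cell-mean term,

    Y_ijk = mu + G_i + E_j + R_k(j) + GE_ij + (allele x region) + e_ijk,

with genotype, environment, replicate-within-environment and GE random.
Estimated marginal means for the six (allele, region) cells come from the
GLS solution; pairwise differences are tested with t statistics built on
the GLS covariance and adjusted over the nine-contrast family (the three
within-region allele contrasts plus the three region pairs within each
allele) by the Tukey studentized-range method.

Two compartmentalizations are supported: by testing region (where the
plot was grown) and by line origin (observations kept only when the
line's breeding-program origin matches the testing region), the latter
guarding against genetic-background confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gsfoundry.mixedlm import RandomTerm, fit_mixed_model, indicator_matrix
from gsfoundry.pheno import _prepare

__all__ = [
    "RegionMap",
    "QEResult",
    "filter_calls",
    "fit_qe_model",
    "pairwise_contrasts",
    "tukey_adjust",
]

VALID_CALLS = {"present", "absent", "heterozygous", "null", "failed"}


@dataclass
class RegionMap:
    """Location -> region and line -> origin labels."""

    location_region: dict[str, str]
    line_origin: dict[str, str] | None = None

    def regions(self) -> list[str]:
        return sorted(set(self.location_region.values()))


@dataclass
class QEResult:
    gene: str
    trait: str
    emms: pd.DataFrame            # allele, region, emm, se, n
    emm_cov: np.ndarray
    df_resid: float
    carrier_frequency: float
    stratify_by: str
    contrasts: pd.DataFrame | None = None
    low_power_flag: bool = False


def filter_calls(
    calls: pd.DataFrame,
    gene: str,
    min_lines: int = 20,
) -> tuple[pd.Series, float]:
    """Keep only present/absent calls for a gene; return calls + frequency.

    Heterozygous, null and failed calls are discarded.  Raises when fewer
    than ``min_lines`` usable calls remain (the gene is then skipped).
    """
    d = calls[calls["gene"] == gene]
    if d.empty:
        raise KeyError(f"gene {gene!r} not in call table")
    bad = set(d["call"]) - VALID_CALLS
    if bad:
        raise ValueError(f"unknown call value(s) {sorted(bad)}")
    kept = d[d["call"].isin(["present", "absent"])]
    if len(kept) < min_lines:
        raise ValueError(
            f"gene {gene!r}: only {len(kept)} usable present/absent calls "
            f"(minimum {min_lines}); skipping"
        )
    s = kept.set_index("line_id")["call"]
    freq = float((s == "present").mean())
    return s, freq


def fit_qe_model(
    t: pd.DataFrame,
    calls: pd.Series,
    regions: RegionMap,
    trait: str,
    gene: str = "",
    stratify_by: str = "region",
    **reml_kwargs,
) -> QEResult:
    """REML fit with fixed allele-by-region cell means for one gene.

    ``calls`` maps line ids to {present, absent} (from
    :func:`filter_calls`).  ``stratify_by="origin"`` restricts records to
    lines whose origin matches the testing region before fitting.
    """
    if stratify_by not in ("region", "origin"):
        raise ValueError("stratify_by must be 'region' or 'origin'")
    d = _prepare(t, trait)
    d = d[d["line_id"].isin(calls.index)].copy()
    if d.empty:
        raise ValueError("no trial records for lines with usable calls")
    unmapped = sorted(set(d["location"]) - set(regions.location_region))
    if unmapped:
        raise ValueError(f"locations without region assignment: {unmapped}")
    d["region"] = d["location"].map(regions.location_region)
    d["allele"] = d["line_id"].map(calls)
    if stratify_by == "origin":
        if regions.line_origin is None:
            raise ValueError("RegionMap has no line origins")
        d["origin"] = d["line_id"].map(regions.line_origin)
        d = d[d["origin"] == d["region"]]
        if d.empty:
            raise ValueError("no records with origin matching testing region")

    region_of_allele = d.groupby("allele")["region"].nunique()
    if (region_of_allele < 2).any():
        warnings.warn(
            "an allele class appears in fewer than 2 regions; region "
            "contrasts for it will be undefined", UserWarning,
        )

    cells_all = [(a, r) for a in ("absent", "present")
                 for r in regions.regions()]
    cell_label = d["allele"] + ":" + d["region"]
    counts = cell_label.value_counts()
    present_cells = [c for c in cells_all if f"{c[0]}:{c[1]}" in counts.index]
    X = np.zeros((len(d), len(present_cells)))
    for j, (a, r) in enumerate(present_cells):
        X[:, j] = (cell_label == f"{a}:{r}").to_numpy(dtype=float)

    y = d["value"].to_numpy(dtype=float)
    terms = []
    Zg, lg = indicator_matrix(d["line_id"].to_numpy())
    terms.append(RandomTerm("G", Zg, lg))
    if d["env"].nunique() >= 2:
        Ze, le = indicator_matrix(d["env"].to_numpy())
        terms.append(RandomTerm("E", Ze, le))
        if d.groupby("env")["rep"].nunique().max() > 1:
            Zr, lr = indicator_matrix(
                (d["env"].astype(str) + ":" + d["rep"].astype(str)).to_numpy())
            terms.append(RandomTerm("R", Zr, lr))
        ge = (d["line_id"].astype(str) + ":" + d["env"].astype(str))
        if len(d) > ge.nunique():
            Zge, lge = indicator_matrix(ge.to_numpy())
            terms.append(RandomTerm("GE", Zge, lge))
    fit = fit_mixed_model(y, X, terms, **reml_kwargs)

    emm_rows = []
    for j, (a, r) in enumerate(present_cells):
        emm_rows.append({
            "allele": a, "region": r,
            "emm": float(fit.beta[j]),
            "se": float(np.sqrt(max(fit.beta_cov[j, j], 0.0))),
            "n": int(counts[f"{a}:{r}"]),
        })
    for a, r in set(cells_all) - set(present_cells):
        emm_rows.append({"allele": a, "region": r, "emm": np.nan,
                         "se": np.nan, "n": 0})
    emms = pd.DataFrame(emm_rows).sort_values(
        ["allele", "region"]).reset_index(drop=True)

    freq_lines = calls[calls.index.isin(d["line_id"].unique())]
    freq = float((freq_lines == "present").mean())
    qe = QEResult(
        gene=gene,
        trait=trait,
        emms=emms,
        emm_cov=fit.beta_cov,
        df_resid=float(len(d) - len(present_cells)),
        carrier_frequency=freq,
        stratify_by=stratify_by,
        low_power_flag=bool(freq < 0.02 or freq > 0.98),
    )
    qe._cells = present_cells
    qe.contrasts = pairwise_contrasts(qe)
    return qe


def _contrast_family(regions: list[str]):
    fam = []
    for r in regions:
        fam.append((("present", r), ("absent", r)))
    for a in ("present", "absent"):
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                fam.append(((a, regions[i]), (a, regions[j])))
    return fam


def tukey_adjust(t_stat: float, k: int, df: float) -> float:
    """Tukey (studentized-range) adjusted p for a pairwise mean contrast."""
    q = abs(t_stat) * np.sqrt(2.0)
    return float(stats.studentized_range.sf(q, k, df))


def pairwise_contrasts(qe: QEResult) -> pd.DataFrame:
    """The nine-contrast family with raw and Tukey-adjusted p-values.

    Family: present vs absent within each region, plus region pairs
    within each allele.  The studentized-range adjustment uses the number
    of estimable cells as the family's mean count.
    """
    cells = getattr(qe, "_cells", None)
    if cells is None:
        cells = [(a, r) for a, r in
                 qe.emms.loc[qe.emms["n"] > 0, ["allele", "region"]]
                 .itertuples(index=False)]
    pos = {c: i for i, c in enumerate(cells)}
    regions = sorted({r for _, r in cells} |
                     set(qe.emms["region"].unique()))
    beta = np.array([qe.emms.set_index(["allele", "region"])
                     .loc[c, "emm"] if c in pos else np.nan for c in
                     [(a, r) for a in ("absent", "present") for r in regions]])
    k = len(cells)
    rows = []
    for (c1, c2) in _contrast_family(regions):
        label = f"{c1[0]}:{c1[1]} - {c2[0]}:{c2[1]}"
        if c1 not in pos or c2 not in pos:
            rows.append({"contrast": label, "estimate": np.nan,
                         "se": np.nan, "t": np.nan,
                         "p_raw": np.nan, "p_tukey": np.nan,
                         "note": "cell empty"})
            continue
        i, j = pos[c1], pos[c2]
        est = float(qe.emms.set_index(["allele", "region"]).loc[c1, "emm"]
                    - qe.emms.set_index(["allele", "region"]).loc[c2, "emm"])
        var = (qe.emm_cov[i, i] + qe.emm_cov[j, j] - 2 * qe.emm_cov[i, j])
        if var <= 0:
            rows.append({"contrast": label, "estimate": est, "se": 0.0,
                         "t": np.nan, "p_raw": np.nan, "p_tukey": np.nan,
                         "note": "degenerate covariance"})
            continue
        se = float(np.sqrt(var))
        tval = est / se
        p_raw = float(2 * stats.t.sf(abs(tval), qe.df_resid))
        p_tuk = tukey_adjust(tval, k, qe.df_resid)
        rows.append({"contrast": label, "estimate": est, "se": se,
                     "t": tval, "p_raw": p_raw,
                     "p_tukey": max(p_tuk, p_raw), "note": ""})
    return pd.DataFrame(rows)
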