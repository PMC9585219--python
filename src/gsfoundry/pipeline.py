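"""End-to-end workflow: simulate -> QC -> cluster -> fit -> TP -> predict -> validate -> QE.

A single :class:`PipelineConfig` drives all stages in dependency order;
every stage writes its artifacts under the output directory and appends
to a manifest (stage -> outputs, sha256 checksums, wall time) so a rerun
under the same seed is verifiably identical.  A stage failure leaves the
manifest with the completed stages recorded, and a rerun with
``resume=True`` skips them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gsfoundry import envclust, gblup, genotype, pheno, qe, simulate, tpopt, validation

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "cluster", "genetic_values", "tp_selection",
          "prediction", "validation", "qe"]


@dataclass
class PipelineConfig:
    out_dir: str = "gsfoundry_run"
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    traits: list[str] = field(default_factory=lambda: ["YLD"])
    # QC thresholds
    maf_min: float = 0.05
    het_max: float = 0.10
    marker_missing_max: float = 0.20
    line_missing_max: float = 0.85
    # environment clustering
    n_env_groups: int = 2
    # line-set split
    new_line_fraction: float = 0.3        # untested (prediction) lines
    validation_fraction: float = 0.3      # of new lines, used for validation
    # TP search
    tp: tpopt.TPSearchConfig | None = None
    # selection
    n_top: int = 20
    n_bottom: int = 5
    # QE
    run_qe: bool = True
    min_gene_lines: int = 20

    @classmethod
    def demo(cls, seed: int = 0) -> "PipelineConfig":
        sim = simulate.demo_config(seed=seed)
        tp = tpopt.TPSearchConfig(
            tp_size=100, n_elite=10, ga_population=40, n_iterations=60,
            n_replications=2, n_pcs=20, seed=seed,
        )
        return cls(out_dir="gsfoundry_demo", seed=seed, simulation=sim, tp=tp)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        tp_raw = raw.pop("tp", None)
        genes_raw = (sim_raw or {}).pop("major_genes", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            genes = [simulate.MajorGene(**g) for g in (genes_raw or [])]
            cfg.simulation = simulate.SimulationConfig(
                major_genes=genes, **sim_raw)
        if tp_raw is not None:
            cfg.tp = tpopt.TPSearchConfig(**tp_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out: Path, seed: int, resume: bool):
        self.path = out / "manifest.json"
        if resume and self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"seed": seed, "stages": {}}

    def done(self, stage: str) -> bool:
        return stage in self.data["stages"] and \
            self.data["stages"][stage].get("status") == "ok"

    def record(self, stage: str, outputs: list[Path], t0: float,
               status: str = "ok", note: str = ""):
        self.data["stages"][stage] = {
            "status": status,
            "note": note,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Stage order: simulate, qc, cluster, genetic_values, tp_selection,
    prediction, validation, qe.  Disabling ``cfg.run_qe`` records the QE
    stage as skipped in the manifest.
    """
    if cfg.simulation is None:
        raise ValueError("PipelineConfig.simulation is required")
    if cfg.tp is None:
        raise ValueError("PipelineConfig.tp is required")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg.seed, resume)
    sim = cfg.simulation

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    geno_raw, truth = simulate.simulate_genotypes(sim)
    trials = {}
    for trait in cfg.traits:
        trials[trait] = simulate.simulate_trial(sim, truth, trait=trait)
    trial = pd.concat(trials.values(), ignore_index=True)
    if sim.major_genes:
        calls, trial_y = simulate.simulate_major_genes(
            sim, trial[trial["trait"] == cfg.traits[0]])
        trial = pd.concat(
            [trial_y] + [trials[t] for t in cfg.traits[1:]],
            ignore_index=True)
    else:
        calls = pd.DataFrame(columns=["line_id", "gene", "call"])
    if not manifest.done("simulate"):
        genotype.write_numeric_csv(geno_raw, out / "genotypes.csv")
        genotype.write_hapmap(geno_raw, out / "genotypes.hmp.txt")
        trial.to_csv(out / "trials.csv", index=False)
        calls.to_csv(out / "gene_calls.csv", index=False)
        (out / "truth.json").write_text(json.dumps({
            "true_breeding_values":
                truth.true_breeding_values.round(6).to_dict(),
            "qtl_indices": truth.qtl_indices.tolist(),
            "qtl_effects": truth.qtl_effects.tolist(),
            "subpop_labels": truth.subpop_labels.to_dict(),
        }))
        manifest.record("simulate", [out / "genotypes.csv",
                                     out / "trials.csv",
                                     out / "gene_calls.csv",
                                     out / "truth.json"], t0)

    # --- qc -----------------------------------------------------------
    t0 = time.time()
    geno_f, report = genotype.filter_markers(
        geno_raw, maf_min=cfg.maf_min, het_max=cfg.het_max,
        marker_missing_max=cfg.marker_missing_max,
        line_missing_max=cfg.line_missing_max)
    geno_imp = genotype.impute_missing(geno_f)
    grm = genotype.compute_grm(geno_imp)
    pcs = genotype.genotype_pca(geno_imp, n_components=cfg.tp.n_pcs)
    if not manifest.done("qc"):
        genotype.write_numeric_csv(geno_imp, out / "genotypes_qc.csv")
        grm.write_csv(out / "grm.csv")
        pcs.write_csv(out / "pcs.csv")
        (out / "qc_report.json").write_text(json.dumps(report.as_dict()))
        manifest.record("qc", [out / "genotypes_qc.csv", out / "grm.csv",
                               out / "pcs.csv", out / "qc_report.json"], t0)

    # --- line split ----------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    all_ids = np.array(geno_imp.line_ids)
    n_new = int(round(cfg.new_line_fraction * len(all_ids)))
    new_ids = np.sort(rng.choice(all_ids, n_new, replace=False))
    hist_ids = np.setdiff1d(all_ids, new_ids)
    n_val = max(int(round(cfg.validation_fraction * n_new)), 5)
    val_ids = np.sort(rng.choice(new_ids, min(n_val, n_new), replace=False))
    trait0 = cfg.traits[0]
    hist_trial = trial[trial["line_id"].isin(hist_ids)]

    # --- cluster --------------------------------------------------------
    t0 = time.time()
    tw = envclust.build_two_way(hist_trial, trait0)
    gge = envclust.gge_decompose(tw)
    clustering = envclust.cluster_environments(gge, n_groups=cfg.n_env_groups)
    if not manifest.done("cluster"):
        with open(out / "env_groups.yaml", "w") as fh:
            yaml.safe_dump({int(k): v for k, v in clustering.groups.items()}, fh)
        gge.env_loadings.iloc[:, :2].to_csv(out / "gge_loadings.csv")
        manifest.record("cluster", [out / "env_groups.yaml",
                                    out / "gge_loadings.csv"], t0)

    # --- genetic values -------------------------------------------------
    t0 = time.time()
    gv_frames, h2 = [], {}
    for trait in cfg.traits:
        sub = hist_trial[hist_trial["trait"] == trait]
        rfit = pheno.fit_random_genotype(sub, trait)
        ffit = pheno.fit_fixed_genotype(sub, trait)
        h2[trait] = pheno.cullis_h2(rfit)
        gv = ffit.values[["line_id", "emm", "n_obs"]].merge(
            rfit.values[["line_id", "blup", "blup_plus_mu"]], on="line_id")
        gv.insert(1, "trait", trait)
        gv_frames.append(gv)
    gvalues = pd.concat(gv_frames, ignore_index=True)
    if not manifest.done("genetic_values"):
        gvalues.to_csv(out / "genetic_values.csv", index=False)
        (out / "heritability.json").write_text(json.dumps(h2))
        manifest.record("genetic_values", [out / "genetic_values.csv",
                                           out / "heritability.json"], t0)

    # --- TP selection ---------------------------------------------------
    t0 = time.time()
    tp = tpopt.ga_select(list(hist_ids), list(new_ids), pcs, cfg.tp)
    if not manifest.done("tp_selection"):
        (out / "training_set.json").write_text(json.dumps(tp.as_dict()))
        (out / "training_set.txt").write_text("\n".join(tp.members) + "\n")
        manifest.record("tp_selection", [out / "training_set.json",
                                         out / "training_set.txt"], t0)

    # --- prediction -----------------------------------------------------
    t0 = time.time()
    emm0 = gvalues[gvalues["trait"] == trait0].set_index("line_id")["emm"]
    fit = gblup.fit_gblup(emm0.reindex(tp.members).dropna(), geno=geno_imp)
    gebvs = gblup.predict_gebv(fit, geno_imp)
    new_gebvs = gebvs[gebvs["line_id"].isin(new_ids)].reset_index(drop=True)
    sel = gblup.rank_select(new_gebvs, n_top=min(cfg.n_top, len(new_gebvs) - cfg.n_bottom),
                            n_bottom=min(cfg.n_bottom, len(new_gebvs)))
    if not manifest.done("prediction"):
        gebvs.to_csv(out / "gebvs.csv", index=False)
        sel["top"].to_csv(out / "selected_top.csv", index=False)
        sel["bottom"].to_csv(out / "selected_bottom.csv", index=False)
        manifest.record("prediction", [out / "gebvs.csv",
                                       out / "selected_top.csv",
                                       out / "selected_bottom.csv"], t0)

    # --- validation -----------------------------------------------------
    t0 = time.time()
    tp_emm = emm0.reindex(tp.members).dropna()
    cv = validation.five_fold_cv(tp_emm, geno_imp, trait=trait0,
                                 seed=cfg.seed, value_type="emm")
    val_trial = trial[(trial["line_id"].isin(val_ids))
                      & (trial["trait"] == trait0)]
    val_obs = pheno.fit_fixed_genotype(val_trial, trait0).emms
    val_pred = gebvs.set_index("line_id")["gebv"]
    r_ext, quad = validation.external_validate(val_pred, val_obs)
    val_summary = {
        "cv_mean_accuracy": cv.mean_accuracy,
        "cv_fold_accuracies": cv.fold_accuracies,
        "external_r": r_ext,
        "quadrant_pct": quad.percentages,
        "pct_correctly_classified": quad.pct_correct,
        "n_validation_lines": int(len(quad.quadrants)),
    }
    if not manifest.done("validation"):
        (out / "validation.json").write_text(json.dumps(val_summary))
        manifest.record("validation", [out / "validation.json"], t0)

    # --- QE -------------------------------------------------------------
    t0 = time.time()
    if cfg.run_qe and len(calls):
        regions = qe.RegionMap(location_region=dict(sim.region_map))
        qe_rows = []
        trial_qe = trial[trial["trait"] == trait0]
        for gene in sorted(calls["gene"].unique()):
            try:
                gcalls, freq = qe.filter_calls(calls, gene,
                                               min_lines=cfg.min_gene_lines)
            except ValueError as e:
                logger.info("%s", e)
                continue
            res = qe.fit_qe_model(trial_qe, gcalls, regions, trait0,
                                  gene=gene)
            c = res.contrasts.copy()
            c.insert(0, "gene", gene)
            c["carrier_frequency"] = freq
            qe_rows.append(c)
        qe_table = (pd.concat(qe_rows, ignore_index=True)
                    if qe_rows else pd.DataFrame())
        if not manifest.done("qe"):
            qe_table.to_csv(out / "qe_contrasts.csv", index=False)
            manifest.record("qe", [out / "qe_contrasts.csv"], t0)
    elif not manifest.done("qe"):
        manifest.record("qe", [], t0, status="skipped",
                        note="QE disabled or no gene calls")
    return manifest.data
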