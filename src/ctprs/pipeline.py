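"""End-to-end orchestration: simulate -> qc -> clump -> score -> pca -> tune -> assoc -> power.

Every stage writes plain-text artifacts into the run directory and the
manifest records, per stage, its parameters, the seed in force, and the
SHA-256 of every file it produced, so any stage can be re-run and
checked byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .association import assoc_prs, interaction_model, stratified_models
from .containers import PhenoTable
from .ld import R2_GRID, ClumpSpec, clump, prune
from .pca import compute_pcs
from .power import PowerSpec, detectable_or_closed_form
from .scoring import P_GRID, score_grid
from .simulate import (
    SimConfig,
    simulate_discovery_sumstats,
    simulate_effects,
    simulate_ld_genotypes,
    simulate_target_cohort,
)
from .tuning import tune_cv2, tune_external

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort", "simulate_and_analyze"]


def analyze_cohort(
    ss,
    geno,
    pheno,
    scheme: str = "cv2",
    criterion: str = "auc",
    n_pcs: int = 10,
    r2_grid=R2_GRID,
    clump_window_bp: int = 2_000_000,
    seed: int = 0,
    with_pca: bool = True,
    with_qc: bool = True,
    models: tuple = ("main", "interaction", "stratified"),
):
    """In-memory harmonize -> qc -> clump -> score -> pca -> tune -> associate.

    The file-free core of :func:`run_pipeline`, used for replicate
    studies.  Returns a dict with the tuned scores (``tuned``), the
    phenotype table used (``pheno``), and the fitted ``main``,
    ``interaction`` and ``stratified`` association results.
    """
    ss_h, geno_h, _ = io_mod.harmonize(ss, geno)
    if with_qc:
        geno_q, ss_q, _ = io_mod.qc_filter(geno_h, ss_h)
    else:
        geno_q, ss_q = geno_h, ss_h
    pheno_q = pheno.aligned_to(geno_q.sample_ids)

    clumps = {
        r2: clump(ss_q, geno_q, ClumpSpec(r2, clump_window_bp)) for r2 in r2_grid
    }
    grid = score_grid(geno_q, ss_q, clumps)

    if with_pca:
        pruned = prune(geno_q)
        k = min(n_pcs, geno_q.n_samples - 1, len(pruned))
        pcs = compute_pcs(geno_q, pruned, k=k)
        merged = pheno_q.table.merge(
            pcs.pc_frame().rename(columns={"IID": "sample_id"}), on="sample_id"
        )
        pheno_q = PhenoTable(merged)

    if scheme == "cv2":
        tuned = tune_cv2(grid, pheno_q, criterion=criterion, seed=seed)
    else:
        tuned = tune_external(grid, pheno_q, criterion=criterion)

    out = {"tuned": tuned, "pheno": pheno_q, "grid": grid}
    if "main" in models:
        out["main"] = assoc_prs(tuned.final_scores, pheno_q)
    if "interaction" in models:
        out["interaction"] = interaction_model(tuned.final_scores, pheno_q)
    if "stratified" in models:
        out["stratified"] = stratified_models(tuned.final_scores, pheno_q)
    return out


def simulate_and_analyze(sim: SimConfig, **kwargs):
    """Simulate one linked discovery/target pair and analyze it."""
    geno_d = simulate_ld_genotypes(sim, sim.n_discovery)
    effects = simulate_effects(sim, sim.n_variants)
    ss = simulate_discovery_sumstats(geno_d, effects, sim)
    geno_t = simulate_ld_genotypes(sim, sim.n_target, rng=sim.rng("target-geno"))
    pheno = simulate_target_cohort(geno_t, effects, sim)
    kwargs.setdefault("seed", sim.seed)
    return analyze_cohort(ss, geno_t, pheno, **kwargs)


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    sim: SimConfig = field(default_factory=SimConfig)
    scheme: str = "cv2"              # "cv2" | "external"
    criterion: str = "auc"
    n_pcs: int = 10
    r2_grid: tuple = R2_GRID
    clump_window_bp: int = 2_000_000
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": []}

    def record(stage, params, files):
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "seed": config.seed,
                "outputs": {str(f): _sha256(Path(f)) for f in files},
            }
        )

    # --- simulate ---------------------------------------------------------
    sim = config.sim
    if sim.seed != config.seed:
        sim = SimConfig(**{**asdict(sim), "seed": config.seed})
    geno_disc = simulate_ld_genotypes(sim, sim.n_discovery)
    effects = simulate_effects(sim, sim.n_variants)
    ss = simulate_discovery_sumstats(geno_disc, effects, sim)
    geno_t = simulate_ld_genotypes(sim, sim.n_target, rng=sim.rng("target-geno"))
    pheno = simulate_target_cohort(geno_t, effects, sim)

    f_ss = out / "sumstats.tsv"
    f_geno = out / "target_dosages.tsv"
    f_pheno = out / "pheno.tsv"
    io_mod.write_sumstats(ss, f_ss)
    io_mod.write_dosage_tsv(geno_t, f_geno)
    io_mod.write_pheno(pheno, f_pheno)
    record("simulate", asdict(sim), [f_ss, f_geno, f_pheno])

    # --- harmonize + qc ---------------------------------------------------
    ss_h, geno_h, _ = io_mod.harmonize(ss, geno_t)
    geno_q, ss_q, qc_rep = io_mod.qc_filter(geno_h, ss_h)
    f_qc = out / "qc_report.json"
    f_qc.write_text(
        json.dumps(
            {
                "samples_removed": [list(map(str, t)) for t in qc_rep.samples_removed],
                "variants_removed": [list(map(str, t)) for t in qc_rep.variants_removed],
                "thresholds": asdict(qc_rep.thresholds),
            },
            indent=1,
        )
    )
    record("qc", asdict(qc_rep.thresholds), [f_qc])

    pheno_q = pheno.aligned_to(geno_q.sample_ids)

    # --- clump + score grid ----------------------------------------------
    clumps = {
        r2: clump(ss_q, geno_q, ClumpSpec(r2, config.clump_window_bp))
        for r2 in config.r2_grid
    }
    f_clump = out / "clumps.tsv"
    with open(f_clump, "w") as fh:
        fh.write("R2\tINDEX_SNP\tN_MEMBERS\tMEMBERS\n")
        for r2, res in clumps.items():
            members = {}
            for rem, idx in res.removed.items():
                members.setdefault(idx, []).append(rem)
            for idx in res.index_variants:
                mem = members.get(idx, [])
                fh.write(f"{r2}\t{idx}\t{len(mem)}\t{','.join(mem) or '.'}\n")
    grid = score_grid(geno_q, ss_q, clumps)
    f_prs = out / "prs_grid.tsv"
    prs_df = pd.DataFrame({"IID": grid.sample_ids})
    for (r2, p) in grid.cells:
        prs_df[f"r2_{r2:g}_p_{p:g}"] = grid.scores[(r2, p)]
    prs_df.to_csv(f_prs, sep="\t", index=False, float_format="%.10g")
    record(
        "clump+score",
        {"r2_grid": list(config.r2_grid), "p_grid": list(P_GRID),
         "window_bp": config.clump_window_bp},
        [f_clump, f_prs],
    )

    # --- pca --------------------------------------------------------------
    pruned = prune(geno_q)
    k = min(config.n_pcs, geno_q.n_samples - 1, len(pruned))
    pcs = compute_pcs(geno_q, pruned, k=k)
    f_pcs = out / "pcs.tsv"
    pcs.pc_frame().to_csv(f_pcs, sep="\t", index=False, float_format="%.10g")
    record("pca", {"k": k, "n_pruned": len(pruned)}, [f_pcs])

    pheno_pc = pheno_q.table.merge(
        pcs.pc_frame().rename(columns={"IID": "sample_id"}), on="sample_id"
    )
    pheno_q = PhenoTable(pheno_pc)

    # --- tune -------------------------------------------------------------
    if config.scheme == "cv2":
        tuned = tune_cv2(grid, pheno_q, criterion=config.criterion, seed=config.seed)
    else:
        tuned = tune_external(grid, pheno_q, criterion=config.criterion)
    f_tuned = out / "tuned_scores.tsv"
    pd.DataFrame({"IID": grid.sample_ids, "SCORE": tuned.final_scores}).to_csv(
        f_tuned, sep="\t", index=False, float_format="%.10g"
    )
    record(
        "tune",
        {"scheme": tuned.scheme, "criterion": tuned.criterion,
         "selected": json.loads(json.dumps(str(tuned.selected)))},
        [f_tuned],
    )

    # --- association ------------------------------------------------------
    main = assoc_prs(tuned.final_scores, pheno_q)
    inter = interaction_model(tuned.final_scores, pheno_q)
    strat = stratified_models(tuned.final_scores, pheno_q)
    assoc = {
        "main": main.to_dict(),
        "interaction": inter.to_dict(),
        "stratified": {k: (v.to_dict() if v else None) for k, v in strat.items()},
    }
    f_assoc = out / "assoc.json"
    f_assoc.write_text(json.dumps(assoc, indent=1))
    record("assoc", {"covariates": "sex+intervention+cohort+PCs"}, [f_assoc])

    # --- power ------------------------------------------------------------
    y = pheno_q.table["outcome"].to_numpy()
    sex = pheno_q.table["sex"].to_numpy()
    power = {}
    for label, mask in (("full", np.ones_like(y, bool)), ("male", sex == 1),
                        ("female", sex == 0)):
        n, c = int(mask.sum()), int(y[mask].sum())
        if 0 < c < n:
            power[label] = {
                "n": n,
                "n_cases": c,
                "detectable_or": detectable_or_closed_form(
                    PowerSpec(n=n, n_cases=c)
                ).detectable_or,
            }
    f_power = out / "power.json"
    f_power.write_text(json.dumps(power, indent=1))
    record("power", {"alpha": 0.05, "power": 0.80}, [f_power])

    f_manifest = out / "manifest.json"
    f_manifest.write_text(json.dumps(manifest, indent=1))
    return manifest
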