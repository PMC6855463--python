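"""End-to-end orchestration: simulate/ingest -> stage-1 -> QC -> kernels
-> DAPC -> cross-validation -> method comparison, with every artifact
written to a run directory plus a manifest (seeds, config hash, stage
counts)."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import compare, crossval, io, markers, pheno, simdata, structure

log = logging.getLogger("clonegs")


class PipelineError(RuntimeError):
    def __init__(self, stage, original):
        self.stage = stage
        super().__init__(f"pipeline failed in stage {stage!r}: {original}")


def run_pipeline(config: io.RunConfig) -> Path:
    """Run the full analysis described by ``config``; returns the run dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def record(stage, t0, **counts):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2), **counts}
        log.info("stage %s done: %s", stage, counts)

    def save(name, writer, *args):
        path = out / name
        writer(*args, path)
        manifest["outputs"].append(name)
        return path

    stage = "ingest"
    try:
        t0 = time.time()
        if config.genotype_path:
            geno = io.read_genotypes(config.genotype_path)
            trials = io.read_trials(config.phenotype_path)
            truth = None
        else:
            sim_cfg = simdata.SimulationConfig(
                seed=config.child_seed("simulate"), **config.simulate
            )
            geno, trials, truth = simdata.simulate_study(sim_cfg)
            save("genotypes.csv", lambda g, p: io.write_dosage_csv(g, p), geno)
            save("trials.csv", lambda t, p: io.write_trials(t, p), trials)
            truth.true_breeding_values.to_csv(out / "truth_breeding_values.csv")
            manifest["outputs"].append("truth_breeding_values.csv")
        traits = config.traits or [
            c
            for c in trials.columns
            if c not in ("clone", "location", "year", "rep", "block", "design")
        ]
        missing = [t for t in traits if t not in trials.columns]
        if missing:
            raise KeyError(f"trait columns missing from trial table: {missing}")
        record(stage, t0, clones=trials["clone"].nunique(), plots=len(trials))

        stage = "stage1"
        t0 = time.time()
        estimates = {}
        for trait in traits:
            est = pheno.fit_clonal_lmm(trials, trait)
            estimates[trait] = est
            io.write_estimates(
                est, out / f"estimates_{trait}.csv", out / f"varcomp_{trait}.json"
            )
            manifest["outputs"] += [f"estimates_{trait}.csv", f"varcomp_{trait}.json"]
        record(stage, t0, traits=len(traits))

        stage = "qc"
        t0 = time.time()
        geno_qc = markers.qc_pipeline(geno, config.min_call_rate, config.min_maf)
        (out / "qc_report.json").write_text(json.dumps(geno_qc.qc_report, indent=2))
        manifest["outputs"].append("qc_report.json")
        record(stage, t0, markers_kept=geno_qc.n_markers)

        stage = "kernels"
        t0 = time.time()
        G = markers.additive_G(geno_qc)
        K = markers.gaussian_K(geno_qc)
        save("kinship_G.csv", io.write_kinship, G)
        save("kinship_K.csv", io.write_kinship, K)
        record(stage, t0)

        stage = "dapc"
        t0 = time.time()
        model = structure.dapc_fit(
            geno_qc,
            k=config.dapc_k,
            pc_variance_threshold=config.pc_variance,
            df_variance_threshold=config.df_variance,
            seed=config.child_seed("dapc"),
        )
        labels = pd.Series(model.labels_, index=geno_qc.samples, name="cluster")
        labels.to_csv(out / "dapc_labels.csv", index_label="id")
        manifest["outputs"].append("dapc_labels.csv")
        record(stage, t0, k=model.n_clusters_, sizes=model.cluster_sizes_.tolist())

        stage = "cv"
        t0 = time.time()
        kernels = {"additive_G": G, "gaussian_K": K}
        mcmc = {"n_iter": config.n_iter, "burn_in": config.burn_in, "thin": config.thin}
        results = []
        for strat in config.strategies:
            plan = crossval.make_cv_plan(
                strat,
                geno_qc.samples,
                cluster_labels=labels if strat != "S1_random" else None,
                folds=config.folds,
                replicates=config.replicates,
                seed=config.child_seed(f"cv:{strat}"),
            )
            for method in config.methods:
                for trait in traits:
                    results.append(
                        crossval.run_cv(
                            plan, method, geno_qc, estimates[trait],
                            kernels=kernels, mcmc=mcmc,
                        )
                    )
        cv_results = pd.concat(results, ignore_index=True)
        cv_results.to_csv(out / "cv_results.csv", index=False)
        manifest["outputs"].append("cv_results.csv")
        record(stage, t0, folds=len(cv_results))

        stage = "compare"
        t0 = time.time()
        if len(config.methods) >= 2 and config.replicates >= 2:
            for trait in traits:
                for strat in config.strategies:
                    sub = cv_results.query(
                        "trait == @trait and strategy == @strat"
                    )
                    if sub.empty:
                        continue
                    table = compare.deviance_analysis(
                        sub, "predictive_ability",
                        with_structure=strat != "S1_random",
                    )
                    name = f"deviance_{trait}_{strat}.csv"
                    pd.concat(
                        [table.terms, table.method_means], axis=0
                    ).to_csv(out / name, index=False)
                    manifest["outputs"].append(name)
        record(stage, t0)

    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        raise PipelineError(stage, exc) from exc

    for name in manifest["outputs"]:
        p = out / name
        if not p.exists() or p.stat().st_size == 0:
            raise PipelineError("manifest", f"declared output {name} missing/empty")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
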