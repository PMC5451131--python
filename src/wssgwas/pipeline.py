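"""End-to-end pipeline driver: simulate/read -> QC -> relationships ->
threshold-model chain -> diagnostics -> weighted GWAS -> window scan.

Configuration is a plain nested dict (YAML/JSON on disk) with blocks
``simulation`` (or ``paths``), ``qc``, ``gibbs`` and ``wssgblup``; a run
writes the QC reports, the thinned chain, a diagnostics table, the window
table and a manifest (config echo, seed, versions, per-stage timings).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .diagnostics import diagnostics_table
from .gwas import WssGblup
from .qc import PhenotypeEditor, QcThresholds, filter_markers, filter_samples
from .simulate import SimConfig, simulate_dataset

STAGES = ["inputs", "qc_genotypes", "qc_phenotypes", "relationship",
          "threshold_gibbs", "diagnostics", "wssgblup"]


def _sim_config(block: dict, seed: int | None) -> SimConfig:
    if seed is not None:
        block = {**block, "seed": seed}
    return SimConfig(**block)


def run_pipeline(config: dict, out_dir: str, seed: int | None = None) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure is recorded in the manifest (with the stage name)
    before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": seed, "config": config,
                "stages": [], "numpy": np.__version__}
    t_all = time.time()

    def stage(name):
        manifest["stages"].append({"name": name, "seconds": None})
        return time.time()

    def done(t0):
        manifest["stages"][-1]["seconds"] = round(time.time() - t0, 3)

    try:
        t0 = stage("inputs")
        if "simulation" in config:
            sim = simulate_dataset(_sim_config(config["simulation"], seed))
            pedigree, phenotypes = sim.pedigree, sim.phenotypes
            panel = sim.genotyped_panel
            genotyped_ids = sim.genotyped_ids
        else:
            paths = config["paths"]
            pedigree = io.read_pedigree(paths["pedigree"])
            phenotypes = io.read_phenotypes(paths["phenotypes"])
            panel = io.read_genotypes(paths["genotypes"], paths["map"],
                                      paths.get("quality"))
            genotyped_ids = panel.animal_ids
            sim = None
        io.write_pedigree(pedigree, out / "pedigree.csv")
        done(t0)

        t0 = stage("qc_genotypes")
        thresholds = QcThresholds(**config.get("qc", {}))
        panel, marker_report = filter_markers(panel, thresholds)
        panel, sample_report = filter_samples(panel, thresholds)
        genotyped_ids = panel.animal_ids
        marker_report.to_frame().to_csv(out / "qc_markers.tsv", sep="\t",
                                        index=False)
        sample_report.to_frame().to_csv(out / "qc_samples.tsv", sep="\t",
                                        index=False)
        done(t0)

        t0 = stage("qc_phenotypes")
        editor = PhenotypeEditor().fit(phenotypes)
        phenotypes = editor.grouped_
        editor.edit_report_.to_frame().to_csv(out / "qc_edits.tsv", sep="\t",
                                              index=False)
        editor.cg_report_.to_frame().to_csv(out / "qc_groups.tsv", sep="\t",
                                            index=False)
        done(t0)

        wss_cfg = dict(config.get("wssgblup", {}))
        gibbs_cfg = dict(config.get("gibbs", {}))
        n_cat = int(phenotypes["trait"].max()) + 1
        t0 = stage("relationship")  # built per round inside the estimator
        est = WssGblup(
            n_rounds=wss_cfg.get("n_rounds", 2),
            window_bp=wss_cfg.get("window_bp", 1_000_000),
            top_k=wss_cfg.get("top_k", 20),
            blend_weight=wss_cfg.get("blend_weight", 0.05),
            n_categories=n_cat,
            n_iterations=gibbs_cfg.get("n_iterations", 20_000),
            burn_in=gibbs_cfg.get("burn_in", 2_000),
            thin=gibbs_cfg.get("thin", 10),
            seed=seed if seed is not None else gibbs_cfg.get("seed", 0))
        done(t0)

        t0 = stage("threshold_gibbs")
        est.fit(phenotypes, pedigree, panel, genotyped_ids)
        done(t0)

        t0 = stage("diagnostics")
        final = est.states_[-1]
        chain = est.model_.chain_
        io.write_chain(chain, out / "chain.csv")
        est.model_.breeding_values_.to_csv(out / "breeding_values.tsv",
                                           sep="\t", index=False)
        chains = {"sigma_a2": chain.sigma_a2, "h2": chain.h2}
        if chain.t2 is not None:
            chains["t2"] = chain.t2
        diagnostics_table(chains).to_csv(out / "diagnostics.tsv", sep="\t",
                                         index=False)
        done(t0)

        t0 = stage("wssgblup")
        est.windows_.to_csv(out / "windows.tsv", sep="\t", index=False)
        effects = pd.DataFrame({
            "marker_id": est.marker_map_["marker_id"],
            "u_hat": final.u_hat,
            "weight": final.weights,
        })
        effects.to_csv(out / "snp_effects.tsv", sep="\t", index=False)
        done(t0)

        manifest["h2_mean"] = est.h2_mean_
        manifest["n_windows"] = int(len(est.windows_))
        manifest["seconds_total"] = round(time.time() - t_all, 3)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = manifest["stages"][-1]["name"] if manifest["stages"] else None
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
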