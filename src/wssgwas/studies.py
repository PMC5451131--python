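"""Reproducible simulation studies: heritability recovery and scan power.

These are the package's standing validation experiments. Each study draws
replicate populations from :mod:`wssgwas.simulate`, pushes them through
QC, the single-step relationship matrices and the threshold-model chain,
and measures how well known truth is recovered. They are deliberately
desk-scale: ~2,400 animals, 2,000 markers and 20,000-sweep chains for the
heritability studies; ~1,400 animals with 500 genotyped for the window
power study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gwas import WssGblup
from .qc import PhenotypeEditor, filter_markers, filter_samples
from .relationship import build_h_inverse
from .simulate import SimConfig, simulate_dataset
from .threshold_model import ThresholdModel

_MOD = 2**31 - 1


def derive_seed(seed: int, replicate: int) -> int:
    """Spread a master seed over replicates, keeping values below 2^31."""
    return (seed * 100003 + replicate * 7919 + 1) % _MOD


def fit_replicate(seed: int, true_h2: float, trait_kind: str = "binary",
                  thresholds: tuple = (0.0,), n_iterations: int = 20_000,
                  burn_in: int = 2_000, thin: int = 10,
                  sim_overrides: dict | None = None) -> dict:
    """Simulate one population at a known heritability and refit it.

    Returns the posterior-mean h2 plus the replicate's realized h2 (from
    the true breeding values of the phenotyped generations).
    """
    overrides = sim_overrides or {}
    cfg = SimConfig(seed=seed, h2_true=true_h2, trait_kind=trait_kind,
                    thresholds=thresholds, **overrides)
    sim = simulate_dataset(cfg)
    panel, _ = filter_markers(sim.genotyped_panel)
    panel, _ = filter_samples(panel)
    phenotypes = PhenotypeEditor().fit(sim.phenotypes).grouped_
    h_inv, _, _ = build_h_inverse(sim.pedigree, panel, panel.animal_ids)
    model = ThresholdModel(n_iterations=n_iterations, burn_in=burn_in,
                           thin=thin, seed=derive_seed(seed, 1),
                           n_categories=cfg.n_categories)
    model.fit(phenotypes, h_inv, sim.pedigree)
    gen = sim.pedigree.df["generation"].to_numpy()
    va = float(sim.model.true_breeding_values[gen >= 1].var())
    return {"h2_post_mean": model.h2_mean_,
            "h2_realized": va / (va + 1.0),
            "n_records": len(phenotypes),
            "n_genotyped": panel.n_animals}


def h2_recovery_study(true_h2: float, trait_kind: str = "binary",
                      thresholds: tuple = (0.0,), n_replicates: int = 10,
                      seed: int = 1, **fit_kwargs) -> dict:
    """Across-replicate mean of posterior-mean h2 at a fixed simulated truth."""
    reps = [fit_replicate(derive_seed(seed, r), true_h2, trait_kind,
                          thresholds, **fit_kwargs)
            for r in range(n_replicates)]
    means = np.array([r["h2_post_mean"] for r in reps])
    return {"true_h2": true_h2,
            "replicates": reps,
            "posterior_means": means,
            "mean_h2": float(means.mean()),
            "n_records": int(np.mean([r["n_records"] for r in reps]))}


@dataclass
class PowerReplicate:
    hit: bool
    qtl_window_rank: int
    qtl_share_realized: float


def _major_qtl_window(sim) -> tuple[str, int]:
    """(chrom, window start bp) of the largest-variance QTL."""
    model, panel = sim.model, sim.panel
    dos = panel.dosages[model.qtl_indices]
    p = np.nanmean(dos, axis=1) / 2.0
    v = 2.0 * p * (1.0 - p) * model.qtl_effects**2
    big = model.qtl_indices[int(np.argmax(v))]
    row = panel.marker_map.iloc[big]
    start = int((row["bp"] - 1) // 1_000_000) * 1_000_000 + 1
    return str(row["chrom"]), start


def window_power_replicate(seed: int, qtl_share: float = 0.15,
                           top_k: int = 20,
                           n_iterations: int = 6_000, burn_in: int = 1_200,
                           thin: int = 10) -> PowerReplicate:
    """One power draw: does the major-QTL window rank in the top 20?

    Population: ~3,000 animals over 5 generations (liability h2 is only
    weakly identified from fewer binary records, which degrades the
    breeding values the scan rests on), ~500 genotyped, 2,000 markers,
    one QTL carrying ``qtl_share`` of the genetic variance.
    """
    cfg = SimConfig(seed=seed, n_founders=500, genotyped_fraction=0.167,
                    h2_true=0.3, n_qtl=50, major_qtl_share=qtl_share)
    sim = simulate_dataset(cfg)
    chrom, start = _major_qtl_window(sim)
    panel, _ = filter_markers(sim.genotyped_panel)
    panel, _ = filter_samples(panel)
    phenotypes = PhenotypeEditor().fit(sim.phenotypes).grouped_
    est = WssGblup(n_rounds=2, top_k=top_k, n_iterations=n_iterations,
                   burn_in=burn_in, thin=thin, seed=derive_seed(seed, 2))
    est.fit(phenotypes, sim.pedigree, panel, panel.animal_ids)
    win = est.windows_
    row = win[(win["chrom"] == chrom) & (win["start_bp"] == start)]
    rank = int(row["rank"].iloc[0]) if len(row) else len(win) + 1

    dosq = sim.panel.dosages[sim.model.qtl_indices]
    pq = np.nanmean(dosq, axis=1) / 2.0
    v = 2.0 * pq * (1.0 - pq) * sim.model.qtl_effects**2
    share = float(v.max() / v.sum()) if v.sum() > 0 else 0.0
    return PowerReplicate(rank <= top_k, rank, share)


def window_power_study(n_replicates: int = 20, seed: int = 1,
                       **kwargs) -> dict:
    reps = [window_power_replicate(derive_seed(seed, 100 + r), **kwargs)
            for r in range(n_replicates)]
    return {"replicates": reps,
            "hit_rate": float(np.mean([r.hit for r in reps])),
            "ranks": [r.qtl_window_rank for r in reps]}


def le_window_percentage_sum(seed: int = 1, n_animals: int = 1000,
                             n_markers: int = 2000) -> float:
    """Sum of window variance percentages on a linkage-equilibrium panel.

    Founders-only population: every marker segregates independently, so
    window covariances vanish in expectation and the percentages should
    add to ~100.
    """
    from .gwas import window_scan

    cfg = SimConfig(seed=seed, n_founders=n_animals, n_generations=0,
                    n_markers=n_markers, missing_rate=0.0,
                    low_quality_rate=0.0)
    sim = simulate_dataset(cfg)
    rng = np.random.default_rng(derive_seed(seed, 3))
    u_hat = rng.standard_normal(n_markers) * 0.01
    d = sim.panel.dosages.T
    z = d - d.mean(axis=0)
    win = window_scan(u_hat, z, sim.panel.marker_map)
    return float(win["pct_variance"].sum())
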