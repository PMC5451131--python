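"""Weighted single-step GWAS: SNP back-solving, weight iteration, window scan.

SNP allele-substitution effects are back-solved from the genomic breeding
values of the genotyped animals,

    u_hat = D Z' [Z D Z']^-1 a_hat_g,

where Z is the 2p-centered dosage matrix (animals x markers) and D the
diagonal marker-weight matrix. Weights are then refreshed as
d_i = u_hat_i^2 p_i (1 - p_i) and rescaled by a single constant so
sum_i d_i 2 p_i (1 - p_i) — the marker-variance budget — stays at its
round-0 value, keeping the total genetic variance constant across rounds.
The default two evaluation rounds (identity weights, then one re-weighting)
follow the usual weighted single-step recipe.

The window scan tiles every chromosome with non-overlapping 1-Mb windows
anchored at position 1 ([k Mb + 1, (k+1) Mb], 1-based inclusive) and
reports, per window, the variance across genotyped animals of the window's
aggregate genomic value sum_{i in w} Z_i u_hat_i as a percentage of the
variance of the total Z u_hat (configurably of sigma2_a instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GenotypePanel, Pedigree
from .relationship import build_h_inverse
from .threshold_model import ThresholdModel

WINDOW_BP = 1_000_000


@dataclass
class SnpWeightState:
    """One round of the weight iteration."""

    round_index: int
    u_hat: np.ndarray        # per-marker allele-substitution effects
    weights: np.ndarray      # diagonal of D, >= 0
    p: np.ndarray            # second-allele frequencies
    z: np.ndarray            # centered dosages, genotyped animals x markers
    h2_mean: float | None = None

    def __post_init__(self):
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def variance_budget(self) -> float:
        """sum_i d_i 2 p_i (1 - p_i); held constant across rounds."""
        return float(np.sum(self.weights * 2.0 * self.p * (1.0 - self.p)))


def backsolve_snp_effects(a_hat_g: np.ndarray, z: np.ndarray,
                          weights: np.ndarray,
                          gram: np.ndarray | None = None) -> np.ndarray:
    """u_hat = D Z' (Z D Z')^-1 a_hat_g; exact projection: Z u_hat = a_hat_g.

    ``gram`` substitutes an invertible stand-in for Z D Z' (typically the
    blended genomic matrix times 2 sum p q) when the raw cross-product is
    singular or ill-conditioned; the projection then holds approximately,
    to within the blend weight.
    """
    a_hat_g = np.asarray(a_hat_g, dtype=float)
    d = np.asarray(weights, dtype=float)
    zdz = (z * d) @ z.T if gram is None else gram
    try:
        alpha = np.linalg.solve(zdz, a_hat_g)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Z D Z' is singular; blend the genomic matrix toward A22 or drop "
            "zero-weight markers") from exc
    return d * (z.T @ alpha)


def update_weights(state: SnpWeightState) -> SnpWeightState:
    """Next-round weights d_i = u_hat_i^2 p_i (1 - p_i), renormalized so the
    marker-variance budget matches round 0."""
    d = state.u_hat**2 * state.p * (1.0 - state.p)
    total = np.sum(d * 2.0 * state.p * (1.0 - state.p))
    if total <= 0.0:
        warnings.warn("all back-solved effects are zero; keeping uniform weights")
        d = np.ones_like(d)
        total = np.sum(d * 2.0 * state.p * (1.0 - state.p))
    target = state.variance_budget
    d = d * (target / total)
    return replace(state, round_index=state.round_index + 1, weights=d,
                   u_hat=np.zeros_like(state.u_hat), h2_mean=None)


def window_scan(u_hat: np.ndarray, z: np.ndarray, marker_map: pd.DataFrame,
                window_bp: int = WINDOW_BP, top_k: int = 20,
                total_variance: float | None = None) -> pd.DataFrame:
    """Per-window share of additive genetic variance.

    Windows tile each chromosome from position 1 up to the last typed
    marker. The statistic is var_animals(sum_{i in w} Z_i u_hat_i) divided
    by ``total_variance`` (default: variance of the total genomic values
    Z u_hat), times 100. Empty windows report 0 and stay in the output.
    Ranked descending, ties broken by (chromosome, start).
    """
    gv_total = z @ u_hat
    if total_variance is None:
        total_variance = float(gv_total.var())
    bp = marker_map["bp"].to_numpy(np.int64)
    chrom = marker_map["chrom"].to_numpy(str)
    win_of_marker = (bp - 1) // window_bp
    rows = []
    for c in pd.unique(chrom):
        on_c = chrom == c
        n_win = int(win_of_marker[on_c].max()) + 1
        for w in range(n_win):
            sel = on_c & (win_of_marker == w)
            if sel.any():
                gv = z[:, sel] @ u_hat[sel]
                pct = 100.0 * float(gv.var()) / total_variance if total_variance > 0 else 0.0
            else:
                pct = 0.0
            rows.append((c, w * window_bp + 1, (w + 1) * window_bp,
                         int(sel.sum()), pct))
    out = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_snps",
                                      "pct_variance"])
    order = out.sort_values(["pct_variance", "chrom", "start_bp"],
                            ascending=[False, True, True], kind="stable").index
    ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
    out["rank"] = ranks
    out["top20"] = out["rank"] <= top_k
    return out


class WssGblup(BaseEstimator):
    """Iteratively re-weighted single-step GWAS (sklearn-style).

    Each round builds the weighted genomic matrix with the current D,
    assembles H^-1, refreshes the genomic breeding values with a (typically
    shortened) threshold-model chain, back-solves SNP effects and
    re-weights. Round 0 uses identity weights.

    Attributes after ``fit``: ``states_`` (one :class:`SnpWeightState` per
    completed round), ``windows_`` (scan of the final round),
    ``marker_map_`` (map of the markers used in G).
    """

    def __init__(self, n_rounds: int = 2, window_bp: int = WINDOW_BP,
                 top_k: int = 20, blend_weight: float = 0.05,
                 n_categories: int = 2, n_iterations: int = 20_000,
                 burn_in: int = 2_000, thin: int = 10, seed: int = 0,
                 variance_denominator: str = "genomic"):
        self.n_rounds = n_rounds
        self.window_bp = window_bp
        self.top_k = top_k
        self.blend_weight = blend_weight
        self.n_categories = n_categories
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.variance_denominator = variance_denominator

    def fit(self, phenotypes: pd.DataFrame, pedigree: Pedigree,
            genotyped_panel: GenotypePanel, genotyped_ids: list[str]):
        if self.n_rounds < 1:
            raise ValueError("need at least one evaluation round")
        if self.variance_denominator not in ("genomic", "sigma_a2"):
            raise ValueError("variance_denominator must be 'genomic' or 'sigma_a2'")
        states: list[SnpWeightState] = []
        weights = None
        state = None
        for rnd in range(self.n_rounds):
            mats = build_h_inverse(
                pedigree, genotyped_panel, genotyped_ids,
                blend_weight=self.blend_weight, weights=weights)
            h_inv, p_all, used = mats.h_inv, mats.p, mats.used_markers
            model = ThresholdModel(
                n_iterations=self.n_iterations, burn_in=self.burn_in,
                thin=self.thin, seed=self.seed + rnd,
                n_categories=self.n_categories)
            model.fit(phenotypes, h_inv, pedigree)
            a_hat_g = model.predict(genotyped_ids)

            d = genotyped_panel.dosages.T[:, used].astype(float).copy()
            p = p_all[used]
            nanmask = np.isnan(d)
            if nanmask.any():
                d[nanmask] = np.broadcast_to(2.0 * p, d.shape)[nanmask]
            z = d - 2.0 * p
            if state is None:
                state = SnpWeightState(0, np.zeros(len(p)), np.ones(len(p)),
                                       p, z)
            else:
                state = replace(state, z=z)
            # invert through the blended genomic matrix (x 2 sum pq) so the
            # system stays well-posed even when D concentrates on few markers
            het = float(2.0 * np.sum(p * (1.0 - p)))
            u_hat = backsolve_snp_effects(a_hat_g, z, state.weights,
                                          gram=mats.g_blended * het)
            state = replace(state, u_hat=u_hat, h2_mean=model.h2_mean_)
            states.append(state)
            self.model_ = model  # final round's fitted threshold model
            if rnd + 1 < self.n_rounds:
                state = update_weights(state)
                weights_full = np.zeros(genotyped_panel.n_markers)
                weights_full[used] = state.weights
                weights = weights_full

        final = states[-1]
        self.states_ = states
        self.marker_map_ = genotyped_panel.marker_map.iloc[used].reset_index(drop=True)
        total = None
        if self.variance_denominator == "sigma_a2":
            total = states[-1].h2_mean / (1.0 - states[-1].h2_mean)
        self.windows_ = window_scan(final.u_hat, final.z, self.marker_map_,
                                    self.window_bp, self.top_k, total)
        self.h2_mean_ = final.h2_mean
        return self


def run_wssgblup(phenotypes: pd.DataFrame, pedigree: Pedigree,
                 genotyped_panel: GenotypePanel, genotyped_ids: list[str],
                 n_rounds: int = 2, **kwargs) -> list[SnpWeightState]:
    """Functional wrapper returning the per-round states."""
    est = WssGblup(n_rounds=n_rounds, **kwargs)
    est.fit(phenotypes, pedigree, genotyped_panel, genotyped_ids)
    return est.states_
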