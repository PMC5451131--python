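"""Bayesian threshold animal model on the liability scale.

The observed category of each record is modeled as a discretization of a
latent liability

    y = X beta + Z_a a + e,        e ~ N(0, I),  sigma2_e = 1
    a | sigma2_a ~ N(0, H sigma2_a)

with category 0 below t1, category 1 between t1 and t2, category 2 above t2.
Identification: t1 is fixed at 0 and the residual variance at 1 (the
standard probit/Albert-Chib anchoring); for three categories t2 is sampled.
Priors: flat on the contemporary-group effects and t2. For sigma2_a the
default is the proper, neutral uniform prior on the heritability
h2 = sigma2_a/(sigma2_a + 1), i.e. p(sigma2_a) = (1 + sigma2_a)^-2. A flat
prior on the variance itself is also offered but produces an improper
posterior whenever every animal has a single categorical record (each
breeding value can then separate its own category perfectly, so the
likelihood stays bounded as sigma2_a grows and the chain escapes upward);
use it only with well-replicated records. A scaled-inverse-chi-square
(nu, S) prior is the third option.

Fitting runs a single Gibbs chain (compiled sweep loop); breeding values
are updated by single-site Gauss-Seidel passes over the sparse H^-1 mixed
model system, which leaves the stationary distribution unchanged relative
to a joint draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._gibbs_kernel import run_chain_kernel
from .datatypes import Pedigree
from .relationship import HInverseParts


@dataclass(frozen=True)
class GibbsConfig:
    """Chain settings; defaults are the full-scale production settings."""

    n_iterations: int = 500_000
    burn_in: int = 50_000
    thin: int = 50
    seed: int = 0
    prior: str = "uniform_h2"
    prior_nu: float = -2.0
    prior_scale: float = 0.0

    def __post_init__(self):
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        """Stored sample count: floor((n_iterations - burn_in) / thin)."""
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples and running breeding-value moments."""

    sigma_a2: np.ndarray
    h2: np.ndarray
    t2: np.ndarray | None
    breeding_values: pd.DataFrame  # animal, mean, sd
    config: GibbsConfig

    @property
    def n_samples(self) -> int:
        return len(self.sigma_a2)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "sample": np.arange(1, self.n_samples + 1),
            "sigma_a2": self.sigma_a2,
            "h2": self.h2,
        })
        if self.t2 is not None:
            out["t2"] = self.t2
        return out


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    m = int(np.ceil(level * n))
    m = max(2, min(m, n))
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def posterior_summary(samples: np.ndarray, level: float = 0.95) -> dict:
    """Posterior mean, sd, and HPD interval of one parameter's samples."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    sd = 0.0 if x.max() == x.min() else float(x.std(ddof=1))
    lo, hi = hpd_interval(x, level)
    return {
        "mean": float(x.mean()),
        "sd": sd,
        "hpd_low": lo,
        "hpd_high": hi,
        "degenerate": sd == 0.0,
    }


class ThresholdModel(BaseEstimator):
    """Threshold animal model fit by Gibbs sampling (sklearn-style).

    Parameters
    ----------
    n_iterations, burn_in, thin, seed :
        Chain settings; the stored sample count is
        floor((n_iterations - burn_in) / thin).
    n_categories :
        2 (binary) or 3 (ordinal); with 3 the upper threshold is sampled.
    prior :
        "uniform_h2" (default; proper, neutral on the heritability),
        "flat_variance" (improper; only safe with replicated records), or
        "scaled_inv_chi2" with hyperparameters ``prior_nu``/``prior_scale``.
    sigma_a2_init :
        Starting additive variance (h2 of 0.2 by default).
    fix_sigma_a2 :
        If set, the variance is held at this value instead of sampled.

    Attributes (after ``fit``)
    --------------------------
    chain_ : PosteriorChain
    h2_samples_, sigma_a2_samples_, t2_samples_ : thinned sample arrays
    h2_mean_, sigma_a2_mean_ : posterior means
    breeding_values_ : DataFrame (animal, mean, sd) over all pedigree animals
    """

    def __init__(self, n_iterations: int = 500_000, burn_in: int = 50_000,
                 thin: int = 50, seed: int = 0, n_categories: int = 2,
                 prior: str = "uniform_h2", prior_nu: float = -2.0,
                 prior_scale: float = 0.0, sigma_a2_init: float = 0.25,
                 fix_sigma_a2: float | None = None):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.n_categories = n_categories
        self.prior = prior
        self.prior_nu = prior_nu
        self.prior_scale = prior_scale
        self.sigma_a2_init = sigma_a2_init
        self.fix_sigma_a2 = fix_sigma_a2

    # -- helpers ----------------------------------------------------------
    def _config(self) -> GibbsConfig:
        return GibbsConfig(self.n_iterations, self.burn_in, self.thin,
                           self.seed, self.prior, self.prior_nu,
                           self.prior_scale)

    def _prior_code(self) -> tuple[int, float, float]:
        if self.prior == "uniform_h2":
            return 1, 0.0, 0.0
        if self.prior == "flat_variance":
            return 0, -2.0, 0.0
        if self.prior == "scaled_inv_chi2":
            return 0, float(self.prior_nu), float(self.prior_scale)
        raise ValueError(f"unknown prior {self.prior!r}")

    @staticmethod
    def _group_csr(codes: np.ndarray, n_groups: int):
        order = np.argsort(codes, kind="stable").astype(np.int64)
        counts = np.bincount(codes, minlength=n_groups)
        ptr = np.zeros(n_groups + 1, dtype=np.int64)
        np.cumsum(counts, out=ptr[1:])
        return ptr, order

    def fit(self, phenotypes: pd.DataFrame, h_inv: HInverseParts,
            pedigree: Pedigree, liabilities: np.ndarray | None = None):
        """Run the chain.

        ``phenotypes`` needs columns animal, trait and cg_id (qc output).
        ``liabilities`` switches off liability sampling and conditions on
        the given continuous values (the model then reduces to a Gaussian
        animal model — used for validation).
        """
        config = self._config()
        if self.n_categories not in (2, 3):
            raise ValueError("n_categories must be 2 or 3")
        cat = phenotypes["trait"].to_numpy(np.int64)
        if cat.min() < 0 or cat.max() >= self.n_categories:
            raise ValueError("trait categories outside the declared range")
        sample_t2 = self.n_categories == 3
        if sample_t2 and liabilities is None:
            present = set(np.unique(cat))
            if present != {0, 1, 2}:
                raise ValueError(
                    f"ordinal model needs all 3 categories present, saw {sorted(present)}")

        rec_animal = pedigree.indices(phenotypes["animal"])
        if h_inv.n_animals != pedigree.n_animals:
            raise ValueError("H-inverse dimension does not match pedigree")
        cg_codes, cg_labels = pd.factorize(phenotypes["cg_id"])
        cg_codes = cg_codes.astype(np.int64)
        n_cg = len(cg_labels)
        n_an = pedigree.n_animals

        an_ptr, an_rec = self._group_csr(rec_animal, n_an)
        cg_ptr, cg_rec = self._group_csr(cg_codes, n_cg)
        nrec = np.bincount(rec_animal, minlength=n_an).astype(np.float64)

        h = h_inv.to_sparse().tocsr()
        h.sort_indices()

        freqs = np.bincount(cat, minlength=self.n_categories) / len(cat)
        t1 = 0.0
        if sample_t2:
            t2_init = float(norm.ppf(min(freqs[0] + freqs[1], 1 - 1e-6))
                            - norm.ppf(max(freqs[0], 1e-6)))
            t2_init = max(t2_init, 0.1)
        else:
            t2_init = np.inf

        if liabilities is not None:
            y0 = np.asarray(liabilities, dtype=np.float64).copy()
            if len(y0) != len(cat):
                raise ValueError("liabilities length must match record count")
            sample_liab = False
        else:
            mids = {0: t1 - 0.5, 1: (t1 + t2_init) / 2 if sample_t2 else t1 + 0.5,
                    2: t2_init + 0.5}
            y0 = np.array([mids[c] for c in cat], dtype=np.float64)
            sample_liab = True

        sample_var = self.fix_sigma_a2 is None
        sigma_a2_init = (self.sigma_a2_init if sample_var
                         else float(self.fix_sigma_a2))

        prior_kind, nu, s_prior = self._prior_code()
        (sig, t2s, a_sum, a_sumsq, y_final, beta, a_final, stored,
         t2_at_y) = run_chain_kernel(
            int(self.seed) & 0x7FFFFFFF, int(self.n_iterations),
            int(self.burn_in), int(self.thin),
            rec_animal, cg_codes, cat, y0,
            an_ptr, an_rec, cg_ptr, cg_rec, nrec,
            h.indptr.astype(np.int64), h.indices.astype(np.int64),
            h.data.astype(np.float64),
            t1, t2_init, sample_t2,
            prior_kind, nu, s_prior, sigma_a2_init,
            sample_liab, sample_var)
        if stored != config.n_samples:  # pragma: no cover - kernel contract
            raise AssertionError("stored sample count does not match config")

        n_s = stored
        a_mean = a_sum / n_s
        a_var = np.maximum(a_sumsq / n_s - a_mean**2, 0.0)
        bv = pd.DataFrame({"animal": pedigree.animal_ids, "mean": a_mean,
                           "sd": np.sqrt(a_var)})
        self.chain_ = PosteriorChain(
            sigma_a2=sig, h2=sig / (sig + 1.0),
            t2=t2s if sample_t2 else None,
            breeding_values=bv, config=config)
        self.sigma_a2_samples_ = sig
        self.h2_samples_ = self.chain_.h2
        self.t2_samples_ = self.chain_.t2
        self.sigma_a2_mean_ = float(sig.mean())
        self.h2_mean_ = float(self.chain_.h2.mean())
        self.breeding_values_ = bv
        self.final_state_ = {"y": y_final, "beta": beta, "a": a_final,
                             "cat": cat, "t1": t1,
                             "t2": float(t2_at_y) if sample_t2 else np.inf}
        if sample_liab:
            self._check_category_concordance()
        return self

    def _check_category_concordance(self) -> None:
        """Every record's final liability must lie in its category interval."""
        st = self.final_state_
        y, cat = st["y"], st["cat"]
        t1, t2 = st["t1"], st["t2"]
        bad = ((cat == 0) & (y > t1)) | ((cat == self.n_categories - 1)
                                         & (y < (t2 if self.n_categories == 3 else t1)))
        if self.n_categories == 3:
            bad |= (cat == 1) & ((y < t1) | (y > t2))
        if bad.any():
            raise AssertionError(
                f"{int(bad.sum())} liabilities inconsistent with their category")

    def predict(self, animal_ids) -> np.ndarray:
        """Posterior-mean breeding values for the given animals."""
        bv = self.breeding_values_.set_index("animal")["mean"]
        return bv.loc[list(animal_ids)].to_numpy()

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = {"sigma_a2": posterior_summary(self.sigma_a2_samples_, level),
                "h2": posterior_summary(self.h2_samples_, level)}
        if self.t2_samples_ is not None:
            rows["t2"] = posterior_summary(self.t2_samples_, level)
        return pd.DataFrame(rows).T


def run_chain(phenotypes: pd.DataFrame, h_inv: HInverseParts,
              pedigree: Pedigree, config: GibbsConfig = GibbsConfig(),
              n_categories: int = 2) -> PosteriorChain:
    """Functional wrapper over :class:`ThresholdModel`."""
    model = ThresholdModel(config.n_iterations, config.burn_in, config.thin,
                           config.seed, n_categories, config.prior,
                           config.prior_nu, config.prior_scale)
    model.fit(phenotypes, h_inv, pedigree)
    return model.chain_
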