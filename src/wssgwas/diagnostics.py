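"""MCMC convergence diagnostics: Geweke z-test and effective sample size.

The Geweke statistic compares the means of an early window (first 10% by
default) and a late window (last 50%) of a chain,

    z = (m1 - m2) / sqrt(s1/n1 + s2/n2),

where s1, s2 are spectral densities at frequency zero estimated within each
window by an autoregressive fit whose order is picked by AIC (the approach
of the classic Bayesian output-analysis packages). ESS divides the chain
length by the integrated autocorrelation time, with the autocorrelation sum
truncated by Geyer's initial-positive-sequence rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.regression.linear_model import yule_walker


@dataclass
class ChainDiagnostics:
    parameter: str
    geweke_z: float
    geweke_p: float
    ess: float

    def to_row(self) -> dict:
        return {"parameter": self.parameter, "geweke_z": self.geweke_z,
                "geweke_p": self.geweke_p, "ess": self.ess}


def spectral_density_zero(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density at frequency 0 via an AIC-selected AR(p) fit:
    s(0) = sigma2 / (1 - sum(phi))^2."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("window too short for a spectral estimate")
    if x.std() == 0.0:
        raise ValueError("constant chain: spectral density undefined")
    if max_order is None:
        max_order = min(20, n // 10)
    xc = x - x.mean()
    best = (np.inf, None)
    var0 = float(xc.var())
    for p in range(0, max_order + 1):
        if p == 0:
            sigma2, rho = var0, np.array([])
        else:
            rho, sigma = yule_walker(xc, order=p, method="mle")
            sigma2 = float(sigma**2)
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2.0 * (p + 1)
        if aic < best[0]:
            best = (aic, (sigma2, rho))
    sigma2, rho = best[1]
    denom = (1.0 - rho.sum()) ** 2 if len(rho) else 1.0
    if denom <= 0:
        raise ValueError("explosive AR fit: spectral density undefined")
    return sigma2 / denom


def geweke_z(samples: np.ndarray, frac_first: float = 0.1,
             frac_last: float = 0.5) -> tuple[float, float]:
    """Geweke convergence z-score and its two-sided normal p-value."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need a chain of at least 100 samples")
    n1 = int(np.floor(frac_first * n))
    n2 = int(np.floor(frac_last * n))
    if n1 < 10 or n2 < 10:
        raise ValueError("window fractions leave too few samples")
    first, last = x[:n1], x[n - n2:]
    if first.std() == 0.0 or last.std() == 0.0:
        raise ValueError("constant window: Geweke diagnostic undefined")
    s1 = spectral_density_zero(first)
    s2 = spectral_density_zero(last)
    z = (first.mean() - last.mean()) / np.sqrt(s1 / n1 + s2 / n2)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS = N / (1 + 2 sum rho_k) with the autocorrelation sum evaluated
    through the spectral density at zero, s(0)/var(x) = 1 + 2 sum rho_k,
    using the same AIC-selected autoregressive fit as the Geweke windows
    (the estimator of the classic Bayesian-output-analysis packages).
    Capped at the chain length."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need a chain of at least 10 samples")
    if x.std() == 0.0:
        raise ValueError("constant chain: ESS undefined")
    s0 = spectral_density_zero(x)
    ess = n * float(x.var()) / s0
    return float(min(ess, float(n)))


def diagnose_chain(samples: np.ndarray, parameter: str = "",
                   frac_first: float = 0.1, frac_last: float = 0.5,
                   ) -> ChainDiagnostics:
    z, p = geweke_z(samples, frac_first, frac_last)
    return ChainDiagnostics(parameter, z, p, effective_sample_size(samples))


def diagnostics_table(chains: dict[str, np.ndarray]) -> pd.DataFrame:
    """Geweke z/p and ESS for each named parameter chain."""
    return pd.DataFrame([diagnose_chain(v, k).to_row()
                         for k, v in chains.items()])
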