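"""Stationary abundance distribution under the neutral model.

At equilibrium the Wright-Fisher diffusion with immigration
dX = lambda (p - X) dtau + sqrt(2 X (1 - X)) dW has a Beta stationary
law with shape parameters (lambda p, lambda (1 - p)): mean p and
variance p (1 - p) / (lambda + 1).  A taxon's predicted abundance band
can therefore be read off the fitted lambda_i and p_i and compared with
the observed abundance histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BetaPrediction", "stationary_beta", "equilibrium_check"]


@dataclass
class BetaPrediction:
    """Predicted stationary Beta law for one taxon's relative abundance."""

    taxon_id: str
    alpha: float  # lambda * p
    beta: float  # lambda * (1 - p)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s**2 * (s + 1.0))

    def pdf(self, x):
        return stats.beta.pdf(x, self.alpha, self.beta)

    def cdf(self, x):
        return stats.beta.cdf(x, self.alpha, self.beta)

    def ppf(self, q):
        return stats.beta.ppf(q, self.alpha, self.beta)


def stationary_beta(
    lambda_i: float, p_i: float, taxon_id: str = ""
) -> BetaPrediction:
    """Stationary Beta(lambda p, lambda (1 - p)) prediction for one taxon."""
    if lambda_i <= 0:
        raise ValueError(
            f"lambda must be positive for a stationary prediction, got {lambda_i}"
        )
    if not 0.0 < p_i < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p_i}")
    return BetaPrediction(
        taxon_id=taxon_id, alpha=lambda_i * p_i, beta=lambda_i * (1.0 - p_i)
    )


def equilibrium_check(
    observed_X: np.ndarray,
    pred: BetaPrediction,
    *,
    band: tuple[float, float] = (0.025, 0.975),
) -> dict:
    """Compare observed abundances with the predicted stationary law.

    Returns the Kolmogorov-Smirnov distance between the empirical
    distribution of the observations (boundary values 0 and 1 excluded,
    with the exclusion count reported) and the predicted Beta CDF,
    plus the predicted central abundance band for monitoring use.
    """
    x = np.asarray(observed_X, dtype=float)
    interior = x[(x > 0.0) & (x < 1.0)]
    n_excluded = len(x) - len(interior)
    if len(interior) < 10:
        raise ValueError(
            f"need >= 10 interior observations, got {len(interior)}"
        )
    ks = stats.kstest(interior, pred.cdf)
    lo, hi = pred.ppf(band[0]), pred.ppf(band[1])
    return {
        "taxon_id": pred.taxon_id,
        "ks_distance": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_obs": int(len(interior)),
        "n_excluded": int(n_excluded),
        "band_lower": float(lo),
        "band_upper": float(hi),
    }
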