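"""Nucleotide substitution models: JC69 and GTR+Gamma.

Branch lengths are expected substitutions per site, so every rate matrix is
normalized to one expected substitution per site per unit length at
stationarity.  GTR+Gamma uses the discrete-gamma approximation with
equal-probability categories and mean-of-bin category rates, the de-facto
standard of ML phylogenetics programs.

The random-parameter scheme (:func:`sample_gtr_params`) draws, per
replicate, base frequencies from Dirichlet(1,1,1,1), six exchangeabilities
i.i.d. LogNormal(0, 1) normalized by the G-T rate, and a gamma shape from
Normal(0.5, sd 0.1) truncated to positive values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "BASES",
    "JCModel",
    "GTRGammaModel",
    "jc_match_prob",
    "transition_matrix",
    "sample_gtr_params",
    "discrete_gamma_rates",
]

BASES = "ACGT"


def jc_match_prob(t: float) -> float:
    """Probability that two nucleotide states separated by branch length
    ``t`` are identical under JC69: 1/4 + 3/4 * exp(-4 t / 3).

    The complementary probability is split equally among the three other
    bases.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    return 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean-of-bin discrete-gamma category rates (mean exactly 1).

    The Gamma(alpha, mean 1) density is cut at its ``k/ncat`` quantiles and
    each category is assigned the conditional mean of its bin.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    if ncat == 1:
        return np.ones(1)
    # quantile boundaries of Gamma(shape=alpha, scale=1/alpha)
    probs = np.arange(1, ncat) / ncat
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([cuts, [np.inf]])
    lower = np.concatenate([[0.0], cuts])
    # E[X; a<X<b] for X~Gamma(alpha, 1/alpha) is I(alpha+1, alpha*b) - I(alpha+1, alpha*a)
    mass = gammainc(alpha + 1.0, alpha * upper) - gammainc(alpha + 1.0, alpha * lower)
    rates = ncat * mass
    return rates / rates.mean()  # remove last-digit drift


@dataclass(frozen=True)
class JCModel:
    """Jukes–Cantor model: equal base frequencies and exchange rates."""

    @property
    def pi(self) -> np.ndarray:
        return np.full(4, 0.25)

    @property
    def category_rates(self) -> np.ndarray:
        return np.ones(1)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        if t < 0 or rate <= 0 or not np.isfinite(t) or not np.isfinite(rate):
            raise ValueError("need finite t >= 0 and rate > 0")
        match = jc_match_prob(t * rate)
        off = (1.0 - match) / 3.0
        p = np.full((4, 4), off)
        np.fill_diagonal(p, match)
        return p

    def transition_matrices(self, t: float, rates) -> np.ndarray:
        """Stack of transition matrices, one per rate multiplier."""
        rates = np.asarray(rates, dtype=float)
        match = 0.25 + 0.75 * np.exp(-4.0 * t * rates / 3.0)
        off = (1.0 - match) / 3.0
        p = np.repeat(off[:, None, None], 4, axis=1).repeat(4, axis=2)
        idx = np.arange(4)
        p[:, idx, idx] = match[:, None]
        return p

    def to_config(self) -> dict:
        return {"model": "JC"}


class GTRGammaModel:
    """General time-reversible model with discrete-gamma rate variation.

    Parameters
    ----------
    pi:
        Stationary base frequencies in ACGT order (sum 1).
    rates:
        Six exchangeabilities in the order AC, AG, AT, CG, CT, GT.
    alpha:
        Gamma shape of among-site rate variation.
    ncat:
        Number of discrete-gamma categories (default 4).

    The rate matrix satisfies detailed balance and is scaled so the mean
    substitution rate at stationarity is 1.
    """

    def __init__(self, pi, rates, alpha: float, ncat: int = 4):
        pi = np.asarray(pi, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must be 4 frequencies summing to 1")
        if rates.shape != (6,) or np.any(rates <= 0):
            raise ValueError("need 6 positive exchangeability rates")
        if not np.isfinite(alpha) or alpha <= 0:
            raise ValueError("gamma shape must be finite and > 0")
        self.pi = pi / pi.sum()
        self.rates = rates
        self.alpha = float(alpha)
        self.ncat = int(ncat)
        self.category_rates = discrete_gamma_rates(self.alpha, self.ncat)

        q = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(rates, idx):
            q[i, j] = r * self.pi[j]
            q[j, i] = r * self.pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(q))  # expected rate at stationarity
        q /= mu
        self.Q = q
        # symmetrize for a stable eigendecomposition: B = D^{1/2} Q D^{-1/2}
        sqrt_pi = np.sqrt(self.pi)
        b = q * sqrt_pi[:, None] / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        # P(t) = D^{-1/2} V exp(L t) V' D^{1/2} with D = diag(pi)
        self._eigval = eigval
        self._right = eigvec / sqrt_pi[:, None]
        self._left = eigvec.T * sqrt_pi[None, :]

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        if t < 0 or rate <= 0 or not np.isfinite(t) or not np.isfinite(rate):
            raise ValueError("need finite t >= 0 and rate > 0")
        expl = np.exp(self._eigval * t * rate)
        p = (self._right * expl[None, :]) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_matrices(self, t: float, rates) -> np.ndarray:
        """Stack of transition matrices, one per rate multiplier."""
        rates = np.asarray(rates, dtype=float)
        expl = np.exp(self._eigval[None, :] * (t * rates)[:, None])
        p = (self._right[None, :, :] * expl[:, None, :]) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p

    def to_config(self) -> dict:
        return {
            "model": "GTR+G",
            "pi": self.pi.tolist(),
            "rates": self.rates.tolist(),
            "alpha": self.alpha,
            "ncat": self.ncat,
        }

    @classmethod
    def from_config(cls, config: dict) -> "GTRGammaModel":
        return cls(config["pi"], config["rates"], config["alpha"], config.get("ncat", 4))

    def to_json(self) -> str:
        return json.dumps(self.to_config())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<GTRGammaModel alpha={self.alpha:.3f} pi={np.round(self.pi, 3).tolist()}>"


def transition_matrix(model, t: float, rate: float = 1.0) -> np.ndarray:
    """Transition probability matrix P(t * rate) for a JC or GTR+Gamma
    model; rows sum to 1 and P(0) is the identity."""
    return model.transition_matrix(t, rate)


def sample_gtr_params(rng: np.random.Generator, ncat: int = 4, min_freq: float = 1e-6) -> GTRGammaModel:
    """Draw a random GTR+Gamma model for one simulation replicate.

    Base frequencies ~ Dirichlet(1,1,1,1) (floored at ``min_freq`` for
    numerical safety and renormalized); exchangeabilities i.i.d.
    LogNormal(0,1) divided by the G-T rate; gamma shape ~ Normal(0.5, 0.1)
    redrawn until positive.
    """
    pi = rng.dirichlet(np.ones(4))
    pi = np.maximum(pi, min_freq)
    pi /= pi.sum()
    rates = rng.lognormal(mean=0.0, sigma=1.0, size=6)
    rates /= rates[-1]
    alpha = rng.normal(0.5, 0.1)
    while alpha <= 0:
        alpha = rng.normal(0.5, 0.1)
    return GTRGammaModel(pi, rates, alpha, ncat=ncat)
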