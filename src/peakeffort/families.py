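"""Exponential-family response distributions for the mixed-model engine.

Each family supplies the pieces penalized IRLS and the Laplace
approximation need: the conditional log-likelihood, the inverse link,
Fisher-scoring working weights and working responses, and a simulator for
the parametric bootstrap. Dispersion-like quantities (the Gaussian residual
SD ``sigma``, the negative-binomial size ``theta``) are passed through
``aux`` so the outer optimizer can treat them as free parameters.

Negative binomial uses the NB2 parameterization: Var(y) = mu + mu^2/theta,
with ``theta`` reported as the dispersion parameter (larger theta = closer
to Poisson).
"""

from __future__ import annotations

import numpy as np
from scipy import special

_ETA_MAX = 30.0  # clamp linear predictors; exp(30) ~ 1e13 is already absurd


def _clip_eta(eta: np.ndarray) -> np.ndarray:
    return np.clip(eta, -_ETA_MAX, _ETA_MAX)


class Family:
    name: str = ""
    link: str = ""
    has_sigma = False   # Gaussian residual SD estimated in the outer optimizer
    has_theta = False   # NB size parameter estimated in the outer optimizer

    def mean(self, eta): ...
    def loglik(self, y, eta, aux): ...
    def weights(self, mu, aux): ...
    def working_response(self, y, eta, mu): ...
    def simulate(self, rng, eta, aux): ...


class Poisson(Family):
    name = "poisson"
    link = "log"

    def mean(self, eta):
        return np.exp(_clip_eta(eta))

    def loglik(self, y, eta, aux):
        eta = _clip_eta(eta)
        return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1.0)))

    def weights(self, mu, aux):
        return np.maximum(mu, 1e-10)

    def working_response(self, y, eta, mu):
        return eta + (y - mu) / np.maximum(mu, 1e-10)

    def simulate(self, rng, eta, aux):
        return rng.poisson(self.mean(eta))


class NegativeBinomial(Family):
    name = "negative_binomial"
    link = "log"
    has_theta = True

    def mean(self, eta):
        return np.exp(_clip_eta(eta))

    def loglik(self, y, eta, aux):
        theta = aux["theta"]
        mu = self.mean(eta)
        y = np.asarray(y, dtype=float)
        if theta > 1e4 and np.all(y == np.floor(y)):
            # large-theta regime: gammaln(y+theta)-gammaln(theta) cancels
            # catastrophically; for integer counts use the exact rising
            # factorial sum log prod_{k<y}(theta+k), and log1p for the
            # theta*log(theta/(theta+mu)) term
            yi = y.astype(int)
            ks = np.arange(max(yi.max(), 1))
            csum = np.concatenate([[0.0], np.cumsum(np.log(theta + ks))])
            comb = csum[yi]
        else:
            comb = special.gammaln(y + theta) - special.gammaln(theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            ylog = np.where(y > 0, y * (np.log(mu) - np.log(mu + theta)), 0.0)
        return float(np.sum(
            comb - special.gammaln(y + 1.0) + ylog
            - theta * np.log1p(mu / theta)
        ))

    def weights(self, mu, aux):
        theta = aux["theta"]
        mu = np.maximum(mu, 1e-10)
        # (dmu/deta)^2 / Var = mu^2 / (mu + mu^2/theta)
        return mu * theta / (mu + theta)

    def working_response(self, y, eta, mu):
        return eta + (y - mu) / np.maximum(mu, 1e-10)

    def simulate(self, rng, eta, aux):
        theta = aux["theta"]
        mu = self.mean(eta)
        return rng.poisson(rng.gamma(theta, mu / theta))


class Binomial(Family):
    """Bernoulli (0/1 response) with logit link — the peak-year and
    mast-peak models are binary, so single-trial suffices."""

    name = "binomial"
    link = "logit"

    def mean(self, eta):
        return special.expit(_clip_eta(eta))

    def loglik(self, y, eta, aux):
        eta = _clip_eta(eta)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def weights(self, mu, aux):
        return np.maximum(mu * (1.0 - mu), 1e-10)

    def working_response(self, y, eta, mu):
        return eta + (y - mu) / np.maximum(mu * (1.0 - mu), 1e-10)

    def simulate(self, rng, eta, aux):
        return rng.binomial(1, self.mean(eta))


class Gaussian(Family):
    name = "gaussian"
    link = "identity"
    has_sigma = True

    def mean(self, eta):
        return eta

    def loglik(self, y, eta, aux):
        s2 = aux["sigma"] ** 2
        r = y - eta
        return float(-0.5 * np.sum(r * r / s2 + np.log(2.0 * np.pi * s2)))

    def weights(self, mu, aux):
        return np.full_like(np.asarray(mu, dtype=float), 1.0 / aux["sigma"] ** 2)

    def working_response(self, y, eta, mu):
        return y

    def simulate(self, rng, eta, aux):
        return rng.normal(eta, aux["sigma"])


FAMILIES: dict[str, Family] = {
    f.name: f for f in (Poisson(), NegativeBinomial(), Binomial(), Gaussian())
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
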