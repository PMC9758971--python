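"""Count error distributions for log-link mixed models.

Three families are supported, named after the mean-variance relationship
they impose:

``poisson``
    variance = mu (equidispersion).
``nbinom1``
    variance = phi * mu, phi > 1 — a negative binomial with a *linear*
    mean-variance relationship (the "quasi-Poisson" shape).
``nbinom2``
    variance = mu + mu**2 / theta, theta > 0 — the classical negative
    binomial with a *quadratic* mean-variance relationship.

Both negative binomials are Gamma-Poisson mixtures; they differ only in how
the Gamma shape tracks the mean.  NB1 uses shape r = mu / (phi - 1) and
success probability p = 1 / phi, which yields variance phi * mu exactly.
NB2 uses shape r = theta and p = theta / (theta + mu).

A :class:`ZeroInflated` wrapper mixes any base family with a point mass at
zero: P(y = 0) = pi + (1 - pi) * f(0 | mu), P(y = k) = (1 - pi) * f(k | mu)
for k > 0.  ``pi`` is per-observation and logit-linked in the fitting code.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, psi


def _trigamma(x):
    """Vectorized trigamma via recurrence + asymptotic series.

    Accurate to ~1e-12 for x > 0; avoids scipy's slow generic polygamma
    path, which dominates NB1 fitting time otherwise.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    xs = x.copy()
    # shift arguments above 6 where the asymptotic series converges fast
    for _ in range(6):
        small = xs < 6.0
        if not small.any():
            break
        out = np.where(small, out + 1.0 / (xs * xs), out)
        xs = np.where(small, xs + 1.0, xs)
    z = 1.0 / (xs * xs)
    series = (
        1.0 / xs + 0.5 * z
        + z / xs * (1.0 / 6.0 - z * (1.0 / 30.0 - z * (1.0 / 42.0 - z / 30.0)))
    )
    return out + series

__all__ = [
    "CountFamily",
    "Poisson",
    "NB1",
    "NB2",
    "ZeroInflated",
    "family_by_name",
    "FAMILY_NAMES",
]

FAMILY_NAMES = ("poisson", "nbinom1", "nbinom2")


def _check_mu(mu):
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be strictly positive and finite")
    return mu


def _check_y(y):
    y = np.asarray(y)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    return y.astype(float)


class CountFamily:
    """Base class: a count distribution parameterized by its mean."""

    name: str = ""
    #: number of dispersion parameters estimated alongside the mean model
    n_dispersion: int = 0

    def log_pmf(self, y, mu):  # pragma: no cover - abstract
        raise NotImplementedError

    def variance(self, mu):  # pragma: no cover - abstract
        raise NotImplementedError

    def simulate(self, mu, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    # dispersion lives on an unconstrained scale inside the optimizer
    def dispersion_from_unconstrained(self, raw: float) -> "CountFamily":
        return self

    def unconstrained_from_dispersion(self) -> list[float]:
        return []

    def dispersion_dict(self) -> dict:
        return {}

    def __repr__(self):
        d = self.dispersion_dict()
        inner = ", ".join(f"{k}={v:.4g}" for k, v in d.items())
        return f"{type(self).__name__}({inner})"


class Poisson(CountFamily):
    name = "poisson"
    n_dispersion = 0

    def log_pmf(self, y, mu):
        y, mu = _check_y(y), _check_mu(mu)
        return self._log_pmf_raw(y, mu, gammaln(y + 1.0))

    def _log_pmf_raw(self, y, mu, lgy1):
        # validation-free path for inner-loop likelihood evaluation
        return y * np.log(mu) - mu - lgy1

    def variance(self, mu):
        return np.asarray(mu, dtype=float)

    def simulate(self, mu, rng):
        return rng.poisson(_check_mu(mu))

    def db_derivatives(self, y, mu):
        """(d/db, d2/db2) of log pmf where mu = exp(eta + b)."""
        return y - mu, -mu

    def d_disp_raw(self, y, mu):
        return None


class NB1(CountFamily):
    """Negative binomial, linear mean-variance: var = phi * mu."""

    name = "nbinom1"
    n_dispersion = 1

    def __init__(self, phi: float = 2.0):
        if not np.isfinite(phi) or phi <= 1.0:
            raise ValueError("NB1 dispersion phi must be > 1")
        self.phi = float(phi)

    def _shape(self, mu):
        return mu / (self.phi - 1.0)

    def log_pmf(self, y, mu):
        y, mu = _check_y(y), _check_mu(mu)
        return self._log_pmf_raw(y, mu, gammaln(y + 1.0))

    def _log_pmf_raw(self, y, mu, lgy1):
        r = self._shape(mu)
        p = 1.0 / self.phi
        return (
            gammaln(y + r)
            - gammaln(r)
            - lgy1
            + r * np.log(p)
            + y * np.log1p(-p)
        )

    def variance(self, mu):
        return self.phi * np.asarray(mu, dtype=float)

    def simulate(self, mu, rng):
        mu = _check_mu(mu)
        return rng.negative_binomial(self._shape(mu), 1.0 / self.phi)

    def db_derivatives(self, y, mu):
        # r = mu/(phi-1) so dr/db = r; chain rule through gammaln terms
        r = self._shape(mu)
        core = psi(y + r) - psi(r) - np.log(self.phi)
        d1 = core * r
        d2 = core * r + (_trigamma(y + r) - _trigamma(r)) * r * r
        return d1, d2

    def d_disp_raw(self, y, mu):
        """d log pmf / d log(phi - 1), the unconstrained dispersion scale."""
        phi = self.phi
        r = self._shape(mu)
        core = psi(y + r) - psi(r) - np.log(phi)
        dldphi = (
            core * (-r / (phi - 1.0))
            - r / phi
            + y * (1.0 / (phi - 1.0) - 1.0 / phi)
        )
        return dldphi * (phi - 1.0)

    def dispersion_from_unconstrained(self, raw):
        return NB1(phi=1.0 + np.exp(raw))

    def unconstrained_from_dispersion(self):
        return [float(np.log(self.phi - 1.0))]

    def dispersion_dict(self):
        return {"phi": self.phi}


class NB2(CountFamily):
    """Negative binomial, quadratic mean-variance: var = mu + mu**2/theta."""

    name = "nbinom2"
    n_dispersion = 1

    def __init__(self, theta: float = 1.0):
        if not np.isfinite(theta) or theta <= 0.0:
            raise ValueError("NB2 dispersion theta must be > 0")
        self.theta = float(theta)

    def log_pmf(self, y, mu):
        y, mu = _check_y(y), _check_mu(mu)
        return self._log_pmf_raw(y, mu, gammaln(y + 1.0))

    def _log_pmf_raw(self, y, mu, lgy1):
        t = self.theta
        return (
            gammaln(y + t)
            - gammaln(t)
            - lgy1
            + t * np.log(t / (t + mu))
            + y * np.log(mu / (t + mu))
        )

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu + mu * mu / self.theta

    def simulate(self, mu, rng):
        mu = _check_mu(mu)
        t = self.theta
        return rng.negative_binomial(t, t / (t + mu))

    def db_derivatives(self, y, mu):
        t = self.theta
        d1 = y - (y + t) * mu / (t + mu)
        d2 = -(y + t) * t * mu / (t + mu) ** 2
        return d1, d2

    def d_disp_raw(self, y, mu):
        """d log pmf / d log(theta)."""
        t = self.theta
        dldt = (
            psi(y + t) - psi(t)
            + np.log(t / (t + mu))
            + 1.0
            - (y + t) / (t + mu)
        )
        return dldt * t

    def dispersion_from_unconstrained(self, raw):
        return NB2(theta=np.exp(raw))

    def unconstrained_from_dispersion(self):
        return [float(np.log(self.theta))]

    def dispersion_dict(self):
        return {"theta": self.theta}


class ZeroInflated:
    """Mixture of a point mass at zero and a base count family.

    pi is the per-observation probability of a structural zero.
    """

    def __init__(self, base: CountFamily):
        self.base = base
        self.name = "zi_" + base.name

    @staticmethod
    def _check_pi(pi):
        pi = np.asarray(pi, dtype=float)
        if np.any(pi < 0) or np.any(pi >= 1):
            raise ValueError("pi must lie in [0, 1)")
        return pi

    def log_pmf(self, y, mu, pi):
        y = np.asarray(y)
        pi = self._check_pi(pi)
        base_lp = self.base.log_pmf(y, mu)
        pi, base_lp = np.broadcast_arrays(pi, base_lp)
        out = np.where(pi > 0, np.log1p(-pi), 0.0) + base_lp
        at_zero = np.asarray(y) == 0
        if np.any(at_zero):
            # log(pi + (1-pi) f(0|mu)), computed stably via logaddexp
            with np.errstate(divide="ignore"):
                log_pi = np.log(pi, where=pi > 0, out=np.full_like(pi, -np.inf))
            mix = np.logaddexp(log_pi, np.log1p(-pi) + base_lp)
            out = np.where(at_zero, mix, out)
        return out

    def simulate(self, mu, pi, rng):
        pi = self._check_pi(pi)
        y = self.base.simulate(mu, rng)
        structural = rng.random(np.shape(y)) < pi
        return np.where(structural, 0, y)


def family_by_name(name: str, **disp) -> CountFamily:
    """Construct a family from its workflow name.

    Dispersion keywords: ``phi`` for nbinom1, ``theta`` for nbinom2.
    """
    name = name.lower()
    if name == "poisson":
        return Poisson()
    if name == "nbinom1":
        return NB1(**({"phi": disp["phi"]} if "phi" in disp else {}))
    if name == "nbinom2":
        return NB2(**({"theta": disp["theta"]} if "theta" in disp else {}))
    raise ValueError(f"unknown family {name!r}; expected one of {FAMILY_NAMES}")
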