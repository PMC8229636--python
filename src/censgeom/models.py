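"""Exponential-family lifetime models in natural-parameter form.

A model here is a family ``f(x; theta) = exp{ sum_i alpha_i(theta) c_i(x) - psi(theta) }``
whose reliability (survival) function also has exponential form
``R(x; theta) = exp{ sum_i beta_i(theta) d_i(x) - phi_rel(theta) }``.  Under a
progressive Type-II censoring scheme the joint log-likelihood of the censored
order statistics is linear in the *natural statistics*

    e_i(x, R_r) = c_i(x) + R_r d_i(x)        (per free coordinate theta_i)

minus ``m * phi(theta)`` where the censored cumulant combines the density and
reliability cumulants, ``phi = psi + ((n - m)/m) * phi_rel``.  All geometric
quantities of the censored model reduce to derivatives of ``phi``.

Coordinates follow the lifetime-analysis convention in which the rate-type
parameter itself (e.g. lambda for the Rayleigh law ``f = 2 lambda x e^{-lambda x^2}``)
is the coordinate; it is an affine image of the canonical natural parameter, so
the e-connection still vanishes identically.

Built-ins: :class:`Rayleigh`, :class:`Exponential` (k = 1) and a two-parameter
:class:`GammaModel` used to exercise k = 2 geometry.  The Gamma reliability has
no exponential closed form, so it is restricted to schemes without removals.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from . import _fd
from .schemes import CensoringScheme

__all__ = [
    "ExponentialFamilyModel",
    "Rayleigh",
    "Exponential",
    "GammaModel",
    "get_model",
    "MODELS",
]


class DomainError(ValueError):
    """Parameter outside the model's open domain."""


class ExponentialFamilyModel:
    """Abstract natural-form lifetime model; see module docstring."""

    name: str = "abstract"
    k: int = 1
    #: open box (per-coordinate lower/upper bounds) of admissible theta
    theta_domain: tuple[tuple[float, float], ...] = ((0.0, np.inf),)
    #: support of the lifetime variable
    support: tuple[float, float] = (0.0, np.inf)
    #: whether the reliability function has the exponential (natural) form
    has_natural_reliability: bool = True

    # -- parameter handling -------------------------------------------------

    def check_theta(self, theta) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.shape != (self.k,):
            raise DomainError(
                f"{self.name}: theta must have {self.k} coordinate(s), got {theta.shape}"
            )
        for i, (lo, hi) in enumerate(self.theta_domain):
            if not (lo < theta[i] < hi) or not np.isfinite(theta[i]):
                raise DomainError(
                    f"{self.name}: theta[{i}]={theta[i]} outside open domain ({lo}, {hi})"
                )
        return theta

    # -- cumulants and statistics (override in subclasses) -------------------

    def psi(self, theta) -> float:
        raise NotImplementedError

    def phi_rel(self, theta) -> float:
        """Reliability cumulant; zero for the built-in k=1 laws."""
        return 0.0

    def density_stat(self, x) -> np.ndarray:
        """Natural statistics ``c_i(x)`` of the density, shape (k,) + x.shape."""
        raise NotImplementedError

    def reliability_stat(self, x) -> np.ndarray:
        """Natural statistics ``d_i(x)`` of the reliability function."""
        raise NotImplementedError

    def data_offset(self, x):
        """theta-free part of ``log f``; 0 unless overridden."""
        return np.zeros_like(np.asarray(x, dtype=float))

    def natural_stat(self, x, R) -> np.ndarray:
        """``e_i(x, R) = c_i(x) + R d_i(x)`` per free coordinate."""
        R = np.asarray(R)
        if not self.has_natural_reliability:
            if np.any(R != 0):
                raise ValueError(
                    f"{self.name}: reliability has no natural form; only schemes "
                    "with all removals R_r = 0 are supported"
                )
            return self.density_stat(x)
        return self.density_stat(x) + R * self.reliability_stat(x)

    # -- distribution functions ----------------------------------------------

    def log_density(self, x, theta):
        theta = self.check_theta(theta)
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        stat = self.density_stat(x)
        val = np.tensordot(theta, stat, axes=(0, 0)) + self.data_offset(x) - self.psi(theta)
        return np.where((x >= lo) & (x < hi), val, -np.inf)

    def density(self, x, theta):
        return np.exp(self.log_density(x, theta))

    def log_reliability(self, x, theta):
        theta = self.check_theta(theta)
        x = np.asarray(x, dtype=float)
        stat = self.reliability_stat(x)
        val = np.tensordot(theta, stat, axes=(0, 0)) - self.phi_rel(theta)
        lo, hi = self.support
        return np.where(x <= lo, 0.0, np.where(x >= hi, -np.inf, val))

    def reliability(self, x, theta):
        return np.exp(self.log_reliability(x, theta))

    def cdf(self, x, theta):
        return 1.0 - self.reliability(x, theta)

    def quantile(self, p, theta):
        raise NotImplementedError

    # -- censored cumulant ----------------------------------------------------

    def censored_cumulant(self, theta, scheme: CensoringScheme) -> float:
        """``phi(theta) = psi + ((n-m)/m) phi_rel`` so that m*phi is the joint
        normalizer ``m*psi + (n-m)*phi_rel``."""
        theta = self.check_theta(theta)
        w = (scheme.n - scheme.m) / scheme.m
        if w != 0.0 and not self.has_natural_reliability:
            raise ValueError(
                f"{self.name}: censored cumulant undefined for schemes with removals"
            )
        return float(self.psi(theta) + w * self.phi_rel(theta))

    # optional closed-form cumulant derivatives; return None to use finite
    # differences on the censored cumulant
    def dpsi(self, theta):
        return None

    def d2psi(self, theta):
        return None

    def d3psi(self, theta):
        return None

    def dphi_rel(self, theta):
        return np.zeros(self.k)

    def d2phi_rel(self, theta):
        return np.zeros((self.k, self.k))

    def d3phi_rel(self, theta):
        return np.zeros((self.k, self.k, self.k))

    def phi_derivatives(self, theta, scheme: CensoringScheme, order: int) -> np.ndarray:
        """Partial-derivative tensor of the censored cumulant phi.

        order 1 -> shape (k,), 2 -> (k, k), 3 -> (k, k, k).  Closed forms are
        used when the model supplies them; otherwise central finite differences
        with one Richardson extrapolation level.
        """
        theta = self.check_theta(theta)
        if order not in (1, 2, 3):
            raise ValueError(f"order must be 1, 2 or 3, got {order}")
        w = (scheme.n - scheme.m) / scheme.m
        closed = {1: self.dpsi, 2: self.d2psi, 3: self.d3psi}[order](theta)
        if closed is not None:
            rel = {1: self.dphi_rel, 2: self.d2phi_rel, 3: self.d3phi_rel}[order](theta)
            return np.asarray(closed, dtype=float) + w * np.asarray(rel, dtype=float)
        f = lambda t: self.censored_cumulant(t, scheme)
        self._check_fd_room(theta)
        if order == 1:
            return _fd.fd_gradient(f, theta)
        if order == 2:
            return _fd.fd_hessian(f, theta)
        return _fd.fd_third(f, theta)

    def psi_derivatives(self, theta, order: int) -> np.ndarray:
        """Partial derivatives of the density cumulant psi (closed form or FD)."""
        theta = self.check_theta(theta)
        if order not in (1, 2, 3):
            raise ValueError(f"order must be 1, 2 or 3, got {order}")
        closed = {1: self.dpsi, 2: self.d2psi, 3: self.d3psi}[order](theta)
        if closed is not None:
            return np.asarray(closed, dtype=float)
        self._check_fd_room(theta)
        f = lambda t: self.psi(t)
        return {1: _fd.fd_gradient, 2: _fd.fd_hessian, 3: _fd.fd_third}[order](f, theta)

    def _check_fd_room(self, theta: np.ndarray) -> None:
        h = 40.0 * _fd.fd_step(theta)  # widest stencil reach (third derivatives)
        for i, (lo, hi) in enumerate(self.theta_domain):
            if theta[i] - h[i] <= lo or theta[i] + h[i] >= hi:
                raise DomainError(
                    f"{self.name}: theta[{i}]={theta[i]} too close to the domain "
                    "boundary for the finite-difference stencil"
                )


class Rayleigh(ExponentialFamilyModel):
    """Rayleigh law ``f(x; lam) = 2 lam x exp(-lam x^2)``, coordinate theta = lam.

    Natural statistic ``e_1(x, R) = -(1 + R) x^2``; cumulants
    ``psi = -ln(2 lam)``, ``phi_rel = 0``.  ``X^2`` is exponential(lam), which
    drives the conjugate Gamma machinery used throughout.
    """

    name = "rayleigh"
    k = 1
    theta_domain = ((0.0, np.inf),)

    def psi(self, theta):
        return -np.log(2.0 * theta[0])

    def density_stat(self, x):
        x = np.asarray(x, dtype=float)
        return -(x**2)[None, ...]

    def reliability_stat(self, x):
        x = np.asarray(x, dtype=float)
        return -(x**2)[None, ...]

    def data_offset(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(x)

    def quantile(self, p, theta):
        theta = self.check_theta(theta)
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("p must lie in [0, 1)")
        return np.sqrt(-np.log1p(-p) / theta[0])

    def dpsi(self, theta):
        return np.array([-1.0 / theta[0]])

    def d2psi(self, theta):
        return np.array([[1.0 / theta[0] ** 2]])

    def d3psi(self, theta):
        return np.array([[[-2.0 / theta[0] ** 3]]])


class Exponential(ExponentialFamilyModel):
    """Exponential law ``f(x; lam) = lam exp(-lam x)``, coordinate theta = lam."""

    name = "exponential"
    k = 1
    theta_domain = ((0.0, np.inf),)

    def psi(self, theta):
        return -np.log(theta[0])

    def density_stat(self, x):
        x = np.asarray(x, dtype=float)
        return -x[None, ...]

    def reliability_stat(self, x):
        x = np.asarray(x, dtype=float)
        return -x[None, ...]

    def quantile(self, p, theta):
        theta = self.check_theta(theta)
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("p must lie in [0, 1)")
        return -np.log1p(-p) / theta[0]


class GammaModel(ExponentialFamilyModel):
    """Two-parameter Gamma law in natural-form coordinates.

    theta = (theta_1, theta_2) with rate b = theta_1 and shape a = theta_2 + 1:
    ``log f = -theta_1 x + theta_2 ln x - psi``,
    ``psi = ln Gamma(theta_2 + 1) - (theta_2 + 1) ln theta_1``.

    The reliability function involves an incomplete gamma integral with no
    exponential closed form, so censoring is unsupported: the model only
    accepts schemes with all removals zero (complete ordered samples).
    """

    name = "gamma"
    k = 2
    theta_domain = ((0.0, np.inf), (-1.0, np.inf))
    has_natural_reliability = False

    def psi(self, theta):
        b, t2 = theta
        return float(special.gammaln(t2 + 1.0) - (t2 + 1.0) * np.log(b))

    def density_stat(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            return np.stack([-x, np.log(x)])

    def reliability_stat(self, x):
        raise ValueError("gamma: reliability has no natural (exponential) form")

    def log_reliability(self, x, theta):
        theta = self.check_theta(theta)
        return stats.gamma.logsf(x, a=theta[1] + 1.0, scale=1.0 / theta[0])

    def cdf(self, x, theta):
        theta = self.check_theta(theta)
        return stats.gamma.cdf(x, a=theta[1] + 1.0, scale=1.0 / theta[0])

    def quantile(self, p, theta):
        theta = self.check_theta(theta)
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("p must lie in [0, 1)")
        return stats.gamma.ppf(p, a=theta[1] + 1.0, scale=1.0 / theta[0])

    def dpsi(self, theta):
        b, t2 = theta
        return np.array([-(t2 + 1.0) / b, special.digamma(t2 + 1.0) - np.log(b)])

    def d2psi(self, theta):
        b, t2 = theta
        return np.array(
            [
                [(t2 + 1.0) / b**2, -1.0 / b],
                [-1.0 / b, special.polygamma(1, t2 + 1.0)],
            ]
        )

    def d3psi(self, theta):
        b, t2 = theta
        out = np.zeros((2, 2, 2))
        out[0, 0, 0] = -2.0 * (t2 + 1.0) / b**3
        out[0, 0, 1] = out[0, 1, 0] = out[1, 0, 0] = 1.0 / b**2
        out[1, 1, 1] = special.polygamma(2, t2 + 1.0)
        return out


MODELS: dict[str, type[ExponentialFamilyModel]] = {
    "rayleigh": Rayleigh,
    "exponential": Exponential,
    "gamma": GammaModel,
}


def get_model(name: str) -> ExponentialFamilyModel:
    """Look up a built-in model by registry name."""
    try:
        return MODELS[name.lower()]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODELS)}") from None
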