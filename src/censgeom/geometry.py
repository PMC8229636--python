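"""Metric, skewness, connection, torsion and curvature tensors of the
censored-model manifold.

In the coordinates used here the censored joint likelihood is linear in the
natural statistics minus ``m * phi(theta)``, so every tensor reduces to
derivatives of the censored cumulant:

    g_ij        = m d_i d_j phi            (Fisher metric)
    T_ijk       = m d_i d_j d_k phi        (skewness tensor)
    Gamma_ijk   = 0                        (affine connection; theta is 1-affine)
    Gamma^a_ijk = ((1 - a) m / 2) d_i d_j d_k phi

Alongside the joint-likelihood tensors, a *marginal-informed* variant forms
the expectations ``h_{i,r} = E[e_i(x_{r:m:n})]`` under the exact marginal of
each censored order statistic and combines them into modified connection and
skewness tensors.  Because the marginals are the true ones, the totals obey
``h_i = m d_i phi`` (the score has mean zero), so the modified tensors vanish
identically — the collapse is computed and exposed rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import integrate

from . import _fd
from .models import ExponentialFamilyModel
from .sampling import marginal_pdf_rth
from .schemes import CensoringScheme

__all__ = [
    "GeometryTensors",
    "MarginalInformedTensors",
    "geometry_tensors",
    "metric_tensor",
    "skewness_tensor",
    "alpha_connection",
    "marginal_informed_connection",
    "collapse_double_sum",
    "collapse_double_sum_exact",
    "torsion_tensor",
    "torsion_of",
    "rc_curvature",
]


@dataclass(frozen=True)
class GeometryTensors:
    """Joint-likelihood geometric quantities at a parameter point."""

    theta: np.ndarray
    alpha: float
    g: np.ndarray          # (k, k) Fisher metric
    g_inv: np.ndarray      # (k, k)
    T: np.ndarray          # (k, k, k) skewness
    Gamma: np.ndarray      # (k, k, k) affine connection (zero here)
    Gamma_alpha: np.ndarray  # (k, k, k)
    T_contr: np.ndarray    # (k,)  T_i = T_ijk g^{jk}
    Gamma_alpha_mixed: np.ndarray  # (k, k, k)  Gamma^{a,l}_{ij} = Gamma^a_ijk g^{kl}


@dataclass(frozen=True)
class MarginalInformedTensors:
    """Tensors built from per-order-statistic marginal expectations."""

    theta: np.ndarray
    alpha: float
    h_r: np.ndarray        # (m, k) per-r expectations h_{i,r}
    h: np.ndarray          # (k,) totals
    m_dphi: np.ndarray     # (k,) m * d_i phi for comparison
    g: np.ndarray          # metric (unchanged)
    Gamma_tilde: np.ndarray        # (k, k, k)
    T_tilde: np.ndarray            # (k, k, k)
    Gamma_tilde_alpha: np.ndarray  # (k, k, k)


def metric_tensor(model: ExponentialFamilyModel, theta, scheme: CensoringScheme) -> np.ndarray:
    """Fisher metric ``g_ij = m d_i d_j phi``; must be symmetric positive definite."""
    g = scheme.m * model.phi_derivatives(theta, scheme, 2)
    _check_spd(g, theta)
    return g


def _check_spd(g: np.ndarray, theta) -> None:
    eig = np.linalg.eigvalsh(0.5 * (g + g.T))
    if np.any(eig <= 0):
        raise np.linalg.LinAlgError(
            f"Fisher metric not positive definite at theta={np.asarray(theta)}: "
            f"eigenvalues {eig}"
        )


def skewness_tensor(model: ExponentialFamilyModel, theta, scheme: CensoringScheme) -> np.ndarray:
    """Skewness tensor ``T_ijk = m d_i d_j d_k phi``; fully symmetric."""
    return scheme.m * model.phi_derivatives(theta, scheme, 3)


def geometry_tensors(
    model: ExponentialFamilyModel, theta, scheme: CensoringScheme, alpha: float = 0.0
) -> GeometryTensors:
    """All joint-likelihood tensors and contractions at one parameter point."""
    theta_v = model.check_theta(theta)
    k = model.k
    g = metric_tensor(model, theta_v, scheme)
    g_inv = np.linalg.inv(g)
    T = skewness_tensor(model, theta_v, scheme)
    Gamma = np.zeros((k, k, k))
    Gamma_alpha = Gamma + 0.5 * (1.0 - alpha) * T
    T_contr = np.einsum("ijk,jk->i", T, g_inv)
    Gamma_alpha_mixed = np.einsum("ijk,kl->ijl", Gamma_alpha, g_inv)
    return GeometryTensors(
        theta=theta_v, alpha=alpha, g=g, g_inv=g_inv, T=T, Gamma=Gamma,
        Gamma_alpha=Gamma_alpha, T_contr=T_contr, Gamma_alpha_mixed=Gamma_alpha_mixed,
    )


def alpha_connection(
    model: ExponentialFamilyModel, theta, scheme: CensoringScheme, alpha: float
) -> GeometryTensors:
    """Alias of :func:`geometry_tensors` emphasising the requested alpha."""
    return geometry_tensors(model, theta, scheme, alpha)


# -- marginal-informed tensors -------------------------------------------------


def _h_ir(model, theta, scheme, r: int) -> np.ndarray:
    """Quadrature of e_i(x, R_r) against the r-th marginal density."""
    R_r = scheme.R[r - 1]
    lo, hi = model.support
    out = np.empty(model.k)
    for i in range(model.k):
        def integrand(x, _i=i):
            e = model.natural_stat(np.asarray(x), R_r)
            return float(e[_i]) * float(
                marginal_pdf_rth(model, theta, scheme, r, np.asarray(x))
            )
        val, _ = integrate.quad(integrand, lo, hi, epsrel=1e-9, epsabs=1e-12, limit=200)
        out[i] = val
    return out


def marginal_informed_connection(
    model: ExponentialFamilyModel, theta, scheme: CensoringScheme, alpha: float = 0.0
) -> MarginalInformedTensors:
    """Connection and skewness tensors formed from the exact per-order-statistic
    marginal expectations ``h_{i,r}``.

    The construction treats the summed statistics as if their means could
    differ from the joint-score mean; with the true marginals the totals
    satisfy ``h_i = m d_i phi`` and every modified tensor vanishes.  Both the
    assembled tensors and the ingredients are returned so the collapse is
    observable.
    """
    theta_v = model.check_theta(theta)
    m, k = scheme.m, model.k
    h_r = np.stack([_h_ir(model, theta_v, scheme, r) for r in range(1, m + 1)])
    h = h_r.sum(axis=0)
    m_dphi = m * model.phi_derivatives(theta_v, scheme, 1)
    g = metric_tensor(model, theta_v, scheme)
    diff = h - m_dphi  # (k,)
    Gamma_tilde = np.einsum("ij,k->ijk", g, -diff)
    T_tilde = np.einsum("i,j,k->ijk", diff, diff, diff)
    Gamma_tilde_alpha = Gamma_tilde + 0.5 * (1.0 - alpha) * T_tilde
    return MarginalInformedTensors(
        theta=theta_v, alpha=alpha, h_r=h_r, h=h, m_dphi=m_dphi, g=g,
        Gamma_tilde=Gamma_tilde, T_tilde=T_tilde, Gamma_tilde_alpha=Gamma_tilde_alpha,
    )


def collapse_double_sum(scheme: CensoringScheme) -> float:
    """The scalar ``sum_r sum_s (1 + R_r) c_{r-1} a_{s,r} gamma_s^{-2}``,
    which equals ``m`` for every admissible scheme (the collapse identity)."""
    return float(collapse_double_sum_exact(scheme))


def collapse_double_sum_exact(scheme: CensoringScheme) -> Fraction:
    """Exact-rational evaluation of :func:`collapse_double_sum`."""
    total = Fraction(0)
    for r in range(1, scheme.m + 1):
        c, a = scheme.marginal_coefficients_exact(r)
        R_r = scheme.R[r - 1]
        for s in range(r):
            total += (1 + R_r) * c * a[s] * Fraction(1, scheme.gamma[s] ** 2)
    return total


# -- torsion and curvature -----------------------------------------------------


def torsion_of(connection: np.ndarray) -> np.ndarray:
    """``S_ijk = Gamma_ijk - Gamma_jik`` for an arbitrary connection array."""
    return connection - connection.transpose(1, 0, 2)


def torsion_tensor(
    model: ExponentialFamilyModel, theta, scheme: CensoringScheme, alpha: float = 0.0
) -> np.ndarray:
    """Torsion of the alpha-connection; identically zero (symmetric in i, j)."""
    geo = geometry_tensors(model, theta, scheme, alpha)
    return torsion_of(geo.Gamma_alpha)


def rc_curvature(
    model: ExponentialFamilyModel, theta, scheme: CensoringScheme, alpha: float = 0.0
) -> np.ndarray:
    """Riemann-Christoffel curvature of the alpha-connection,

    ``R^a_ijkm = (d_i G^{a,s}_jk - d_j G^{a,s}_ik) g_sm
                 + (G^a_irm G^{a,r}_jk - G^a_jrm G^{a,r}_ik)``,

    with the derivative of the mixed connection taken by central finite
    differences in theta.  Zero for k = 1, and zero at alpha = +/-1 for
    natural-form models (dual flatness).
    """
    theta_v = model.check_theta(theta)
    k = model.k
    geo = geometry_tensors(model, theta_v, scheme, alpha)

    def mixed_at(t: np.ndarray) -> np.ndarray:
        return geometry_tensors(model, t, scheme, alpha).Gamma_alpha_mixed

    h = _fd.fd_step(theta_v)
    dmixed = np.empty((k, k, k, k))  # index [i] = d_i Gamma^{a,s}_{jk} as [i,j,k,s]
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        dmixed[i] = (mixed_at(theta_v + e) - mixed_at(theta_v - e)) / (2 * h[i])

    term1 = np.einsum("ijks,sm->ijkm", dmixed, geo.g) - np.einsum(
        "jiks,sm->ijkm", dmixed, geo.g
    )
    term2 = np.einsum("irm,jkr->ijkm", geo.Gamma_alpha, geo.Gamma_alpha_mixed) - np.einsum(
        "jrm,ikr->ijkm", geo.Gamma_alpha, geo.Gamma_alpha_mixed
    )
    return term1 + term2
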