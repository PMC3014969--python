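"""Linear stability of the homogeneous steady state.

Perturbations ~ exp(ikx + lambda t) of the reaction-diffusion system

    dt alpha = delta * lap(alpha) + f_alpha,   dt gamma = lap(gamma) + f_gamma

obey the characteristic polynomial lambda^2 + a1(k) lambda + a0(k) = 0 with

    a1(k) = k^2 (1 + delta) + 1 - qB + A,
    a0(k) = delta k^4 + k^2 (delta (1 - qB) + A) + A,

where A = -d f_alpha/d alpha and B = -d f_alpha/d gamma at the steady state.
In closed form, with the saturation ratio Lambda = L / (eps + nu q)^n,

    A = (sigma - nu)^2 / (sigma (1 + Lambda)),
    B = (sigma - nu) nu / sigma * n Lambda / ((eps + nu q)(1 + Lambda)).

A Hopf bifurcation (k = 0) occurs where 1 + A - qB = 0, a quadratic in sigma
whose two roots bound the oscillatory window; the Hopf frequency is
omega_H = sqrt(A).  A Turing bifurcation occurs where the discriminant
T = [delta(qB - 1) - A]^2 - 4 delta A vanishes with a real critical
wavenumber k_c.  At the upper Hopf root the two conditions combine into the
codimension-2 closed form delta_TH = (A + 2 + 2 sqrt(A+1)) / A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .models import FULL, LOW_FLUX, KineticParams, reaction_derivatives, steady_state

__all__ = [
    "StabilityCoeffs",
    "HopfResult",
    "TuringResult",
    "saturation_ratio",
    "stability_coeffs",
    "dispersion",
    "hopf_sigma",
    "at_hopf",
    "turing_locus",
    "turing_hopf_delta",
]


@dataclass(frozen=True)
class StabilityCoeffs:
    """Jacobian combinations A, B and the saturation ratio Lambda."""

    A: float
    B: float
    Lambda: float


@dataclass(frozen=True)
class HopfResult:
    """Roots of the Hopf condition 1 + A(sigma) - qB(sigma) = 0.

    ``sigma_lo``/``sigma_hi`` bound the oscillatory window (a1(0) < 0 for
    sigma strictly between them); simulations and amplitude-equation
    expansions use the upper root.  ``omega_H`` is sqrt(A) at ``sigma_hi``.
    ``r`` and ``s`` are the coefficients of the quadratic
    sigma^2 - 2 r sigma + s = 0 (None in low-flux mode, where the Hopf
    condition is linear in the rescaled sigma).
    """

    sigma_lo: Optional[float]
    sigma_hi: Optional[float]
    omega_H: Optional[float]
    r: Optional[float] = None
    s: Optional[float] = None

    @property
    def exists(self) -> bool:
        return self.sigma_hi is not None


@dataclass(frozen=True)
class TuringResult:
    """Turing discriminant T and critical wavenumber k_c (None if no finite-k
    minimum of a0 exists below the k=0 value)."""

    T_value: float
    k_c: Optional[float]


def saturation_ratio(params: KineticParams) -> float:
    """Lambda = L / (eps + nu q)^n evaluated at the steady state gamma_s."""
    return params.L / (params.eps + params.nu * params.q) ** params.n


def stability_coeffs(params: KineticParams) -> StabilityCoeffs:
    """Closed-form A, B at the steady state.

    Equal to minus the alpha- and gamma-derivatives of f_alpha there (and
    1/q times the corresponding f_gamma derivatives, up to the -1 decay
    term), which is asserted in the test suite against the analytic
    derivative machinery.
    """
    nu, sigma, q, n, eps = params.nu, params.sigma, params.q, params.n, params.eps
    E = eps + nu * q
    if params.flux_mode == LOW_FLUX:
        A = sigma * E**n
        B = nu * n / E
        Lam = math.inf
    else:
        if sigma <= nu:
            raise ValueError("sigma must exceed nu")
        Lam = saturation_ratio(params)
        A = (sigma - nu) ** 2 / (sigma * (1.0 + Lam))
        B = (sigma - nu) * nu / sigma * n * Lam / (E * (1.0 + Lam))
    return StabilityCoeffs(A=A, B=B, Lambda=Lam)


def dispersion(params: KineticParams, delta: float, k):
    """Dispersion relation coefficients a1(k), a0(k) and the leading root.

    Returns (a1, a0, lambda_plus) where lambda_plus is the root of
    lambda^2 + a1 lambda + a0 with the larger real part.  Vectorized in k.
    """
    sc = stability_coeffs(params)
    k2 = np.asarray(k, dtype=float) ** 2
    a1 = k2 * (1.0 + delta) + 1.0 - params.q * sc.B + sc.A
    a0 = delta * k2**2 + k2 * (delta * (1.0 - params.q * sc.B) + sc.A) + sc.A
    disc = np.asarray(a1, dtype=complex) ** 2 - 4.0 * a0
    lam_p = 0.5 * (-a1 + np.sqrt(disc))
    lam_m = 0.5 * (-a1 - np.sqrt(disc))
    lam = np.where(lam_p.real >= lam_m.real, lam_p, lam_m)
    if np.ndim(k) == 0:
        return float(a1), float(a0), complex(lam)
    return a1, a0, lam


def hopf_sigma(params: KineticParams) -> HopfResult:
    """Solve the Hopf condition for sigma, all other parameters fixed.

    Full mode: sigma^2 - 2 r sigma + s = 0 with

        r = nu + 1/2 (Lambda_h [((n-1) nu q - eps)/(eps + nu q)] - 1),
        s = nu^2 (1 + Lambda_h n q / (eps + nu q)),

    Lambda_h the saturation ratio at gamma_s (independent of sigma).  Returns
    both roots when real and > nu, else an empty result.  Low-flux mode: the
    condition is linear in the rescaled sigma, with single threshold
    sigma_bar_H = (nu n q/(eps + nu q) - 1) / (eps + nu q)^n and
    omega_H^2 = (nu q (n-1) - eps) / (nu q + eps).
    """
    nu, q, n, eps = params.nu, params.q, params.n, params.eps
    E = eps + nu * q
    if params.flux_mode == LOW_FLUX:
        qB = q * nu * n / E  # B = nu*n/E is independent of sigma here
        if qB <= 1.0:
            return HopfResult(None, None, None)
        sigma_h = (qB - 1.0) / E**n
        omega = math.sqrt(qB - 1.0)
        return HopfResult(sigma_lo=None, sigma_hi=sigma_h, omega_H=omega)

    Lam = saturation_ratio(params)
    r = nu + 0.5 * (Lam * (((n - 1) * nu * q - eps) / E) - 1.0)
    s = nu**2 * (1.0 + Lam * n * q / E)
    disc = r * r - s
    if disc < 0:
        return HopfResult(None, None, None, r=r, s=s)
    root = math.sqrt(disc)
    lo, hi = r - root, r + root
    if hi <= nu:
        return HopfResult(None, None, None, r=r, s=s)
    if lo <= nu:
        lo = None
    A_hi = stability_coeffs(params.with_sigma(hi)).A
    return HopfResult(sigma_lo=lo, sigma_hi=hi, omega_H=math.sqrt(A_hi), r=r, s=s)


def at_hopf(params: KineticParams) -> KineticParams:
    """Parameters with sigma placed at the upper Hopf root."""
    h = hopf_sigma(params)
    if not h.exists:
        raise ValueError("no Hopf bifurcation for these parameters")
    return params.with_sigma(h.sigma_hi)


def turing_locus(params: KineticParams, delta: float) -> TuringResult:
    """Turing discriminant T(delta, p) and critical wavenumber.

    T = [delta(qB - 1) - A]^2 - 4 delta A; the bifurcation sits at T = 0 with
    real k_c, where k_c^2 = [delta(qB - 1) - A]/(2 delta) is the minimizer of
    a0(k)."""
    sc = stability_coeffs(params)
    bracket = delta * (params.q * sc.B - 1.0) - sc.A
    T = bracket**2 - 4.0 * delta * sc.A
    k_c = math.sqrt(bracket / (2.0 * delta)) if bracket > 0 else None
    return TuringResult(T_value=T, k_c=k_c)


def turing_hopf_delta(params: KineticParams) -> float:
    """Diffusion ratio of the Turing-Hopf codimension-2 point.

    At the upper Hopf root the identity qB - 1 = A collapses T = 0 to
    A (delta - 1)^2 = 4 delta, whose root > 1 is

        delta_TH = (A + 2 + 2 sqrt(A + 1)) / A,   A = omega_H^2.

    Larger cooperativity (larger A) needs less scale separation: delta_TH
    decreases toward 1 as A grows.
    """
    h = hopf_sigma(params)
    if not h.exists:
        raise ValueError("no Hopf bifurcation for these parameters")
    A = h.omega_H**2
    return (A + 2.0 + 2.0 * math.sqrt(A + 1.0)) / A
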