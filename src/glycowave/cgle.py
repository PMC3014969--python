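"""Reduction to the complex Ginzburg-Landau equation at the Hopf point.

Near a supercritical Hopf bifurcation the reaction-diffusion dynamics is
governed by the amplitude equation

    dt A = (1 + i c1) lap(A) + A - (1 + i c3) |A|^2 A.

The linear dispersion coefficient c1 = Im(d)/Re(d) with d = u0* D u0
(D = diag(delta, 1)) has the closed form c1 = omega_H (delta-1)/(delta+1).
The nonlinear dispersion coefficient c3 = Im(g)/Re(g) follows from the
standard second/third-order contraction of the reaction nonlinearity with
the Hopf eigenvectors:

    g = -2 u0* M (u0, V0) - 2 u0* M (conj(u0), V+) - 3 u0* N (u0, u0, conj(u0)),
    V0 = -2 J^{-1} M (u0, conj(u0)),   V+ = -(J - 2 i omega I)^{-1} M (u0, u0),

where M and N hold one half / one sixth of the second / third partials of
(f_alpha, f_gamma) at the steady state.  The sign conventions are fixed by
the reference eigenvector gauge

    u0 = ((-1 + i/omega)/q, 1),   u0* = (1/2) (-i q omega, 1 - i omega),

which satisfies J u0 = i omega u0, u0* J = i omega u0*, u0*.u0 = 1 for the
Hopf-point Jacobian J = [[-A, -(1+A)/q], [qA, A]].  Both c1 and c3 are
ratios and therefore gauge independent.

Wave phenomenology: c1 - c3 > 0 gives inward propagating waves
(anti-spirals), c1 - c3 < 0 outward; 1 + c1 c3 < 0 is the Benjamin-Feir
instability of plane waves (spatio-temporal chaos nearby); for diffusion
ratios at or beyond the Turing-Hopf point the oscillatory branch is
preempted by stationary patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import LOW_FLUX, KineticParams, reaction_derivatives, steady_state
from .linstab import at_hopf, hopf_sigma, stability_coeffs, turing_hopf_delta

__all__ = [
    "HopfEigen",
    "CGLECoeffs",
    "hopf_eigen",
    "c1_coefficient",
    "c3_coefficient",
    "c3_lowflux_closed_form",
    "classify_regime",
    "coefficients",
]

REGIME_OUTWARD = "outward_waves"
REGIME_INWARD = "inward_waves"
REGIME_BF = "bf_unstable"
REGIME_TURING = "turing_preempted"
REGIME_BOUNDARY = "boundary"

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class HopfEigen:
    """Hopf-point eigenstructure in the fixed reference gauge."""

    omega: float
    J: np.ndarray  # 2x2 real Jacobian
    u0: np.ndarray  # right eigenvector, J u0 = i omega u0
    u0star: np.ndarray  # left eigenvector (row), normalized u0star.u0 = 1


@dataclass(frozen=True)
class CGLECoeffs:
    """CGLE coefficients and regime classification at one (params, delta)."""

    c1: float
    c3: float
    d: complex
    g: complex
    omega: float
    delta: float
    delta_TH: float
    regime: str


def hopf_eigen(params: KineticParams, *, atol: float = 1e-9) -> HopfEigen:
    """Eigenstructure at the Hopf point.

    ``params.sigma`` must already sit at the (upper) Hopf root, where the
    Jacobian takes the form [[-A, -(1+A)/q], [qA, A]]; use
    :func:`glycowave.linstab.at_hopf` to place it there.
    """
    fa, fg = _jacobian_check(params, atol)
    J = np.array([[fa.grad[0], fa.grad[1]], [fg.grad[0], fg.grad[1]]])
    A = -fa.grad[0]
    if A <= 0:
        raise ValueError("Jacobian trace structure invalid: A <= 0")
    omega = math.sqrt(A)
    q = params.q
    u0 = np.array([(-1.0 + 1j / omega) / q, 1.0 + 0j])
    u0star = 0.5 * np.array([-1j * q * omega, 1.0 - 1j * omega])
    return HopfEigen(omega=omega, J=J, u0=u0, u0star=u0star)


def _jacobian_check(params: KineticParams, atol: float):
    ss = steady_state(params)
    fa, fg = reaction_derivatives(params, ss.alpha_s, ss.gamma_s)
    trace = fa.grad[0] + fg.grad[1]
    if abs(trace) > atol * max(1.0, abs(fa.grad[0])):
        raise ValueError(
            f"sigma is not at the Hopf point: Jacobian trace {trace:.3e} != 0; "
            "use linstab.at_hopf first"
        )
    return fa, fg


def c1_coefficient(hopf: HopfEigen, delta: float) -> float:
    """c1 = Im(d)/Re(d), d = u0* diag(delta, 1) u0.

    Equals omega_H (delta - 1)/(delta + 1) identically in the reference
    gauge; the test suite asserts the two routes agree to machine precision.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    d = _d_value(hopf, delta)
    return d.imag / d.real


def _d_value(hopf: HopfEigen, delta: float) -> complex:
    D = np.diag([delta, 1.0])
    return complex(hopf.u0star @ D @ hopf.u0)


def c3_coefficient(params: KineticParams) -> tuple[complex, float]:
    """Nonlinear CGLE coefficient by the full tensor reduction.

    ``params.sigma`` must sit at the Hopf point.  Returns (g, c3) with
    c3 = Im(g)/Re(g).  All contractions are explicit small-tensor sums over
    the two species components and up to three concentration indices.
    """
    ss = steady_state(params)
    fa, fg = reaction_derivatives(params, ss.alpha_s, ss.gamma_s)
    eig = hopf_eigen(params)
    u0, u0s, J, omega = eig.u0, eig.u0star, eig.J, eig.omega

    M = np.stack([0.5 * fa.hess, 0.5 * fg.hess])  # shape (2, 2, 2): l, i, j
    N = np.stack([fa.third / 6.0, fg.third / 6.0])  # shape (2, 2, 2, 2)

    Mu0u0bar = np.einsum("lij,i,j->l", M, u0, np.conj(u0))
    Mu0u0 = np.einsum("lij,i,j->l", M, u0, u0)

    V0 = -2.0 * np.linalg.solve(J.astype(complex), Mu0u0bar)
    Lp = J - 2j * omega * np.eye(2)
    # eigenvalues of J are +/- i omega, so J - 2 i omega I is never singular
    Vp = -np.linalg.solve(Lp, Mu0u0)

    g = (
        -2.0 * np.einsum("l,lij,i,j->", u0s, M, u0, V0)
        - 2.0 * np.einsum("l,lij,i,j->", u0s, M, np.conj(u0), Vp)
        - 3.0 * np.einsum("l,lijk,i,j,k->", u0s, N, u0, u0, np.conj(u0))
    )
    g = complex(g)
    if g.real == 0:
        raise ValueError("degenerate Hopf: Re(g) = 0")
    return g, g.imag / g.real


def c3_lowflux_closed_form(n: int, nu_q: float, eps: float) -> float:
    """Closed polynomial form of c3 in the low-glycolytic-flux regime.

        c3 = [P2 (nu q)^2 + eps P1 (nu q) + eps^2 P0]
             / [P3 (nu q + eps) omega_H],

        P0 = 9n - 3,  P1 = -9n^2 + 13n - 6,  P2 = 2n^3 - 5n^2 + 6n - 3,
        P3 = 3 (n-1)^2 (nu q) - 3 eps (n - 3),
        omega_H^2 = (nu q (n-1) - eps) / (nu q + eps).

    For eps = 0 (Hill/Sel'kov) both c1 and c3 are independent of nu q.
    """
    w2 = (nu_q * (n - 1) - eps) / (nu_q + eps)
    if w2 <= 0:
        raise ValueError("no Hopf bifurcation: omega_H^2 <= 0")
    omega = math.sqrt(w2)
    P0 = 9 * n - 3
    P1 = -9 * n**2 + 13 * n - 6
    P2 = 2 * n**3 - 5 * n**2 + 6 * n - 3
    P3 = 3 * (n - 1) ** 2 * nu_q - 3 * eps * (n - 3)
    return (P2 * nu_q**2 + eps * P1 * nu_q + eps**2 * P0) / (P3 * (nu_q + eps) * omega)


def classify_regime(c1: float, c3: float, delta: float, delta_TH: float) -> str:
    """Classify the expected pattern phenotype from the CGLE coefficients.

    Precedence: Turing preemption (delta >= delta_TH, stationary patterns
    replace waves), then Benjamin-Feir instability (1 + c1 c3 < 0), then the
    wave-propagation direction by the sign of c1 - c3 (within an absolute
    tolerance for the boundary)."""
    for v in (c1, c3, delta, delta_TH):
        if not math.isfinite(v):
            raise ValueError("classification inputs must be finite")
    if delta >= delta_TH:
        return REGIME_TURING
    if 1.0 + c1 * c3 < 0.0:
        return REGIME_BF
    diff = c1 - c3
    if diff > _BOUNDARY_TOL:
        return REGIME_INWARD
    if diff < -_BOUNDARY_TOL:
        return REGIME_OUTWARD
    return REGIME_BOUNDARY


def coefficients(params: KineticParams, delta: float, *, auto_hopf: bool = True) -> CGLECoeffs:
    """Convenience wrapper: place sigma at the upper Hopf root (unless
    ``auto_hopf=False``), compute c1, c3 and classify the regime."""
    p = at_hopf(params) if auto_hopf else params
    eig = hopf_eigen(p)
    d = _d_value(eig, delta)
    c1 = d.imag / d.real
    g, c3 = c3_coefficient(p)
    dTH = turing_hopf_delta(p)
    return CGLECoeffs(
        c1=c1,
        c3=c3,
        d=d,
        g=g,
        omega=eig.omega,
        delta=delta,
        delta_TH=dTH,
        regime=classify_regime(c1, c3, delta, dTH),
    )
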