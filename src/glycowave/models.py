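"""Kinetic models for product-activated allosteric enzymes.

Two classical activation mechanisms for an oligomeric enzyme (the canonical
example being yeast phosphofructokinase, activated by its product ADP) are
expressed through a single unified rate law,

    phi(alpha, gamma) = alpha (eps + gamma)^n / (L + (1 + alpha)(eps + gamma)^n),

where ``alpha`` is the dimensionless substrate (inhibitor) concentration,
``gamma`` the dimensionless product (activator) concentration, ``n`` the
number of product-binding subunits and ``L`` the allosteric constant
(equilibrium ratio of inactive to active conformations).  The
Monod-Wyman-Changeux (MWC) sequential-activation mechanism corresponds to
``eps = 1, L > 1``; the Sel'kov Hill-type mechanism (simultaneous binding of
all n activator molecules, i.e. the infinite-affinity limit) corresponds to
``eps = 0, L = 1``.  Intermediate ``eps`` values interpolate between the two
via a rescaling of the product-binding affinity.

The local (well-mixed) dynamics is

    d alpha / dt = nu - sigma * phi,
    d gamma / dt = q * sigma * phi - gamma,

with substrate supply rate ``nu``, maximal enzyme rate ``sigma`` and
product/substrate concentration-scale ratio ``q``.  In the low-flux regime
(gamma_s^n << 1 for Hill, (1+gamma_s)^n << L for MWC) the rate law reduces to
``phi = alpha (eps + gamma)^n`` with the factor 1/L absorbed into a rescaled
maximal rate sigma_bar = sigma / L; this variant is exposed as a first-class
model (``flux_mode="low_flux"``) because the amplitude-equation coefficients
admit closed polynomial forms there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from math import comb
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "SteadyState",
    "RateDerivatives",
    "phi",
    "phi_from_state_enumeration",
    "reaction_terms",
    "reaction_derivatives",
    "steady_state",
    "hill_coefficient",
    "hill_coefficient_derivative",
    "effective_allosteric_constant",
    "selkov_limit_family",
]

FULL = "full"
LOW_FLUX = "low_flux"


@dataclass(frozen=True)
class KineticParams:
    """Dimensionless kinetic parameterization shared by both mechanisms.

    Parameters
    ----------
    nu : float
        Substrate supply rate (> 0).
    sigma : float
        Maximal enzyme rate; must exceed ``nu`` for a positive steady state.
        In ``low_flux`` mode this is the rescaled rate sigma_bar = sigma / L
        (the allosteric constant is absorbed).
    q : float
        Product/substrate concentration-scale ratio (> 0).
    n : int
        Number of product-binding subunits (>= 1).
    L : float
        Allosteric constant (>= 1); ignored by the low-flux rate law.
    eps : float
        Binding-affinity interpolation parameter in [0, 1]; 0 gives the
        Sel'kov/Hill mechanism, 1 the MWC mechanism.
    flux_mode : str
        ``"full"`` for the full rational rate law, ``"low_flux"`` for the
        low-glycolytic-flux approximation.
    """

    nu: float
    sigma: float
    q: float = 1.0
    n: int = 8
    L: float = 1.0
    eps: float = 1.0
    flux_mode: str = FULL

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError(f"nu must be positive, got {self.nu}")
        if self.q <= 0:
            raise ValueError(f"q must be positive, got {self.q}")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"n must be an integer >= 1, got {self.n}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError(f"eps must lie in [0, 1], got {self.eps}")
        if self.flux_mode not in (FULL, LOW_FLUX):
            raise ValueError(f"unknown flux_mode {self.flux_mode!r}")
        object.__setattr__(self, "n", int(self.n))

    @property
    def gamma_s(self) -> float:
        """Steady-state activator concentration nu*q."""
        return self.nu * self.q

    def with_sigma(self, sigma: float) -> "KineticParams":
        return replace(self, sigma=sigma)

    # -- plain-text (key: value) serialization ------------------------------

    def to_config(self) -> str:
        lines = [
            f"nu: {self.nu!r}",
            f"sigma: {self.sigma!r}",
            f"q: {self.q!r}",
            f"n: {self.n}",
            f"L: {self.L!r}",
            f"eps: {self.eps!r}",
            f"flux_mode: {self.flux_mode}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "KineticParams":
        d = _parse_kv(text)
        return cls(
            nu=float(d["nu"]),
            sigma=float(d["sigma"]),
            q=float(d.get("q", 1.0)),
            n=int(d.get("n", 8)),
            L=float(d.get("L", 1.0)),
            eps=float(d.get("eps", 1.0)),
            flux_mode=d.get("flux_mode", FULL),
        )


def _parse_kv(text: str) -> dict:
    """Parse a flat ``key: value`` plain-text config block."""
    out: dict = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = line.split(":", 1)
        out[key.strip()] = val.strip()
    return out


@dataclass(frozen=True)
class SteadyState:
    """Homogeneous fixed point (alpha_s, gamma_s) of the reaction kinetics."""

    alpha_s: float
    gamma_s: float


@dataclass(frozen=True)
class RateDerivatives:
    """Value and partial derivatives (to third order) of one reaction term.

    Index convention: 0 -> alpha, 1 -> gamma.  ``hess`` and ``third`` are
    symmetric under any permutation of their indices.
    """

    value: float
    grad: np.ndarray  # shape (2,)
    hess: np.ndarray  # shape (2, 2)
    third: np.ndarray  # shape (2, 2, 2)


# ---------------------------------------------------------------------------
# rate law
# ---------------------------------------------------------------------------


def phi(params: KineticParams, alpha, gamma):
    """Fractional saturation of the enzyme (dimensionless reaction rate).

    Accepts scalars or numpy arrays for ``alpha`` and ``gamma``.  In
    ``low_flux`` mode returns alpha*(eps+gamma)^n (the 1/L factor lives in
    the rescaled sigma).
    """
    alpha = np.asarray(alpha, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(alpha < 0) or np.any(gamma < 0):
        raise ValueError("concentrations must be non-negative")
    u = (params.eps + gamma) ** params.n
    if params.flux_mode == LOW_FLUX:
        out = alpha * u
    else:
        out = alpha * u / (params.L + (1.0 + alpha) * u)
    return out if out.ndim else float(out)


def phi_from_state_enumeration(n: int, L: float, alpha: float, gamma: float) -> float:
    """Fractional saturation of the MWC mechanism by explicit state counting.

    Enumerates the active enzyme states R_{lm} (l = 0, 1 substrate molecules
    bound, m = 0..n activator molecules bound) with their binomial
    statistical weights, R_{0m}/R_{00} = C(n, m) gamma^m and
    R_{1m} = alpha R_{0m}, plus the inactive state T_00 = L R_00, and forms
    the ratio of occupied substrate sites to total enzyme.  Serves as a
    combinatorial oracle for ``phi`` with MWC parameters (eps = 1); intended
    for small n (the sums are exact but explicitly enumerated).
    """
    if alpha < 0 or gamma < 0:
        raise ValueError("concentrations must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    # weights relative to R_00
    r0 = [comb(n, m) * gamma**m for m in range(n + 1)]
    r1 = [alpha * w for w in r0]
    occupied = sum(r1)
    total = L + sum(r0) + sum(r1)
    return occupied / total


def reaction_terms(params: KineticParams, alpha, gamma):
    """Reaction terms (f_alpha, f_gamma) of the two-species kinetics."""
    p = phi(params, alpha, gamma)
    f_a = params.nu - params.sigma * p
    f_g = params.q * params.sigma * p - np.asarray(gamma, dtype=float)
    if np.ndim(f_g) == 0:
        return float(f_a), float(f_g)
    return f_a, f_g


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def steady_state(params: KineticParams) -> SteadyState:
    """Unique positive homogeneous steady state.

    gamma_s = nu*q always; alpha_s follows from phi(alpha_s, gamma_s) = nu/sigma:

    full mode:     alpha_s = nu/(sigma - nu) * (1 + L/(eps + nu q)^n)
    low-flux mode: alpha_s = nu / (sigma_bar (eps + nu q)^n)
    """
    gamma_s = params.nu * params.q
    u = (params.eps + gamma_s) ** params.n
    if params.flux_mode == LOW_FLUX:
        alpha_s = params.nu / (params.sigma * u)
    else:
        if params.sigma <= params.nu:
            raise ValueError(
                f"no positive steady state: sigma={params.sigma} <= nu={params.nu}"
            )
        alpha_s = params.nu / (params.sigma - params.nu) * (1.0 + params.L / u)
    return SteadyState(alpha_s=alpha_s, gamma_s=gamma_s)


# ---------------------------------------------------------------------------
# analytic derivatives
# ---------------------------------------------------------------------------


def _powers(E: float, n: int):
    """(E^n, d/dE E^n, d2, d3) with zero-coefficient guards for small n."""
    u = E**n
    u1 = n * E ** (n - 1) if n >= 1 else 0.0
    u2 = n * (n - 1) * E ** (n - 2) if n >= 2 else 0.0
    u3 = n * (n - 1) * (n - 2) * E ** (n - 3) if n >= 3 else 0.0
    return u, u1, u2, u3


def _phi_partials(params: KineticParams, alpha: float, gamma: float):
    """All partials of phi up to third order, as a dict keyed (i, j) with
    i derivatives in alpha and j in gamma.

    For the full rational law the alpha-dependence is handled in closed form
    and the gamma-dependence through the chain rule in u = (eps+gamma)^n.
    """
    if alpha < 0 or gamma < 0:
        raise ValueError("concentrations must be non-negative")
    E = params.eps + gamma
    n = params.n
    u, u1, u2, u3 = _powers(E, n)

    if params.flux_mode == LOW_FLUX:
        return {
            (0, 0): alpha * u,
            (1, 0): u,
            (0, 1): alpha * u1,
            (2, 0): 0.0,
            (1, 1): u1,
            (0, 2): alpha * u2,
            (3, 0): 0.0,
            (2, 1): 0.0,
            (1, 2): u2,
            (0, 3): alpha * u3,
        }

    L = params.L
    D = L + (1.0 + alpha) * u
    D2, D3, D4 = D * D, D * D * D, D * D * D * D

    p_a = u * (L + u) / D2
    p_aa = -2.0 * u * u * (L + u) / D3
    p_aaa = 6.0 * u**3 * (L + u) / D4
    p_u = alpha * L / D2
    p_uu = -2.0 * alpha * L * (1.0 + alpha) / D3
    p_uuu = 6.0 * alpha * L * (1.0 + alpha) ** 2 / D4
    p_au = L / D2 - 2.0 * alpha * L * u / D3
    p_aau = -4.0 * L * u / D3 + 6.0 * alpha * L * u * u / D4
    p_auu = -2.0 * L * (1.0 + 2.0 * alpha) / D3 + 6.0 * alpha * L * (1.0 + alpha) * u / D4

    return {
        (0, 0): alpha * u / D,
        (1, 0): p_a,
        (0, 1): p_u * u1,
        (2, 0): p_aa,
        (1, 1): p_au * u1,
        (0, 2): p_uu * u1 * u1 + p_u * u2,
        (3, 0): p_aaa,
        (2, 1): p_aau * u1,
        (1, 2): p_auu * u1 * u1 + p_au * u2,
        (0, 3): p_uuu * u1**3 + 3.0 * p_uu * u1 * u2 + p_u * u3,
    }


def _tensorize(c: dict, scale: float, lin_gamma: float = 0.0) -> RateDerivatives:
    """Assemble symmetric derivative tensors of scale*phi (+ linear gamma term)."""
    grad = np.array([scale * c[(1, 0)], scale * c[(0, 1)] + lin_gamma])
    hess = np.array(
        [
            [scale * c[(2, 0)], scale * c[(1, 1)]],
            [scale * c[(1, 1)], scale * c[(0, 2)]],
        ]
    )
    third = np.empty((2, 2, 2))
    vals = {0: c[(3, 0)], 1: c[(2, 1)], 2: c[(1, 2)], 3: c[(0, 3)]}
    for i in range(2):
        for j in range(2):
            for k in range(2):
                third[i, j, k] = scale * vals[i + j + k]
    return RateDerivatives(value=0.0, grad=grad, hess=hess, third=third)


def reaction_derivatives(
    params: KineticParams, alpha: float, gamma: float
) -> tuple[RateDerivatives, RateDerivatives]:
    """Exact partial derivatives of (f_alpha, f_gamma) up to third order.

    f_alpha = nu - sigma*phi and f_gamma = q*sigma*phi - gamma, so apart from
    the linear -1 term in d f_gamma / d gamma every derivative of f_gamma is
    -q times the corresponding derivative of f_alpha.
    """
    c = _phi_partials(params, alpha, gamma)
    s = params.sigma
    fa = _tensorize(c, -s)
    fg = _tensorize(c, params.q * s, lin_gamma=-1.0)
    fa = replace_value(fa, params.nu - s * c[(0, 0)])
    fg = replace_value(fg, params.q * s * c[(0, 0)] - gamma)
    return fa, fg


def replace_value(d: RateDerivatives, value: float) -> RateDerivatives:
    return RateDerivatives(value=value, grad=d.grad, hess=d.hess, third=d.third)


# ---------------------------------------------------------------------------
# cooperativity
# ---------------------------------------------------------------------------


def hill_coefficient(params: KineticParams, gamma: float) -> float:
    """Effective Hill coefficient n_H = (gamma/M) dM/dgamma, M = phi/(1-phi).

    Closed form: n_H = gamma/(eps+gamma) * n L / (L + (eps+gamma)^n).
    Independent of alpha.  n_H > 1 signals positive cooperativity.  For the
    Sel'kov mechanism (eps=0, L=1) this reduces to n/(1+gamma^n).
    """
    if np.any(np.asarray(gamma) <= 0):
        raise ValueError("gamma must be positive")
    E = params.eps + np.asarray(gamma, dtype=float)
    out = (np.asarray(gamma) / E) * params.n * params.L / (params.L + E**params.n)
    return out if out.ndim else float(out)


def hill_coefficient_derivative(params: KineticParams, gamma: float) -> float:
    """Analytic d n_H / d gamma of the closed form above."""
    g = np.asarray(gamma, dtype=float)
    E = params.eps + g
    n, L = params.n, params.L
    un = E**n
    # n_H = nL * g / (E (L + un))
    num = n * L * ((params.eps) * (L + un) - g * n * un)
    out = num / (E * (L + un)) ** 2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# MWC -> Sel'kov interpolation
# ---------------------------------------------------------------------------


def effective_allosteric_constant(L: float, eps: float) -> float:
    """Effective allosteric constant L_eff = eps (L - 1) + 1.

    This is the allosteric constant appearing in the unified rate law for the
    interpolated model with affinity rescaling eps: it equals L at eps = 1
    (MWC) and tends to 1 as eps -> 0 (Sel'kov).  The *true* allosteric
    constant of the underlying MWC scheme is L_eff / eps^n, which diverges in
    the Sel'kov limit.  Not to be confused with the saturation ratio
    Lambda = L/(eps + gamma_s)^n used in the stability analysis.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return eps * (L - 1.0) + 1.0


def true_allosteric_constant(L: float, eps: float, n: int) -> float:
    """Allosteric constant L_M = L_eff / eps^n of the interpolated MWC scheme."""
    if eps <= 0:
        raise ValueError("eps must be positive (the Sel'kov limit is a limit)")
    return effective_allosteric_constant(L, eps) / eps**n


def selkov_limit_family(
    L: float,
    eps_values: Iterable[float],
    *,
    nu: float = 0.5,
    sigma: float = 10.0,
    q: float = 1.0,
    n: int = 8,
    flux_mode: str = FULL,
) -> list[KineticParams]:
    """Family of interpolated models between the MWC (eps=1) and Sel'kov limits.

    Each returned parameter set carries the effective allosteric constant
    eps(L-1)+1 in its ``L`` slot so that phi interpolates continuously: at
    eps = 1 it is the MWC model with allosteric constant L, and as eps -> 0
    it converges uniformly (on compact concentration boxes) to the Hill rate
    law with L = 1.  eps = 0 itself is rejected for L != 1 since the limit
    must be taken, not evaluated.
    """
    out = []
    for eps in eps_values:
        if eps == 0.0 and L != 1.0:
            raise ValueError("eps=0 with L != 1: take the limit, do not evaluate it")
        out.append(
            KineticParams(
                nu=nu,
                sigma=sigma,
                q=q,
                n=n,
                L=effective_allosteric_constant(L, eps),
                eps=eps,
                flux_mode=flux_mode,
            )
        )
    return out
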