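"""Phase-diagram curves in the (mechanism parameter, diffusion ratio) plane.

Three codimension-1 curves organize the pattern phenotypes of the coupled
system as the diffusion ratio delta = D_inhibitor / D_activator varies:

* ``TH``  - Turing-Hopf codimension-2 curve, delta = delta_TH; above it the
  oscillatory branch is preempted by stationary Turing patterns.
* ``AS``  - anti-wave transition c1 - c3 = 0; above it (and below TH) waves
  propagate inward (anti-spirals).
* ``BF``  - Benjamin-Feir instability 1 + c1 c3 = 0; plane waves are
  unstable to long-wavelength perturbations on its chaotic side.

Two sweep axes are supported: ``eps_axis`` interpolates between the MWC
(eps = 1) and Hill (eps -> 0) mechanisms in the low-flux model, and
``gamma_s_axis`` sweeps the steady-state activator concentration
gamma_s = nu q (via nu) in the full model.  At every sweep point sigma is
re-solved to the upper Hopf root before the CGLE coefficients are formed.
The Hill-coefficient overlay n_H(gamma_s) links the anti-wave region to the
rising flank (d n_H / d gamma_s > 0) of the cooperativity curve.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .models import FULL, LOW_FLUX, KineticParams, hill_coefficient, hill_coefficient_derivative
from .linstab import at_hopf, hopf_sigma, turing_hopf_delta
from .cgle import c1_coefficient, c3_coefficient, hopf_eigen

__all__ = [
    "PhaseCurve",
    "HillOverlay",
    "trace_curve",
    "hill_overlay",
    "curve_residual",
]

log = logging.getLogger(__name__)

LABELS = ("TH", "AS", "BF")
AXES = ("eps_axis", "gamma_s_axis")

_BISECT_TOL = 1e-8
_POINT_TOL = 1e-6


@dataclass(frozen=True)
class PhaseCurve:
    """One traced bifurcation/transition curve.

    ``points`` is a list of (x, delta) pairs sorted in x, where x is the
    swept parameter (eps or gamma_s).  Every point satisfies the curve's
    defining equation to within ``_POINT_TOL``.
    """

    label: str
    axis: str
    points: tuple[tuple[float, float], ...]

    def to_csv(self) -> str:
        df = pd.DataFrame(self.points, columns=["parameter", "value"])
        df.insert(0, "branch", self.label)
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, axis: str) -> "PhaseCurve":
        df = pd.read_csv(io.StringIO(text))
        label = str(df["branch"].iloc[0])
        pts = tuple(zip(df["parameter"].astype(float), df["value"].astype(float)))
        return cls(label=label, axis=axis, points=pts)


@dataclass(frozen=True)
class HillOverlay:
    """Hill-coefficient curve n_H(gamma_s) with slope signs and argmax."""

    gamma_s: np.ndarray
    n_H: np.ndarray
    slope_sign: np.ndarray  # sign of d n_H / d gamma_s at each grid point
    argmax: Optional[float]  # interior maximizer, None if monotone on grid


def _params_at_x(axis: str, fixed: KineticParams, x: float) -> KineticParams:
    if axis == "eps_axis":
        return replace(fixed, eps=float(x))
    if axis == "gamma_s_axis":
        return replace(fixed, nu=float(x) / fixed.q)
    raise ValueError(f"unknown axis {axis!r}")


def _defining_function(label: str, params_h: KineticParams) -> Callable[[float], float]:
    """g(delta) whose root defines the curve at one sweep point.

    ``params_h`` must already sit at the upper Hopf root (delta-independent).
    """
    if label == "TH":
        d_th = turing_hopf_delta(params_h)
        return lambda delta: delta - d_th
    eig = hopf_eigen(params_h)
    _, c3 = c3_coefficient(params_h)
    if label == "AS":
        return lambda delta: c1_coefficient(eig, delta) - c3
    if label == "BF":
        return lambda delta: 1.0 + c1_coefficient(eig, delta) * c3
    raise ValueError(f"unknown curve label {label!r}")


def trace_curve(
    label: str,
    axis: str,
    fixed: KineticParams,
    x_grid: Sequence[float],
    delta_bracket: tuple[float, float] = (0.25, 16.0),
    *,
    max_expand: int = 4,
) -> PhaseCurve:
    """Trace one curve over ``x_grid`` by bisection in delta.

    At each sweep value the Hopf root is re-solved; points where no Hopf
    exists or where the defining function does not change sign over the
    (expandable) delta bracket are omitted with a log entry, never
    interpolated.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    pts: list[tuple[float, float]] = []
    for x in sorted(float(v) for v in x_grid):
        p = _params_at_x(axis, fixed, x)
        h = hopf_sigma(p)
        if not h.exists:
            log.info("%s curve: no Hopf at %s=%g, point omitted", label, axis, x)
            continue
        ph = p.with_sigma(h.sigma_hi)
        try:
            g = _defining_function(label, ph)
        except ValueError as exc:
            log.info("%s curve: %s at %s=%g, point omitted", label, exc, axis, x)
            continue
        lo, hi = delta_bracket
        glo, ghi = g(lo), g(hi)
        expand = 0
        while glo * ghi > 0 and expand < max_expand:
            lo, hi = lo / 2.0, hi * 2.0
            glo, ghi = g(lo), g(hi)
            expand += 1
        if glo * ghi > 0:
            log.info("%s curve: no sign change in delta at %s=%g, point omitted",
                     label, axis, x)
            continue
        delta = brentq(g, lo, hi, xtol=_BISECT_TOL)
        pts.append((x, float(delta)))
    return PhaseCurve(label=label, axis=axis, points=tuple(pts))


def curve_residual(curve: PhaseCurve, fixed: KineticParams) -> np.ndarray:
    """Defining-equation residual at each stored point (for round-trip checks)."""
    res = []
    for x, delta in curve.points:
        p = at_hopf(_params_at_x(curve.axis, fixed, x))
        res.append(_defining_function(curve.label, p)(delta))
    return np.asarray(res)


def hill_overlay(fixed: KineticParams, gamma_s_grid: Sequence[float]) -> HillOverlay:
    """Hill coefficient along a gamma_s grid, with slope signs and argmax.

    The interior maximum (present for the MWC mechanism, absent for the
    monotone Sel'kov form) is located by bounded scalar maximization inside
    the bracketing grid triple."""
    g = np.asarray(sorted(float(v) for v in gamma_s_grid))
    if np.any(g <= 0):
        raise ValueError("gamma_s must be positive")
    nh = np.array([hill_coefficient(fixed, gs) for gs in g])
    slope = np.sign([hill_coefficient_derivative(fixed, gs) for gs in g])
    argmax = None
    i = int(np.argmax(nh))
    if 0 < i < len(g) - 1:
        res = minimize_scalar(
            lambda x: -hill_coefficient(fixed, x),
            bounds=(g[i - 1], g[i + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        argmax = float(res.x)
    return HillOverlay(gamma_s=g, n_H=nh, slope_sign=np.asarray(slope), argmax=argmax)
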