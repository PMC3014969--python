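"""Preset registry for the six reference simulation panels.

Keys ``fig3A``..``fig3F`` carry the reference simulation conditions for the
two mechanisms: Sel'kov/Hill kinetics (nu=0.5, q=1, n=8, sigma=1770, near
the upper Hopf root at ~1791) for panels A-C and MWC kinetics (L=10^3,
sigma=50 or 60, upper Hopf root at ~64) for panels D-F, each with its grid
spacing, time step, total time, diffusion ratio and initial condition.
Panels B, D, E start from crossed concentration gradients that seed a single
phase defect (spiral core); A, C, F start from uniform 5% random noise
around the steady state.

Expected phenotypes: A spatio-temporal chaos, B and D outward spirals,
E inward (anti-)spiral, C and F stationary Turing patterns.
"""

from __future__ import annotations

from dataclasses import replace

from .models import KineticParams
from .pde import SimConfig

__all__ = ["PRESETS", "preset", "preset_names", "EXPECTED_CLASS", "STABLE_DT"]

_SELKOV = KineticParams(nu=0.5, sigma=1770.0, q=1.0, n=8, L=1.0, eps=0.0)
_MWC = KineticParams(nu=0.5, sigma=60.0, q=1.0, n=8, L=1.0e3, eps=1.0)

PRESETS: dict[str, tuple[KineticParams, SimConfig]] = {
    "fig3A": (
        _SELKOV,
        SimConfig(N=176, dx=3.0, dt=0.05, t_end=22.0, delta=1.0, ic="random",
                  amplitude=0.05, seed=0, allow_unstable_dt=True),
    ),
    "fig3B": (
        _SELKOV,
        SimConfig(N=176, dx=3.0, dt=0.05, t_end=22.0, delta=1.5,
                  ic="crossed_gradients", kappa=2.0 / 3.0, seed=0,
                  allow_unstable_dt=True),
    ),
    "fig3C": (
        _SELKOV,
        SimConfig(N=176, dx=0.3, dt=3.0e-3, t_end=22.0, delta=3.0, ic="random",
                  amplitude=0.05, seed=0, allow_unstable_dt=True),
    ),
    "fig3D": (
        replace(_MWC, sigma=50.0),
        SimConfig(N=176, dx=3.0, dt=0.05, t_end=44.0, delta=1.0,
                  ic="crossed_gradients", kappa=1.0 / 70.0, seed=0,
                  allow_unstable_dt=True),
    ),
    "fig3E": (
        _MWC,
        SimConfig(N=176, dx=10.0, dt=0.1, t_end=44.0, delta=3.0,
                  ic="crossed_gradients", kappa=1.0 / 70.0, seed=0,
                  allow_unstable_dt=True),
    ),
    "fig3F": (
        _MWC,
        SimConfig(N=176, dx=0.3, dt=3.0e-3, t_end=44.0, delta=5.0, ic="random",
                  amplitude=0.05, seed=0, allow_unstable_dt=True),
    ),
}

EXPECTED_CLASS = {
    "fig3A": "irregular",
    "fig3B": "coherent_waves",
    "fig3C": "stationary",
    "fig3D": "coherent_waves",
    "fig3E": "coherent_waves",
    "fig3F": "stationary",
}


# Largest RK4-stable time steps for the stiff large-amplitude Hill panels:
# once the relaxation excursion develops, local reaction rates reach
# ~1.7e3 per time unit and the reference dt = 0.05 violates positivity.
STABLE_DT = {"fig3A": 1.0e-3, "fig3B": 1.0e-3}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def preset(name: str, *, N: int | None = None, seed: int | None = None,
           stable_dt: bool = False):
    """Return (params, config) for a named preset.

    ``N`` rescales the grid (the reference runs use N=176), ``seed`` reseeds
    the random initial condition, and ``stable_dt=True`` substitutes the
    largest RK4-stable time step for panels whose reference dt cannot
    integrate the stiff relaxation phases (see ``STABLE_DT``)."""
    try:
        params, cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {preset_names()}")
    if N is not None:
        cfg = replace(cfg, N=int(N))
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    if stable_dt and name in STABLE_DT:
        cfg = replace(cfg, dt=STABLE_DT[name])
    return params, cfg
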