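"""2D reaction-diffusion integration and pattern diagnostics.

Method of lines on a square N x N grid: five-point Laplacian with no-flux
(mirror) boundaries, classical fixed-step RK4 in time.  The integrator
records periodic snapshots of both concentration fields and a space-time
slice along one grid row, from which the diagnostics classify the late-time
dynamics into the three phenotypes relevant for mechanism discrimination:

* ``stationary``     - Turing pattern: spatial structure, no oscillation;
* ``coherent_waves`` - rotating spiral / target waves with a well defined
  phase field (propagation inward or outward relative to the core);
* ``irregular``      - spatio-temporal chaos: sustained oscillations whose
  spatial phase field is disordered.

Concentrations are in units of the respective binding constants, lengths in
units of the activator diffusion length sqrt(D_activator / k_d), time in
units of 1/k_d (k_d = product consumption rate).  The physical side length
of the domain in units of the *inhibitor* diffusion length is
l_s = dx * N / sqrt(delta).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np

from .models import FULL, LOW_FLUX, KineticParams, steady_state, _parse_kv

__all__ = [
    "SimConfig",
    "SimResult",
    "PatternDiagnostics",
    "NumericalInstability",
    "laplacian_noflux",
    "make_ic_random",
    "make_ic_gradients",
    "integrate",
    "diagnostics",
    "propagation_sign_from_slice",
    "side_length",
    "save_result",
    "load_result",
]

STATIONARY = "stationary"
COHERENT = "coherent_waves"
IRREGULAR = "irregular"

OUTWARD = +1
INWARD = -1


class NumericalInstability(RuntimeError):
    """Raised when the integration produces NaN or negative concentrations."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one 2D simulation.

    ``dt`` is guarded by the conservative diffusive stability bound
    dt <= 0.2 dx^2 / (4 max(delta, 1)); reference parameter sets that exceed
    it but remain inside the RK4 stability region can set
    ``allow_unstable_dt=True``.
    """

    N: int = 176
    dx: float = 3.0
    dt: float = 0.05
    t_end: float = 22.0
    delta: float = 1.0
    seed: int = 0
    ic: str = "random"  # or "crossed_gradients"
    amplitude: float = 0.05
    kappa: float = 1.0 / 70.0
    record_row: Optional[int] = None  # None -> middle row
    record_dt: float = 0.05  # space-time slice cadence (time units)
    n_snapshots: int = 9
    allow_unstable_dt: bool = False

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("N must be >= 3")
        if self.dx <= 0 or self.dt <= 0 or self.t_end <= 0 or self.delta <= 0:
            raise ValueError("dx, dt, t_end, delta must be positive")
        if self.ic not in ("random", "crossed_gradients"):
            raise ValueError(f"unknown ic {self.ic!r}")
        if not self.allow_unstable_dt:
            bound = 0.2 * self.dx**2 / (4.0 * max(self.delta, 1.0))
            if self.dt > bound:
                raise ValueError(
                    f"dt={self.dt} exceeds the diffusive stability guard {bound:.3g}; "
                    "set allow_unstable_dt=True to override"
                )

    def to_config(self) -> str:
        d = asdict(self)
        return "\n".join(f"{k}: {v}" for k, v in d.items()) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SimConfig":
        d = _parse_kv(text)
        kw: dict = {}
        for f_ in (
            "N", "seed", "n_snapshots",
        ):
            if f_ in d:
                kw[f_] = int(d[f_])
        for f_ in ("dx", "dt", "t_end", "delta", "amplitude", "kappa", "record_dt"):
            if f_ in d:
                kw[f_] = float(d[f_])
        if "ic" in d:
            kw["ic"] = d["ic"]
        if "record_row" in d:
            kw["record_row"] = None if d["record_row"] == "None" else int(d["record_row"])
        if "allow_unstable_dt" in d:
            kw["allow_unstable_dt"] = d["allow_unstable_dt"] in ("True", "true", "1")
        return cls(**kw)


@dataclass(frozen=True)
class PatternDiagnostics:
    """Late-time classification of a simulation."""

    pattern_class: str
    propagation_sign: Optional[int]  # +1 outward, -1 inward, None undefined
    dominant_wavelength: Optional[float]
    temporal_variance: float
    spatial_amplitude: float
    spectral_concentration: float
    phase_coherence: float
    core_index: Optional[int]


@dataclass
class SimResult:
    """Output of :func:`integrate`."""

    params: KineticParams
    config: SimConfig
    times: np.ndarray  # snapshot times
    snapshots_alpha: np.ndarray  # (n_snap, N, N)
    snapshots_gamma: np.ndarray
    slice_times: np.ndarray  # (T,)
    spacetime: np.ndarray  # (N, T) alpha along the recorded row
    steady: "object" = None

    @property
    def final_alpha(self) -> np.ndarray:
        return self.snapshots_alpha[-1]


# ---------------------------------------------------------------------------
# spatial operator and initial conditions
# ---------------------------------------------------------------------------


def laplacian_noflux(f: np.ndarray, dx: float) -> np.ndarray:
    """Five-point Laplacian with zero-flux (cell-centered mirror) boundaries.

    Ghost cells duplicate the boundary cells, which makes the operator
    exactly mass conserving (its sum over the grid vanishes); its 1D
    eigenmodes are cos(pi m (j + 1/2)/N) with eigenvalue
    -(2/dx^2)(1 - cos(pi m / N)).
    """
    p = np.pad(f, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f
    ) / dx**2


def make_ic_random(steady, N: int, amplitude: float = 0.05, seed: int = 0):
    """Uniform multiplicative noise: field = s * (1 + amplitude*(2r - 1)),
    r ~ U[0, 1] i.i.d. per cell, independently for both fields."""
    if not abs(amplitude) < 1:
        raise ValueError("amplitude must satisfy |amplitude| < 1")
    rng = np.random.default_rng(seed)
    a = steady.alpha_s * (1.0 + amplitude * (2.0 * rng.random((N, N)) - 1.0))
    g = steady.gamma_s * (1.0 + amplitude * (2.0 * rng.random((N, N)) - 1.0))
    return a, g


def make_ic_gradients(steady, N: int, kappa: float):
    """Crossed linear ramps seeding a single phase defect.

    alpha ramps along x (columns), gamma along y (rows):
    alpha = alpha_s (1 + kappa (2x/N - 1)), similarly gamma in y."""
    if not abs(kappa) < 1:
        raise ValueError("|kappa| must be < 1")
    x = np.arange(1, N + 1, dtype=float)
    ramp = kappa * (2.0 * x / N - 1.0)
    a = steady.alpha_s * (1.0 + ramp)[None, :] * np.ones((N, 1))
    g = steady.gamma_s * (1.0 + ramp)[:, None] * np.ones((1, N))
    return a, g


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _make_rhs(params: KineticParams, delta: float, dx: float):
    nu, sigma, q, n, L, eps = (
        params.nu, params.sigma, params.q, params.n, params.L, params.eps,
    )
    low = params.flux_mode == LOW_FLUX

    def rhs(a, g):
        u = (eps + g) ** n
        if low:
            p = a * u
        else:
            p = a * u / (L + (1.0 + a) * u)
        sp = sigma * p
        fa = delta * laplacian_noflux(a, dx) + nu - sp
        fg = laplacian_noflux(g, dx) + q * sp - g
        return fa, fg

    return rhs


def integrate(params: KineticParams, config: SimConfig) -> SimResult:
    """Integrate the reaction-diffusion system with fixed-step RK4.

    Aborts with :class:`NumericalInstability` if the fields become negative
    or non-finite (the exact dynamics preserves positivity, so a violation
    indicates a numerically unstable step size)."""
    ss = steady_state(params)
    N, dt, dx = config.N, config.dt, config.dx
    if config.ic == "random":
        a, g = make_ic_random(ss, N, config.amplitude, config.seed)
    else:
        a, g = make_ic_gradients(ss, N, config.kappa)

    rhs = _make_rhs(params, config.delta, dx)
    n_steps = int(round(config.t_end / dt))
    rec_stride = max(1, int(round(config.record_dt / dt)))
    row = config.record_row if config.record_row is not None else N // 2
    snap_stride = max(1, n_steps // max(1, config.n_snapshots - 1))

    slice_rows = [a[row].copy()]
    slice_times = [0.0]
    snaps_a = [a.copy()]
    snaps_g = [g.copy()]
    snap_times = [0.0]

    half = 0.5 * dt
    sixth = dt / 6.0
    for step in range(1, n_steps + 1):
        k1a, k1g = rhs(a, g)
        k2a, k2g = rhs(a + half * k1a, g + half * k1g)
        k3a, k3g = rhs(a + half * k2a, g + half * k2g)
        k4a, k4g = rhs(a + dt * k3a, g + dt * k3g)
        a = a + sixth * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        g = g + sixth * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
        t = step * dt
        if step % 25 == 0 or step == n_steps:
            if not (np.isfinite(a).all() and np.isfinite(g).all()):
                raise NumericalInstability(f"non-finite field at t={t:.4g}")
            if (a <= 0).any() or (g <= 0).any():
                raise NumericalInstability(
                    f"negative concentration at t={t:.4g} (time step too large)"
                )
        if step % rec_stride == 0:
            slice_rows.append(a[row].copy())
            slice_times.append(t)
        if step % snap_stride == 0 or step == n_steps:
            if snap_times[-1] != t:
                snaps_a.append(a.copy())
                snaps_g.append(g.copy())
                snap_times.append(t)

    return SimResult(
        params=params,
        config=config,
        times=np.asarray(snap_times),
        snapshots_alpha=np.stack(snaps_a),
        snapshots_gamma=np.stack(snaps_g),
        slice_times=np.asarray(slice_times),
        spacetime=np.stack(slice_rows, axis=1),
        steady=ss,
    )


def side_length(dx: float, N: int, delta: float) -> float:
    """Dimensionless domain side length l_s = dx * N / sqrt(delta)
    (in units of the inhibitor diffusion length)."""
    if dx <= 0 or N <= 0 or delta <= 0:
        raise ValueError("inputs must be positive")
    return dx * N / math.sqrt(delta)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

# classification thresholds (dimensionless ratios; see docs/methods.md)
_STATIONARY_RATIO = 0.15  # oscillation amplitude / spatial pattern amplitude
_PHASE_COHERENCE_MIN = 0.85  # local phase-gradient alignment for coherent waves
_EDGE_MARGIN = 0.05  # fraction of the slice excluded at each edge
_CORE_EXCLUSION = 3  # slice cells around the core excluded from velocimetry


def _late_window(result: SimResult, burn_in_frac: float):
    T = result.spacetime.shape[1]
    i0 = int(burn_in_frac * T)
    if T - i0 < 8:
        raise ValueError("insufficient recorded data after burn-in")
    return result.spacetime[:, i0:], result.slice_times[i0:]


def _phase_field(late: np.ndarray):
    """Complex amplitude of each slice cell at the dominant shared frequency.

    Returns (Z, peak_bin, concentration) where concentration is the fraction
    of non-DC temporal power within +/-1 bin of the peak."""
    resid = late - late.mean(axis=1, keepdims=True)
    w = np.hanning(resid.shape[1])
    F = np.fft.rfft(resid * w, axis=1)
    P = (np.abs(F) ** 2).mean(axis=0)
    if len(P) < 3:
        return None, 0, 0.0
    b = 1 + int(np.argmax(P[1:]))
    conc = P[max(1, b - 1): b + 2].sum() / max(P[1:].sum(), 1e-300)
    return F[:, b], b, float(conc)


def propagation_sign_from_slice(
    late: np.ndarray,
    times: np.ndarray,
    core_index: Optional[int] = None,
) -> Optional[int]:
    """Sign of wave propagation relative to the core along a space-time slice.

    Estimates the local phase velocity v(x) from the identity
    v = -<s_t s_x>/<s_x^2> of traveling profiles and averages
    v(x)*sign(x - core) weighted by the local wave energy s_x^2; positive
    means propagation away from the core (outward), negative toward it
    (inward).  The core defaults to the minimum of the (smoothed) local
    oscillation amplitude, which is where a spiral's phase singularity
    pins the amplitude to zero."""
    Nx, T = late.shape
    resid = late - late.mean(axis=1, keepdims=True)
    if core_index is None:
        amp = resid.std(axis=1)
        kern = np.ones(5) / 5.0
        amp_s = np.convolve(amp, kern, mode="same")
        lo = int(_EDGE_MARGIN * Nx)
        core_index = lo + int(np.argmin(amp_s[lo: Nx - lo]))
    st = np.gradient(resid, times, axis=1)
    sx = np.gradient(resid, axis=0)
    lo = int(_EDGE_MARGIN * Nx)
    sgn = np.sign(np.arange(Nx) - core_index)
    mask = np.zeros(Nx, dtype=bool)
    mask[lo: Nx - lo] = True
    mask[max(0, core_index - _CORE_EXCLUSION): core_index + _CORE_EXCLUSION + 1] = False
    w = (sx[mask] ** 2).sum()
    if w <= 0:
        return None
    outward = -(st[mask] * sx[mask] * sgn[mask, None]).sum() / w
    if outward == 0:
        return None
    return OUTWARD if outward > 0 else INWARD


def _radial_wavelength(field: np.ndarray, dx: float) -> Optional[float]:
    """Dominant wavelength from the radially binned 2D power spectrum."""
    f = field - field.mean()
    N = f.shape[0]
    F = np.abs(np.fft.fft2(f)) ** 2
    k = 2.0 * np.pi * np.fft.fftfreq(N, d=dx)
    KX, KY = np.meshgrid(k, k, indexing="ij")
    KR = np.sqrt(KX**2 + KY**2)
    dk = 2.0 * np.pi / (N * dx)
    nbins = N // 2
    idx = np.minimum((KR / dk).astype(int), nbins)
    power = np.bincount(idx.ravel(), weights=F.ravel(), minlength=nbins + 1)[:nbins]
    if len(power) < 3:
        return None
    b = 1 + int(np.argmax(power[1:]))
    k_peak = b * dk
    return 2.0 * np.pi / k_peak if k_peak > 0 else None


def diagnostics(result: SimResult, burn_in_frac: float = 0.5) -> PatternDiagnostics:
    """Classify the late-time dynamics of a simulation.

    Requires at least two snapshots and a populated space-time slice."""
    if result.snapshots_alpha.shape[0] < 2 or result.spacetime.shape[1] < 16:
        raise ValueError("insufficient data for diagnostics")
    late, times = _late_window(result, burn_in_frac)
    resid = late - late.mean(axis=1, keepdims=True)
    # the stationary-vs-oscillatory decision looks at the final quarter only:
    # a Turing mode can outgrow a coexisting weakly unstable Hopf mode late
    T4 = result.spacetime.shape[1] * 3 // 4
    tail = result.spacetime[:, T4:]
    tail_resid = tail - tail.mean(axis=1, keepdims=True)
    osc_amp = float(tail_resid.std(axis=1).mean())
    final = result.final_alpha
    spat_amp = float(final.std())
    wavelength = _radial_wavelength(final, result.config.dx)

    Z, _, conc = _phase_field(late)
    if Z is not None:
        dphase = Z[1:] * np.conj(Z[:-1])
        norm = np.abs(dphase).sum()
        phase_coh = float(np.abs(dphase.sum()) / norm) if norm > 0 else 0.0
    else:
        phase_coh = 0.0

    if osc_amp < _STATIONARY_RATIO * spat_amp:
        return PatternDiagnostics(
            pattern_class=STATIONARY,
            propagation_sign=None,
            dominant_wavelength=wavelength,
            temporal_variance=osc_amp**2,
            spatial_amplitude=spat_amp,
            spectral_concentration=conc,
            phase_coherence=phase_coh,
            core_index=None,
        )

    coherent = phase_coh >= _PHASE_COHERENCE_MIN
    sign = propagation_sign_from_slice(late, times) if coherent else None
    resid_amp = resid.std(axis=1)
    kern = np.ones(5) / 5.0
    lo = int(_EDGE_MARGIN * late.shape[0])
    amp_s = np.convolve(resid_amp, kern, mode="same")
    core = lo + int(np.argmin(amp_s[lo: late.shape[0] - lo])) if coherent else None
    return PatternDiagnostics(
        pattern_class=COHERENT if coherent else IRREGULAR,
        propagation_sign=sign,
        dominant_wavelength=wavelength,
        temporal_variance=osc_amp**2,
        spatial_amplitude=spat_amp,
        spectral_concentration=conc,
        phase_coherence=phase_coh,
        core_index=core,
    )


# ---------------------------------------------------------------------------
# archives
# ---------------------------------------------------------------------------


def save_result(result: SimResult, path: str) -> None:
    """Write arrays to ``<path>.npz`` and a JSON manifest to ``<path>.json``."""
    np.savez_compressed(
        path + ".npz",
        times=result.times,
        snapshots_alpha=result.snapshots_alpha,
        snapshots_gamma=result.snapshots_gamma,
        slice_times=result.slice_times,
        spacetime=result.spacetime,
    )
    manifest = {
        "params": result.params.to_config(),
        "config": result.config.to_config(),
        "seed": result.config.seed,
        "arrays": ["times", "snapshots_alpha", "snapshots_gamma",
                   "slice_times", "spacetime"],
    }
    with open(path + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_result(path: str) -> SimResult:
    with open(path + ".json") as fh:
        manifest = json.load(fh)
    params = KineticParams.from_config(manifest["params"])
    config = SimConfig.from_config(manifest["config"])
    arrs = np.load(path + ".npz")
    return SimResult(
        params=params,
        config=config,
        times=arrs["times"],
        snapshots_alpha=arrs["snapshots_alpha"],
        snapshots_gamma=arrs["snapshots_gamma"],
        slice_times=arrs["slice_times"],
        spacetime=arrs["spacetime"],
        steady=steady_state(params),
    )
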