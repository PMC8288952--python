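"""Synthetic benchmarks: a time-variant coupled Lorenz ring and a linear oracle.

The main benchmark is a ring of q classic Lorenz subsystems (n = 3q state
variables) coupled diffusively through their x-coordinates, with a coupling
strength that is slowly modulated in time so the system is non-stationary:

    dx_i/dt = sigma (y_i - x_i) + c(t) (x_{i-1} - x_i)
    dy_i/dt = x_i (rho - z_i) - y_i
    dz_i/dt = x_i y_i - beta z_i,      c(t) = c0 (1 + A sin(2 pi t / P))

with indices mod q.  Diffusive coupling vanishes on the synchronization
manifold, so for c0 above the ring-synchronization threshold the collective
motion is *synchronized chaos*: the full 3q-dimensional state collapses onto
a low-dimensional attractor carrying the original chaotic Lorenz dynamics,
while the modulation of c(t) periodically weakens transversal stability and
produces time-variant desynchronization bursts.  This is the regime the
method's applicability conditions describe — a high-dimensional observation
of a shared low-dimensional attractor, with every variable subset conveying
the collective state — and the default c0 sits above that threshold (for a
nearest-neighbour ring of 30 the threshold is roughly lambda_max /
(1 - cos(2 pi / 30)) ~ 40, and c(t) dips to c0/2).

The default configuration emits a 90-dimensional series (q = 30) of 55
points: 30 for training plus 25 to be predicted.  Observational noise is
modeled as additive i.i.d. Gaussian draws per cell.

A discrete linear system x(t+1) = A x(t) with spectral radius < 1 serves as an
exactly solvable oracle for end-to-end correctness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import MultivariateSeries

__all__ = [
    "LorenzConfig",
    "NoiseSpec",
    "LinearSystemConfig",
    "simulate_coupled_lorenz",
    "add_gaussian_noise",
    "linear_transition_matrix",
    "simulate_linear_system",
    "iterate_linear",
]


@dataclass
class LorenzConfig:
    """Ring of q coupled Lorenz subsystems with time-modulated coupling.

    Variables are ordered subsystem-major: x1, y1, z1, x2, y2, z2, ...
    ``dt`` is the integrator step; every ``sample_stride``-th state is
    emitted after discarding ``transient`` integrator steps, so the sampling
    interval of the emitted series is ``dt * sample_stride``.
    """

    q: int = 30
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    coupling: float = 80.0
    time_variance_amplitude: float = 0.5
    period: float = 10.0
    dt: float = 0.01
    sample_stride: int = 10
    M_total: int = 55
    transient: int = 4000
    seed: int = 0
    initial_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be at least 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.M_total < 2:
            raise ValueError("M_total must be at least 2")
        if self.transient < 0:
            raise ValueError("transient must be nonnegative")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be at least 1")
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")

    @property
    def n(self) -> int:
        return 3 * self.q


@dataclass
class NoiseSpec:
    """Additive i.i.d. Gaussian observational noise per cell."""

    mean: float = 0.0
    sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class LinearSystemConfig:
    """x(t+1) = A x(t); A either given or seeded random, rescaled to the
    requested spectral radius (< 1 so trajectories stay bounded)."""

    dimension: int = 10
    matrix: np.ndarray | None = None
    spectral_radius: float = 0.95
    initial_state: np.ndarray | None = None
    M_total: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be at least 1")
        if self.matrix is None and not 0 < self.spectral_radius < 1:
            raise ValueError("auto-generated transition matrix needs spectral radius in (0, 1)")
        if self.M_total < 2:
            raise ValueError("M_total must be at least 2")


def _lorenz_deriv(u: np.ndarray, t: float, cfg: LorenzConfig) -> np.ndarray:
    x, y, z = u[0::3], u[1::3], u[2::3]
    c = cfg.coupling * (1.0 + cfg.time_variance_amplitude * np.sin(2.0 * np.pi * t / cfg.period))
    du = np.empty_like(u)
    du[0::3] = cfg.sigma * (y - x) + c * (np.roll(x, 1) - x)
    du[1::3] = x * (cfg.rho - z) - y
    du[2::3] = x * y - cfg.beta * z
    return du


def simulate_coupled_lorenz(config: LorenzConfig) -> MultivariateSeries:
    """Integrate the ring with fixed-step 4th-order Runge-Kutta.

    Discards the transient, then emits M_total samples, one every
    sample_stride steps (the first emitted point is the state right after the
    transient).  Deterministic given the seed, which draws the initial state
    uniformly from [-10, 10]^n unless an explicit initial state is supplied.
    """
    n = config.n
    if config.initial_state is not None:
        u = np.asarray(config.initial_state, dtype=float).copy()
        if u.shape != (n,):
            raise ValueError(f"initial_state must have shape ({n},)")
    else:
        u = np.random.default_rng(config.seed).uniform(-10.0, 10.0, size=n)
    dt = config.dt
    t = 0.0
    out = np.empty((n, config.M_total))
    total_steps = config.transient + (config.M_total - 1) * config.sample_stride
    emit_every = config.sample_stride
    col = 0
    for step in range(total_steps + 1):
        if step >= config.transient and (step - config.transient) % emit_every == 0:
            out[:, col] = u
            col += 1
            if col == config.M_total:
                break
        k1 = _lorenz_deriv(u, t, config)
        k2 = _lorenz_deriv(u + 0.5 * dt * k1, t + 0.5 * dt, config)
        k3 = _lorenz_deriv(u + 0.5 * dt * k2, t + 0.5 * dt, config)
        k4 = _lorenz_deriv(u + dt * k3, t + dt, config)
        u = u + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += dt
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(f"coupled-Lorenz integration blew up at step {step + 1}")
    names = [f"{c}{i + 1}" for i in range(config.q) for c in ("x", "y", "z")]
    return MultivariateSeries(out, names, tau=dt * emit_every, start_time=config.transient * dt)


def add_gaussian_noise(series: MultivariateSeries, spec: NoiseSpec) -> MultivariateSeries:
    """Return a noisy copy; the input series is left untouched."""
    rng = np.random.default_rng(spec.seed)
    noisy = series.values + rng.normal(spec.mean, spec.sd, size=series.values.shape)
    return MultivariateSeries(noisy, list(series.variable_names),
                              tau=series.tau, start_time=series.start_time)


def linear_transition_matrix(config: LinearSystemConfig) -> np.ndarray:
    """The resolved transition matrix A (given, or seeded random rescaled to
    the requested spectral radius)."""
    if config.matrix is not None:
        A = np.asarray(config.matrix, dtype=float)
        if A.shape != (config.dimension, config.dimension):
            raise ValueError("transition matrix shape does not match dimension")
        return A
    rng = np.random.default_rng(config.seed)
    A = rng.normal(size=(config.dimension, config.dimension))
    radius = np.abs(np.linalg.eigvals(A)).max()
    return A * (config.spectral_radius / radius)


def iterate_linear(A: np.ndarray, x0: np.ndarray, steps: int) -> np.ndarray:
    """Exact trajectory [x0, A x0, ..., A^steps x0] as a (d, steps+1) array."""
    d = len(x0)
    out = np.empty((d, steps + 1))
    out[:, 0] = x0
    for t in range(steps):
        out[:, t + 1] = A @ out[:, t]
    return out


def simulate_linear_system(config: LinearSystemConfig) -> MultivariateSeries:
    """Emit M_total points of the exact linear iteration (the oracle fixture)."""
    A = linear_transition_matrix(config)
    if config.initial_state is not None:
        x0 = np.asarray(config.initial_state, dtype=float)
        if x0.shape != (config.dimension,):
            raise ValueError("initial_state shape does not match dimension")
    else:
        x0 = np.random.default_rng(config.seed + 1).uniform(0.5, 1.5, size=config.dimension)
    traj = iterate_linear(A, x0, config.M_total - 1)
    names = [f"v{i + 1}" for i in range(config.dimension)]
    return MultivariateSeries(traj, names, tau=1.0, start_time=0.0)
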