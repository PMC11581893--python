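"""Kuramoto phase-oscillator dynamics and metastability profiles.

Each network node i is a phase oscillator with intrinsic frequency
``omega_i`` evolving as

    dtheta_i/dt = omega_i + lambda * sum_j A_ij sin(theta_j - theta_i)

on the binary adjacency ``A`` (no noise, no conduction delays).  The
coupling ``lambda = K / (N d)`` is normalised by the adjacency density
``d = (1/N^2) sum_ij A_ij`` -- i.e. ``lambda = K N / sum_ij A_ij``,
equivalently ``K / mean_degree`` -- so that networks of different
density are driven comparably: the summed coupling a typical node feels
is ~``K``, and a sweep of K in [0, 3] spans the whole transition for
frequency spreads of order 1 rad/s.

Global coherence at any instant is the Kuramoto order parameter

    r e^{i Psi} = (1/N) sum_j e^{i theta_j},

with r = 0 full incoherence and r = 1 full synchrony.  *Metastability*
is the standard deviation of r over the post-transient window, and the
*metastability profile* is the curve of metastability across a sweep of
K spanning the transition from incoherence to synchrony.  The profile is
the dynamical signature used to pick a representative group network.

Integration is explicit Euler.  The integrator advances all couplings of
the sweep simultaneously (one batched state per K value), which is what
makes profile computation for whole cohorts tractable; phases are kept
unwrapped internally since ``sin(theta_j - theta_i)`` is wrap-invariant,
and wrapped to (-pi, pi] only when reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import BinaryConnectome

__all__ = [
    "SimulationConfig", "CouplingGrid", "OscillatorState",
    "OrderParameterSeries", "MetastabilityProfile", "coupling_lambda",
    "integrate", "order_parameter", "metastability", "metastability_profile",
    "draw_state",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation protocol parameters.

    Defaults: 100 s of simulated time per realisation with the first 50 s
    discarded as transient, Euler step 1 ms, natural frequencies drawn
    from Normal(40 Hz ~ 251.33 rad/s, 1 rad/s).  The mean frequency only
    sets the rotating frame and does not affect the metastability
    profile; the small frequency spread keeps the synchronisation
    transition structural rather than frequency-driven (a spread of 0
    would abolish the transition entirely).
    """

    total_time: float = 100.0
    transient_time: float = 50.0
    dt: float = 0.001
    mean_frequency: float = TWO_PI * 40.0
    frequency_sd: float = 1.0
    n_realisations: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.transient_time < self.total_time:
            raise ValueError("need 0 <= transient_time < total_time")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frequency_sd < 0:
            raise ValueError("frequency_sd must be >= 0")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be >= 1")

    @classmethod
    def smoke(cls, rng_seed: int = 0, **kw) -> "SimulationConfig":
        """Reduced preset (10 s total, 5 s transient, dt 5 ms) for fast runs."""
        kw.setdefault("total_time", 10.0)
        kw.setdefault("transient_time", 5.0)
        kw.setdefault("dt", 0.005)
        return cls(rng_seed=rng_seed, **kw)


@dataclass(frozen=True)
class CouplingGrid:
    """Ascending grid of global coupling constants K."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("coupling grid must be a non-empty 1-D array")
        if v[0] < 0 or np.any(np.diff(v) <= 0):
            raise ValueError("coupling grid must be strictly ascending, first >= 0")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def default(cls) -> "CouplingGrid":
        """K = 0 to 3 in steps of 0.125: 25 values spanning the transition."""
        return cls(values=np.arange(0.0, 3.0 + 1e-12, 0.125))


@dataclass(frozen=True)
class OscillatorState:
    """Initial phases (reported wrapped to (-pi, pi]) and natural frequencies."""

    phases: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float)
        w = np.asarray(self.frequencies, dtype=float)
        if p.shape != w.shape or p.ndim != 1:
            raise ValueError("phases and frequencies must be equal-length vectors")
        object.__setattr__(self, "phases", p)
        object.__setattr__(self, "frequencies", w)


@dataclass(frozen=True)
class OrderParameterSeries:
    """Post-transient order-parameter time series."""

    times: np.ndarray
    r: np.ndarray
    psi: np.ndarray


@dataclass(frozen=True)
class MetastabilityProfile:
    """Metastability per coupling value, averaged over realisations."""

    grid: CouplingGrid
    values: np.ndarray
    realisation_sd: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.grid) or len(self.realisation_sd) != len(self.grid):
            raise ValueError("profile length must match the coupling grid")


def coupling_lambda(K: float, adjacency: np.ndarray) -> float:
    """Density-normalised coupling ``lambda = K / (N d) = K N / sum_ij A_ij``.

    ``d = sum_ij A_ij / N^2`` is the density of the adjacency matrix, so
    ``lambda`` equals ``K`` divided by the mean degree: the total
    coupling a typical node receives is ~``K`` regardless of density.
    """
    adjacency = np.asarray(adjacency)
    total = float(adjacency.sum())
    if total == 0.0:
        if K > 0:
            warnings.warn(
                "edgeless network: coupling undefined, using 0 (free rotation)"
            )
        return 0.0
    return K * adjacency.shape[0] / total


def order_parameter(phases: np.ndarray) -> tuple[float, float]:
    """Modulus r and mean phase Psi of the average unit phasor."""
    z = np.exp(1j * np.asarray(phases, dtype=float)).mean()
    return float(np.abs(z)), float(np.angle(z))


def draw_state(n_nodes: int, config: SimulationConfig, realisation: int = 0) -> OscillatorState:
    """Random initial phases in (-pi, pi) and normal natural frequencies.

    The draw depends only on ``(config.rng_seed, realisation, n_nodes)``,
    never on the network, so networks of equal size compared under one
    config share identical initial conditions and frequencies (common
    random numbers).
    """
    rng = np.random.default_rng([realisation, config.rng_seed])
    phases = rng.uniform(-math.pi, math.pi, size=n_nodes)
    freqs = rng.normal(config.mean_frequency, config.frequency_sd, size=n_nodes)
    return OscillatorState(phases=phases, frequencies=freqs)


def _euler_r_batch(
    adjacency: np.ndarray,
    theta0: np.ndarray,  # (B, N)
    omega: np.ndarray,  # (B, N)
    lam: np.ndarray,  # (B,)
    config: SimulationConfig,
    record_psi: bool = False,
):
    """Euler-integrate B independent coupling settings simultaneously.

    Returns ``(times, r, psi)`` where r has shape (B, n_kept) containing
    the order parameter at every step with t >= transient_time.
    """
    A = np.asarray(adjacency, dtype=float)
    dt = config.dt
    n_steps = int(round(config.total_time / dt))
    first_kept = int(math.ceil(config.transient_time / dt - 1e-9))
    n_kept = n_steps - first_kept + 1
    B, N = theta0.shape

    theta = theta0.astype(float).copy()
    lam_col = lam[:, None]
    r_out = np.empty((B, n_kept))
    psi_out = np.empty((B, n_kept)) if record_psi else None

    k = 0
    for m in range(n_steps + 1):
        s = np.sin(theta)
        c = np.cos(theta)
        if m >= first_kept:
            ms, mc = s.mean(axis=1), c.mean(axis=1)
            r_out[:, k] = np.hypot(mc, ms)
            if record_psi:
                psi_out[:, k] = np.arctan2(ms, mc)
            k += 1
        if m == n_steps:
            break
        # sum_j A_ij sin(theta_j - theta_i) = cos_i (A s)_i - sin_i (A c)_i
        coupling = c * (s @ A) - s * (c @ A)
        theta = theta + dt * (omega + lam_col * coupling)
        if m % 1000 == 999 and not np.all(np.isfinite(theta)):
            raise FloatingPointError(
                f"non-finite phase encountered at integration step {m + 1}"
            )

    times = (first_kept + np.arange(n_kept)) * dt
    return times, r_out, psi_out


def integrate(
    adjacency: np.ndarray | BinaryConnectome,
    state: OscillatorState,
    K: float,
    config: SimulationConfig,
) -> OrderParameterSeries:
    """Integrate one network at one coupling; return the post-transient KOP."""
    if isinstance(adjacency, BinaryConnectome):
        adjacency = adjacency.adjacency
    lam = np.array([coupling_lambda(K, adjacency)])
    times, r, psi = _euler_r_batch(
        adjacency,
        state.phases[None, :],
        state.frequencies[None, :],
        lam,
        config,
        record_psi=True,
    )
    return OrderParameterSeries(times=times, r=r[0], psi=psi[0])


def metastability(series) -> float:
    """Population standard deviation of the order parameter over time."""
    r = series.r if isinstance(series, OrderParameterSeries) else np.asarray(series, float)
    if r.size == 0:
        raise ValueError("empty order-parameter series")
    return float(np.std(r))


def metastability_profile(
    network: BinaryConnectome | np.ndarray,
    grid: CouplingGrid | None = None,
    config: SimulationConfig | None = None,
) -> MetastabilityProfile:
    """Metastability at every coupling of the sweep.

    Each realisation draws one (initial phase, frequency) pair and reuses
    it for every K on the grid; the profile is the per-K mean over
    realisations, with the across-realisation sample SD reported
    alongside (0 for a single realisation).  Deterministic given
    ``config.rng_seed``.
    """
    if grid is None:
        grid = CouplingGrid.default()
    if config is None:
        config = SimulationConfig()
    A = network.adjacency if isinstance(network, BinaryConnectome) else network
    n = A.shape[0]
    lam = np.array([coupling_lambda(K, A) for K in grid.values])

    per_real = np.empty((config.n_realisations, len(grid)))
    for real in range(config.n_realisations):
        state = draw_state(n, config, realisation=real)
        theta0 = np.broadcast_to(state.phases, (len(grid), n))
        omega = np.broadcast_to(state.frequencies, (len(grid), n))
        _, r, _ = _euler_r_batch(A, np.array(theta0), np.array(omega), lam, config)
        per_real[real] = np.std(r, axis=1)

    values = per_real.mean(axis=0)
    if config.n_realisations > 1:
        spread = per_real.std(axis=0, ddof=1)
    else:
        spread = np.zeros(len(grid))
    return MetastabilityProfile(grid=grid, values=values, realisation_sd=spread)
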