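"""Overdamped Langevin toy systems and burst-ensemble harvesting.

This module provides the self-contained test bed of the pipeline: a 2D
four-well potential integrated with the Euler–Maruyama scheme, plus the
machinery to subsample a long equilibrium trajectory into *N* initial
states and to launch *M* short bursts from each of them.  The resulting
:class:`EnsembleData` (``X0`` of shape ``(N, d)`` and ``Xtau`` of shape
``(N, M, d)``) is the sole input the membership-function learner needs.

Units follow the molecular convention: lengths in nm, energies in
kJ/mol, times in ps, temperatures in K.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

__all__ = [
    "PotentialSpec",
    "LangevinParams",
    "Trajectory",
    "EnsembleData",
    "IntegrationError",
    "four_well_potential",
    "euler_maruyama_step",
    "sample_long_trajectory",
    "harvest_ensemble",
]

MOLAR_KB = 8.314e-3  # kJ / (K mol)

#: Any coordinate exceeding this magnitude aborts the integration: the
#: overdamped dynamics of a confining potential can never reach it, so
#: hitting it indicates a diverging timestep.
DIVERGENCE_BOUND = 1.0e6


class IntegrationError(RuntimeError):
    """Raised when the Euler–Maruyama update diverges."""


@dataclass(frozen=True)
class PotentialSpec:
    """A confining potential V with its analytic gradient.

    ``energy`` and ``gradient`` must accept arrays of shape ``(..., d)``
    and return shapes ``(...)`` and ``(..., d)`` respectively.
    ``jit_gradient``, when present, is a numba-compiled scalar-state
    gradient used by the fast long-trajectory driver.
    """

    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    dimension: int
    name: str = "custom"
    jit_gradient: Optional[Callable] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of overdamped Langevin dynamics.

    The derived quantities follow the fluctuation–dissipation relation:
    ``beta = 1/(kB*T)`` (mol/kJ) and ``diffusion = kB*T/(m*gamma)``
    (nm^2/ps).
    """

    temperature: float = 300.0
    boltzmann_constant: float = MOLAR_KB
    mass: float = 1.0
    friction: float = 1.0
    timestep: float = 0.001

    def __post_init__(self) -> None:
        for name in ("temperature", "boltzmann_constant", "mass", "friction", "timestep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kT(self) -> float:
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @property
    def diffusion(self) -> float:
        return self.kT / (self.mass * self.friction)


@dataclass(frozen=True)
class Trajectory:
    positions: np.ndarray  # (n_frames, d)
    timestep: float
    seed: int

    def __post_init__(self) -> None:
        if self.positions.ndim != 2 or len(self.positions) < 1:
            raise ValueError("positions must be a (n_frames, d) array with n_frames >= 1")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory contains non-finite positions")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class EnsembleData:
    """Paired initial states and burst endpoints.

    ``X0`` has shape ``(N, d)``; ``Xtau`` has shape ``(N, M, d)`` where
    ``Xtau[n, m]`` is the endpoint of the m-th burst launched from
    ``X0[n]``.  ``lag`` is the burst length in ps.
    """

    X0: np.ndarray
    Xtau: np.ndarray
    lag: float
    seed: int

    def __post_init__(self) -> None:
        if self.X0.ndim != 2 or self.Xtau.ndim != 3:
            raise ValueError("X0 must be (N, d) and Xtau must be (N, M, d)")
        if self.Xtau.shape[0] != self.X0.shape[0] or self.Xtau.shape[2] != self.X0.shape[1]:
            raise ValueError("Xtau first/last axes must match X0")
        if self.X0.shape[0] < 2:
            raise ValueError("need at least N = 2 initial states")
        if self.Xtau.shape[1] < 1:
            raise ValueError("need at least M = 1 burst per state")
        if not (np.all(np.isfinite(self.X0)) and np.all(np.isfinite(self.Xtau))):
            raise ValueError("ensemble contains non-finite entries")

    @property
    def n_states(self) -> int:
        return self.X0.shape[0]

    @property
    def n_bursts(self) -> int:
        return self.Xtau.shape[1]

    @property
    def dimension(self) -> int:
        return self.X0.shape[1]

    def save(self, path: str | Path) -> None:
        """Write the ensemble to a single ``.npz`` container plus an
        ``X0`` CSV fallback next to it."""
        path = Path(path)
        np.savez(
            path,
            X0=self.X0,
            Xtau=self.Xtau,
            lag=np.asarray(self.lag),
            seed=np.asarray(self.seed),
        )
        csv_path = path.with_suffix(".csv")
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([f"x{i}" for i in range(self.dimension)])
            writer.writerows(self.X0.tolist())

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleData":
        with np.load(Path(path).with_suffix(".npz")) as data:
            return cls(
                X0=data["X0"],
                Xtau=data["Xtau"],
                lag=float(data["lag"]),
                seed=int(data["seed"]),
            )


# ---------------------------------------------------------------------------
# Four-well potential (2D)
# ---------------------------------------------------------------------------

def _four_well_energy(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    a, b = x[..., 0], x[..., 1]
    return 10.0 * (a**2 - 1.0) ** 2 + 5.0 * a * b + 10.0 * (b**2 - 1.0) ** 2 + 2.2 * a


def _four_well_gradient(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    a, b = x[..., 0], x[..., 1]
    gx = 40.0 * a * (a**2 - 1.0) + 5.0 * b + 2.2
    gy = 5.0 * a + 40.0 * b * (b**2 - 1.0)
    return np.stack([gx, gy], axis=-1)


def _compile_four_well_gradient():
    from numba import njit

    @njit(cache=True, fastmath=False)
    def grad(x, out):
        a = x[0]
        b = x[1]
        out[0] = 40.0 * a * (a * a - 1.0) + 5.0 * b + 2.2
        out[1] = 5.0 * a + 40.0 * b * (b * b - 1.0)

    return grad


_FOUR_WELL_JIT = None


def four_well_potential() -> PotentialSpec:
    """The 2D four-well landscape V(x,y) = 10(x^2-1)^2 + 5xy + 10(y^2-1)^2 + 2.2x.

    Four local minima of staggered depth sit near the corners of
    [-1, 1]^2; the tilt terms (5xy and 2.2x) make (-1, 1) the deepest
    well and (1, 1) the shallowest.
    """
    global _FOUR_WELL_JIT
    if _FOUR_WELL_JIT is None:
        try:
            _FOUR_WELL_JIT = _compile_four_well_gradient()
        except Exception:  # pragma: no cover - numba unavailable
            _FOUR_WELL_JIT = False
    jit = _FOUR_WELL_JIT if _FOUR_WELL_JIT else None
    return PotentialSpec(
        energy=_four_well_energy,
        gradient=_four_well_gradient,
        dimension=2,
        name="four-well",
        jit_gradient=jit,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def euler_maruyama_step(
    state: np.ndarray,
    potential: PotentialSpec,
    params: LangevinParams,
    noise: np.ndarray,
) -> np.ndarray:
    """One explicit Euler–Maruyama update of the overdamped dynamics.

    ``x' = x - beta*D*grad(V)(x)*dt + sqrt(2*D*dt)*noise`` applied
    componentwise; ``noise`` must hold i.i.d. standard normals.  Works on
    a single state ``(d,)`` or a batch ``(n, d)``.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise IntegrationError("non-finite state passed to euler_maruyama_step")
    dt = params.timestep
    drift = params.beta * params.diffusion * potential.gradient(state) * dt
    new = state - drift + np.sqrt(2.0 * params.diffusion * dt) * np.asarray(noise, dtype=float)
    if not np.all(np.abs(new) < DIVERGENCE_BOUND):
        raise IntegrationError(
            "Euler-Maruyama update diverged (|x| > %.0e); reduce the timestep" % DIVERGENCE_BOUND
        )
    return new


_DRIVER_CACHE: dict = {}


def _get_jit_driver(jit_gradient):
    """Build (once per gradient) a numba loop running the whole trajectory."""
    key = id(jit_gradient)
    if key in _DRIVER_CACHE:
        return _DRIVER_CACHE[key]
    from numba import njit

    @njit(cache=False)
    def drive(x0, noise, betaD_dt, amp, bound, out):
        d = x0.shape[0]
        x = x0.copy()
        g = np.empty(d)
        out[0] = x
        n = noise.shape[0]
        for k in range(n):
            jit_gradient(x, g)
            for j in range(d):
                x[j] = x[j] - betaD_dt * g[j] + amp * noise[k, j]
                if not (np.abs(x[j]) < bound):
                    return k + 1
            out[k + 1] = x
        return n + 1

    _DRIVER_CACHE[key] = drive
    return drive


def sample_long_trajectory(
    potential: PotentialSpec,
    params: LangevinParams,
    n_steps: int,
    initial: np.ndarray,
    seed: int,
    burn_in_fraction: float = 0.0,
) -> Trajectory:
    """Integrate ``n_steps`` Euler–Maruyama steps from ``initial``.

    Deterministic for a given ``seed``.  ``burn_in_fraction`` drops the
    leading fraction of frames after integration (the default keeps
    everything; the toy landscape equilibrates quickly when started in a
    minimum).  Returns all retained frames including the initial point.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    initial = np.asarray(initial, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, potential.dimension))
    betaD_dt = params.beta * params.diffusion * params.timestep
    amp = np.sqrt(2.0 * params.diffusion * params.timestep)

    positions = np.empty((n_steps + 1, potential.dimension), dtype=float)
    if potential.jit_gradient is not None:
        drive = _get_jit_driver(potential.jit_gradient)
        written = drive(initial, noise, betaD_dt, amp, DIVERGENCE_BOUND, positions)
        if written != n_steps + 1:
            raise IntegrationError(
                f"trajectory diverged at step {written}; reduce the timestep"
            )
    else:
        x = initial.copy()
        positions[0] = x
        for k in range(n_steps):
            x = x - betaD_dt * potential.gradient(x) + amp * noise[k]
            if not np.all(np.abs(x) < DIVERGENCE_BOUND):
                raise IntegrationError(
                    f"trajectory diverged at step {k + 1}; reduce the timestep"
                )
            positions[k + 1] = x
    if burn_in_fraction > 0.0:
        start = int(burn_in_fraction * len(positions))
        positions = positions[start:]
    return Trajectory(positions=positions, timestep=params.timestep, seed=seed)


def harvest_ensemble(
    traj: Trajectory,
    n_states: int,
    stride: int,
    n_bursts: int,
    burst_steps: int,
    potential: PotentialSpec,
    params: LangevinParams,
    seed: int,
) -> EnsembleData:
    """Subsample ``n_states`` frames (one every ``stride``) and launch
    ``n_bursts`` independent bursts of ``burst_steps`` steps from each.

    The burst noise streams are spawned from ``seed`` independently of
    the trajectory, so changing ``n_bursts`` or ``burst_steps`` never
    perturbs ``X0``.  Bursts are integrated for all states at once
    (vectorized over the ``N * M`` replicas).
    """
    if stride < 1 or n_states < 1 or n_bursts < 1 or burst_steps < 0:
        raise ValueError("n_states, stride, n_bursts must be >= 1 and burst_steps >= 0")
    needed = (n_states - 1) * stride + 1
    if needed > len(traj):
        raise ValueError(
            f"trajectory too short: need {needed} frames for n_states={n_states}, "
            f"stride={stride}, have {len(traj)}"
        )
    X0 = np.array(traj.positions[: needed : stride], dtype=float)
    d = X0.shape[1]
    replicas = np.repeat(X0, n_bursts, axis=0)  # (N*M, d)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for _ in range(burst_steps):
        noise = rng.standard_normal(replicas.shape)
        replicas = euler_maruyama_step(replicas, potential, params, noise)
    Xtau = replicas.reshape(n_states, n_bursts, d)
    return EnsembleData(X0=X0, Xtau=Xtau, lag=burst_steps * params.timestep, seed=seed)


def boltzmann_density_2d(
    potential: PotentialSpec,
    params: LangevinParams,
    grid: int = 50,
    bounds: tuple[float, float] = (-2.0, 2.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized equilibrium density exp(-beta*V)/Z on a square grid.

    Returns ``(edges_x, edges_y, density)`` where ``density`` holds cell
    probabilities (summing to one), computed by midpoint quadrature.
    Used as the independent reference for equilibrium-consistency checks.
    """
    if potential.dimension != 2:
        raise ValueError("boltzmann_density_2d requires a 2D potential")
    edges = np.linspace(bounds[0], bounds[1], grid + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(mids, mids, indexing="ij")
    pts = np.stack([xx, yy], axis=-1)
    w = np.exp(-params.beta * potential.energy(pts))
    return edges, edges, w / w.sum()
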