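"""Markov-chain Monte Carlo sampling of driven-chain configurations.

Two non-local move types update the chain: a *crankshaft* rotation of an
interior sub-chain about the axis through its two bounding joints, and a
*pivot* rotation of a terminal sub-chain about a random axis through the pivot
joint. Proposals carrying a hard-sphere overlap are rejected outright;
otherwise the standard Metropolis rule ``min(1, exp(-ΔE))`` applies. The
anchored joint ``r_0`` never moves.

The production sampler (:func:`run_simulation`) runs a numba-compiled kernel;
the per-move functions here are plain numpy and expose the same moves for
inspection and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _mckernels
from .polymer import (
    ChainConfiguration,
    ConformationVariables,
    EnergyParameters,
    total_energy,
)

__all__ = [
    "MCSchedule",
    "MCResult",
    "crankshaft_move",
    "pivot_move",
    "has_overlap",
    "metropolis_step",
    "run_simulation",
    "observables_table",
    "blocked_standard_error",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCSchedule:
    """Sweep counts, sampling interval, move amplitude and seed of one MC run.

    One sweep is N attempted moves. Defaults (2·10⁴ equilibration sweeps,
    10⁴ sampling sweeps retained every 10² sweeps, half-π move amplitude) are
    calibrated so the bending-only closed forms reproduce within 1%.
    """

    n_equilibration_sweeps: int = 20_000
    n_sample_sweeps: int = 10_000
    sample_interval: int = 100
    max_rotation_angle: float = np.pi / 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_equilibration_sweeps, self.n_sample_sweeps, self.sample_interval) < 1:
            raise ValueError("all schedule counts must be >= 1")
        if not 0 < self.max_rotation_angle <= np.pi:
            raise ValueError("max_rotation_angle must lie in (0, pi]")
        if self.sample_interval > self.n_sample_sweeps:
            raise ValueError("sample_interval exceeds n_sample_sweeps")


@dataclass
class MCResult:
    """Retained samples and per-sample observables of one MC run."""

    samples: np.ndarray  # (n_kept, N+1, 3)
    energy_trace: np.ndarray
    acceptance_rates: dict
    observables: pd.DataFrame  # columns r2, rg2, rxz
    params: EnergyParameters
    schedule: MCSchedule
    n_bonds: int
    bond_length: float = 1.0
    self_avoiding: bool = True

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def configurations(self) -> list[ChainConfiguration]:
        return [ChainConfiguration(s, self.bond_length) for s in self.samples]


# ---------------------------------------------------------------------------
# single moves (numpy reference implementations of the jitted kernel's moves)
# ---------------------------------------------------------------------------


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    ux, uy, uz = u
    cross = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(u, u)


def crankshaft_move(
    config: ChainConfiguration, rng: np.random.Generator, max_angle: float
) -> ChainConfiguration:
    """Rotate an interior sub-chain about the axis through two chosen joints.

    Endpoints ``a < b`` are drawn with ``b >= a + 2`` so at least one joint
    moves; the joints strictly between them rotate by a uniform angle in
    ``[-max_angle, max_angle]``. Bond lengths are preserved exactly (rigid
    rotation).
    """
    n = config.n_bonds
    if n < 3:
        raise ValueError("crankshaft needs at least 3 bonds")
    a = int(rng.integers(0, n - 1))
    b = int(rng.integers(a + 2, n + 1))
    axis = config.joints[b] - config.joints[a]
    if np.linalg.norm(axis) == 0:  # impossible under chain invariants
        raise RuntimeError("degenerate crankshaft axis")
    angle = rng.uniform(-max_angle, max_angle)
    rot = _rotation_matrix(axis, angle)
    joints = config.joints.copy()
    seg = joints[a + 1 : b] - joints[a]
    joints[a + 1 : b] = seg @ rot.T + joints[a]
    return ChainConfiguration(joints, config.bond_length)


def pivot_move(
    config: ChainConfiguration, rng: np.random.Generator, max_angle: float
) -> ChainConfiguration:
    """Rotate the tail sub-chain beyond a uniformly chosen pivot joint.

    The rotation axis is isotropically random through the pivot; joint 0 (the
    anchored end) never moves.
    """
    n = config.n_bonds
    p = int(rng.integers(0, n))
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:
        axis = rng.normal(size=3)
    angle = rng.uniform(-max_angle, max_angle)
    rot = _rotation_matrix(axis, angle)
    joints = config.joints.copy()
    seg = joints[p + 1 :] - joints[p]
    joints[p + 1 :] = seg @ rot.T + joints[p]
    return ChainConfiguration(joints, config.bond_length)


def has_overlap(config: ChainConfiguration) -> bool:
    """Hard-sphere self-avoidance test; see :meth:`ChainConfiguration.has_overlap`."""
    return config.has_overlap()


def metropolis_step(
    config: ChainConfiguration,
    params: EnergyParameters,
    rng: np.random.Generator,
    schedule: MCSchedule,
    self_avoiding: bool = True,
) -> tuple[ChainConfiguration, bool]:
    """One Metropolis update: propose a crankshaft or pivot (equal odds),
    reject outright on overlap, otherwise accept with ``min(1, exp(-ΔE))``.

    Returns ``(new_config, accepted)``; on rejection the input configuration
    is returned unchanged.
    """
    max_angle = schedule.max_rotation_angle
    if config.n_bonds >= 3 and rng.random() < 0.5:
        proposal = crankshaft_move(config, rng, max_angle)
    else:
        proposal = pivot_move(config, rng, max_angle)
    if self_avoiding and proposal.has_overlap():
        return config, False
    de = total_energy(proposal, params) - total_energy(config, params)
    if de <= 0 or rng.random() < np.exp(-de):
        return proposal, True
    return config, False


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def observables_table(samples: np.ndarray) -> pd.DataFrame:
    """Per-sample conformation variables (r2, rg2, rxz) of a sample stack."""
    centered = samples - samples.mean(axis=1, keepdims=True)
    rg2 = np.mean(np.sum(centered**2, axis=2), axis=1)
    rxz = np.mean(centered[:, :, 0] * centered[:, :, 2], axis=1)
    ee = samples[:, -1] - samples[:, 0]
    r2 = np.sum(ee**2, axis=1)
    return pd.DataFrame({"r2": r2, "rg2": rg2, "rxz": rxz})


def run_simulation(
    params: EnergyParameters,
    n_bonds: int,
    schedule: MCSchedule,
    bond_length: float = 1.0,
    self_avoiding: bool = True,
) -> MCResult:
    """Run one seeded MC simulation from a straight rod along x̂.

    Deterministic given ``schedule.seed``. Retains
    ``n_sample_sweeps // sample_interval`` configurations after discarding the
    equilibration sweeps and computes conformation observables per retained
    sample. An equilibration acceptance rate below 1% is logged as a warning
    (not fatal).
    """
    if n_bonds < 3:
        raise ValueError("run_simulation requires at least 3 bonds")
    init = ChainConfiguration.straight_rod(n_bonds, bond_length)
    samples, etrace, accepted, attempted = _mckernels.run_mc(
        init.joints,
        params.kappa,
        params.f,
        params.gamma,
        bond_length,
        schedule.n_equilibration_sweeps,
        schedule.n_sample_sweeps,
        schedule.sample_interval,
        schedule.max_rotation_angle,
        schedule.seed,
        self_avoiding,
    )
    rates = {
        "crankshaft": float(accepted[0] / max(attempted[0], 1)),
        "pivot": float(accepted[1] / max(attempted[1], 1)),
        "overall": float(accepted.sum() / max(attempted.sum(), 1)),
    }
    if rates["overall"] < 0.01:
        logger.warning(
            "MC acceptance rate %.4f below 1%% (kappa=%g f=%g gamma=%g)",
            rates["overall"],
            params.kappa,
            params.f,
            params.gamma,
        )
    return MCResult(
        samples=samples,
        energy_trace=etrace,
        acceptance_rates=rates,
        observables=observables_table(samples),
        params=params,
        schedule=schedule,
        n_bonds=n_bonds,
        bond_length=bond_length,
        self_avoiding=self_avoiding,
    )


def blocked_standard_error(x: np.ndarray, n_blocks: int = 20) -> float:
    """Standard error of the mean of a (possibly correlated) MC series,
    estimated from ``n_blocks`` block means."""
    x = np.asarray(x, dtype=float)
    n_blocks = min(n_blocks, len(x))
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))
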