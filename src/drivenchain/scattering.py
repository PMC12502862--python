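"""2D scattering function I_xz(Q) of chain ensembles on a rectangular Q grid.

The single-configuration scattering function is the normalized interference
pattern of the joints,

    I(Q) = | sum_j exp(i Q . r_j) |^2 / M^2 ,   Q = (Q_x, 0, Q_z),

with M the number of scatterers (all N+1 joints, including the anchored one).
Ensemble maps are arithmetic means over retained MC samples — no orientational
averaging, since the anisotropy induced by the forces is the signal. The
normalization by M² guarantees I(0) = 1 and 0 ≤ I ≤ 1 everywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "QGrid",
    "ScatteringMap",
    "make_q_grid",
    "single_config_intensity",
    "ensemble_intensity",
]


@dataclass(frozen=True)
class QGrid:
    """Rectangular (Q_x, Q_z) grid, units 1/l_b.

    Flattening order is fixed and row-major with Q_x as the outer axis:
    flat index = ix * len(qz) + iz. The hash of the axis arrays travels with
    datasets so training and inversion grids can be verified identical.
    """

    qx: np.ndarray
    qz: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "qx", np.asarray(self.qx, dtype=float))
        object.__setattr__(self, "qz", np.asarray(self.qz, dtype=float))
        for ax in (self.qx, self.qz):
            if ax.ndim != 1 or ax.size == 0:
                raise ValueError("grid axes must be non-empty 1D arrays")
            if np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.qx.size * self.qz.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.qx.size, self.qz.size)

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.qx.tobytes())
        h.update(self.qz.tobytes())
        return h.hexdigest()

    def origin_index(self) -> tuple[int, int]:
        ix = int(np.argmin(np.abs(self.qx)))
        iz = int(np.argmin(np.abs(self.qz)))
        return ix, iz


def make_q_grid(n_per_axis: int, q_max: float) -> QGrid:
    """Uniform symmetric grid on [-q_max, q_max]² with n_per_axis² points.

    ``n_per_axis`` must be odd so Q = 0 is a grid point (needed for the
    I(0) = 1 normalization check); the protocol grid is 51 points per axis
    with q_max = 50π/L.
    """
    if n_per_axis < 1 or n_per_axis % 2 == 0:
        raise ValueError("n_per_axis must be odd so the origin is a grid point")
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    axis = np.linspace(-q_max, q_max, n_per_axis)
    axis[n_per_axis // 2] = 0.0  # exact zero at the centre
    return QGrid(axis, axis.copy())


def single_config_intensity(points: np.ndarray, grid: QGrid) -> np.ndarray:
    """I(Q_x, Q_z) of one point set via the complex scattering amplitude.

    O(n_grid · M) through separable phase factors — never the O(M²) pair sum,
    but exactly equal to it. Rows index Q_x, columns Q_z.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] == 0:
        raise ValueError("points must be a non-empty (M, 3) array")
    m = points.shape[0]
    phase_x = np.exp(1j * np.outer(grid.qx, points[:, 0]))
    phase_z = np.exp(1j * np.outer(grid.qz, points[:, 2]))
    amplitude = phase_x @ phase_z.T
    return np.abs(amplitude) ** 2 / m**2


@dataclass
class ScatteringMap:
    """Ensemble-averaged 2D intensity on a Q grid."""

    grid: QGrid
    intensity: np.ndarray  # shape (len(qx), len(qz))
    n_configurations: int

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != grid shape {self.grid.shape}"
            )

    def flatten(self) -> np.ndarray:
        """Row-major flattening, Q_x outer / Q_z inner."""
        return self.intensity.ravel(order="C")

    def validate(self, atol: float = 1e-9) -> None:
        i = self.intensity
        if np.any(i < -atol) or np.any(i > 1 + atol):
            raise ValueError("intensities must lie in [0, 1]")
        ix, iz = self.grid.origin_index()
        if abs(self.grid.qx[ix]) < 1e-15 and abs(self.grid.qz[iz]) < 1e-15:
            if abs(i[ix, iz] - 1.0) > atol:
                raise ValueError(f"I(0,0) = {i[ix, iz]!r} != 1")
        if not np.allclose(i, i[::-1, ::-1], atol=atol):
            raise ValueError("inversion symmetry I(Q) = I(-Q) violated")

    # -- IO ----------------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("intensity", data=self.intensity)
            h5.create_dataset("qx", data=self.grid.qx)
            h5.create_dataset("qz", data=self.grid.qz)
            h5.attrs["meta"] = json.dumps(
                {"n_configurations": self.n_configurations, "grid_hash": self.grid.hash}
            )

    @classmethod
    def load(cls, path) -> "ScatteringMap":
        with h5py.File(path, "r") as h5:
            grid = QGrid(h5["qx"][:], h5["qz"][:])
            meta = json.loads(h5.attrs["meta"])
            return cls(grid, h5["intensity"][:], meta["n_configurations"])

    def to_csv(self, path) -> None:
        """Long-format CSV export (columns qx, qz, I)."""
        qx, qz = np.meshgrid(self.grid.qx, self.grid.qz, indexing="ij")
        pd.DataFrame(
            {"qx": qx.ravel(), "qz": qz.ravel(), "I": self.flatten()}
        ).to_csv(path, index=False)


def ensemble_intensity(result, grid: QGrid) -> ScatteringMap:
    """Arithmetic mean of single-configuration intensities over an ensemble.

    ``result`` may be an :class:`~drivenchain.mc.MCResult` or a raw
    (n_samples, M, 3) stack of joint positions.
    """
    samples = getattr(result, "samples", result)
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[0] == 0:
        raise ValueError("need at least one retained sample")
    acc = np.zeros(grid.shape)
    for s in samples:
        acc += single_config_intensity(s, grid)
    acc /= samples.shape[0]
    return ScatteringMap(grid, acc, int(samples.shape[0]))
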