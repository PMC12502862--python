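"""Dataset assembly: sample energy parameters, run the forward model, and
collect flattened scattering maps with their six inversion targets.

The protocol draws (κ, f, γL) uniformly — κ ~ U(2, 20), f ~ U(0, 0.5),
γL ~ U(0, 2) — runs one MC simulation per draw, computes the ensemble map
I_xz(Q) on a shared grid, and stacks the flattened maps into the matrix F
(n_samples × n_grid_points). Targets per row are the three energy parameters
plus the ensemble-mean conformation variables normalized by contour length:
R²/L², Rg²/L² and R_xz/L² (the normalization exponent of the gyration
quantities is configurable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .mc import MCSchedule, run_simulation
from .polymer import EnergyParameters
from .scattering import QGrid, ScatteringMap, ensemble_intensity

__all__ = [
    "DEFAULT_RANGES",
    "TARGET_COLUMNS",
    "ParameterSample",
    "ScatteringDataset",
    "sample_parameters",
    "build_dataset",
    "split_dataset",
    "child_seed",
]

logger = logging.getLogger(__name__)

#: protocol sampling ranges for (kappa, f, gammaL)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "kappa": (2.0, 20.0),
    "f": (0.0, 0.5),
    "gammaL": (0.0, 2.0),
}

#: the six inversion targets, energy parameters first
TARGET_COLUMNS = ("kappa", "f", "gammaL", "r2_over_L2", "rg2_norm", "rxz_norm")


@dataclass(frozen=True)
class ParameterSample:
    """One (κ, f, γL) draw; γL is the contour-length normalized shear."""

    kappa: float
    f: float
    gammaL: float


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-row seed (< 2³¹) so any row reproduces in isolation."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def sample_parameters(
    n: int, ranges: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` independent uniform (kappa, f, gammaL) triples.

    Degenerate intervals [a, a] are allowed (constant column); inverted or
    non-finite intervals raise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    cols = {}
    for name in ("kappa", "f", "gammaL"):
        lo, hi = ranges[name]
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
            raise ValueError(f"invalid interval for {name}: [{lo}, {hi}]")
        cols[name] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    return pd.DataFrame(cols)


@dataclass
class ScatteringDataset:
    """Matrix F of flattened scattering maps plus the per-row target table."""

    F: np.ndarray  # (n_samples, n_grid_points)
    targets: pd.DataFrame  # columns TARGET_COLUMNS
    grid: QGrid
    manifest: dict

    def __post_init__(self) -> None:
        if self.F.shape[0] != len(self.targets):
            raise ValueError("F and targets disagree on the number of rows")
        if self.F.shape[1] != self.grid.n_points:
            raise ValueError("F row length does not match the grid")
        self.manifest = dict(self.manifest)
        self.manifest.setdefault("grid_hash", self.grid.hash)

    @property
    def n_samples(self) -> int:
        return self.F.shape[0]

    def map_for_row(self, i: int) -> ScatteringMap:
        return ScatteringMap(
            self.grid,
            self.F[i].reshape(self.grid.shape),
            int(self.manifest.get("n_configurations_per_map", 0)) or 1,
        )

    def subset(self, rows: np.ndarray, tag: str = "subset") -> "ScatteringDataset":
        manifest = dict(self.manifest)
        manifest["parent_rows"] = [int(r) for r in rows]
        manifest["subset_tag"] = tag
        return ScatteringDataset(
            self.F[rows], self.targets.iloc[rows].reset_index(drop=True), self.grid, manifest
        )

    # -- IO ----------------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("F", data=self.F)
            h5.create_dataset("targets", data=self.targets.to_numpy(dtype=float))
            h5.attrs["target_columns"] = json.dumps(list(self.targets.columns))
            h5.create_dataset("qx", data=self.grid.qx)
            h5.create_dataset("qz", data=self.grid.qz)
            h5.attrs["manifest"] = json.dumps(self.manifest)

    @classmethod
    def load(cls, path) -> "ScatteringDataset":
        with h5py.File(path, "r") as h5:
            grid = QGrid(h5["qx"][:], h5["qz"][:])
            cols = json.loads(h5.attrs["target_columns"])
            targets = pd.DataFrame(h5["targets"][:], columns=cols)
            return cls(h5["F"][:], targets, grid, json.loads(h5.attrs["manifest"]))

    def export_targets_csv(self, path) -> None:
        self.targets.to_csv(path, index=False)


def _build_row(
    row: ParameterSample,
    n_bonds: int,
    bond_length: float,
    schedule: MCSchedule,
    grid: QGrid,
    seed: int,
    self_avoiding: bool,
    norm_exponent: int,
):
    contour = n_bonds * bond_length
    params = EnergyParameters(row.kappa, row.f, row.gammaL / contour)
    result = run_simulation(
        params, n_bonds, replace(schedule, seed=seed), bond_length, self_avoiding
    )
    smap = ensemble_intensity(result, grid)
    obs = result.observables.mean()
    targets = {
        "kappa": row.kappa,
        "f": row.f,
        "gammaL": row.gammaL,
        "r2_over_L2": obs["r2"] / contour**2,
        "rg2_norm": obs["rg2"] / contour**norm_exponent,
        "rxz_norm": obs["rxz"] / contour**norm_exponent,
    }
    return smap.flatten(), targets


def build_dataset(
    samples: pd.DataFrame,
    n_bonds: int,
    schedule: MCSchedule,
    grid: QGrid,
    seed: int = 0,
    bond_length: float = 1.0,
    self_avoiding: bool = True,
    norm_exponent: int = 2,
    noise_level: float | None = None,
    n_jobs: int = 1,
) -> ScatteringDataset:
    """Run the forward model for every parameter row and assemble F.

    Rows are independent (parallelizable via ``n_jobs``) and order-preserving;
    each row's MC run uses a seed derived deterministically from
    ``(seed, row index)``. A failed simulation excludes its row with a logged
    reason recorded in the manifest — never silently dropped.

    ``noise_level`` optionally applies multiplicative Gaussian noise to the
    finished maps (off by default: training is on clean simulated curves).
    """
    tasks = []
    for i, rec in enumerate(samples.itertuples(index=False)):
        tasks.append((i, ParameterSample(rec.kappa, rec.f, rec.gammaL), child_seed(seed, i)))

    def work(i, ps, row_seed):
        try:
            return i, _build_row(
                ps, n_bonds, bond_length, schedule, grid, row_seed, self_avoiding, norm_exponent
            ), None
        except Exception as exc:  # pragma: no cover - defensive
            return i, None, f"{type(exc).__name__}: {exc}"

    if n_jobs == 1:
        outcomes = [work(*t) for t in tasks]
    else:
        outcomes = Parallel(n_jobs=n_jobs)(delayed(work)(*t) for t in tasks)

    rows, target_rows, failures = [], [], []
    for i, payload, err in outcomes:
        if err is not None:
            logger.warning("row %d failed and was excluded: %s", i, err)
            failures.append({"row": i, "reason": err})
            continue
        flat, targets = payload
        rows.append(flat)
        target_rows.append(targets)

    if not rows:
        raise RuntimeError("every forward simulation failed")

    F = np.vstack(rows)
    if noise_level:
        noise_rng = np.random.default_rng(child_seed(seed, len(tasks)))
        F = F * noise_rng.normal(1.0, noise_level, size=F.shape)
    targets = pd.DataFrame(target_rows, columns=list(TARGET_COLUMNS))
    manifest = {
        "n_requested": len(tasks),
        "n_built": len(rows),
        "failed_rows": failures,
        "master_seed": int(seed),
        "n_bonds": int(n_bonds),
        "bond_length": float(bond_length),
        "contour_length": float(n_bonds * bond_length),
        "self_avoiding": bool(self_avoiding),
        "norm_exponent": int(norm_exponent),
        "noise_level": noise_level,
        "schedule": {
            "n_equilibration_sweeps": schedule.n_equilibration_sweeps,
            "n_sample_sweeps": schedule.n_sample_sweeps,
            "sample_interval": schedule.sample_interval,
            "max_rotation_angle": schedule.max_rotation_angle,
        },
        "n_configurations_per_map": schedule.n_sample_sweeps // schedule.sample_interval,
        "flatten_order": "row-major, qx outer, qz inner",
    }
    return ScatteringDataset(F, targets, grid, manifest)


def split_dataset(
    ds: ScatteringDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[ScatteringDataset, ScatteringDataset]:
    """Disjoint uniformly random train/test row partition.

    ``n_train = round(train_fraction * n)``; the protocol split of a 1680-row
    dataset at 0.7 is 1176 train / 504 test. Both halves carry the same grid.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return ds.subset(np.sort(perm[:n_train]), "train"), ds.subset(
        np.sort(perm[n_train:]), "test"
    )
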