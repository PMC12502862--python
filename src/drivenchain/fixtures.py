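"""Deterministic fixture generators for tests and examples.

Every fixture satisfies the invariants of the object it produces, except the
ideal random walk, which deliberately bypasses self-avoidance (flagged below)
to make closed-form random-walk statistics exact.
"""

from __future__ import annotations

import numpy as np

from .gpr import KernelSpec, kernel_matrix
from .polymer import ChainConfiguration

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("straight_rod", "planar_zigzag", "ideal_random_walk", "gp_toy_dataset")


def _straight_rod(params: dict) -> ChainConfiguration:
    return ChainConfiguration.straight_rod(
        params.get("n_bonds", 200), params.get("bond_length", 1.0)
    )


def _planar_zigzag(params: dict) -> ChainConfiguration:
    """Right-angle zigzag confined to the (x, y) plane: x,y,x,y,... steps.

    Non-consecutive joints are at least √2·l_b apart, so the configuration is
    overlap-free.
    """
    n = params.get("n_bonds", 10)
    lb = params.get("bond_length", 1.0)
    joints = np.zeros((n + 1, 3))
    pos = np.zeros(3)
    for i in range(n):
        step = np.array([lb, 0.0, 0.0]) if i % 2 == 0 else np.array([0.0, lb, 0.0])
        pos = pos + step
        joints[i + 1] = pos
    return ChainConfiguration(joints, lb)


def _ideal_random_walk(params: dict, rng: np.random.Generator) -> ChainConfiguration:
    """Freely jointed chain with isotropic unit steps — NOT self-avoiding.

    Closed forms like <R²> = N·l_b² are exact for this fixture; validate it
    with ``self_avoiding=False``.
    """
    n = params.get("n_bonds", 50)
    lb = params.get("bond_length", 1.0)
    steps = rng.normal(size=(n, 3))
    steps *= lb / np.linalg.norm(steps, axis=1)[:, None]
    joints = np.zeros((n + 1, 3))
    joints[1:] = np.cumsum(steps, axis=0)
    return ChainConfiguration(joints, lb)


def _gp_toy_dataset(params: dict, rng: np.random.Generator):
    """(X, y) drawn from the RBF + white-noise GP itself.

    Used by hyperparameter-recovery tests: fitting should approximately find
    the generating (l*, σ*).
    """
    n = params.get("n", 100)
    dim = params.get("dim", 2)
    spec = KernelSpec(
        params.get("length_scale", 1.0),
        params.get("noise", 0.1),
        params.get("mean", 0.0),
    )
    X = rng.normal(size=(n, dim))
    K = kernel_matrix(X, None, spec)
    L = np.linalg.cholesky(K + 1e-12 * np.eye(n))
    y = spec.constant_mean + L @ rng.normal(size=n)
    return X, y


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a named deterministic fixture.

    ``kind`` is one of :data:`FIXTURE_KINDS`; unknown kinds raise with the
    list of available ones.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "straight_rod":
        return _straight_rod(params)
    if kind == "planar_zigzag":
        return _planar_zigzag(params)
    if kind == "ideal_random_walk":
        return _ideal_random_walk(params, rng)
    if kind == "gp_toy_dataset":
        return _gp_toy_dataset(params, rng)
    raise ValueError(f"unknown fixture kind {kind!r}; available: {FIXTURE_KINDS}")
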