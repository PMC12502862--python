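"""Chain configurations, the driven-chain energy, and conformation observables.

The model is a discrete worm-like chain of ``N`` bonds of fixed length ``l_b``
(so ``N + 1`` joints ``r_0 .. r_N``), with one end pinned at the origin. Bond
tangents are ``t_i = (r_{i+1} - r_i) / l_b``. The chain is driven by a
stretching force ``f`` along x and a shear coupling ``gamma`` along z, on top
of a bending stiffness ``kappa``; all energies are measured in units of the
thermal energy k_B·T = 1 and lengths in units of ``l_b`` (natural units).

The total energy implemented here is

    E = sum_{i=1}^{N-1} kappa * (1 - t_{i-1} . t_i)
        - f * l_b * sum_{i=0}^{N-1} (t_i . x̂)
        - gamma * l_b * sum_{i=0}^{N-1} z_i * (t_i . x̂)

with ``z_i`` the z coordinate of the *starting* joint of bond ``i``. Joints
carry hard spheres of radius ``l_b / 2`` for self-avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "InvalidConfigurationError",
    "EnergyParameters",
    "ChainConfiguration",
    "ConformationVariables",
    "tangent_vectors",
    "total_energy",
    "energy_terms",
    "conformation_variables",
    "normalized_targets",
]

#: relative tolerance on bond lengths
BOND_RTOL = 1e-9
#: slack on the hard-sphere overlap test so exactly-touching spheres never trigger
OVERLAP_SLACK = 1e-12


class InvalidConfigurationError(ValueError):
    """Raised when chain coordinates violate the model's structural invariants."""


@dataclass(frozen=True)
class EnergyParameters:
    """Energy parameters of the driven chain, in thermal units (k_B·T = 1).

    Parameters
    ----------
    kappa : float
        Bending modulus (k_B·T). Sets the persistence length, roughly
        ``kappa * l_b`` for stiff chains.
    f : float
        Stretching force along x (k_B·T / l_b).
    gamma : float
        Shear-rate coupling along z (k_B·T / l_b²). The dimensionless
        ``gamma * L`` is the form used for sampling and inversion.
    """

    kappa: float
    f: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kappa", "f", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class ConformationVariables:
    """Scalar conformation observables of a single chain configuration.

    ``r2`` is the squared end-to-end distance |r_N - r_0|², ``rg2`` the squared
    radius of gyration (trace of the gyration tensor) and ``rxz`` the xz
    component of the gyration tensor, which measures shear-induced tilt and may
    be negative. All in units of l_b².
    """

    r2: float
    rg2: float
    rxz: float


@dataclass
class ChainConfiguration:
    """An ``N``-bond chain given by its ``N + 1`` joint positions.

    Invariants (checked by :meth:`validate`): the first joint sits at the
    origin, every bond has length ``bond_length`` to within ``BOND_RTOL``
    relative tolerance, and no two non-consecutive joints approach closer than
    ``bond_length`` (hard spheres of radius ``bond_length / 2``).
    """

    joints: np.ndarray
    bond_length: float = 1.0

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.ndim != 2 or self.joints.shape[1] != 3:
            raise InvalidConfigurationError(
                f"joints must be an (N+1, 3) array, got shape {self.joints.shape}"
            )
        if self.joints.shape[0] < 2:
            raise InvalidConfigurationError("a chain needs at least one bond")
        if self.bond_length <= 0:
            raise InvalidConfigurationError("bond_length must be positive")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_bonds(self) -> int:
        return self.joints.shape[0] - 1

    @property
    def contour_length(self) -> float:
        """Contour length L = N * l_b."""
        return self.n_bonds * self.bond_length

    def tangents(self) -> np.ndarray:
        """Unit bond tangents t_i = (r_{i+1} - r_i) / l_b, shape (N, 3)."""
        bonds = np.diff(self.joints, axis=0)
        lengths = np.linalg.norm(bonds, axis=1)
        if np.any(lengths == 0):
            raise InvalidConfigurationError("zero-length bond")
        return bonds / lengths[:, None]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.joints, axis=0), axis=1)

    def validate(self, self_avoiding: bool = True) -> None:
        """Raise :class:`InvalidConfigurationError` on any violated invariant."""
        if not np.all(np.isfinite(self.joints)):
            raise InvalidConfigurationError("non-finite joint coordinates")
        if not np.allclose(self.joints[0], 0.0, atol=BOND_RTOL):
            raise InvalidConfigurationError("first joint must sit at the origin")
        lengths = self.bond_lengths()
        if not np.allclose(lengths, self.bond_length, rtol=BOND_RTOL, atol=0):
            worst = float(np.max(np.abs(lengths - self.bond_length)))
            raise InvalidConfigurationError(
                f"bond lengths deviate from l_b by up to {worst:.3g}"
            )
        if self_avoiding and self.has_overlap():
            raise InvalidConfigurationError("hard-sphere overlap between joints")

    def has_overlap(self) -> bool:
        """True iff any non-consecutive joint pair is closer than ``bond_length``.

        Consecutive joints sit at exactly ``bond_length`` and never count; a
        multiplicative 1e-12 slack keeps exactly-touching spheres from
        triggering through rounding.
        """
        m = self.joints.shape[0]
        if m < 3:
            return False
        d = pdist(self.joints)
        # condensed index of pair (i, i+1) is i*m - i*(i+1)//2  + 0
        idx = np.arange(m - 1)
        consecutive = idx * m - idx * (idx + 1) // 2
        mask = np.ones(d.shape[0], dtype=bool)
        mask[consecutive] = False
        return bool(np.any(d[mask] < self.bond_length * (1.0 - OVERLAP_SLACK)))

    # -- constructors / IO -------------------------------------------------

    @classmethod
    def straight_rod(cls, n_bonds: int, bond_length: float = 1.0) -> "ChainConfiguration":
        """A straight chain along x̂ — the overlap-free initial state."""
        joints = np.zeros((n_bonds + 1, 3))
        joints[:, 0] = np.arange(n_bonds + 1) * bond_length
        return cls(joints, bond_length)

    def to_csv(self, path) -> None:
        """Write joints as plain CSV (columns x,y,z) at full double precision."""
        np.savetxt(
            path, self.joints, delimiter=",", header="x,y,z", comments="", fmt="%.17g"
        )

    @classmethod
    def from_csv(cls, path, bond_length: float = 1.0) -> "ChainConfiguration":
        joints = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(joints, bond_length)


def tangent_vectors(config: ChainConfiguration) -> np.ndarray:
    """Unit bond tangents of ``config``; see :meth:`ChainConfiguration.tangents`."""
    return config.tangents()


def energy_terms(
    config: ChainConfiguration, params: EnergyParameters
) -> tuple[float, float, float]:
    """Additive energy decomposition ``(E_bend, E_stretch, E_shear)`` in k_B·T.

    This is the single code location defining the sign and prefactor of each
    term; :func:`total_energy` and the jitted MC kernel follow it.
    """
    if not np.all(np.isfinite(config.joints)):
        raise InvalidConfigurationError("non-finite joint coordinates")
    t = config.tangents()
    lb = config.bond_length
    e_bend = params.kappa * float(np.sum(1.0 - np.einsum("ij,ij->i", t[:-1], t[1:])))
    e_stretch = -params.f * lb * float(np.sum(t[:, 0]))
    # z of the bond's starting joint couples with the bond's x tangent
    e_shear = -params.gamma * lb * float(np.dot(config.joints[:-1, 2], t[:, 0]))
    return e_bend, e_stretch, e_shear


def total_energy(config: ChainConfiguration, params: EnergyParameters) -> float:
    """Total driven-chain energy E = E_bend + E_stretch + E_shear (k_B·T)."""
    return float(sum(energy_terms(config, params)))


def conformation_variables(config: ChainConfiguration) -> ConformationVariables:
    """End-to-end distance squared, Rg² and the xz gyration-tensor component.

    Gyration quantities are computed in centroid form, O(N); the pair-average
    form (half the mean squared distance over all joint pairs) is equivalent
    and asserted in the test suite.
    """
    r = config.joints
    dv = r[-1] - r[0]
    r2 = float(dv @ dv)
    centered = r - r.mean(axis=0)
    rg2 = float(np.mean(np.sum(centered**2, axis=1)))
    rxz = float(np.mean(centered[:, 0] * centered[:, 2]))
    return ConformationVariables(r2=r2, rg2=rg2, rxz=rxz)


def normalized_targets(
    cv: ConformationVariables, contour_length: float, exponent: int = 2
) -> dict[str, float]:
    """Contour-length normalized conformation targets.

    ``r2`` is always divided by L²; the gyration quantities are divided by
    ``L**exponent`` (default 2, giving dimensionless values; ``exponent=1``
    reproduces the alternative per-contour-length normalization).
    """
    L = contour_length
    return {
        "r2_over_L2": cv.r2 / L**2,
        "rg2_norm": cv.rg2 / L**exponent,
        "rxz_norm": cv.rxz / L**exponent,
    }
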