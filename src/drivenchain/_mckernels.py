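"""Numba-jitted inner loops of the Monte Carlo engine.

Everything here operates on a raw (N+1, 3) position array; the user-facing
API lives in :mod:`drivenchain.mc`. The energy expression must stay in sync
with :func:`drivenchain.polymer.energy_terms` (asserted in the tests).
"""

import numpy as np
from numba import njit

# move-type codes in the acceptance bookkeeping
CRANKSHAFT = 0
PIVOT = 1

_OVERLAP_SLACK = 1e-12


@njit(cache=True)
def chain_energy(pos, kappa, f, gamma, lb):
    """Total driven-chain energy of a position array (k_B·T)."""
    n = pos.shape[0] - 1
    e = 0.0
    inv_lb2 = 1.0 / (lb * lb)
    for i in range(n):
        tx = (pos[i + 1, 0] - pos[i, 0]) / lb
        e -= f * lb * tx
        e -= gamma * lb * pos[i, 2] * tx
    for i in range(1, n):
        dot = 0.0
        for k in range(3):
            dot += (pos[i + 1, k] - pos[i, k]) * (pos[i, k] - pos[i - 1, k])
        e += kappa * (1.0 - dot * inv_lb2)
    return e


@njit(cache=True)
def segment_overlap(pos, m0, m1, lb):
    """Hard-sphere test of moved joints ``m0..m1`` against the rest.

    A rigid rotation preserves distances within the moved block and the
    unmoved block is untouched, so only cross pairs need checking. Strict
    inequality with a 1e-12 slack: exactly-touching spheres never trigger.
    """
    m = pos.shape[0]
    lim = (lb * (1.0 - _OVERLAP_SLACK)) ** 2
    for i in range(m0, m1 + 1):
        for j in range(m):
            if m0 <= j <= m1:
                continue
            if j == i - 1 or j == i + 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < lim:
                return True
    return False


@njit(cache=True)
def rotate_segment(pos, m0, m1, ox, oy, oz, ux, uy, uz, angle):
    """Rodrigues rotation of joints ``m0..m1`` about unit axis u through (ox,oy,oz)."""
    c = np.cos(angle)
    s = np.sin(angle)
    omc = 1.0 - c
    for i in range(m0, m1 + 1):
        px = pos[i, 0] - ox
        py = pos[i, 1] - oy
        pz = pos[i, 2] - oz
        dot = ux * px + uy * py + uz * pz
        cx = uy * pz - uz * py
        cy = uz * px - ux * pz
        cz = ux * py - uy * px
        pos[i, 0] = ox + px * c + cx * s + ux * dot * omc
        pos[i, 1] = oy + py * c + cy * s + uy * dot * omc
        pos[i, 2] = oz + pz * c + cz * s + uz * dot * omc


@njit(cache=True)
def run_mc(
    pos_init,
    kappa,
    f,
    gamma,
    lb,
    n_equil,
    n_sample,
    interval,
    max_angle,
    seed,
    self_avoiding,
):
    """Metropolis sampling with 50/50 crankshaft/pivot moves.

    One sweep = N attempted moves. Returns retained configurations (one every
    ``interval`` sweeps after equilibration), the energy at each retained
    sample, and per-move-type (accepted, attempted) counters.
    """
    np.random.seed(seed)
    m = pos_init.shape[0]
    n = m - 1
    pos = pos_init.copy()
    trial = pos_init.copy()
    energy = chain_energy(pos, kappa, f, gamma, lb)

    n_keep = n_sample // interval
    samples = np.empty((n_keep, m, 3))
    etrace = np.empty(n_keep)
    accepted = np.zeros(2, dtype=np.int64)
    attempted = np.zeros(2, dtype=np.int64)

    kept = 0
    for sweep in range(n_equil + n_sample):
        for _ in range(n):
            if n >= 3 and np.random.random() < 0.5:
                mt = CRANKSHAFT
                a = np.random.randint(0, n - 1)  # a in [0, N-2]
                b = np.random.randint(a + 2, n + 1)  # b in [a+2, N]
                m0 = a + 1
                m1 = b - 1
                ax = pos[b, 0] - pos[a, 0]
                ay = pos[b, 1] - pos[a, 1]
                az = pos[b, 2] - pos[a, 2]
                norm = np.sqrt(ax * ax + ay * ay + az * az)
                ax /= norm
                ay /= norm
                az /= norm
                ox = pos[a, 0]
                oy = pos[a, 1]
                oz = pos[a, 2]
            else:
                mt = PIVOT
                p = np.random.randint(0, n)  # p in [0, N-1]
                m0 = p + 1
                m1 = n
                ax = np.random.normal()
                ay = np.random.normal()
                az = np.random.normal()
                norm = np.sqrt(ax * ax + ay * ay + az * az)
                while norm < 1e-12:
                    ax = np.random.normal()
                    ay = np.random.normal()
                    az = np.random.normal()
                    norm = np.sqrt(ax * ax + ay * ay + az * az)
                ax /= norm
                ay /= norm
                az /= norm
                ox = pos[p, 0]
                oy = pos[p, 1]
                oz = pos[p, 2]
            angle = (2.0 * np.random.random() - 1.0) * max_angle
            attempted[mt] += 1

            rotate_segment(trial, m0, m1, ox, oy, oz, ax, ay, az, angle)

            ok = True
            if self_avoiding and segment_overlap(trial, m0, m1, lb):
                ok = False
            if ok:
                e_new = chain_energy(trial, kappa, f, gamma, lb)
                de = e_new - energy
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    accepted[mt] += 1
                    for i in range(m0, m1 + 1):
                        pos[i, 0] = trial[i, 0]
                        pos[i, 1] = trial[i, 1]
                        pos[i, 2] = trial[i, 2]
                    energy = e_new
                else:
                    ok = False
            if not ok:
                for i in range(m0, m1 + 1):
                    trial[i, 0] = pos[i, 0]
                    trial[i, 1] = pos[i, 1]
                    trial[i, 2] = pos[i, 2]

        if sweep >= n_equil and (sweep - n_equil + 1) % interval == 0:
            for i in range(m):
                samples[kept, i, 0] = pos[i, 0]
                samples[kept, i, 1] = pos[i, 1]
                samples[kept, i, 2] = pos[i, 2]
            etrace[kept] = energy
            kept += 1

    return samples, etrace, accepted, attempted
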