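"""Lattice diffusion-limited aggregation (DLA).

Two-dimensional on-lattice DLA is the reference fractal for
diffusion-limited growth: its clusters have a fractal dimension of about
1.71, the regime early tumor vasculature is often compared against.  The
generator here is the ground-truth source for the box-counting estimator
in :mod:`camulm.metrics`.

Rules: a single seed particle sits at the lattice center; walkers are
launched uniformly on a birth circle of radius ``max cluster radius + 5``,
take uniform 4-neighbor lattice steps, stick onto the first site adjacent
(4-connectivity) to the cluster, and are discarded beyond a kill circle of
3× the birth radius.  The inner walker loop is JIT-compiled with numba and
driven by an explicit xorshift RNG, so a given seed reproduces the same
cluster bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["generate_dla_cluster"]


@njit(cache=True)
def _xorshift64(state: np.uint64) -> np.uint64:
    # xorshift64* style mixing; cheap, full-period, platform-stable
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def _splitmix64(x: np.uint64) -> np.uint64:
    # Steele et al. splitmix64 finalizer: decorrelates consecutive seeds
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x ^ (x >> np.uint64(31))


@njit(cache=True)
def _dla_core(n_particles: int, seed: np.uint64, grid: np.ndarray) -> int:
    size = grid.shape[0]
    c = size // 2
    grid[c, c] = 1
    r_max = 0.0
    state = _splitmix64(seed)
    if state == np.uint64(0):
        state = np.uint64(0x9E3779B97F4A7C15)

    placed = 1
    while placed < n_particles:
        birth_r = r_max + 5.0
        kill_r2 = (3.0 * birth_r) ** 2

        state = _xorshift64(state)
        ang = 2.0 * np.pi * (np.float64(state & np.uint64(0xFFFFFFFF)) / 4294967296.0)
        x = int(round(birth_r * np.cos(ang)))
        y = int(round(birth_r * np.sin(ang)))

        while True:
            state = _xorshift64(state)
            step = state & np.uint64(3)
            if step == np.uint64(0):
                x += 1
            elif step == np.uint64(1):
                x -= 1
            elif step == np.uint64(2):
                y += 1
            else:
                y -= 1

            r2 = np.float64(x * x + y * y)
            if r2 > kill_r2:
                # killed: relaunch a fresh walker
                state = _xorshift64(state)
                ang = 2.0 * np.pi * (np.float64(state & np.uint64(0xFFFFFFFF)) / 4294967296.0)
                x = int(round(birth_r * np.cos(ang)))
                y = int(round(birth_r * np.sin(ang)))
                continue

            if r2 > (r_max + 2.0) * (r_max + 2.0):
                continue  # cannot be adjacent to the cluster yet

            gx, gy = c + x, c + y
            if gx < 1 or gx >= size - 1 or gy < 1 or gy >= size - 1:
                continue
            if (grid[gx + 1, gy] or grid[gx - 1, gy]
                    or grid[gx, gy + 1] or grid[gx, gy - 1]):
                grid[gx, gy] = 1
                placed += 1
                r = np.sqrt(r2)
                if r > r_max:
                    r_max = r
                break
    return placed


def generate_dla_cluster(n_particles: int, seed: int) -> np.ndarray:
    """Grow a 2-D lattice DLA cluster and return its occupancy mask.

    Parameters
    ----------
    n_particles
        Number of particles in the final cluster (>= 1), seed included.
    seed
        RNG seed; identical seeds give identical clusters.

    Returns
    -------
    numpy.ndarray of bool
        Occupied-site mask cropped to the cluster bounding box with a
        1-pixel margin.  The occupied set is 4-connected by construction.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    # radius scales ~ n^(1/1.71); generous margin for the lattice prefactor
    est_r = int(3.0 * n_particles ** (1.0 / 1.71)) + 16
    size = 2 * est_r + 1
    grid = np.zeros((size, size), dtype=np.uint8)
    _dla_core(int(n_particles), np.uint64(seed), grid)

    occ = np.argwhere(grid > 0)
    x0, y0 = occ.min(axis=0)
    x1, y1 = occ.max(axis=0)
    out = np.zeros((x1 - x0 + 3, y1 - y0 + 3), dtype=bool)
    out[1:-1, 1:-1] = grid[x0:x1 + 1, y0:y1 + 1] > 0
    return out
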