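"""Radial k-space undersampling patterns and acceleration bookkeeping.

Acquisition is emulated with pseudo-radial Cartesian masks: straight rays
through the k-space centre are rasterized onto the Cartesian grid (nearest
grid point every half-pixel step along the ray), which keeps ``A^H A``
diagonal in per-frame spatial-frequency coordinates — the property the
solver's closed-form quadratic updates rely on.  Each frame carries the same
number of uniformly spaced rays; the whole spoke set is rotated by a random
offset per frame to decorrelate the aliasing across time.
"""

from __future__ import annotations

import math

import numpy as np

from .operators import SamplingMask

__all__ = ["radial_mask", "nyquist_ray_count", "undersampling_factor"]


def nyquist_ray_count(n: int) -> int:
    """Number of radial projections needed for full Nyquist coverage of an
    n x n grid: ``round((pi / 2) * n)`` (201 for n = 128)."""
    if n < 1:
        raise ValueError("grid size must be >= 1")
    return round(math.pi / 2 * n)


def undersampling_factor(n: int, n_rays: int, *, rounded: bool = False) -> float | int:
    """Acceleration factor of an ``n_rays``-spoke acquisition relative to the
    Nyquist count: ``nyquist_ray_count(n) / n_rays`` (8 rays on a 128 grid
    gives 201/8, i.e. ~25-fold undersampling)."""
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    factor = nyquist_ray_count(n) / n_rays
    return round(factor) if rounded else factor


def _rasterize_ray(frame: np.ndarray, angle: float) -> None:
    """Mark the grid points nearest a straight line through the centre."""
    n = frame.shape[0]
    c = n // 2
    steps = np.arange(-c, n - c, 0.5)
    ix = np.rint(c + steps * math.cos(angle)).astype(int)
    iy = np.rint(c + steps * math.sin(angle)).astype(int)
    keep = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
    frame[ix[keep], iy[keep]] = True


def radial_mask(
    Nx: int,
    Ny: int,
    Nt: int,
    n_rays: int,
    seed: int = 0,
    *,
    random_rotation: bool = True,
) -> SamplingMask:
    """Pseudo-radial Cartesian sampling mask.

    Each frame holds ``n_rays`` straight rays through the grid centre with
    angular spacing ``pi / n_rays``; frame ``t``'s spoke set is rotated by an
    offset drawn uniformly from ``[0, pi / n_rays)`` (seeded, hence
    deterministic).  The DC sample is always included.

    Parameters
    ----------
    Nx, Ny, Nt
        Grid and frame counts; ray geometry requires a square grid.
    n_rays
        Rays per frame; must not exceed the Nyquist count ``round(pi/2 * Nx)``.
    seed
        Seed for the per-frame rotation offsets.
    random_rotation
        Disable to pin every frame's offset to zero (useful for geometry
        tests; breaks temporal incoherence).
    """
    if Nx != Ny:
        raise ValueError(f"radial ray geometry requires a square grid, got {Nx}x{Ny}")
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    nyq = nyquist_ray_count(Nx)
    if n_rays > nyq:
        raise ValueError(f"n_rays={n_rays} exceeds the Nyquist ray count {nyq} for n={Nx}")
    if Nt < 1:
        raise ValueError("Nt must be >= 1")

    rng = np.random.default_rng(seed)
    spacing = math.pi / n_rays
    support = np.zeros((Nx, Ny, Nt), dtype=bool)
    for t in range(Nt):
        offset = rng.uniform(0.0, spacing) if random_rotation else 0.0
        frame = support[:, :, t]
        for i in range(n_rays):
            _rasterize_ray(frame, offset + i * spacing)
        frame[Nx // 2, Ny // 2] = True  # DC always sampled
    return SamplingMask(support=support, n_rays=n_rays, seed=seed)
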