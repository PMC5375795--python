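"""Synthetic dynamic-MRI phantom with exact low-rank + sparse structure.

The generator produces a ground-truth series F = L + S that satisfies, by
construction, the structural premise of the reconstruction model:

* the Casorati matrix of L (slowly varying anatomical background) is an
  explicit sum of ``rank`` outer products — smooth random spatial maps
  times low-order polynomial temporal envelopes — so its rank is exact;
* S (cardiac-like dynamics) is a set of spatially compact hard-edged
  ellipses whose intensities oscillate as zero-mean sums of
  integer-frequency sinusoids, making the temporal Fourier transform of S
  exactly sparse: each dynamic pixel carries at most
  ``2 * temporal_harmonics`` nonzero temporal-frequency coefficients
  (conjugate pairs; the resting baseline of each ellipse is static and
  therefore part of L).

A smooth spatial phase map multiplies both components, giving realistically
complex-valued data without disturbing either the rank of L (a diagonal
unit-modulus scaling of Casorati rows) or the temporal sparsity of S (the
phase is time-independent).

Measurements are simulated as ``d = A(F) + n`` with i.i.d. complex Gaussian
noise, all randomness flowing from a single seed via deterministic
sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .operators import DynamicImage, KTMeasurements, SamplingMask, forward_sample

__all__ = ["PhantomSpec", "generate_phantom", "simulate_measurements"]


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry and statistics.

    Defaults describe a 64 x 64, 32-frame series with a rank-3 background
    and two pulsating ellipses carrying three temporal harmonics each —
    small enough to reconstruct in seconds yet exhibiting the full
    low-rank-plus-sparse structure.  ``contrast`` sets the background
    magnitude scale; the default of 1e2 matches typical in vivo magnitude
    ranges (the scale on which the solver's default regularization weights
    are meaningful).
    """

    Nx: int = 64
    Ny: int = 64
    Nt: int = 32
    rank: int = 3
    n_dynamic: int = 2
    temporal_harmonics: int = 3
    contrast: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.Nx, self.Ny, self.Nt) < 1:
            raise ValueError("dimensions must be >= 1")
        if not 1 <= self.rank <= min(self.Nx * self.Ny, self.Nt):
            raise ValueError(f"rank must lie in [1, min(Nx*Ny, Nt)], got {self.rank}")
        if self.n_dynamic < 0:
            raise ValueError("n_dynamic must be >= 0")
        if self.n_dynamic > 0 and not 1 <= self.temporal_harmonics <= self.Nt // 2:
            raise ValueError("temporal_harmonics must lie in [1, Nt/2]")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def _smooth_field(rng: np.random.Generator, nx: int, ny: int, sigma: float) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal((nx, ny)), sigma=sigma, mode="wrap")
    return field / np.abs(field).max()


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicImage, DynamicImage, DynamicImage]:
    """Generate (F, L_true, S_true) with F = L_true + S_true.

    Deterministic for a fixed ``spec.seed``.
    """
    nx, ny, nt = spec.Nx, spec.Ny, spec.Nt
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_bg, rng_dyn, rng_phase = (np.random.default_rng(s) for s in streams[:3])

    # --- sparse dynamics: pulsating hard ellipses ---------------------------
    # zero-mean time courses: the resting baseline of each ellipse is part of
    # the static background (folded into L below), S carries pure dynamics
    S = np.zeros((nx, ny, nt))
    baseline = np.zeros((nx, ny))
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    t_idx = np.arange(nt)
    max_freq = max(nt // 2 - 1, 1)
    for _ in range(spec.n_dynamic):
        cx = rng_dyn.uniform(0.3 * nx, 0.7 * nx)
        cy = rng_dyn.uniform(0.3 * ny, 0.7 * ny)
        a = rng_dyn.uniform(nx / 16.0, nx / 6.0)
        b = rng_dyn.uniform(ny / 16.0, ny / 6.0)
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        n_h = min(spec.temporal_harmonics, max_freq)
        freqs = rng_dyn.choice(np.arange(1, max_freq + 1), size=n_h, replace=False)
        courses = np.zeros((nx, ny, nt))
        for f in freqs:
            # integer frequency -> exactly two nonzero DFT coefficients per
            # pixel; smoothly varying amplitude and phase across the ellipse
            # keep the dynamics spatially heterogeneous (S is not low rank)
            amp = 0.25 + 0.08 * _smooth_field(rng_dyn, nx, ny, sigma=max(nx, ny) / 10.0)
            psi = np.pi * _smooth_field(rng_dyn, nx, ny, sigma=max(nx, ny) / 10.0)
            phi = rng_dyn.uniform(0.0, 2.0 * np.pi)
            courses += amp[:, :, None] * np.cos(
                2.0 * np.pi * f * t_idx[None, None, :] / nt + phi + psi[:, :, None]
            )
        S += spec.contrast * inside[:, :, None] * courses
        baseline += 0.5 * spec.contrast * inside

    # --- low-rank background: sum of rank outer products -------------------
    # component 0 is strictly static (constant temporal envelope) and carries
    # the anatomy plus the resting baseline of the dynamic ellipses, so the
    # Casorati rank of L stays exactly spec.rank.  The remaining components
    # are normalized so their singular values sit near a tenth of the static
    # one — well above the dynamic component's, as in gated cine data where
    # background modulation dominates the localized dynamic signal.
    tau = np.linspace(-1.0, 1.0, nt)
    L = np.zeros((nx, ny, nt))
    static = np.zeros((nx, ny))
    for i in range(spec.rank):
        spatial = _smooth_field(rng_bg, nx, ny, sigma=max(nx, ny) / 8.0)
        if i == 0:
            static = spec.contrast * np.abs(spatial) + baseline
            L += static[:, :, None] * np.ones(nt)[None, None, :]
            continue
        # low-order polynomial temporal envelope: Legendre P_i plus a small
        # random low-order admixture, mean-removed so the time-varying
        # components stay linearly independent of the static one
        coeffs = 0.25 * rng_bg.uniform(-1.0, 1.0, size=spec.rank)
        coeffs[i] = 1.0
        envelope = np.polynomial.legendre.legval(tau, coeffs)
        envelope -= envelope.mean()
        sigma_static = np.linalg.norm(static) * np.sqrt(nt)
        weight = 0.1 * 0.85 ** (i - 1) * sigma_static
        L += (
            weight
            * (spatial / np.linalg.norm(spatial))[:, :, None]
            * (envelope / np.linalg.norm(envelope))[None, None, :]
        )

    # --- shared smooth phase ------------------------------------------------
    phase = np.exp(1j * np.pi * 0.5 * _smooth_field(rng_phase, nx, ny, sigma=max(nx, ny) / 6.0))
    Lc = L * phase[:, :, None]
    Sc = S * phase[:, :, None]
    return DynamicImage(Lc + Sc), DynamicImage(Lc), DynamicImage(Sc)


def simulate_measurements(
    F: DynamicImage | np.ndarray,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KTMeasurements:
    """Sample ``d = A(F) + n`` with i.i.d. complex Gaussian noise whose real
    and imaginary parts each have variance ``noise_sigma**2 / 2`` (so the
    complex standard deviation is ``noise_sigma``)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    clean = forward_sample(F, mask)
    if noise_sigma == 0.0:
        return clean
    rng = np.random.default_rng(seed)
    scale = noise_sigma / np.sqrt(2.0)
    noise = rng.normal(0.0, scale, clean.d.shape) + 1j * rng.normal(0.0, scale, clean.d.shape)
    return KTMeasurements(clean.d + noise, mask, noise_sigma=noise_sigma)
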