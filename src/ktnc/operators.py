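"""Linear operators of the dynamic-MRI imaging model.

A dynamic image series is a complex array of shape ``(Nx, Ny, Nt)``.  Its
*Casorati matrix* stacks each frame, flattened in row-major (C) order, as
one column of an ``(Nx*Ny, Nt)`` matrix; strong inter-frame correlation
makes this matrix approximately low rank.

Conventions (fixed throughout the package):

* All DFTs are **unitary** (``norm="ortho"``), so every forward transform's
  adjoint equals its inverse and the sampling operator's adjoint is a
  zero-filled inverse DFT.
* Spatial k-space is stored **fftshifted**: the DC sample of an ``N``-point
  axis sits at index ``N // 2``.  Sampling-mask geometry (radial rays,
  centre point) is expressed in these centred coordinates.
* Measurement vectors ``d`` are stacked frame-major: frame 0's sampled
  points in row-major scan order, then frame 1's, and so on.
* The temporal Fourier transform acts along the last axis, unshifted
  (temporal DC at index 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicImage",
    "SamplingMask",
    "KTMeasurements",
    "casorati_fold",
    "casorati_unfold",
    "spatial_ft",
    "spatial_ift",
    "forward_sample",
    "adjoint_sample",
    "temporal_ft",
    "temporal_ift",
]


@dataclass
class DynamicImage:
    """A complex-valued dynamic image series I(x, y, t).

    Parameters
    ----------
    data
        Complex array of shape ``(Nx, Ny, Nt)``.  Real input is promoted.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"DynamicImage needs a 3-D (Nx, Ny, Nt) array, got shape {arr.shape}")
        if any(s < 1 for s in arr.shape):
            raise ValueError(f"all dimensions must be >= 1, got {arr.shape}")
        if not np.iscomplexobj(arr):
            arr = arr.astype(np.complex128)
        if not np.all(np.isfinite(arr)):
            raise ValueError("DynamicImage entries must be finite")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class SamplingMask:
    """Binary per-frame k-space sampling pattern (the support of the operator A).

    ``support`` has shape ``(Nx, Ny, Nt)`` with entries in {0, 1}, expressed in
    centred (fftshifted) k-space coordinates; the DC sample of every frame must
    be included.
    """

    support: np.ndarray
    n_rays: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        sup = np.asarray(self.support)
        if sup.ndim != 3:
            raise ValueError(f"mask support must be 3-D (Nx, Ny, Nt), got shape {sup.shape}")
        sup = sup.astype(bool)
        per_frame = sup.sum(axis=(0, 1))
        if np.any(per_frame == 0):
            raise ValueError("every frame must contain at least one sample")
        self.support = sup

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.support.shape  # type: ignore[return-value]

    @property
    def n_samples(self) -> int:
        """Total number of (k, t) samples P."""
        return int(self.support.sum())

    def sampled_fraction(self) -> float:
        return self.n_samples / self.support.size


@dataclass
class KTMeasurements:
    """Undersampled (k,t)-space data ``d = A(F) + n`` with its sampling mask."""

    d: np.ndarray
    mask: SamplingMask
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if d.ndim != 1:
            raise ValueError("d must be a 1-D stacked sample vector")
        if d.size != self.mask.n_samples:
            raise ValueError(
                f"measurement vector length {d.size} does not match mask support size {self.mask.n_samples}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        self.d = d.astype(np.complex128)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.mask.shape


# ---------------------------------------------------------------------------
# Casorati matricization


def casorati_fold(img: DynamicImage | np.ndarray) -> np.ndarray:
    """Rearrange an ``(Nx, Ny, Nt)`` series into its Casorati matrix.

    Column ``t`` is frame ``t`` flattened in row-major order; the operation
    is a lossless bijection inverted by :func:`casorati_unfold`.
    """
    arr = img.data if isinstance(img, DynamicImage) else np.asarray(img)
    nx, ny, nt = arr.shape
    return arr.reshape(nx * ny, nt)


def casorati_unfold(mat: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`casorati_fold` for a series of the given shape."""
    nx, ny, nt = shape
    mat = np.asarray(mat)
    if mat.shape != (nx * ny, nt):
        raise ValueError(f"expected Casorati shape {(nx * ny, nt)}, got {mat.shape}")
    return mat.reshape(nx, ny, nt)


# ---------------------------------------------------------------------------
# Fourier transforms


def spatial_ft(arr: np.ndarray) -> np.ndarray:
    """Per-frame unitary 2-D DFT, fftshifted so DC sits at the array centre."""
    return np.fft.fftshift(np.fft.fft2(arr, axes=(0, 1), norm="ortho"), axes=(0, 1))


def spatial_ift(ksp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`spatial_ft`."""
    return np.fft.ifft2(np.fft.ifftshift(ksp, axes=(0, 1)), axes=(0, 1), norm="ortho")


def temporal_ft(img: DynamicImage | np.ndarray) -> DynamicImage | np.ndarray:
    """Unitary 1-D DFT along the temporal axis (per-pixel time courses).

    Unitarity gives ``Ft^H Ft = I``; :func:`temporal_ift` inverts exactly.
    """
    if isinstance(img, DynamicImage):
        return DynamicImage(np.fft.fft(img.data, axis=2, norm="ortho"))
    return np.fft.fft(np.asarray(img), axis=2, norm="ortho")


def temporal_ift(img: DynamicImage | np.ndarray) -> DynamicImage | np.ndarray:
    if isinstance(img, DynamicImage):
        return DynamicImage(np.fft.ifft(img.data, axis=2, norm="ortho"))
    return np.fft.ifft(np.asarray(img), axis=2, norm="ortho")


# ---------------------------------------------------------------------------
# The undersampled Fourier operator A and its adjoint


def _extract_samples(ksp: np.ndarray, support: np.ndarray) -> np.ndarray:
    # frame-major stacking: transpose to (t, kx, ky) so boolean indexing
    # scans frames first, then row-major within each frame
    return np.transpose(ksp, (2, 0, 1))[np.transpose(support, (2, 0, 1))]


def _embed_samples(d: np.ndarray, support: np.ndarray) -> np.ndarray:
    out = np.zeros((support.shape[2], support.shape[0], support.shape[1]), dtype=np.complex128)
    out[np.transpose(support, (2, 0, 1))] = d
    return np.transpose(out, (1, 2, 0))


def forward_sample(img: DynamicImage | np.ndarray, mask: SamplingMask) -> KTMeasurements:
    """Apply the undersampled Fourier operator: ``d = A(F)`` (noiseless).

    Each frame is transformed by the unitary 2-D DFT and restricted to the
    mask support; samples are stacked frame-major.
    """
    arr = img.data if isinstance(img, DynamicImage) else np.asarray(img, dtype=np.complex128)
    if arr.shape != mask.shape:
        raise ValueError(f"image shape {arr.shape} does not match mask shape {mask.shape}")
    ksp = spatial_ft(arr)
    return KTMeasurements(_extract_samples(ksp, mask.support), mask)


def adjoint_sample(meas: KTMeasurements) -> DynamicImage:
    """Apply the adjoint A^H: zero-fill onto the k-space grid, then inverse DFT.

    Because the DFT is unitary, this is the exact adjoint:
    ``<A x, y> = <x, A^H y>`` for all x, y.  On fully sampled data it inverts
    :func:`forward_sample`; on undersampled data it is the zero-filled
    inverse-DFT (ZF-IDFT) reconstruction.
    """
    ksp = _embed_samples(meas.d, meas.mask.support)
    return DynamicImage(spatial_ift(ksp))
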