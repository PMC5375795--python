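"""File I/O: NPZ is the canonical container (complex-safe); MAT v5 and
magnitude-only NIfTI are interop exports.

A dataset NPZ may hold any of the named arrays ``image`` (complex,
Nx x Ny x Nt), ``mask`` (uint8), ``d`` (complex sample vector) and always a
``meta`` JSON string carrying seeds and acquisition/solver parameters so
every artifact can exactly rerun its producing step.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
from scipy.io import loadmat, savemat

from .operators import DynamicImage, KTMeasurements, SamplingMask

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_mat",
    "load_mat",
    "save_nifti_magnitude",
]


def save_dataset(
    path: str | Path,
    *,
    image: DynamicImage | np.ndarray | None = None,
    mask: SamplingMask | None = None,
    meas: KTMeasurements | None = None,
    meta: dict[str, Any] | None = None,
) -> None:
    """Write a dataset NPZ with whichever of image / mask / measurements are given."""
    arrays: dict[str, np.ndarray] = {}
    meta = dict(meta or {})
    if image is not None:
        arrays["image"] = image.data if isinstance(image, DynamicImage) else np.asarray(image)
    if meas is not None:
        arrays["d"] = meas.d
        meta.setdefault("noise_sigma", meas.noise_sigma)
        if mask is None:
            mask = meas.mask
    if mask is not None:
        arrays["mask"] = mask.support.astype(np.uint8)
        meta.setdefault("n_rays", mask.n_rays)
        meta.setdefault("mask_seed", mask.seed)
    if not arrays:
        raise ValueError("nothing to save")
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(Path(path), **arrays)


def load_dataset(path: str | Path) -> dict[str, Any]:
    """Read a dataset NPZ back into domain objects.

    Returns a dict with any of the keys ``image`` (DynamicImage), ``mask``
    (SamplingMask), ``meas`` (KTMeasurements) and ``meta`` (dict).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as npz:
        names = set(npz.files)
        out: dict[str, Any] = {}
        meta = json.loads(str(npz["meta"])) if "meta" in names else {}
        out["meta"] = meta
        if "image" in names:
            out["image"] = DynamicImage(npz["image"])
        if "mask" in names:
            out["mask"] = SamplingMask(
                support=npz["mask"].astype(bool),
                n_rays=int(meta.get("n_rays", 0) or 0),
                seed=meta.get("mask_seed"),
            )
        if "d" in names:
            if "mask" not in out:
                raise ValueError(f"{path}: measurement vector 'd' requires a 'mask' array")
            out["meas"] = KTMeasurements(
                npz["d"], out["mask"], noise_sigma=float(meta.get("noise_sigma", 0.0))
            )
    return out


def save_mat(path: str | Path, **arrays: np.ndarray) -> None:
    """MAT v5 export of named arrays (complex supported)."""
    if not arrays:
        raise ValueError("nothing to save")
    savemat(str(path), {k: np.asarray(v) for k, v in arrays.items()})


def load_mat(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = loadmat(str(path))
    return {k: v for k, v in raw.items() if not k.startswith("__")}


def save_nifti_magnitude(path: str | Path, image: DynamicImage | np.ndarray) -> None:
    """Export the magnitude series as NIfTI (x, y, t axis order) for viewers.

    NIfTI has no complex dtype in common use, so only ``|image|`` is written.
    """
    arr = image.data if isinstance(image, DynamicImage) else np.asarray(image)
    nib.save(nib.Nifti1Image(np.abs(arr).astype(np.float32), affine=np.eye(4)), str(path))
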