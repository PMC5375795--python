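"""Proximal and thresholding operators.

These are the per-iteration building blocks of the reconstruction ADMM:

* :func:`soft_threshold` — magnitude shrinkage, the L1 proximal map;
* :func:`svt` — singular value thresholding, the nuclear-norm proximal map;
* :func:`schatten_p_threshold` — weighted singular-value thresholding for
  the non-convex Schatten-p (0 < p <= 1) low-rank penalty, applied one-shot
  with weights from the input's own singular values;
* :func:`gisa_scalar` / :func:`lq_shrink` — the generalized iterated
  shrinkage (GISA) solution of the scalar Lq-penalized problem
  ``min_y  mu * |y|^q + (y - c)^2 / 2``, extended elementwise to complex
  arrays with the phase preserved.

All operators reduce to their convex counterparts at p = 1 / q = 1, which
is the convex low-rank-plus-sparse special case of the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GisaSpec",
    "SchattenSpec",
    "soft_threshold",
    "svt",
    "schatten_p_threshold",
    "gisa_threshold",
    "gisa_scalar",
    "lq_shrink",
]


@dataclass(frozen=True)
class GisaSpec:
    """Parameters of the Lq shrinkage: penalty weight ``mu_tilde`` (the ratio
    mu2 / alpha2 inside the ADMM), exponent ``q`` in (0, 1], and the number of
    fixed-point refinement iterations."""

    mu_tilde: float
    q: float
    inner_iters: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"q must lie in (0, 1], got {self.q}")
        if self.mu_tilde < 0:
            raise ValueError("mu_tilde must be nonnegative")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")


@dataclass(frozen=True)
class SchattenSpec:
    """Parameters of the Schatten-p singular-value shrinkage: weight
    mu1 / alpha1 and exponent ``p`` in (0, 1]."""

    weight: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


def _complex_sign(y: np.ndarray) -> np.ndarray:
    """y / |y| with the convention sign(0) = 0."""
    mag = np.abs(y)
    out = np.zeros_like(np.asarray(y, dtype=complex))
    nz = mag > 0
    out[nz] = y[nz] / mag[nz]
    return out


def soft_threshold(Y: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise magnitude shrinkage ``sign(Y) * max(|Y| - tau, 0)``.

    For complex input the sign is ``y / |y|``, i.e. the phase is preserved
    and only the magnitude is shrunk.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    Y = np.asarray(Y)
    mag = np.abs(Y)
    shrunk = np.maximum(mag - tau, 0.0)
    if not np.iscomplexobj(Y):
        return np.sign(Y) * shrunk
    return _complex_sign(Y) * shrunk


def svt(Y: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding ``U soft_threshold(S) V^H`` — the proximal
    operator of ``tau * ||.||_*``."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    u, s, vh = np.linalg.svd(np.asarray(Y), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vh


def schatten_p_threshold(Y: np.ndarray, spec: SchattenSpec) -> np.ndarray:
    """Weighted singular-value thresholding for the Schatten-p penalty.

    Each singular value sigma_i of Y is replaced by
    ``max(sigma_i - weight * sigma_i^(p-1), 0)`` with the singular vectors
    kept; a zero singular value maps to zero (the limit of the expression,
    avoiding 0 to a negative power).  With p = 1 this is exactly
    :func:`svt` with threshold ``weight``.
    """
    u, s, vh = np.linalg.svd(np.asarray(Y), full_matrices=False)
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = np.maximum(s[nz] - spec.weight * s[nz] ** (spec.p - 1.0), 0.0)
    return (u * out) @ vh


def gisa_threshold(spec: GisaSpec) -> float:
    """Dead-zone threshold tau of the Lq scalar problem.

    Below this magnitude the minimizer of ``mu*|y|^q + (y-c)^2/2`` is exactly
    zero.  Closed form for q < 1:
    ``tau = (2 mu (1-q))^(1/(2-q)) + mu q (2 mu (1-q))^((q-1)/(2-q))``;
    at q = 1 the soft-threshold limit ``tau = mu`` applies.
    """
    mu, q = spec.mu_tilde, spec.q
    if mu == 0.0:
        return 0.0
    if q == 1.0:
        return mu
    base = 2.0 * mu * (1.0 - q)
    return base ** (1.0 / (2.0 - q)) + mu * q * base ** ((q - 1.0) / (2.0 - q))


def _gisa_magnitudes(mags: np.ndarray, spec: GisaSpec) -> np.ndarray:
    """Vectorized GISA on an array of nonnegative magnitudes."""
    mu, q = spec.mu_tilde, spec.q
    out = np.zeros_like(mags, dtype=float)
    if mu == 0.0:
        return mags.astype(float)
    if q == 1.0:
        return np.maximum(mags - mu, 0.0)
    tau = gisa_threshold(spec)
    above = mags > tau
    if not np.any(above):
        return out
    c = mags[above]
    # fixed point of y = c - mu*q*y^(q-1), approached monotonically from y0 = c
    y = c.copy()
    for _ in range(spec.inner_iters):
        y_new = c - mu * q * y ** (q - 1.0)
        if np.max(np.abs(y_new - y)) < 1e-8:
            y = y_new
            break
        y = y_new
    out[above] = y
    return out


def gisa_scalar(c: float, spec: GisaSpec) -> float:
    """GISA solution of ``min_y mu*|y|^q + (y-c)^2/2`` for a scalar c >= 0.

    Returns 0 in the dead zone ``c <= tau`` and otherwise the fixed point of
    ``y = c - mu*q*y^(q-1)`` iterated from ``y = c``, which is the global
    minimizer of the scalar objective.
    """
    if c < 0:
        raise ValueError("c must be nonnegative (pass the magnitude)")
    return float(_gisa_magnitudes(np.asarray([c], dtype=float), spec)[0])


def lq_shrink(C: np.ndarray, spec: GisaSpec) -> np.ndarray:
    """Elementwise Lq shrinkage of a complex array: the magnitude of each
    entry is passed through :func:`gisa_scalar`; the phase is untouched."""
    C = np.asarray(C)
    mags = np.abs(C)
    shrunk = _gisa_magnitudes(mags, spec)
    if not np.iscomplexobj(C):
        return np.sign(C) * shrunk
    return _complex_sign(C) * shrunk
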