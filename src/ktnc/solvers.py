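"""ADMM solvers for low-rank plus sparse dynamic MRI reconstruction.

Two problems are solved here:

1. :func:`rpca_admm` — robust principal component analysis of a fully
   sampled Casorati matrix X, i.e.

       min_{L,S}  ||L||_* + rho ||S||_1   s.t.  X = L + S,

   by the classic ADMM alternation of singular-value thresholding and
   soft thresholding with a multiplier update.

2. :func:`kt_ncrpca` — reconstruction of a dynamic series from
   undersampled (k,t)-space data d by

       min_{L,S}  1/2 ||A(L+S) - d||_2^2 + mu1 ||L||_p^p + mu2 ||Ft(S)||_q^q,

   where A is the masked per-frame unitary Fourier operator, Ft the
   temporal Fourier transform, ||.||_p^p the Schatten-p quasi-norm of the
   Casorati matrix of L (0 < p <= 1) and ||.||_q^q the entrywise Lq
   quasi-norm (0 < q <= 1).  The ADMM splitting introduces P = L (in
   Casorati form) and Q = Ft(S); the P and Q subproblems are handled by
   Schatten-p singular-value thresholding and GISA Lq shrinkage, the L and
   S subproblems are quadratics solved exactly per spatial frequency, and
   the penalty parameters follow a x1.2 continuation each iteration.

At p = q = 1 the iteration degenerates to the convex low-rank plus sparse
reconstruction, provided independently as :func:`kt_rpca_convex`; the
unregularized zero-filled inverse DFT baseline is :func:`zf_idft`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import ser
from .operators import (
    DynamicImage,
    KTMeasurements,
    adjoint_sample,
    casorati_fold,
    casorati_unfold,
    spatial_ft,
    spatial_ift,
    temporal_ft,
    temporal_ift,
)
from .prox import GisaSpec, SchattenSpec, lq_shrink, schatten_p_threshold

__all__ = [
    "SolverConfig",
    "SolverResult",
    "rpca_admm",
    "solve_L_quadratic",
    "solve_S_quadratic",
    "kt_ncrpca",
    "kt_rpca_convex",
    "zf_idft",
    "stopping_check",
]


@dataclass(frozen=True)
class SolverConfig:
    """Reconstruction parameters.

    Parameters
    ----------
    mu1
        Low-rank regularization weight (default 2e2).
    mu2
        Sparsity regularization weight; ``None`` resolves to ``rho * mu1``.
    rho
        Ratio mu2 / mu1; ``None`` resolves to ``1 / max(Nx*Ny, Nt)`` at
        solve time.
    alpha1, alpha2
        Initial ADMM penalty parameters; ``None`` resolves to
        ``2e-3 * max |A^H d|`` (data-scaled).  Low initial values keep the
        thresholding steps active longer and speed up convergence; the
        continuation restores constraint satisfaction.
    p, q
        Schatten-p and Lq exponents in (0, 1]; defaults 0.9 and 0.8.
        ``p = q = 1`` recovers the convex model.
    continuation
        Multiplicative growth of alpha1, alpha2 per iteration (default 1.2).
    eps, kmax
        Stopping rule: relative change of F below ``eps`` (default 1e-4) or
        more than ``kmax`` iterations (default 300).
    gisa_inner
        Fixed-point refinements inside the Lq shrinkage.
    """

    mu1: float = 2e2
    mu2: float | None = None
    rho: float | None = None
    alpha1: float | None = None
    alpha2: float | None = None
    p: float = 0.9
    q: float = 0.8
    continuation: float = 1.2
    eps: float = 1e-4
    kmax: int = 300
    gisa_inner: int = 10

    def __post_init__(self) -> None:
        if self.mu1 <= 0:
            raise ValueError("mu1 must be positive")
        for name in ("mu2", "rho", "alpha1", "alpha2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.p <= 1.0 or not 0.0 < self.q <= 1.0:
            raise ValueError("p and q must lie in (0, 1]")
        if self.continuation < 1.0:
            raise ValueError("continuation must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")

    def resolved(self, shape: tuple[int, int, int], ahd_max: float) -> "SolverConfig":
        """Fill data-dependent defaults for a problem of the given shape."""
        nx, ny, nt = shape
        rho = self.rho if self.rho is not None else 1.0 / max(nx * ny, nt)
        mu2 = self.mu2 if self.mu2 is not None else rho * self.mu1
        alpha0 = 2e-3 * ahd_max if ahd_max > 0 else 1e-2
        alpha1 = self.alpha1 if self.alpha1 is not None else alpha0
        alpha2 = self.alpha2 if self.alpha2 is not None else alpha0
        return replace(self, rho=rho, mu2=mu2, alpha1=alpha1, alpha2=alpha2)


@dataclass
class SolverResult:
    """Output of a reconstruction run: F* = L* + S* (exactly), the iteration
    count, and per-iteration diagnostics."""

    F_star: DynamicImage
    L_star: DynamicImage
    S_star: DynamicImage
    iterations: int
    history: dict[str, list[float]] = field(default_factory=dict)


def stopping_check(F_new: np.ndarray, F_old: np.ndarray, eps: float, k: int, kmax: int) -> bool:
    """Stopping rule: relative change ``||F_new - F_old|| / ||F_old|| <= eps``
    or ``k > kmax``.  A zero previous iterate never stops on the first term."""
    if k > kmax:
        return True
    denom = np.linalg.norm(F_old)
    if denom == 0:
        return False
    return bool(np.linalg.norm(F_new - F_old) / denom <= eps)


def _check_finite(arr: np.ndarray, what: str, k: int) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"solver diverged: non-finite {what} at iteration {k}")


# ---------------------------------------------------------------------------
# Algorithm 1-style RPCA of a fully observed matrix


def rpca_admm(
    X: np.ndarray,
    rho: float | None = None,
    alpha: float | None = None,
    eps: float = 1e-7,
    kmax: int = 300,
    continuation: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank plus sparse decomposition of a fully observed matrix.

    Iterates, from S = Z = 0,

        L <- SVT_{1/alpha}(X - S + Z/alpha)
        S <- soft_{rho/alpha}(X - L + Z/alpha)
        Z <- Z + alpha (X - L - S)

    until the relative change of L + S falls below ``eps`` or ``kmax``
    iterations have run.  ``rho`` defaults to ``1/max(m, n)``; note that the
    exact-recovery regime of the underlying convex program calls for
    ``1/sqrt(max(m, n))``, which the caller may pass explicitly.  ``alpha``
    defaults to ``1.25 / ||X||_2`` — inverse to the data scale, so the
    initial singular-value threshold ``1/alpha`` is commensurate with the
    spectrum — and grows by ``continuation`` each iteration so the
    constraint X = L + S is met at convergence.
    """
    X = np.asarray(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    m, n = X.shape
    if rho is None:
        rho = 1.0 / max(m, n)
    if not np.any(X):
        return np.zeros_like(X), np.zeros_like(X)
    if alpha is None:
        alpha = 1.25 / float(np.linalg.norm(X, 2))

    from .prox import soft_threshold, svt  # local import keeps module surface tidy

    S = np.zeros_like(X)
    Z = np.zeros_like(X)
    F_old = np.zeros_like(X)
    for k in range(1, kmax + 1):
        L = svt(X - S + Z / alpha, 1.0 / alpha)
        S = soft_threshold(X - L + Z / alpha, rho / alpha)
        Z = Z + alpha * (X - L - S)
        _check_finite(L, "L", k)
        _check_finite(S, "S", k)
        F_new = L + S
        if stopping_check(F_new, F_old, eps, k, kmax):
            break
        F_old = F_new
        alpha *= continuation
    return L, S


# ---------------------------------------------------------------------------
# Closed-form quadratic subproblem solutions
#
# Because A^H A equals masking in per-frame k-space and the DFTs are unitary,
# (A^H A + alpha I) is diagonal in spatial-frequency coordinates: solving the
# normal equations reduces to dividing by (m + alpha) per (k, t) sample.


def _mask_and_grid(meas: KTMeasurements) -> tuple[np.ndarray, np.ndarray]:
    m = meas.mask.support.astype(float)
    grid = np.zeros((m.shape[2], m.shape[0], m.shape[1]), dtype=np.complex128)
    grid[np.transpose(meas.mask.support, (2, 0, 1))] = meas.d
    return m, np.transpose(grid, (1, 2, 0))


def solve_L_quadratic(
    Sk: np.ndarray, P: np.ndarray, Z1: np.ndarray, alpha1: float, meas: KTMeasurements
) -> np.ndarray:
    """Exact minimizer of the L subproblem,
    ``(A^H A + alpha1 I) L = A^H d + alpha1 P - Z1 - A^H A S``,
    via per-frequency division in k-space.  All image-domain arguments have
    shape (Nx, Ny, Nt)."""
    if alpha1 <= 0:
        raise ValueError("alpha1 must be positive (the system is singular otherwise)")
    m, d_grid = _mask_and_grid(meas)
    rhs_hat = m * d_grid + spatial_ft(alpha1 * np.asarray(P) - np.asarray(Z1)) - m * spatial_ft(np.asarray(Sk))
    return spatial_ift(rhs_hat / (m + alpha1))


def solve_S_quadratic(
    Lk1: np.ndarray, Q: np.ndarray, Z2: np.ndarray, alpha2: float, meas: KTMeasurements
) -> np.ndarray:
    """Exact minimizer of the S subproblem,
    ``(A^H A + alpha2 I) S = A^H d + Ft^H(alpha2 Q - Z2) - A^H A L``.
    Q and Z2 live in the temporal-frequency domain; Ft unitarity makes the
    same per-frequency division apply."""
    if alpha2 <= 0:
        raise ValueError("alpha2 must be positive (the system is singular otherwise)")
    m, d_grid = _mask_and_grid(meas)
    back = temporal_ift(alpha2 * np.asarray(Q) - np.asarray(Z2))
    rhs_hat = m * d_grid + spatial_ft(back) - m * spatial_ft(np.asarray(Lk1))
    return spatial_ift(rhs_hat / (m + alpha2))


# ---------------------------------------------------------------------------
# k-t NCRPCA reconstruction


def kt_ncrpca(
    meas: KTMeasurements,
    cfg: SolverConfig | None = None,
    truth: DynamicImage | None = None,
) -> SolverResult:
    """Reconstruct a dynamic series from undersampled (k,t)-space data by
    non-convex low-rank plus sparse ADMM.

    Starting from ``F = L = A^H d`` and ``S = Z1 = Z2 = 0``, each iteration

    1. thresholds the singular values of the Casorati matrix of
       ``L + Z1/alpha1`` by the Schatten-p rule (P update),
    2. applies GISA Lq shrinkage to ``Ft(S) + Z2/alpha2`` (Q update),
    3. solves the two quadratic subproblems for L and S exactly in k-space,
    4. updates the multipliers ``Z1 <- Z1 - alpha1 (P - L)``,
       ``Z2 <- Z2 - alpha2 (Q - Ft(S))``,
    5. sets ``F = L + S`` and grows alpha1, alpha2 by the continuation
       factor,

    stopping when the relative change of F drops below ``cfg.eps`` or after
    ``cfg.kmax`` iterations.  Entirely deterministic.

    Parameters
    ----------
    meas
        The (k,t)-space data with its sampling mask.
    cfg
        Solver configuration; data-dependent defaults are resolved here.
    truth
        Optional ground-truth series; when given, per-iteration SER is
        recorded in ``result.history["ser_db"]``.
    """
    if cfg is None:
        cfg = SolverConfig()
    shape = meas.image_shape
    if meas.mask.n_samples == 0:
        raise ValueError("empty sampling mask")

    ahd = adjoint_sample(meas).data
    cfg = cfg.resolved(shape, float(np.abs(ahd).max()))
    assert cfg.mu2 is not None and cfg.alpha1 is not None and cfg.alpha2 is not None

    L = ahd.copy()
    S = np.zeros(shape, dtype=np.complex128)
    Z1 = np.zeros(shape, dtype=np.complex128)
    Z2 = np.zeros(shape, dtype=np.complex128)
    F = L + S
    alpha1, alpha2 = cfg.alpha1, cfg.alpha2

    history: dict[str, list[float]] = {
        "relative_change": [],
        "data_fidelity": [],
        "alpha1": [],
    }
    if truth is not None:
        history["ser_db"] = []

    m, d_grid = _mask_and_grid(meas)
    iterations = 0
    for k in range(1, cfg.kmax + 1):
        iterations = k
        P = casorati_unfold(
            schatten_p_threshold(
                casorati_fold(L + Z1 / alpha1), SchattenSpec(weight=cfg.mu1 / alpha1, p=cfg.p)
            ),
            shape,
        )
        Q = lq_shrink(
            temporal_ft(S) + Z2 / alpha2,
            GisaSpec(mu_tilde=cfg.mu2 / alpha2, q=cfg.q, inner_iters=cfg.gisa_inner),
        )
        L = solve_L_quadratic(S, P, Z1, alpha1, meas)
        S = solve_S_quadratic(L, Q, Z2, alpha2, meas)
        ftS = temporal_ft(S)
        Z1 = Z1 - alpha1 * (P - L)
        Z2 = Z2 - alpha2 * (Q - ftS)
        F_new = L + S
        _check_finite(F_new, "F", k)

        resid = m * spatial_ft(F_new) - d_grid
        history["data_fidelity"].append(0.5 * float(np.linalg.norm(resid) ** 2))
        denom = np.linalg.norm(F)
        rel = float(np.linalg.norm(F_new - F) / denom) if denom > 0 else np.inf
        history["relative_change"].append(rel)
        history["alpha1"].append(alpha1)
        if truth is not None:
            history["ser_db"].append(ser(F_new, truth))

        stop = stopping_check(F_new, F, cfg.eps, k, cfg.kmax)
        F = F_new
        if stop:
            break
        alpha1 *= cfg.continuation
        alpha2 *= cfg.continuation

    return SolverResult(
        F_star=DynamicImage(F),
        L_star=DynamicImage(L),
        S_star=DynamicImage(S),
        iterations=iterations,
        history=history,
    )


def kt_rpca_convex(
    meas: KTMeasurements,
    cfg: SolverConfig | None = None,
    truth: DynamicImage | None = None,
) -> SolverResult:
    """Convex low-rank plus sparse reconstruction (nuclear norm + temporal-
    Fourier L1), coded independently of :func:`kt_ncrpca`.

    This is the p = q = 1 special case of the non-convex model; the P update
    is plain singular value thresholding and the Q update plain soft
    thresholding, written out here directly (no shared thresholding code) so
    the two solvers can cross-validate each other.
    """
    if cfg is None:
        cfg = SolverConfig(p=1.0, q=1.0)
    shape = meas.image_shape
    if meas.mask.n_samples == 0:
        raise ValueError("empty sampling mask")

    ahd = adjoint_sample(meas).data
    cfg = cfg.resolved(shape, float(np.abs(ahd).max()))
    assert cfg.mu2 is not None and cfg.alpha1 is not None and cfg.alpha2 is not None

    m, d_grid = _mask_and_grid(meas)
    L = ahd.copy()
    S = np.zeros(shape, dtype=np.complex128)
    Z1 = np.zeros(shape, dtype=np.complex128)
    Z2 = np.zeros(shape, dtype=np.complex128)
    F = L + S
    alpha1, alpha2 = cfg.alpha1, cfg.alpha2

    history: dict[str, list[float]] = {"relative_change": []}
    if truth is not None:
        history["ser_db"] = []

    iterations = 0
    for k in range(1, cfg.kmax + 1):
        iterations = k
        # nuclear-norm proximal step on the Casorati matrix
        u, s, vh = np.linalg.svd(casorati_fold(L + Z1 / alpha1), full_matrices=False)
        P = casorati_unfold((u * np.maximum(s - cfg.mu1 / alpha1, 0.0)) @ vh, shape)
        # L1 proximal step in the temporal-Fourier domain
        C = temporal_ft(S) + Z2 / alpha2
        mag = np.abs(C)
        scale = np.where(mag > 0, np.maximum(mag - cfg.mu2 / alpha2, 0.0) / np.where(mag > 0, mag, 1.0), 0.0)
        Q = C * scale
        # exact quadratic solves in k-space
        rhs = m * d_grid + spatial_ft(alpha1 * P - Z1) - m * spatial_ft(S)
        L = spatial_ift(rhs / (m + alpha1))
        rhs = m * d_grid + spatial_ft(temporal_ift(alpha2 * Q - Z2)) - m * spatial_ft(L)
        S = spatial_ift(rhs / (m + alpha2))
        ftS = temporal_ft(S)
        Z1 = Z1 - alpha1 * (P - L)
        Z2 = Z2 - alpha2 * (Q - ftS)
        F_new = L + S
        _check_finite(F_new, "F", k)

        denom = np.linalg.norm(F)
        history["relative_change"].append(float(np.linalg.norm(F_new - F) / denom) if denom > 0 else np.inf)
        if truth is not None:
            history["ser_db"].append(ser(F_new, truth))
        stop = stopping_check(F_new, F, cfg.eps, k, cfg.kmax)
        F = F_new
        if stop:
            break
        alpha1 *= cfg.continuation
        alpha2 *= cfg.continuation

    return SolverResult(
        F_star=DynamicImage(F),
        L_star=DynamicImage(L),
        S_star=DynamicImage(S),
        iterations=iterations,
        history=history,
    )


def zf_idft(meas: KTMeasurements) -> DynamicImage:
    """Zero-filled inverse DFT baseline: the adjoint applied to the data."""
    return adjoint_sample(meas)
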