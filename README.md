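# ktnc — non-convex low-rank + sparse dynamic MRI reconstruction

`ktnc` reconstructs dynamic MRI image series (cardiac cine, perfusion) from
undersampled (k,t)-space measurements. Acquiring every k-space sample of
every time frame is slow; radially undersampling each frame accelerates the
scan by an order of magnitude but leaves a badly ill-posed inverse problem.
`ktnc` solves it by exploiting the spatio-temporal structure of dynamic
series: stacked as a Casorati matrix **F** ∈ ℂ^(NxNy×Nt) (one flattened
frame per column), the slowly varying background **L** is approximately low
rank while the dynamic content **S** is sparse after a temporal Fourier
transform.

## The model

Given measurements d = 𝒜(F) + n, where 𝒜 is the masked per-frame unitary
Fourier operator, the reconstruction solves

    min_{L,S}  ½‖𝒜(L+S) − d‖₂² + μ₁‖L‖ₚᵖ + μ₂‖F_t(S)‖_q^q

with the non-convex Schatten-p quasi-norm ‖L‖ₚᵖ = Σᵢ σᵢᵖ(L) (0 < p ≤ 1) as
the low-rank surrogate and the entrywise L_q quasi-norm (0 < q ≤ 1) of the
temporal-Fourier coefficients as the sparsity surrogate. An ADMM splitting
(P = L, Q = F_t(S)) reduces each iteration to four closed-form steps:

* **P** — weighted singular-value thresholding
  σᵢ ← max(σᵢ − (μ₁/α₁)·σᵢ^(p−1), 0);
* **Q** — elementwise L_q shrinkage via the generalized iterated shrinkage
  algorithm (GISA): a closed-form dead-zone threshold plus a fixed-point
  refinement, phase preserved;
* **L**, **S** — exact quadratic solves, diagonal in per-frame k-space
  because 𝒜ᴴ𝒜 is a frequency mask and the DFTs are unitary;

followed by multiplier updates and a ×1.2 continuation of the penalties
α₁, α₂. At p = q = 1 the iteration reduces to the convex low-rank + sparse
reconstruction (provided independently as `kt_rpca_convex`); the
unregularized baseline is the zero-filled inverse DFT (`zf_idft`). A plain
RPCA decomposition of a fully sampled Casorati matrix (`rpca_admm`) and a
structured dynamic phantom generator round out the toolkit.

## Worked example

Simulate a 64×64×32 phantom (rank-3 background plus two pulsating
ellipses), sample it with 8 radial spokes per frame (~25-fold
undersampling), reconstruct, and score:

```sh
ktnc simulate --size 64 --frames 32 --rays 8 --seed 0 --out-prefix demo_
ktnc reconstruct --input demo_meas.npz --truth demo_truth.npz --out demo_rec.npz
ktnc evaluate --rec demo_rec.npz --truth demo_truth.npz --out demo_report.json
```

which prints

```
INFO ktnc: ncrpca finished in 27 iterations
INFO ktnc: SER vs truth: 20.09 dB
INFO ktnc: metrics: {'ser_db': 20.08524429057218, 'ssim': 0.9532596283132669}
```

The signal-to-error ratio SER = −10·log₁₀(‖F_rec − F_truth‖²/‖F_truth‖²) of
20.1 dB means the residual carries about 1% of the signal energy; the mean
frame-wise structural similarity of 0.953 confirms the anatomy and dynamics
are preserved. The same data reconstructed by zero filling alone
(`--method zf`) scores 14.86 dB — about 5 dB worse. The equivalent library calls:

```python
from ktnc import (PhantomSpec, generate_phantom, radial_mask,
                  simulate_measurements, kt_ncrpca, ser)

F, L, S = generate_phantom(PhantomSpec(seed=0))          # 64x64x32 truth
mask = radial_mask(64, 64, 32, n_rays=8, seed=0)         # 8 spokes/frame
meas = simulate_measurements(F, mask)                    # d = A(F)
result = kt_ncrpca(meas, truth=F)                        # ADMM reconstruction
print(ser(result.F_star, F))                             # ~20 dB
```

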