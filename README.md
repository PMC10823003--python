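# neurospd

EEG functional-connectivity graphs on the manifold of symmetric positive
definite (SPD) matrices, for emotion decoding and related multichannel
classification problems.

## The problem

Multichannel EEG carries class information not only in per-channel power but
in the *coupling between channels*. A standard way to capture it is a
functional-connectivity matrix: one scalar dependence value per channel pair.
This package computes four such estimators per 1-s epoch of a C-channel
recording:

- **PLV** (phase locking value): `PLV_mn = |1/T Σ_t exp(j(φ_m,t − φ_n,t))|`,
  with φ the instantaneous phase from the analytic signal;
- **PCC** (Pearson correlation) in the time domain;
- **COH** (magnitude-squared spectral coherence)
  `|P_mn(f)|² / (P_mm(f) P_nn(f))`, Welch-estimated and averaged over
  1–47 Hz;
- **MI** (mutual information, bits) from a 16×16 equal-width joint histogram,
  sensitive to nonlinear coupling.

Connectivity matrices are not SPD, so they cannot be fed directly to
Riemannian-geometry classifiers. The core construction here fixes that:
threshold the matrix by magnitude into an undirected graph `A`, form the
graph Laplacian `L = D − A` (symmetric, positive *semi*-definite), and
rectify its spectrum,

```
L_spd = U max(ε I, Σ) Uᵀ ,      L = U Σ Uᵀ,  ε = 1e-4
```

which clamps every eigenvalue below ε up to ε and yields an SPD matrix that
lives on the Riemannian manifold.

Each feature's SPD matrices are classified by an **SPD matrix network**:
K blocks of BiMap (`S ↦ W S Wᵀ` with row-orthonormal `W`, shrinking the
dimension while staying on the manifold) and ReEig (eigenvalue
rectification, the manifold analogue of ReLU), then one LogEig layer
(matrix logarithm into flat space), flatten, dropout, and a dense softmax
head. For 62-channel input the dimension chain is 62→31→20→16→12. BiMap
weights are trained by Stiefel-manifold SGD (tangent projection + QR
retraction); the whole network, including backprop through the
eigendecompositions, is implemented in numpy. Predictions from the
per-feature networks are combined by **average decision-level fusion**
(elementwise mean of softmax probabilities).

The package also ships the supporting protocol: zero-phase 4th-order
Butterworth band-pass (1–47 Hz), anti-aliased downsampling to 200 Hz,
segmentation of the last two minutes of each trial into 1-s non-overlapping
epochs, and a trial-wise train/test split (first 9 trials train, last 6
test), plus a synthetic-data generator that plants class-conditional
coupling structure so the full pipeline is testable without any private
recordings.

## Worked example

```python
import numpy as np
from neurospd import (SyntheticSpec, generate_dataset, TrainConfig,
                      connectivity_matrix, spd_from_connectivity, is_spd)
from neurospd.preprocessing import split_trials
from neurospd.fusion import run_mode

spec = SyntheticSpec(n_channels=8, n_trials_per_class=5, epochs_per_trial=40,
                     coupling_strength=0.9, noise_sd=0.1, seed=11)
epochs = generate_dataset(spec)
print(f"{epochs.n_epochs} epochs, {epochs.n_channels} channels, fs={epochs.fs} Hz")

conn = connectivity_matrix(epochs.data[0], "plv")
print("PLV(0, 7) =", round(conn.values[0, 7], 3))
S = spd_from_connectivity(conn, threshold=0.6)
print("rectified Laplacian SPD:", is_spd(S))

train, test = split_trials(epochs, n_train_trials=9, n_test_trials=6)
result = run_mode(train, test, ("plv", "pcc", "coh"), TrainConfig(seed=5))
print("per-feature accuracy:", {k: round(v, 3) for k, v in result.per_kind.items()})
print("fused accuracy:", round(result.mean, 3))
```

prints

```
600 epochs, 8 channels, fs=200.0 Hz
PLV(0, 7) = 0.942
rectified Laplacian SPD: True
per-feature accuracy: {'plv': 1.0, 'pcc': 1.0, 'coh': 0.971}
fused accuracy: 1.0
```

Channels 0 and 7 are a planted coupled pair in class 0, so their PLV is
high (0.94); thresholding at 0.6 keeps such edges and drops the noise
floor. Each single-feature network separates the three planted classes on
held-out trials, and averaging the three probability vectors keeps the best
single-feature performance.

The same pipeline is available from the shell:

```sh
neurospd simulate --config run.yaml --out epochs.h5
neurospd extract  --in epochs.h5 --kinds plv,pcc,coh,mi --out feats_{kind}.h5
neurospd graphify --in feats_plv.h5 --threshold 0.6 --out spd_plv.h5
neurospd train    --in spd_plv.h5 --out model.npz
neurospd run      --config run.yaml --results results/
```

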