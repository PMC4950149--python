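# hsunmix

Unsupervised chemical unmixing, sparse spectral sampling and outlier
masking for hyperspectral microscopy images — built for coherent Raman
data (CARS, SRS) but applicable to spontaneous Raman and any other
image contrast that is linear (after a transform) in composition.

A hyperspectral image is a stack of images of one sample region over a
range of vibrational wavenumbers.  Flattened into a non-negative matrix
**D** (spatial points × spectral points), it is modelled as

    D = C · Sᵀ + E

with non-negative concentrations **C** (P × k), non-negative component
spectra **S** (S × k) and residual **E**, solved by multiplicative-update
non-negative matrix factorization (NMF).  Absolute volume fractions are
fixed by scaling each component so the summed concentration per pixel
best approaches unity (a filled volume).  On top of this core the
package provides:

* **Spatial error weighting** — minimizing only the global error makes
  the factorization blind to components concentrated in a few pixels.
  Each pixel gets a weight iterated as
  `w_p ← exp(−β·|E_Cp|) · w_p · (E_Sp/Ē_S)^(1−α)`, where `E_Sp` is the
  pixel's normalized spectral error and `E_Cp` its deviation from unit
  summed concentration, equalizing the error across the image so that
  even a single aberrant pixel's spectrum is recovered.  Pixels whose
  weight diverges (e.g. motion artifacts) are excluded once it crosses
  `γ·P^¼`.
* **Unsupervised component count** — `k` grows while one more component
  improves the per-pixel RMS spectral error by more than `η` standard
  deviations of the error map, first unweighted, then with add/remove
  trials inside the weighted loop.
* **Sparse spectral sampling** — choose `S′` wavenumber positions that
  minimize the noise amplification of the linear reconstruction
  `D_rec = ũ·û⁻¹·D` built from the leading singular spectra of a pilot
  image; a Gram–Schmidt-conditioned inverse exposes per-component noise
  gains, and components above `ξ ×` the leading component's gain are
  dropped.
* **SVD outlier masking** — entries whose residual against a rank-k SVD
  model exceeds `ξ` times the RMS residual are masked and inpainted from
  the model, iteratively, removing spikes from objects moving through
  the field during sequential acquisition.
* **Synthetic phantoms** — Lorentzian-band component spectra, blob
  concentration maps, a single-modified-pixel protocol and spike
  injection, each carrying its exact ground truth.

## Worked example

Recover the spectrum of a single mixed pixel hidden in 2 749 pure ones
— the regime where an unweighted factorization fails:

```python
import numpy as np
from hsunmix import (FSC3Params, WeightParams, make_modified_pixel_phantom,
                     multi_start_fsc3, weighted_fsc3)

# 55 × 50 image of substance A; the center pixel is 50% A + 50% B,
# Gaussian noise of 1% of the peak amplitude
ph = make_modified_pixel_phantom(ny=50, nx=55, f=0.5, noise_sigma=0.01, seed=101)
params = FSC3Params(k=2, n=20, tau_H=0.1, tau_L=1e-3, seed=11)

unweighted = multi_start_fsc3(ph.matrix, params)
weighted = weighted_fsc3(ph.matrix, params, WeightParams(alpha=0.0, beta=0.0))

mix = 0.5 * ph.truth_S[:, 0] + 0.5 * ph.truth_S[:, 1]
for name, res in [("unweighted", unweighted), ("weighted", weighted)]:
    dev = min(np.sqrt(np.mean((res.S[:, j] - mix) ** 2)) for j in range(2))
    print(f"{name:10s} RMS deviation from the mixture spectrum: {dev:.4f}")
```

prints

```
unweighted RMS deviation from the mixture spectrum: 0.0862
weighted   RMS deviation from the mixture spectrum: 0.0152
```

The weighted run recovers the mixture spectrum to roughly the noise
level (the recovery bound used throughout is 10% of the pure-B spectrum
RMS, 0.0436 here), while the best unweighted component misses it by
twice that bound: its second component fits noise instead of the
modified pixel.

The same pipeline is available from the shell:

```sh
hsunmix simulate --kind modified-pixel -f 0.5 --seed 101 -o sim/
hsunmix fsc3 -i sim/cube.h5 -k 2 --weighted --alpha 0 --beta 0 -o fit/
```

which writes concentration maps (TIFF), component spectra (CSV), error
and weight maps, and a reproducibility manifest into `fit/`.

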