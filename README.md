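# desmoke

Variational removal of surgical smoke from laparoscopic RGB images.

During laparoscopic surgery, smoke from electrocautery and laser ablation
washes out the camera image, hiding tissue from the surgeon and degrading
the computer-vision algorithms behind image-guided navigation. Unlike
outdoor haze, smoke density is a local phenomenon unrelated to scene
depth, so depth-based dehazing (transmission/atmospheric-light estimation)
does not transfer. This package removes the smoke by estimating and
subtracting its additive component directly.

## Method

The observed image is decomposed as

```
I = L + F,        L = J_s · t_s,        F = A_s · (1 − t_s),
```

where `L` is the *direct attenuation* (scene radiance dimmed by smoke
with transmission `t_s`) and `F` is the *smoke veil* — airlight scattered
off the smoke toward the camera. The veil is whitish, spatially smooth,
and nearly identical across the R, G, B channels. Both priors are encoded
in a single convex energy over the 3-D field `F(x, y, c)`:

```
E(F) = (γ/2) ‖F − I‖² + Σᵢ √( θₓ²[DₓF]ᵢ² + θᵧ²[DᵧF]ᵢ² + θ_c²[D_cF]ᵢ² )
```

an isotropic total-variation norm whose third direction runs across the
color channels, penalizing inter-channel differences the way the temporal
direction of a video-TV model penalizes flicker. The energy is minimized
with ADMM: an FFT-diagonalized quadratic solve for `F` (exact under the
periodic boundaries used by all difference operators), an isotropic
vector soft-threshold for the splitting variable, and a multiplier ascent
step. Defaults: `γ = 1`, `ρ = 5`, `θₓ = θᵧ = θ_c = 1`.

Recovery subtracts the veil with per-channel weights and stretches the
result to the full display range:

```
L = I − α(c) · F,       J_s = (L − min L) / (max L − min L),
```

with `α(c)` set to the spatial mean of veil channel `c` — heavier smoke
gives a brighter veil and a larger deduction.

The package also ships a synthetic-smoke generator (procedural organ-like
scenes + Perlin-noise or smooth parametric smoke fields, composited as
`I = (1 − w·s)·J + w·s·A`) and full-reference metrics (PSNR, SSIM, a
visible-edge restoration score), so the whole pipeline is testable
without any dataset download.

## Worked example

```
$ desmoke simulate fixtures --n 3 --seed 42
$ desmoke desmoke fixtures/degraded/000.png desmoked.png --save-intermediates panels
INFO desmoke: alpha=(0.5589, 0.5589, 0.5589) iterations=50 final energy=317.35
$ desmoke evaluate fixtures scores.csv
INFO desmoke: 000.png: PSNR 16.04 -> 25.23 dB, SSIM 0.8944 -> 0.9355, RE 0.249
INFO desmoke: 001.png: PSNR 15.36 -> 23.05 dB, SSIM 0.8714 -> 0.9176, RE 0.351
INFO desmoke: 002.png: PSNR 16.73 -> 24.46 dB, SSIM 0.9007 -> 0.9409, RE 0.189
INFO desmoke: mean PSNR 16.04 -> 24.25 dB, mean SSIM 0.8888 -> 0.9313, mean RE 0.263
```

`simulate` writes paired clean/degraded PNGs with a JSON manifest;
`desmoke` removes smoke from one image (the `alpha` line shows the
veil-mean subtraction weights, here ≈ 0.56 per channel, and
`panels/` receives the estimated veil and direct-attenuation images);
`evaluate` desmokes every fixture and scores it against its clean
reference — PSNR and SSIM rise and the positive RE means edges invisible
in the smoked input become visible after restoration.

The same pipeline is available as a library:

```python
from desmoke import make_fixture_set, desmoke, psnr

fx = make_fixture_set(1, size=(128, 128), seed=42)[0]
result = desmoke(fx.degraded)
print(psnr(fx.clean, fx.degraded), psnr(fx.clean, result.smoke_free))
```

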