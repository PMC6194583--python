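# Methods

## Model and assumptions

A smoked laparoscopic image is modeled additively as `I = L + F`: direct
attenuation `L = J_s·t_s` (scene radiance surviving passage through the
smoke, transmission `t_s = e^{−β·d_s}` set by smoke thickness, not scene
depth) plus the smoke veil `F = A_s·(1 − t_s)`, the airlight scattered
off the smoke. Neither `t_s` nor `A_s` is estimated — the decomposition
is resolved by two priors on the veil alone:

1. **Smoothness.** Illumination and smoke thickness vary smoothly except
   at large depth jumps, so `F` has low spatial contrast.
2. **Channel balance.** Scattering is treated as wavelength-independent,
   so the veil is (nearly) equal in R, G and B.

Both priors enter one convex energy: a quadratic data term `(γ/2)‖F−I‖²`
plus an isotropic TV norm over the three directions x, y and channel,
`Σᵢ √(θₓ²[DₓF]ᵢ² + θᵧ²[DᵧF]ᵢ² + θ_c²[D_cF]ᵢ²)`. Small γ means `F`
follows only the large-scale structure of `I`; the channel direction of
the TV term drives inter-channel differences toward zero.

All computation happens on `float64` intensities in [0, 1]; the 8-bit
integer representation exists only at the PNG/JPEG boundary. The energy
weights are therefore scale-free, and γ = 1 refers to this unit scale.

## Optimization

The energy is split (`D F = u` with `D = [θₓDₓ; θᵧDᵧ; θ_cD_c]`) and
solved by ADMM:

- **F-update** — the normal equations `(γ + ρ DᵀD) F = γI + ρDᵀu − Dᵀr`
  are diagonalized by the 3-D FFT and solved exactly in one pass.
  All difference operators are circular (periodic), including the
  channel axis of length 3 (B wraps to R); periodicity is what makes the
  FFT quotient the exact minimizer rather than an approximation.
- **u-update** — the isotropic vector soft-threshold
  `u_d = max(v − 1/ρ, 0)·v_d/v` with `v_d = θ_d D_d F + r_d/ρ` and
  `v = max(√Σ v_d², ε)`; the shared norm couples the three directions.
- **r-update** — multiplier ascent `r_d += ρ(θ_d D_d F − u_d)`.

Initialization is `F⁰ = I`, `u⁰ = r⁰ = 0` (the γ→∞ limit, making the
first data term vanish). Iteration stops when the relative change of F
drops below `tol` or after `max_iters` sweeps. The iterates are never
clipped — the subproblem is an unconstrained solve — and the returned
veil is clipped to [0, 1] once, at the end.

### Parameters

| name | default | meaning |
|---|---|---|
| `gamma` | 1 | data-fidelity weight on the [0,1] intensity scale; larger values pull F toward I (verified as a strict monotonicity property in the tests) |
| `rho` | 5 | ADMM penalty; also the shrinkage threshold 1/ρ |
| `theta_x,y,c` | 1 | direction weights, spatial smoothness vs channel balance |
| `eps` | 1e-6 | floor on the shrinkage norm and relative-change denominators |
| `max_iters` | 50 | enough for 128×128 frames to reach visually stable veils in well under a second |
| `tol` | 1e-4 | relative change of F |

The adjoint `Dᵀ` is implemented as the negated circular backward
difference and verified against the inner-product identity
`⟨DF, G⟩ = ⟨F, DᵀG⟩` to 1e-10 on random fields. With γ = 0 the DC mode
of the quotient vanishes and the solve raises a singular-solve error
rather than dividing by zero.

Correctness of the optimizer is established two ways, both against
references that share no code with the solver: the FFT solve is compared
with an explicitly assembled dense solve of the normal equations
(agreement ~1e-15), and the full ADMM run is compared with an L-BFGS
minimization of the ε-smoothed energy (ADMM's final energy is lower by
~3e-8 relative).

## Recovery

`L = I − α(c)·F` with `α(c)` the spatial mean of veil channel `c`
(computed after the final clipping, since the veil is reported as an
image), followed by a linear stretch of `L` to the full display range.
The stretch uses one joint min/max across all three channels by default:
per-channel stretching (available behind a flag) would rescale the
channels independently and introduce exactly the color shift this method
is designed to avoid. `L` is not clipped before the stretch; negative
values carry range information and participate in the minimum. A
degenerate range (< 1e-6) falls back to a plain clip so constant images
pass through unchanged.

## Synthetic data

Fixtures composite a smoke field `s ∈ [0,1]` onto a clean image `J` as
`I = (1 − w·s)·J + w·s·A`, i.e. the additive model with
`t_s = 1 − w·s`. Defaults `w = 0.75` and neutral gray `A = (0.85, 0.85,
0.85)` put the degraded inputs in the mid-to-high-teens input-PSNR
regime of moderately smoked frames.

Clean scenes are procedural: low-frequency reddish color fields
(Perlin-based) with fine texture, a near-black instrument/cavity band,
endoscope-style peripheral vignetting and saturated specular highlights.
The full dynamic range matters: the recovery stretches its output to
[0, 1], so clean references that span the display range are required for
full-reference scores to be meaningful.

Smoke fields come in two profiles. `perlin` maps multi-octave
gradient-lattice Perlin noise (self-contained implementation — lattice
gradients, quintic fade, octave summation — so fixtures reproduce from
the seed alone on any platform) into the density window [0.15, 0.70]:
frame-covering moderate smoke whose transmission varies over a limited
range, the smooth-smoke operating regime of the veil-subtraction
recovery; dense heterogeneous smoke is a known failure mode of this
family of methods and is deliberately not the default test condition.
`smooth_veil` produces parametric level + gradient + Gaussian-blob
fields, channel-equal by construction, giving exact ground truth for
estimator probes.

What the generator does **not** emulate: sensor noise, motion blur,
interlacing, non-gray smoke tinted by tissue reflectance, and smoke that
is optically thick enough to saturate. Passing tests on these fixtures
therefore demonstrate the machinery works in the regime the model
assumes, not performance on adversarial real footage.

## Metrics

PSNR is `10·log₁₀(1/MSE)` on the unit scale (identical images report
infinity). SSIM is single-scale on Rec. 601 luma with an 11-tap Gaussian
window (σ = 1.5) and the standard stabilizers; luma was chosen over
per-channel averaging as a convention. The restored-edges score is a
simplified visible-edge ratio: a pixel is a visible edge when its Sobel
gradient magnitude on luma exceeds 0.05, and the score is the relative
change in visible-edge count from input to restoration. It is meant for
comparative use only; its absolute value depends on the threshold
convention.

## Known limitations

- The estimated veil deliberately retains the scene's large-scale
  luminance (that is what a small γ buys): on scenes with strong smooth
  structure — vignetting, instrument shadows — the raw correlation
  between the estimated veil and the true embedded smoke component is
  modest (~0.55-0.6 pattern correlation on the smooth-veil fixtures).
  The scene-cancelled response, `F(degraded) − F(clean)` against
  `degraded − clean`, reaches ~0.75-0.8; both numbers are recomputed by
  `scripts/acceptance.py`. Separating scene luminance from veil would
  require priors this model does not have.
- A single global stretch cannot restore spatially varying contrast
  loss: regions under thick smoke stay flatter than their clean
  counterparts while clear regions are slightly over-amplified.
- TV staircasing: at full convergence the veil can develop piecewise-
  flat patches where the true veil ramps smoothly.
- Periodic boundaries wrap content across image borders; veils with a
  strong global gradient pick up a wrap seam near the frame edge.
- Frames are processed independently; no temporal consistency.
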