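"""Synthetic surgical-smoke fixtures with known ground truth.

Paired clean/degraded images are built by linearly compositing a smoke
field ``s`` onto a clean image ``J``:

    I = (1 - w * s) * J + w * s * A,

with smoke weight ``w`` in [0, 1] and veil color ``A`` (a whitish gray).
This is the additive smoke model ``I = J * t + A * (1 - t)`` with
transmission ``t = 1 - w * s``: where the smoke field is dense, the scene
is attenuated and replaced by scattered airlight.

Two kinds of smoke field are provided: classic gradient-lattice Perlin
noise (plausible wispy smoke, the standard way synthetic surgical smoke
is rendered for evaluation) and smooth parametric veils
(level + gradient + Gaussian blob, identical across channels) whose
ground truth exactly satisfies the smoothness and channel-equality
assumptions of the veil estimator.

Clean images are procedurally generated organ-like scenes — smooth
reddish low-frequency color fields with added texture, a dark
instrument-like band and bright specular spots — so the whole pipeline
is testable without any dataset download.  The Perlin generator is
self-contained (lattice gradients, quintic fade, octave summation) so a
fixture is reproducible across platforms from its seed alone.

Defaults: smoke weight 0.75 and neutral-gray veil color (0.85, 0.85,
0.85), which degrade the clean images into the high-teens input-PSNR
regime typical of moderately smoked laparoscopic frames.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_io import write_image

__all__ = [
    "SmokeFixture",
    "perlin_field",
    "smooth_veil",
    "embed_smoke",
    "organ_scene",
    "make_fixture_set",
    "write_fixture_set",
]

DEFAULT_WEIGHT = 0.75
DEFAULT_VEIL_COLOR = (0.85, 0.85, 0.85)


def _fade(t: np.ndarray) -> np.ndarray:
    # quintic smoothstep 6t^5 - 15t^4 + 10t^3: zero 1st/2nd derivative at cell edges
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def _perlin_octave(
    height: int, width: int, cell: float, rng: np.random.Generator
) -> np.ndarray:
    """One octave of gradient-lattice noise with lattice spacing ``cell``."""
    ys = np.arange(height) / cell
    xs = np.arange(width) / cell
    y0 = ys.astype(np.int64)
    x0 = xs.astype(np.int64)
    ty = (ys - y0)[:, None]
    tx = (xs - x0)[None, :]

    angles = rng.uniform(0.0, 2.0 * np.pi, size=(int(y0.max()) + 2, int(x0.max()) + 2))
    gcos = np.cos(angles)
    gsin = np.sin(angles)
    Y0 = y0[:, None]
    X0 = x0[None, :]

    def corner(dy: int, dx: int) -> np.ndarray:
        # dot product of the corner gradient with the offset to the pixel
        return gcos[Y0 + dy, X0 + dx] * (tx - dx) + gsin[Y0 + dy, X0 + dx] * (
            ty - dy
        )

    u = _fade(tx)
    v = _fade(ty)
    top = corner(0, 0) + u * (corner(0, 1) - corner(0, 0))
    bottom = corner(1, 0) + u * (corner(1, 1) - corner(1, 0))
    return top + v * (bottom - top)


def perlin_field(
    height: int,
    width: int,
    base_scale: int = 32,
    octaves: int = 4,
    persistence: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Classic multi-octave Perlin noise, min-max normalized to [0, 1].

    Octave ``k`` uses lattice spacing ``base_scale / 2**k`` (floored at
    one pixel) and amplitude ``persistence**k``.  Fully determined by
    ``seed``.
    """
    if height < 1 or width < 1:
        raise ValueError("dimensions must be positive")
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    rng = np.random.default_rng(seed)
    total = np.zeros((height, width))
    amplitude = 1.0
    for k in range(octaves):
        cell = max(base_scale / 2**k, 1.0)
        total += amplitude * _perlin_octave(height, width, cell, rng)
        amplitude *= persistence
    lo, hi = total.min(), total.max()
    if hi - lo < 1e-12:  # degenerate (e.g. 1x1 image)
        return np.full((height, width), 0.5)
    return (total - lo) / (hi - lo)


def smooth_veil(
    height: int,
    width: int,
    level: float = 0.4,
    gradient: tuple[float, float] = (0.0, 0.0),
    blob: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Smooth parametric ground-truth veil, identical across channels.

    ``gradient = (gx, gy)`` adds a linear ramp of total swing ``gx``
    across the width and ``gy`` across the height (centered);
    ``blob = (cy, cx, radius, amplitude)`` adds a Gaussian bump.  The
    result is clamped to [0, 1] (with a warning if the clamp is active)
    and replicated to 3 channels.
    """
    y = np.arange(height)[:, None]
    x = np.arange(width)[None, :]
    f = np.full((height, width), float(level))
    gx, gy = gradient
    if width > 1:
        f = f + gx * (x / (width - 1) - 0.5)
    if height > 1:
        f = f + gy * (y / (height - 1) - 0.5)
    if blob is not None:
        cy, cx, radius, amplitude = blob
        d2 = (y - cy) ** 2 + (x - cx) ** 2
        f = f + amplitude * np.exp(-d2 / (2.0 * radius**2))
    if f.min() < 0.0 or f.max() > 1.0:
        warnings.warn(
            "smooth_veil parameters drive values outside [0, 1]; clamping",
            stacklevel=2,
        )
        f = np.clip(f, 0.0, 1.0)
    return np.repeat(f[:, :, None], 3, axis=2)


def embed_smoke(
    clean: np.ndarray,
    s: np.ndarray,
    veil_color: tuple[float, float, float],
    weight: float,
) -> np.ndarray:
    """Linearly composite smoke field ``s`` onto ``clean``.

    ``I = (1 - w s) J + w s A`` pointwise; the output is clipped to
    [0, 1], a no-op whenever the inputs are in range.
    """
    clean = np.asarray(clean, dtype=np.float64)
    ws = weight * np.asarray(s, dtype=np.float64)[:, :, None]
    color = np.asarray(veil_color, dtype=np.float64)
    return np.clip((1.0 - ws) * clean + ws * color, 0.0, 1.0)


def organ_scene(height: int, width: int, seed: int) -> np.ndarray:
    """Procedural organ-like clean scene.

    Smooth reddish low-frequency color fields plus fine texture, with a
    probability-1/2 dark diagonal band standing in for an instrument and
    a few bright Gaussian spots standing in for specular highlights.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31, size=4)
    span = max(height, width)
    base = perlin_field(height, width, base_scale=span, octaves=2, seed=int(sub[0]))
    shade = perlin_field(
        height, width, base_scale=max(span // 2, 2), octaves=2, seed=int(sub[1])
    )
    tex = perlin_field(
        height, width, base_scale=max(span // 8, 2), octaves=3, seed=int(sub[2])
    )

    # bright close-illuminated tissue: luma around 0.5 so that the default
    # smoke weight degrades clean scenes into the high-teens input-PSNR regime
    r = 0.68 + 0.15 * (base - 0.5) + 0.08 * (tex - 0.5)
    g = 0.45 + 0.12 * (shade - 0.5) + 0.07 * (tex - 0.5)
    b = 0.38 + 0.10 * (shade - 0.5) + 0.05 * (tex - 0.5)
    img = np.stack([r, g, b], axis=2)

    y = np.arange(height)[:, None]
    x = np.arange(width)[None, :]
    # instrument shaft / cavity: a near-black band, as in real frames
    theta = rng.uniform(0.0, np.pi)
    offset = rng.uniform(0.25, 0.75) * span
    half_width = rng.uniform(0.03, 0.07) * span
    dist = np.abs(x * np.cos(theta) + y * np.sin(theta) - offset)
    band = 1.0 / (1.0 + np.exp((half_width - dist) / max(1.0, 0.1 * half_width)))
    img *= (0.03 + 0.97 * band)[:, :, None]

    # endoscope illumination falloff: corners fall toward black
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    d2 = ((y - cy) / max(cy, 1.0)) ** 2 + ((x - cx) / max(cx, 1.0)) ** 2
    vignette = 1.0 - 0.55 * (d2 / 2.0) ** 1.5
    img *= vignette[:, :, None]

    for _ in range(int(rng.integers(1, 4))):  # saturated specular highlights
        py = rng.uniform(0, height)
        px = rng.uniform(0, width)
        sigma = rng.uniform(0.01, 0.03) * span + 1.0
        spot = np.exp(-((y - py) ** 2 + (x - px) ** 2) / (2.0 * sigma**2))
        img += (1.0 - img) * np.minimum(1.4 * spot, 1.0)[:, :, None]

    return np.clip(img, 0.0, 1.0)


@dataclass
class SmokeFixture:
    """A clean/degraded pair with its generating smoke field and recipe.

    The degraded image is, bit-exactly, the linear composite of the
    stored components — :meth:`composite` recomputes it and
    :meth:`is_consistent` verifies the identity.
    """

    clean: np.ndarray
    smoke_field: np.ndarray
    veil_color: tuple[float, float, float]
    weight: float
    degraded: np.ndarray
    seed: int
    recipe: dict = field(default_factory=dict)

    @property
    def true_veil(self) -> np.ndarray:
        """Additive airlight component ``w * s * A`` of the degraded image."""
        ws = self.weight * self.smoke_field[:, :, None]
        return ws * np.asarray(self.veil_color)

    @property
    def transmission(self) -> np.ndarray:
        return 1.0 - self.weight * self.smoke_field

    def composite(self) -> np.ndarray:
        return embed_smoke(
            self.clean, self.smoke_field, self.veil_color, self.weight
        )

    def is_consistent(self) -> bool:
        return bool(np.array_equal(self.degraded, self.composite()))


def _perlin_smoke(h: int, w: int, seed: int) -> tuple[np.ndarray, dict]:
    # frame-covering moderate smoke: the normalized field is mapped into
    # [0.15, 0.70] so the transmission 1 - w*s varies over a limited range,
    # the smooth-smoke operating regime of the veil-subtraction recovery
    params = dict(
        base_scale=max(h, w) // 2, octaves=3, persistence=0.5, seed=seed
    )
    s = 0.15 + 0.55 * perlin_field(h, w, **params)
    return s, {"kind": "perlin", "density_range": [0.15, 0.70], **params}


def _smooth_smoke(
    h: int, w: int, seed: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    level = float(rng.uniform(0.35, 0.55))
    direction = float(rng.uniform(0.0, 2.0 * np.pi))
    magnitude = float(rng.uniform(0.25, 0.4))
    gradient = (magnitude * np.cos(direction), magnitude * np.sin(direction))
    blob = (
        float(rng.uniform(0.2, 0.8) * h),
        float(rng.uniform(0.2, 0.8) * w),
        float(rng.uniform(0.1, 0.25) * max(h, w)),
        float(rng.uniform(0.15, 0.3)),
    )
    veil = smooth_veil(h, w, level=level, gradient=gradient, blob=blob)
    recipe = {
        "kind": "smooth_veil",
        "level": level,
        "gradient": [float(gradient[0]), float(gradient[1])],
        "blob": list(blob),
        "seed": seed,
    }
    return veil[:, :, 0], recipe


def make_fixture_set(
    n: int,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    profile: str = "perlin",
    weight: float = DEFAULT_WEIGHT,
    veil_color: tuple[float, float, float] = DEFAULT_VEIL_COLOR,
) -> list[SmokeFixture]:
    """Generate ``n`` reproducible fixtures.

    ``profile`` selects the smoke field: ``'perlin'`` (wispy noise),
    ``'smooth_veil'`` (parametric ground-truth veils) or ``'mixed'``
    (alternating).  Per-fixture seeds are derived from ``seed`` via a
    seed sequence, so every fixture is stable across runs and platforms.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if profile not in ("perlin", "smooth_veil", "mixed"):
        raise ValueError(f"unknown profile {profile!r}")
    h, w = size
    fixtures = []
    for i in range(n):
        ss = np.random.SeedSequence([int(seed), i])
        scene_seed, smoke_seed, aux_seed = (
            int(s) & 0x7FFFFFFF for s in ss.generate_state(3)
        )
        clean = organ_scene(h, w, scene_seed)
        kind = profile
        if profile == "mixed":
            kind = "perlin" if i % 2 == 0 else "smooth_veil"
        if kind == "perlin":
            s, smoke_recipe = _perlin_smoke(h, w, smoke_seed)
        else:
            aux_rng = np.random.default_rng(aux_seed)
            s, smoke_recipe = _smooth_smoke(h, w, smoke_seed, aux_rng)
        degraded = embed_smoke(clean, s, veil_color, weight)
        recipe = {
            "index": i,
            "scene_seed": scene_seed,
            "smoke": smoke_recipe,
            "weight": weight,
            "veil_color": list(veil_color),
            "size": [h, w],
        }
        fixtures.append(
            SmokeFixture(
                clean=clean,
                smoke_field=s,
                veil_color=tuple(veil_color),
                weight=weight,
                degraded=degraded,
                seed=scene_seed,
                recipe=recipe,
            )
        )
    return fixtures


def write_fixture_set(
    fixtures: list[SmokeFixture], outdir: str | os.PathLike
) -> str:
    """Write fixtures as PNG trios plus a JSON manifest; returns manifest path.

    Layout: ``clean/NNN.png``, ``degraded/NNN.png``, ``veil/NNN.png``
    (smoke field as grayscale RGB) and ``manifest.json`` recording each
    fixture's seeds and recipe.
    """
    outdir = os.fspath(outdir)
    for sub in ("clean", "degraded", "veil"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    entries = []
    for i, fx in enumerate(fixtures):
        name = f"{i:03d}.png"
        write_image(fx.clean, os.path.join(outdir, "clean", name))
        write_image(fx.degraded, os.path.join(outdir, "degraded", name))
        write_image(
            np.repeat(fx.smoke_field[:, :, None], 3, axis=2),
            os.path.join(outdir, "veil", name),
        )
        entries.append({"file": name, "recipe": fx.recipe})
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"n": len(fixtures), "fixtures": entries}, fh, indent=2)
    return manifest_path
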