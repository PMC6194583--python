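"""Image-quality measures for evaluating desmoking on paired fixtures.

Full-reference: PSNR on the [0, 1] scale and single-scale SSIM computed
on Rec. 601 luma with the standard Gaussian window (sigma = 1.5,
stabilizers C1 = 0.01^2, C2 = 0.03^2).  Reduced-reference: a simplified
restored-edges (RE) score — the relative change in the count of visible
edge pixels, a pixel counting as a visible edge when its local gradient
magnitude on luma exceeds a 5% visibility threshold.  RE > 0 means the
restoration made edges visible that were hidden before.

RE here is the visible-edge ratio only, intended for comparative use;
trained no-reference measures (fog density, sharpness, contrast models)
are out of scope, and the report schema leaves an ``extras`` slot so
externally computed scores can be merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import sobel
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "psnr", "ssim", "restored_edges", "score_pair"]

#: Rec. 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

#: minimum gradient magnitude for a pixel to count as a visible edge
EDGE_VISIBILITY_THRESHOLD = 0.05


def _luma(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64) @ _LUMA


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def psnr(ref: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on the [0, 1] scale.

    ``10 * log10(1 / MSE)`` with the MSE over all pixels and channels;
    identical images return ``inf``.
    """
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    _check_shapes(ref, test)
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def ssim(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity of the two images' luma channels."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    _check_shapes(ref, test)
    if min(ref.shape[0], ref.shape[1]) < 11:
        raise ValueError("image smaller than the 11-tap SSIM window")
    return float(
        structural_similarity(
            _luma(ref),
            _luma(test),
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def restored_edges(before: np.ndarray, after: np.ndarray) -> float:
    """Relative change in visible-edge count, ``(n_a - n_b) / max(n_b, 1)``."""
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    _check_shapes(before, after)
    n_b = int(np.count_nonzero(sobel(_luma(before)) > EDGE_VISIBILITY_THRESHOLD))
    n_a = int(np.count_nonzero(sobel(_luma(after)) > EDGE_VISIBILITY_THRESHOLD))
    return (n_a - n_b) / max(n_b, 1)


@dataclass
class MetricReport:
    """Per-image quality scores, with room for externally merged extras."""

    psnr_db: float
    ssim: float
    restored_edges: float
    extras: dict = field(default_factory=dict)


def score_pair(
    clean: np.ndarray, degraded: np.ndarray, restored: np.ndarray
) -> MetricReport:
    """Score a restored image against its clean reference.

    PSNR/SSIM compare ``restored`` with ``clean``; RE compares edge
    visibility of ``restored`` against the ``degraded`` input.
    """
    return MetricReport(
        psnr_db=psnr(clean, restored),
        ssim=ssim(clean, restored),
        restored_edges=restored_edges(degraded, restored),
    )
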