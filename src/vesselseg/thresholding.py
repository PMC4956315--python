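"""Otsu thresholding, wide/thin fusion, and region-based offset thresholds.

The classifier works in three moves.  A global Otsu threshold — the gray
level t* maximizing the between-class variance

    sigma2_B(t) = w0 (mu0 - muT)^2 + w1 (mu1 - muT)^2

over all candidate splits S0 = {0..t}, S1 = {t+1..L-1} — binarizes the
wide-vessel enhanced image.  The resulting wide-vessel mask is fused into
the thin-vessel enhanced image by saturating its pixels to 1.0, so both
calibers are prominent in one image.  Finally a two-valued region
threshold map classifies the fused image: t_global + offset inside a
dilated neighborhood of the wide vessels (suppressing noise next to
strong vessels), t_global - offset elsewhere (recovering faint thin
vessels far from them).

Statistics also expose the within/total variances and the ratios
alpha = sigma2_B / sigma2_W, beta = sigma2_B / sigma2_T and
gamma = sigma2_T / sigma2_W; since sigma2_T is constant in t, maximizing
alpha, beta or sigma2_B pick the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "GrayHistogram",
    "OtsuStats",
    "ThresholdMap",
    "DegenerateHistogramError",
    "EmptyFOVError",
    "build_histogram",
    "otsu_threshold",
    "level_to_intensity",
    "apply_threshold",
    "fuse_wide_into_thin",
    "region_threshold_map",
    "classify_pixels",
]


class DegenerateHistogramError(ValueError):
    """All mass sits in a single gray level; no two-class split exists."""


class EmptyFOVError(ValueError):
    """The field-of-view mask selects no pixels."""


@dataclass(frozen=True)
class GrayHistogram:
    """Gray-level histogram over L levels: counts n_i, total n, P_i = n_i/n."""

    counts: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        if self.counts.shape != (self.levels,):
            raise ValueError("counts must have one entry per level")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        n = self.n
        if n == 0:
            return np.zeros(self.levels, dtype=np.float64)
        return self.counts.astype(np.float64) / n


@dataclass(frozen=True)
class OtsuStats:
    """Class statistics at a split t: probabilities, means, variances, ratios."""

    omega0: float
    omega1: float
    mu0: float
    mu1: float
    mu_t: float
    muT: float
    sigma2_W: float
    sigma2_B: float
    sigma2_T: float
    alpha: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class ThresholdMap:
    """Per-pixel thresholds: t_global + offset near wide vessels, - offset away."""

    values: np.ndarray
    t_global: float
    offset: float
    neighborhood_radius: int


def quantize_levels(img: np.ndarray, levels: int) -> np.ndarray:
    """Map [0,1] intensities to integer levels by round-half-up: floor(v(L-1)+0.5)."""
    return np.floor(np.clip(img, 0.0, 1.0) * (levels - 1) + 0.5).astype(np.intp)


def build_histogram(
    img: np.ndarray, fov: np.ndarray | None = None, levels: int = 256
) -> GrayHistogram:
    """Histogram of FOV pixels after quantization to *levels* gray levels."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(img, dtype=np.float64)
    if fov is not None:
        fov = np.asarray(fov).astype(bool)
        if fov.shape != img.shape:
            raise ValueError("fov shape must match the image")
        values = img[fov]
        if values.size == 0:
            raise EmptyFOVError("field-of-view mask selects no pixels")
    else:
        values = img.ravel()
    lev = quantize_levels(values, levels)
    counts = np.bincount(lev, minlength=levels)
    return GrayHistogram(counts=counts, levels=levels)


def _stats_at(P: np.ndarray, t: int) -> OtsuStats:
    L = P.size
    i = np.arange(L, dtype=np.float64)
    muT = float(np.sum(i * P))
    sigma2_T = float(np.sum((i - muT) ** 2 * P))
    omega0 = float(np.sum(P[: t + 1]))
    omega1 = 1.0 - omega0
    mu_t = float(np.sum(i[: t + 1] * P[: t + 1]))
    mu0 = mu_t / omega0 if omega0 > 0 else 0.0
    mu1 = (muT - mu_t) / omega1 if omega1 > 0 else 0.0
    sigma2_0 = (
        float(np.sum((i[: t + 1] - mu0) ** 2 * P[: t + 1])) / omega0
        if omega0 > 0
        else 0.0
    )
    sigma2_1 = (
        float(np.sum((i[t + 1 :] - mu1) ** 2 * P[t + 1 :])) / omega1
        if omega1 > 0
        else 0.0
    )
    sigma2_W = omega0 * sigma2_0 + omega1 * sigma2_1
    sigma2_B = omega0 * (mu0 - muT) ** 2 + omega1 * (mu1 - muT) ** 2
    alpha = sigma2_B / sigma2_W if sigma2_W > 0 else float("inf")
    beta = sigma2_B / sigma2_T if sigma2_T > 0 else 0.0
    gamma = sigma2_T / sigma2_W if sigma2_W > 0 else float("inf")
    return OtsuStats(
        omega0=omega0,
        omega1=omega1,
        mu0=mu0,
        mu1=mu1,
        mu_t=mu_t,
        muT=muT,
        sigma2_W=sigma2_W,
        sigma2_B=sigma2_B,
        sigma2_T=sigma2_T,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
    )


def otsu_threshold(hist: GrayHistogram) -> tuple[int, OtsuStats]:
    """Exhaustive Otsu split of a gray-level histogram.

    Evaluates sigma2_B at every t in {0..L-2} and returns the maximizer
    (the smallest on ties, so the output is deterministic) together with
    the full class statistics at t*.  Requires at least two populated
    levels; a single-spike histogram has no meaningful split.
    """
    if int(np.count_nonzero(hist.counts)) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two populated gray levels"
        )
    counts = [int(c) for c in hist.counts]
    L = hist.levels
    n = sum(counts)
    total_moment = sum(i * c for i, c in enumerate(counts))
    # Up to normalization by n^2, sigma2_B(t) equals
    #   (total_moment*c0 - moment_t*n)^2 / (c0*(n - c0)),
    # a ratio of integers; comparing splits by cross-multiplication keeps the
    # argmax exact, so ties break toward the smallest level deterministically.
    c0 = 0
    moment = 0
    best_t = 0
    best_num, best_den = -1, 1
    for t in range(L - 1):
        c0 += counts[t]
        moment += t * counts[t]
        if c0 == 0 or c0 == n:
            num, den = 0, 1
        else:
            num = (total_moment * c0 - moment * n) ** 2
            den = c0 * (n - c0)
        if num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    return best_t, _stats_at(hist.probabilities, best_t)


def level_to_intensity(t: int, levels: int) -> float:
    """Map a gray level back to the [0,1] intensity scale: t / (L-1)."""
    return t / (levels - 1)


def apply_threshold(
    img: np.ndarray, t: float, fov: np.ndarray | None = None
) -> np.ndarray:
    """Binarize at an intensity threshold, inclusively: mask = (img >= t)."""
    img = np.asarray(img, dtype=np.float64)
    mask = (img >= t).astype(np.uint8)
    if fov is not None:
        mask = mask * np.asarray(fov).astype(np.uint8)
    return mask


def fuse_wide_into_thin(thin_img: np.ndarray, wide_mask: np.ndarray) -> np.ndarray:
    """Saturate the wide-vessel pixels of the thin-enhanced image to 1.0.

    Equivalent to the pixel-wise maximum of the thin image and the binary
    wide-vessel map; wide vessels then survive any clamped threshold.
    """
    thin_img = np.asarray(thin_img, dtype=np.float64)
    wide_mask = np.asarray(wide_mask)
    if thin_img.shape != wide_mask.shape:
        raise ValueError(
            f"shape mismatch: thin {thin_img.shape} vs wide mask {wide_mask.shape}"
        )
    return np.where(wide_mask > 0, 1.0, thin_img)


def region_threshold_map(
    t_global: float,
    wide_mask: np.ndarray,
    offset: float = 0.05,
    radius: int = 8,
) -> ThresholdMap:
    """Two-valued threshold map around the global Otsu threshold.

    The neighborhood N is the wide-vessel mask dilated by a disk of the
    given radius; the map is t_global + offset on N and t_global - offset
    off N, clamped to [0,1].
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    wide = np.asarray(wide_mask).astype(bool)
    if radius > 0 and wide.any():
        neighborhood = ndimage.binary_dilation(
            wide, structure=disk(radius).astype(bool)
        )
    else:
        neighborhood = wide
    hi = min(t_global + offset, 1.0)
    lo = max(t_global - offset, 0.0)
    values = np.where(neighborhood, hi, lo)
    return ThresholdMap(
        values=values,
        t_global=float(t_global),
        offset=float(offset),
        neighborhood_radius=int(radius),
    )


def classify_pixels(
    fused: np.ndarray, tmap: ThresholdMap, wide_mask: np.ndarray
) -> np.ndarray:
    """Vessel classification: wide_mask OR (fused >= local threshold)."""
    fused = np.asarray(fused, dtype=np.float64)
    wide_mask = np.asarray(wide_mask)
    if fused.shape != tmap.values.shape or fused.shape != wide_mask.shape:
        raise ValueError(
            f"shape mismatch: fused {fused.shape}, map {tmap.values.shape}, "
            f"wide mask {wide_mask.shape}"
        )
    return ((wide_mask > 0) | (fused >= tmap.values)).astype(np.uint8)
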