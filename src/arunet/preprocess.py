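"""Three-stage MRI enhancement chain: CLAHE -> non-local means -> Kuwahara.

The chain targets the two dominant nuisances of clinical brain MRI slices:
low-frequency intensity inhomogeneity (coil bias fields) and additive
acquisition noise.  Contrast-limited adaptive histogram equalisation (CLAHE)
restores local tumor/tissue contrast, non-local means removes the noise that
local equalisation amplifies, and an edge-preserving Kuwahara filter smooths
homogeneous texture without blurring tumor boundaries.  The order of the three
stages is fixed.

All stages operate on 8-bit grayscale images (``uint8``-valued 2D arrays,
intensities in ``[0, 255]``), are fully deterministic, and use reflection
padding at image borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "ClaheParams",
    "NlmParams",
    "KuwaharaParams",
    "PipelineResult",
    "to_grayscale",
    "validate_gray_image",
    "clahe",
    "nlm_denoise",
    "kuwahara",
    "preprocess_pipeline",
    "michelson_contrast",
    "local_michelson_contrast",
]

#: number of gray levels of an 8-bit image
L_LEVELS = 256


@dataclass
class ClaheParams:
    """CLAHE configuration.

    ``clip_limit`` is expressed as a multiple of the uniform histogram bin
    height (``tile_pixels / 256``); ``2.0`` therefore allows each bin to hold
    at most twice the count of a perfectly flat histogram before the excess is
    redistributed.
    """

    tile_rows: int = 8
    tile_cols: int = 8
    clip_limit: float = 2.0

    def validate(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ParameterError("CLAHE tile grid must be at least 1x1")
        if self.clip_limit <= 0:
            raise ParameterError("CLAHE clip_limit must be positive")


@dataclass
class NlmParams:
    """Non-local means configuration.

    ``h`` is the smoothing bandwidth applied to intensities normalised to
    ``[0, 1]``; useful values lie around 0.8-1.2.
    """

    patch_radius: int = 1
    search_radius: int = 5
    h: float = 1.0

    def validate(self) -> None:
        if self.patch_radius < 1 or self.search_radius < 1:
            raise ParameterError("NLM radii must be >= 1")
        if self.h <= 0:
            raise ParameterError("NLM smoothing parameter h must be positive")


@dataclass
class KuwaharaParams:
    """Kuwahara filter configuration.

    ``mode`` is ``"standard"`` (each pixel takes the mean of the
    lowest-variance quadrant) or ``"linear"`` (variance-weighted blend of the
    four quadrant means, which is robust against the block-selection
    instability of the standard filter).  ``linear_temp`` is the sharpness
    exponent of the blend; as it grows the linear filter approaches the
    standard one.
    """

    window_size: int = 5
    mode: str = "linear"
    linear_temp: float = 8.0

    def validate(self) -> None:
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ParameterError("Kuwahara window_size must be odd and >= 3")
        if self.mode not in ("standard", "linear"):
            raise ParameterError(f"unknown Kuwahara mode {self.mode!r}")
        if self.linear_temp <= 0:
            raise ParameterError("linear_temp must be positive")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an ``(H, W)`` or ``(H, W, 3)`` uint8 array to grayscale.

    Color inputs are reduced with ITU-R BT.601 luminance weights; MRI slices
    stored as RGB are intensity images replicated across channels, for which
    this is exact.
    """
    img = np.asarray(img)
    if img.ndim == 3:
        if img.shape[2] == 1:
            img = img[:, :, 0]
        else:
            lum = (
                0.299 * img[..., 0].astype(np.float64)
                + 0.587 * img[..., 1]
                + 0.114 * img[..., 2]
            )
            img = np.floor(lum + 0.5).astype(np.uint8)
    return img


def validate_gray_image(img: np.ndarray) -> np.ndarray:
    """Check the 8-bit grayscale contract and return the image as uint8."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ParameterError(f"expected a 2D image, got shape {img.shape}")
    if img.dtype != np.uint8:
        if not np.issubdtype(img.dtype, np.integer):
            if not np.all(img == np.floor(img)):
                raise ParameterError("gray image values must be integral")
        if img.min() < 0 or img.max() > L_LEVELS - 1:
            raise ParameterError("gray image values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _box_sums(a: np.ndarray, q: int) -> np.ndarray:
    """Sums of all q-by-q blocks of ``a`` (top-left anchored), via 2D cumsum.

    Integer inputs stay in exact int64 arithmetic.
    """
    dtype = np.int64 if np.issubdtype(a.dtype, np.integer) else np.float64
    c = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=dtype)
    np.cumsum(np.cumsum(a, axis=0, dtype=dtype), axis=1, out=c[1:, 1:])
    return c[q:, q:] - c[:-q, q:] - c[q:, :-q] + c[:-q, :-q]


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _clahe_tile_mapping(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Per-tile clipped-equalisation lookup table (length 256)."""
    mn = tile.size
    hist = np.bincount(tile.ravel(), minlength=L_LEVELS).astype(np.float64)
    clip = clip_limit * mn / L_LEVELS
    excess = np.maximum(hist - clip, 0.0).sum()
    if excess > 0:
        hist = np.minimum(hist, clip)
        # one uniform redistribution pass over all bins
        hist += excess / L_LEVELS
    cdf = np.cumsum(hist)
    return np.clip(_round_half_up((L_LEVELS - 1) / mn * cdf), 0, L_LEVELS - 1)


def clahe(img: np.ndarray, params: Optional[ClaheParams] = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation.

    The image is divided into a ``tile_rows x tile_cols`` grid (padded by
    reflection when the grid does not divide the image).  Each tile's
    histogram is clipped at ``clip_limit`` times the uniform bin height, the
    clipped excess is spread uniformly over all bins, and the tile mapping is

        I' = round((L - 1) / MN * cumsum(h))

    with ``MN`` the tile pixel count.  Pixel outputs are bilinearly
    interpolated between the mappings of the four nearest tile centres, which
    removes visible tile seams.
    """
    params = params or ClaheParams()
    params.validate()
    img = validate_gray_image(img)
    h, w = img.shape
    tr, tc = params.tile_rows, params.tile_cols
    if h < tr or w < tc:
        raise ParameterError(
            f"image {h}x{w} smaller than one pixel per tile for grid {tr}x{tc}"
        )
    th = -(-h // tr)  # ceil
    tw = -(-w // tc)
    padded = np.pad(img, ((0, th * tr - h), (0, tw * tc - w)), mode="reflect")

    maps = np.empty((tr, tc, L_LEVELS), dtype=np.float64)
    for r in range(tr):
        for c in range(tc):
            tile = padded[r * th:(r + 1) * th, c * tw:(c + 1) * tw]
            maps[r, c] = _clahe_tile_mapping(tile, params.clip_limit)

    hp, wp = padded.shape
    ty = np.clip((np.arange(hp) - (th - 1) / 2.0) / th, 0.0, tr - 1.0)
    tx = np.clip((np.arange(wp) - (tw - 1) / 2.0) / tw, 0.0, tc - 1.0)
    y0 = np.floor(ty).astype(np.intp)
    x0 = np.floor(tx).astype(np.intp)
    y1 = np.minimum(y0 + 1, tr - 1)
    x1 = np.minimum(x0 + 1, tc - 1)
    fy = (ty - y0)[:, None]
    fx = (tx - x0)[None, :]

    v = padded
    y0c, y1c = y0[:, None], y1[:, None]
    x0c, x1c = x0[None, :], x1[None, :]
    out = (1.0 - fy) * ((1.0 - fx) * maps[y0c, x0c, v] + fx * maps[y0c, x1c, v]) + \
        fy * ((1.0 - fx) * maps[y1c, x0c, v] + fx * maps[y1c, x1c, v])
    out = np.clip(_round_half_up(out), 0, L_LEVELS - 1).astype(np.uint8)
    return out[:h, :w]


# ---------------------------------------------------------------------------
# Non-local means
# ---------------------------------------------------------------------------

def nlm_denoise(img: np.ndarray, params: Optional[NlmParams] = None) -> np.ndarray:
    """Non-local means denoising.

    Each output pixel is a weighted average of the pixels in its search
    window, the weight of neighbour ``y`` being

        w(x, y) ∝ exp(-||P(x) - P(y)||^2 / (2 h^2))

    where ``P(.)`` is the square intensity patch around a pixel (intensities
    normalised to ``[0, 1]`` so that ``h`` is scale-free) and the weights are
    normalised to sum to one.  Borders are handled by reflection.
    """
    params = params or NlmParams()
    params.validate()
    img = validate_gray_image(img)
    h_img, w_img = img.shape
    pr, sr = params.patch_radius, params.search_radius
    pad = pr + sr
    if pad > min(h_img, w_img) - 1:
        raise ParameterError(
            f"patch_radius + search_radius = {pad} too large for a "
            f"{h_img}x{w_img} image (reflection padding needs it < min(H, W))"
        )
    x = img.astype(np.float64) / (L_LEVELS - 1)
    big = np.pad(x, pad, mode="reflect")
    two_h2 = 2.0 * params.h ** 2
    patch_size = 2 * pr + 1

    num = np.zeros((h_img, w_img))
    den = np.zeros((h_img, w_img))
    # D(dy,dx)(i,j) = sum over the patch of (I(i+u) - I(i+d+u))^2, computed as
    # a box filter over the squared shifted difference.
    base = big[sr:sr + h_img + 2 * pr, sr:sr + w_img + 2 * pr]
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            shifted = big[sr + dy:sr + dy + h_img + 2 * pr,
                          sr + dx:sr + dx + w_img + 2 * pr]
            sq = (base - shifted) ** 2
            dist = _box_sums(sq, patch_size)
            w = np.exp(-dist / two_h2)
            vals = big[pad + dy:pad + dy + h_img, pad + dx:pad + dx + w_img]
            num += w * vals
            den += w
    out = (L_LEVELS - 1) * num / den
    return np.clip(_round_half_up(out), 0, L_LEVELS - 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# Kuwahara
# ---------------------------------------------------------------------------

def _kuwahara_quadrant_stats(img: np.ndarray, window_size: int):
    """Exact integer sums / sum-of-squares of the four window quadrants.

    For a ``w x w`` window the quadrants are the four ``ceil(w/2)``-square
    corner subwindows sharing the centre row and column (classical Kuwahara
    decomposition), stacked in NW, NE, SW, SE order.
    Returns ``(sums, crit, n)`` where ``crit = n * sum(x^2) - sum(x)^2`` is an
    exact integer quantity proportional to the quadrant variance.
    """
    r = window_size // 2
    q = r + 1
    h, w = img.shape
    padded = np.pad(img.astype(np.int64), r, mode="reflect")
    s1 = _box_sums(padded, q)
    s2 = _box_sums(padded * padded, q)
    n = q * q
    sl = [(slice(0, h), slice(0, w)), (slice(0, h), slice(r, r + w)),
          (slice(r, r + h), slice(0, w)), (slice(r, r + h), slice(r, r + w))]
    sums = np.stack([s1[a, b] for a, b in sl])
    sqs = np.stack([s2[a, b] for a, b in sl])
    crit = n * sqs - sums * sums
    return sums, crit, n


def kuwahara(img: np.ndarray, params: Optional[KuwaharaParams] = None) -> np.ndarray:
    """Edge-preserving Kuwahara smoothing (standard or linear variant).

    Standard mode replaces each pixel with the mean of the quadrant of its
    window having the lowest variance (ties broken toward the lowest quadrant
    index, NW < NE < SW < SE, for determinism).  Linear mode blends the four
    quadrant means with weights ``(sigma_k^2 + eps)^(-linear_temp)``
    normalised to sum to one, which degrades gracefully when two quadrants
    have near-equal variance.  Quadrant selection uses exact integer
    arithmetic, so results are reproducible to the bit.
    """
    params = params or KuwaharaParams()
    params.validate()
    img = validate_gray_image(img)
    sums, crit, n = _kuwahara_quadrant_stats(img, params.window_size)
    if params.mode == "standard":
        k = np.argmin(crit, axis=0)  # first minimum: NW, NE, SW, SE order
        sel = np.take_along_axis(sums, k[None], axis=0)[0]
        out = sel / n
    else:
        var = crit.astype(np.float64) / (n * n)
        wgt = (var + 1e-6) ** (-params.linear_temp)
        means = sums / n
        # fixed left-to-right quadrant order keeps the float sum reproducible
        num = wgt[0] * means[0] + wgt[1] * means[1] + wgt[2] * means[2] + wgt[3] * means[3]
        den = wgt[0] + wgt[1] + wgt[2] + wgt[3]
        out = num / den
    return np.clip(_round_half_up(out), 0, L_LEVELS - 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Output image of the preprocessing chain plus a stage provenance log."""

    image: np.ndarray
    stages: list = field(default_factory=list)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.image, dtype=dtype)


def preprocess_pipeline(
    img: np.ndarray,
    clahe_params: Optional[ClaheParams] = None,
    nlm_params: Optional[NlmParams] = None,
    kuwahara_params: Optional[KuwaharaParams] = None,
    *,
    apply_defaults: bool = False,
) -> PipelineResult:
    """Apply CLAHE, then non-local means, then Kuwahara, in that fixed order.

    A stage runs when its parameter set is given (or when ``apply_defaults``
    is true, in which case missing parameter sets fall back to defaults);
    passing no parameter sets yields the identity.  The returned
    :class:`PipelineResult` records which stages ran with which parameters.
    """
    if apply_defaults:
        clahe_params = clahe_params or ClaheParams()
        nlm_params = nlm_params or NlmParams()
        kuwahara_params = kuwahara_params or KuwaharaParams()
    img = validate_gray_image(to_grayscale(img))
    stages = []
    out = img
    if clahe_params is not None:
        out = clahe(out, clahe_params)
        stages.append({"stage": "clahe", **asdict(clahe_params)})
    if nlm_params is not None:
        out = nlm_denoise(out, nlm_params)
        stages.append({"stage": "nlm_denoise", **asdict(nlm_params)})
    if kuwahara_params is not None:
        out = kuwahara(out, kuwahara_params)
        stages.append({"stage": "kuwahara", **asdict(kuwahara_params)})
    return PipelineResult(image=out, stages=stages)


def local_michelson_contrast(
    img: np.ndarray,
    mask: np.ndarray,
    dilate: int = 16,
    percentiles: tuple = (5.0, 95.0),
) -> float:
    """Michelson contrast ``(Lmax - Lmin) / (Lmax + Lmin)`` of the tumor
    neighbourhood.

    The luminance extremes are taken as robust percentiles over the region
    within ``dilate`` pixels of the mask (tumor plus surrounding texture), so
    the value measures the local dynamic range that separates the lesion from
    its background rather than a global mean difference.
    """
    from scipy import ndimage

    region = ndimage.binary_dilation(np.asarray(mask) > 0, iterations=dilate)
    vals = np.asarray(img, dtype=np.float64)[region]
    lo, hi = np.percentile(vals, percentiles)
    if lo + hi == 0:
        return 0.0
    return float((hi - lo) / (hi + lo))


def michelson_contrast(img: np.ndarray, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Michelson contrast ``(m_fg - m_bg) / (m_fg + m_bg)`` between two regions."""
    img = np.asarray(img, dtype=np.float64)
    m_fg = img[np.asarray(fg_mask, bool)].mean()
    m_bg = img[np.asarray(bg_mask, bool)].mean()
    denom = m_fg + m_bg
    if denom == 0:
        return 0.0
    return float((m_fg - m_bg) / denom)
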