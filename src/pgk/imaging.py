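"""Image preprocessing, segmentation and trait extraction.

The pipeline mirrors standard RGB plant-phenotyping practice: resize to
a working resolution, smooth, separate plant from background with a
vegetation index, then measure morphology, colour and texture on the
foreground.

Traits are measured as follows (each is an explicit, documented proxy
that is monotone in the named property, and swappable via the extractor
registry):

    LC  mean excess-green index ExG = 2g - r - b on chromatic
        coordinates over the foreground, rescaled from [-1, 2] to [0, 1]
    LA  foreground pixel count / image area
    TU  1 - normalised GLCM entropy of the foreground grey levels
        (8 levels, distance 1, four symmetric directions averaged)
    VP  ridge-filter (Sato) response density inside the foreground
    ES  mean gradient magnitude along the mask boundary
    WI  1 - solidity (foreground area / convex hull area)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage import feature, filters, measure, morphology, transform

from .encoding import TRAIT_CODES, RawTraitRecord

__all__ = [
    "SegmentationError",
    "PreprocessConfig",
    "preprocess_segment",
    "extract_traits",
    "excess_green",
    "glcm_features",
]


class SegmentationError(ValueError):
    """Raised when no plant foreground can be found in an image."""


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    ``working_size``: target long-side resolution; larger images are
    downscaled (aspect preserved), smaller or equal ones left unchanged.
    ``smooth_sigma``: Gaussian smoothing radius in pixels.
    ``segmenter``: "exg" (excess-green + Otsu, default) or "hsv"
    (hue-band threshold on green hues).
    """

    working_size: int = 512
    smooth_sigma: float = 1.0
    segmenter: str = "exg"
    hue_band: tuple[float, float] = (0.17, 0.45)


def excess_green(image: np.ndarray) -> np.ndarray:
    """ExG = 2g - r - b on chromatic coordinates; range [-1, 2].

    ``image`` is RGB in any numeric range; pixels summing to zero get
    ExG = 0 (fully black carries no greenness evidence).
    """
    img = np.asarray(image, dtype=float)
    s = img.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r, g, b = (np.where(s > 0, img[..., i] / s, 1.0 / 3.0) for i in range(3))
    return 2.0 * g - r - b


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3 or img.size == 0:
        raise ValueError(f"expected a non-empty HxWx3 RGB image, got shape {img.shape}")
    return img


def preprocess_segment(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resize, smooth and segment a plant image.

    Returns ``(preprocessed, mask)`` where ``preprocessed`` is float RGB
    in [0, 1] at working resolution and ``mask`` the boolean foreground
    (largest connected component above the vegetation threshold).

    Raises :class:`SegmentationError` when thresholding leaves no
    foreground pixels.
    """
    config = config or PreprocessConfig()
    img = _validate_rgb(image).astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    h, w = img.shape[:2]
    long_side = max(h, w)
    if long_side > config.working_size:
        scale = config.working_size / long_side
        img = transform.resize(
            img,
            (int(round(h * scale)), int(round(w * scale))),
            anti_aliasing=True,
            preserve_range=True,
        )
    if config.smooth_sigma > 0:
        img = filters.gaussian(img, sigma=config.smooth_sigma, channel_axis=-1)

    if config.segmenter == "exg":
        exg = excess_green(img)
        if np.ptp(exg) == 0:
            raise SegmentationError("image has no greenness contrast; nothing to segment")
        mask = exg > filters.threshold_otsu(exg)
    elif config.segmenter == "hsv":
        from skimage.color import rgb2hsv

        hsv = rgb2hsv(img)
        lo, hi = config.hue_band
        mask = (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi) & (hsv[..., 1] > 0.15)
    else:
        raise ValueError(f"unknown segmenter {config.segmenter!r}")

    if not mask.any():
        raise SegmentationError("segmentation produced an empty foreground mask")
    labelled = measure.label(mask)
    counts = np.bincount(labelled.ravel())
    counts[0] = 0
    mask = labelled == int(np.argmax(counts))
    return img, mask


def glcm_features(
    gray: np.ndarray, mask: np.ndarray, levels: int = 8
) -> tuple[float, float]:
    """Foreground GLCM (entropy, contrast), averaged over four directions.

    ``gray`` is a [0, 1] grey image.  Foreground pixels are quantised to
    ``levels`` grey levels; background is excluded by mapping it to a
    reserved level whose co-occurrence rows/columns are dropped before
    normalisation.  Entropy is in bits, normalised to [0, 1] by the
    maximum log2(levels^2); contrast is the standard weighted
    sum-of-squared-level-differences.  A perfectly uniform foreground
    yields exactly (0.0, 0.0).
    """
    if not mask.any():
        raise ValueError("empty mask")
    q = np.zeros(gray.shape, dtype=np.uint8)  # 0 = background sentinel
    fg = np.clip((gray[mask] * levels).astype(int), 0, levels - 1)
    q[mask] = fg + 1
    glcm = feature.graycomatrix(
        q,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )
    glcm = glcm[1:, 1:, 0, :].astype(float)  # drop background row/col
    entropies, contrasts = [], []
    ii, jj = np.mgrid[0:levels, 0:levels]
    for a in range(glcm.shape[-1]):
        m = glcm[..., a]
        total = m.sum()
        if total == 0:
            continue
        p = m / total
        nz = p[p > 0]
        entropies.append(float(-(nz * np.log2(nz)).sum()) / (2.0 * np.log2(levels)))
        contrasts.append(float((p * (ii - jj) ** 2).sum()))
    if not entropies:
        return 0.0, 0.0
    return float(np.mean(entropies)), float(np.mean(contrasts))


def _gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:
        img = img / 255.0
    return img @ np.array([0.2126, 0.7152, 0.0722])


def _lc(image, mask):  # mean ExG rescaled from [-1, 2] to [0, 1]
    return float(np.clip((excess_green(image)[mask].mean() + 1.0) / 3.0, 0.0, 1.0))


def _la(image, mask):
    return float(mask.sum()) / mask.size


def _tu(image, mask):
    entropy, _ = glcm_features(_gray(image), mask)
    return float(np.clip(1.0 - entropy, 0.0, 1.0))


def _vp(image, mask):
    resp = filters.sato(_gray(image), sigmas=(1.0, 2.0), black_ridges=True)
    resp = np.where(mask, resp, 0.0)
    peak = resp.max()
    if peak <= 0:
        return 0.0
    return float((resp[mask] > 0.5 * peak).mean())


def _es(image, mask):
    grad = filters.sobel(_gray(image))
    boundary = mask & ~morphology.erosion(mask)
    if not boundary.any():
        boundary = mask
    return float(np.clip(grad[boundary].mean(), 0.0, 1.0))


def _wi(image, mask):
    props = measure.regionprops(mask.astype(np.uint8))[0]
    return float(np.clip(1.0 - props.solidity, 0.0, 1.0))


#: Trait-extractor registry; replace an entry to swap a proxy.
TRAIT_EXTRACTORS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "LC": _lc,
    "LA": _la,
    "TU": _tu,
    "VP": _vp,
    "ES": _es,
    "WI": _wi,
}


def extract_traits(
    image: np.ndarray,
    mask: np.ndarray,
    plant_id: str = "plant",
    zone_id: str = "zone",
    acre_id: str = "acre",
    condition: str | None = None,
) -> RawTraitRecord:
    """Measure the six canonical traits on a segmented image."""
    img = _validate_rgb(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("cannot extract traits from an empty mask")
    values = {code: TRAIT_EXTRACTORS[code](img, mask) for code in TRAIT_CODES}
    return RawTraitRecord(
        plant_id=plant_id,
        zone_id=zone_id,
        acre_id=acre_id,
        values=values,
        condition=condition,
    )
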