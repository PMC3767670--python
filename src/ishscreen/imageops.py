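"""Low-level image operations: Otsu thresholding and per-pixel features.

The Otsu threshold is computed directly on the 256-bin histogram with a fixed
convention: the threshold ``t`` maximizing the between-class variance of the
split ``[0..t]`` vs ``[t+1..255]`` (first maximum wins), and the *dark* class
``value <= t`` is the foreground, since ISH signal is dark on a light
background.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import footprint_rectangle


def otsu_threshold(image: np.ndarray) -> int:
    """Between-class-variance-optimal integer threshold of an 8-bit image.

    Raises ``ValueError`` on a constant image (the split is undefined).
    """
    image = np.asarray(image)
    hist = np.bincount(image.ravel().astype(np.uint8), minlength=256).astype(float)
    n = hist.sum()
    if n == 0 or np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for a constant or empty image")
    p = hist / n
    omega = np.cumsum(p)  # weight of class [0..t]
    mu = np.cumsum(p * np.arange(256))  # first moment of class [0..t]
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def dark_foreground(image: np.ndarray) -> np.ndarray:
    """Otsu segmentation with dark pixels as foreground."""
    return np.asarray(image) <= otsu_threshold(image)


def pixel_features(image: np.ndarray, size: int = 9) -> np.ndarray:
    """Per-pixel feature stack ``(H, W, 4)``: intensity, local mean, local
    standard deviation and local entropy in a ``size x size`` neighbourhood.

    Used by the segmentation QC forest that classifies points as inside or
    outside the cell-body bands.
    """
    img = np.asarray(image, dtype=float)
    mean = uniform_filter(img, size=size)
    sq = uniform_filter(img * img, size=size)
    std = np.sqrt(np.clip(sq - mean * mean, 0.0, None))
    ent = _rank_entropy(
        np.asarray(image, dtype=np.uint8), footprint_rectangle((size, size))
    )
    return np.stack([img, mean, std, ent], axis=-1)
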