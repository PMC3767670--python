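"""Texture description of segmented hippocampal regions.

Each of the 13 regions is described, at one or two window sizes, by eleven
features: seven first-order statistics of the raw window intensities
(mean, standard deviation, coefficient of variation, skewness, kurtosis,
histogram energy, histogram entropy) and four second-order Haralick features
of a 16-level gray-level co-occurrence matrix (contrast, correlation, energy,
homogeneity).  The GLCM is symmetric and non-directional: co-occurrences are
counted in both orders over the four unit-distance directions and pooled
before normalization.

With the standard window map (two sizes for the band-core and neuropil
regions, one for the flanks) the descriptor has exactly
20 (region, window) pairs x 11 features = 220 named values.

Conventions for degenerate windows (constant intensity): coefficient of
variation, skewness, kurtosis and GLCM correlation are defined as 0, so every
window yields a finite vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_LEVELS = 16
OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

#: window sizes per region (px); band-core ("a") and distal-neuropil regions
#: get two scales, the flanking regions one.
WINDOW_MAP: dict[str, tuple[int, ...]] = {
    "CA1a": (18, 36), "CA1b": (24,), "CA1c": (24,), "CA1d": (14, 28),
    "CA3a": (18, 36), "CA3b": (24,), "CA3c": (24,), "CA3d": (14, 28),
    "DGa": (18, 36), "DGb": (24,), "DGc": (24,), "DGd": (14, 28),
    "DGe": (18, 36),
}

FIRST_ORDER_NAMES = ("mean", "sd", "cv", "skewness", "kurtosis", "energy", "entropy")
SECOND_ORDER_NAMES = ("contrast", "correlation", "energy2", "homogeneity")
FEATURE_NAMES = FIRST_ORDER_NAMES + SECOND_ORDER_NAMES


def canonical_feature_names(window_map: dict[str, tuple[int, ...]] = WINDOW_MAP) -> list[str]:
    """The fixed feature order: region, then window size, then feature."""
    names = []
    for region, sizes in window_map.items():
        for size in sizes:
            for feat in FEATURE_NAMES:
                names.append(f"{region}_{size}_{feat}")
    return names


def quantize(window: np.ndarray, levels: int = N_LEVELS) -> np.ndarray:
    """Uniform quantization of 8-bit intensities: ``v -> floor(v / 16)``."""
    q = np.asarray(window).astype(np.int64) * levels // 256
    return np.minimum(q, levels - 1)


@dataclass
class GLCM:
    matrix: np.ndarray
    levels: int = N_LEVELS
    offsets: tuple[tuple[int, int], ...] = OFFSETS


def compute_glcm(window: np.ndarray, offsets=OFFSETS, levels: int = N_LEVELS) -> GLCM:
    """Pooled symmetric non-directional GLCM of a quantized window.

    ``window`` holds level indices in ``[0, levels)``.  Every ordered pair at
    each offset is counted in both directions, pooled across offsets, and the
    matrix normalized to sum 1.
    """
    q = np.asarray(window, dtype=np.int64)
    if q.ndim != 2:
        raise ValueError("window must be 2-D")
    counts = np.zeros(levels * levels, dtype=np.int64)
    any_pair = False
    for dr, dc in offsets:
        h, w = q.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(counts, a * levels + b, 1)
        np.add.at(counts, b * levels + a, 1)
        any_pair = True
    if not any_pair:
        raise ValueError("window too small for every offset")
    m = counts.reshape(levels, levels).astype(float)
    return GLCM(m / m.sum(), levels, tuple(offsets))


def glcm_features(g: GLCM) -> tuple[float, float, float, float]:
    """Haralick (contrast, correlation, energy, homogeneity) of a GLCM."""
    p = g.matrix
    n = g.levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(np.sum(p * (i - j) ** 2))
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    var_i = float(np.sum(p * (i - mu_i) ** 2))
    var_j = float(np.sum(p * (j - mu_j) ** 2))
    denom = np.sqrt(var_i * var_j)
    correlation = float(np.sum(p * (i - mu_i) * (j - mu_j)) / denom) if denom > 0 else 0.0
    energy = float(np.sum(p * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    return contrast, correlation, energy, homogeneity


def first_order_features(window: np.ndarray) -> tuple[float, ...]:
    """(mean, sd, cv, skewness, kurtosis, energy, entropy) of raw intensities.

    Moments are population moments; kurtosis is the plain standardized fourth
    moment (3 for a Gaussian).  Energy and entropy are computed on the
    16-bin normalized intensity histogram, with ``0 log 0 = 0``.
    """
    x = np.asarray(window, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    mean = float(x.mean())
    sd = float(x.std())
    cv = sd / mean if mean != 0 else 0.0
    if sd > 0:
        z = (x - mean) / sd
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4))
    else:
        skewness = 0.0
        kurtosis = 0.0
    hist = np.bincount(quantize(window).ravel(), minlength=N_LEVELS).astype(float)
    h = hist / hist.sum()
    energy = float(np.sum(h * h))
    nz = h[h > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return mean, sd, cv, skewness, kurtosis, energy, entropy


def window_features(window: np.ndarray) -> np.ndarray:
    """All 11 features of one raw 8-bit window, in canonical order."""
    fo = first_order_features(window)
    so = glcm_features(compute_glcm(quantize(window)))
    return np.array(fo + so)


@dataclass
class WindowPlacement:
    boxes: list[tuple[int, int, int, int]]
    fallback: bool = False


def place_windows(
    mask: np.ndarray, size: int, min_coverage: float = 0.5
) -> WindowPlacement:
    """Window placement covering a region mask as much as possible.

    The region's bounding box is tiled with non-overlapping ``size x size``
    windows anchored at its top-left corner; windows with at least
    ``min_coverage`` of their pixels inside the mask are kept.  If none
    qualifies, the single best-covered candidate is used; if no candidate fits
    in the bounding box at all, one window is centered on the region centroid
    (clipped to the image) and the placement flagged as a fallback.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty region mask")
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    candidates = [
        (r, c, r + size, c + size)
        for r in range(r0, r1 - size + 1, size)
        for c in range(c0, c1 - size + 1, size)
    ]
    if not candidates:
        cr = int(round(rows.mean()))
        cc = int(round(cols.mean()))
        h, w = mask.shape
        rr = int(np.clip(cr - size // 2, 0, max(h - size, 0)))
        cc0 = int(np.clip(cc - size // 2, 0, max(w - size, 0)))
        return WindowPlacement([(rr, cc0, min(rr + size, h), min(cc0 + size, w))], True)
    coverage = [mask[b[0] : b[2], b[1] : b[3]].mean() for b in candidates]
    kept = [b for b, cov in zip(candidates, coverage) if cov >= min_coverage]
    if kept:
        return WindowPlacement(kept, False)
    return WindowPlacement([candidates[int(np.argmax(coverage))]], True)


def extract_region_features(
    image: np.ndarray, mask: np.ndarray, window_sizes: tuple[int, ...]
) -> dict[str, float]:
    """Per-(window-size, feature) means over the windows covering a region."""
    out: dict[str, float] = {}
    for size in window_sizes:
        placement = place_windows(mask, size)
        vals = np.mean(
            [window_features(image[b[0] : b[2], b[1] : b[3]]) for b in placement.boxes],
            axis=0,
        )
        for name, v in zip(FEATURE_NAMES, vals):
            out[f"{size}_{name}"] = float(v)
    return out


def assemble_feature_vector(
    image: np.ndarray,
    regions,
    window_map: dict[str, tuple[int, ...]] = WINDOW_MAP,
) -> pd.Series:
    """The full named texture descriptor of one section (length 220).

    ``regions`` is a mapping from region name to boolean mask (a
    :class:`~ishscreen.segmentation.RegionSet` works via its ``regions``
    attribute).
    """
    masks = getattr(regions, "regions", regions)
    values: dict[str, float] = {}
    for region, sizes in window_map.items():
        if region not in masks:
            raise KeyError(f"missing region '{region}' in segmentation")
        feats = extract_region_features(image, masks[region], sizes)
        for key, v in feats.items():
            values[f"{region}_{key}"] = v
    order = canonical_feature_names(window_map)
    return pd.Series([values[k] for k in order], index=order, dtype=float)


# ---------------------------------------------------------------------------
# Feature-table I/O (TSV; one row per probe, canonical column order).

ID_COLUMNS = ("gene", "probe", "level")


def write_feature_table(path, table: pd.DataFrame) -> None:
    expected = list(ID_COLUMNS) + canonical_feature_names()
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing[:3]}...")
    table[expected].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    expected = list(ID_COLUMNS) + canonical_feature_names()
    if list(table.columns) != expected:
        raise ValueError("feature table columns are not in canonical order")
    return table
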