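"""Localization of the hippocampal cell-body bands in a section image.

The stage mirrors classical statistical-shape-model practice: a 15-point
deformable template (8 control points on the Ammon's-horn band midline, 7 on
the dentate-gyrus midline) with principal-component deformation modes is
fitted to a preprocessed image by minimizing an energy with Differential
Evolution.  A separate two-step affine registration (damped least squares,
then Particle Swarm Optimization) matches a section against a reference atlas
to pick the slice level and hippocampus ROI.

Energy
------
The fitted polylines should run along dark, signal-dense tissue that has
light tissue on its outer side.  The energy is the negative mean, over
polyline samples, of ``inv + lambda * fg + mu * (inv - inv_outside)`` with
``lambda = mu = 1``, where ``inv`` is the Gaussian-smoothed inverted
intensity, ``fg`` the box-filtered Otsu foreground density, and
``inv_outside`` the inverted intensity probed two band widths away on the
outer-normal side.  The smoothing makes the landscape descendable by DE
despite the punctate signal; the contrast term keeps the model on the
cell-body band rather than on a strongly enriched neuropil margin (which is
backed by the dark band instead of light tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.optimize import least_squares
from skimage import exposure, measure
from skimage.registration import phase_cross_correlation

from .imageops import otsu_threshold
from .optimizers import DEParams, PSOParams, de_optimize, pso_optimize
from .synthetic_data import N_AH_POINTS, N_DG_POINTS

ATLAS_LEVEL_RANGE = (117, 175)
DEFAULT_ATLAS_LEVEL = 145


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class PreprocessedROI:
    image: np.ndarray  # enhanced 8-bit image
    foreground: np.ndarray  # boolean mask, at most the 5 largest components
    ok: bool = True


def pooled_intensity_stats(images) -> tuple[float, float]:
    """Median and IQR pooled over a training set of ROIs."""
    vals = np.concatenate([np.asarray(im, dtype=float).ravel() for im in images])
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(med), float(max(q3 - q1, 1e-6))


def preprocess_roi(
    image: np.ndarray,
    norm_stats: tuple[float, float] | None = None,
    saturation_pct: float = 1.0,
    keep_components: int = 5,
) -> PreprocessedROI:
    """Intensity normalization, saturation, CLAHE, and Otsu foreground.

    The image is optionally matched (median/IQR) to pooled training
    statistics, its darkest/brightest ``saturation_pct`` percent saturated,
    contrast-limited adaptive histogram equalization applied, and the dark
    Otsu class reduced to its ``keep_components`` largest connected components
    (ties broken by first-pixel raster order).  A constant image yields an
    empty mask with ``ok=False``.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() == img.max():
        return PreprocessedROI(img.astype(np.uint8), np.zeros(img.shape, bool), ok=False)

    if norm_stats is not None:
        med_t, iqr_t = norm_stats
        q1, med, q3 = np.percentile(img, [25, 50, 75])
        iqr = max(q3 - q1, 1e-6)
        img = (img - med) * (iqr_t / iqr) + med_t

    lo, hi = np.percentile(img, [saturation_pct, 100 - saturation_pct])
    if hi <= lo:
        hi = lo + 1.0
    img = np.clip(img, lo, hi)
    img = (img - lo) / (hi - lo)

    enhanced = exposure.equalize_adapthist(img, clip_limit=0.02)
    enhanced = np.rint(enhanced * 255).astype(np.uint8)

    try:
        t = otsu_threshold(enhanced)
    except ValueError:
        return PreprocessedROI(enhanced, np.zeros(img.shape, bool), ok=False)
    fg = enhanced <= t
    labels = measure.label(fg, connectivity=2)
    if labels.max() > keep_components:
        flat = labels.ravel()
        areas = np.bincount(flat)
        first_pixel = np.full(labels.max() + 1, flat.size, dtype=np.int64)
        nz = np.nonzero(flat)[0]
        # first occurrence per label (nz scanned in raster order)
        np.minimum.at(first_pixel, flat[nz], nz)
        order = sorted(range(1, labels.max() + 1), key=lambda l: (-areas[l], first_pixel[l]))
        keep = set(order[:keep_components])
        fg = np.isin(labels, list(keep))
    return PreprocessedROI(enhanced, fg, ok=True)


# ---------------------------------------------------------------------------
# Shape model


@dataclass
class ShapeModel:
    """Point-distribution model: mean shape plus principal deformation modes.

    ``mean`` is ``(15, 2)`` (8 AH + 7 DG points); ``modes`` is
    ``(k, 15, 2)`` with unit-norm directions and ``sigmas`` their standard
    deviations over the training shapes.  Mode coefficients are bounded at
    ``+-3 sigma`` when fitting.
    """

    mean: np.ndarray
    modes: np.ndarray
    sigmas: np.ndarray
    n_ah: int = N_AH_POINTS
    n_dg: int = N_DG_POINTS

    def validate(self) -> None:
        if self.mean.shape != (self.n_ah + self.n_dg, 2):
            raise ValueError("mean shape must have exactly 8 AH + 7 DG points")

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        shape = self.mean.copy()
        for b, mode in zip(coeffs, self.modes):
            shape = shape + b * mode
        return shape

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "n_ah": self.n_ah,
                    "n_dg": self.n_dg,
                    "mean": self.mean.tolist(),
                    "modes": self.modes.tolist(),
                    "sigmas": self.sigmas.tolist(),
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        d = yaml.safe_load(Path(path).read_text())
        model = cls(
            mean=np.array(d["mean"], dtype=float),
            modes=np.array(d["modes"], dtype=float),
            sigmas=np.array(d["sigmas"], dtype=float),
            n_ah=d["n_ah"],
            n_dg=d["n_dg"],
        )
        model.validate()
        return model


def build_shape_model(shapes, n_modes: int = 4) -> ShapeModel:
    """Principal-component point-distribution model from training shapes."""
    X = np.stack([np.asarray(s, dtype=float).reshape(-1) for s in shapes])
    mean = X.mean(axis=0)
    centered = X - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_modes, len(svals))
    sigmas = svals[:k] / np.sqrt(max(len(X) - 1, 1))
    modes = vt[:k].reshape(k, -1, 2)
    model = ShapeModel(mean.reshape(-1, 2), modes, sigmas)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Shape fitting


@dataclass
class LocalizationResult:
    ah_points: np.ndarray | None
    dg_points: np.ndarray | None
    energy: float
    roi: tuple[int, int, int, int]
    atlas_level: int | None = None
    ok: bool = True
    reason: str = ""

    @property
    def points(self) -> np.ndarray:
        return np.vstack([self.ah_points, self.dg_points])


def _resample_matrix(n_points: int, n_samples: int) -> np.ndarray:
    """Linear operator mapping control points to a densely sampled polyline.

    Sampling is uniform in the chained segment parameter, which makes the
    polyline samples a fixed linear function of the control points and lets a
    whole DE population be evaluated with one matrix product.
    """
    t = np.linspace(0.0, n_points - 1.0, n_samples)
    W = np.zeros((n_samples, n_points))
    i = np.minimum(t.astype(int), n_points - 2)
    frac = t - i
    W[np.arange(n_samples), i] = 1.0 - frac
    W[np.arange(n_samples), i + 1] = frac
    return W


_W_AH = _resample_matrix(N_AH_POINTS, 60)
_W_DG = _resample_matrix(N_DG_POINTS, 50)
_W_BOTH = np.block(
    [
        [_W_AH, np.zeros((60, N_DG_POINTS))],
        [np.zeros((50, N_AH_POINTS)), _W_DG],
    ]
)

ENERGY_LAMBDA = 1.0
ENERGY_MU = 1.0  # weight of the band-edge contrast term


def energy_maps(
    enhanced: np.ndarray, foreground: np.ndarray, band_width: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed inverted-intensity and foreground-density maps."""
    inv = ndimage.gaussian_filter((255.0 - np.asarray(enhanced, float)) / 255.0, 2.0)
    fgd = ndimage.uniform_filter(foreground.astype(float), size=int(round(band_width)))
    return inv, fgd


def _outside_offsets(samples: np.ndarray, band_width: float) -> np.ndarray:
    """Probe points two band widths away on the negative-normal (outer) side.

    ``samples`` is ``(..., n_samples, 2)`` with the AH samples first and the
    DG samples after; tangents are taken per structure.  The cell-body band
    has light tissue on its outer side whereas the neuropil margin is backed
    by the dark band itself, so an inner/outer intensity contrast
    disambiguates the two dark ridges when the neuropil is strongly enriched.
    """
    n_ah = _W_AH.shape[0]
    out = np.empty_like(samples)
    for sl in (np.s_[..., :n_ah, :], np.s_[..., n_ah:, :]):
        seg = samples[sl]
        tang = np.gradient(seg, axis=-2)
        norm = np.linalg.norm(tang, axis=-1, keepdims=True)
        tang = tang / np.where(norm > 0, norm, 1.0)
        normal = np.stack([-tang[..., 1], tang[..., 0]], axis=-1)
        out[sl] = seg - 2.0 * band_width * normal
    return out


def _sample_map(m: np.ndarray, coords: np.ndarray) -> np.ndarray:
    flat = coords.reshape(-1, 2).T
    return ndimage.map_coordinates(m, flat, order=1, mode="constant", cval=0.0).reshape(
        coords.shape[:-1]
    )


def _energy_from_samples(
    samples: np.ndarray, inv: np.ndarray, fgd: np.ndarray, band_width: float
) -> np.ndarray:
    """Energy of candidate shapes given their polyline samples (lower = better)."""
    iv = _sample_map(inv, samples)
    fv = _sample_map(fgd, samples)
    ov = _sample_map(inv, _outside_offsets(samples, band_width))
    score = iv + ENERGY_LAMBDA * fv + ENERGY_MU * (iv - ov)
    return -score.mean(axis=-1)


def polyline_energy(
    points: np.ndarray, inv: np.ndarray, fgd: np.ndarray, band_width: float = 8.0
) -> float:
    """Energy of one candidate 15-point shape (lower is better)."""
    samples = _W_BOTH @ np.asarray(points, dtype=float)
    return float(_energy_from_samples(samples[None], inv, fgd, band_width)[0])


def _pose_apply(shapes: np.ndarray, pose: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """Apply (t_r, t_c, theta, log_scale) poses to (pop, 15, 2) shapes."""
    tr, tc, theta, logs = pose[:, 0], pose[:, 1], pose[:, 2], pose[:, 3]
    s = np.exp(logs)
    cos, sin = np.cos(theta), np.sin(theta)
    rel = shapes - pivot
    r = rel[..., 0]
    c = rel[..., 1]
    rot_r = cos[:, None] * r - sin[:, None] * c
    rot_c = sin[:, None] * r + cos[:, None] * c
    out = np.empty_like(shapes)
    out[..., 0] = pivot[0] + s[:, None] * rot_r + tr[:, None]
    out[..., 1] = pivot[1] + s[:, None] * rot_c + tc[:, None]
    return out


def fit_shape(
    image: np.ndarray,
    model: ShapeModel,
    de: DEParams = DEParams(),
    foreground: np.ndarray | None = None,
    band_width: float = 8.0,
    max_translation: float = 25.0,
    max_rotation: float = 0.25,
    max_log_scale: float = 0.2,
) -> LocalizationResult:
    """Fit the deformable model to a preprocessed image with DE.

    ``image`` is the enhanced ROI; ``foreground`` its binary mask (computed
    via :func:`preprocess_roi` when omitted).  The DE search space is the pose
    (translation, rotation, isotropic log-scale about the mean-shape centroid)
    plus the mode coefficients bounded at three standard deviations.
    """
    model.validate()
    if foreground is None:
        pre = preprocess_roi(image)
        image, foreground = pre.image, pre.foreground
    roi = (0, 0, image.shape[0], image.shape[1])
    if not foreground.any():
        return LocalizationResult(None, None, np.inf, roi, ok=False, reason="empty foreground")

    inv, fgd = energy_maps(image, foreground, band_width)
    pivot = model.mean.mean(axis=0)
    k = model.n_modes
    bounds = (
        [(-max_translation, max_translation)] * 2
        + [(-max_rotation, max_rotation), (-max_log_scale, max_log_scale)]
        + [(-3 * s, 3 * s) for s in model.sigmas]
    )

    def objective(pop: np.ndarray) -> np.ndarray:
        pop = np.atleast_2d(pop)
        coeffs = pop[:, 4 : 4 + k]
        shapes = model.mean[None] + np.einsum("pk,kij->pij", coeffs, model.modes)
        shapes = _pose_apply(shapes, pop[:, :4], pivot)
        samples = np.einsum("sn,pnc->psc", _W_BOTH, shapes)
        return _energy_from_samples(samples, inv, fgd, band_width)

    de = DEParams(
        crossover_rate=de.crossover_rate, F=de.F, population=de.population,
        generations=de.generations, seed=de.seed, vectorized=True,
    )
    best, energy = de_optimize(objective, bounds, de)
    shape = model.synthesize(best[4 : 4 + k])
    shape = _pose_apply(shape[None], best[None, :4], pivot)[0]
    return LocalizationResult(
        ah_points=shape[: model.n_ah],
        dg_points=shape[model.n_ah :],
        energy=float(energy),
        roi=roi,
    )


# ---------------------------------------------------------------------------
# Atlas registration


@dataclass
class AtlasSlice:
    level: int
    image: np.ndarray
    roi: tuple[int, int, int, int]


@dataclass
class RegistrationResult:
    atlas_level: int | None
    roi: tuple[int, int, int, int] | None
    params: np.ndarray | None  # affine (a11, a12, a21, a22, t_r, t_c)
    similarity: float
    ok: bool = True
    reason: str = ""


def _warp(slice_img: np.ndarray, p: np.ndarray, shape) -> np.ndarray:
    matrix = np.array([[1.0 + p[0], p[1]], [p[2], 1.0 + p[3]]])
    return ndimage.affine_transform(
        slice_img, matrix, offset=p[4:6], output_shape=shape, order=1, mode="nearest"
    )


def _normcorr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_to_atlas(
    image: np.ndarray,
    atlas: list[AtlasSlice],
    pso: PSOParams = PSOParams(),
    top_k: int = 2,
    min_similarity: float = 0.3,
    smooth_sigma: float = 2.0,
) -> RegistrationResult:
    """Two-step affine registration of a section against a reference atlas.

    Step 1 refines a 6-parameter affine per slice with damped least squares on
    the intensity difference (smoothed images); step 2 refines the ``top_k``
    candidates with PSO on the same objective.  The best slice below
    ``min_similarity`` normalized correlation signals failure (which triggers
    slice retry at the pipeline level).
    """
    if not atlas:
        raise ValueError("atlas must be non-empty")
    target = ndimage.gaussian_filter(np.asarray(image, dtype=float), smooth_sigma)
    shape = target.shape

    candidates = []
    for sl in atlas:
        src = ndimage.gaussian_filter(np.asarray(sl.image, dtype=float), smooth_sigma)
        # coarse translation init by phase correlation, then damped least squares
        shift, _, _ = phase_cross_correlation(target, src, normalization=None)
        x0 = np.zeros(6)
        x0[4:6] = -shift  # affine offset maps output coords into source coords

        def residuals(p, src=src):
            return (_warp(src, p, shape) - target).ravel() / target.size

        fit = least_squares(residuals, x0, method="lm", max_nfev=400)
        candidates.append((float(np.sum(fit.fun**2)), sl, src, fit.x))
    candidates.sort(key=lambda t: t[0])

    best = None
    for _, sl, src, x0 in candidates[:top_k]:
        lin = [(x - 0.05, x + 0.05) for x in x0[:4]]
        trans = [(x - 4.0, x + 4.0) for x in x0[4:6]]

        def objective(p, src=src):
            return float(np.sum((_warp(src, p, shape) - target) ** 2))

        init = np.tile(x0, (pso.particles, 1))
        rng = np.random.default_rng(pso.seed)
        init[1:] += rng.uniform(-1, 1, size=(pso.particles - 1, 6)) * (
            [0.02] * 4 + [2.0] * 2
        )
        x, f = pso_optimize(objective, lin + trans, pso, init=init)
        if best is None or f < best[0]:
            best = (f, sl, src, x)

    f, sl, src, x = best
    sim = _normcorr(_warp(src, x, shape), target)
    if sim < min_similarity:
        return RegistrationResult(None, None, None, sim, ok=False, reason="low similarity")

    # map the slice ROI into the image frame through the inverse transform
    matrix = np.array([[1.0 + x[0], x[1]], [x[2], 1.0 + x[3]]])
    inv = np.linalg.inv(matrix)
    r0, c0, r1, c1 = sl.roi
    corners = np.array([[r0, c0], [r0, c1], [r1, c0], [r1, c1]], dtype=float)
    mapped = (inv @ (corners - x[4:6]).T).T
    rr0, cc0 = np.floor(mapped.min(axis=0)).astype(int)
    rr1, cc1 = np.ceil(mapped.max(axis=0)).astype(int)
    h, w = shape
    roi = (max(rr0, 0), max(cc0, 0), min(rr1, h), min(cc1, w))
    return RegistrationResult(sl.level, roi, x, sim, ok=True)
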