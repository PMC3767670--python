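"""13-region segmentation of the hippocampus and its quality control.

From the fitted control points three rectangular areas of interest are
selected: around the maximum-curvature points of the CA1 and CA3 ends of the
Ammon's-horn chain, and on the medial half of the dentate-gyrus chain.  Each
area is thresholded (Otsu, dark foreground) and partitioned geometrically,
perpendicular to the local band axis, into the 13 named regions

    CA1a-d, CA3a-d, DGa-e

where ``a`` is the band core (central half along the axis), ``b``/``c`` the
two lateral band quarters, and ``d`` (``d``/``e`` for the DG) neuropil strips
one band-width wide starting a small guard gap beyond the band edge, on the
stratum-radiatum side of the curve (both sides for the DG).

A two-stage Random-Forest check accepts or rejects the segmentation: a pixel
classifier votes on 12 random points per tested region (inside vs outside the
cell-body bands), and a second forest maps the resulting point accuracy plus
per-region area/intensity statistics to an accept/reject decision.  When a
slice is rejected the pipeline retries neighbouring atlas levels (145 first,
then alternating outward) and finally discards the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .geometry import centered_box, clip_box, polyline_frame
from .imageops import otsu_threshold, pixel_features
from .localization import (
    DEFAULT_ATLAS_LEVEL,
    LocalizationResult,
    _resample_matrix,
)
from .synthetic_data import N_AH_POINTS, N_DG_POINTS, REGION_NAMES

QC_REGIONS = ("CA1a", "CA1d", "CA3a", "CA3d", "DGa", "DGd")
QC_POINTS_PER_REGION = 12

#: band regions are inset to this fraction of the nominal half-width; the
#: neuropil strips start at 1.2x the half-width plus the guard gap.
BAND_CORE_FRACTION = 0.8


class SegmentationError(RuntimeError):
    """Raised when an area cannot be segmented (empty band mask etc.)."""


@dataclass
class SourceBoxes:
    """The three areas of interest and the geometry used to derive them."""

    boxes: dict[str, tuple[int, int, int, int]]
    centers: dict[str, tuple[float, float]]
    size: dict[str, int]
    curvature_fallback: bool = False


def _discrete_curvature(points: np.ndarray) -> np.ndarray:
    """Absolute turn angle at each interior point of a chain."""
    v1 = points[1:-1] - points[:-2]
    v2 = points[2:] - points[1:-1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    cosang = np.einsum("ij,ij->i", v1, v2) / np.maximum(n1 * n2, 1e-12)
    return np.abs(np.arccos(np.clip(cosang, -1.0, 1.0)))


def select_areas(loc: LocalizationResult, box_scale: float = 2.0) -> SourceBoxes:
    """Areas around the CA1/CA3 curvature maxima and the medial DG half.

    Box size is ``box_scale`` times the mean adjacent control-point spacing of
    the owning chain.  If the AH chain is (near) collinear the curvature is
    undefined; the chain endpoints are used instead and the result flagged.
    """
    ah = np.asarray(loc.ah_points, dtype=float)
    dg = np.asarray(loc.dg_points, dtype=float)
    if ah.shape != (N_AH_POINTS, 2) or dg.shape != (N_DG_POINTS, 2):
        raise ValueError("localization result must carry 8 AH and 7 DG points")

    kappa = _discrete_curvature(ah)
    fallback = bool(np.all(kappa < 1e-3))
    if fallback:
        ca1_center, ca3_center = ah[0], ah[-1]
    else:
        interior = np.arange(1, N_AH_POINTS - 1)
        half = len(interior) // 2
        ca1_idx = interior[:half][np.argmax(kappa[:half])]
        ca3_idx = interior[half:][np.argmax(kappa[half:])]
        ca1_center, ca3_center = ah[ca1_idx], ah[ca3_idx]

    ah_spacing = float(np.mean(np.linalg.norm(np.diff(ah, axis=0), axis=1)))
    dg_spacing = float(np.mean(np.linalg.norm(np.diff(dg, axis=0), axis=1)))
    ah_size = int(round(box_scale * ah_spacing))
    dg_size = int(round(box_scale * dg_spacing))

    # midpoint (by arc length) of the medial half of the DG chain
    seg = np.linalg.norm(np.diff(dg, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = 0.25 * s[-1]
    dg_center = np.array(
        [np.interp(target, s, dg[:, 0]), np.interp(target, s, dg[:, 1])]
    )

    centers = {"CA1": tuple(ca1_center), "CA3": tuple(ca3_center), "DG": tuple(dg_center)}
    sizes = {"CA1": ah_size, "CA3": ah_size, "DG": dg_size}
    boxes = {k: centered_box(centers[k], sizes[k]) for k in centers}
    return SourceBoxes(boxes, centers, sizes, fallback)


def otsu_segment(area: np.ndarray) -> np.ndarray:
    """Otsu threshold of one area; foreground is the dark (signal) class."""
    area = np.asarray(area)
    if area.size == 0 or area.min() == area.max():
        raise SegmentationError("constant area: Otsu threshold undefined")
    return area <= otsu_threshold(area)


@dataclass
class RegionSet:
    """The 13 named region masks plus the source boxes they came from."""

    regions: dict[str, np.ndarray]
    source_boxes: SourceBoxes
    shape: tuple[int, int]

    def validate(self) -> None:
        if set(self.regions) != set(REGION_NAMES):
            raise ValueError("a region set must contain exactly the 13 named regions")
        total = np.zeros(self.shape, dtype=np.int16)
        for m in self.regions.values():
            total += m
        if total.max() > 1:
            raise ValueError("region masks overlap")

    def label_raster(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.uint8)
        for i, name in enumerate(REGION_NAMES, start=1):
            out[self.regions[name]] = i
        return out


_DENSE_AH = _resample_matrix(N_AH_POINTS, 200)
_DENSE_DG = _resample_matrix(N_DG_POINTS, 200)


def partition_regions(
    boxes: SourceBoxes,
    masks: dict[str, np.ndarray],
    loc: LocalizationResult,
    image_shape: tuple[int, int],
    band_width: float = 8.0,
    margin_gap: float = 3.5,
) -> RegionSet:
    """Partition the three areas into the 13 named regions.

    ``masks`` maps area name (CA1/CA3/DG) to its Otsu foreground; an empty
    band mask in any area raises :class:`SegmentationError`.  The split is
    purely geometric around the fitted midline: the configured nominal band
    width defines the band; the Otsu masks guarantee there is signal to
    describe.  Pixels are assigned in canonical region order, so the masks are
    disjoint by construction.
    """
    for name in ("CA1", "CA3", "DG"):
        if name not in masks or not np.asarray(masks[name]).any():
            raise SegmentationError(f"empty band mask in area {name}")

    h = band_width / 2.0
    core = BAND_CORE_FRACTION * h
    lo = h + margin_gap
    hi = lo + band_width
    ah_poly = _DENSE_AH @ np.asarray(loc.ah_points, dtype=float)
    dg_poly = _DENSE_DG @ np.asarray(loc.dg_points, dtype=float)

    label = np.zeros(image_shape, dtype=np.uint8)
    order = {name: i + 1 for i, name in enumerate(REGION_NAMES)}

    def area_pixels(box):
        r0, c0, r1, c1 = clip_box(box, image_shape)
        if r0 >= r1 or c0 >= c1:
            raise SegmentationError("area box lies outside the image")
        rr, cc = np.mgrid[r0:r1, c0:c1]
        return np.column_stack([rr.ravel(), cc.ravel()])

    def paint(name, pts, sel):
        idx = (pts[sel, 0], pts[sel, 1])
        free = label[idx] == 0
        label[idx[0][free], idx[1][free]] = order[name]

    for area, poly, two_sided in (("CA1", ah_poly, False), ("CA3", ah_poly, False), ("DG", dg_poly, True)):
        pts = area_pixels(boxes.boxes[area])
        s, d = polyline_frame(poly, pts.astype(float))
        band = np.abs(d) <= core
        if not band.any():
            raise SegmentationError(f"fitted band does not cross area {area}")
        s0, s1 = s[band].min(), s[band].max()
        q = (s1 - s0) / 4.0
        inside_s = (s >= s0) & (s <= s1)
        paint(area + "a", pts, band & (s >= s0 + q) & (s <= s1 - q))
        paint(area + "b", pts, band & (s >= s0) & (s < s0 + q))
        paint(area + "c", pts, band & (s > s1 - q) & (s <= s1))
        paint(area + "d", pts, inside_s & (d > lo) & (d <= hi))
        if two_sided:
            paint(area + "e", pts, inside_s & (d < -lo) & (d >= -hi))

    regions = {name: label == order[name] for name in REGION_NAMES}
    empty = [n for n, m in regions.items() if not m.any()]
    if empty:
        raise SegmentationError(f"empty regions after partition: {empty}")
    rs = RegionSet(regions, boxes, image_shape)
    rs.validate()
    return rs


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QcResult:
    point_accuracy: float
    region_stats: dict[str, tuple[float, float, float]]  # name -> (area, mean, sd)
    accepted: bool
    per_region_accuracy: dict[str, float] | None = None


def region_stats(
    image: np.ndarray, regions: RegionSet
) -> dict[str, tuple[float, float, float]]:
    img = np.asarray(image, dtype=float)
    out = {}
    for name, mask in regions.regions.items():
        vals = img[mask]
        if vals.size:
            out[name] = (float(mask.sum()), float(vals.mean()), float(vals.std()))
        else:
            out[name] = (0.0, 0.0, 0.0)
    return out


def _sample_mask_points(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    idx = np.flatnonzero(mask.ravel())
    pick = rng.choice(idx, size=n, replace=len(idx) < n)
    return np.column_stack(np.unravel_index(pick, mask.shape))


def qc_point_features(
    image: np.ndarray, regions: RegionSet, seed: int, stack: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel features and expected in-band labels of the 72 QC sample points."""
    if stack is None:
        stack = pixel_features(image)
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for name in QC_REGIONS:
        pts = _sample_mask_points(regions.regions[name], QC_POINTS_PER_REGION, rng)
        feats.append(stack[pts[:, 0], pts[:, 1]])
        labels.append(np.full(len(pts), 1 if name.endswith("a") else 0))
    return np.vstack(feats), np.concatenate(labels)


def qc_row(
    image: np.ndarray,
    regions: RegionSet,
    rf_inside: RandomForestClassifier,
    seed: int,
    stack: np.ndarray | None = None,
) -> tuple[float, np.ndarray, dict[str, float]]:
    """QC feature row for the accept/reject forest.

    The row holds the pooled point accuracy, the per-tested-region accuracy
    (the band-core regions are diagnostic on their own: they must classify as
    in-band whatever the neuropil enrichment), and the per-region
    (area, mean intensity, intensity sd) statistics.
    """
    feats, expected = qc_point_features(image, regions, seed, stack)
    predicted = rf_inside.predict(feats)
    correct = (predicted == expected).reshape(len(QC_REGIONS), QC_POINTS_PER_REGION)
    per_region = {name: float(c.mean()) for name, c in zip(QC_REGIONS, correct)}
    acc = float(correct.mean())
    stats = region_stats(image, regions)
    row = np.concatenate(
        [[acc], [per_region[n] for n in QC_REGIONS]]
        + [list(stats[name]) for name in REGION_NAMES]
    )
    return acc, row, per_region


def qc_segmentation(
    image: np.ndarray,
    regions: RegionSet,
    rf_inside: RandomForestClassifier,
    rf_accept: RandomForestClassifier,
    seed: int = 0,
) -> QcResult:
    """Accept or reject a segmentation with the two-stage forest check."""
    for rf in (rf_inside, rf_accept):
        if not hasattr(rf, "estimators_"):
            raise ValueError("QC forests must be trained before use")
    acc, row, per_region = qc_row(image, regions, rf_inside, seed)
    accepted = bool(rf_accept.predict(row[None])[0])
    return QcResult(acc, region_stats(image, regions), accepted, per_region)


# ---------------------------------------------------------------------------
# Training of the QC forests on a synthetic cohort


def truth_localization(truth) -> LocalizationResult:
    """A LocalizationResult built from planted ground-truth points."""
    return LocalizationResult(
        ah_points=np.asarray(truth.ah_points, float),
        dg_points=np.asarray(truth.dg_points, float),
        energy=0.0,
        roi=(0, 0) + tuple(truth.ah_band.shape),
    )


def segment_from_localization(
    image: np.ndarray,
    loc: LocalizationResult,
    band_width: float = 8.0,
    margin_gap: float = 3.5,
) -> RegionSet:
    """select_areas + Otsu + partition in one call."""
    boxes = select_areas(loc)
    masks = {}
    for name, box in boxes.boxes.items():
        r0, c0, r1, c1 = clip_box(box, image.shape)
        masks[name] = otsu_segment(image[r0:r1, c0:c1])
    return partition_regions(boxes, masks, loc, image.shape, band_width, margin_gap)


def train_inside_forest(
    cohort, seed: int = 0, n_per_class: int = 200, n_estimators: int = 100
) -> RandomForestClassifier:
    """Pixel classifier (inside sp/sg band vs outside) from ground truth."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for item in cohort:
        stack = pixel_features(item.image)
        band = item.truth.band_mask
        for mask, lab in ((band, 1), (~band, 0)):
            pts = _sample_mask_points(mask, n_per_class, rng)
            X.append(stack[pts[:, 0], pts[:, 1]])
            y.append(np.full(len(pts), lab))
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(np.vstack(X), np.concatenate(y))
    return rf


def _shifted_localization(truth, rng: np.random.Generator, band_width: float) -> LocalizationResult:
    """A planted failure: control points shifted off the bands."""
    shift = rng.uniform(2.5, 4.0) * band_width
    angle = rng.uniform(0, 2 * np.pi)
    delta = shift * np.array([np.sin(angle), np.cos(angle)])
    loc = truth_localization(truth)
    return LocalizationResult(
        ah_points=loc.ah_points + delta,
        dg_points=loc.dg_points + delta,
        energy=0.0,
        roi=loc.roi,
    )


def train_accept_forest(
    cohort,
    rf_inside: RandomForestClassifier,
    seed: int = 0,
    band_width: float = 8.0,
    n_estimators: int = 100,
) -> RandomForestClassifier:
    """Accept/reject forest from correct and deliberately shifted segmentations."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for item in cohort:
        stack = pixel_features(item.image)
        try:
            good = segment_from_localization(item.image, truth_localization(item.truth), band_width)
            _, row, _ = qc_row(item.image, good, rf_inside, int(rng.integers(2**31)), stack)
            rows.append(row)
            labels.append(1)
        except SegmentationError:
            pass
        for _ in range(2):
            try:
                bad = segment_from_localization(
                    item.image, _shifted_localization(item.truth, rng, band_width), band_width
                )
                _, row, _ = qc_row(item.image, bad, rf_inside, int(rng.integers(2**31)), stack)
                rows.append(row)
                labels.append(0)
            except SegmentationError:
                pass
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(np.vstack(rows), np.array(labels))
    return rf


# ---------------------------------------------------------------------------
# Slice-retry / discard logic


DISCARD = "DISCARD"


def retry_order(levels: Sequence[int], default: int = DEFAULT_ATLAS_LEVEL) -> list[int]:
    """Default level first, then alternating -1/+1 outward toward the bounds."""
    return sorted(levels, key=lambda l: (abs(l - default), l > default))


@dataclass
class SeriesResult:
    regions: RegionSet | None
    atlas_level: int | None
    localization: LocalizationResult | None
    discarded: bool
    attempts: list[tuple[int, str]] = field(default_factory=list)


def process_series(
    series: Sequence[tuple[int, np.ndarray]],
    fit,
    rf_inside: RandomForestClassifier,
    rf_accept: RandomForestClassifier,
    seed: int = 0,
    band_width: float = 8.0,
) -> SeriesResult:
    """Try slices (default level first, then outward) until one passes QC.

    ``series`` is a list of ``(atlas_level, image)``; ``fit`` maps an image to
    a :class:`LocalizationResult` (localization is injected so the retry logic
    is testable in isolation).  Returns a discard result when every slice
    fails.
    """
    attempts: list[tuple[int, str]] = []
    by_level = dict(series)
    rng = np.random.default_rng(seed)
    for level in retry_order(list(by_level)):
        image = by_level[level]
        qc_seed = int(rng.integers(2**31))
        loc = fit(image)
        if not loc.ok:
            attempts.append((level, f"localization failure: {loc.reason}"))
            continue
        try:
            regions = segment_from_localization(image, loc, band_width)
        except SegmentationError as exc:
            attempts.append((level, f"segmentation failure: {exc}"))
            continue
        qc = qc_segmentation(image, regions, rf_inside, rf_accept, qc_seed)
        if qc.accepted:
            attempts.append((level, "accepted"))
            loc.atlas_level = level
            return SeriesResult(regions, level, loc, False, attempts)
        attempts.append((level, f"QC reject (point accuracy {qc.point_accuracy:.2f})"))
    return SeriesResult(None, None, None, True, attempts)
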