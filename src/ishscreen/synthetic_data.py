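"""Synthetic ISH-like hippocampus sections with known ground truth.

The generator emulates the appearance of colorimetric in situ hybridization
of a parasagittal mouse hippocampus: dark punctate signal densely packed in
the two cell-body bands (the stratum pyramidale of Ammon's horn and the
stratum granulosum of the dentate gyrus), with a controllable fraction of
puncta spilling into the adjacent neuropil, on a light noisy background.

Geometry
--------
Both cell-body bands are elliptic arcs.  The Ammon's-horn (AH) arc is an
upward dome traversed so that its positive normal side (see
:mod:`ishscreen.geometry`) points into the dome; the dentate-gyrus (DG) arc is
a smaller dome nested below it, traversed so that its positive normal points
up, toward the AH.  The neuropil margin of each structure therefore lies on
the positive-offset side, between the two bands — mimicking the stratum
radiatum / molecular layer where neuropil-enriched transcripts accumulate.

Signal model
------------
Puncta centers are sampled from a Poisson point process: density
``soma_density`` (puncta per 100 px^2) inside the bands and
``e * soma_density`` in the neuropil margin, where ``e`` is the planted
enrichment.  Each punctum is a dark stamp (flat core with a Gaussian
shoulder, hard cutoff at the core radius + 1.5 px) composited with a
pixelwise minimum, so overlapping puncta saturate instead of stacking.
Band puncta model packed somata (``puncta_radius``, default 1.5 px, which
renders a near-confluent band); neuropil puncta model fine transcript
granules — smaller (``neuropil_puncta_radius``, default 0.5 px) and fainter
(``neuropil_puncta_amplitude``, default 70 vs 170 intensity counts) than the
cell-body staining — so the margin darkens gradually over the whole
enrichment range instead of saturating a fraction of the way in.  The margin starts a small
guard gap beyond the band edge so that, at ``e = 0``, no band punctum bleeds a
single intensity count into the margin.

Puncta counts are drawn through the Poisson quantile function evaluated at a
fixed uniform deviate, and positions are drawn from a per-region stream, so
that for a fixed seed the realization at a lower enrichment is a strict
subset of the realization at a higher one.  This makes the mean margin
intensity monotonically non-increasing in ``e`` — a property the test suite
relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import poisson

from .geometry import Arc, pixel_grid, polyline_frame, resample_arclength

# Canonical region names, in canonical order.
REGION_NAMES = (
    "CA1a", "CA1b", "CA1c", "CA1d",
    "CA3a", "CA3b", "CA3c", "CA3d",
    "DGa", "DGb", "DGc", "DGd", "DGe",
)

N_AH_POINTS = 8
N_DG_POINTS = 7

# Stamp shape: flat dark core with a Gaussian shoulder and a hard cutoff.
_EDGE_SIGMA = 0.5
_EDGE_EXTENT = 1.5  # shoulder length, px; stamp cutoff = puncta_radius + this

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class SectionParams:
    """Parameters of one synthetic section.

    ``neuropil_enrichment`` is the ratio of neuropil to band puncta density
    (dimensionless, >= 0).  ``soma_density`` is in puncta per 100 px^2; the
    default renders a near-confluent cell-body band, matching the solid
    appearance of the pyramidal/granular layers in real sections.
    """

    image_size: tuple[int, int] = (192, 256)
    ah_curve: Arc = field(
        default_factory=lambda: Arc((108.0, 128.0), (70.0, 95.0), (340 * _DEG, 200 * _DEG))
    )
    dg_curve: Arc = field(
        default_factory=lambda: Arc((116.0, 128.0), (30.0, 46.0), (200 * _DEG, 340 * _DEG))
    )
    band_width: float = 8.0
    soma_density: float = 30.0
    neuropil_enrichment: float = 0.5
    puncta_radius: float = 1.5
    neuropil_puncta_radius: float = 0.5
    puncta_amplitude: float = 170.0
    neuropil_puncta_amplitude: float = 70.0
    background_level: float = 230.0
    noise_sd: float = 6.0
    margin_gap: float = 3.5
    margin_width: float = 16.0  # 2x band_width by default
    seed: int = 0

    def validate(self) -> None:
        if self.neuropil_enrichment < 0:
            raise ValueError("neuropil_enrichment must be >= 0")
        if self.soma_density <= 0:
            raise ValueError("soma_density must be > 0")
        if self.band_width <= 0 or self.puncta_radius <= 0:
            raise ValueError("band_width and puncta_radius must be > 0")
        h, w = self.image_size
        reach = self.band_width / 2 + self.margin_gap + self.margin_width
        for arc in (self.ah_curve, self.dg_curve):
            poly = arc.polyline(200)
            if (
                poly[:, 0].min() < reach
                or poly[:, 1].min() < reach
                or poly[:, 0].max() > h - reach
                or poly[:, 1].max() > w - reach
            ):
                raise ValueError("curve (with its band and margin) does not fit inside the image")
        from .geometry import min_curve_distance

        if min_curve_distance(self.ah_curve.polyline(300), self.dg_curve.polyline(300)) <= self.band_width:
            raise ValueError("AH and DG curves intersect or are closer than one band width")


@dataclass
class GroundTruth:
    """Planted geometry and signal of a synthetic section."""

    ah_points: np.ndarray  # (8, 2) control points on the AH band midline
    dg_points: np.ndarray  # (7, 2) control points on the DG band midline
    region_masks: dict[str, np.ndarray]  # the 13 true region masks
    enrichment: float
    ah_band: np.ndarray = None
    dg_band: np.ndarray = None
    ah_margin: np.ndarray = None
    dg_margin: np.ndarray = None
    band_puncta: np.ndarray = None  # (n, 2) planted centers inside bands
    margin_puncta: np.ndarray = None  # (m, 2) planted centers in the margin
    band_area: float = 0.0
    margin_area: float = 0.0
    params: SectionParams = None

    @property
    def band_mask(self) -> np.ndarray:
        return self.ah_band | self.dg_band

    @property
    def margin_mask(self) -> np.ndarray:
        return self.ah_margin | self.dg_margin

    @property
    def points(self) -> np.ndarray:
        return np.vstack([self.ah_points, self.dg_points])

    def planted_density_ratio(self) -> float:
        """Observed neuropil/band planted puncta density ratio."""
        band = len(self.band_puncta) / self.band_area
        if band == 0:
            return np.nan
        return (len(self.margin_puncta) / self.margin_area) / band


def _sample_poisson_points(
    mask_idx: np.ndarray, n_cols: int, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson(mu) many puncta uniformly over the pixels in ``mask_idx``.

    The count comes from the Poisson quantile at a single uniform draw and the
    positions from a fixed-width draw per punctum, so for a fixed generator
    state the realization at a smaller ``mu`` is a prefix of the realization
    at a larger one.
    """
    u0 = rng.uniform()
    n = int(poisson.ppf(u0, mu)) if mu > 0 else 0
    if n == 0 or len(mask_idx) == 0:
        return np.empty((0, 2))
    u = rng.uniform(size=(n, 3))
    pix = mask_idx[np.minimum((u[:, 0] * len(mask_idx)).astype(int), len(mask_idx) - 1)]
    rows = pix // n_cols + (u[:, 1] - 0.5)
    cols = pix % n_cols + (u[:, 2] - 0.5)
    return np.column_stack([rows, cols])


def _render_puncta(
    canvas: np.ndarray, centers: np.ndarray, radius: float, amplitude: float
) -> None:
    """Min-composite dark stamps onto ``canvas`` (in place)."""
    h, w = canvas.shape
    cut = radius + _EDGE_EXTENT
    iw = int(np.ceil(cut))
    for cr, cc in centers:
        r0 = max(int(np.floor(cr)) - iw, 0)
        r1 = min(int(np.ceil(cr)) + iw + 1, h)
        c0 = max(int(np.floor(cc)) - iw, 0)
        c1 = min(int(np.ceil(cc)) + iw + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1)[:, None] - cr
        ccv = np.arange(c0, c1)[None, :] - cc
        dist = np.sqrt(rr * rr + ccv * ccv)
        shoulder = np.clip(dist - radius, 0.0, None)
        dip = amplitude * np.exp(-(shoulder**2) / (2 * _EDGE_SIGMA**2))
        dip[dist > cut] = 0.0
        np.maximum(canvas[r0:r1, c0:c1], dip, out=canvas[r0:r1, c0:c1])


def _region_masks_from_frames(
    shape: tuple[int, int],
    ah_frame: tuple[np.ndarray, np.ndarray],
    ah_len: float,
    dg_frame: tuple[np.ndarray, np.ndarray],
    dg_len: float,
    band_width: float,
    margin_gap: float,
) -> dict[str, np.ndarray]:
    """True 13-region partition from the planted geometry.

    CA1 occupies the first 35% of the AH arc, CA3 the last 35%; the DG regions
    occupy the medial (first) half of the DG arc.  Within each area: ``a`` is
    the central half of the band along its axis, ``b``/``c`` the two lateral
    quarters, and ``d`` (plus ``e`` for the DG) a one-band-width neuropil
    strip starting one guard gap beyond the band edge.
    """
    h = band_width / 2.0
    lo, hi = h + margin_gap, h + margin_gap + band_width
    label = np.zeros(shape, dtype=np.uint8)

    def paint(code, s, d, s0, s1, d0, d1, absd=False):
        off = (np.abs(d) >= d0) & (np.abs(d) <= d1) if absd else (d > d0) & (d <= d1)
        sel = (s >= s0) & (s <= s1) & off & (label.reshape(-1) == 0)
        label.reshape(-1)[sel] = code

    specs = []
    for s0, s1, frame, base in (
        (0.0, 0.35 * ah_len, ah_frame, "CA1"),
        (0.65 * ah_len, ah_len, ah_frame, "CA3"),
        (0.0, 0.5 * dg_len, dg_frame, "DG"),
    ):
        q = (s1 - s0) / 4.0
        specs += [
            (base + "a", frame, s0 + q, s1 - q, 0.0, h, True),
            (base + "b", frame, s0, s0 + q, 0.0, h, True),
            (base + "c", frame, s1 - q, s1, 0.0, h, True),
            (base + "d", frame, s0, s1, lo, hi, False),
        ]
        if base == "DG":
            specs.append(("DGe", frame, s0, s1, -hi, -lo, False))

    order = {name: i + 1 for i, name in enumerate(REGION_NAMES)}
    for name, frame, s0, s1, d0, d1, absd in sorted(specs, key=lambda t: order[t[0]]):
        s, d = frame
        if name == "DGe":
            paint(order[name], s, -d, s0, s1, lo, hi, False)
        else:
            paint(order[name], s, d, s0, s1, d0, d1, absd)
    return {name: label == order[name] for name in REGION_NAMES}


def generate_section(params: SectionParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic section; deterministic given ``params.seed``.

    Returns the 8-bit image and the ground truth (control points, 13 region
    masks, band/margin masks, planted puncta centers and areas).
    """
    params.validate()
    shape = params.image_size
    h = params.band_width / 2.0
    m0 = h + params.margin_gap
    m1 = m0 + params.margin_width

    ah_poly = params.ah_curve.polyline(600)
    dg_poly = params.dg_curve.polyline(600)
    ah_len = float(np.linalg.norm(np.diff(ah_poly, axis=0), axis=1).sum())
    dg_len = float(np.linalg.norm(np.diff(dg_poly, axis=0), axis=1).sum())

    grid = pixel_grid(shape)
    ah_s, ah_d = polyline_frame(ah_poly, grid)
    dg_s, dg_d = polyline_frame(dg_poly, grid)

    def as_mask(flat):
        return flat.reshape(shape)

    ah_band = as_mask(np.abs(ah_d) <= h)
    dg_band = as_mask(np.abs(dg_d) <= h)
    ah_margin = as_mask((ah_d > m0) & (ah_d <= m1)) & ~dg_band
    dg_margin = as_mask((dg_d > m0) & (dg_d <= m1)) & ~ah_band & ~ah_margin

    region_masks = _region_masks_from_frames(
        shape, (ah_s, ah_d), ah_len, (dg_s, dg_d), dg_len,
        params.band_width, params.margin_gap,
    )

    ss = np.random.SeedSequence(params.seed)
    rng_ah_band, rng_dg_band, rng_ah_m, rng_dg_m, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    ncols = shape[1]
    rho = params.soma_density / 100.0
    e = params.neuropil_enrichment
    idx_ah_band = np.flatnonzero(ah_band.reshape(-1))
    idx_dg_band = np.flatnonzero(dg_band.reshape(-1))
    idx_ah_m = np.flatnonzero(ah_margin.reshape(-1))
    idx_dg_m = np.flatnonzero(dg_margin.reshape(-1))

    band_puncta = np.vstack([
        _sample_poisson_points(idx_ah_band, ncols, rho * len(idx_ah_band), rng_ah_band),
        _sample_poisson_points(idx_dg_band, ncols, rho * len(idx_dg_band), rng_dg_band),
    ])
    margin_puncta = np.vstack([
        _sample_poisson_points(idx_ah_m, ncols, e * rho * len(idx_ah_m), rng_ah_m),
        _sample_poisson_points(idx_dg_m, ncols, e * rho * len(idx_dg_m), rng_dg_m),
    ])

    dip = np.zeros(shape, dtype=float)
    _render_puncta(dip, band_puncta, params.puncta_radius, params.puncta_amplitude)
    _render_puncta(
        dip, margin_puncta, params.neuropil_puncta_radius, params.neuropil_puncta_amplitude
    )

    img = np.full(shape, params.background_level, dtype=float) - dip
    if params.noise_sd > 0:
        img += params.noise_sd * rng_noise.standard_normal(shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        ah_points=resample_arclength(ah_poly, N_AH_POINTS),
        dg_points=resample_arclength(dg_poly, N_DG_POINTS),
        region_masks=region_masks,
        enrichment=e,
        ah_band=ah_band,
        dg_band=dg_band,
        ah_margin=ah_margin,
        dg_margin=dg_margin,
        band_puncta=band_puncta,
        margin_puncta=margin_puncta,
        band_area=float(len(idx_ah_band) + len(idx_dg_band)),
        margin_area=float(len(idx_ah_m) + len(idx_dg_m)),
        params=params,
    )
    return image, truth


def jitter_params(
    base: SectionParams, rng: np.random.Generator, *, enrichment: float | None = None,
    seed: int | None = None,
) -> SectionParams:
    """Perturb the section geometry the way neighbouring atlas slices differ."""

    def jarc(arc: Arc) -> Arc:
        return Arc(
            (arc.center[0] + rng.uniform(-4, 4), arc.center[1] + rng.uniform(-4, 4)),
            (arc.radii[0] * rng.uniform(0.94, 1.06), arc.radii[1] * rng.uniform(0.94, 1.06)),
            (arc.span[0] + rng.uniform(-0.05, 0.05), arc.span[1] + rng.uniform(-0.05, 0.05)),
        )

    kwargs = dict(ah_curve=jarc(base.ah_curve), dg_curve=jarc(base.dg_curve))
    if enrichment is not None:
        kwargs["neuropil_enrichment"] = float(enrichment)
    if seed is not None:
        kwargs["seed"] = int(seed)
    return replace(base, **kwargs)


@dataclass
class CohortItem:
    gene_id: str
    image: np.ndarray
    truth: GroundTruth
    label: str  # "positive" | "negative"


def generate_cohort(
    n_pos: int,
    n_neg: int,
    e_pos: tuple[float, float] = (1.2, 1.6),
    e_neg: tuple[float, float] = (0.0, 0.3),
    seed: int = 0,
    base: SectionParams | None = None,
) -> list[CohortItem]:
    """Labeled training cohort with disjoint planted enrichment ranges.

    Defaults mirror the 3-positive / 17-negative, 20-gene training design:
    positives carry a clear planted neuropil enrichment, negatives little or
    none.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n_pos > 0 and n_neg > 0 and min(e_pos) <= max(e_neg):
        raise ValueError("enrichment ranges must be disjoint with e_pos > e_neg")
    base = base or SectionParams()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    items: list[CohortItem] = []
    specs = [("pos", i, e_pos) for i in range(n_pos)] + [
        ("neg", i, e_neg) for i in range(n_neg)
    ]
    for kind, i, erange in specs:
        e = rng.uniform(*erange)
        sec_seed = int(rng.integers(0, 2**31 - 1))
        params = jitter_params(base, rng, enrichment=e, seed=sec_seed)
        image, truth = generate_section(params)
        label = "positive" if kind == "pos" else "negative"
        items.append(CohortItem(f"{kind}{i:03d}", image, truth, label))
    return items


# ---------------------------------------------------------------------------
# On-disk format: PNG image + JSON sidecar + TSV cohort manifest.


def save_section(path: str | Path, image: np.ndarray, truth: GroundTruth, label: str = "") -> None:
    path = Path(path)
    Image.fromarray(image, mode="L").save(path)
    sidecar = {
        "ah_points": truth.ah_points.tolist(),
        "dg_points": truth.dg_points.tolist(),
        "enrichment": truth.enrichment,
        "label": label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def save_cohort(outdir: str | Path, items: list[CohortItem]) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for item in items:
        fname = f"{item.gene_id}.png"
        save_section(outdir / fname, item.image, item.truth, item.label)
        rows.append((fname, item.label, item.truth.enrichment))
    manifest = pd.DataFrame(rows, columns=["image", "label", "enrichment"])
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
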