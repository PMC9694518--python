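"""Synthetic FASGA-like cross-section phantoms with ground truth.

A phantom emulates the concentric architecture of a grass internode: an
epidermis ring, a dark sclerenchyma-rich rind with embedded bundles, a
light rind band, and a medullary pith holding scattered vascular bundles,
a peripheral poorly-lignified (blue) band, a lignified (red) core, and an
optional central hole. Each tissue draws per-pixel HSV values from a
narrow distribution centered inside the S/V class the default catalogue
assigns to it, so a noise-free phantom is exactly recoverable by the
segmentation pipeline.

The rendered image is written at HALF intensity: real slide-scanner
acquisitions are dim, which is what the pipeline's ×2 contrast step
compensates; halving the ideal RGB and letting the pipeline double it
back reproduces the intended HSV values up to quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .io import DEFAULT_PIXEL_SIZE_UM, RgbImage
from .pixel_classes import RangeSet
from .preprocess import hsv_planes_to_rgb
from .regions import RegionMaskSet, RegionParams
from .tissues import TissueCatalogue, TissueLabelMap


class PhantomSpecError(ValueError):
    """Raised for infeasible phantom geometry."""


@dataclass(frozen=True)
class TissueColor:
    """HSV distribution of one phantom tissue.

    Draws are normal around (h, s, v) with ``jitter_sd``, clipped into
    the per-channel windows, which sit inside the S/V class the tissue
    maps to with margin for 8-bit quantization.
    """

    h: float
    s: float
    v: float
    h_clip: tuple[float, float]
    s_clip: tuple[float, float]
    v_clip: tuple[float, float]
    jitter_sd: float = 0.008


# Tissue placements: ET1 epidermis (class 3), DRT1 dark-rind ground
# (class 7, low-S: carries the density signal), DRT8 rind-bundle
# sclerenchyma (class 14), LRT3 light rind (class 12), MT2a blue pith
# band (class 11, blue hue), MT1a red pith core (class 14, red hue),
# BT5 bundle body (class 8, low-S), BT1 sclerenchyma caps (class 13).
DEFAULT_TISSUE_HSV: dict[str, TissueColor] = {
    "background": TissueColor(0.0, 0.004, 0.995, (0.0, 1.0), (0.0, 0.015), (0.985, 1.0)),
    "ET1": TissueColor(0.08, 0.90, 0.20, (0.02, 0.15), (0.84, 0.98), (0.05, 0.40)),
    "DRT1": TissueColor(0.08, 0.155, 0.535, (0.0, 0.2), (0.075, 0.235), (0.44, 0.63)),
    "DRT8": TissueColor(0.02, 0.89, 0.795, (0.0, 0.1), (0.81, 0.98), (0.68, 0.91)),
    "LRT3": TissueColor(0.60, 0.52, 0.975, (0.5, 0.7), (0.29, 0.75), (0.956, 0.994)),
    "MT2a": TissueColor(0.71, 0.52, 0.795, (0.53, 0.89), (0.29, 0.75), (0.68, 0.91)),
    "MT1a": TissueColor(0.0475, 0.89, 0.795, (0.015, 0.08), (0.81, 0.98), (0.68, 0.91)),
    "BT5": TissueColor(0.13, 0.155, 0.795, (0.05, 0.25), (0.075, 0.235), (0.68, 0.91)),
    "BT1": TissueColor(0.01, 0.89, 0.535, (0.0, 0.085), (0.81, 0.98), (0.44, 0.63)),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of a synthetic cross section (pixels)."""

    image_size: int = 1024
    section_radius: int = 480
    epidermis_width: int = 6
    dark_rind_width: int = 40
    light_rind_width: int = 10
    n_rind_bundles: int = 12
    n_pith_bundles: int = 8
    #: Semi-major axis bounds (px). At 5.17 µm/px these correspond to
    #: bundles 0.3-0.4 mm across, the scale of maize pith bundles; the
    #: lower bound also keeps every bundle wider than the
    #: region-detection density window, without which a planted bundle
    #: would be undetectable by construction. Minor axis: 75-100% of it.
    bundle_radius_range: tuple[int, int] = (25, 40)
    rind_bundle_radius: int = 7
    pith_blue_band_width: int = 60
    hole_radius: int = 0
    noise_sd: float = 0.0
    seed: int = 0
    #: Separate seed for pith-bundle placement; None reuses ``seed``.
    #: Lets two phantoms share every ring, rind bundle and color draw
    #: while differing only in where the pith bundles sit.
    pith_bundle_seed: int | None = None
    tissue_hsv: dict[str, TissueColor] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_HSV)
    )
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        rings = self.epidermis_width + self.dark_rind_width + self.light_rind_width
        if rings + self.pith_blue_band_width >= self.section_radius:
            raise PhantomSpecError("ring widths exceed the section radius")
        if 2 * self.section_radius >= self.image_size:
            raise PhantomSpecError("section does not fit in the image")
        pith_outer = self.section_radius - rings
        if self.hole_radius and self.hole_radius >= pith_outer - self.pith_blue_band_width:
            raise PhantomSpecError("central hole swallows the pith core")
        lo, hi = self.bundle_radius_range
        if not 0 < lo <= hi:
            raise PhantomSpecError("invalid bundle radius range")
        if 2 * self.rind_bundle_radius + 6 > self.dark_rind_width:
            raise PhantomSpecError("rind bundles do not fit inside the dark rind band")


def _ellipse_mask(shape, cy, cx, a, b, theta):
    """Boolean ellipse mask plus the normalized axis/radius fields."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    w = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    r2 = u * u + w * w
    return r2 <= 1.0, np.broadcast_to(u, r2.shape), r2


def generate_phantom(
    spec: PhantomSpec | None = None,
    catalogue: TissueCatalogue | None = None,
) -> tuple[RgbImage, TissueLabelMap, RegionMaskSet]:
    """Render a phantom image plus its ground-truth tissue and region maps.

    Fully reproducible from ``spec.seed``; ground truth is recorded
    before quantization and noise.
    """
    spec = spec or PhantomSpec()
    catalogue = catalogue or TissueCatalogue.default()
    rind_ss, pith_ss, color_ss = np.random.SeedSequence(spec.seed).spawn(3)
    if spec.pith_bundle_seed is not None:
        pith_ss = np.random.SeedSequence(spec.pith_bundle_seed)
    rng_rind = np.random.default_rng(rind_ss)
    rng_pith = np.random.default_rng(pith_ss)
    rng_color = np.random.default_rng(color_ss)
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.ogrid[:n, :n]
    r = np.hypot(yy - c, xx - c)

    r_epi_in = spec.section_radius - spec.epidermis_width
    r_dark_in = r_epi_in - spec.dark_rind_width
    r_pith_out = r_dark_in - spec.light_rind_width
    r_core = r_pith_out - spec.pith_blue_band_width

    section = r <= spec.section_radius
    if spec.hole_radius:
        section &= r >= spec.hole_radius
    epidermis = section & (r > r_epi_in)
    dark_ring = section & (r > r_dark_in) & (r <= r_epi_in)
    light_ring = section & (r > r_pith_out) & (r <= r_dark_in)
    pith_all = section & (r <= r_pith_out)
    blue_band = pith_all & (r > r_core)
    red_core = pith_all & (r <= r_core)

    # Tissue layout as small integer codes (fast to assign and count).
    code_names = [
        "background", "ET1", "DRT1", "LRT3", "MT2a", "MT1a", "DRT8", "BT5", "BT1"
    ]
    code = {name: k for k, name in enumerate(code_names)}
    layout = np.zeros((n, n), dtype=np.uint8)
    layout[epidermis] = code["ET1"]
    layout[dark_ring] = code["DRT1"]
    layout[light_ring] = code["LRT3"]
    layout[blue_band] = code["MT2a"]
    layout[red_core] = code["MT1a"]

    # Rind bundles: sclerenchyma blobs embedded in the dark rind band.
    r_mid = (r_epi_in + r_dark_in) / 2.0
    for k in range(spec.n_rind_bundles):
        ang = 2 * np.pi * (k + rng_rind.uniform(-0.2, 0.2)) / max(spec.n_rind_bundles, 1)
        cy = c + r_mid * np.sin(ang)
        cx = c + r_mid * np.cos(ang)
        a = spec.rind_bundle_radius
        b = max(2, int(round(a * rng_rind.uniform(0.7, 1.0))))
        blob, _, _ = _ellipse_mask((n, n), cy, cx, a, b, rng_rind.uniform(0, np.pi))
        blob &= dark_ring
        layout[blob] = code["DRT8"]

    # Pith bundles: rejection-sampled ellipses, kept clear of each other,
    # of the light rind and of the hole so density blobs never merge.
    sep_margin = 24
    lo, hi = spec.bundle_radius_range
    bundles_truth = np.zeros((n, n), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(placed) < spec.n_pith_bundles:
        tries += 1
        if tries > 20000:
            raise PhantomSpecError(
                f"could not place {spec.n_pith_bundles} bundles in the pith"
            )
        a = rng_pith.uniform(lo, hi)
        b = rng_pith.uniform(0.75 * a, a)
        max_r = r_pith_out - a - sep_margin
        min_r = (spec.hole_radius + a + sep_margin) if spec.hole_radius else 0.0
        if max_r <= min_r:
            raise PhantomSpecError("no room for pith bundles")
        rad = np.sqrt(rng_pith.uniform((min_r / max_r) ** 2, 1.0)) * max_r
        ang = rng_pith.uniform(0, 2 * np.pi)
        cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
        if any(
            np.hypot(cy - py, cx - px) < a + pa + sep_margin for py, px, pa in placed
        ):
            continue
        blob, u, r2 = _ellipse_mask((n, n), cy, cx, a, b, rng_pith.uniform(0, np.pi))
        # Sclerenchyma caps sit at the two poles of the bundle, inset
        # behind a thin low-S rim (the parenchyma sheath surrounding a
        # real bundle), so the bundle's low-S body stays one closed ring.
        caps = blob & (np.abs(u) >= 0.50) & (r2 <= 0.60)
        layout[blob] = code["BT5"]
        layout[caps] = code["BT1"]
        bundles_truth |= blob
        placed.append((cy, cx, a))

    # Ground-truth label and region maps (before noise, by construction).
    id_lut = np.zeros(len(code_names), dtype=np.uint8)
    for name, k in code.items():
        if name != "background":
            id_lut[k] = catalogue.id_of(name)
    labels = id_lut[layout]
    truth_map = TissueLabelMap(labels=labels, catalogue=catalogue, ranges=RangeSet())

    dark_region = (epidermis | dark_ring) & ~bundles_truth
    region_truth = RegionMaskSet(
        section=section,
        dark_rind=dark_region,
        bundles=bundles_truth,
        light_rind=light_ring & ~bundles_truth,
        pith=pith_all & ~bundles_truth,
        params=RegionParams(),
    )
    region_truth.validate()

    # Render: per-tissue HSV draws -> ideal RGB -> half intensity + noise.
    h = np.zeros((n, n))
    s = np.zeros((n, n))
    v = np.zeros((n, n))
    for k in np.unique(layout):
        tc = spec.tissue_hsv[code_names[int(k)]]
        where = layout == k
        m = int(where.sum())
        for plane, mean, clip in (
            (h, tc.h, tc.h_clip),
            (s, tc.s, tc.s_clip),
            (v, tc.v, tc.v_clip),
        ):
            draws = rng_color.normal(mean, tc.jitter_sd, size=m)
            plane[where] = np.clip(draws, clip[0], clip[1])

    rgb_ideal = hsv_planes_to_rgb(h, s, v)
    half = rgb_ideal / 2.0
    if spec.noise_sd > 0:
        half = half + rng_color.normal(0.0, spec.noise_sd, size=half.shape)
    pixels = np.clip(np.rint(half), 0, 255).astype(np.uint8)
    image = RgbImage(pixels, pixel_size_um=spec.pixel_size_um)
    return image, truth_map, region_truth


def scaled_spec(image_size: int, **overrides) -> PhantomSpec:
    """A PhantomSpec with geometry scaled from the 1024-pixel defaults."""
    f = image_size / 1024.0
    base = PhantomSpec()
    params = dict(
        image_size=image_size,
        section_radius=int(base.section_radius * f),
        epidermis_width=max(3, int(base.epidermis_width * f)),
        dark_rind_width=max(12, int(base.dark_rind_width * f)),
        light_rind_width=max(8, int(base.light_rind_width * f)),
        pith_blue_band_width=max(16, int(base.pith_blue_band_width * f)),
        bundle_radius_range=(
            max(12, int(base.bundle_radius_range[0] * f)),
            max(16, int(base.bundle_radius_range[1] * f)),
        ),
        rind_bundle_radius=max(3, int(base.rind_bundle_radius * f)),
        n_rind_bundles=max(4, int(base.n_rind_bundles * f)),
        n_pith_bundles=max(3, int(base.n_pith_bundles * f)),
    )
    params.update(overrides)
    return PhantomSpec(**params)


def scaled_region_params(image_size: int) -> RegionParams:
    """Region-mask parameters scaled from the 1024-pixel defaults.

    The default morphology parameters are calibrated to full-size scans;
    phantoms rendered at a smaller grid need the density radius, band
    width and area bounds scaled with them.
    """
    f = image_size / 1024.0
    base = RegionParams()
    return RegionParams(
        density_radius=max(4, round(base.density_radius * f)),
        density_threshold=base.density_threshold,
        min_bundle_area=max(10, round(base.min_bundle_area * f * f)),
        max_bundle_area=max(500, round(base.max_bundle_area * f * f)),
        rind_band_width=max(8, round(base.rind_band_width * f)),
        section_close_radius=base.section_close_radius,
        min_hole_area=max(50, round(base.min_hole_area * f * f)),
    )


def boundary_exclusion(labels: np.ndarray, band: int = 3) -> np.ndarray:
    """Mask of pixels within ``band`` pixels of any label boundary."""
    footprint = morphology.disk(band)
    lo = ndimage.minimum_filter(labels, footprint=footprint)
    hi = ndimage.maximum_filter(labels, footprint=footprint)
    return lo != hi


def label_agreement(
    truth: np.ndarray, predicted: np.ndarray, band: int = 3
) -> float:
    """Fraction of pixels agreeing with truth, outside boundary bands."""
    keep = ~boundary_exclusion(truth, band)
    if not keep.any():
        return float("nan")
    return float(np.mean(truth[keep] == predicted[keep]))
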