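"""Automatic derivation of the spatial region masks of a cross section.

The low-saturation pixel selection (S in [0.05, 0.26)) is spatially
structured: it is dense inside the dark rind band and inside vascular
bundles, and sparse in the pith and the light rind. Measuring its local
density with a circular mean filter and thresholding therefore separates
(1) a dense structure hugging the section's outer boundary — the dark
rind, which by convention also absorbs the epidermis layers outside it
and any bundle fused to it, (2) dense interior blobs of plausible bundle
size — the vascular bundles, and (3) the remainder, which is split into a
light-rind band adjacent to the dark rind and the medullary pith.

All parameters are fixed defaults shared by every image; there is no
per-image tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .pixel_classes import BACKGROUND_CLASS, NEAR_WHITE_CLASS, PixelClassMap

logger = logging.getLogger(__name__)


class NoSectionError(ValueError):
    """Raised when an image contains no detectable section foreground."""


@dataclass(frozen=True)
class RegionParams:
    """Morphology parameters of the region-mask derivation.

    density_radius : px — radius of the circular mean filter measuring
        local low-S density (default 15, ≈ 78 µm at 5.17 µm/px).
    density_threshold : fraction — minimum low-S density of "dense"
        structure (default 0.5).
    min_bundle_area, max_bundle_area : px — admissible bundle blob areas
        at 5.17 µm/px (≈ 1.3e3–5.3e5 µm²).
    rind_band_width : px — width of the outer boundary band used for
        rind adjacency, and of the light-rind band kept inside the rind.
    section_close_radius : px — closing radius when building the section.
    min_hole_area : px — section holes at least this large are kept open
        (true biological holes); smaller ones are filled.
    """

    density_radius: int = 15
    density_threshold: float = 0.5
    min_bundle_area: int = 50
    max_bundle_area: int = 20000
    rind_band_width: int = 10
    section_close_radius: int = 2
    min_hole_area: int = 500


@dataclass
class RegionMaskSet:
    """Mutually exclusive region masks partitioning the section."""

    section: np.ndarray
    dark_rind: np.ndarray
    bundles: np.ndarray
    light_rind: np.ndarray
    pith: np.ndarray
    params: RegionParams = field(default_factory=RegionParams)

    def validate(self) -> None:
        parts = [self.dark_rind, self.bundles, self.light_rind, self.pith]
        total = np.zeros_like(self.section, dtype=np.int16)
        for p in parts:
            total += p.astype(np.int16)
        if total.max(initial=0) > 1:
            raise ValueError("region masks overlap")
        if not np.array_equal(total.astype(bool), self.section):
            raise ValueError("region masks do not partition the section")

    @property
    def shape(self) -> tuple[int, int]:
        return self.section.shape


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def build_section_mask(
    class_map: PixelClassMap, params: RegionParams | None = None, image_name: str = "image"
) -> np.ndarray:
    """Binary mask of the biological section.

    Foreground is every pixel that is neither the background class nor the
    near-white class (the slide background is nearly white: saturation
    below every range with value at the top of the scale). The foreground
    is closed, the largest connected component kept, and holes below
    ``min_hole_area`` filled; larger interior holes are genuine biological
    holes and stay open.
    """
    params = params or RegionParams()
    foreground = ~np.isin(class_map.labels, [BACKGROUND_CLASS, NEAR_WHITE_CLASS])
    if not foreground.any():
        raise NoSectionError(f"no section detected in {image_name}")
    closed = morphology.closing(
        foreground, footprint=morphology.disk(params.section_close_radius)
    )
    section = _largest_component(closed)
    if not section.any():
        raise NoSectionError(f"no section detected in {image_name}")
    return morphology.remove_small_holes(section, max_size=params.min_hole_area)


def low_s_mask(class_map: PixelClassMap, section: np.ndarray) -> np.ndarray:
    """Pixels whose S value lies in the first S range, inside the section."""
    from .pixel_classes import s_bin_family

    return np.isin(class_map.labels, sorted(s_bin_family(1))) & section


def low_s_density(
    class_map: PixelClassMap, section: np.ndarray, params: RegionParams | None = None
) -> np.ndarray:
    """Local density of the low-S selection (S range 1) inside the section."""
    params = params or RegionParams()
    low_s = low_s_mask(class_map, section)
    disk = morphology.disk(params.density_radius).astype(np.float64)
    disk /= disk.sum()
    return ndimage.correlate(low_s.astype(np.float64), disk, mode="constant", cval=0.0)


def build_region_masks(
    class_map: PixelClassMap,
    section: np.ndarray,
    params: RegionParams | None = None,
) -> RegionMaskSet:
    """Partition the section into dark rind, bundles, light rind and pith."""
    params = params or RegionParams()
    if not section.any():
        raise NoSectionError("empty section mask")

    density = low_s_density(class_map, section, params)
    dense = (density >= params.density_threshold) & section

    # Outer boundary band of the section proper: holes are filled first so
    # the rim of a biological hole never counts as "outer boundary".
    filled = ndimage.binary_fill_holes(section)
    outer_band = (
        filled
        & ~morphology.erosion(filled, footprint=morphology.disk(params.rind_band_width))
        & section
    )

    # Dark rind: dense components adjacent to the outer boundary, plus the
    # non-dense shell outside them (epidermis layers) that touches the
    # boundary band. A shell component is absorbed only if it stays close
    # to the outer boundary — otherwise a local breach of the dense ring
    # would pour the whole interior into the rind.
    dense_labels, n_dense = ndimage.label(dense)
    touching = np.unique(dense_labels[outer_band])
    touching = touching[touching > 0]
    dark_rind = np.isin(dense_labels, touching)
    if not dark_rind.any():
        logger.warning("dark rind empty: no dense structure touches the outer boundary")
    else:
        depth = ndimage.distance_transform_edt(filled)
        shell_labels, n_shell = ndimage.label(section & ~dense)
        shell_touch = np.unique(shell_labels[outer_band])
        shell_touch = shell_touch[shell_touch > 0]
        if len(shell_touch):
            max_depth = ndimage.labeled_comprehension(
                depth, shell_labels, shell_touch, np.max, float, 0.0
            )
            shallow = shell_touch[max_depth <= 2.0 * params.rind_band_width]
            dark_rind |= np.isin(shell_labels, shallow)
        dark_rind = morphology.closing(dark_rind, footprint=morphology.disk(2))
        dark_rind = morphology.remove_small_holes(
            dark_rind, max_size=params.max_bundle_area
        )
        dark_rind &= section

    # Bundles: dense interior blobs mark bundle cores; each core is grown
    # to its full connected component of the (closed) low-S selection so
    # the mask covers the whole bundle, not just the part where the
    # density window fits, then hole-filled — high-S sclerenchyma islands
    # inside a bundle belong to it. Blobs fused to the dark rind are
    # absorbed into it (rind-embedded bundle sclerenchyma); components
    # outside the admissible area range are returned to the pith pathway.
    interior_dense = dense & ~dark_rind
    bundles = np.zeros_like(section, dtype=bool)
    if interior_dense.any():
        low_s = low_s_mask(class_map, section) & ~dark_rind
        low_s = morphology.closing(low_s, footprint=morphology.disk(2)) & section
        cc_labels, _ = ndimage.label(low_s)
        seeded = np.unique(cc_labels[interior_dense & (cc_labels > 0)])
        grown = np.isin(cc_labels, seeded) | interior_dense
        grown = morphology.remove_small_holes(grown, max_size=params.max_bundle_area)
        grown &= section
        blob_labels, n_blobs = ndimage.label(grown)
        rind_border = morphology.dilation(dark_rind, footprint=morphology.disk(1))
        for lbl in range(1, n_blobs + 1):
            blob = blob_labels == lbl
            if (blob & rind_border).any():
                dark_rind |= blob
                continue
            area = int(blob.sum())
            if params.min_bundle_area <= area <= params.max_bundle_area:
                bundles |= blob
        bundles &= section & ~dark_rind

    # Remainder: pith core beyond a light-rind band inward of the dark rind.
    remainder = section & ~dark_rind & ~bundles
    if dark_rind.any():
        inner_band = (
            morphology.dilation(
                dark_rind, footprint=morphology.disk(params.rind_band_width)
            )
            & remainder
        )
        pith = _largest_component(remainder & ~inner_band)
    else:
        pith = _largest_component(remainder)
    light_rind = remainder & ~pith

    masks = RegionMaskSet(
        section=section,
        dark_rind=dark_rind,
        bundles=bundles,
        light_rind=light_rind,
        pith=pith,
        params=params,
    )
    masks.validate()
    return masks
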