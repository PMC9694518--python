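"""End-to-end segmentation of a single cross-section image.

Runs the full chain: contrast enhancement and smoothing, HSV
decomposition, 15-class S/V pixel typology, automatic region masks,
tissue assignment, and the medullary hue sub-split, returning every
intermediate product for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RgbImage
from .pixel_classes import PixelClassMap, RangeSet, classify_pixels
from .preprocess import HsvImage, enhance, to_hsv
from .regions import RegionMaskSet, RegionParams, build_region_masks, build_section_mask
from .tissues import (
    TissueCatalogue,
    TissueLabelMap,
    assign_tissues,
    split_medullary_by_hue,
)


@dataclass
class SegmentationResult:
    """Every stage of one image's segmentation."""

    enhanced: RgbImage
    hsv: HsvImage
    class_map: PixelClassMap
    regions: RegionMaskSet
    tissue_map_presplit: TissueLabelMap
    tissue_map: TissueLabelMap

    @property
    def pixel_size_um(self) -> float:
        return self.enhanced.pixel_size_um


def segment_image(
    image: RgbImage,
    ranges: RangeSet | None = None,
    region_params: RegionParams | None = None,
    catalogue: TissueCatalogue | None = None,
    image_name: str = "image",
) -> SegmentationResult:
    """Segment one stained cross-section image into the 40 tissue types.

    Thresholds, morphology parameters and the catalogue are global
    constants of a run — the same values apply to every image.
    """
    ranges = ranges or RangeSet()
    region_params = region_params or RegionParams()
    catalogue = catalogue or TissueCatalogue.default()

    enhanced = enhance(image)
    hsv = to_hsv(enhanced)
    class_map = classify_pixels(hsv, ranges)
    section = build_section_mask(class_map, region_params, image_name=image_name)
    regions = build_region_masks(class_map, section, region_params)
    presplit = assign_tissues(class_map, regions, catalogue)
    final = split_medullary_by_hue(presplit, hsv.h, ranges)
    return SegmentationResult(
        enhanced=enhanced,
        hsv=hsv,
        class_map=class_map,
        regions=regions,
        tissue_map_presplit=presplit,
        tissue_map=final,
    )
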