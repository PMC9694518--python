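"""Color renderings of segmentation label maps.

Each tissue carries a distinct display color grouped by family hue (reds
for lignified medullary types, blues for poorly lignified ones, greens
for bundles, browns for the dark rind and epidermis, yellows for the
light rind); background renders white. Colors are distinct, so a render
is invertible back to its label map given the palette.
"""

from __future__ import annotations

import numpy as np

from .quantify import GroupedMap
from .tissues import TissueCatalogue, TissueLabelMap

BACKGROUND_COLOR = (255, 255, 255)

_GROUP_COLORS = {
    "background": BACKGROUND_COLOR,
    "epidermis": (74, 35, 16),
    "dark_rind": (140, 90, 43),
    "light_rind": (232, 208, 64),
    "bundles": (46, 139, 46),
    "medullary": (192, 0, 0),
    "rind": (140, 90, 43),
    "lignified_medullary": (192, 0, 0),
    "low_lignified_medullary": (32, 64, 192),
}


def tissue_palette(catalogue: TissueCatalogue | None = None) -> dict[int, tuple[int, int, int]]:
    """tissue_id → RGB triple, with background (0) mapped to white."""
    catalogue = catalogue or TissueCatalogue.default()
    palette = {0: BACKGROUND_COLOR}
    for e in catalogue.entries:
        palette[e.tissue_id] = e.color
    return palette


def grouped_palette(grouped: GroupedMap) -> dict[int, tuple[int, int, int]]:
    return {gid: _GROUP_COLORS[name] for gid, name in grouped.legend.items()}


def colorize(
    label_map: TissueLabelMap | GroupedMap | np.ndarray,
    palette: dict[int, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Pure palette lookup: label image → H×W×3 uint8 render."""
    if isinstance(label_map, TissueLabelMap):
        labels = label_map.labels
        palette = palette or tissue_palette(label_map.catalogue)
    elif isinstance(label_map, GroupedMap):
        labels = label_map.labels
        palette = palette or grouped_palette(label_map)
    else:
        labels = np.asarray(label_map)
        if palette is None:
            raise ValueError("a palette is required for a bare label array")
    present = np.unique(labels)
    missing = [int(v) for v in present if int(v) not in palette]
    if missing:
        raise ValueError(f"labels without palette entries: {missing}")
    lut = np.zeros((int(max(palette)) + 1, 3), dtype=np.uint8)
    for label, rgb in palette.items():
        lut[label] = rgb
    return lut[labels]


def uncolorize(
    render: np.ndarray, palette: dict[int, tuple[int, int, int]]
) -> np.ndarray:
    """Invert :func:`colorize` (palette triples must be distinct)."""
    colors = {}
    for label, rgb in palette.items():
        if tuple(rgb) in colors:
            raise ValueError("palette colors are not distinct; cannot invert")
        colors[tuple(rgb)] = label
    flat = render.reshape(-1, 3).astype(np.int64)
    out = np.zeros(flat.shape[0], dtype=np.int32)
    packed = flat[:, 0] * 65536 + flat[:, 1] * 256 + flat[:, 2]
    lut = {r * 65536 + g * 256 + b: label for (r, g, b), label in colors.items()}
    uniq = np.unique(packed)
    unknown = [int(u) for u in uniq if int(u) not in lut]
    if unknown:
        raise ValueError("render contains colors outside the palette")
    for value, label in lut.items():
        out[packed == value] = label
    return out.reshape(render.shape[:2])
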