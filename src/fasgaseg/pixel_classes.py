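"""The 15-class pixel typology from saturation / value range filters.

Three empirically fixed saturation ranges and three value ranges are
applied to every pixel. A pixel can fall in an S range only (classes 1-3),
a V range only (classes 4-6), or in both (the nine combination classes
7-15, id = 6 + 3*(s_bin-1) + v_bin). Pixels outside every S range and
every V range form the background class 0. The same ranges apply to every
stained section — the scheme has no per-image parameters.

Interval convention: ranges within one dimension are half-open
[low, high) except the last, which is closed [low, high]; a boundary
shared by two abutting ranges therefore belongs to the upper one, and the
printed gaps between ranges (e.g. V in [0.65, 0.66)) are real gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import HsvImage

N_CLASSES = 15  # non-background pixel classes
BACKGROUND_CLASS = 0
#: V-range-3-only pixels (V >= 0.95 with S below every range) are the
#: near-white slide background surrounding the section.
NEAR_WHITE_CLASS = 6

_DEFAULT_S = ((0.05, 0.26), (0.26, 0.78), (0.78, 1.0))
_DEFAULT_V = ((0.42, 0.65), (0.66, 0.93), (0.95, 1.0))
_DEFAULT_H_RED = (0.005, 0.09)
_DEFAULT_H_BLUE = (0.51, 0.91)


@dataclass(frozen=True)
class RangeSet:
    """The fixed S/V range filters and the two hue-splitting intervals.

    ``h_split_red`` captures red (safranin, lignified) hues and
    ``h_split_blue`` blue (alcian, poorly lignified) hues; both are used
    only for the medullary a/b sub-split, never for the 15-class typology.
    """

    s_ranges: tuple[tuple[float, float], ...] = _DEFAULT_S
    v_ranges: tuple[tuple[float, float], ...] = _DEFAULT_V
    h_split_red: tuple[float, float] = _DEFAULT_H_RED
    h_split_blue: tuple[float, float] = _DEFAULT_H_BLUE

    def __post_init__(self) -> None:
        for name in ("s_ranges", "v_ranges"):
            ranges = getattr(self, name)
            if len(ranges) != 3:
                raise ValueError(f"{name} must hold exactly 3 intervals")
            flat = [x for interval in ranges for x in interval]
            if any(x < 0 or x > 1 for x in flat):
                raise ValueError(f"{name} must lie within [0, 1]")
            for lo, hi in ranges:
                if not lo < hi:
                    raise ValueError(f"{name}: degenerate interval [{lo}, {hi}]")
            for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
                if lo2 < hi:
                    raise ValueError(f"{name}: overlapping intervals")
        for name in ("h_split_red", "h_split_blue"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"{name}: invalid interval [{lo}, {hi}]")

    @classmethod
    def from_cuts(
        cls,
        s_cuts: list[float] | None = None,
        v_cuts: list[float] | None = None,
        h_red: tuple[float, float] | None = None,
        h_blue: tuple[float, float] | None = None,
    ) -> "RangeSet":
        """Build a RangeSet from strictly increasing cut lists.

        A cut list of 4 values yields 3 abutting intervals; 6 values yield
        3 intervals with explicit gaps ([c0,c1], [c2,c3], [c4,c5]).
        """

        def to_ranges(cuts, default):
            if cuts is None:
                return default
            cuts = list(cuts)
            if len(cuts) == 4:
                return tuple((cuts[i], cuts[i + 1]) for i in range(3))
            if len(cuts) == 6:
                return tuple((cuts[2 * i], cuts[2 * i + 1]) for i in range(3))
            raise ValueError("cut lists must hold 4 (abutting) or 6 (gapped) values")

        return cls(
            s_ranges=to_ranges(s_cuts, _DEFAULT_S),
            v_ranges=to_ranges(v_cuts, _DEFAULT_V),
            h_split_red=h_red or _DEFAULT_H_RED,
            h_split_blue=h_blue or _DEFAULT_H_BLUE,
        )


@dataclass
class PixelClassMap:
    """Integer class labels over {0..15} aligned to the HSV grid."""

    labels: np.ndarray
    ranges: RangeSet = field(default_factory=RangeSet)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _bin_index(values: np.ndarray, ranges) -> np.ndarray:
    """0-based range index per value, -1 where the value is in no range."""
    out = np.full(values.shape, -1, dtype=np.int8)
    last = len(ranges) - 1
    for k, (lo, hi) in enumerate(ranges):
        if k == last:
            inside = (values >= lo) & (values <= hi)
        else:
            inside = (values >= lo) & (values < hi)
        out[inside] = k
    return out


def classify_pixels(hsv: HsvImage, ranges: RangeSet | None = None) -> PixelClassMap:
    """Assign each pixel its S/V class id (0 = background, 1-15 as above).

    The hue plane plays no role here; hue only enters at the medullary
    sub-split stage.
    """
    ranges = ranges or RangeSet()
    s_bin = _bin_index(hsv.s, ranges.s_ranges)
    v_bin = _bin_index(hsv.v, ranges.v_ranges)
    labels = np.zeros(hsv.shape, dtype=np.uint8)
    s_only = (s_bin >= 0) & (v_bin < 0)
    v_only = (s_bin < 0) & (v_bin >= 0)
    both = (s_bin >= 0) & (v_bin >= 0)
    labels[s_only] = 1 + s_bin[s_only]
    labels[v_only] = 4 + v_bin[v_only]
    labels[both] = 7 + 3 * s_bin[both] + v_bin[both]
    return PixelClassMap(labels=labels, ranges=ranges)


def class_mask(class_map: PixelClassMap, ids) -> np.ndarray:
    """Binary mask of pixels whose class id is in ``ids``."""
    ids = set(ids)
    unknown = ids - set(range(N_CLASSES + 1))
    if unknown:
        raise ValueError(f"unknown pixel class ids: {sorted(unknown)}")
    return np.isin(class_map.labels, sorted(ids))


def s_bin_family(s_bin: int) -> frozenset[int]:
    """All class ids whose S value lies in S range ``s_bin`` (1-based).

    The union of these classes reproduces the raw S-interval selection.
    """
    if s_bin not in (1, 2, 3):
        raise ValueError("s_bin must be 1, 2 or 3")
    return frozenset({s_bin} | {6 + 3 * (s_bin - 1) + j for j in (1, 2, 3)})


def v_bin_family(v_bin: int) -> frozenset[int]:
    """All class ids whose V value lies in V range ``v_bin`` (1-based)."""
    if v_bin not in (1, 2, 3):
        raise ValueError("v_bin must be 1, 2 or 3")
    return frozenset({3 + v_bin} | {6 + 3 * (i - 1) + v_bin for i in (1, 2, 3)})
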