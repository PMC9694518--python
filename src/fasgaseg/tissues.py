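"""The tissue taxonomy: pixel class × region → named tissue types.

Combining the 15 S/V pixel classes with the four spatial region masks
yields 36 tissue types: within the dark-rind mask 2 epidermal (ET) and 9
dark-rind (DRT) types, within the bundle mask 5 bundle (BT) types, and
within the light-rind and pith masks 10 light-rind (LRT) and 10 medullary
(MT) types that share class definitions and differ only by location.
Four medullary types are then sub-split by hue — red (safranin) hues mark
lignified walls, blue (alcian) hues poorly lignified ones — giving
MT1a/b, MT2a/b, MT4a/b, MT5a/b and a final taxonomy of 40 tissue types.

The default catalogue below honors the family censuses (2 ET, 9 DRT,
10 LRT, 5 BT, 14 MT names) and orders names by lignification signal:
low-numbered MT/BT names are the stain-dense, heavily lignified tissues
(MT1/MT4 red parenchyma, BT1/BT4 sclerenchyma poles), higher numbers the
pale, easily digestible ones (MT2/MT5 blue parenchyma, BT2 bundle
parenchyma, BT5 phloem). It can be replaced wholesale by a CSV mapping
table; the census invariants are enforced on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pixel_classes import N_CLASSES, PixelClassMap, RangeSet
from .regions import RegionMaskSet

#: Family tag → spatial mask its tissues are assigned from.
FAMILY_TO_MASK = {
    "ET": "dark_rind",
    "DRT": "dark_rind",
    "LRT": "light_rind",
    "BT": "bundles",
    "MT": "pith",
}

#: Family tag → reporting region label in area tables.
FAMILY_TO_REGION = {
    "ET": "epidermis",
    "DRT": "dark_rind",
    "LRT": "light_rind",
    "BT": "bundles",
    "MT": "medullary",
}

#: Pre-split medullary sentinel labels used between tissue assignment and
#: the hue sub-split (never present in a final label map).
PRESPLIT_MT = {"MT1": 101, "MT2": 102, "MT4": 104, "MT5": 105}
HUE_SPLIT_RULES = {"MT1": "red", "MT2": "blue", "MT4": "red", "MT5": "blue"}


@dataclass(frozen=True)
class TissueEntry:
    tissue_id: int
    name: str
    family: str
    source_classes: frozenset[int]
    color: tuple[int, int, int]
    hue_rule: str | None = None  # "red_in"/"red_out"/"blue_in"/"blue_out"

    @property
    def base_name(self) -> str:
        return self.name[:-1] if self.hue_rule else self.name

    @property
    def region(self) -> str:
        return FAMILY_TO_REGION[self.family]


# name, family, classes, hex color. Within each spatial mask the class sets
# of the base names are disjoint and cover all 15 classes; catch-all
# entries (DRT7, LRT10, MT10, BT3) absorb the single-dimension classes.
_DEFAULT_ROWS = [
    ("ET1", "ET", "3", "4a2310"),
    ("ET2", "ET", "13", "6b3a1f"),
    ("DRT1", "DRT", "7", "8c5a2b"),
    ("DRT2", "DRT", "8", "a06a33"),
    ("DRT3", "DRT", "9", "b47e42"),
    ("DRT4", "DRT", "10", "7a4a22"),
    ("DRT5", "DRT", "11", "915c2e"),
    ("DRT6", "DRT", "12", "aa7038"),
    ("DRT7", "DRT", "1+2+4+5+6", "c89a66"),
    ("DRT8", "DRT", "14", "5e2f14"),
    ("DRT9", "DRT", "15", "44220e"),
    ("LRT1", "LRT", "14", "b8a000"),
    ("LRT2", "LRT", "11", "d0b820"),
    ("LRT3", "LRT", "12", "e8d040"),
    ("LRT4", "LRT", "13", "a08800"),
    ("LRT5", "LRT", "15", "887000"),
    ("LRT6", "LRT", "10", "f0e060"),
    ("LRT7", "LRT", "7", "f8ec88"),
    ("LRT8", "LRT", "8", "fff4a8"),
    ("LRT9", "LRT", "9", "fffacc"),
    ("LRT10", "LRT", "1+2+3+4+5+6", "d8c878"),
    ("BT1", "BT", "3+13", "0a4a0a"),
    ("BT2", "BT", "2+11+12", "2e8b2e"),
    ("BT3", "BT", "1+4+10", "55aa55"),
    ("BT4", "BT", "14+15", "116611"),
    ("BT5", "BT", "5+6+7+8+9", "8cd98c"),
    ("MT1a", "MT", "14", "c00000"),
    ("MT1b", "MT", "14", "e06060"),
    ("MT2a", "MT", "11", "2040c0"),
    ("MT2b", "MT", "11", "7090e0"),
    ("MT3", "MT", "12", "9060c0"),
    ("MT4a", "MT", "13", "800000"),
    ("MT4b", "MT", "13", "b04040"),
    ("MT5a", "MT", "15", "102080"),
    ("MT5b", "MT", "15", "5060b0"),
    ("MT6", "MT", "10", "c080d0"),
    ("MT7", "MT", "7", "e0a0e0"),
    ("MT8", "MT", "8", "f0c0f0"),
    ("MT9", "MT", "9", "f8d8f8"),
    ("MT10", "MT", "1+2+3+4+5+6", "a890b8"),
]

_EXPECTED_CENSUS = {"ET": 2, "DRT": 9, "LRT": 10, "BT": 5, "MT": 14}


def _hue_rule_for(name: str, family: str) -> str | None:
    if family != "MT":
        return None
    base, suffix = name[:-1], name[-1]
    if base in HUE_SPLIT_RULES and suffix in ("a", "b"):
        color = HUE_SPLIT_RULES[base]
        return f"{color}_{'in' if suffix == 'a' else 'out'}"
    return None


@dataclass
class TissueCatalogue:
    """The ordered catalogue of the 40 tissue types.

    Tissue ids are the 1-based positions in catalogue order
    (ET1..ET2, DRT1..DRT9, LRT1..LRT10, BT1..BT5, MT1a..MT10), fixed so
    that label maps are comparable across runs and machines.
    """

    entries: tuple[TissueEntry, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.entries) != 40:
            raise ValueError(f"catalogue must hold 40 tissues, got {len(self.entries)}")
        census: dict[str, int] = {}
        for e in self.entries:
            census[e.family] = census.get(e.family, 0) + 1
        if census != _EXPECTED_CENSUS:
            raise ValueError(f"family census {census} != {_EXPECTED_CENSUS}")
        ids = [e.tissue_id for e in self.entries]
        if ids != list(range(1, 41)):
            raise ValueError("tissue ids must be 1..40 in catalogue order")
        if len({e.name for e in self.entries}) != 40:
            raise ValueError("tissue names must be unique")
        if len({e.color for e in self.entries}) != 40:
            raise ValueError("display colors must be distinct")
        # Per spatial mask: base-name class sets disjoint and covering 1..15.
        for mask_family in ("dark_rind", "light_rind", "bundles", "pith"):
            seen: dict[str, frozenset[int]] = {}
            for e in self.entries:
                if FAMILY_TO_MASK[e.family] != mask_family:
                    continue
                prev = seen.get(e.base_name)
                if prev is not None and prev != e.source_classes:
                    raise ValueError(f"{e.base_name}: split variants disagree on classes")
                seen[e.base_name] = e.source_classes
            covered: set[int] = set()
            for base, classes in seen.items():
                if covered & classes:
                    raise ValueError(f"overlapping classes in mask {mask_family}")
                covered |= classes
            if covered != set(range(1, N_CLASSES + 1)):
                raise ValueError(
                    f"mask {mask_family} covers classes {sorted(covered)}, expected 1..15"
                )

    @classmethod
    def default(cls) -> "TissueCatalogue":
        entries = []
        for i, (name, family, classes, hexcolor) in enumerate(_DEFAULT_ROWS, start=1):
            entries.append(
                TissueEntry(
                    tissue_id=i,
                    name=name,
                    family=family,
                    source_classes=frozenset(int(c) for c in classes.split("+")),
                    color=tuple(int(hexcolor[k : k + 2], 16) for k in (0, 2, 4)),
                    hue_rule=_hue_rule_for(name, family),
                )
            )
        return cls(entries=tuple(entries))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TissueCatalogue":
        """Load a mapping table (tissue_name, region, class_ids, color_hex).

        ``region`` is the family tag (ET/DRT/LRT/BT/MT) or one of the
        reporting region names; rows must appear in catalogue order.
        """
        region_to_family = {v: k for k, v in FAMILY_TO_REGION.items()}
        entries = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh), start=1):
                family = row["region"].strip()
                family = region_to_family.get(family, family)
                if family not in FAMILY_TO_REGION:
                    raise ValueError(f"unknown region/family {row['region']!r}")
                name = row["tissue_name"].strip()
                hexcolor = row["color_hex"].strip().lstrip("#")
                entries.append(
                    TissueEntry(
                        tissue_id=i,
                        name=name,
                        family=family,
                        source_classes=frozenset(
                            int(c) for c in row["class_ids"].split("+")
                        ),
                        color=tuple(int(hexcolor[k : k + 2], 16) for k in (0, 2, 4)),
                        hue_rule=_hue_rule_for(name, family),
                    )
                )
        return cls(entries=tuple(entries))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["tissue_name", "region", "class_ids", "color_hex"])
            for e in self.entries:
                w.writerow(
                    [
                        e.name,
                        e.family,
                        "+".join(str(c) for c in sorted(e.source_classes)),
                        "%02x%02x%02x" % e.color,
                    ]
                )
        return path

    def by_name(self, name: str) -> TissueEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def id_of(self, name: str) -> int:
        return self.by_name(name).tissue_id

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def presplit_names(self) -> list[str]:
        """The 36 assignable names before the medullary hue sub-split."""
        seen: list[str] = []
        for e in self.entries:
            base = e.base_name
            if base not in seen:
                seen.append(base)
        return seen

    def class_lookup(self, mask_family: str) -> dict[int, int]:
        """pixel class id → label for tissues assigned from ``mask_family``.

        Hue-split medullary bases map to their pre-split sentinel labels.
        Class 0 (background pixels swallowed into the section by closing)
        maps to the same tissue as class 1, the region's catch-all entry.
        """
        lookup: dict[int, int] = {}
        for e in self.entries:
            if FAMILY_TO_MASK[e.family] != mask_family:
                continue
            label = PRESPLIT_MT.get(e.base_name, e.tissue_id)
            for c in e.source_classes:
                lookup[c] = label
        lookup[0] = lookup[1]
        return lookup


@dataclass
class TissueLabelMap:
    """Integer tissue labels over {0} ∪ catalogue ids (plus, before the
    hue sub-split, the pre-split medullary sentinels)."""

    labels: np.ndarray
    catalogue: TissueCatalogue = field(default_factory=TissueCatalogue.default)
    ranges: RangeSet = field(default_factory=RangeSet)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def is_split(self) -> bool:
        return not np.isin(self.labels, list(PRESPLIT_MT.values())).any()


def assign_tissues(
    class_map: PixelClassMap,
    regions: RegionMaskSet,
    catalogue: TissueCatalogue | None = None,
) -> TissueLabelMap:
    """Label every section pixel with its tissue (pre-hue-split stage).

    The result uses final catalogue ids except for the four hue-split
    medullary bases, which carry pre-split sentinel labels until
    :func:`split_medullary_by_hue` resolves them; 36 distinct names are
    assignable at this stage.
    """
    catalogue = catalogue or TissueCatalogue.default()
    if class_map.shape != regions.shape:
        raise ValueError("class map and region masks must share one shape")
    labels = np.zeros(class_map.shape, dtype=np.uint8)
    for mask_family in ("dark_rind", "light_rind", "bundles", "pith"):
        mask = getattr(regions, mask_family)
        if not mask.any():
            continue
        lookup = catalogue.class_lookup(mask_family)
        table = np.zeros(N_CLASSES + 1, dtype=np.uint8)
        for c, label in lookup.items():
            table[c] = label
        labels[mask] = table[class_map.labels[mask]]
    return TissueLabelMap(labels=labels, catalogue=catalogue, ranges=class_map.ranges)


def split_medullary_by_hue(
    tissue_map: TissueLabelMap, h: np.ndarray, ranges: RangeSet | None = None
) -> TissueLabelMap:
    """Resolve the pre-split medullary labels by hue.

    Lignified bases (MT1, MT4): hue inside the red interval → the "a"
    variant, otherwise "b". Poorly lignified bases (MT2, MT5): hue inside
    the blue interval → "a", otherwise "b". Both intervals are closed.
    """
    ranges = ranges or tissue_map.ranges
    cat = tissue_map.catalogue
    labels = tissue_map.labels.copy()
    intervals = {"red": ranges.h_split_red, "blue": ranges.h_split_blue}
    for base, sentinel in PRESPLIT_MT.items():
        where = labels == sentinel
        if not where.any():
            continue
        lo, hi = intervals[HUE_SPLIT_RULES[base]]
        inside = (h >= lo) & (h <= hi)
        labels[where & inside] = cat.id_of(base + "a")
        labels[where & ~inside] = cat.id_of(base + "b")
    return TissueLabelMap(labels=labels, catalogue=cat, ranges=ranges)
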