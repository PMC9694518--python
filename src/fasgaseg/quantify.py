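"""Per-tissue area statistics and region-grouped label maps.

Areas are reported as pixel counts, physical areas (pixel count × pixel
size²) and percentages of the enclosing quantification region, following
the conventions of FASGA histology studies: %MT is percent of all
medullary tissue, %BT percent of all bundle tissue, and %RT percent of
all rind tissue — epidermal, dark-rind and light-rind types share the
rind denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tissues import FAMILY_TO_REGION, TissueCatalogue, TissueLabelMap

logger = logging.getLogger(__name__)

#: Family tag → percentage denominator group.
FAMILY_TO_PCT_GROUP = {
    "ET": "rind",
    "DRT": "rind",
    "LRT": "rind",
    "BT": "bundles",
    "MT": "medullary",
}

REGIONS5_LEGEND = {
    0: "background",
    1: "epidermis",
    2: "dark_rind",
    3: "light_rind",
    4: "bundles",
    5: "medullary",
}
_FAMILY_TO_REGIONS5 = {"ET": 1, "DRT": 2, "LRT": 3, "BT": 4, "MT": 5}

LEGLAND4_LEGEND = {
    0: "background",
    1: "rind",
    2: "bundles",
    3: "lignified_medullary",
    4: "low_lignified_medullary",
}
#: Medullary bases the grouping names as lignified; every other medullary
#: tissue defaults to the low-lignified group (switchable).
_LIGNIFIED_BASES = ("MT1", "MT4")


def tissue_areas(
    tissue_map: TissueLabelMap, pixel_size_um: float = 5.17
) -> pd.DataFrame:
    """Tissue area table: one row per catalogue tissue, in catalogue order.

    Columns: tissue_id, tissue_name, region, pixel_count, area_um2,
    pct_of_region. Tissues absent from the map keep a row with count 0.
    """
    cat = tissue_map.catalogue
    counts = np.bincount(tissue_map.labels.ravel(), minlength=256)
    rows = []
    group_totals: dict[str, int] = {}
    for e in cat.entries:
        group = FAMILY_TO_PCT_GROUP[e.family]
        group_totals[group] = group_totals.get(group, 0) + int(counts[e.tissue_id])
    for group, total in group_totals.items():
        if total == 0:
            logger.warning("quantification region %s holds zero pixels", group)
    for e in cat.entries:
        n = int(counts[e.tissue_id])
        total = group_totals[FAMILY_TO_PCT_GROUP[e.family]]
        rows.append(
            {
                "tissue_id": e.tissue_id,
                "tissue_name": e.name,
                "region": FAMILY_TO_REGION[e.family],
                "pixel_count": n,
                "area_um2": n * pixel_size_um**2,
                "pct_of_region": 100.0 * n / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupedMap:
    """A label map regrouped into histological regions."""

    labels: np.ndarray
    scheme: str
    legend: dict[int, str]


def group_tissues(
    tissue_map: TissueLabelMap,
    scheme: str,
    extra_medullary_lignified: bool = False,
) -> GroupedMap:
    """Regroup the 40-tissue map into coarse histological regions.

    ``regions5`` keeps the five tissue families apart (epidermis, dark
    rind, light rind, bundles, medullary). ``legland4`` merges the whole
    rind and splits the medulla by lignification: MT1a/b and MT4a/b form
    the lignified group, MT2a/b and MT5a/b the low-lignified one; the
    remaining medullary types join the low-lignified group by default
    (set ``extra_medullary_lignified`` to move them).
    """
    if scheme not in ("regions5", "legland4"):
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    if not tissue_map.is_split:
        raise ValueError("grouping requires a hue-split tissue map")
    cat = tissue_map.catalogue
    table = np.zeros(256, dtype=np.uint8)
    if scheme == "regions5":
        legend = dict(REGIONS5_LEGEND)
        for e in cat.entries:
            table[e.tissue_id] = _FAMILY_TO_REGIONS5[e.family]
    else:
        legend = dict(LEGLAND4_LEGEND)
        for e in cat.entries:
            if e.family != "MT":
                table[e.tissue_id] = 2 if e.family == "BT" else 1
            elif e.base_name in _LIGNIFIED_BASES:
                table[e.tissue_id] = 3
            elif e.hue_rule is not None:  # MT2, MT5
                table[e.tissue_id] = 4
            else:  # MT3, MT6-MT10
                table[e.tissue_id] = 3 if extra_medullary_lignified else 4
    return GroupedMap(labels=table[tissue_map.labels], scheme=scheme, legend=legend)


def grouped_areas(grouped: GroupedMap, pixel_size_um: float = 5.17) -> pd.DataFrame:
    """Pixel counts and areas per group of a :class:`GroupedMap`."""
    counts = np.bincount(grouped.labels.ravel(), minlength=256)
    rows = []
    for gid, name in sorted(grouped.legend.items()):
        if gid == 0:
            continue
        n = int(counts[gid])
        rows.append(
            {
                "group_id": gid,
                "group_name": name,
                "pixel_count": n,
                "area_um2": n * pixel_size_um**2,
            }
        )
    return pd.DataFrame(rows)
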