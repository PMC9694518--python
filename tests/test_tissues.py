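"""Tissue catalogue, class-x-region assignment, and the medullary hue split."""

import numpy as np
import pytest

from fasgaseg import RangeSet, TissueCatalogue, assign_tissues, split_medullary_by_hue
from fasgaseg.pixel_classes import PixelClassMap
from fasgaseg.regions import RegionMaskSet, RegionParams
from fasgaseg.tissues import FAMILY_TO_MASK, PRESPLIT_MT, TissueLabelMap


def test_default_catalogue_censuses(catalogue):
    names = catalogue.names()
    assert len(names) == 40
    families = {}
    for e in catalogue.entries:
        families.setdefault(e.family, []).append(e.name)
    assert len(families["ET"]) == 2
    assert len(families["DRT"]) == 9
    assert len(families["LRT"]) == 10
    assert len(families["BT"]) == 5
    assert len(families["MT"]) == 14
    assert len(catalogue.presplit_names()) == 36


def test_catalogue_csv_round_trip(tmp_path, catalogue):
    path = catalogue.to_csv(tmp_path / "catalogue.csv")
    back = TissueCatalogue.from_csv(path)
    assert back.names() == catalogue.names()
    for a, b in zip(back.entries, catalogue.entries):
        assert a.source_classes == b.source_classes
        assert a.color == b.color
        assert a.hue_rule == b.hue_rule


def test_catalogue_census_violation_rejected(catalogue):
    import dataclasses

    entries = list(catalogue.entries)
    # duplicate one DRT entry's family into ET -> census breaks
    entries[2] = dataclasses.replace(entries[2], family="ET")
    with pytest.raises(ValueError, match="census"):
        TissueCatalogue(entries=tuple(entries))


def test_every_class_resolves_in_every_region(catalogue):
    """15 pixel classes x 4 spatial masks each map to exactly one name."""
    resolved = set()
    for mask_family in ("dark_rind", "light_rind", "bundles", "pith"):
        lookup = catalogue.class_lookup(mask_family)
        for class_id in range(0, 16):
            assert class_id in lookup
        resolved |= {(mask_family, label) for label in lookup.values()}
    # 36 distinct assignable names before the hue split
    labels = {label for _, label in resolved}
    assert len(labels) == 36


def _tiny_scene(catalogue):
    """A 2x8 scene: one pixel per region for two pixel classes."""
    class_ids = np.array([[3, 3, 3, 3], [8, 8, 8, 8]], dtype=np.uint8)
    class_map = PixelClassMap(labels=class_ids, ranges=RangeSet())
    shape = class_ids.shape
    zeros = np.zeros(shape, dtype=bool)
    col = lambda j: np.isin(np.arange(4)[None, :].repeat(2, 0), [j])
    masks = RegionMaskSet(
        section=np.ones(shape, dtype=bool),
        dark_rind=col(0),
        light_rind=col(1),
        bundles=col(2),
        pith=col(3),
        params=RegionParams(),
    )
    return class_map, masks


def test_assign_tissues_direct_lookup(catalogue):
    class_map, masks = _tiny_scene(catalogue)
    out = assign_tissues(class_map, masks, catalogue)
    # dark-rind pixel with ET1's source class -> ET1
    assert out.labels[0, 0] == catalogue.id_of("ET1")
    # light-rind class 8 -> LRT8; bundle class 3 -> BT1; class 8 -> BT5
    assert out.labels[1, 1] == catalogue.id_of("LRT8")
    assert out.labels[0, 2] == catalogue.id_of("BT1")
    assert out.labels[1, 2] == catalogue.id_of("BT5")
    # pith class 8 -> pre-split MT8 (no hue rule), class 3 -> MT10 catch-all
    assert out.labels[1, 3] == catalogue.id_of("MT8")
    assert out.labels[0, 3] == catalogue.id_of("MT10")


def test_bundle_mask_toggle_only_changes_that_blob(catalogue, phantom_512):
    spec, image, truth, region_truth, result = phantom_512
    import dataclasses

    from scipy import ndimage

    regions = result.regions
    cc, n = ndimage.label(regions.bundles)
    blob = cc == 1
    toggled = dataclasses.replace(
        regions,
        bundles=regions.bundles & ~blob,
        pith=regions.pith | blob,
    )
    a = assign_tissues(result.class_map, regions, catalogue)
    b = assign_tissues(result.class_map, toggled, catalogue)
    changed = a.labels != b.labels
    assert changed.any()
    assert not (changed & ~blob).any()


@pytest.mark.parametrize(
    "base,h,expected",
    [
        ("MT1", 0.05, "MT1a"),  # red interval contains 0.05
        ("MT1", 0.5, "MT1b"),
        ("MT2", 0.7, "MT2a"),  # blue interval contains 0.7
        ("MT2", 0.3, "MT2b"),
        ("MT4", 0.005, "MT4a"),  # closed lower bound
        ("MT5", 0.91, "MT5a"),  # closed upper bound
    ],
)
def test_hue_split_examples(catalogue, base, h, expected):
    labels = np.full((1, 1), PRESPLIT_MT[base], dtype=np.uint8)
    tm = TissueLabelMap(labels=labels, catalogue=catalogue, ranges=RangeSet())
    out = split_medullary_by_hue(tm, np.full((1, 1), h))
    assert out.labels[0, 0] == catalogue.id_of(expected)


def test_hue_split_matches_interval_oracle_on_sweep(catalogue):
    ranges = RangeSet()
    hs = np.round(np.arange(0, 1001) / 1000.0, 10).reshape(1, -1)
    for base, interval in (
        ("MT1", ranges.h_split_red),
        ("MT2", ranges.h_split_blue),
        ("MT4", ranges.h_split_red),
        ("MT5", ranges.h_split_blue),
    ):
        labels = np.full(hs.shape, PRESPLIT_MT[base], dtype=np.uint8)
        tm = TissueLabelMap(labels=labels, catalogue=catalogue, ranges=ranges)
        out = split_medullary_by_hue(tm, hs)
        lo, hi = interval
        expected_a = (hs >= lo) & (hs <= hi)
        assert np.array_equal(out.labels == catalogue.id_of(base + "a"), expected_a)
        assert np.array_equal(
            out.labels == catalogue.id_of(base + "b"), ~expected_a
        )


def test_split_partitions_each_presplit_base(phantom_512, catalogue):
    spec, image, truth, region_truth, result = phantom_512
    pre = result.tissue_map_presplit
    post = result.tissue_map
    assert not pre.is_split  # phantom pith holds hue-split bases
    assert post.is_split
    for base, sentinel in PRESPLIT_MT.items():
        where = pre.labels == sentinel
        ids = {catalogue.id_of(base + "a"), catalogue.id_of(base + "b")}
        assert set(np.unique(post.labels[where])) <= ids
        # and nothing outside the pre-split base becomes a/b
        outside = ~where
        assert not np.isin(post.labels[outside], list(ids)).any()


def test_final_map_families_match_regions(phantom_512, catalogue):
    spec, image, truth, region_truth, result = phantom_512
    id_to_mask = {
        e.tissue_id: FAMILY_TO_MASK[e.family] for e in catalogue.entries
    }
    for mask_family in ("dark_rind", "light_rind", "bundles", "pith"):
        mask = getattr(result.regions, mask_family)
        present = np.unique(result.tissue_map.labels[mask])
        for tid in present:
            assert id_to_mask[int(tid)] == mask_family
    # labels are nonzero exactly on the section
    assert np.array_equal(result.tissue_map.labels > 0, result.regions.section)
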