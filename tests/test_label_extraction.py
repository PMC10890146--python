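import numpy as np
import pytest

from ppmval.label_extraction import (
    AnnotationMap,
    POISet,
    detect_pois,
    extract_labels,
    rasterize_poi_areas,
    warp_poi_mask,
)
from ppmval.preprocessing import SpecimenImage
from ppmval.registration import DisplacementField
from ppmval.synthetic_data import (
    CLASS_LEGEND,
    PhantomSpec,
    generate_smooth_deformation,
    generate_specimen_pair,
)


def disk_pixels(cx, cy, r, shape):
    """Pixel-center-inside-circle oracle."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


class TestPOISet:
    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError):
            POISet(centers=[(5.0, 5.0), (5.0, 5.0)], radius=2.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            POISet(centers=[(5.0, 5.0)], radius=0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            POISet(centers=np.empty((0, 2)), radius=1.0)


class TestDetectPois:
    def test_phantom_dots_within_one_pixel(self):
        ph = generate_specimen_pair(PhantomSpec(seed=7, deform_amplitude=0.0))
        pois = detect_pois(ph.s_poi, ph.s_o, radius=ph.poi_radius)
        assert len(pois) == len(ph.poi_centers)
        # match detections to truth greedily
        for c in ph.poi_centers:
            d = np.sqrt(np.sum((pois.centers - c) ** 2, axis=1)).min()
            assert d < 1.0

    def test_no_dots_errors(self):
        ph = generate_specimen_pair(PhantomSpec(seed=7, deform_amplitude=0.0))
        with pytest.raises(ValueError):
            detect_pois(ph.s_o, ph.s_o)

    def test_min_area_filtering(self):
        # 9-pixel dots (rasterized radius 1.5): dropped at min_area=20, kept at 5
        base = np.full((64, 64, 3), 0.1)
        spotted = base.copy()
        for cx, cy in [(16, 16), (40, 30), (25, 50)]:
            spotted[disk_pixels(cx, cy, 1.5, (64, 64))] = 1.0
        area = int(disk_pixels(16, 16, 1.5, (64, 64)).sum())
        assert area == 9
        s_o = SpecimenImage(pixels=base, role="S_O")
        s_poi = SpecimenImage(pixels=spotted, role="S_POI")
        with pytest.raises(ValueError):
            detect_pois(s_poi, s_o, min_area=20)
        pois = detect_pois(s_poi, s_o, min_area=5)
        assert len(pois) == 3

    def test_merged_dots_warn(self):
        base = np.full((64, 64, 3), 0.1)
        spotted = base.copy()
        # two overlapping dots plus two normal ones
        for cx, cy in [(20, 20), (23, 20), (45, 45), (10, 50)]:
            spotted[disk_pixels(cx, cy, 2.5, (64, 64))] = 1.0
        with pytest.warns(RuntimeWarning, match="overlapping"):
            detect_pois(
                SpecimenImage(pixels=spotted, role="S_POI"),
                SpecimenImage(pixels=base, role="S_O"),
            )

    def test_dimension_mismatch(self):
        a = SpecimenImage(pixels=np.zeros((8, 8, 3)))
        b = SpecimenImage(pixels=np.zeros((8, 9, 3)))
        with pytest.raises(ValueError):
            detect_pois(a, b)


class TestRasterizePoiAreas:
    def test_small_disk_matches_oracle(self):
        pois = POISet(centers=[(50.0, 50.0)], radius=1.5)
        out = rasterize_poi_areas(pois, (100, 100))
        np.testing.assert_array_equal(out == 1, disk_pixels(50, 50, 1.5, (100, 100)))
        assert out.sum() == 9  # 9-pixel disk, all labeled 1

    def test_indices_follow_poi_order(self):
        pois = POISet(centers=[(10.0, 10.0), (30.0, 30.0)], radius=3.0)
        out = rasterize_poi_areas(pois, (50, 50))
        assert out[10, 10] == 1
        assert out[30, 30] == 2

    def test_overlap_errors(self):
        pois = POISet(centers=[(20.0, 20.0), (24.0, 20.0)], radius=4.0)
        with pytest.raises(ValueError, match="overlap"):
            rasterize_poi_areas(pois, (50, 50))

    def test_out_of_bounds_errors(self):
        pois = POISet(centers=[(2.0, 25.0)], radius=5.0)
        with pytest.raises(ValueError, match="bounds"):
            rasterize_poi_areas(pois, (50, 50))


class TestWarpPoiMask:
    def test_zero_field_identity(self):
        pois = POISet(centers=[(20.0, 15.0), (40.0, 35.0)], radius=4.0)
        mask = rasterize_poi_areas(pois, (60, 60))
        out = warp_poi_mask(mask, DisplacementField.zero((60, 60)))
        np.testing.assert_array_equal(out, mask)

    def test_unit_translation_shifts_disks(self):
        pois = POISet(centers=[(20.0, 15.0)], radius=4.0)
        mask = rasterize_poi_areas(pois, (60, 60))
        fld = DisplacementField(u=np.ones((60, 60)), v=np.zeros((60, 60)))
        out = warp_poi_mask(mask, fld)
        np.testing.assert_array_equal(out[:, :-1], mask[:, 1:])

    def test_label_codes_preserved(self):
        pois = POISet(centers=[(20.0, 15.0), (40.0, 35.0)], radius=4.0)
        mask = rasterize_poi_areas(pois, (60, 60))
        spec = PhantomSpec(seed=3, deform_amplitude=4.0, deform_scale=16.0)
        out = warp_poi_mask(mask, generate_smooth_deformation(spec, (60, 60)))
        assert set(np.unique(out)) <= set(np.unique(mask))

    def test_smooth_deformation_centroids(self):
        ph = generate_specimen_pair(PhantomSpec(seed=9, deform_amplitude=8.0))
        pois = POISet(centers=ph.poi_centers, radius=ph.poi_radius)
        mask = rasterize_poi_areas(pois, ph.field.shape)
        out = warp_poi_mask(mask, ph.field)
        for k, target in enumerate(ph.poi_centers_histology, start=1):
            ys, xs = np.nonzero(out == k)
            assert len(xs) > 0
            centroid = np.array([xs.mean(), ys.mean()])
            assert np.linalg.norm(centroid - target) < 2.0


class TestExtractLabels:
    def test_single_class_disk(self):
        ann = AnnotationMap(
            labels=np.full((50, 50), 2, dtype=np.int32),
            legend={2: "connective"},
        )
        mask = rasterize_poi_areas(POISet(centers=[(25.0, 25.0)], radius=5.0), (50, 50))
        report = extract_labels(mask, ann, background_label=-1)
        assert report.entries[0].percentages == {"connective": 100.0}

    def test_half_plane_boundary(self):
        labels = np.ones((80, 80), dtype=np.int32)
        labels[:, 40:] = 2
        ann = AnnotationMap(labels=labels, legend={1: "fat", 2: "tumor"})
        # disk centered on the geometric boundary between pixel columns 39 and 40
        mask = rasterize_poi_areas(POISet(centers=[(39.5, 40.0)], radius=10.3), (80, 80))
        report = extract_labels(mask, ann, background_label=0)
        pct = report.entries[0].percentages
        assert pct["fat"] == pytest.approx(50.0, abs=2.0)
        assert pct["tumor"] == pytest.approx(50.0, abs=2.0)

    def test_pie_slice_fractions(self):
        yy, xx = np.mgrid[0:120, 0:120]
        ang = np.degrees(np.arctan2(yy - 60, xx - 60)) % 360.0
        labels = np.where(ang < 180.0, 1, np.where(ang < 288.0, 2, 3)).astype(np.int32)
        ann = AnnotationMap(labels=labels, legend={1: "a", 2: "b", 3: "c"})
        mask = rasterize_poi_areas(POISet(centers=[(60.0, 60.0)], radius=30.0), (120, 120))
        pct = extract_labels(mask, ann, background_label=0).entries[0].percentages
        assert pct["a"] == pytest.approx(50.0, abs=2.0)
        assert pct["b"] == pytest.approx(30.0, abs=2.0)
        assert pct["c"] == pytest.approx(20.0, abs=2.0)

    def test_percentages_sum_to_100(self, rng):
        labels = rng.integers(0, 4, (60, 60)).astype(np.int32)
        ann = AnnotationMap(labels=labels, legend=dict(CLASS_LEGEND))
        pois = POISet(centers=[(15.0, 15.0), (45.0, 40.0)], radius=6.0)
        mask = rasterize_poi_areas(pois, (60, 60))
        report = extract_labels(mask, ann)
        for e in report.entries:
            assert sum(e.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_background_flagged(self):
        ann = AnnotationMap(labels=np.zeros((40, 40), dtype=np.int32),
                            legend={0: "background"})
        mask = rasterize_poi_areas(POISet(centers=[(20.0, 20.0)], radius=4.0), (40, 40))
        report = extract_labels(mask, ann)
        assert report.entries[0].outside_tissue
        assert report.entries[0].percentages["background"] == 100.0

    def test_self_label_consistency(self):
        # annotation = the disks' own indices; identity DDF => each POI 100% itself
        pois = POISet(centers=[(15.0, 15.0), (45.0, 40.0)], radius=5.0)
        mask = rasterize_poi_areas(pois, (60, 60))
        warped = warp_poi_mask(mask, DisplacementField.zero((60, 60)))
        ann = AnnotationMap(
            labels=mask.astype(np.int32),
            legend={0: "background", 1: "poi1", 2: "poi2"},
        )
        report = extract_labels(warped, ann)
        assert report.entries[0].percentages["poi1"] == 100.0
        assert report.entries[1].percentages["poi2"] == 100.0

    def test_dimension_mismatch(self):
        ann = AnnotationMap(labels=np.zeros((10, 10), dtype=np.int32),
                            legend={0: "background"})
        with pytest.raises(ValueError):
            extract_labels(np.ones((9, 10), dtype=np.int32), ann)


class TestEndToEndOnPhantom:
    def test_detect_rasterize_identity_extract(self):
        ph = generate_specimen_pair(PhantomSpec(seed=11, deform_amplitude=0.0))
        pois = detect_pois(ph.s_poi, ph.s_o, radius=ph.poi_radius)
        mask = rasterize_poi_areas(pois, ph.class_layout.shape)
        warped = warp_poi_mask(mask, DisplacementField.zero(ph.class_layout.shape))
        ann = AnnotationMap(labels=ph.class_layout, legend=dict(CLASS_LEGEND))
        report = extract_labels(warped, ann, pois=pois)
        got = []
        for e in report.entries:
            top = max(e.percentages, key=e.percentages.get)
            assert e.percentages[top] == 100.0
            got.append(top)
        # detections are unordered; compare as multisets
        assert sorted(got) == sorted(ph.intended_labels)
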