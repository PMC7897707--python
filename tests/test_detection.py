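import numpy as np
import pytest

from scaffoldcount import (
    Channel,
    DetectionParams,
    FieldGeometry,
    FusedImage,
    count_field,
    render_mask,
    segment_nuclei,
)
from scaffoldcount.detection import AreaUnit, RejectionReason

from oracles import components_as_sets, flood_fill_label

PX = 1.625  # um/px


def _image(pixels, pixel_size=PX):
    pixels = np.asarray(pixels)
    return FusedImage(
        pixels=pixels.astype(np.uint16),
        focus_index=np.zeros(pixels.shape, dtype=np.intp),
        pixel_size_um=pixel_size,
        channel=Channel.total_nuclei,
        source_field="test",
    )


def _gaussian_blob(shape, cy, cx, sigma_px, peak):
    ys, xs = np.mgrid[: shape[0], : shape[1]]
    return peak * np.exp(-((ys - cy) ** 2 + (xs - cx) ** 2) / (2 * sigma_px**2))


class TestSegmentNuclei:
    def test_blank_image_yields_nothing(self):
        objects, overlay = segment_nuclei(_image(np.zeros((32, 32))))
        assert objects == []
        assert overlay.accepted_labels.max() == 0

    def test_dim_blob_excluded_by_intensity_threshold(self):
        """Three bright nuclei pass; a 5000-peak blob never enters the
        supra-threshold set at the 7000 threshold."""
        img = np.zeros((64, 64))
        for cy, cx, peak in [(10, 10, 20000), (10, 50, 20000), (50, 10, 20000)]:
            img += _gaussian_blob(img.shape, cy, cx, 1.0, peak)
        img += _gaussian_blob(img.shape, 50, 50, 1.0, 5000)
        objects, overlay = segment_nuclei(_image(img))
        assert len(objects) == 3
        assert not overlay.rejection_reasons  # dim blob absent, not rejected

    def test_touching_haloes_with_separate_cores_split(self):
        """Two nuclei whose sub-threshold haloes overlap are still counted
        as two because only the bright cores exceed the threshold."""
        img = np.zeros((40, 40))
        img += _gaussian_blob(img.shape, 20, 16, 2.0, 20000)
        img += _gaussian_blob(img.shape, 20, 24, 2.0, 20000)
        assert (img[20, 16:25] > 500).all()  # haloes form one bridge
        objects, _ = segment_nuclei(_image(img, pixel_size=1.0))
        assert len(objects) == 2

    def test_oversized_object_rejected_with_reason(self):
        img = np.zeros((64, 64))
        img[20:30, 20:30] = 30000  # 100 px -> 264 um^2 core
        img += _gaussian_blob(img.shape, 50, 50, 1.0, 20000)
        objects, overlay = segment_nuclei(_image(img))
        assert len(objects) == 1
        assert set(overlay.rejection_reasons.values()) == {RejectionReason.too_large}
        # the rejected component's physical area really is over the limit
        rejected_px = (overlay.rejected_labels > 0).sum()
        assert rejected_px * PX**2 >= 30.0

    def test_single_hot_pixel_rejected_as_speck(self):
        img = np.zeros((32, 32))
        img[5, 5] = 60000  # 1 px = 1 um^2, below the 2 um^2 floor
        objects, overlay = segment_nuclei(_image(img, pixel_size=1.0))
        assert objects == []
        assert set(overlay.rejection_reasons.values()) == {RejectionReason.too_small}

    def test_boundary_values_excluded_strictly(self):
        """Pixels exactly at the threshold do not pass; areas exactly at
        the maximum are rejected."""
        img = np.zeros((16, 16))
        img[2, 2] = 7000  # not 'more than 7000'
        objects, _ = segment_nuclei(_image(img))
        assert objects == []
        params = DetectionParams(min_area_um2=0.0, max_area_um2=4 * PX**2)
        img2 = np.zeros((16, 16))
        img2[4:6, 4:6] = 20000  # exactly 4 px = max area
        objects2, overlay2 = segment_nuclei(_image(img2), params)
        assert objects2 == []
        assert set(overlay2.rejection_reasons.values()) == {RejectionReason.too_large}

    def test_threshold_above_bit_depth_rejected(self):
        with pytest.raises(ValueError, match="nothing can pass"):
            segment_nuclei(_image(np.zeros((8, 8))), DetectionParams(intensity_threshold=70000))

    def test_eight_bit_input_rescaled_before_threshold(self):
        img8 = np.zeros((16, 16), dtype=np.uint8)
        img8[4:6, 4:6] = 100  # -> 25700 on the 16-bit scale
        fused = FusedImage(
            pixels=img8, focus_index=np.zeros_like(img8, dtype=np.intp),
            pixel_size_um=PX, channel=Channel.total_nuclei, source_field="t",
        )
        objects, _ = segment_nuclei(fused, DetectionParams(min_area_um2=0.0))
        assert len(objects) == 1
        assert objects[0].peak_intensity == 25700

    def test_diameter_unit_interpretation(self):
        """With area_unit set to equivalent diameter, '30 um' bounds the
        equivalent-circle diameter rather than the area."""
        img = np.zeros((64, 64))
        img[20:28, 20:28] = 30000  # 64 px = 169 um^2, eq. diameter ~14.7 um
        p_area = DetectionParams()
        p_diam = DetectionParams(max_area_um2=30.0, min_area_um2=2.0,
                                 area_unit=AreaUnit.equivalent_diameter_um)
        assert len(segment_nuclei(_image(img), p_area)[0]) == 0
        assert len(segment_nuclei(_image(img), p_diam)[0]) == 1

    def test_raising_threshold_never_adds_objects(self):
        img = np.zeros((64, 64))
        for cy, cx in [(10, 10), (30, 40), (50, 20)]:
            img += _gaussian_blob(img.shape, cy, cx, 1.2, 20000)
        counts = [
            len(segment_nuclei(_image(img), DetectionParams(intensity_threshold=t))[0])
            for t in (7000, 10000, 15000, 19000, 25000)
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill_oracle(self, rng, connectivity):
        """Connected components agree with an independent BFS flood fill on
        random boolean rasters."""
        params = DetectionParams(connectivity=connectivity, min_area_um2=0.0,
                                 max_area_um2=1e9)
        for _ in range(100):
            mask = rng.random((24, 24)) < rng.uniform(0.05, 0.5)
            _, overlay = segment_nuclei(_image(mask * 20000), params)
            oracle = flood_fill_label(mask, connectivity)
            assert components_as_sets(overlay.accepted_labels) == components_as_sets(oracle)

    def test_centroids_in_physical_units(self):
        img = np.zeros((32, 32))
        img[10, 12] = 20000
        img[10, 13] = 20000
        objects, _ = segment_nuclei(_image(img), DetectionParams(min_area_um2=0.0))
        (obj,) = objects
        assert obj.centroid_xy_um == pytest.approx((12.5 * PX, 10 * PX))
        assert obj.area_um2 == pytest.approx(2 * PX**2)


class TestCountField:
    GEOM = FieldGeometry(B=1000, C=1000, D=530)

    def test_counts_accepted_objects(self):
        img = np.zeros((64, 64))
        for cy, cx in [(10, 10), (10, 50), (50, 10), (50, 50)]:
            img += _gaussian_blob(img.shape, cy, cx, 1.2, 20000)
        objects, _ = segment_nuclei(_image(img))
        fc = count_field(objects, self.GEOM, field_id="f1")
        assert fc.n == 4
        assert fc.geometry is self.GEOM

    def test_empty_field(self):
        fc = count_field([], self.GEOM)
        assert fc.n == 0


class TestRenderMask:
    def test_writes_image_and_reconcilable_label_rasters(self, tmp_path):
        img = np.zeros((64, 64))
        for cy, cx in [(10, 10), (10, 50), (50, 10)]:
            img += _gaussian_blob(img.shape, cy, cx, 1.2, 20000)
        img[30:45, 28:45] = 30000  # one oversized reject
        objects, overlay = segment_nuclei(_image(img))
        out = tmp_path / "mask.png"
        render_mask(overlay, out)
        assert out.exists()
        import tifffile

        acc = tifffile.imread(tmp_path / "mask_accepted_labels.tif")
        rej = tifffile.imread(tmp_path / "mask_rejected_labels.tif")
        assert len(np.unique(acc[acc > 0])) == len(objects) == 3
        assert len(np.unique(rej[rej > 0])) == 1
        legend = (tmp_path / "mask_legend.txt").read_text()
        assert "too_large" in legend

    def test_empty_overlay_round_trips(self, tmp_path):
        objects, overlay = segment_nuclei(_image(np.zeros((16, 16))))
        out = tmp_path / "empty.png"
        render_mask(overlay, out)
        assert out.exists()
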