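import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bonegraphcut.imageio import IntensityImage
from bonegraphcut.markers import (
    HORIZONTAL_1X3,
    SQUARE_3X3,
    CorrectionStroke,
    MarkerClass,
    MarkerImage,
    StructuringElement,
    apply_corrections,
    dilate,
    erode,
    load_strokes,
    load_trimap,
    morphological_close,
    morphological_open,
    morphology_markers,
    otsu_threshold,
    save_trimap,
    trimap_from_threshold,
)


def img(rows):
    return IntensityImage(np.array(rows, dtype=np.uint8))


def brute_force_otsu(values):
    """Independent oracle: scan all 256 levels, compute between-class
    variance straight from its definition."""
    vals = values.ravel()
    best_t, best_var = None, -1.0
    for t in range(256):
        lo = vals[vals < t]
        hi = vals[vals >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / vals.size
        w1 = hi.size / vals.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_two_value_image_threshold_strictly_between(self):
        image = img([[10, 200] * 4])
        t = otsu_threshold(image)
        assert 10 < t <= 200
        assert t == brute_force_otsu(image.values)

    def test_threshold_separates_two_values_exactly(self):
        image = img([[10, 10, 200], [200, 10, 200]])
        t = otsu_threshold(image)
        assert ((image.values >= t) == (image.values == 200)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(img([[7, 7], [7, 7]]))

    def test_matches_exhaustive_scan_on_random_images(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            vals = np.concatenate(
                [
                    rng.normal(60, 15, 150).clip(0, 255),
                    rng.normal(190, 20, 100).clip(0, 255),
                ]
            ).astype(np.uint8)
            image = IntensityImage(vals.reshape(10, 25))
            assert otsu_threshold(image) == brute_force_otsu(image.values)

    def test_close_to_skimage_on_bimodal_data(self):
        # independent library cross-check (conventions differ only at ties)
        skfilters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(18)
        vals = np.concatenate(
            [rng.normal(60, 15, 300).clip(0, 255), rng.normal(190, 20, 200).clip(0, 255)]
        ).astype(np.uint8)
        image = IntensityImage(vals.reshape(20, 25))
        t_sk = skfilters.threshold_otsu(image.values, nbins=256)
        assert abs(otsu_threshold(image) - t_sk) <= 2


class TestTrimap:
    def test_zero_margin_marks_every_pixel(self):
        image = img([[10, 200], [90, 150]])
        m = trimap_from_threshold(image, 100, margin=0)
        assert m.count(MarkerClass.UNKNOWN) == 0

    def test_pixel_inside_band_is_unknown(self):
        image = img([[110, 10, 200]])
        m = trimap_from_threshold(image, 100, margin=20)
        assert m.classes[0, 0] == MarkerClass.UNKNOWN
        assert m.classes[0, 1] == MarkerClass.BACKGROUND
        assert m.classes[0, 2] == MarkerClass.OBJECT

    def test_two_value_image_fully_marked_for_valid_margin(self):
        image = img([[10, 200], [10, 200]])
        t = otsu_threshold(image)
        m = trimap_from_threshold(image, t, margin=1)
        assert m.count(MarkerClass.UNKNOWN) == 0
        assert (m.classes[image.values == 200] == MarkerClass.OBJECT).all()
        assert (m.classes[image.values == 10] == MarkerClass.BACKGROUND).all()

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(4)
        image = IntensityImage(rng.integers(0, 256, (8, 8), dtype=np.uint8))
        m = trimap_from_threshold(image, 128, margin=30)
        total = sum(m.count(c) for c in MarkerClass)
        assert total == 64

    def test_excessive_margin_error_names_empty_class(self):
        with pytest.raises(ValueError, match="BACKGROUND"):
            trimap_from_threshold(img([[100, 200]]), 120, margin=50)
        with pytest.raises(ValueError, match="OBJECT"):
            trimap_from_threshold(img([[100, 140]]), 120, margin=50)

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            trimap_from_threshold(img([[0, 255]]), 128, margin=-1)


class TestMorphologyOps:
    def test_erosion_of_ones_by_1x3_clears_boundary_columns(self):
        m = np.ones((4, 5), dtype=bool)
        e = erode(m, HORIZONTAL_1X3)
        expected = np.ones((4, 5), dtype=bool)
        expected[:, 0] = expected[:, -1] = False
        np.testing.assert_array_equal(e, expected)

    def test_hand_computed_5x5_erosion_dilation(self):
        m = np.array(
            [
                [0, 0, 0, 0, 0],
                [0, 1, 1, 1, 0],
                [0, 0, 1, 0, 0],
                [1, 1, 1, 1, 1],
                [0, 0, 0, 0, 0],
            ],
            dtype=bool,
        )
        # erosion by 1x3: keep pixels whose left+right neighbours are set
        e_expected = np.zeros((5, 5), dtype=bool)
        e_expected[1, 2] = True      # run of 3 keeps its centre
        e_expected[3, 1:4] = True    # full row keeps all but border cols
        np.testing.assert_array_equal(erode(m, HORIZONTAL_1X3), e_expected)
        # dilation by 1x3: spread one pixel left and right
        d_expected = np.array(
            [
                [0, 0, 0, 0, 0],
                [1, 1, 1, 1, 1],
                [0, 1, 1, 1, 0],
                [1, 1, 1, 1, 1],
                [0, 0, 0, 0, 0],
            ],
            dtype=bool,
        )
        np.testing.assert_array_equal(dilate(m, HORIZONTAL_1X3), d_expected)

    @settings(max_examples=60, derandomize=True)
    @given(hnp.arrays(bool, (6, 7)))
    def test_opening_anti_extensive_and_idempotent(self, m):
        opened = morphological_open(m, HORIZONTAL_1X3)
        assert (opened <= m).all()
        np.testing.assert_array_equal(morphological_open(opened, HORIZONTAL_1X3), opened)

    def test_opening_removes_isolated_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert not morphological_open(m, HORIZONTAL_1X3).any()

    def test_opening_preserves_horizontal_run_of_three(self):
        m = np.zeros((3, 5), dtype=bool)
        m[1, 1:4] = True
        np.testing.assert_array_equal(morphological_open(m, HORIZONTAL_1X3), m)

    def test_opening_removes_vertical_run(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 2] = True
        assert not morphological_open(m, HORIZONTAL_1X3).any()

    def test_closing_fills_horizontal_gap(self):
        m = np.zeros((3, 7), dtype=bool)
        m[1, 1:3] = m[1, 4:6] = True
        closed = morphological_close(m, HORIZONTAL_1X3)
        assert closed[1, 3]  # the one-pixel gap is bridged
        assert (closed >= m).all()  # extensive

    def test_invalid_structuring_element(self):
        with pytest.raises(ValueError, match="anchor"):
            StructuringElement(shape=((1, 1, 1),), anchor=(0, 5))
        with pytest.raises(ValueError, match="non-empty"):
            StructuringElement(shape=((0, 0),), anchor=(0, 0))


class TestMorphologyMarkers:
    def test_toy_block_pipeline_by_hand(self):
        # 7x7: bright 3x5 block rows 2-4, cols 1-5 on dark field
        values = np.full((7, 7), 10, dtype=np.uint8)
        values[2:5, 1:6] = 200
        m = morphology_markers(IntensityImage(values))
        obj = m.classes == MarkerClass.OBJECT
        bkg = m.classes == MarkerClass.BACKGROUND
        unk = m.classes == MarkerClass.UNKNOWN
        # opening preserves the block exactly (width 5 >= 3)
        block = np.zeros((7, 7), dtype=bool)
        block[2:5, 1:6] = True
        np.testing.assert_array_equal(obj, block)
        # background = outside the block's 3x3 dilation (rows 1-5, cols 0-6)
        far = np.ones((7, 7), dtype=bool)
        far[1:6, 0:7] = False
        np.testing.assert_array_equal(bkg, far)
        # unknown = the one-pixel rim
        np.testing.assert_array_equal(unk, ~(block | far))

    def test_block_of_width_two_is_erased_and_raises(self):
        values = np.full((7, 7), 10, dtype=np.uint8)
        values[2:5, 3:5] = 200  # width 2 < structuring element
        with pytest.raises(ValueError, match="opening"):
            morphology_markers(IntensityImage(values))

    def test_salt_noise_absent_from_object_marks(self):
        values = np.full((9, 12), 10, dtype=np.uint8)
        values[3:6, 2:9] = 200  # wide block
        for r, c in [(0, 0), (1, 10), (7, 4), (8, 11)]:  # isolated bright pixels
            values[r, c] = 220
        m = morphology_markers(IntensityImage(values))
        obj = m.classes == MarkerClass.OBJECT
        for r, c in [(0, 0), (1, 10), (7, 4), (8, 11)]:
            assert not obj[r, c]
        assert obj[4, 5]

    def test_object_marks_subset_of_threshold_foreground(self):
        rng = np.random.default_rng(23)
        values = np.full((20, 20), 60, dtype=np.uint8)
        values[5:15, 4:16] = 200
        values = np.clip(
            values.astype(int) + rng.normal(0, 15, (20, 20)), 0, 255
        ).astype(np.uint8)
        image = IntensityImage(values)
        t = otsu_threshold(image)
        m = morphology_markers(image)
        obj = m.classes == MarkerClass.OBJECT
        bkg = m.classes == MarkerClass.BACKGROUND
        assert (obj <= (image.values >= t)).all()
        # background marks keep a clear pixel of distance from the opened marks
        opened_dilated = dilate(
            morphological_open(image.values >= t, HORIZONTAL_1X3), SQUARE_3X3
        )
        assert not (bkg & opened_dilated).any()


class TestCorrections:
    def make_markers(self):
        return MarkerImage(np.full((4, 4), MarkerClass.UNKNOWN, dtype=np.uint8))

    def test_empty_stroke_list_is_identity(self):
        m = self.make_markers()
        out = apply_corrections(m, [])
        np.testing.assert_array_equal(out.classes, m.classes)
        assert out is not m

    def test_stroke_overrides_unknown(self):
        out = apply_corrections(
            self.make_markers(),
            [CorrectionStroke([(1, 2)], MarkerClass.OBJECT)],
        )
        assert out.classes[1, 2] == MarkerClass.OBJECT

    def test_later_stroke_wins(self):
        out = apply_corrections(
            self.make_markers(),
            [
                CorrectionStroke([(0, 0)], MarkerClass.OBJECT),
                CorrectionStroke([(0, 0)], MarkerClass.BACKGROUND),
            ],
        )
        assert out.classes[0, 0] == MarkerClass.BACKGROUND

    def test_out_of_bounds_stroke_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            apply_corrections(
                self.make_markers(), [CorrectionStroke([(9, 9)], MarkerClass.OBJECT)]
            )


class TestMarkerIO:
    def test_trimap_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        m = MarkerImage(rng.integers(0, 3, (6, 6)).astype(np.uint8))
        save_trimap(m, tmp_path / "t.png")
        back = load_trimap(tmp_path / "t.png")
        np.testing.assert_array_equal(back.classes, m.classes)

    def test_stroke_file_parsing(self, tmp_path):
        (tmp_path / "s.txt").write_text("# comment\n1 2 object\n3 4 background\n")
        strokes = load_strokes(tmp_path / "s.txt")
        assert strokes[0].pixels == ((1, 2),)
        assert strokes[0].assigned_class == MarkerClass.OBJECT
        assert strokes[1].assigned_class == MarkerClass.BACKGROUND

    def test_bad_stroke_class_rejected(self, tmp_path):
        (tmp_path / "s.txt").write_text("1 2 froreground\n")
        with pytest.raises(ValueError, match="class"):
            load_strokes(tmp_path / "s.txt")
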