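import numpy as np
import pytest

from colonyquant import thresholding as th
from colonyquant.errors import ValidationError
from colonyquant.geometry import WellImage

from conftest import make_well


class TestAreaThresholdCurve:
    def test_all_white_well(self):
        c = th.area_threshold_curve(make_well([255] * 100))
        assert (c.A[:255] == 0).all()
        assert c.A[255] == 100

    def test_half_black_half_white(self):
        c = th.area_threshold_curve(make_well([0] * 50 + [255] * 50))
        assert c.A[0] == 50
        assert c.A[254] == 50
        assert c.A[255] == 100

    def test_matches_brute_force_cumulative_histogram(self):
        vals = [3, 3, 7, 100, 100, 100, 200, 254, 255, 255]
        c = th.area_threshold_curve(make_well(vals))
        for t in range(256):
            expected = 100.0 * sum(v <= t for v in vals) / len(vals)
            assert c.A[t] == pytest.approx(expected)

    def test_invariants(self, bimodal_well):
        well, _, _ = bimodal_well
        c = th.area_threshold_curve(well)
        assert (np.diff(c.A) >= 0).all()
        assert c.A[255] == pytest.approx(100.0)
        assert (c.dA >= 0).all()
        assert c.dA.sum() == pytest.approx(100.0)

    def test_derivative_scheme_is_backward_difference(self, bimodal_well):
        well, _, _ = bimodal_well
        c = th.area_threshold_curve(well)
        assert c.dA[0] == c.A[0]
        assert c.dA[1:] == pytest.approx(np.diff(c.A))
        assert c.d2A[0] == c.dA[0]
        assert c.d2A[1:] == pytest.approx(np.diff(c.dA))

    def test_outside_mask_pixels_ignored(self):
        # junk value 37 outside the mask must not contribute
        c = th.area_threshold_curve(make_well([200] * 64))
        assert c.A[37] == 0

    def test_empty_mask_rejected(self):
        w = WellImage("E1", np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))
        with pytest.raises(ValidationError):
            th.area_threshold_curve(w)


class TestDetectThreshold:
    def test_bimodal_uniform_ranges(self, bimodal_well):
        """Valley lands in the empty gap; area at the threshold is exact."""
        well, ncell, n = bimodal_well
        res = th.detect_threshold(th.area_threshold_curve(well))
        assert 100 <= res.threshold < 200
        c = th.area_threshold_curve(well)
        assert c.A[res.threshold] == pytest.approx(100 * ncell / n)
        assert res.method == "auto"

    def test_two_spikes(self):
        res = th.detect_threshold(
            th.area_threshold_curve(make_well([50] * 500 + [250] * 500))
        )
        assert 50 <= res.threshold < 250
        c = th.area_threshold_curve(make_well([50] * 500 + [250] * 500))
        assert c.A[res.threshold] == pytest.approx(50.0)

    def test_constant_well_is_no_colonies(self):
        res = th.detect_threshold(th.area_threshold_curve(make_well([220] * 400)))
        assert res.method == "no_colonies"
        c = th.area_threshold_curve(make_well([220] * 400))
        assert c.A[res.threshold] == 0

    def test_exhaustive_scan_equivalence(self):
        """Detected threshold falls in the brute-force-validated window.

        The oracle enumerates all 256 candidate thresholds and keeps those
        that classify the two disjoint ranges perfectly.
        """
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.integers(40, 81, 900), rng.integers(160, 231, 2100)]
        )
        well = make_well(vals)
        res = th.detect_threshold(th.area_threshold_curve(well))
        cells = vals[:900]
        bg = vals[900:]
        valid = [
            t
            for t in range(256)
            if (cells <= t).all() and not (bg <= t).any()
        ]
        assert res.threshold in valid

    @pytest.mark.parametrize("s", [1.0, 0.8, 0.5, 0.3])
    def test_scale_invariance_within_rounding(self, s):
        rng = np.random.default_rng(11)
        vals = np.concatenate(
            [rng.integers(60, 101, 1200), rng.integers(200, 241, 2800)]
        )
        base = th.detect_threshold(th.area_threshold_curve(make_well(vals)))
        scaled_vals = np.floor(vals * s + 0.5).astype(np.uint8)
        scaled = th.detect_threshold(th.area_threshold_curve(make_well(scaled_vals)))
        assert abs(scaled.threshold - s * base.threshold) <= 2

    def test_scaled_threshold_uses_max_intensity(self, bimodal_well):
        well, _, _ = bimodal_well
        res = th.detect_threshold(th.area_threshold_curve(well))
        max_int = int(well.masked_values.max())
        assert res.max_intensity == max_int
        assert res.scaled_threshold == pytest.approx(res.threshold * 200 / max_int)

    def test_restricted_search_range(self):
        vals = np.concatenate(
            [np.full(300, 60), np.full(500, 150), np.full(1200, 230)]
        )
        # full-range analysis separates at the 150/230 gap ...
        full = th.detect_threshold(th.area_threshold_curve(make_well(vals)))
        assert 150 <= full.threshold < 230
        # ... a window around the middle mode separates at the 60/150 gap
        win = th.detect_threshold(
            th.area_threshold_curve(make_well(vals)), search_range=(100, 200)
        )
        assert 60 <= win.threshold < 150


class TestHarmonize:
    @staticmethod
    def _res(t, max_int=200, method="auto"):
        return th.ThresholdResult(
            threshold=t,
            scaled_threshold=t * 200 / max_int,
            max_intensity=max_int,
            method=method,
        )

    def _wells_and_results(self):
        """Three wells whose max intensity is 200 (scaled == native).

        The third carries a deliberately wrong initial threshold of 180;
        its histogram has cells at [40, 60] and background modes at
        [140, 160] and [190, 200], so the restricted window finds the
        valley below the 150 mode.
        """
        rng = np.random.default_rng(5)

        def tri(ncell):
            v = np.concatenate(
                [
                    rng.integers(40, 61, ncell),
                    rng.integers(140, 161, 1500),
                    rng.integers(190, 201, 1500),
                ]
            )
            v[-1] = 200  # pin the maximum
            return make_well(v)

        wells = [tri(600), tri(700), tri(650)]
        initial = [self._res(100), self._res(105), self._res(180)]
        return wells, initial

    def test_worked_example_flags_only_the_outlier(self):
        """Scaled thresholds [100, 105, 180] at tolerance 50: mean 128.33,
        so only |180 - 128.33| = 51.67 exceeds the tolerance."""
        wells, initial = self._wells_and_results()
        out = th.harmonize_thresholds(wells, initial, tolerance=50)
        assert [r.flagged for r in out] == [False, False, True]
        assert out[0].threshold == 100 and out[1].threshold == 105
        assert out[2].method == "restricted"
        # re-evaluated threshold lies inside the mean +/- 50 window
        assert 78 <= out[2].threshold <= 178

    def test_no_flags_when_consistent(self):
        wells, _ = self._wells_and_results()
        initial = [self._res(100), self._res(105), self._res(110)]
        out = th.harmonize_thresholds(wells, initial, tolerance=50)
        assert out == initial

    def test_single_well_passes_through(self):
        wells, initial = self._wells_and_results()
        out = th.harmonize_thresholds(wells[:1], initial[:1])
        assert out == initial[:1]

    def test_idempotent(self):
        wells, initial = self._wells_and_results()
        once = th.harmonize_thresholds(wells, initial, tolerance=50)
        twice = th.harmonize_thresholds(wells, once, tolerance=50)
        assert twice == once

    def test_no_colonies_wells_excluded_from_mean(self):
        wells, _ = self._wells_and_results()
        initial = [
            self._res(100),
            self._res(105),
            self._res(219, method="no_colonies"),
        ]
        out = th.harmonize_thresholds(wells, initial, tolerance=50)
        # mean over the two colony wells is 102.5; nothing deviates > 50
        assert [r.flagged for r in out] == [False, False, False]
        assert out[2].method == "no_colonies"

    def test_misaligned_inputs_rejected(self):
        wells, initial = self._wells_and_results()
        with pytest.raises(ValidationError):
            th.harmonize_thresholds(wells, initial[:2])


class TestApplyThresholdInvert:
    @pytest.mark.parametrize(
        "pixel, threshold, density",
        [(80, 150, 175), (200, 150, 0), (150, 150, 105), (0, 0, 255), (254, 254, 1)],
    )
    def test_inversion_rule(self, pixel, threshold, density):
        well = make_well([pixel] * 10)
        tw = th.apply_threshold_invert(well, threshold)
        assert tw.density[well.mask][0] == density

    def test_cell_densities_at_least_one(self, bimodal_well):
        well, _, _ = bimodal_well
        tw = th.apply_threshold_invert(well, 150)
        cells = tw.density[tw.mask & (tw.density > 0)]
        assert cells.min() >= 1

    def test_outside_mask_is_zero(self):
        well = make_well([40] * 10)  # junk 37 outside the mask is below 150
        tw = th.apply_threshold_invert(well, 150)
        assert tw.density[~well.mask].max() == 0

    def test_threshold_255_rejected(self):
        with pytest.raises(ValidationError):
            th.apply_threshold_invert(make_well([10] * 4), 255)


class TestManualThreshold:
    def test_uniform_manual(self):
        wells = [make_well([80] * 20, well_id=f"A{i}") for i in (1, 2, 3)]
        tws, results = th.manual_threshold(wells, 120)
        assert [r.method for r in results] == ["manual"] * 3
        assert all((tw.density[tw.mask] == 175).all() for tw in tws)

    def test_map_missing_well_rejected(self):
        wells = [make_well([80] * 20, well_id="A1"), make_well([80] * 20, well_id="A2")]
        with pytest.raises(ValidationError, match="A2"):
            th.manual_threshold(wells, {"A1": 120})

    def test_manual_matches_auto_at_same_threshold(self, bimodal_well):
        well, _, _ = bimodal_well
        auto = th.detect_threshold(th.area_threshold_curve(well))
        tws, _ = th.manual_threshold([well], auto.threshold)
        direct = th.apply_threshold_invert(well, auto.threshold)
        assert (tws[0].density == direct.density).all()
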