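import numpy as np
import pytest

from conftest import dtw_reference, lorentzian_spectrum
from rxntriage.nmrproc import (
    NmrConfigError,
    NmrSpectrum,
    apply_line_broadening,
    chemical_change,
    combine_references,
    dtw_distance,
    guest_binding_test,
    parity_check,
    pick_peaks,
    preprocess,
    symmetric_product_test,
)


class TestPreprocess:
    def test_idempotent_on_gridded_normalized_input(self):
        spec = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        again = preprocess(spec)
        assert np.allclose(spec.intensity, again.intensity)
        assert np.allclose(spec.ppm, again.ppm)

    def test_scale_invariance(self):
        raw = lorentzian_spectrum([(3.0, 1.0, 2.0), (7.0, 0.5, 2.0)])
        scaled = NmrSpectrum(raw.ppm, 10.0 * raw.intensity, raw.field_mhz)
        assert np.allclose(preprocess(raw).intensity, preprocess(scaled).intensity)

    def test_masked_region_zeroed(self):
        raw = lorentzian_spectrum([(3.3, 1.0, 2.0)], masked=[(3.2, 3.4)])
        out = preprocess(raw)
        sel = (out.ppm >= 3.2) & (out.ppm <= 3.4)
        assert np.all(out.intensity[sel] == 0)

    def test_grid_outside_range_rejected(self):
        raw = lorentzian_spectrum([(3.0, 1.0, 2.0)], lo=1.0, hi=9.0)
        with pytest.raises(ValueError, match="outside source range"):
            preprocess(raw, grid=np.linspace(0, 12, 100))

    def test_area_normalization(self):
        out = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]), normalization="area")
        step = np.mean(np.diff(out.ppm))
        assert np.sum(np.abs(out.intensity)) * step == pytest.approx(1.0)


class TestCombineReferences:
    def test_single_spectrum_identity(self):
        a = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        out = combine_references([a])
        assert np.allclose(out.intensity, a.intensity)

    def test_disjoint_peaks_union(self):
        a = preprocess(lorentzian_spectrum([(2.0, 1.0, 2.0)]))
        b = preprocess(lorentzian_spectrum([(8.0, 1.0, 2.0)]))
        out = combine_references([a, b])
        assert len(pick_peaks(out, smooth_hz=0)) == 2

    def test_zero_weight_drops_spectrum(self):
        a = preprocess(lorentzian_spectrum([(2.0, 1.0, 2.0)]))
        b = preprocess(lorentzian_spectrum([(8.0, 1.0, 2.0)]))
        out = combine_references([a, b], weights=[1.0, 0.0])
        assert np.allclose(out.intensity, a.intensity)

    def test_mismatched_grids_rejected(self):
        a = preprocess(lorentzian_spectrum([(2.0, 1.0, 2.0)]))
        b = lorentzian_spectrum([(8.0, 1.0, 2.0)], step=0.004)
        with pytest.raises(ValueError, match="common grid"):
            combine_references([a, b])


class TestDtw:
    def test_identical_spectra_zero_distance(self):
        a = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0), (7.2, 0.6, 2.0)]))
        res = dtw_distance(a, a)
        assert res.distance == 0.0
        assert res.normalized_distance == 0.0

    def test_single_point_sequences(self):
        res = dtw_distance(np.array([2.0]), np.array([5.0]))
        assert res.distance == pytest.approx(3.0)
        assert res.path_length == 1

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(120), rng.random(120)
        assert dtw_distance(a, b).distance == pytest.approx(dtw_distance(b, a).distance)

    def test_band_dominates_unconstrained(self):
        rng = np.random.default_rng(11)
        a, b = rng.random(80), rng.random(80)
        wide = dtw_distance(a, b, band=80).distance
        narrow = dtw_distance(a, b, band=3).distance
        assert narrow >= wide - 1e-12

    def test_matches_reference_dp_on_small_sequences(self):
        rng = np.random.default_rng(3)
        for n in (5, 17, 50):
            a, b = rng.random(n), rng.random(n)
            got = dtw_distance(a, b, band=n).distance
            assert got == pytest.approx(dtw_reference(a, b), abs=1e-12)

    def test_distance_nondecreasing_with_peak_shift(self):
        # a singlet displaced beyond the warping band costs more the further it moves
        base = preprocess(lorentzian_spectrum([(4.0, 1.0, 8.0)]))
        dists = []
        for delta in (0.0, 0.6, 1.5):
            moved = preprocess(lorentzian_spectrum([(4.0 + delta, 1.0, 8.0)]))
            dists.append(dtw_distance(base, moved, band=25).normalized_distance)
        assert dists[0] <= dists[1] <= dists[2]
        assert dists[2] > dists[0]


class TestChangeAndParity:
    def test_no_change_for_identical_inputs(self):
        a = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        changed, res = chemical_change(a, a, threshold=1e-9)
        assert not changed and res.distance == 0.0

    def test_disjoint_peaks_flag_change(self):
        a = preprocess(lorentzian_spectrum([(2.0, 1.0, 8.0)]))
        b = preprocess(lorentzian_spectrum([(8.0, 1.0, 8.0)]))
        changed, res = chemical_change(a, b)
        assert changed
        assert res.normalized_distance > 0

    def test_infinite_threshold_never_fires(self):
        a = preprocess(lorentzian_spectrum([(2.0, 1.0, 8.0)]))
        b = preprocess(lorentzian_spectrum([(8.0, 1.0, 8.0)]))
        changed, _ = chemical_change(a, b, threshold=np.inf)
        assert not changed

    def test_parity_for_identical_spectra(self):
        a = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        ok, _ = parity_check(a, a)
        assert ok

    def test_large_extra_peak_breaks_parity(self):
        # a substantial new resonance (broad impurity hump) breaks scale-up parity
        screen = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        scaleup = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0), (7.5, 1.0, 16.0)]))
        ok, res = parity_check(screen, scaleup)
        assert not ok
        assert res.normalized_distance > 0

    def test_threshold_ordering_enforced(self):
        a = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        with pytest.raises(NmrConfigError):
            parity_check(a, a, parity_threshold=0.02, change_threshold=0.02)


class TestPeakPicking:
    def test_recovers_well_separated_peaks(self):
        positions = [1.5, 3.0, 5.0, 7.4, 9.1]
        spec = preprocess(lorentzian_spectrum([(p, 1.0, 2.0) for p in positions]))
        peaks = pick_peaks(spec)
        assert len(peaks) == 5
        assert np.allclose(peaks.positions, positions, atol=0.01)

    def test_flat_spectrum_has_no_peaks(self):
        grid = np.linspace(0, 12, 1000)
        spec = NmrSpectrum(grid, np.zeros_like(grid))
        assert len(pick_peaks(spec)) == 0

    def test_close_peaks_merge(self):
        spec = preprocess(
            lorentzian_spectrum([(4.00, 1.0, 2.0), (4.01, 0.9, 2.0)])
        )
        assert len(pick_peaks(spec, min_separation=0.05)) == 1

    def test_masked_peaks_excluded(self):
        spec = preprocess(
            lorentzian_spectrum([(3.3, 1.0, 2.0), (7.0, 1.0, 2.0)], masked=[(3.2, 3.4)])
        )
        peaks = pick_peaks(spec)
        assert np.allclose(peaks.positions, [7.0], atol=0.01)


class TestSymmetricProductTest:
    def _peaks(self, positions):
        spec = preprocess(lorentzian_spectrum([(p, 1.0, 2.0) for p in positions]))
        return pick_peaks(spec)

    def test_shifted_full_count_passes(self):
        sm = [self._peaks([1.0, 2.0, 3.0, 4.0]), self._peaks([6.0, 7.0, 8.0])]
        rxn = self._peaks([1.3, 2.3, 3.3, 4.3, 6.3, 7.3, 8.3])
        assert symmetric_product_test(rxn, sm)

    def test_oligomer_peak_forest_fails(self):
        sm = [self._peaks([1.0, 2.0, 3.0, 4.0]), self._peaks([6.0, 7.0, 8.0])]
        rxn = self._peaks(list(np.linspace(0.5, 9.5, 15)))
        assert not symmetric_product_test(rxn, sm)

    def test_unshifted_starting_materials_fail(self):
        sm = [self._peaks([1.0, 2.0, 3.0, 4.0]), self._peaks([6.0, 7.0, 8.0])]
        rxn = self._peaks([1.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0])
        assert not symmetric_product_test(rxn, sm)


class TestLineBroadening:
    def test_zero_broadening_is_identity(self):
        spec = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        out = apply_line_broadening(spec, 0.0)
        assert np.allclose(out.intensity, spec.intensity)

    def test_negative_broadening_rejected(self):
        spec = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0)]))
        with pytest.raises(ValueError):
            apply_line_broadening(spec, -1.0)

    def test_total_area_preserved(self):
        spec = preprocess(lorentzian_spectrum([(3.0, 1.0, 2.0), (6.5, 0.7, 2.0)]))
        for lb in (2.0, 10.0, 25.0):
            out = apply_line_broadening(spec, lb)
            assert np.sum(out.intensity) == pytest.approx(np.sum(spec.intensity), rel=1e-6)

    def test_heavy_broadening_merges_close_peaks(self):
        # 0.05 ppm apart = 4 Hz at 80 MHz; 20 Hz broadening swallows the gap
        spec = preprocess(lorentzian_spectrum([(4.00, 1.0, 2.0), (4.05, 1.0, 2.0)]))
        assert len(pick_peaks(spec, smooth_hz=0)) == 2
        broad = apply_line_broadening(spec, 20.0)
        assert len(pick_peaks(broad, smooth_hz=0)) == 1

    def test_broadening_approximately_composes(self):
        # Lorentzian kernels convolve to a Lorentzian of summed width
        spec = preprocess(lorentzian_spectrum([(5.0, 1.0, 4.0)]))
        twice = apply_line_broadening(apply_line_broadening(spec, 6.0), 4.0)
        once = apply_line_broadening(spec, 10.0)
        num = np.sum(np.abs(twice.intensity - once.intensity))
        den = np.sum(np.abs(once.intensity))
        assert num / den < 0.01


class TestGuestBinding:
    def test_identical_spectra_not_bound(self):
        host = preprocess(lorentzian_spectrum([(7.2, 1.0, 2.0), (8.1, 0.8, 2.0)]))
        bound, report = guest_binding_test(host, host)
        assert not bound
        assert all(r["delta_ppm"] == pytest.approx(0.0, abs=1e-9) for r in report)

    def test_aromatic_shift_detected(self):
        host = preprocess(lorentzian_spectrum([(7.2, 1.0, 2.0), (8.1, 0.8, 2.0)]))
        moved = preprocess(lorentzian_spectrum([(7.25, 1.0, 2.0), (8.1, 0.8, 2.0)]))
        bound, _ = guest_binding_test(host, moved, shift_min=0.02)
        assert bound

    def test_aliphatic_shift_ignored(self):
        host = preprocess(lorentzian_spectrum([(1.2, 1.0, 2.0), (7.2, 1.0, 2.0)]))
        moved = preprocess(lorentzian_spectrum([(1.45, 1.0, 2.0), (7.2, 1.0, 2.0)]))
        bound, _ = guest_binding_test(host, moved, shift_min=0.02)
        assert not bound

    def test_empty_window_rejected(self):
        host = preprocess(lorentzian_spectrum([(7.2, 1.0, 2.0)]))
        with pytest.raises(ValueError, match="window"):
            guest_binding_test(host, host, window=(9.5, 6.0))
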