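import numpy as np
import pytest

from scamp import (
    FractionSet,
    FractionSpectrum,
    Peak,
    average_blanks,
    bin_across_fractions,
    count_unit_bins,
    deisotope,
    filter_snr,
    subtract_blank,
)
from scamp.chem_mass import C13_DELTA


class TestAverageBlanks:
    def test_single_blank_is_identity(self):
        blank = FractionSpectrum(1, [Peak(200.0, 300.0)])
        avg = average_blanks([blank])
        assert [(p.mz, p.intensity) for p in avg.peaks] == [(200.0, 300.0)]

    def test_mean_of_two(self):
        blanks = [FractionSpectrum(1, [Peak(200.0, 300.0)]),
                  FractionSpectrum(1, [Peak(200.0, 100.0)])]
        avg = average_blanks(blanks)
        assert avg.peaks[0].intensity == pytest.approx(200.0)

    def test_absent_replicates_count_as_zero(self):
        blanks = [FractionSpectrum(1, [Peak(500.0, 900.0)]),
                  FractionSpectrum(1, []),
                  FractionSpectrum(1, [])]
        avg = average_blanks(blanks)
        assert avg.peaks[0].intensity == pytest.approx(300.0)

    def test_requires_input(self):
        with pytest.raises(ValueError):
            average_blanks([])


class TestSubtractBlank:
    def test_matched_peak_removed(self):
        sample = FractionSpectrum(1, [Peak(200.00000, 500.0)])
        blank = FractionSpectrum(1, [Peak(200.00005, 400.0)])
        out = subtract_blank(sample, blank, tol_ppm=1.0, ratio=3.0)
        assert len(out) == 0

    def test_strong_signal_survives_trace_blank(self):
        sample = FractionSpectrum(1, [Peak(200.00000, 5000.0)])
        blank = FractionSpectrum(1, [Peak(200.00005, 400.0)])
        out = subtract_blank(sample, blank, tol_ppm=1.0, ratio=3.0)
        assert len(out) == 1

    def test_infinite_ratio_removes_on_mass_alone(self):
        sample = FractionSpectrum(1, [Peak(200.00000, 5e9)])
        blank = FractionSpectrum(1, [Peak(200.00005, 1.0)])
        out = subtract_blank(sample, blank, tol_ppm=1.0, ratio=float("inf"))
        assert len(out) == 0

    def test_no_blank_within_tolerance_keeps_peak(self):
        sample = FractionSpectrum(1, [Peak(200.0, 500.0)])
        blank = FractionSpectrum(1, [Peak(200.01, 400.0)])  # 50 ppm away
        assert len(subtract_blank(sample, blank, 1.0, 3.0)) == 1

    def test_empty_blank_is_identity(self):
        sample = FractionSpectrum(1, [Peak(200.0, 500.0)])
        out = subtract_blank(sample, FractionSpectrum(1, []), 1.0, 3.0)
        assert [(p.mz, p.intensity) for p in out.peaks] == [(200.0, 500.0)]


class TestFilterSnr:
    def test_strictly_greater(self):
        spec = FractionSpectrum(1, [Peak(100.0, 1.0, 3.0), Peak(101.0, 1.0, 4.0),
                                    Peak(102.0, 1.0, 5.0)])
        out = filter_snr(spec, 4.0)
        assert [p.snr for p in out.peaks] == [5.0]

    def test_missing_snr_kept(self):
        spec = FractionSpectrum(1, [Peak(100.0, 1.0), Peak(101.0, 1.0, 1.0)])
        out = filter_snr(spec, 4.0)
        assert [p.mz for p in out.peaks] == [100.0]

    def test_survivor_count_matches_brute_force(self, rng):
        snrs = rng.uniform(0, 10, 1000)
        spec = FractionSpectrum(1, [
            Peak(float(m), 1.0, float(s))
            for m, s in zip(np.sort(rng.uniform(120, 1200, 1000)), snrs)
        ])
        out = filter_snr(spec, 4.0)
        assert len(out) == int((snrs > 4.0).sum())


class TestDeisotope:
    def test_quercetin_like_satellites_removed(self):
        spec = FractionSpectrum(1, [Peak(301.03538, 100.0),
                                    Peak(302.03873, 16.5),
                                    Peak(303.04209, 1.9)])
        out = deisotope(spec, tol_ppm=1.0, max_shift=3)
        assert [(p.mz, p.intensity) for p in out.peaks] == [(301.03538, 100.0)]

    def test_single_peak_unchanged(self):
        spec = FractionSpectrum(1, [Peak(301.03538, 100.0)])
        assert len(deisotope(spec)) == 1

    def test_non_isotopic_spacing_untouched(self):
        spec = FractionSpectrum(1, [Peak(300.0, 100.0), Peak(300.5, 50.0)])
        assert len(deisotope(spec)) == 2

    def test_more_intense_satellite_position_not_removed(self):
        # a peak at the +1 position that is MORE intense is a distinct species
        spec = FractionSpectrum(1, [Peak(301.03538, 100.0),
                                    Peak(301.03538 + C13_DELTA, 200.0)])
        assert len(deisotope(spec)) == 2

    def test_removed_satellite_cannot_shelter_its_own(self):
        # chain A -> A+1 -> A+2: A+2 lies within tolerance of (A+1)+1 only;
        # since A+1 is removed by A, A+2 must still be removed via A's +2 test
        base = 400.0
        spec = FractionSpectrum(1, [Peak(base, 100.0),
                                    Peak(base + C13_DELTA, 30.0),
                                    Peak(base + 2 * C13_DELTA, 5.0)])
        out = deisotope(spec, tol_ppm=1.0, max_shift=3)
        assert len(out) == 1

    def test_idempotent(self, rng):
        mzs = np.sort(rng.uniform(120, 1200, 200))
        spec = FractionSpectrum(1, [
            Peak(float(m), float(i))
            for m, i in zip(mzs, rng.uniform(1, 1e5, 200))
        ])
        once = deisotope(spec)
        twice = deisotope(once)
        assert [(p.mz, p.intensity) for p in once.peaks] == \
               [(p.mz, p.intensity) for p in twice.peaks]

    def test_never_removes_most_intense_peak(self, rng):
        spec = FractionSpectrum(1, [
            Peak(float(m), float(i))
            for m, i in zip(rng.uniform(120, 1200, 300),
                            rng.uniform(1, 1e6, 300))
        ])
        top = max(spec.peaks, key=lambda p: p.intensity)
        out = deisotope(spec)
        assert any(p.mz == top.mz for p in out.peaks)
        assert len(out) <= len(spec)


class TestBinning:
    def test_close_peaks_share_a_bin(self):
        fset = FractionSet([
            FractionSpectrum(1, [Peak(301.03538, 100.0)]),
            FractionSpectrum(2, [Peak(301.03540, 60.0)]),  # 0.07 ppm apart
        ])
        m = bin_across_fractions(fset, bin_ppm=0.5)
        assert m.n_bins == 1
        assert np.allclose(m.intensities[0], [100.0, 60.0])

    def test_distant_peaks_split(self):
        fset = FractionSet([
            FractionSpectrum(1, [Peak(301.0354, 100.0)]),
            FractionSpectrum(2, [Peak(301.0360, 60.0)]),  # ~2 ppm apart
        ])
        assert bin_across_fractions(fset, bin_ppm=0.5).n_bins == 2

    def test_same_fraction_intensities_summed(self):
        fset = FractionSet([
            FractionSpectrum(1, [Peak(500.00000, 100.0), Peak(500.00002, 50.0)]),
        ])
        m = bin_across_fractions(fset, bin_ppm=0.5)
        assert m.n_bins == 1
        assert m.intensities[0, 0] == pytest.approx(150.0)

    def test_total_intensity_conserved(self, rng):
        fset = FractionSet([
            FractionSpectrum(k, [
                Peak(float(m), float(i))
                for m, i in zip(rng.uniform(120, 1200, 150),
                                rng.uniform(1, 1e5, 150))
            ])
            for k in range(1, 6)
        ])
        m = bin_across_fractions(fset, bin_ppm=0.5)
        total_in = sum(p.intensity for spec in fset for p in spec.peaks)
        assert m.intensities.sum() == pytest.approx(total_in, rel=1e-12)

    def test_members_within_tolerance_of_centroid(self, rng):
        mz0 = 600.0
        offsets = rng.uniform(-1e-4, 1e-4, 20)  # within +-0.17 ppm
        fset = FractionSet([
            FractionSpectrum(1, [Peak(mz0 + float(o), float(i))
                                 for o, i in zip(offsets,
                                                 rng.uniform(1, 100, 20))]),
        ])
        m = bin_across_fractions(fset, bin_ppm=0.5)
        assert m.n_bins == 1
        for o in offsets:
            assert abs(mz0 + o - m.bin_centers[0]) / m.bin_centers[0] * 1e6 <= 0.5

    def test_input_order_invariance(self, rng):
        peaks = [(float(m), float(i))
                 for m, i in zip(rng.uniform(120, 1200, 100),
                                 rng.uniform(1, 1e5, 100))]
        fwd = FractionSet([FractionSpectrum(1, [Peak(m, i) for m, i in peaks])])
        rev = FractionSet([FractionSpectrum(1, [Peak(m, i)
                                                for m, i in reversed(peaks)])])
        a = bin_across_fractions(fwd, 0.5)
        b = bin_across_fractions(rev, 0.5)
        assert np.allclose(a.bin_centers, b.bin_centers)
        assert np.allclose(a.intensities, b.intensities)


class TestUnitBins:
    @pytest.mark.parametrize("lo, hi, n", [(120, 1200, 1081), (120, 120, 1),
                                           (122, 1200, 1079)])
    def test_counts(self, lo, hi, n):
        assert count_unit_bins(lo, hi) == n

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            count_unit_bins(1200, 120)
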