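"""Peak picking, co-elution filtering, scoring and template propagation."""

import math

import numpy as np
import pytest

import helpers
from conftest import make_scan, make_template
from ria15n import chem, extraction
from ria15n.spectra_io import PeptideTarget


class TestPickPeaks:
    def test_exact_match_picks_all_slots_with_zero_ppm(self):
        template = make_template([500.0, 500.5, 501.0])
        scan = make_scan([500.0, 500.5, 501.0], [100, 50, 10])
        ps = extraction.pick_peaks(scan, template, 10, 20)
        assert ps.slots == [0, 1, 2]
        assert all(p.ppm == 0 for p in ps.peaks)

    def test_missing_gate_peak_empty_even_if_rest_match(self):
        template = make_template([500.0, 500.5, 501.0])
        scan = make_scan([500.5, 501.0], [50, 10])
        ps = extraction.pick_peaks(scan, template, 10, 20)
        assert not ps.peaks

    def test_most_abundant_in_window_wins_over_closest(self):
        template = make_template([500.0])
        # both peaks inside +/-10 ppm of 500; the closer one is weaker
        scan = make_scan([500.0005, 500.003], [5, 9])
        ps = extraction.pick_peaks(scan, template, 10, 20)
        assert ps.peaks[0].intensity == 9

    def test_missing_interior_slot_leaves_no_gap_stop(self):
        template = make_template([500.0, 500.5, 501.0, 501.5])
        scan = make_scan([500.0, 501.0, 501.5], [100, 10, 5])
        ps = extraction.pick_peaks(scan, template, 10, 20)
        assert ps.slots == [0, 2, 3]

    def test_separate_tolerances_for_gate_and_isotopes(self):
        template = make_template([500.0, 500.5])
        # gate deviates 15 ppm (outside 10), isotope deviates 15 ppm (inside 20)
        scan = make_scan([500.0075, 500.5075], [100, 50])
        assert not extraction.pick_peaks(scan, template, 10, 20).peaks
        assert extraction.pick_peaks(scan, template, 20, 20).n_picked == 2

    def test_deterministic(self, rng):
        template = make_template(np.sort(rng.uniform(500, 510, 8)))
        scan = make_scan(rng.uniform(499, 511, 200), rng.uniform(1, 1e5, 200))
        a = extraction.pick_peaks(scan, template, 10, 20)
        b = extraction.pick_peaks(scan, template, 10, 20)
        assert a.peaks == b.peaks


class TestCoelutionFilter:
    def run(self, scan, template, ratio=3.0):
        picked = extraction.pick_peaks(scan, template, 10, 20)
        return extraction.coelution_filter(scan, template, picked, ratio, 20)

    def test_ratio_at_or_below_threshold_unchanged(self):
        template = make_template([500.0, 500.5])
        scan = make_scan([500.0, 500.5], [100, 250])
        out = self.run(scan, template)
        assert [p.intensity for p in out.peaks] == [100, 250]

    def test_offender_without_alternative_removed(self):
        template = make_template([500.0, 500.5])
        scan = make_scan([500.0, 500.5], [100, 310])
        out = self.run(scan, template)
        assert out.slots == [0]

    def test_offender_replaced_by_alternative_peak(self):
        template = make_template([500.0, 500.5])
        # second window holds the 310 interferent plus a plausible 120 peak
        scan = make_scan([500.0, 500.4995, 500.5], [100, 120, 310])
        out = self.run(scan, template)
        assert out.slots == [0, 1]
        assert out.peaks[1].intensity == 120

    def test_cascade_removal_at_high_mz_tail(self):
        template = make_template([500.0, 500.5, 501.0])
        # each tail peak > 3x its predecessor: both are stripped in turn
        scan = make_scan([500.0, 500.5, 501.0], [100, 400, 1500])
        out = self.run(scan, template)
        assert out.slots == [0]

    def test_rising_flank_of_labeled_envelope_preserved(self):
        # bimodal partial-labeling shape: natural envelope, valley, rising
        # 15N flank; the steep rise is signal, not interference
        template = make_template([500.0 + 0.5 * k for k in range(8)])
        inten = [1000, 600, 200, 20, 90, 400, 1500, 2500]
        scan = make_scan([500.0 + 0.5 * k for k in range(8)], inten)
        out = self.run(scan, template)
        assert [p.intensity for p in out.peaks] == inten

    def test_interior_spike_removed(self):
        template = make_template([500.0 + 0.5 * k for k in range(5)])
        inten = [1000, 600, 5000, 200, 80]  # 5000 is a co-eluting spike
        scan = make_scan([500.0 + 0.5 * k for k in range(5)], inten)
        out = self.run(scan, template)
        assert [p.intensity for p in out.peaks] == [1000, 600, 200, 80]

    def test_gate_peak_never_removed(self):
        template = make_template([500.0, 500.5])
        scan = make_scan([500.0, 500.5], [1, 2])  # gate tiny but exempt
        out = self.run(scan, template)
        assert out.slots == [0, 1]

    def test_fixed_point_reached_on_random_spectra(self, rng):
        # termination + idempotence: re-applying the filter changes nothing
        for _ in range(25):
            positions = 500.0 + 0.5 * np.arange(10)
            scan = make_scan(positions, rng.uniform(1, 1e4, 10))
            template = make_template(positions)
            once = self.run(scan, template)
            again = extraction.coelution_filter(scan, template, once, 3.0, 20)
            assert again.peaks == once.peaks


class TestPenaltyCheck:
    def build(self, first_int, interferent_int=None):
        mz = [500.0, 500.5]
        inten = [first_int, 200.0]
        if interferent_int is not None:
            mz = [499.5] + mz
            inten = [interferent_int] + inten
        scan = make_scan(mz, inten)
        picked = extraction.pick_peaks(scan, make_template([500.0, 500.5]), 10, 20)
        return scan, picked

    def test_no_peak_below_gate_no_penalty(self):
        scan, picked = self.build(100.0)
        assert extraction.penalty_check(scan, picked) == 0.0

    def test_interferent_in_band_penalized(self):
        scan, picked = self.build(100.0, interferent_int=120.0)
        assert extraction.penalty_check(scan, picked) == 3.0

    @pytest.mark.parametrize("factor", [0.4, 0.5, 2.0, 10.0])
    def test_interferent_outside_band_not_penalized(self, factor):
        scan, picked = self.build(100.0, interferent_int=100.0 * factor)
        assert extraction.penalty_check(scan, picked) == 0.0

    def test_single_peak_spectrum_no_penalty(self):
        scan = make_scan([500.0], [100.0])
        picked = extraction.pick_peaks(scan, make_template([500.0]), 10, 20)
        assert extraction.penalty_check(scan, picked) == 0.0


class TestScoreSpectrum:
    def test_components_hand_computed(self, config):
        template = make_template([500.0, 500.5])
        # ppm deviations: +2 on gate, +12 on isotope; intensities 9 and 1
        scan = make_scan([500.0 + 500.0 * 2e-6, 500.5 + 500.5 * 12e-6], [9e5, 1e5])
        picked = extraction.pick_peaks(scan, template, 10, 20)
        score = extraction.score_spectrum(picked, scan, n_prev=10, config=config)
        assert score.i_mip0 == pytest.approx(math.log10(9e5), abs=1e-12)
        assert score.w_ppm == pytest.approx(0.9 * 2 + 0.1 * 12, abs=1e-6)
        assert score.coverage == pytest.approx(0.2)
        assert score.penalty == 0.0
        assert score.total == pytest.approx(
            score.i_mip0 + score.coverage - score.w_ppm / config.tol_iso_ppm, abs=1e-12
        )

    def test_log_intensity_of_gate(self, config):
        template = make_template([500.0])
        scan = make_scan([500.0], [1e6])
        picked = extraction.pick_peaks(scan, template, 10, 20)
        score = extraction.score_spectrum(picked, scan, 1, config)
        assert score.i_mip0 == pytest.approx(6.0)

    def test_coverage_uses_previous_count(self, config):
        template = make_template([500.0 + 0.5 * k for k in range(8)])
        scan = make_scan([500.0 + 0.5 * k for k in range(8)], [100] * 8)
        picked = extraction.pick_peaks(scan, template, 10, 20)
        score = extraction.score_spectrum(picked, scan, n_prev=10, config=config)
        assert score.coverage == pytest.approx(0.8)

    def test_empty_spectrum_unscored(self, config):
        ps = extraction.PickedSpectrum(None, None, 1.0)
        assert extraction.score_spectrum(ps, make_scan([500.0], [1.0]), 1, config) is None


class TestBestScan:
    def test_single_candidate_returned(self, config):
        template = make_template([500.0, 500.5])
        scan = make_scan([500.0, 500.5], [100, 50], rt=10.0)
        best = extraction.best_scan([scan], template, 3, config)
        assert best.scan_rt == 10.0

    def test_all_scans_missing_gate_gives_none(self, config):
        template = make_template([500.0, 500.5])
        scans = [make_scan([510.0], [100], rt=float(i)) for i in range(5)]
        assert extraction.best_scan(scans, template, 3, config) is None

    def test_matches_exhaustive_rescoring_oracle(self, rng, config):
        """best_scan equals an independent argmax over per-scan re-scores."""
        positions = 500.0 + 0.5 * np.arange(6)
        template = make_template(positions)
        for _ in range(40):
            scans = []
            for i in range(int(rng.integers(2, 8))):
                n_extra = int(rng.integers(0, 10))
                mz = np.concatenate(
                    [
                        positions + positions * rng.normal(0, 4e-6, 6),
                        rng.uniform(498, 505, n_extra),
                    ]
                )
                inten = np.concatenate(
                    [10 ** rng.uniform(2, 6, 6), rng.uniform(1, 100, n_extra)]
                )
                keep = rng.random(mz.size) > 0.2
                if not keep.any():
                    keep[0] = True
                scans.append(make_scan(mz[keep], inten[keep], rt=float(i)))
            n_prev = int(rng.integers(3, 8))
            best = extraction.best_scan(scans, template, n_prev, config)
            # independent oracle: re-pick and re-score every scan directly
            expected_rt, expected_score = None, -np.inf
            for scan in scans:
                ps = extraction.coelution_filter(
                    scan,
                    template,
                    extraction.pick_peaks(scan, template, 10, 20),
                    3.0,
                    20.0,
                )
                if not ps.peaks or ps.peaks[0].intensity <= 0:
                    continue
                penalty = extraction.penalty_check(scan, ps)
                total = helpers.rescore_envelope(
                    [(p.intensity, abs(p.ppm)) for p in ps.peaks], n_prev, penalty=penalty
                )
                if total > expected_score:
                    expected_rt, expected_score = scan.rt, total
            if best is None:
                assert expected_rt is None
            else:
                assert best.scan_rt == expected_rt
                assert best.score.total == pytest.approx(expected_score, abs=1e-9)

    def test_tie_broken_by_earliest_rt(self, config):
        template = make_template([500.0, 500.5])
        scans = [make_scan([500.0, 500.5], [100, 50], rt=rt) for rt in (3.0, 5.0)]
        best = extraction.best_scan(scans, template, 3, config)
        assert best.scan_rt == 3.0


class TestTemplatePropagation:
    def test_propagated_template_keeps_theoretical_values(self):
        template = chem.build_template("MPSAVGYQPTLGTEMGTLQER", 2)
        scan = make_scan(template.full_mz[[0, 1, 2, 3]], [100, 80, 60, 40])
        picked = extraction.pick_peaks(scan, template, 10, 20)
        new = extraction.propagate_template(template, picked)
        assert new.size == 4
        np.testing.assert_array_equal(new.mz, template.full_mz[[0, 1, 2, 3]])

    def test_empty_pick_resets_to_full_theoretical(self):
        template = chem.build_template("MPSAVGYQPTLGTEMGTLQER", 2).subset([0, 1, 2])
        new = extraction.propagate_template(template, extraction.PickedSpectrum(None, None, 1.0))
        assert new.size == 27

    def test_repeated_propagation_never_grows(self, rng, config):
        template = chem.build_template("AVANQPIAVAVEGGGR", 2)
        size = template.size
        for _ in range(6):
            present = np.sort(
                rng.choice(template.slots, size=max(1, template.size - 1), replace=False)
            )
            scan = make_scan(
                template.full_mz[present], rng.uniform(10, 100, present.size)
            )
            picked = extraction.pick_peaks(scan, template, 10, 20)
            template = extraction.propagate_template(template, picked)
            assert template.size <= size
            size = template.size


class TestTp0NoiseFilter:
    def case(self, slots, template_slots=None):
        template = make_template(
            [500.0 + 0.5 * k for k in range(6)], slots=template_slots or list(range(6))
        )
        peaks = [extraction.PickedPeak(s, 500.0 + 0.5 * s, 10.0, 0.0) for s in slots]
        ps = extraction.PickedSpectrum(None, None, 1.0, peaks)
        return extraction.tp0_noise_filter(ps, template)

    def test_everything_after_first_gap_removed(self):
        assert self.case([0, 1, 2, 4, 5]).slots == [0, 1, 2]

    def test_contiguous_envelope_unchanged(self):
        assert self.case([0, 1, 2, 3]).slots == [0, 1, 2, 3]

    def test_empty_spectrum_stays_empty(self):
        template = make_template([500.0, 500.5])
        ps = extraction.PickedSpectrum(None, None, 1.0)
        assert not extraction.tp0_noise_filter(ps, template).peaks

    def test_gap_measured_against_propagated_slot_sequence(self):
        # template slots {0,1,2,4,5}: 2 -> 4 is NOT a gap of that sequence
        out = self.case([0, 1, 2, 4], template_slots=[0, 1, 2, 4, 5])
        assert out.slots == [0, 1, 2, 4]


class TestExtractTimeSeries:
    def test_envelope_counts_non_increasing_in_reverse_order(self, config):
        # hand-built 3-TP series: envelope grows with labeling time
        template = chem.build_template("AVANQPIAVAVEGGGR", 2)
        counts_by_tp = {0.0: 3, 24.0: 5, 48.0: 9}
        runs = []
        for tp, n in counts_by_tp.items():
            mz = template.full_mz[:n]
            scans = [make_scan(mz, np.linspace(100, 50, n), rt=42.0 + i * 0.2) for i in range(3)]
            runs.append((tp, scans))
        target = PeptideTarget("AVANQPIAVAVEGGGR", 2, 42.5, "G7JAR7")
        series = extraction.extract_time_series(target, runs, config)
        counts = [ps.n_picked for _, ps in series]
        assert counts == [3, 5, 9]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_absent_peptide_gives_all_none(self, config):
        runs = [
            (tp, [make_scan([900.0], [10.0], rt=42.0)]) for tp in (0.0, 24.0, 48.0)
        ]
        target = PeptideTarget("AVANQPIAVAVEGGGR", 2, 42.0, "G7JAR7")
        series = extraction.extract_time_series(target, runs, config)
        assert [ps for _, ps in series] == [None, None, None]

    def test_results_in_chronological_order(self, config):
        template = chem.build_template("AVANQPIAVAVEGGGR", 2)
        runs = [
            (tp, [make_scan(template.full_mz[:4], [100, 80, 60, 40], rt=42.0)])
            for tp in (0.0, 24.0, 48.0)
        ]
        target = PeptideTarget("AVANQPIAVAVEGGGR", 2, 42.0, "G7JAR7")
        series = extraction.extract_time_series(target, runs, config)
        assert [tp for tp, _ in series] == [0.0, 24.0, 48.0]

    def test_two_time_points_required(self, config):
        target = PeptideTarget("AVANQPIAVAVEGGGR", 2, 42.0, "G7JAR7")
        with pytest.raises(ValueError):
            extraction.extract_time_series(target, [(0.0, [])], config)
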