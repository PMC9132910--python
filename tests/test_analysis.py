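import numpy as np
import pytest
from scipy import stats

from hebbtone.analysis import (
    IntervalProfile,
    classify_partners,
    compare_reference,
    count_emerged,
    extract_profile,
    harmonic_count_experiment,
    resolution_invariance,
    symmetry_report,
)
from hebbtone.hebbnet import SparseSynapticState, TrainingParams, train
from hebbtone.lattice import ToneLattice, reference_table
from hebbtone.stimuli import SweepSchedule


def _profile_from_magnitudes(mags_by_span, resolution=100.0):
    spans = np.array(sorted(mags_by_span), dtype=float)
    mags = np.array([mags_by_span[s] for s in spans])
    return IntervalProfile(
        tonic_index=0, resolution_cents=resolution, spans=spans, magnitudes=mags
    )


class TestExtractProfile:
    def test_untrained_state_has_only_the_unison(self, small_lattice):
        state = SparseSynapticState(small_lattice.n_tones)
        profile = extract_profile(state, small_lattice, 18)
        assert count_emerged(profile) == 1
        assert profile.magnitude_of(0.0) == 1.0  # the innate diagonal

    def test_first_sweep_positive_spans_match_harmonic_differences(self, linear5):
        lat = ToneLattice()
        sched = SweepSchedule("ascending", n_sweeps=1, repetitions=1)
        state = train(lat, linear5, sched, TrainingParams(kappa=0.0), storage="sparse")
        profile = extract_profile(state, lat, 4800)
        assert sorted(profile.emerged_spans(0, 1200)) == [
            0.0, 386.0, 498.0, 702.0, 884.0, 1200.0
        ]

    def test_unison_outranks_everything_and_octave_leads_intervals(self, tencent_run):
        lattice, state = tencent_run
        ranking = extract_profile(state, lattice, 480).ranking()
        assert ranking["span_cents"].iloc[0] == 0.0
        assert ranking["span_cents"].iloc[1] == 1200.0

    def test_edge_tonic_warns_and_truncates(self, small_lattice):
        state = SparseSynapticState(small_lattice.n_tones)
        with pytest.warns(UserWarning, match="edge"):
            profile = extract_profile(state, small_lattice, 2)
        assert profile.spans.min() == -200.0

    def test_ranking_tie_break_prefers_small_then_positive_span(self):
        profile = _profile_from_magnitudes({-300.0: 5.0, 300.0: 5.0, 100.0: 5.0, 0.0: 9.0})
        ranking = profile.ranking(-1200.0, 1200.0)
        assert ranking["span_cents"].tolist() == [0.0, 100.0, 300.0, -300.0]


class TestClassifyPartners:
    def test_constructed_gap_found_after_rank_three(self):
        profile = _profile_from_magnitudes(
            {0.0: 100.0, 100.0: 90.0, 200.0: 80.0, 300.0: 1.0, 400.0: 0.9,
             500.0: 0.8, 600.0: 0.7}
        )
        pc = classify_partners(profile)
        assert pc.boundary_rank == 3
        assert pc.first_order == (0.0, 100.0, 200.0)
        assert pc.gap_ratio == pytest.approx(80.0)
        assert not pc.degenerate

    def test_geometric_magnitudes_are_degenerate(self):
        profile = _profile_from_magnitudes(
            {float(s): 2.0 ** (-s / 100) for s in range(0, 800, 100)}
        )
        pc = classify_partners(profile)
        assert pc.degenerate
        assert pc.boundary_rank == 1

    def test_too_few_spans_unavailable(self):
        profile = _profile_from_magnitudes({0.0: 2.0, 100.0: 1.0})
        with pytest.raises(ValueError, match="classification unavailable"):
            classify_partners(profile)


class TestCompareReference:
    def _reference_like_profile(self, swap=None):
        refs = sorted(
            (r for r in reference_table() if r.helmholtz_rank),
            key=lambda r: r.helmholtz_rank,
        )
        mags = {float(round(r.cents)): float(100 - r.helmholtz_rank) for r in refs}
        if swap:
            a, b = swap
            ca, cb = float(round(refs[a - 1].cents)), float(round(refs[b - 1].cents))
            mags[ca], mags[cb] = mags[cb], mags[ca]
        return _profile_from_magnitudes(mags, resolution=1.0), refs

    def test_identical_order_gives_perfect_tau_and_overlap(self):
        profile, refs = self._reference_like_profile()
        report = compare_reference(profile, refs, tolerance_cents=0.5, top_k=13)
        assert report.kendall_tau == pytest.approx(1.0)
        assert report.top_k_overlap == 13
        assert report.n_matched == 13

    def test_one_adjacent_swap_costs_one_discordant_pair(self):
        # an adjacent transposition inverts exactly one pair, so
        # tau = 1 - 2*1/C(13,2) = 0.97435...; cross-checked against scipy on
        # the explicitly permuted ranks
        profile, refs = self._reference_like_profile(swap=(9, 10))
        report = compare_reference(profile, refs, tolerance_cents=0.5, top_k=13)
        expected = 1 - 2 * 1 / (13 * 12 / 2)
        assert report.kendall_tau == pytest.approx(expected)
        perm = [1, 2, 3, 4, 5, 6, 7, 8, 10, 9, 11, 12, 13]
        assert report.kendall_tau == pytest.approx(
            stats.kendalltau(range(1, 14), perm).statistic
        )

    def test_tolerance_below_half_resolution_rejected(self):
        profile = _profile_from_magnitudes({0.0: 1.0}, resolution=10.0)
        with pytest.raises(ValueError):
            compare_reference(profile, reference_table(), tolerance_cents=1.0)

    def test_matches_prefer_the_prominent_representative(self):
        # 390 (strong) and 380 (faint) both sit within tolerance of the just
        # major third at 386.3; the strong span is the interval's emergent face
        profile = _profile_from_magnitudes(
            {0.0: 10.0, 390.0: 5.0, 380.0: 0.01}, resolution=10.0
        )
        m3 = [r for r in reference_table() if r.name == "major_third"]
        report = compare_reference(profile, m3, tolerance_cents=10.0)
        assert report.rows["matched_span"].iloc[0] == 390.0


class TestSymmetry:
    def test_symmetric_toy_state_has_zero_asymmetry(self, small_lattice):
        state = SparseSynapticState(small_lattice.n_tones)
        tonic = 18
        for offset, w in ((7, 2.0), (12, 0.5)):
            state.set_weight(tonic, tonic + offset, w)
            state.set_weight(tonic, tonic - offset, w)
        report = symmetry_report(state, small_lattice, tonic)
        assert report.set_symmetric
        assert report.max_relative_asymmetry == 0.0

    def test_one_sided_span_breaks_set_symmetry(self, small_lattice):
        state = SparseSynapticState(small_lattice.n_tones)
        state.set_weight(18, 25, 1.0)
        report = symmetry_report(state, small_lattice, 18)
        assert not report.set_symmetric
        assert report.unmatched_spans == (700.0,)

    def test_sweep_one_mirror_symmetry_is_exact(self, linear5):
        lat = ToneLattice()
        sched = SweepSchedule("ascending", n_sweeps=1, repetitions=1)
        state = train(lat, linear5, sched, TrainingParams(kappa=0.0), storage="sparse")
        report = symmetry_report(state, lat, 4800)
        assert report.set_symmetric
        assert report.max_relative_asymmetry < 1e-12


class TestResolutionInvariance:
    def test_single_profile_trivially_invariant(self):
        profile = _profile_from_magnitudes(
            {0.0: 10.0, 700.0: 5.0, 1200.0: 7.0, 500.0: 3.0, 400.0: 2.0,
             900.0: 1.5, 300.0: 0.1}
        )
        report = resolution_invariance({100.0: profile}, k_top=6)
        assert report.invariant and not report.flagged

    def test_k_beyond_emerged_is_flagged(self):
        profile = _profile_from_magnitudes({0.0: 1.0, 700.0: 0.5})
        report = resolution_invariance({100.0: profile}, k_top=6)
        assert report.flagged

    def test_disagreeing_sets_not_invariant(self):
        a = _profile_from_magnitudes({0.0: 3.0, 700.0: 2.0})
        b = _profile_from_magnitudes({0.0: 3.0, 300.0: 2.0})
        report = resolution_invariance({100.0: a, 50.0: b}, k_top=2)
        assert not report.invariant


class TestHarmonicCountExperiment:
    def test_more_harmonics_keep_the_most_consonant_intervals(self):
        result = harmonic_count_experiment(
            h_values=range(5, 8), resolution_cents=100.0, n_octaves=3,
            n_sweeps=2, repetitions=2, tonic_index=18,
        )
        assert set(result.containment) == {6, 7}
        assert all(result.containment.values())
        for h, spans in result.first_order_sets.items():
            assert 0.0 in spans and 1200.0 in spans

    def test_emerged_top_set_is_five_limit_at_fine_resolution(self, tencent_run):
        lattice, state = tencent_run
        profile = extract_profile(state, lattice, 480)
        refs = reference_table()
        # two-fold nearest-lattice rounding bounds the error by one full step
        tol = lattice.resolution_cents
        for span in profile.ranking()["span_cents"].head(12):
            nearest = min(refs, key=lambda r: abs(r.cents - span))
            assert abs(nearest.cents - span) <= tol
            assert nearest.five_limit
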