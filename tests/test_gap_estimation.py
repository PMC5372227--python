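"""Binning, scoring, candidate selection, support rule, and gap estimation."""

import random

import pytest

from gapstitch.convolution import Contribution, OffsetDifferenceSpectrum, string_convolution
from gapstitch.gap_estimation import (
    BinnedHistogram,
    bin_differences,
    estimate_gap,
    round_half_away,
    score_binned,
    select_candidate,
    support_check,
)
from gapstitch.params import Params
from gapstitch.synthetic import SimulationConfig, simulate_protein, simulate_spectra
from gapstitch.tagging import generate_tags

from conftest import ideal_tagset, random_protein


def conv_from(pairs):
    conv = OffsetDifferenceSpectrum()
    for d, m in pairs:
        conv.add(d, m=m)
    return conv


class TestBinning:
    def test_scale_and_bin_arithmetic(self):
        hist = bin_differences(conv_from([(129.042593, 1)]), h=4)
        assert hist.scaled == {1290426: 1}
        assert hist.binned == {129: 1}

    def test_rounding_collision_merges_scaled(self):
        hist = bin_differences(conv_from([(129.04259, 2), (129.04261, 3)]), h=4)
        assert hist.scaled == {1290426: 5}
        assert hist.binned == {129: 5}

    def test_nearest_integer_binning(self):
        hist = bin_differences(conv_from([(-0.4, 1), (0.6, 1)]), h=4)
        assert set(hist.binned) == {0, 1}

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_through_binning(self, seed):
        rng = random.Random(seed)
        conv = conv_from(
            [(rng.uniform(-50, 2000), rng.randrange(1, 5)) for _ in range(200)]
        )
        hist = bin_differences(conv, h=4)
        total = conv.total_multiplicity()
        assert sum(hist.scaled.values()) == total
        assert sum(hist.binned.values()) == total
        assert sum(sum(d.values()) for d in hist.scaled_by_bin.values()) == total

    def test_half_rounding_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(2.4) == 2


class TestScore:
    def test_three_bin_sum(self):
        hist = BinnedHistogram(h=4, binned={1583: 25, 1582: 10})
        assert score_binned(1583, hist) == 35

    def test_isolated_bin(self):
        hist = BinnedHistogram(h=4, binned={500: 20})
        assert score_binned(500, hist) == 20

    def test_all_absent(self):
        assert score_binned(42, BinnedHistogram(h=4)) == 0


class TestSelectCandidate:
    def test_empty_histogram(self):
        assert select_candidate(BinnedHistogram(h=4), Params()) is None

    def test_only_bins_at_bmax_enter_scoring(self):
        # 501 has the max multiplicity (30); 500 and 700 (25 each) are ignored
        # even though 500 would boost a neighbour score
        conv = conv_from([(500.0, 25), (700.0, 25), (501.0, 30)])
        hist = bin_differences(conv, h=4)
        result = select_candidate(hist, Params())
        assert result is not None
        d_hat, db = result
        assert db == 501

    def test_tie_prefers_smaller_bin(self):
        conv = conv_from([(800.0, 25), (900.0, 25)])
        hist = bin_differences(conv, h=4)
        _, db = select_candidate(hist, Params())
        assert db == 800

    def test_filters_negative_above_gmax_below_bmin(self):
        conv = conv_from([(-5.0, 100), (3500.0, 100), (40.0, 5)])
        assert select_candidate(bin_differences(conv, h=4), Params()) is None

    def test_refined_estimate_is_modal_scaled_value(self):
        conv = conv_from([(120.0001, 10), (120.0003, 25), (120.0004, 5)])
        d_hat, db = select_candidate(bin_differences(conv, h=4), Params())
        assert db == 120
        assert d_hat == pytest.approx(120.0003)

    def test_candidate_respects_bounds(self):
        conv = conv_from([(150.25, 30), (2999.9, 45)])
        d_hat, db = select_candidate(bin_differences(conv, h=4), Params())
        assert 0 <= db <= 3000
        assert d_hat == pytest.approx(2999.9)


def hist_with_support(support, neighbor=None, db=100):
    """Histogram with explicit per-bin support window counts."""
    hist = BinnedHistogram(h=4, binned={db: 50})
    hist.support[db] = (set(range(support[0])), set(range(support[1])))
    if neighbor is not None:
        nb_db, nb_counts = neighbor
        hist.binned[nb_db] = 5
        hist.support[nb_db] = (set(range(nb_counts[0])), set(range(nb_counts[1])))
    return hist


class TestSupportCheck:
    def test_m_star(self):
        assert Params(a_min=6, k=4).m_star == 3

    def test_both_at_m_star_accepts(self):
        result = support_check(100, hist_with_support((3, 3)), Params())
        assert result.accepted and (result.count1, result.count2) == (3, 3)

    def test_unbalanced_plus_minus_one_accepts(self):
        assert support_check(100, hist_with_support((4, 2)), Params()).accepted
        assert support_check(100, hist_with_support((2, 4)), Params()).accepted

    def test_neighbor_fallback_accepts(self):
        hist = hist_with_support((2, 2), neighbor=(101, (2, 3)))
        result = support_check(100, hist, Params())
        assert result.accepted and result.via_neighbor == 101

    def test_no_qualifying_neighbor_rejects(self):
        assert not support_check(100, hist_with_support((2, 2)), Params()).accepted
        hist = hist_with_support((2, 2), neighbor=(99, (2, 2)))
        assert not support_check(100, hist, Params()).accepted

    def test_below_m_star_minus_one_rejects(self):
        hist = hist_with_support((1, 5), neighbor=(101, (3, 3)))
        assert not support_check(100, hist, Params()).accepted


class TestEstimateGap:
    def test_recovers_separating_mass_on_ideal_data(self):
        rng = random.Random(5)
        protein = random_protein(rng, 80)
        s1, gap, s2 = protein[5:25], protein[25:37], protein[37:60]
        tagset = ideal_tagset(protein, n_spectra=2)
        from gapstitch.chem import sequence_mass

        est = estimate_gap(s1, s2, tagset, Params())
        assert est is not None
        assert abs(est.estimate - sequence_mass(gap)) < 0.01

    def test_adjacent_fragments_near_zero_gap(self):
        rng = random.Random(6)
        protein = random_protein(rng, 80)
        s1, s2 = protein[5:25], protein[25:48]
        tagset = ideal_tagset(protein, n_spectra=2)
        est = estimate_gap(s1, s2, tagset, Params())
        assert est is not None
        assert abs(est.estimate) < 0.01 and est.binned == 0

    def test_unrelated_proteins_rejected(self):
        rng = random.Random(7)
        p1, p2 = random_protein(rng, 60), random_protein(rng, 60)
        tagset = ideal_tagset(p1, n_spectra=2)
        for tag in ideal_tagset(p2, n_spectra=2):
            tagset.add(
                type(tag)(tag.sequence, tag.offset, "other_" + tag.spectrum_id)
            )
        est = estimate_gap(p1[5:25], p2[30:50], tagset, Params())
        assert est is None

    def test_raising_bmin_never_converts_reject_to_accept(self):
        rng = random.Random(8)
        protein = random_protein(rng, 70)
        s1, s2 = protein[5:20], protein[30:50]
        tagset = ideal_tagset(protein, n_spectra=2)
        accepted = [
            estimate_gap(s1, s2, tagset, Params(b_min=b)) is not None
            for b in (1, 10, 50, 200, 10_000)
        ]
        # once rejected at some Bmin, stays rejected for every larger Bmin
        assert accepted == sorted(accepted, reverse=True)

    def test_plus_minus_one_errors_aggregate_into_score(self):
        config = SimulationConfig(
            protein_length=200,
            n_spectra=120,
            p_shift=0.3,
            fragment_lengths=(35, 35),
            gap_lengths=(10,),
            flip_probability=0.0,
            seed=21,
        )
        protein = simulate_protein(config.protein_length, config.seed)
        spectra, _ = simulate_spectra(protein, config)
        tagset = generate_tags(spectra, Params())
        from gapstitch.synthetic import simulate_fragment_strings

        strings, truth = simulate_fragment_strings(protein, config)
        est = estimate_gap(strings[0], strings[1], tagset, Params())
        assert est is not None
        assert est.score >= est.multiplicity  # neighbours only ever add
        assert abs(est.binned - truth.separating_masses[0]) <= 1.0

    def test_report_is_auditable(self):
        rng = random.Random(9)
        protein = random_protein(rng, 70)
        tagset = ideal_tagset(protein, n_spectra=2)
        report = {}
        est = estimate_gap(protein[5:20], protein[30:50], tagset, Params(), report=report)
        assert report["accepted"] == (est is not None)
        if est is not None:
            assert report["candidate"]["binned"] == est.binned
            assert report["candidate"]["support"] == [est.support1, est.support2]
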