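"""Binding-site attribution: coverage statistic, Monte-Carlo null,
right-tailed p-values, BH adjustment and entry-level summaries."""

import numpy as np
import pytest

from convdti import ModelConfig, DTIModel, encode_sequence
from convdti.attribution import (
    NullDistribution,
    attribute_entry,
    bh_adjust,
    expected_events_coverage,
    right_tailed_p,
    sample_null,
    summarize_significance,
    top_k_coverage,
    window_coverage,
)
from convdti.io_data import BindingSiteAnnotation
from convdti.synthetic import plant_motif_filters


def brute_force_bh(p):
    """Independent step-up implementation: sort ascending, p_(i)*m/i,
    enforce monotonicity from the top, cap at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


class TestWindowCoverage:
    @pytest.mark.parametrize("starts,ws,residues,events,distinct", [
        ([1], 3, {2, 5}, 1, 1),
        ([1, 1], 3, {2}, 2, 1),       # duplicate starts count multiply in events
        ([10], 2, {1, 2}, 0, 0),      # disjoint
        ([1, 2], 2, {2}, 2, 1),
    ])
    def test_examples(self, starts, ws, residues, events, distinct):
        assert window_coverage(starts, ws, residues, "events") == events
        assert window_coverage(starts, ws, residues, "residues") == distinct

    def test_empty_residues_rejected(self):
        with pytest.raises(ValueError):
            window_coverage([1], 3, set())

    def test_zero_based_starts_rejected(self):
        with pytest.raises(ValueError):
            window_coverage([0], 3, {1})


class TestSampleNull:
    def test_degenerate_single_start(self):
        null = sample_null(true_length=6, window_size=6, n_results=5,
                           n_reps=50, residues={2, 4}, seed=0)
        assert null.sd == 0.0
        assert null.mean == 5 * 2  # every window covers both residues

    def test_full_coverage_mean_exact(self):
        # annotation covering the whole sequence: every window covers
        # exactly WS residues, so each replicate equals n_results * WS
        null = sample_null(true_length=20, window_size=4, n_results=7,
                           n_reps=100, residues=set(range(1, 21)), seed=1)
        assert null.mean == 7 * 4
        assert null.sd == 0.0

    def test_empirical_mean_matches_closed_form(self, rng):
        for _ in range(10):
            L = int(rng.integers(30, 120))
            ws = int(rng.integers(2, 12))
            residues = set((rng.choice(L, size=8, replace=False) + 1).tolist())
            n_reps = 3000
            null = sample_null(L, ws, 16, n_reps, residues,
                               seed=int(rng.integers(2**31)))
            expected = expected_events_coverage(L, ws, 16, residues)
            se = null.sd / np.sqrt(n_reps)
            assert abs(null.mean - expected) <= max(3 * se, 1e-9)

    def test_reproducible_from_seed(self):
        a = sample_null(50, 5, 8, 200, {3, 9, 30}, seed=7)
        b = sample_null(50, 5, 8, 200, {3, 9, 30}, seed=7)
        assert (a.mean, a.sd) == (b.mean, b.sd)

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            sample_null(5, 6, 8, 100, {1}, seed=0)

    def test_residue_beyond_sequence_rejected(self):
        with pytest.raises(ValueError):
            sample_null(10, 3, 8, 100, {11}, seed=0)

    def test_residues_mode_bounded_by_site_size(self, rng):
        null = sample_null(60, 6, 32, 500, set(range(1, 11)),
                           mode="residues", seed=3)
        assert null.mean <= 10.0


class TestRightTailedP:
    def test_observed_at_mean_is_half(self):
        null = NullDistribution(4, 8, 100, mean=10.0, sd=2.0)
        assert right_tailed_p(10.0, null) == pytest.approx(0.5)

    def test_95th_percentile(self):
        null = NullDistribution(4, 8, 100, mean=10.0, sd=2.0)
        assert right_tailed_p(10.0 + 1.6449 * 2.0, null) == pytest.approx(0.05, abs=1e-3)

    def test_far_below_mean_approaches_one(self):
        null = NullDistribution(4, 8, 100, mean=10.0, sd=2.0)
        assert right_tailed_p(0.0, null) > 0.9999

    def test_degenerate_null(self):
        null = NullDistribution(4, 8, 100, mean=10.0, sd=0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert right_tailed_p(10.0, null) == 0.5
        with pytest.warns(UserWarning):
            assert right_tailed_p(9.0, null) == 1.0
        with pytest.warns(UserWarning):
            assert right_tailed_p(11.0, null) == 0.0


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.005, 0.05, 0.5], [0.015, 0.075, 0.5]),
        ([0.2], [0.2]),
    ])
    def test_hand_run_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(20)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 30)))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def planted_model():
    """Model whose single-window filters exactly match one motif."""
    cfg = ModelConfig(window_sizes=(6,), filters_per_window=8,
                      embedding_size=8, mpl=120, fingerprint_bits=16,
                      protein_dense_sizes=(8,), drug_dense_sizes=(8,),
                      joint_dense_sizes=(8,), conv_bias=False, seed=13)
    model = DTIModel(cfg)
    motif = "WYKDCH"
    plant_motif_filters(model, [motif])
    return model, motif


class TestAttributeEntry:
    def test_planted_filter_detects_motif_site(self, planted_model, make_sequence):
        model, motif = planted_model
        for i in range(5):
            background = make_sequence(100)
            offset = 20 + 11 * i
            seq = background[:offset] + motif + background[offset + 6:]
            residues = frozenset(range(offset + 1, offset + 7))
            ann = BindingSiteAnnotation(f"e{i}", f"p{i}", residues)
            enc = encode_sequence(seq, mpl=120)
            res = attribute_entry(model, enc, ann, n_reps=2000, seed=i)
            assert res.min_adjusted_p < 0.05

    def test_annotation_beyond_protein_rejected(self, planted_model):
        model, _ = planted_model
        enc = encode_sequence("MKVLAWTTYHH", mpl=120)
        ann = BindingSiteAnnotation("e1", "p1", frozenset({50}))
        with pytest.raises(ValueError, match="beyond"):
            attribute_entry(model, enc, ann, n_reps=100, seed=0)

    def test_whole_sequence_annotation_degenerate(self, planted_model, make_sequence):
        model, _ = planted_model
        seq = make_sequence(40)
        ann = BindingSiteAnnotation("e1", "p1", frozenset(range(1, 41)))
        enc = encode_sequence(seq, mpl=120)
        with pytest.warns(UserWarning, match="degenerate"):
            res = attribute_entry(model, enc, ann, n_reps=500, seed=0)
        # observed coverage is forced to equal the (constant) null mean
        assert res.min_adjusted_p == pytest.approx(0.5)

    def test_adjusted_at_least_raw(self, planted_model, make_sequence):
        model, _ = planted_model
        enc = encode_sequence(make_sequence(80), mpl=120)
        ann = BindingSiteAnnotation("e1", "p1", frozenset({5, 17, 40}))
        res = attribute_entry(model, enc, ann, n_reps=500, seed=1)
        for ws in res.window_sizes:
            assert res.p_adjusted[ws] >= res.p_values[ws] - 1e-15
        assert res.min_adjusted_p == min(res.p_adjusted.values())


class TestSummaries:
    def _result(self, p):
        from convdti.attribution import AttributionResult
        return AttributionResult("e", "p", (4,), {4: 1}, {4: p}, {4: p}, {}, p)

    def test_all_significant(self):
        res = [self._result(0.001) for _ in range(4)]
        assert summarize_significance(res) == {0.01: 1.0, 0.05: 1.0, 0.10: 1.0}

    def test_none_significant(self):
        res = [self._result(0.5) for _ in range(4)]
        assert summarize_significance(res) == {0.01: 0.0, 0.05: 0.0, 0.10: 0.0}

    def test_monotone_in_level(self, rng):
        res = [self._result(float(p)) for p in rng.random(30)]
        s = summarize_significance(res)
        assert s[0.01] <= s[0.05] <= s[0.10]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_significance([])


class TestTopKCoverage:
    def test_single_window_contiguous_run(self, planted_model, make_sequence):
        model, _ = planted_model
        enc = encode_sequence(make_sequence(50), mpl=120)
        counts = top_k_coverage(model, enc, k=1)
        covered = sorted(counts)
        assert len(covered) == 6  # one window of span 6
        assert covered == list(range(covered[0], covered[0] + 6))

    def test_counts_sum_accounting_identity(self, planted_model, make_sequence):
        model, _ = planted_model
        enc = encode_sequence(make_sequence(50), mpl=120)
        k = 4
        counts = top_k_coverage(model, enc, k=k)
        # each selected window contributes its span, clipped at sequence end
        assert sum(counts.values()) <= k * 6
        assert sum(counts.values()) >= k * 6 - (6 - 1)

    def test_k_capped_with_warning(self, planted_model, make_sequence):
        model, _ = planted_model
        enc = encode_sequence(make_sequence(50), mpl=120)
        with pytest.warns(UserWarning, match="exceeds"):
            capped = top_k_coverage(model, enc, k=99)
        assert capped == top_k_coverage(model, enc, k=8)
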