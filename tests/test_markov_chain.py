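"""State encoding, window construction, and transition estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gogomarkov as gm
from gogomarkov import synthetic_data as sd

binary_seqs = st.lists(st.integers(0, 1), min_size=3, max_size=60)


def seq(outcomes, pid="p01", env="2D", trial_indices=None):
    return gm.OutcomeSequence(participant_id=pid, environment=env,
                              outcomes=np.asarray(outcomes), trial_indices=trial_indices)


def brute_force_transition_counts(outcomes, k):
    """Independent tally: scan every position with a full k-history."""
    counts = {h: [0, 0] for h in itertools.product((0, 1), repeat=k)}
    for n in range(k, len(outcomes)):
        h = tuple(outcomes[n - k:n])
        counts[h][outcomes[n]] += 1
    return counts


class TestEncodeOutcomes:
    def test_correct_maps_to_one(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["p01"] * 3,
                "environment": ["2D"] * 3,
                "trial_index": [1, 2, 3],
                "correct": [1, 0, 1],
            }
        )
        [s] = gm.encode_outcomes(trials)
        assert list(s.outcomes) == [1, 0, 1]

    def test_round_trip_against_correct_column(self, small_cohort):
        *_, trials, _ = small_cohort
        for s in gm.encode_outcomes(trials):
            block = trials[(trials["participant_id"] == s.participant_id)
                           & (trials["environment"] == s.environment)].sort_values("trial_index")
            assert list(s.outcomes) == list(block["correct"])

    def test_duplicate_trials_rejected(self):
        trials = pd.DataFrame(
            {"participant_id": ["p01"] * 2, "environment": ["2D"] * 2, "trial_index": [1, 1], "correct": [1, 1]}
        )
        with pytest.raises(gm.DataError, match="duplicate"):
            gm.encode_outcomes(trials)


class TestStateMatrix:
    def test_120_trials_yield_118_windows(self):
        m = gm.build_state_matrix(seq([1] * 120), window_length=3)
        assert m.n_rows == 118

    def test_windows_slide_by_one(self):
        m = gm.build_state_matrix(seq([0, 1, 1, 1]), window_length=3)
        assert [tuple(r) for r in m.rows] == [(0, 1, 1), (1, 1, 1)]

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(gm.SequenceTooShortError):
            gm.build_state_matrix(seq([1, 0]), window_length=3)

    def test_gap_breaking_drops_spanning_windows(self):
        s = seq([1, 1, 0, 0, 1], trial_indices=[1, 2, 3, 5, 6])  # trial 4 filtered out
        stitched = gm.build_state_matrix(s, 3)
        strict = gm.build_state_matrix(s, 3, break_at_gaps=True)
        assert stitched.n_rows == 3
        assert [tuple(r) for r in strict.rows] == [(1, 1, 0)]

    @given(binary_seqs)
    def test_window_count_invariant(self, outcomes):
        m = gm.build_state_matrix(seq(outcomes), window_length=3)
        assert m.n_rows == len(outcomes) - 2
        # consecutive windows overlap in w-1 positions
        for a, b in zip(m.rows, m.rows[1:]):
            assert tuple(a[1:]) == tuple(b[:-1])


class TestBase10:
    def test_endpoint_codes(self):
        assert gm.encode_base10((0, 0, 0)) == 0
        assert gm.encode_base10((1, 1, 1)) == 7

    def test_oldest_trial_is_most_significant(self):
        assert gm.encode_base10((0, 1, 1)) == 3
        assert gm.encode_base10((1, 1, 0)) == 6

    @pytest.mark.parametrize("w", [1, 2, 3, 4, 5, 6])
    def test_bijective_against_enumeration(self, w):
        codes = {gm.encode_base10(row): row for row in itertools.product((0, 1), repeat=w)}
        assert sorted(codes) == list(range(2**w))
        for code, row in codes.items():
            assert gm.decode_base10(code, w) == row

    def test_non_binary_entry_rejected(self):
        with pytest.raises(ValueError):
            gm.encode_base10((0, 2, 1))


class TestStateOccurrences:
    def test_all_ones_sequence(self):
        counts = gm.count_state_occurrences(gm.build_state_matrix(seq([1] * 120), 3))
        assert counts[7] == 118
        assert all(counts[c] == 0 for c in range(7))

    def test_fair_bits_uniform_at_12_5_percent(self):
        rng = np.random.default_rng(42)
        counts = gm.count_state_occurrences(
            gm.build_state_matrix(seq((rng.random(100_000) < 0.5).astype(int)), 3)
        )
        total = sum(counts.values())
        for code in range(8):
            assert abs(counts[code] / total - 0.125) < 0.01

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(7)
        outcomes = (rng.random(50) < 0.5).astype(int)
        counts = gm.count_state_occurrences(gm.build_state_matrix(seq(outcomes), 3))
        brute = {}
        for i in range(len(outcomes) - 2):
            code = int(outcomes[i] * 4 + outcomes[i + 1] * 2 + outcomes[i + 2])
            brute[code] = brute.get(code, 0) + 1
        assert {c: n for c, n in counts.items() if n} == brute


class TestEstimateTransitions:
    def test_alternating_sequence_is_deterministic(self):
        table = gm.estimate_transitions(seq([0, 1] * 15), order=1)
        assert table.p((0,), 1) == 1.0
        assert table.p((1,), 0) == 1.0

    def test_order_zero_is_overall_rate(self):
        table = gm.estimate_transitions(seq([1, 1, 1, 0]), order=0)
        assert table.p_correct(()) == pytest.approx(0.75)

    @given(binary_seqs, st.integers(0, 2))
    def test_counts_match_bruteforce_and_rows_sum_to_one(self, outcomes, k):
        table = gm.estimate_transitions(seq(outcomes), order=k)
        brute = brute_force_transition_counts(outcomes, k)
        for h, (nf, nv) in brute.items():
            assert table.count_f[h] == nf and table.count_v[h] == nv
            if nf + nv:
                assert table.p(h, 0) + table.p(h, 1) == pytest.approx(1.0, abs=1e-12)
            else:
                assert not table.defined(h) and table.p_correct(h) is None

    def test_too_short_sequence_rejected(self):
        with pytest.raises(gm.SequenceTooShortError):
            gm.estimate_transitions(seq([1, 0]), order=2)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            gm.estimate_transitions(seq([1, 0, 1]), order=-1)

    def test_add_one_smoothing_defines_all_rows(self):
        table = gm.estimate_transitions(seq([1, 1, 1, 1]), order=1, smoothing="add_one")
        assert table.defined((0,))
        assert table.p_correct((0,)) == pytest.approx(0.5)
        assert table.p_correct((1,)) == pytest.approx(4 / 5)  # (3+1)/(3+2)

    def test_parameter_recovery_at_1e5_windows(self):
        # generating kernel has P(F|FF) = 0.25; one long block gives >= 1e5 windows
        kernel = sd.AccuracyKernel(
            order=2, probs={(0, 0): 0.75, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 0.5}
        )
        config = sd.GeneratorConfig(trials_per_block=110_000, seed=31)
        prof = sd.ParticipantProfile("p01", "male", False, 1, 0.0)
        rt_model = sd.RTModel(baseline_mean_ms={"2D": 450.0}, anticipatory_rate=0.0)
        block = sd.generate_block(config, prof, kernel, rt_model, "2D")
        [s] = gm.encode_outcomes(block)
        table = gm.estimate_transitions(s, order=2)
        assert table.n_windows >= 100_000
        assert table.p((0, 0), 0) == pytest.approx(0.25, abs=0.01)


class TestPooling:
    def test_single_participant_identity(self):
        s = seq([1, 0, 1, 1, 0, 1, 1])
        alone = gm.estimate_transitions(s, order=1)
        pooled = gm.pool_cohort([s], "2D", order=1)
        assert pooled.count_f == alone.count_f and pooled.count_v == alone.count_v

    def test_windows_never_cross_participants(self):
        seqs = [seq([1] * 120, pid="p01"), seq([1] * 120, pid="p02")]
        pooled = gm.pool_cohort(seqs, "2D", order=2)
        assert pooled.n_windows == 236  # 2 x 118, not 238

    def test_pooled_counts_are_additive(self):
        rng = np.random.default_rng(17)
        seqs = [seq((rng.random(40) < 0.6).astype(int), pid=f"p{i}") for i in range(5)]
        pooled = gm.pool_cohort(seqs, "2D", order=2)
        for h in pooled.histories:
            assert pooled.count_v[h] == sum(gm.estimate_transitions(s, 2).count_v[h] for s in seqs)
            assert pooled.count_f[h] == sum(gm.estimate_transitions(s, 2).count_f[h] for s in seqs)

    def test_mixed_environments_rejected(self):
        with pytest.raises(gm.DataError):
            gm.pool_cohort([seq([1, 0, 1]), seq([1, 0, 1], env="3D")], "2D", order=1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(gm.DataError):
            gm.pool_cohort([], "2D", order=1)
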