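import numpy as np
import pytest

from carelex import (
    InterventionSymbol, ModeSpec, NullModelSpec, PC_MODE, VC_MODE,
    VentEventRow, VentSimConfig, count_intervention_space,
    effective_space_frequency, filter_solutions, fit_power_law,
    gen_vent_sessions, intervention_pattern_length, keyboard_size,
    length_rank_table, observed_vs_null, simulate_monkey, solution_lengths,
)
from carelex.length_analysis import SolutionRecord

from conftest import vc_row


def rec(n, completed=True, patient="p1"):
    return SolutionRecord(subject_id="s1", patient_id=patient,
                          n_interventions=n, completed=completed)


class TestInterventionPatternLength:
    def test_counts_changed_inputs(self):
        sym = InterventionSymbol(scheme="MV", mv_mode="VC",
                                 mv_changes=(0, 0, 0, 1, 0, -1), mv_bolus=0)
        assert intervention_pattern_length(sym) == 2

    def test_vc_maximum_is_seven(self):
        sym = InterventionSymbol(scheme="MV", mv_mode="VC",
                                 mv_changes=(1, 1, 1, 1, 1, 1), mv_bolus=1)
        assert intervention_pattern_length(sym) == 7

    def test_pc_maximum_is_six(self):
        sym = InterventionSymbol(scheme="MV", mv_mode="PC",
                                 mv_changes=(1, -1, 1, -1, 1), mv_bolus=1)
        assert intervention_pattern_length(sym) == 6

    def test_null_intervention_has_length_zero(self):
        sym = InterventionSymbol(scheme="MV", mv_mode="VC",
                                 mv_changes=(0,) * 6, mv_bolus=0)
        assert intervention_pattern_length(sym) == 0

    def test_mode_switch_is_one_changed_input(self):
        sym = InterventionSymbol(scheme="MV", mv_mode="switch_to_PC")
        assert intervention_pattern_length(sym) == 1


class TestLengthRankTable:
    def test_rank_by_frequency(self):
        t = length_rank_table([1, 1, 1, 2, 2, 3])
        assert [(r, int(w), f) for r, w, f in t.rows] == \
            [(1, 1, 3), (2, 2, 2), (3, 3, 1)]

    def test_zero_lengths_dropped(self):
        t = length_rank_table([0, 0, 1])
        assert [(int(w), f) for _, w, f in t.rows] == [(1, 1)]

    def test_frequency_ties_give_smaller_length_smaller_rank(self):
        t = length_rank_table([2, 7, 2, 7, 10, 10])
        assert [int(w) for _, w, _ in t.rows] == [2, 7, 10]

    def test_all_zero_gives_empty_table(self):
        assert len(length_rank_table([0, 0])) == 0


class TestSolutionLengths:
    def test_completed_patient(self):
        rows = [vc_row(step=i) for i in range(1, 5)]
        rows.append(VentEventRow(subject_id="s01", patient_id="p01",
                                 step_index=5, event_type="complete"))
        (r,) = solution_lengths(rows)
        assert r.n_interventions == 4 and r.completed

    def test_baseline_row_not_counted_as_intervention(self):
        rows = [vc_row(step=i) for i in range(0, 5)]  # baseline + 4 adjustments
        rows.append(VentEventRow(subject_id="s01", patient_id="p01",
                                 step_index=5, event_type="complete"))
        (r,) = solution_lengths(rows)
        assert r.n_interventions == 4

    def test_non_solution(self):
        rows = [vc_row(step=i) for i in range(1, 4)]
        (r,) = solution_lengths(rows)
        assert r.n_interventions == 3 and not r.completed

    def test_empty_input(self):
        assert solution_lengths([]) == []


class TestFilterSolutions:
    def test_rules_applied_in_order(self):
        recs = [rec(3, patient="a"), rec(3, patient="b"), rec(5, patient="c"),
                rec(0, patient="d")]
        out = filter_solutions(recs)
        assert [r.n_interventions for r in out] == [3, 3]

    def test_no_change_when_all_qualify(self):
        recs = [rec(2, patient=p) for p in "abc"]
        assert filter_solutions(recs) == recs

    def test_single_unique_solution_removed(self):
        assert filter_solutions([rec(1)]) == []

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        recs = [rec(int(n), patient=str(i))
                for i, n in enumerate(rng.geometric(0.3, size=60))]
        once = filter_solutions(recs)
        assert filter_solutions(once) == once


class TestEffectiveSpaceFrequency:
    def test_share_of_spaces_in_keystroke_stream(self):
        recs = [rec(4, completed=True, patient=str(i)) for i in range(20)]
        assert effective_space_frequency(recs) == pytest.approx(20 / (80 + 20))

    def test_every_patient_completes_immediately(self):
        recs = [rec(1, completed=True, patient=str(i)) for i in range(10)]
        assert effective_space_frequency(recs) == pytest.approx(0.5)

    def test_no_completions(self):
        recs = [rec(3, completed=False, patient=str(i)) for i in range(4)]
        assert effective_space_frequency(recs) == 0.0

    def test_always_a_probability(self):
        rng = np.random.default_rng(11)
        recs = [rec(int(n), completed=bool(rng.random() < 0.5), patient=str(i))
                for i, n in enumerate(rng.geometric(0.25, size=100))]
        assert 0.0 <= effective_space_frequency(recs) <= 1.0


class TestInterventionSpace:
    def test_published_alphabet_counts(self):
        per_mode, total = count_intervention_space()
        assert per_mode == {"VC": 1458, "PC": 486}
        assert total == 1946

    @pytest.mark.parametrize("s", range(1, 9))
    def test_enumeration_matches_closed_form(self, s):
        per_mode, _ = count_intervention_space([ModeSpec(mode="M", n_settings=s)],
                                               n_mode_switches=0)
        assert per_mode["M"] == 2 * 3 ** s

    def test_keyboard_sizes(self):
        assert keyboard_size(VC_MODE) == 14
        assert keyboard_size(PC_MODE) == 12
        assert keyboard_size(ModeSpec(mode="X", n_settings=1)) == 4


class TestObservedVsNull:
    def test_self_consistency_with_matching_typist(self):
        spec = NullModelSpec(n_keys=13, q_space=0.2)
        lengths = simulate_monkey(spec, 100_000, seed=31)
        cmp_ = observed_vs_null(length_rank_table(list(lengths)), spec)
        assert cmp_.tv_distance <= 0.02

    def test_shares_sum_to_one(self):
        spec = NullModelSpec(n_keys=13, q_space=0.3)
        cmp_ = observed_vs_null(length_rank_table([1, 1, 2, 5, 5, 5]), spec)
        assert cmp_.table["observed_share"].sum() == pytest.approx(1.0, abs=1e-12)
        assert cmp_.table["null_share"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_length_maximally_divergent_from_diffuse_model(self):
        spec = NullModelSpec(n_keys=13, q_space=0.2)
        concentrated = observed_vs_null(length_rank_table([5] * 100), spec)
        matched = observed_vs_null(
            length_rank_table(list(simulate_monkey(spec, 50_000, seed=2))), spec)
        assert concentrated.tv_distance > 0.5 > matched.tv_distance

    def test_empty_observed_table_rejected(self):
        with pytest.raises(ValueError):
            observed_vs_null(length_rank_table([]), NullModelSpec(5, 0.2))


class TestPipelineSeparation:
    @pytest.mark.parametrize("seed", [11, 22, 33])
    def test_goal_directed_solutions_steeper_than_intermittent_silence(self, seed):
        """Geometric (goal-directed) solution lengths fall off much faster in
        rank than the stepwise typist prediction parameterized with the
        same data's effective space frequency."""
        cfg = VentSimConfig(n_subjects=8, n_patients_per_subject=40, seed=seed)
        rows = gen_vent_sessions(cfg)
        recs = filter_solutions(solution_lengths(rows))
        q_hat = effective_space_frequency(solution_lengths(rows))
        table = length_rank_table([r.n_interventions for r in recs])
        spec = NullModelSpec(n_keys=1946, q_space=q_hat)
        cmp_ = observed_vs_null(table, spec)
        assert cmp_.observed_slope < cmp_.null_block_slope < 0
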