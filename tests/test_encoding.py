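import itertools

import pytest

from carelex import (
    DEFAULT_MV_GOALS, DerangementSymbol, GoalRange, InterventionSymbol,
    build_vocabulary, encode_hd_derangement, encode_hd_intervention,
    encode_mv_derangement, encode_mv_intervention, enumerate_mv_interventions,
    last_k_patients, make_word, parse_word, validate_dyads,
)
from carelex.encoding import esa_tertile_cuts
from carelex.session_io import DialysisMonthRow

from conftest import pc_row, vc_row


def hd_month(patient="d1", month=0, hgb=11.0, ferritin=300.0, tsat=25.0,
             esa=5000.0, iron_given=0, iron_dose=0.0):
    return DialysisMonthRow(patient_id=patient, month_index=month, hgb=hgb,
                            ferritin=ferritin, tsat=tsat, esa_dose=esa,
                            iron_given=iron_given, iron_dose=iron_dose)


class TestMVDerangement:
    def test_mixed_derangement_codes_per_goal(self):
        row = vc_row(spo2=88.0, ph=7.50, map=70.0, pplat=32.0)
        assert encode_mv_derangement(row).codes == (0, 2, 1, 2)

    def test_all_within_goals(self):
        assert encode_mv_derangement(vc_row()).codes == (1, 1, 1, 1)

    @pytest.mark.parametrize("field,value,expected", [
        ("spo2", 90.0, (0, 1, 1, 1)),   # goal "> 90" is strict: 90 is below
        ("pplat", 30.0, (1, 1, 1, 2)),  # goal "< 30" is strict: 30 is above
        ("map", 65.0, (1, 1, 0, 1)),
        ("ph", 7.45, (1, 2, 1, 1)),
    ])
    def test_goal_boundaries_are_strict(self, field, value, expected):
        assert encode_mv_derangement(vc_row(**{field: value})).codes == expected

    def test_ph_lower_bound_overridable_per_patient(self):
        row = vc_row(ph=7.25)
        assert encode_mv_derangement(row).codes[1] == 0
        permissive = type(row)(**{**row.__dict__, "ph_lb": 7.20})
        assert encode_mv_derangement(permissive).codes[1] == 1

    def test_missing_goal_is_configuration_error(self):
        with pytest.raises(ValueError, match="pplat"):
            encode_mv_derangement(vc_row(), goals=DEFAULT_MV_GOALS[:3])


class TestMVIntervention:
    def test_direction_only_coding(self):
        prev = vc_row(step=0)
        curr = vc_row(step=1, fio2=0.6, rate=10.0)
        sym = encode_mv_intervention(prev, curr)
        assert sym.mv_mode == "VC"
        assert sym.mv_changes == (0, 0, 0, 1, 0, -1)
        assert sym.mv_bolus == 0

    def test_mode_change_yields_switch_symbol(self):
        sym = encode_mv_intervention(vc_row(step=0), pc_row(step=1))
        assert sym.mv_mode == "switch_to_PC"
        assert sym.mv_changes is None

    def test_pure_bolus_is_a_valid_nonempty_intervention(self):
        sym = encode_mv_intervention(vc_row(step=0), vc_row(step=1, bolus=1))
        assert sym.mv_changes == (0, 0, 0, 0, 0, 0)
        assert sym.mv_bolus == 1

    def test_cross_patient_rows_rejected(self):
        with pytest.raises(ValueError, match="different patients"):
            encode_mv_intervention(vc_row(patient="p01"), vc_row(patient="p02", step=1))


class TestHDDerangement:
    CUTS = (4000.0, 8000.0)

    def test_anemic_iron_deficient_falling(self):
        prev = hd_month(month=0, hgb=9.8)
        curr = hd_month(month=1, hgb=9.0, ferritin=150.0, tsat=15.0, esa=6000.0)
        sym = encode_hd_derangement(prev, curr, tertile_cuts=self.CUTS)
        assert sym.codes == (0, 0, 0, 2, 0, 1)

    def test_all_targets_met_stable(self):
        prev = hd_month(month=0, hgb=11.0)
        curr = hd_month(month=1, hgb=11.0, esa=0.0)
        sym = encode_hd_derangement(prev, curr, tertile_cuts=self.CUTS)
        assert sym.codes == (1, 1, 1, 0, 1, 0)

    def test_far_above_target_distance_bin(self):
        curr = hd_month(hgb=14.5)
        sym = encode_hd_derangement(None, curr, tertile_cuts=self.CUTS)
        assert sym.codes[5] == 3
        assert sym.codes[4] == 1  # first month: trend coded stable

    def test_tsat_20_is_below_target(self):
        sym = encode_hd_derangement(None, hd_month(tsat=20.0), tertile_cuts=self.CUTS)
        assert sym.codes[2] == 0

    def test_tertiles_from_positive_doses(self):
        rows = [hd_month(month=m, esa=d) for m, d in
                enumerate([0.0, 1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0])]
        c1, c2 = esa_tertile_cuts(rows)
        assert 1000.0 < c1 < c2 < 6000.0


class TestHDIntervention:
    @pytest.mark.parametrize("prev,curr,expected", [
        (10000.0, 16000.0, "up_gt50"),
        (10000.0, 13000.0, "up_25_50"),
        (10000.0, 11000.0, "none"),     # sub-threshold change
        (0.0, 5000.0, "start"),
        (5000.0, 0.0, "stop"),
        (10000.0, 6000.0, "down_25_50"),
        (10000.0, 4000.0, "down_gt50"),
        (0.0, 0.0, "none"),
    ])
    def test_esa_action_from_dose_ratio(self, prev, curr, expected):
        sym = encode_hd_intervention(hd_month(month=0, esa=prev),
                                     hd_month(month=1, esa=curr))
        assert sym.hd_esa_action == expected

    def test_ratio_sweep_matches_stated_bins(self):
        # oracle: the published category boundaries, checked over a fine grid
        for i in range(1, 401):
            r = i / 100.0
            sym = encode_hd_intervention(hd_month(month=0, esa=1000.0),
                                         hd_month(month=1, esa=1000.0 * r))
            if r > 1.5:
                want = "up_gt50"
            elif 1.25 <= r <= 1.5:
                want = "up_25_50"
            elif r < 0.5:
                want = "down_gt50"
            elif 0.5 <= r <= 0.75:
                want = "down_25_50"
            else:
                want = "none"
            assert sym.hd_esa_action == want, r

    @pytest.mark.parametrize("pg,pd,cg,cd,expected", [
        (0, 0.0, 1, 100.0, "start"),
        (1, 100.0, 0, 0.0, "stop"),
        (1, 100.0, 1, 150.0, "intensify"),
        (1, 100.0, 1, 100.0, "none"),
    ])
    def test_iron_actions(self, pg, pd, cg, cd, expected):
        sym = encode_hd_intervention(hd_month(month=0, iron_given=pg, iron_dose=pd),
                                     hd_month(month=1, iron_given=cg, iron_dose=cd))
        assert sym.hd_iron_action == expected


class TestWords:
    def test_canonical_rendering(self):
        d = DerangementSymbol(scheme="MV", codes=(0, 2, 1, 2))
        i = InterventionSymbol(scheme="MV", mv_mode="VC",
                               mv_changes=(0, 0, 0, 1, 0, -1), mv_bolus=0)
        assert make_word(d, i).canonical == "MV|D0212|VC:000+0-|B0"

    def test_scheme_mismatch_rejected(self):
        d = DerangementSymbol(scheme="MV", codes=(1, 1, 1, 1))
        i = InterventionSymbol(scheme="HD", hd_esa_action="none", hd_iron_action="none")
        with pytest.raises(ValueError, match="mismatch"):
            make_word(d, i)

    def test_exhaustive_vc_alphabet_is_injective_and_round_trips(self):
        derangements = [DerangementSymbol(scheme="MV", codes=c)
                        for c in itertools.product((0, 1, 2), repeat=4)]
        interventions = enumerate_mv_interventions("VC")
        assert len(interventions) == 1458
        seen = set()
        for d in derangements:
            for i in interventions:
                w = make_word(d, i)
                seen.add(w.canonical)
                back = parse_word(w.canonical)
                assert (back.derangement, back.intervention) == (d, i)
        assert len(seen) == 81 * 1458

    def test_hd_alphabet_round_trips(self):
        from carelex.encoding import ESA_ACTIONS, IRON_ACTIONS
        d = DerangementSymbol(scheme="HD", codes=(0, 1, 0, 3, 2, 1))
        for esa in ESA_ACTIONS:
            for iron in IRON_ACTIONS:
                i = InterventionSymbol(scheme="HD", hd_esa_action=esa,
                                       hd_iron_action=iron)
                w = make_word(d, i)
                back = parse_word(w.canonical)
                assert back.intervention == i and back.derangement == d

    def test_switch_words_round_trip(self):
        d = DerangementSymbol(scheme="MV", codes=(1, 1, 1, 1))
        for mode in ("switch_to_VC", "switch_to_PC"):
            i = InterventionSymbol(scheme="MV", mv_mode=mode, mv_bolus=1)
            assert parse_word(make_word(d, i).canonical).intervention == i


class TestVocabularyAndFilters:
    def test_build_vocabulary_counts(self):
        v = build_vocabulary(["w1", "w2", "w1"])
        assert v.counts == {"w1": 2, "w2": 1} and v.total_tokens == 3

    def test_empty_vocabulary(self):
        v = build_vocabulary([])
        assert v.counts == {} and v.total_tokens == 0

    def test_counts_invariant_under_permutation(self):
        a = build_vocabulary(["x", "y", "x", "z"])
        b = build_vocabulary(["z", "x", "y", "x"])
        assert a == b

    def test_validate_dyads_conserves_rows(self):
        rows = [vc_row(step=i) for i in range(99)]
        broken = vc_row(step=99)
        broken = type(broken)(**{**broken.__dict__, "pplat": None})
        clean, excluded = validate_dyads(rows + [broken])
        assert len(clean) == 99 and excluded == 1
        clean2, excluded2 = validate_dyads(rows)
        assert clean2 == rows and excluded2 == 0
        clean3, excluded3 = validate_dyads([broken] * 4)
        assert clean3 == [] and excluded3 == 4

    def test_last_k_patients_keeps_most_recent(self):
        rows = [vc_row(patient=f"p{i:02d}", step=0) for i in range(30)]
        kept = last_k_patients(rows, 25)
        assert sorted({r.patient_id for r in kept}) == [f"p{i:02d}" for i in range(5, 30)]

    def test_last_k_larger_than_cohort_keeps_all(self):
        rows = [vc_row(patient=f"p{i}", step=0) for i in range(3)]
        assert last_k_patients(rows, 25) == rows

    def test_last_k_independent_per_subject(self):
        rows = [vc_row(subject="sA", patient=f"p{i}", step=0) for i in range(4)]
        rows += [vc_row(subject="sB", patient=f"p{i}", step=0) for i in range(2)]
        kept = last_k_patients(rows, 2)
        assert {(r.subject_id, r.patient_id) for r in kept} == \
            {("sA", "p2"), ("sA", "p3"), ("sB", "p0"), ("sB", "p1")}
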