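"""Symbolic encoding of clinical sessions into derangement/intervention words.

The central move of this package is to treat medical practice as a
language.  At each decision point a patient's physiologic state is coded
as a *derangement symbol* — for each goal variable, whether the value is
below, within, or above its goal range — and the practitioner's
contemporaneous ensemble of actions is coded as an *intervention symbol*
(direction of change per setting, magnitude discarded).  Concatenating
the two gives a *word*; the frequency spectrum of the resulting
vocabulary is what the rank-frequency analysis operates on.

Two encoding schemes are implemented:

* ``MV`` — mechanical ventilation.  Four goal variables (SpO2 > 90%,
  lower bound < pH < 7.45, MAP > 65 mmHg, Pplat < 30 cmH2O) give a
  4-tuple derangement code; the intervention is the per-setting change
  direction for the active mode (VC: tidal volume, flow, pause, FiO2,
  PEEP, rate; PC: Pinsp, I-time, FiO2, PEEP, rate), a fluid-bolus flag,
  or a mode switch.
* ``HD`` — hemodialysis anemia management.  Six derangement elements
  (hemoglobin vs 10-12 g/dL, ferritin vs 200-500 ng/mL, TSAT vs 20%,
  ESA-dose tertile, month-over-month hemoglobin trend, and distance of
  hemoglobin from the target band); the intervention is the ESA action
  (start/stop/±25-50%/±>50%) and the iron action (start/stop/intensify).

Goal inequalities are honored exactly as stated: ">" and "<" are strict,
so SpO2 = 90 codes *below*, Pplat = 30 codes *within*, TSAT = 20 codes
*below*.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .session_io import (
    DialysisMonthRow,
    PC_SETTINGS,
    VC_SETTINGS,
    VentEventRow,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GoalRange",
    "DerangementSymbol",
    "InterventionSymbol",
    "Word",
    "VocabularyCounts",
    "BELOW", "WITHIN", "ABOVE",
    "DEFAULT_MV_GOALS",
    "DEFAULT_HD_TARGETS",
    "encode_mv_derangement",
    "encode_mv_intervention",
    "encode_hd_derangement",
    "encode_hd_intervention",
    "esa_tertile_cuts",
    "make_word",
    "parse_word",
    "build_vocabulary",
    "validate_dyads",
    "last_k_patients",
    "encode_vent_words",
    "encode_dialysis_words",
    "enumerate_mv_interventions",
]

BELOW, WITHIN, ABOVE = 0, 1, 2

ESA_ACTIONS = ("none", "start", "stop", "up_25_50", "up_gt50", "down_25_50", "down_gt50")
IRON_ACTIONS = ("none", "start", "stop", "intensify")
_ESA_CODE = {"none": "0", "start": "S", "stop": "X", "up_25_50": "U1",
             "up_gt50": "U2", "down_25_50": "D1", "down_gt50": "D2"}
_ESA_FROM_CODE = {v: k for k, v in _ESA_CODE.items()}
_IRON_CODE = {"none": "0", "start": "S", "stop": "X", "intensify": "I"}
_IRON_FROM_CODE = {v: k for k, v in _IRON_CODE.items()}
_SIGN_CHAR = {-1: "-", 0: "0", 1: "+"}
_SIGN_FROM_CHAR = {v: k for k, v in _SIGN_CHAR.items()}


@dataclass(frozen=True)
class GoalRange:
    """A goal range for one variable; one-sided ranges leave a bound None."""

    variable: str
    lower: float | None = None
    upper: float | None = None
    strict_lower: bool = True
    strict_upper: bool = True

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError(f"goal for {self.variable!r} needs at least one bound")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"goal for {self.variable!r}: lower must be < upper")

    def classify(self, value: float) -> int:
        """Code ``value`` as BELOW(0) / WITHIN(1) / ABOVE(2) this range."""
        if self.lower is not None:
            low = value <= self.lower if self.strict_lower else value < self.lower
            if low:
                return BELOW
        if self.upper is not None:
            high = value >= self.upper if self.strict_upper else value > self.upper
            if high:
                return ABOVE
        return WITHIN


#: Default mechanical-ventilation goal ranges.  The pH lower bound is
#: disease-specific; 7.30 is the package default and can be overridden
#: per patient via the optional ``ph_lb`` column.
DEFAULT_MV_GOALS: tuple[GoalRange, ...] = (
    GoalRange("spo2", lower=90.0),
    GoalRange("ph", lower=7.30, upper=7.45),
    GoalRange("map", lower=65.0),
    GoalRange("pplat", upper=30.0),
)

#: Default dialysis target ranges (hemoglobin g/dL, ferritin ng/mL, TSAT %).
DEFAULT_HD_TARGETS: tuple[GoalRange, ...] = (
    GoalRange("hgb", lower=10.0, upper=12.0),
    GoalRange("ferritin", lower=200.0, upper=500.0),
    GoalRange("tsat", lower=20.0),
)

MV_GOAL_VARIABLES = ("spo2", "ph", "map", "pplat")


@dataclass(frozen=True)
class DerangementSymbol:
    """Discrete code for the pattern of physiologic derangement.

    ``codes`` has length 4 for the MV scheme and 6 for HD; see the
    module docstring for element order and alphabets.
    """

    scheme: str            # MV | HD
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = 4 if self.scheme == "MV" else 6
        if len(self.codes) != expected:
            raise ValueError(f"{self.scheme} derangement needs {expected} codes")


@dataclass(frozen=True)
class InterventionSymbol:
    """Discrete code for the practitioner's contemporaneous response.

    Exactly one scheme's fields are populated.  For MV, ``mv_mode`` is
    the mode the change tuple refers to, or a switch marker
    (``switch_to_VC`` / ``switch_to_PC``) carrying no change tuple.
    """

    scheme: str
    mv_mode: str | None = None                 # VC | PC | switch_to_VC | switch_to_PC
    mv_changes: tuple[int, ...] | None = None  # per-setting -1/0/+1
    mv_bolus: int = 0
    hd_esa_action: str | None = None
    hd_iron_action: str | None = None

    def __post_init__(self) -> None:
        if self.scheme == "MV":
            if self.mv_mode in ("switch_to_VC", "switch_to_PC"):
                if self.mv_changes is not None:
                    raise ValueError("mode-switch symbol carries no change tuple")
            else:
                n = len(VC_SETTINGS) if self.mv_mode == "VC" else len(PC_SETTINGS)
                if self.mv_changes is None or len(self.mv_changes) != n:
                    raise ValueError(f"{self.mv_mode} change tuple must have {n} entries")
        elif self.scheme == "HD":
            if self.hd_esa_action not in ESA_ACTIONS or self.hd_iron_action not in IRON_ACTIONS:
                raise ValueError("HD symbol needs valid ESA and iron actions")
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class Word:
    """A derangement symbol concatenated with its contemporaneous intervention."""

    derangement: DerangementSymbol
    intervention: InterventionSymbol
    canonical: str


@dataclass(frozen=True)
class VocabularyCounts:
    """Word-frequency histogram over canonical strings."""

    counts: Mapping[str, int]
    total_tokens: int


def encode_mv_derangement(row: VentEventRow,
                          goals: Sequence[GoalRange] = DEFAULT_MV_GOALS) -> DerangementSymbol:
    """Code the four MV goal variables as a below/within/above 4-tuple."""
    by_var = {g.variable: g for g in goals}
    missing = [v for v in MV_GOAL_VARIABLES if v not in by_var]
    if missing:
        raise ValueError(f"no goal range configured for: {', '.join(missing)}")
    codes = []
    for var in MV_GOAL_VARIABLES:
        value = getattr(row, var)
        if value is None or not math.isfinite(value):
            raise ValueError(f"row has no finite {var!r}")
        goal = by_var[var]
        if var == "ph" and row.ph_lb is not None:
            goal = replace(goal, lower=row.ph_lb)
        codes.append(goal.classify(value))
    return DerangementSymbol(scheme="MV", codes=tuple(codes))


def encode_mv_intervention(prev: VentEventRow, curr: VentEventRow) -> InterventionSymbol:
    """Code the settings change from ``prev`` to ``curr`` (direction only).

    A mode change yields a switch symbol; otherwise each setting of the
    shared mode contributes sign(curr - prev), and the bolus flag is
    taken from ``curr``.
    """
    if (prev.subject_id, prev.patient_id) != (curr.subject_id, curr.patient_id):
        raise ValueError("rows belong to different patients")
    if not prev.step_index < curr.step_index:
        raise ValueError("steps out of order")
    if prev.mode != curr.mode:
        return InterventionSymbol(scheme="MV", mv_mode=f"switch_to_{curr.mode}",
                                  mv_bolus=int(curr.bolus))
    names = VC_SETTINGS if curr.mode == "VC" else PC_SETTINGS
    changes = []
    for name in names:
        a, b = getattr(prev, name), getattr(curr, name)
        if a is None or b is None:
            raise ValueError(f"setting {name!r} missing for mode {curr.mode}")
        diff = b - a
        changes.append(0 if diff == 0 else (1 if diff > 0 else -1))
    return InterventionSymbol(scheme="MV", mv_mode=curr.mode,
                              mv_changes=tuple(changes), mv_bolus=int(curr.bolus))


def esa_tertile_cuts(rows: Iterable[DialysisMonthRow]) -> tuple[float, float]:
    """Tertile cut points of the positive ESA doses across the whole dataset."""
    import numpy as np

    doses = [r.esa_dose for r in rows if r.esa_dose > 0]
    if not doses:
        raise ValueError("no positive ESA doses in dataset")
    q1, q2 = np.quantile(doses, [1 / 3, 2 / 3])
    return float(q1), float(q2)


def _hgb_distance_bin(hgb: float, goal: GoalRange) -> int:
    """0 = in range, 1 = ≤1 g/dL outside, 2 = ≤2, 3 = >2."""
    if goal.classify(hgb) == WITHIN:
        return 0
    dist = (goal.lower - hgb) if hgb <= goal.lower else (hgb - goal.upper)
    if dist <= 1.0:
        return 1
    if dist <= 2.0:
        return 2
    return 3


def encode_hd_derangement(prev: DialysisMonthRow | None,
                          curr: DialysisMonthRow,
                          targets: Sequence[GoalRange] = DEFAULT_HD_TARGETS,
                          tertile_cuts: tuple[float, float] = (0.0, 0.0),
                          stable_delta: float = 0.5) -> DerangementSymbol:
    """Code one patient-month as a 6-element derangement tuple.

    Elements: hemoglobin state (0-2), ferritin state (0-2), TSAT state
    (0 below / 1 at-or-above 20%), ESA tertile (0 none, 1-3 = T1-T3),
    hemoglobin trend vs the previous available month (0 falling,
    1 stable, 2 rising; stable = |Δ| ≤ ``stable_delta`` g/dL), and
    distance of hemoglobin from the target band (0 in-range, 1 ≤1,
    2 ≤2, 3 >2 g/dL outside).  A missing previous month codes the trend
    as stable (first-month convention).
    """
    by_var = {g.variable: g for g in targets}
    hgb_goal, ferr_goal, tsat_goal = by_var["hgb"], by_var["ferritin"], by_var["tsat"]
    hgb_state = hgb_goal.classify(curr.hgb)
    ferr_state = ferr_goal.classify(curr.ferritin)
    tsat_state = 0 if tsat_goal.classify(curr.tsat) == BELOW else 1
    if curr.esa_dose <= 0:
        tertile = 0
    else:
        c1, c2 = tertile_cuts
        tertile = 1 if curr.esa_dose <= c1 else (2 if curr.esa_dose <= c2 else 3)
    if prev is None:
        trend = 1
        logger.debug("patient %s month %d: no previous month, trend coded stable",
                     curr.patient_id, curr.month_index)
    else:
        delta = curr.hgb - prev.hgb
        trend = 1 if abs(delta) <= stable_delta else (0 if delta < 0 else 2)
    dist = _hgb_distance_bin(curr.hgb, hgb_goal)
    return DerangementSymbol(scheme="HD",
                             codes=(hgb_state, ferr_state, tsat_state, tertile, trend, dist))


def encode_hd_intervention(prev: DialysisMonthRow, curr: DialysisMonthRow) -> InterventionSymbol:
    """Code the ESA and iron actions between two consecutive available months.

    ESA action from the dose ratio r = curr/prev: start (0 -> >0), stop
    (>0 -> 0), up_25_50 for 1.25 ≤ r ≤ 1.5, up_gt50 for r > 1.5,
    down_25_50 for 0.5 ≤ r ≤ 0.75, down_gt50 for r < 0.5; ratios in the
    unassigned gaps (sub-25% changes) code as none.
    """
    if prev.patient_id != curr.patient_id:
        raise ValueError("rows belong to different patients")
    if prev.esa_dose == 0 and curr.esa_dose == 0:
        esa = "none"
    elif prev.esa_dose == 0:
        esa = "start"
    elif curr.esa_dose == 0:
        esa = "stop"
    else:
        r = curr.esa_dose / prev.esa_dose
        if r > 1.5:
            esa = "up_gt50"
        elif r >= 1.25:
            esa = "up_25_50"
        elif r < 0.5:
            esa = "down_gt50"
        elif r <= 0.75:
            esa = "down_25_50"
        else:
            esa = "none"
    prev_iron = prev.iron_dose if prev.iron_given else 0.0
    curr_iron = curr.iron_dose if curr.iron_given else 0.0
    if prev_iron == 0 and curr_iron > 0:
        iron = "start"
    elif prev_iron > 0 and curr_iron == 0:
        iron = "stop"
    elif curr_iron > prev_iron > 0:
        iron = "intensify"
    else:
        iron = "none"
    return InterventionSymbol(scheme="HD", hd_esa_action=esa, hd_iron_action=iron)


def _mv_intervention_str(i: InterventionSymbol) -> str:
    if i.mv_mode == "switch_to_VC":
        core = "SW>VC"
    elif i.mv_mode == "switch_to_PC":
        core = "SW>PC"
    else:
        signs = "".join(_SIGN_CHAR[c] for c in i.mv_changes)
        core = f"{i.mv_mode}:{signs}"
    return f"{core}|B{i.mv_bolus}"


def make_word(d: DerangementSymbol, i: InterventionSymbol) -> Word:
    """Concatenate a derangement and intervention symbol into a canonical word.

    Grammar: ``MV|D<4 digits>|<VC|PC|SW>VC|SW>PC>[:<signs>]|B<0|1>`` and
    ``HD|D<6 codes>|E<esa>|I<iron>``.  The rendering is injective and
    :func:`parse_word` inverts it.
    """
    if d.scheme != i.scheme:
        raise ValueError(f"scheme mismatch: {d.scheme} vs {i.scheme}")
    dstr = "D" + "".join(str(c) for c in d.codes)
    if d.scheme == "MV":
        canonical = f"MV|{dstr}|{_mv_intervention_str(i)}"
    else:
        canonical = f"HD|{dstr}|E{_ESA_CODE[i.hd_esa_action]}|I{_IRON_CODE[i.hd_iron_action]}"
    return Word(derangement=d, intervention=i, canonical=canonical)


def parse_word(canonical: str) -> Word:
    """Parse a canonical word string back into its symbol pair."""
    parts = canonical.split("|")
    scheme = parts[0]
    codes = tuple(int(c) for c in parts[1][1:])
    d = DerangementSymbol(scheme=scheme, codes=codes)
    if scheme == "MV":
        if len(parts) != 4:
            raise ValueError(f"malformed MV word {canonical!r}")
        mode_part, bolus_part = parts[2], parts[3]
        bolus = int(bolus_part[1:])
        if mode_part.startswith("SW>"):
            i = InterventionSymbol(scheme="MV", mv_mode=f"switch_to_{mode_part[3:]}",
                                   mv_bolus=bolus)
        else:
            mode, signs = mode_part.split(":")
            changes = tuple(_SIGN_FROM_CHAR[ch] for ch in signs)
            i = InterventionSymbol(scheme="MV", mv_mode=mode, mv_changes=changes,
                                   mv_bolus=bolus)
    elif scheme == "HD":
        i = InterventionSymbol(scheme="HD",
                               hd_esa_action=_ESA_FROM_CODE[parts[2][1:]],
                               hd_iron_action=_IRON_FROM_CODE[parts[3][1:]])
    else:
        raise ValueError(f"unknown scheme in {canonical!r}")
    return make_word(d, i)


def build_vocabulary(words: Iterable[Word | str]) -> VocabularyCounts:
    """Count word occurrences over canonical strings."""
    counts = Counter(w.canonical if isinstance(w, Word) else w for w in words)
    return VocabularyCounts(counts=dict(counts), total_tokens=sum(counts.values()))


def validate_dyads(rows: Sequence[VentEventRow]) -> tuple[list[VentEventRow], int]:
    """Drop adjust rows with missing physiologic or mode-required setting fields.

    The analogue of excluding the incomplete dyads that keystroke errors
    produce in a hand-operated logger.  Conserves row count:
    clean + excluded = input size.
    """
    clean: list[VentEventRow] = []
    excluded = 0
    for row in rows:
        if row.event_type != "adjust":
            clean.append(row)
            continue
        needed = list(MV_GOAL_VARIABLES)
        needed += list(VC_SETTINGS if row.mode == "VC" else PC_SETTINGS)
        ok = row.mode in ("VC", "PC") and all(
            getattr(row, f) is not None and math.isfinite(getattr(row, f)) for f in needed
        )
        if ok:
            clean.append(row)
        else:
            excluded += 1
    return clean, excluded


def last_k_patients(rows: Sequence[VentEventRow], k: int) -> list[VentEventRow]:
    """Keep, per subject, only the last ``k`` virtual patients encountered.

    Patient order is first-appearance order within the subject's stream,
    which the step-sorted log preserves via patient ids assigned in
    management order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order: dict[str, list[str]] = {}
    for row in rows:
        patients = order.setdefault(row.subject_id, [])
        if row.patient_id not in patients:
            patients.append(row.patient_id)
    keep: dict[str, set[str]] = {}
    for subject, patients in order.items():
        if len(patients) < k:
            logger.warning("subject %s has only %d patients (< k=%d); keeping all",
                           subject, len(patients), k)
        keep[subject] = set(patients[-k:])
    return [r for r in rows if r.patient_id in keep[r.subject_id]]


def encode_vent_words(rows: Sequence[VentEventRow],
                      goals: Sequence[GoalRange] = DEFAULT_MV_GOALS,
                      ) -> list[tuple[str, Word]]:
    """Encode a validated vent log into (subject_id, Word) dyads.

    For each patient, consecutive adjust rows (prev, curr) yield one
    word: the derangement observed at ``curr`` (the state prior to that
    adjustment being resolved) with the intervention taking the settings
    from prev to curr.  The baseline row contributes no word of its own.
    """
    out: list[tuple[str, Word]] = []
    by_patient: dict[tuple[str, str], list[VentEventRow]] = {}
    for r in rows:
        if r.event_type == "adjust":
            by_patient.setdefault((r.subject_id, r.patient_id), []).append(r)
    for (subject, _patient), seq in sorted(by_patient.items()):
        seq.sort(key=lambda r: r.step_index)
        for prev, curr in zip(seq, seq[1:]):
            d = encode_mv_derangement(curr, goals)
            i = encode_mv_intervention(prev, curr)
            out.append((subject, make_word(d, i)))
    return out


def encode_dialysis_words(rows: Sequence[DialysisMonthRow],
                          targets: Sequence[GoalRange] = DEFAULT_HD_TARGETS,
                          ) -> list[tuple[str, Word]]:
    """Encode a dialysis log into (patient_id, Word) dyads over consecutive months."""
    cuts = esa_tertile_cuts(rows)
    by_patient: dict[str, list[DialysisMonthRow]] = {}
    for r in rows:
        by_patient.setdefault(r.patient_id, []).append(r)
    out: list[tuple[str, Word]] = []
    for patient, seq in sorted(by_patient.items()):
        seq.sort(key=lambda r: r.month_index)
        for idx in range(1, len(seq)):
            prev, curr = seq[idx - 1], seq[idx]
            before = seq[idx - 1]  # immediately preceding available month
            d = encode_hd_derangement(before, curr, targets, cuts)
            i = encode_hd_intervention(prev, curr)
            out.append((patient, make_word(d, i)))
    return out


def enumerate_mv_interventions(mode: str) -> list[InterventionSymbol]:
    """Explicitly enumerate every non-switch intervention symbol for a mode.

    VC has 6 settings and PC 5; each setting takes a direction in
    {-1, 0, +1} and the bolus flag doubles the count, so the alphabets
    have 2·3^6 = 1458 and 2·3^5 = 486 members (the all-unchanged,
    no-bolus pattern included).
    """
    from itertools import product

    n = len(VC_SETTINGS) if mode == "VC" else len(PC_SETTINGS)
    out = []
    for changes in product((-1, 0, 1), repeat=n):
        for bolus in (0, 1):
            out.append(InterventionSymbol(scheme="MV", mv_mode=mode,
                                          mv_changes=changes, mv_bolus=bolus))
    return out
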