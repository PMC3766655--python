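"""Seeded synthetic generators with the statistical structure the analysis assumes.

The original study's session logs (29 subjects each managing 100 virtual
ventilation patients; ~30 dialysis patients followed monthly for three
years) were never deposited, so every pipeline stage here is exercised
on generated data whose *generating truth is known*:

* :func:`gen_zipf_tokens` — i.i.d. tokens from an exact Zipf(a) source,
  for fit-recovery tests;
* :func:`gen_monkey_text` — words typed by an intermittent-silence
  typist, for validating the null models;
* :func:`gen_vent_sessions` — multi-subject ventilation sessions whose
  practitioners follow a heavy-tailed (conditional-Zipf) intervention
  policy and complete patients at a fixed per-step probability, so
  solution lengths are geometric and the encoded word stream is a
  Zipf mixture with a recoverable exponent;
* :func:`gen_dialysis_records` — monthly anemia-management records with
  mean-reverting hemoglobin dynamics and a concentrated stochastic
  prescriber policy.

All generators are pure functions of (config, seed); no global random
state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import enumerate_mv_interventions
from .null_models import NullModelSpec
from .session_io import DialysisMonthRow, VC_SETTINGS, PC_SETTINGS, VentEventRow

__all__ = [
    "VentSimConfig",
    "HDSimConfig",
    "gen_zipf_tokens",
    "gen_monkey_text",
    "gen_vent_sessions",
    "gen_dialysis_records",
]


def _zipf_probs(V: int, a: float) -> np.ndarray:
    ranks = np.arange(1, V + 1, dtype=float)
    w = ranks ** (-a)
    return w / w.sum()


def gen_zipf_tokens(V: int, a: float, n: int, seed: int) -> list[str]:
    """n i.i.d. tokens ``w0001..wV`` with P(rank i) proportional to i^-a."""
    if V < 2:
        raise ValueError("V must be >= 2")
    if a < 0:
        raise ValueError("a must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(V, size=n, p=_zipf_probs(V, a))
    width = len(str(V))
    return [f"w{i + 1:0{width}d}" for i in idx]


def gen_monkey_text(spec: NullModelSpec, n_words: int, seed: int) -> list[str]:
    """``n_words`` non-empty words typed by an intermittent-silence typist.

    Each word's length is geometric conditioned on >= 1 (consecutive
    spaces produce no word), and its letters are uniform draws from an
    N-key alphabet; keys are rendered as dot-joined indices so any N is
    supported.  Conditional mean length is 1/q.
    """
    rng = np.random.default_rng(seed)
    q = spec.q_space
    # geometric(q) is exactly the law of L conditioned on L >= 1
    lengths = rng.geometric(q, size=n_words)
    words = []
    for L in lengths:
        keys = rng.integers(0, spec.n_keys, size=L)
        words.append(".".join(str(k) for k in keys))
    return words


@dataclass(frozen=True)
class VentSimConfig:
    """Study conditions for the synthetic mechanical-ventilation sessions.

    Defaults mirror the original study design: 29 subjects (trainees to
    faculty) each managing 100 virtual patients, with a per-step
    completion probability of 0.2 — the observed effective space
    frequency — and a practice policy whose word usage is Zipf with
    exponent 0.95, the population-level slope magnitude.
    ``derangement_mix`` weights a small repertoire of recurring
    derangement states; ``mode_mix`` is the (VC, PC) share of patients;
    ``p_switch`` is the per-step chance of a ventilation-mode switch.
    """

    n_subjects: int = 29
    n_patients_per_subject: int = 100
    policy_exponent: float = 0.95
    p_complete_per_step: float = 0.2
    derangement_mix: tuple[float, ...] = (0.35, 0.25, 0.15, 0.10, 0.08, 0.04, 0.02, 0.01)
    mode_mix: tuple[float, float] = (0.7, 0.3)
    p_switch: float = 0.02
    max_steps: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.policy_exponent <= 0:
            raise ValueError("policy_exponent must be > 0")
        if not 0.0 < self.p_complete_per_step < 1.0:
            raise ValueError("p_complete_per_step must lie in (0, 1)")
        if not math.isclose(sum(self.derangement_mix), 1.0, rel_tol=1e-9):
            raise ValueError("derangement_mix must sum to 1")
        if not math.isclose(sum(self.mode_mix), 1.0, rel_tol=1e-9):
            raise ValueError("mode_mix must sum to 1")


# A small repertoire of recurring derangement states (codes over the four
# goal variables) with physiologic values that encode to each state under
# the default goals.  Values are (spo2, ph, map, pplat).
_DERANGEMENT_STATES: tuple[tuple[tuple[int, int, int, int], tuple[float, float, float, float]], ...] = (
    ((1, 1, 1, 1), (95.0, 7.38, 75.0, 22.0)),   # all within goals
    ((0, 1, 1, 1), (86.0, 7.38, 75.0, 22.0)),   # hypoxemic
    ((1, 0, 1, 1), (95.0, 7.21, 75.0, 22.0)),   # acidemic
    ((1, 1, 1, 2), (95.0, 7.38, 75.0, 34.0)),   # high plateau pressure
    ((0, 0, 1, 1), (87.0, 7.18, 75.0, 22.0)),   # hypoxemic + acidemic
    ((1, 1, 0, 1), (95.0, 7.38, 58.0, 22.0)),   # hypotensive
    ((0, 1, 1, 2), (88.0, 7.38, 75.0, 33.0)),   # hypoxemic + high Pplat
    ((1, 2, 1, 1), (95.0, 7.49, 75.0, 24.0)),   # alkalemic
)

# Step magnitudes applied when a drawn intervention moves a setting.
_STEP = {"tv": 50.0, "flow": 5.0, "pause": 0.1, "fio2": 0.05, "peep": 1.0,
         "rate": 2.0, "pinsp": 2.0, "itime": 0.1}

_BASE_VC = {"tv": 450.0, "flow": 60.0, "pause": 0.5, "fio2": 0.5, "peep": 8.0, "rate": 16.0}
_BASE_PC = {"pinsp": 20.0, "itime": 1.0, "fio2": 0.5, "peep": 8.0, "rate": 16.0}


class _WordPolicy:
    """A population-wide Zipf(a) word usage law over (state, mode, intervention).

    A single global ranked word list carries probability proportional to
    rank**-a.  Global ranks are dealt greedily (largest-remainder, with
    cell capacities) across the derangement-state x mode cells with
    dealing weights (w_d * v_m)**(1/a), which makes each cell's mass
    proportional to w_d * v_m and each cell's conditional law Zipf(a)
    over that cell's own preference ordering — so the population stream,
    every subject's stream, and every single-state stream share the same
    exponent.  Orderings within a cell are a seeded permutation of the
    mode's full intervention alphabet: the population's habitual
    responses to each situation.
    """

    def __init__(self, a: float, state_mix: np.ndarray, mode_mix: np.ndarray,
                 rng: np.random.Generator) -> None:
        self.alphabet = {"VC": enumerate_mv_interventions("VC"),
                         "PC": enumerate_mv_interventions("PC")}
        modes = ("VC", "PC")
        n_states = len(state_mix)
        cells = [(d, m) for d in range(n_states) for m in modes]
        cap = np.array([len(self.alphabet[m]) for _, m in cells])
        u = np.array([(state_mix[d] * mode_mix[i % 2]) ** (1.0 / a)
                      for d, m in cells for i in [modes.index(m)]])
        u = u / u.sum()
        total = int(cap.sum())
        assigned = np.zeros(len(cells), dtype=np.int64)
        cell_of_rank = np.empty(total, dtype=np.int64)
        for k in range(total):
            score = u * (k + 1) - assigned
            score[assigned >= cap] = -np.inf
            c = int(np.argmax(score))
            cell_of_rank[k] = c
            assigned[c] += 1
        probs = np.arange(1, total + 1, dtype=float) ** (-a)
        probs /= probs.sum()
        perms = {(d, m): rng.permutation(len(self.alphabet[m]))
                 for d in range(n_states) for m in modes}
        slot_index = np.zeros(total, dtype=np.int64)  # within-cell rank j-1
        counters = np.zeros(len(cells), dtype=np.int64)
        for k in range(total):
            c = cell_of_rank[k]
            slot_index[k] = counters[c]
            counters[c] += 1
        # per-mode sampling tables: global ranks, cdf, state, intervention
        self._tables = {}
        for mi, m in enumerate(modes):
            mask = np.array([cells[c][1] == m for c in cell_of_rank])
            ranks = np.nonzero(mask)[0]
            p = probs[ranks]
            cdf = np.cumsum(p / p.sum())
            states = np.array([cells[c][0] for c in cell_of_rank[ranks]])
            interv = np.array([perms[cells[c]][slot_index[k]]
                               for k, c in zip(ranks, cell_of_rank[ranks])])
            self._tables[m] = (cdf, states, interv)

    def draw(self, mode: str, rng: np.random.Generator):
        """Return (state_index, InterventionSymbol) for the current mode."""
        cdf, states, interv = self._tables[mode]
        i = int(np.searchsorted(cdf, rng.random(), side="right"))
        i = min(i, len(states) - 1)
        return int(states[i]), self.alphabet[mode][int(interv[i])]


def gen_vent_sessions(cfg: VentSimConfig) -> list[VentEventRow]:
    """Generate schema-valid ventilation sessions under a Zipf word-usage policy.

    At each step the (derangement, intervention) word is drawn from a
    population-wide Zipf(``policy_exponent``) usage law conditioned on
    the current ventilation mode (see :class:`_WordPolicy`); the row's
    physiologic values realize the drawn derangement state and the
    settings move by fixed step sizes in the drawn directions.  Patients
    complete with probability ``p_complete_per_step`` after each
    intervention (geometric solution lengths, mean (1-p)/p) and are
    abandoned at ``max_steps``.
    """
    rng = np.random.default_rng(cfg.seed)
    mix = np.asarray(cfg.derangement_mix, dtype=float)
    n_states = len(_DERANGEMENT_STATES)
    if len(mix) != n_states:
        raise ValueError(f"derangement_mix must have {n_states} entries")
    policy = _WordPolicy(cfg.policy_exponent, mix, np.asarray(cfg.mode_mix), rng)
    rows: list[VentEventRow] = []
    pat_width = len(str(cfg.n_patients_per_subject))
    for s in range(cfg.n_subjects):
        subject = f"s{s + 1:02d}"
        for p in range(cfg.n_patients_per_subject):
            patient = f"p{p + 1:0{pat_width}d}"
            mode = "VC" if rng.random() < cfg.mode_mix[0] else "PC"
            settings = dict(_BASE_VC if mode == "VC" else _BASE_PC)
            state_idx = int(rng.choice(n_states, p=mix))
            rows.append(_vent_row(subject, patient, 0, state_idx, mode, settings, 0))
            step = 0
            completed = False
            while step < cfg.max_steps:
                if rng.random() < cfg.p_complete_per_step:
                    completed = True
                    break
                step += 1
                if rng.random() < cfg.p_switch:
                    mode = "PC" if mode == "VC" else "VC"
                    settings = dict(_BASE_PC if mode == "PC" else _BASE_VC)
                    state_idx = int(rng.choice(n_states, p=mix))
                    bolus = int(rng.random() < 0.1)
                else:
                    state_idx, sym = policy.draw(mode, rng)
                    names = VC_SETTINGS if mode == "VC" else PC_SETTINGS
                    for name, direction in zip(names, sym.mv_changes):
                        settings[name] = settings[name] + direction * _STEP[name]
                    bolus = sym.mv_bolus
                rows.append(_vent_row(subject, patient, step, state_idx, mode,
                                      settings, bolus))
            final = "complete" if completed else "abandon"
            rows.append(VentEventRow(subject_id=subject, patient_id=patient,
                                     step_index=step + 1, event_type=final))
    return rows


def _vent_row(subject: str, patient: str, step: int, state_idx: int, mode: str,
              settings: dict[str, float], bolus: int) -> VentEventRow:
    _codes, (spo2, ph, mapv, pplat) = _DERANGEMENT_STATES[state_idx]
    return VentEventRow(subject_id=subject, patient_id=patient, step_index=step,
                        event_type="adjust", spo2=spo2, ph=ph, map=mapv, pplat=pplat,
                        mode=mode, bolus=bolus,
                        **{k: round(v, 6) for k, v in settings.items()})


@dataclass(frozen=True)
class HDSimConfig:
    """Study conditions for the synthetic dialysis records.

    Defaults emulate a medium-size dialysis unit: ~30 patients followed
    monthly for three years, hemoglobin responding to ESA dose with
    month-to-month noise, and no fixed treatment protocol — prescribers
    act stochastically with a strong preference for a few habitual
    responses per situation.
    """

    n_patients: int = 30
    n_months: int = 36
    hgb_noise_sd: float = 0.5       # g/dL month-to-month noise
    esa_response_gain: float = 1.2  # g/dL per unit log-dose-ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 2:
            raise ValueError("n_months must be >= 2")


def gen_dialysis_records(cfg: HDSimConfig) -> list[DialysisMonthRow]:
    """Generate monthly anemia-management records for a dialysis cohort.

    Hemoglobin mean-reverts toward a dose-dependent setpoint
    (10 + gain·ln(1 + dose/5000) g/dL) with Gaussian noise; the
    prescriber reacts to the hemoglobin band with a concentrated
    stochastic policy whose ESA moves land exactly in the coding bins
    (±30% / ±75%, start/stop) and whose iron moves react to TSAT and
    ferritin.  Output is schema-valid and encodes without error.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[DialysisMonthRow] = []
    for pid in range(cfg.n_patients):
        patient = f"d{pid + 1:02d}"
        hgb = float(rng.normal(10.5, 1.2))
        ferritin = float(rng.normal(350.0, 120.0))
        tsat = float(rng.normal(25.0, 6.0))
        esa = float(rng.choice([0.0, 4000.0, 8000.0, 12000.0], p=[0.2, 0.3, 0.3, 0.2]))
        iron = float(rng.choice([0.0, 100.0], p=[0.6, 0.4]))
        for month in range(cfg.n_months):
            rows.append(DialysisMonthRow(
                patient_id=patient, month_index=month, hgb=round(hgb, 2),
                ferritin=round(max(ferritin, 10.0), 1), tsat=round(max(tsat, 2.0), 1),
                esa_dose=round(esa, 1), iron_given=int(iron > 0),
                iron_dose=round(iron, 1)))
            esa = _esa_policy(rng, hgb, esa)
            iron = _iron_policy(rng, tsat, ferritin, iron)
            setpoint = 10.0 + cfg.esa_response_gain * math.log1p(esa / 5000.0)
            hgb += 0.45 * (setpoint - hgb) + float(rng.normal(0.0, cfg.hgb_noise_sd))
            ferritin += (30.0 if iron > 0 else -20.0) + float(rng.normal(0.0, 25.0))
            ferritin = max(ferritin, 10.0)
            tsat += (2.0 if iron > 0 else -1.0) + float(rng.normal(0.0, 2.0))
            tsat = float(np.clip(tsat, 2.0, 60.0))
    return rows


def _esa_policy(rng: np.random.Generator, hgb: float, esa: float) -> float:
    """Heavy-tailed ESA prescribing: usually the habitual move, sometimes not."""
    if hgb < 10.0:
        if esa == 0:
            return 5000.0 if rng.random() < 0.8 else 0.0
        u = rng.random()
        if u < 0.55:
            return esa            # watchful waiting is the modal response
        if u < 0.85:
            return esa * 1.3      # +25-50% bin
        return esa * 1.75         # +>50% bin
    if hgb > 12.0:
        if esa == 0:
            return 0.0
        u = rng.random()
        if u < 0.45:
            return esa
        if u < 0.75:
            return esa * 0.65     # -25-50% bin
        if u < 0.9:
            return esa * 0.4      # ->50% bin
        return 0.0                # stop
    return esa if rng.random() < 0.9 else esa * (1.3 if rng.random() < 0.5 else 0.65)


def _iron_policy(rng: np.random.Generator, tsat: float, ferritin: float,
                 iron: float) -> float:
    iron_deficient = tsat < 20.0 or ferritin < 200.0
    replete = ferritin > 500.0
    if iron_deficient:
        if iron == 0:
            return 100.0 if rng.random() < 0.7 else 0.0
        return iron * 1.5 if rng.random() < 0.3 else iron
    if replete and iron > 0:
        return 0.0 if rng.random() < 0.6 else iron
    return iron
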