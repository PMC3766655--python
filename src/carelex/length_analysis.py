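"""Intervention-pattern and solution-length distributions vs null models.

Two length notions are analyzed.  The *intervention pattern length* of a
single adjustment is the number of inputs changed (settings plus bolus):
at most 7 in volume-controlled ventilation and 6 in pressure-controlled.
The *solution length* of a virtual patient is the number of
interventions issued before the patient is completed ("non-solutions"
are patients abandoned without completion).  Both are rank-ordered by
appearance frequency and compared with the stepwise rank-frequency
curves of intermittent-silence and random-text typists parameterized by
the keyboard sizes of the two modes and the empirically observed
effective space frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .encoding import InterventionSymbol
from .null_models import (
    NullModelSpec,
    fit_block_table,
    is_asymptotic_slope,
    is_rank_frequency_blocks,
)
from .session_io import PC_SETTINGS, VC_SETTINGS, VentEventRow
from .zipf_stats import RankFrequencyTable, fit_power_law, rank_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "SolutionRecord",
    "ModeSpec",
    "VC_MODE", "PC_MODE",
    "intervention_pattern_length",
    "length_rank_table",
    "solution_lengths",
    "filter_solutions",
    "effective_space_frequency",
    "count_intervention_space",
    "keyboard_size",
    "observed_vs_null",
    "NullComparison",
]


@dataclass(frozen=True)
class SolutionRecord:
    """Per virtual patient: how many interventions, and was it completed.

    ``n_interventions`` counts adjustment events after the baseline row
    (the baseline records initial settings, not an intervention);
    ``completed`` marks patients with a ``complete`` event — the
    "effective space" in the typist analogy.
    """

    subject_id: str
    patient_id: str
    n_interventions: int
    completed: bool


@dataclass(frozen=True)
class ModeSpec:
    """A ventilation mode's keyboard: how many adjustable settings it has."""

    mode: str
    n_settings: int
    has_bolus: bool = True


VC_MODE = ModeSpec(mode="VC", n_settings=len(VC_SETTINGS))
PC_MODE = ModeSpec(mode="PC", n_settings=len(PC_SETTINGS))


def intervention_pattern_length(i: InterventionSymbol) -> int:
    """Number of inputs changed by an intervention symbol.

    Counts the nonzero change directions plus the bolus flag, so VC
    lengths lie in [0, 7] and PC lengths in [0, 6].  A mode switch is a
    single changed input (the mode) and is coded length 1.
    """
    if i.scheme != "MV":
        raise ValueError("intervention pattern length is defined for the MV scheme")
    if i.mv_mode in ("switch_to_VC", "switch_to_PC"):
        logger.debug("mode switch counted as length 1")
        return 1
    return int(sum(1 for c in i.mv_changes if c != 0) + (1 if i.mv_bolus else 0))


def length_rank_table(lengths: Sequence[int]) -> RankFrequencyTable:
    """Rank length *values* by appearance frequency; zero lengths are dropped.

    Ties in frequency give the smaller length the smaller rank (the
    lexicographic tie policy applied to zero-padded keys).
    """
    counts: dict[str, int] = {}
    for L in lengths:
        if L > 0:
            key = f"{L:04d}"  # zero-pad so lexicographic == numeric tie order
            counts[key] = counts.get(key, 0) + 1
    return rank_frequency(counts)


def solution_lengths(rows: Sequence[VentEventRow]) -> list[SolutionRecord]:
    """One record per (subject, patient): intervention count and completion flag."""
    by_patient: dict[tuple[str, str], list[VentEventRow]] = {}
    for r in rows:
        by_patient.setdefault((r.subject_id, r.patient_id), []).append(r)
    out = []
    for (subject, patient), seq in sorted(by_patient.items()):
        if not seq:
            logger.warning("patient %s/%s has no events; skipped", subject, patient)
            continue
        adjusts = [r for r in seq if r.event_type == "adjust"]
        n_adjust = len(adjusts)
        has_baseline = any(r.step_index == 0 for r in adjusts)
        n_interventions = max(0, n_adjust - 1) if has_baseline else n_adjust
        completed = any(r.event_type == "complete" for r in seq)
        out.append(SolutionRecord(subject_id=subject, patient_id=patient,
                                  n_interventions=n_interventions, completed=completed))
    return out


def filter_solutions(recs: Sequence[SolutionRecord]) -> list[SolutionRecord]:
    """Apply the solution-length inclusion rules.

    Drops records with fewer than one intervention, then drops any
    length value whose total appearance count across the remaining
    records is <= 1.  Idempotent.
    """
    nonzero = [r for r in recs if r.n_interventions >= 1]
    counts: dict[int, int] = {}
    for r in nonzero:
        counts[r.n_interventions] = counts.get(r.n_interventions, 0) + 1
    return [r for r in nonzero if counts[r.n_interventions] > 1]


def effective_space_frequency(recs: Sequence[SolutionRecord]) -> float:
    """Empirical probability of the completion ("space") event.

    q-hat = completions / (total interventions + completions): the share
    of spaces in the concatenated stream of keystrokes and spaces.
    """
    if not recs:
        raise ValueError("no solution records")
    completions = sum(1 for r in recs if r.completed)
    interventions = sum(r.n_interventions for r in recs)
    denom = interventions + completions
    if denom == 0:
        raise ValueError("no interventions or completions to estimate q from")
    if completions == 0:
        logger.warning("no completed patients; effective space frequency is 0")
    return completions / denom


def count_intervention_space(specs: Sequence[ModeSpec] = (VC_MODE, PC_MODE),
                             n_mode_switches: int = 2) -> tuple[dict[str, int], int]:
    """Enumerate the discrete intervention alphabet, per mode and total.

    Each setting can move down, stay, or move up and the bolus flag
    doubles the count, so a mode with s settings has 2·3^s patterns
    (the all-unchanged/no-bolus pattern included); mode switches add
    ``n_mode_switches`` more.  Counted by explicit enumeration of the
    pattern space, with the closed form as a cross-check in the tests.
    """
    from itertools import product

    per_mode: dict[str, int] = {}
    for spec in specs:
        n = 0
        for _pattern in product((-1, 0, 1), repeat=spec.n_settings):
            n += 2 if spec.has_bolus else 1
        per_mode[spec.mode] = n
    return per_mode, sum(per_mode.values()) + n_mode_switches


def keyboard_size(spec: ModeSpec) -> int:
    """Keys on the conceptual keyboard for a mode.

    Two change keys per setting (up/down), one bolus key, one space bar:
    14 for volume-controlled, 12 for pressure-controlled.
    """
    return 2 * spec.n_settings + (1 if spec.has_bolus else 0) + 1


@dataclass(frozen=True)
class NullComparison:
    """Observed vs null-model shares on a shared rank support."""

    table: pd.DataFrame           # rank, length, observed_share, null_share
    tv_distance: float            # total variation distance of the shares
    max_abs_log_diff: float       # max |ln(observed share) - ln(null share)|
    observed_slope: float         # log-log OLS slope of the observed rank table
    null_block_slope: float       # fitted slope of the null block rank table
    null_asymptotic_slope: float  # closed-form slope of the null model


def observed_vs_null(observed: RankFrequencyTable, spec: NullModelSpec,
                     L_max_fit: int = 30) -> NullComparison:
    """Compare an observed length rank table with a typist null model.

    The shared support is every length 1..max(observed); per length, the
    observed frequency share is set against the null model's geometric
    length law renormalized over that support, so both share columns sum
    to one and a degenerate observed distribution shows its full
    divergence from the diffuse model.  Rows are ordered by observed
    share (rank order).  The summary adds total-variation and
    max-log-share divergences, plus the fitted log-log slope of the
    observed rank table against the fitted and closed-form slopes of the
    null model's block rank table — the axis on which goal-directed
    practice separates from random typing.
    """
    if len(observed) == 0:
        raise ValueError("observed table is empty")
    q = spec.q_space
    obs_lengths = np.array([int(word) for _, word, _ in observed.rows])
    obs_counts = {int(L): f for L, f in zip(obs_lengths, observed.frequencies)}
    support = np.arange(1, obs_lengths.max() + 1)
    obs = np.array([obs_counts.get(int(L), 0.0) for L in support])
    obs_share = obs / obs.sum()
    null_raw = q * (1.0 - q) ** support.astype(float)
    null_share = null_raw / null_raw.sum()
    order = np.argsort(-obs_share, kind="stable")
    table = pd.DataFrame({
        "rank": np.arange(1, len(support) + 1),
        "length": support[order],
        "observed_share": obs_share[order],
        "null_share": null_share[order],
    })
    tv = 0.5 * float(np.abs(obs_share - null_share).sum())
    with np.errstate(divide="ignore"):
        log_diff = np.abs(np.log(obs_share) - np.log(null_share))
    max_log = float(np.max(log_diff[np.isfinite(log_diff)], initial=0.0))
    if len(observed) >= 2:
        obs_slope = fit_power_law(observed).slope
    else:
        obs_slope = 0.0
    L_cap = L_max_fit
    if spec.n_keys > 1:
        L_cap = min(L_max_fit, int(300 / math.log10(spec.n_keys)))
        blocks = is_rank_frequency_blocks(spec, L_cap)
        null_fit = fit_block_table(blocks)
        null_closed = is_asymptotic_slope(spec)
    else:
        null_fit = float("nan")
        null_closed = float("nan")
    return NullComparison(table=table, tv_distance=tv, max_abs_log_diff=max_log,
                          observed_slope=obs_slope, null_block_slope=null_fit,
                          null_asymptotic_slope=null_closed)
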