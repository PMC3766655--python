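"""Reading, validation, and writing of session logs and text corpora.

Two clinical log schemas are supported:

* ``vent_log.csv`` — mechanical-ventilation sessions, one row per
  adjustment event (:class:`VentEventRow`);
* ``dialysis_log.csv`` — anemia-management records, one row per
  patient-month (:class:`DialysisMonthRow`).

Files are UTF-8 CSV with a header; a tab delimiter is auto-detected from
the header line.  Rows violating schema invariants are rejected
individually (with the line number and a reason) rather than failing the
whole file, so a handful of malformed rows — e.g. keystroke errors in a
hand-entered log — never block an analysis.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VentEventRow",
    "DialysisMonthRow",
    "TokenStream",
    "RejectedRow",
    "SchemaError",
    "read_vent_log",
    "read_dialysis_log",
    "write_vent_log",
    "write_dialysis_log",
    "tokenize_text",
    "read_text_corpus",
    "VC_SETTINGS",
    "PC_SETTINGS",
]

#: Adjustable settings recorded in volume-controlled mode, in canonical order.
VC_SETTINGS = ("tv", "flow", "pause", "fio2", "peep", "rate")
#: Adjustable settings recorded in pressure-controlled mode, in canonical order.
PC_SETTINGS = ("pinsp", "itime", "fio2", "peep", "rate")

_VC_ONLY = ("tv", "flow", "pause")
_PC_ONLY = ("pinsp", "itime")
_PHYSIO = ("spo2", "ph", "map", "pplat")

VENT_COLUMNS = (
    "subject_id", "patient_id", "step_index", "event_type",
    "spo2", "ph", "map", "pplat", "mode",
    "fio2", "peep", "rate", "tv", "flow", "pause", "pinsp", "itime", "bolus",
)

DIALYSIS_COLUMNS = (
    "patient_id", "month_index", "hgb", "ferritin", "tsat",
    "esa_dose", "iron_given", "iron_dose",
)


class SchemaError(ValueError):
    """A log file's header does not match the expected schema."""


@dataclass(frozen=True)
class VentEventRow:
    """One time-stamped mechanical-ventilation event.

    ``event_type`` is ``adjust`` for a settings adjustment (including the
    baseline row, step_index 0, which records initial settings only),
    ``complete`` when the virtual patient reaches its goals, and
    ``abandon`` when the subject gives up.  Mode-specific settings are
    ``None`` when they do not apply: ``tv``/``flow``/``pause`` exist only
    in volume-controlled (VC) mode, ``pinsp``/``itime`` only in
    pressure-controlled (PC) mode.
    """

    subject_id: str
    patient_id: str
    step_index: int
    event_type: str          # adjust | complete | abandon
    spo2: float | None = None    # %
    ph: float | None = None
    map: float | None = None     # mmHg
    pplat: float | None = None   # cmH2O
    mode: str | None = None      # VC | PC
    fio2: float | None = None    # fraction 0-1
    peep: float | None = None    # cmH2O
    rate: float | None = None    # breaths/min
    tv: float | None = None      # mL, VC only
    flow: float | None = None    # L/min, VC only
    pause: float | None = None   # s, VC only
    pinsp: float | None = None   # cmH2O, PC only
    itime: float | None = None   # s, PC only
    bolus: int = 0
    ph_lb: float | None = None   # optional per-patient pH lower goal

    def settings(self) -> tuple[float, ...]:
        """Current settings vector in the canonical order for this row's mode."""
        names = VC_SETTINGS if self.mode == "VC" else PC_SETTINGS
        return tuple(getattr(self, s) for s in names)


@dataclass(frozen=True)
class DialysisMonthRow:
    """One patient-month of anemia-management data in end-stage renal disease."""

    patient_id: str
    month_index: int
    hgb: float        # g/dL
    ferritin: float   # ng/mL
    tsat: float       # %
    esa_dose: float   # units/week; 0 = no ESA
    iron_given: int   # flag
    iron_dose: float  # mg; 0 = none


@dataclass(frozen=True)
class TokenStream:
    """An ordered sequence of cleaned word tokens from a text corpus."""

    tokens: tuple[str, ...]
    source_label: str = ""


@dataclass(frozen=True)
class RejectedRow:
    """A row that failed validation; ``line`` is 1-based in the source file."""

    line: int
    reason: str


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _num(value, allow_none=True):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        if allow_none:
            return None
        raise ValueError("missing value")
    return float(value)


def _validate_vent_row(rec: dict, line: int) -> VentEventRow:
    event_type = str(rec["event_type"]).strip()
    if event_type not in ("adjust", "complete", "abandon"):
        raise ValueError(f"unknown event_type {event_type!r}")
    mode = rec.get("mode")
    mode = None if mode is None or (isinstance(mode, float) and pd.isna(mode)) else str(mode).strip()
    if event_type == "adjust":
        if mode not in ("VC", "PC"):
            raise ValueError(f"adjust row has invalid mode {mode!r}")
        for name in _PHYSIO:
            v = _num(rec.get(name))
            if v is None:
                raise ValueError(f"adjust row missing physiologic value {name!r}")
        other_only = _PC_ONLY if mode == "VC" else _VC_ONLY
        for name in other_only:
            if _num(rec.get(name)) is not None:
                raise ValueError(f"{name!r} set on a {mode} row")
    kwargs = {
        "subject_id": str(rec["subject_id"]),
        "patient_id": str(rec["patient_id"]),
        "step_index": int(rec["step_index"]),
        "event_type": event_type,
        "mode": mode,
        "bolus": int(_num(rec.get("bolus")) or 0),
    }
    for name in _PHYSIO + ("fio2", "peep", "rate", "tv", "flow", "pause", "pinsp", "itime", "ph_lb"):
        kwargs[name] = _num(rec.get(name))
    row = VentEventRow(**kwargs)
    if row.step_index < 0:
        raise ValueError("negative step_index")
    return row


def read_vent_log(path: str | Path) -> tuple[list[VentEventRow], list[RejectedRow]]:
    """Read a mechanical-ventilation log.

    Returns ``(rows, rejected)``: schema-valid rows ordered by
    (subject_id, patient_id, step_index), and per-row rejections with
    line numbers.  A missing column raises :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"subject_id": str, "patient_id": str})
    _require_columns(df, [c for c in VENT_COLUMNS], path)
    rows: list[VentEventRow] = []
    rejected: list[RejectedRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            rows.append(_validate_vent_row(rec, line))
        except (ValueError, TypeError) as exc:
            rejected.append(RejectedRow(line=line, reason=str(exc)))
    rows.sort(key=lambda r: (r.subject_id, r.patient_id, r.step_index))
    _check_monotone_steps(rows, rejected)
    logger.info("read %d vent rows from %s (%d rejected)", len(rows), path, len(rejected))
    return rows, rejected


def _check_monotone_steps(rows: list[VentEventRow], rejected: list[RejectedRow]) -> None:
    seen: dict[tuple[str, str], int] = {}
    dupes = []
    for r in rows:
        key = (r.subject_id, r.patient_id)
        prev = seen.get(key)
        if prev is not None and r.step_index <= prev:
            dupes.append(r)
        else:
            seen[key] = r.step_index
    for r in dupes:
        rows.remove(r)
        rejected.append(RejectedRow(line=-1, reason=f"non-increasing step_index {r.step_index} "
                                                    f"for {r.subject_id}/{r.patient_id}"))


def read_dialysis_log(path: str | Path) -> tuple[list[DialysisMonthRow], list[RejectedRow]]:
    """Read a dialysis anemia-management log; analogous to :func:`read_vent_log`.

    Month gaps within a patient are accepted and logged; downstream trend
    features compare only against the immediately preceding available month.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"patient_id": str})
    _require_columns(df, DIALYSIS_COLUMNS, path)
    rows: list[DialysisMonthRow] = []
    rejected: list[RejectedRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2
        try:
            row = DialysisMonthRow(
                patient_id=str(rec["patient_id"]),
                month_index=int(rec["month_index"]),
                hgb=float(rec["hgb"]),
                ferritin=float(rec["ferritin"]),
                tsat=float(rec["tsat"]),
                esa_dose=float(rec["esa_dose"]),
                iron_given=int(rec["iron_given"]),
                iron_dose=float(rec["iron_dose"]),
            )
            if row.month_index < 0:
                raise ValueError("negative month_index")
            if row.esa_dose < 0 or row.iron_dose < 0:
                raise ValueError("negative dose")
            rows.append(row)
        except (ValueError, TypeError) as exc:
            rejected.append(RejectedRow(line=line, reason=str(exc)))
    rows.sort(key=lambda r: (r.patient_id, r.month_index))
    prev: DialysisMonthRow | None = None
    for r in rows:
        if prev is not None and prev.patient_id == r.patient_id and r.month_index > prev.month_index + 1:
            logger.info("month gap for patient %s: %d -> %d", r.patient_id,
                        prev.month_index, r.month_index)
        prev = r
    logger.info("read %d dialysis rows from %s (%d rejected)", len(rows), path, len(rejected))
    return rows, rejected


def _rows_to_frame(rows: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    records = []
    for r in rows:
        d = {f.name: getattr(r, f.name) for f in dc_fields(r)}
        records.append(d)
    df = pd.DataFrame.from_records(records)
    cols = [c for c in columns if c in df.columns] + [c for c in df.columns if c not in columns]
    return df[cols] if len(df) else pd.DataFrame(columns=list(columns))


def write_vent_log(rows: Sequence[VentEventRow], path: str | Path) -> None:
    """Write rows as ``vent_log.csv``; round-trips through :func:`read_vent_log`."""
    _rows_to_frame(rows, VENT_COLUMNS + ("ph_lb",)).to_csv(path, index=False)


def write_dialysis_log(rows: Sequence[DialysisMonthRow], path: str | Path) -> None:
    _rows_to_frame(rows, DIALYSIS_COLUMNS).to_csv(path, index=False)


_APOSTROPHES = "'’ʼ"
_KEEP = re.compile(r"[a-z0-9]+")


def tokenize_text(raw: str, source_label: str = "") -> TokenStream:
    """Split raw text into cleaned, case-folded word tokens.

    Punctuation (the Unicode P categories, dashes included) splits or is
    stripped; apostrophes are deleted outright so contractions stay one
    token ("don't" -> "dont").  Output tokens contain only ``[a-z0-9]``.
    """
    out = []
    for ch in raw:
        if ch in _APOSTROPHES:
            continue
        cat = unicodedata.category(ch)
        if cat.startswith("P"):
            out.append(" ")
        else:
            out.append(ch)
    folded = "".join(out).casefold()
    tokens = []
    for chunk in folded.split():
        tokens.extend(_KEEP.findall(chunk))
    return TokenStream(tokens=tuple(tokens), source_label=source_label)


def read_text_corpus(path: str | Path) -> TokenStream:
    """Read a plain-text file and tokenize it."""
    path = Path(path)
    return tokenize_text(path.read_text(encoding="utf-8"), source_label=path.name)
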