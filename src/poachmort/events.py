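"""Event coding and encounter-history handling for multi-mark deer data.

An encounter history records, for one individually marked red deer, what was
observed at each annual occasion: nothing (0), a live resighting stratified
by mark type (1-4), or a dead recovery stratified by mark group and assigned
cause of death (5-10).  The marking occasion carries the release code (1, 2
or 3 according to the mark the animal received); later occasions carry
resightings or at most one dead recovery, after which the history is silent.

Event codes
-----------
===== =========================================================
code  meaning
===== =========================================================
0     not observed
1     alive, working GPS collar (automatic, perfect detection)
2     alive, resighted with optical collar
3     alive, resighted with ear tags only
4     alive, resighted with inactive GPS collar
5     recovered dead, poached, working GPS
6     recovered dead, poached, other marks
7     recovered dead, other cause, working GPS
8     recovered dead, other cause, other marks
9     recovered dead, unknown cause, working GPS
10    recovered dead, unknown cause, other marks
===== =========================================================

"other marks" pools optical collars, inactive GPS collars and ear tags:
recoveries of non-GPS animals are too sparse to stratify further.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Event(IntEnum):
    NOT_SEEN = 0
    ALIVE_GPS = 1
    ALIVE_COLLAR = 2
    ALIVE_TAGS = 3
    ALIVE_GPS_OFF = 4
    DEAD_POACHED_GPS = 5
    DEAD_POACHED_MARK = 6
    DEAD_OTHER_GPS = 7
    DEAD_OTHER_MARK = 8
    DEAD_UNKNOWN_GPS = 9
    DEAD_UNKNOWN_MARK = 10


RELEASE_CODES = frozenset({1, 2, 3})
LIVE_CODES = frozenset({1, 2, 3, 4})
DEAD_CODES = frozenset({5, 6, 7, 8, 9, 10})
POACHED_CODES = frozenset({5, 6})
OTHER_CAUSE_CODES = frozenset({7, 8})
UNKNOWN_CAUSE_CODES = frozenset({9, 10})
#: codes used for the live-only CJS goodness-of-fit input; working-GPS
#: detections (code 1) are excluded because they are certain.
GOF_LIVE_CODES = frozenset({2, 3, 4})

#: release code -> initial mark label
MARK_OF_RELEASE = {1: "gps", 2: "collar", 3: "tags"}


@dataclass
class EncounterHistory:
    """One individual's sex, age at marking and per-occasion event codes.

    ``events`` has one entry per study occasion (all individuals in a
    dataset share the same occasion span); entries before the marking
    occasion are zero.
    """

    id: str
    sex: str
    age_at_marking: int
    events: np.ndarray

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=int)

    @property
    def n_occasions(self) -> int:
        return int(self.events.size)

    @property
    def marking_occasion(self) -> int:
        nz = np.flatnonzero(self.events)
        if nz.size == 0:
            raise ValueError(f"history {self.id!r} has no events")
        return int(nz[0])

    @property
    def initial_mark(self) -> str:
        return MARK_OF_RELEASE[int(self.events[self.marking_occasion])]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncounterHistory):
            return NotImplemented
        return (
            self.id == other.id
            and self.sex == other.sex
            and self.age_at_marking == other.age_at_marking
            and np.array_equal(self.events, other.events)
        )


@dataclass(frozen=True)
class Violation:
    rule: str
    occasion: int
    message: str


def validate_history(h: EncounterHistory) -> list[Violation]:
    """Check the coding rules; violations are returned as data, not raised.

    Rules: codes in 0..10; the first event is a release code (1/2/3); at most
    one dead code, with silence afterwards; no live code after a dead code;
    a working-GPS code (1) never follows a non-GPS live code (2/3/4).
    """
    out: list[Violation] = []
    ev = h.events
    if h.sex not in ("M", "F"):
        out.append(Violation("sex", -1, f"sex must be 'M' or 'F', got {h.sex!r}"))
    if h.age_at_marking < 1:
        out.append(Violation("age", -1, f"age at marking must be >= 1, got {h.age_at_marking}"))
    bad = np.flatnonzero((ev < 0) | (ev > 10))
    for t in bad:
        out.append(Violation("code range", int(t), f"event code {ev[t]} outside 0..10"))
    if bad.size:
        return out
    nz = np.flatnonzero(ev)
    if nz.size == 0:
        out.append(Violation("has release", -1, "history contains no events"))
        return out
    f = int(nz[0])
    if ev[f] not in RELEASE_CODES:
        out.append(Violation("release code", f, f"marking event must be 1, 2 or 3, got {ev[f]}"))
    dead_at = [int(t) for t in nz if ev[t] in DEAD_CODES]
    if len(dead_at) > 1:
        out.append(Violation("single dead code", dead_at[1], "more than one dead code"))
    if dead_at:
        d = dead_at[0]
        for t in nz:
            if t > d:
                rule = "live code after dead code" if ev[t] in LIVE_CODES else "event after dead code"
                out.append(Violation(rule, int(t), f"code {ev[t]} at occasion {t} follows dead code at {d}"))
    non_gps_seen = False
    for t in nz:
        if ev[t] in (2, 3, 4):
            non_gps_seen = True
        elif ev[t] == 1 and non_gps_seen:
            out.append(Violation("working-GPS after non-GPS", int(t),
                                 "code 1 after a non-GPS live code (2/3/4)"))
    return out


#: default column layout of the delimited format (the supplementary file's
#: exact layout is configurable because it is not standardized)
DEFAULT_LAYOUT = {
    "id": "id",
    "sex": "sex",
    "age": "age",
    "year_marked": "year_marked",
    # None -> auto-detect columns named y<year>, ordered by year
    "event_columns": None,
}


def _event_columns(df: pd.DataFrame, layout: dict) -> list[str]:
    cols = layout.get("event_columns")
    if cols is None:
        cols = sorted(
            (c for c in df.columns if re.fullmatch(r"y\d{4}", str(c))),
            key=lambda c: int(str(c)[1:]),
        )
    return list(cols)


def parse_histories(source, layout: dict | None = None) -> list[EncounterHistory]:
    """Read encounter histories from delimited text (path, buffer or DataFrame).

    One row per individual, event columns ordered by year.  A malformed code
    rejects the row with a located message; a violated coding rule raises a
    validation error naming the rule.  Input ordering is preserved.
    """
    lay = dict(DEFAULT_LAYOUT)
    lay.update(layout or {})
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        try:
            df = pd.read_csv(source)
        except pd.errors.EmptyDataError:
            return []
    if len(df) == 0:
        return []
    cols = _event_columns(df, lay)
    if not cols:
        raise ValueError("no event columns found in input")
    histories: list[EncounterHistory] = []
    for pos, (idx, row) in enumerate(df.iterrows()):
        ident = str(row[lay["id"]])
        codes = np.empty(len(cols), dtype=int)
        for j, c in enumerate(cols):
            v = row[c]
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {pos} (id={ident}), column {c}: event code {v!r} is not an integer"
                ) from None
            if not 0 <= iv <= 10 or (isinstance(v, float) and v != iv):
                raise ValueError(
                    f"row {pos} (id={ident}), column {c}: event code {v!r} is not in 0..10"
                )
            codes[j] = iv
        h = EncounterHistory(
            id=ident,
            sex=str(row[lay["sex"]]),
            age_at_marking=int(row[lay["age"]]),
            events=codes,
        )
        violations = validate_history(h)
        if violations:
            v = violations[0]
            raise ValueError(
                f"row {pos} (id={ident}): rule '{v.rule}' violated at occasion {v.occasion}: {v.message}"
            )
        histories.append(h)
    return histories


def write_histories(histories: Sequence[EncounterHistory], path=None, base_year: int = 2007) -> str:
    """Serialize histories to CSV text (and optionally to ``path``).

    The output re-parses to an equal list: ``parse_histories`` after
    ``write_histories`` is the identity on valid data.
    """
    if histories:
        T = histories[0].n_occasions
    else:
        T = 0
    cols = ["id", "sex", "age", "year_marked"] + [f"y{base_year + t}" for t in range(T)]
    rows = []
    for h in histories:
        rows.append(
            [h.id, h.sex, h.age_at_marking, base_year + h.marking_occasion] + list(h.events)
        )
    df = pd.DataFrame(rows, columns=cols)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


@dataclass
class DatasetSummary:
    n_individuals: int
    n_by_sex: dict[str, int]
    n_by_initial_mark: dict[str, int]
    n_recoveries_by_sex: dict[str, int]
    n_recoveries_by_cause: dict[str, int]

    @property
    def n_recoveries(self) -> int:
        return sum(self.n_recoveries_by_sex.values())


def summarize_dataset(histories: Iterable[EncounterHistory]) -> DatasetSummary:
    """Census counts computed purely from event codes."""
    n_by_sex: dict[str, int] = {"M": 0, "F": 0}
    n_by_mark = {"gps": 0, "collar": 0, "tags": 0}
    rec_by_sex: dict[str, int] = {"M": 0, "F": 0}
    rec_by_cause = {"poached": 0, "other": 0, "unknown": 0}
    n = 0
    for h in histories:
        n += 1
        n_by_sex[h.sex] = n_by_sex.get(h.sex, 0) + 1
        n_by_mark[h.initial_mark] += 1
        for code in h.events:
            if code in POACHED_CODES:
                rec_by_cause["poached"] += 1
                rec_by_sex[h.sex] = rec_by_sex.get(h.sex, 0) + 1
            elif code in OTHER_CAUSE_CODES:
                rec_by_cause["other"] += 1
                rec_by_sex[h.sex] = rec_by_sex.get(h.sex, 0) + 1
            elif code in UNKNOWN_CAUSE_CODES:
                rec_by_cause["unknown"] += 1
                rec_by_sex[h.sex] = rec_by_sex.get(h.sex, 0) + 1
    return DatasetSummary(
        n_individuals=n,
        n_by_sex=n_by_sex,
        n_by_initial_mark=n_by_mark,
        n_recoveries_by_sex=rec_by_sex,
        n_recoveries_by_cause=rec_by_cause,
    )


def to_live_only_binary(
    histories: Sequence[EncounterHistory],
) -> tuple[np.ndarray, list[EncounterHistory]]:
    """Map histories to binary detection histories for the CJS GOF input.

    Codes {2, 3, 4} become 1; everything else (including certain GPS
    detections, code 1, and all dead recoveries) becomes 0.  Individuals
    whose binary history contains no 1 carry no CJS information and are
    dropped.  Returns the binary matrix and the retained histories, in
    input order.
    """
    kept: list[EncounterHistory] = []
    rows: list[np.ndarray] = []
    for h in histories:
        b = np.isin(h.events, list(GOF_LIVE_CODES)).astype(int)
        if b.any():
            kept.append(h)
            rows.append(b)
    if not rows:
        T = histories[0].n_occasions if histories else 0
        return np.zeros((0, T), dtype=int), kept
    return np.vstack(rows), kept
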