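"""Activity vocabulary, simultaneity semantics, ICATUS-2016 mapping, timeslot grid.

The coded vocabulary mirrors a field instrument of 44 discrete activities, of
which four are "simultaneous": they can be performed concurrently with other
activities (passive childcare, chatting, background radio/TV) and are credited
the full timeslot rather than a share of it.  Every activity maps to exactly
one of the nine ICATUS-2016 major divisions (MD1..MD9); a few activities
(resting/sleeping, study-related interactions) are excluded from time
aggregation but still count toward concurrency.

The analysis window is discretised into fixed-length half-open timeslots
[t, t + slot_minutes); the default grid is 08:00-20:00 at 15 min, i.e. 48
slots per participant-day.
"""

from __future__ import annotations

import datetime
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: The nine ICATUS-2016 major divisions.
DIVISIONS = ("MD1", "MD2", "MD3", "MD4", "MD5", "MD6", "MD7", "MD8", "MD9")

DIVISION_LABELS = {
    "MD1": "employment and related activities",
    "MD2": "production of goods for own final use",
    "MD3": "unpaid domestic services for household and family members",
    "MD4": "unpaid caregiving services for household and family members",
    "MD5": "unpaid volunteer, trainee and other unpaid work",
    "MD6": "learning",
    "MD7": "socializing and communication, community participation, religious practice",
    "MD8": "culture, leisure, mass media and sports practices",
    "MD9": "self-care and maintenance",
}

#: Assessment methods: direct observation (criterion), 24-h recall,
#: image-assisted recall, enumerator image interpretation.
METHODS = ("OBS", "R24H", "IAR", "EII")

DAY_TYPES = ("observation", "non_observation")

TimeLike = Union[datetime.time, str, int]


def _to_minutes(t: TimeLike) -> int:
    """Convert a time-of-day (datetime.time, 'HH:MM[:SS]' or minutes) to minutes past midnight."""
    if isinstance(t, datetime.time):
        if t.second or t.microsecond:
            raise ValueError(f"sub-minute time of day not supported: {t!r}")
        return t.hour * 60 + t.minute
    if isinstance(t, str):
        parts = t.split(":")
        if len(parts) not in (2, 3) or (len(parts) == 3 and int(parts[2]) != 0):
            raise ValueError(f"cannot parse time of day {t!r}; expected 'HH:MM'")
        return int(parts[0]) * 60 + int(parts[1])
    if isinstance(t, int):
        return t
    raise TypeError(f"unsupported time-of-day type: {type(t).__name__}")


def _fmt_minutes(m: int) -> str:
    return f"{m // 60:02d}:{m % 60:02d}"


@dataclass(frozen=True)
class ActivityCode:
    """One coded activity: identifier, simultaneity flag, division, exclusion flag."""

    code: str
    label: str
    simultaneous: bool
    division: str
    excluded_from_aggregation: bool = False

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("activity code must be non-empty")
        if self.division not in DIVISIONS:
            raise ValueError(
                f"division {self.division!r} for code {self.code!r} is not one of {DIVISIONS}"
            )


@dataclass(frozen=True)
class ActivityCatalog:
    """Ordered collection of activity codes with unique identifiers."""

    entries: tuple[ActivityCode, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate activity codes in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code()

    def _by_code(self) -> dict[str, ActivityCode]:
        return {e.code: e for e in self.entries}

    def __getitem__(self, code: str) -> ActivityCode:
        try:
            return self._by_code()[code]
        except KeyError:
            raise KeyError(f"unknown activity code {code!r}") from None

    @property
    def simultaneous_codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries if e.simultaneous)

    @property
    def excluded_codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries if e.excluded_from_aggregation)

    def codes_in_division(self, division: str) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries if e.division == division)

    def validate_codes(self, codes: Iterable[str]) -> None:
        known = self._by_code()
        unknown = sorted({c for c in codes if c not in known})
        if unknown:
            raise KeyError(f"unknown activity codes: {unknown}")

    # -- CSV round trip -----------------------------------------------------

    def to_csv(self, path: Union[str, Path, io.TextIOBase]) -> None:
        """Write columns code,label,simultaneous,division,excluded (flags as 0/1)."""
        df = pd.DataFrame(
            {
                "code": [e.code for e in self.entries],
                "label": [e.label for e in self.entries],
                "simultaneous": [int(e.simultaneous) for e in self.entries],
                "division": [e.division for e in self.entries],
                "excluded": [int(e.excluded_from_aggregation) for e in self.entries],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path, io.TextIOBase]) -> "ActivityCatalog":
        df = pd.read_csv(path, dtype={"code": str, "label": str, "division": str})
        required = {"code", "label", "simultaneous", "division", "excluded"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog CSV missing columns: {sorted(missing)}")
        entries = tuple(
            ActivityCode(
                code=row.code,
                label=row.label,
                simultaneous=bool(int(row.simultaneous)),
                division=row.division,
                excluded_from_aggregation=bool(int(row.excluded)),
            )
            for row in df.itertuples()
        )
        return cls(entries)


def build_default_catalog() -> ActivityCatalog:
    """The default 44-activity vocabulary with its division mapping.

    The mapping is a documented reconstruction of a rural East-African
    field instrument: exactly four activities are simultaneous (care of the
    index child — including feeding — care of other children or adults,
    chatting with friends or family, watching TV or listening to the radio);
    cooking and food preparation fall under domestic chores (MD3);
    post-harvest processing is mapped to MD3 rather than own production,
    matching how variably-coded food-preparation activities are reconciled;
    resting/sleeping and study-related interactions are excluded from time
    aggregation; no activities map to MD5 or MD6.  Override from file with
    :meth:`ActivityCatalog.from_csv`.
    """
    A = ActivityCode
    entries = (
        # MD1 employment and related activities
        A("paid_farm_labor", "paid agricultural labor on another's farm", False, "MD1"),
        A("selling_at_market", "selling produce or foodstuffs at market", False, "MD1"),
        A("petty_trade", "petty trade / running a small shop or stall", False, "MD1"),
        A("handicrafts_for_sale", "making handicrafts or goods for sale", False, "MD1"),
        A("casual_wage_work", "casual wage work (non-agricultural)", False, "MD1"),
        # MD2 production of goods for own final use
        A("cultivating_own_plot", "cultivating or planting own plot", False, "MD2"),
        A("weeding_garden", "weeding the garden or field", False, "MD2"),
        A("harvesting_crops", "harvesting crops for own use", False, "MD2"),
        A("tending_livestock", "tending livestock", False, "MD2"),
        A("tending_poultry", "tending poultry", False, "MD2"),
        A("collecting_wild_foods", "collecting wild foods or firewood for own use", False, "MD2"),
        # MD3 unpaid domestic services
        A("cooking", "cooking", False, "MD3"),
        A("food_preparation", "food preparation (peeling, sorting, washing food)", False, "MD3"),
        A("post_harvest_processing", "post-harvest processing (shelling, pounding, drying)", False, "MD3"),
        A("washing_clothes", "washing clothes", False, "MD3"),
        A("washing_dishes", "washing dishes and utensils", False, "MD3"),
        A("cleaning_house", "cleaning the house", False, "MD3"),
        A("sweeping_compound", "sweeping the compound", False, "MD3"),
        A("fetching_water", "fetching water", False, "MD3"),
        A("fetching_firewood", "fetching firewood or fuel for the household", False, "MD3"),
        A("household_shopping", "shopping for the household", False, "MD3"),
        A("household_repairs", "household maintenance and repairs", False, "MD3"),
        # MD4 unpaid caregiving services
        A("care_of_index_child", "care of the index child (feeding, bathing, supervising)", True, "MD4"),
        A("care_of_other_children_or_adults", "care of other children or adults", True, "MD4"),
        A("playing_with_child", "playing with or stimulating a child (focused)", False, "MD4"),
        A("accompanying_to_clinic", "accompanying a household member to a clinic", False, "MD4"),
        A("caring_for_sick_member", "nursing a sick household member (focused)", False, "MD4"),
        # MD7 socializing, community participation, religious practice
        A("chatting", "chatting with friends or family", True, "MD7"),
        A("attending_religious_service", "attending a religious service", False, "MD7"),
        A("praying", "praying or private religious practice", False, "MD7"),
        A("community_meeting", "attending a community meeting", False, "MD7"),
        A("visiting_neighbors", "visiting neighbors or relatives", False, "MD7"),
        A("phone_call_personal", "personal phone call", False, "MD7"),
        # MD8 culture, leisure, mass media, sports
        A("watching_tv_or_radio", "watching TV or listening to the radio", True, "MD8"),
        A("playing_games", "playing games", False, "MD8"),
        A("sports", "sports or exercise", False, "MD8"),
        A("crafts_hobby", "crafts or hobby (not for sale)", False, "MD8"),
        # MD9 self-care and maintenance
        A("eating_meal", "eating a meal", False, "MD9"),
        A("snacking", "snacking", False, "MD9"),
        A("bathing_self", "bathing or washing self", False, "MD9"),
        A("grooming_dressing", "grooming and dressing", False, "MD9"),
        A("receiving_health_care", "receiving health care", False, "MD9"),
        A("resting_or_sleeping", "resting or sleeping", False, "MD9", True),
        # study-related interactions: recorded but never aggregated
        A("study_interaction", "interactions for the study (incl. answering the study phone)", False, "MD9", True),
    )
    catalog = ActivityCatalog(entries)
    assert len(catalog) == 44, len(catalog)
    assert len(catalog.simultaneous_codes) == 4
    return catalog


@dataclass(frozen=True)
class TimeslotGrid:
    """Analysis window discretised into fixed-length half-open timeslots."""

    window_start: int  # minutes past midnight
    window_end: int
    slot_minutes: int

    def __post_init__(self) -> None:
        if self.slot_minutes <= 0:
            raise ValueError("slot_minutes must be positive")
        span = self.window_end - self.window_start
        if span <= 0:
            raise ValueError("window_end must be after window_start")
        if span % self.slot_minutes:
            raise ValueError(
                f"window of {span} min is not divisible by {self.slot_minutes}-min slots "
                f"(remainder {span % self.slot_minutes} min)"
            )

    @property
    def n_slots(self) -> int:
        return (self.window_end - self.window_start) // self.slot_minutes

    @property
    def slot_starts(self) -> tuple[int, ...]:
        """Start of each slot in minutes past midnight."""
        return tuple(
            self.window_start + i * self.slot_minutes for i in range(self.n_slots)
        )

    def slot_start_labels(self) -> tuple[str, ...]:
        return tuple(_fmt_minutes(m) for m in self.slot_starts)

    def slot_index(self, slot_start: TimeLike) -> int:
        m = _to_minutes(slot_start)
        off = m - self.window_start
        if off < 0 or m >= self.window_end or off % self.slot_minutes:
            raise ValueError(f"{_fmt_minutes(m)} is not a slot start on this grid")
        return off // self.slot_minutes


def build_grid(
    window_start: TimeLike = "08:00",
    window_end: TimeLike = "20:00",
    slot_minutes: int = 15,
) -> TimeslotGrid:
    """Build a timeslot grid; the default is the 12-h 08:00-20:00 window at 15 min (48 slots)."""
    return TimeslotGrid(_to_minutes(window_start), _to_minutes(window_end), slot_minutes)


@dataclass(frozen=True)
class MethodRecord:
    """One participant-day's per-slot activity sets for one assessment method.

    ``slots[i]`` is the set of activity codes recorded in slot i.  Slots whose
    index appears in ``missing_slots`` carry no usable data; a record is
    complete iff that set is empty (incomplete records are excluded from
    analysis under the complete-case rule).
    """

    participant_id: str
    method: str
    slots: tuple[frozenset[str], ...]
    day_type: str = "observation"
    missing_slots: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method {self.method!r} not one of {METHODS}")
        if self.day_type not in DAY_TYPES:
            raise ValueError(f"day_type {self.day_type!r} not one of {DAY_TYPES}")
        object.__setattr__(
            self, "slots", tuple(frozenset(s) for s in self.slots)
        )
        bad = [i for i in self.missing_slots if not 0 <= i < len(self.slots)]
        if bad:
            raise ValueError(f"missing-slot indices out of range: {sorted(bad)}")

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def is_complete(self) -> bool:
        return not self.missing_slots

    def validate_against(self, catalog: ActivityCatalog, grid: TimeslotGrid) -> None:
        if self.n_slots != grid.n_slots:
            raise ValueError(
                f"record {self.participant_id}/{self.method} has {self.n_slots} slots; "
                f"grid has {grid.n_slots}"
            )
        catalog.validate_codes(c for s in self.slots for c in s)

    def with_slots(self, slots: Sequence[frozenset[str]]) -> "MethodRecord":
        return replace(self, slots=tuple(frozenset(s) for s in slots))


def rasterize_intervals(
    episodes: Iterable[tuple[str, TimeLike, TimeLike]],
    grid: TimeslotGrid,
    min_overlap: int = 0,
) -> list[frozenset[str]]:
    """Rasterise continuous (code, start, end) episodes onto the grid.

    An activity is present in a slot iff its overlap with the half-open slot
    interval is at least ``min_overlap`` minutes; with the default of 0, any
    positive overlap marks the slot.  Episodes extending beyond the analysis
    window are clipped (a warning is logged).  Supports continuous logs such
    as camera-epoch annotations; field instruments recording directly in
    slots bypass this.
    """
    slots: list[set[str]] = [set() for _ in range(grid.n_slots)]
    for code, start, end in episodes:
        s, e = _to_minutes(start), _to_minutes(end)
        if e <= s:
            raise ValueError(f"episode {code!r} has end {_fmt_minutes(e)} <= start {_fmt_minutes(s)}")
        if s < grid.window_start or e > grid.window_end:
            logger.warning(
                "episode %r (%s-%s) extends outside the %s-%s window; clipping",
                code, _fmt_minutes(s), _fmt_minutes(e),
                _fmt_minutes(grid.window_start), _fmt_minutes(grid.window_end),
            )
            s = max(s, grid.window_start)
            e = min(e, grid.window_end)
        if e <= s:
            continue
        threshold = min_overlap if min_overlap > 0 else None
        for i, slot_start in enumerate(grid.slot_starts):
            slot_end = slot_start + grid.slot_minutes
            overlap = min(e, slot_end) - max(s, slot_start)
            present = overlap >= threshold if threshold is not None else overlap > 0
            if present:
                slots[i].add(code)
    return [frozenset(s) for s in slots]
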