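"""Synthetic cohorts: criterion-truth schedules and method-degraded versions.

The generator emulates the structure of a rural East-African women's
time-use study day: a 48-slot, 15-min grid from 08:00 to 20:00; heavy
multitasking (most slots hold several concurrent activities, median around
three); omnipresent "passive" simultaneous activities (childcare, chatting,
background radio) present per slot with high probability; and exactly one
persistent "foreground" non-simultaneous activity per slot (cooking,
washing, farming, ...) drawn with division-level prevalence weights and
Markov persistence, optionally joined by a second foreground activity.

Recall-based methods are modelled by degrading the truth: each activity
episode (maximal run of consecutive slots) is omitted with a per-method
probability — larger for simultaneous/background activities under 24-h
recall than under image-assisted recall, since photographs cue recall of
routine passive care — or shifted by one slot.  Enumerator-only image
interpretation (EII) uses strictly larger omission rates than IAR.
Observation-day reactivity (more caregiving, less own production while an
observer is present) is modelled as multiplicative adjustments to the
observation-day presence probabilities.

An analytic expected-bias oracle covers the tractable regime (omission
only, no shifts or merges), where the expected credited-minute bias of a
division equals the sum over its simultaneous activities of
q_sim x n_slots x presence probability x slot minutes.
"""

from __future__ import annotations

import datetime
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np

from .catalog import (
    ActivityCatalog,
    MethodRecord,
    TimeslotGrid,
    build_default_catalog,
    build_grid,
)

__all__ = [
    "MethodErrorModel",
    "SimulationConfig",
    "SyntheticCohort",
    "field_preset",
    "simulate_truth",
    "simulate_cohort",
    "degrade",
    "expected_bias",
    "camera_frame_count",
]


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1]; got {p}")


@dataclass(frozen=True)
class MethodErrorModel:
    """Recall-error structure for one assessment method.

    q_sim / q_act: probability that a simultaneous / non-simultaneous
    activity episode is omitted entirely; shift_prob: probability a retained
    non-simultaneous episode is displaced by one slot; merge_prob:
    probability a one-slot gap between two episodes of the same
    non-simultaneous activity is recalled as a single continuous bout.
    """

    q_sim: float
    q_act: float
    shift_prob: float = 0.0
    merge_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("q_sim", "q_act", "shift_prob", "merge_prob"):
            _check_prob(name, getattr(self, name))


def _default_error_models() -> dict[str, MethodErrorModel]:
    # 24HR misses passive/background activities far more often than IAR;
    # EII (no respondent input) sits between but above IAR on every rate.
    return {
        "R24H": MethodErrorModel(q_sim=0.45, q_act=0.05, shift_prob=0.05),
        "IAR": MethodErrorModel(q_sim=0.12, q_act=0.03, shift_prob=0.02),
        "EII": MethodErrorModel(q_sim=0.30, q_act=0.10, shift_prob=0.02),
    }


def _default_sim_presence() -> dict[str, float]:
    # Per-slot presence probabilities of the four simultaneous activities,
    # set so criterion medians echo a heavy passive-care day: care of the
    # index child most of the day, care of others and chatting about half,
    # background radio/TV rare.
    return {
        "care_of_index_child": 0.5625,
        "care_of_other_children_or_adults": 0.3542,
        "chatting": 0.50,
        "watching_tv_or_radio": 0.05,
    }


def _default_division_weights() -> dict[str, float]:
    # Foreground-activity prevalence by division: domestic chores dominate,
    # then self-care and own production; employment and focused socializing
    # or leisure are rare.
    return {"MD1": 0.05, "MD2": 0.12, "MD3": 0.55, "MD7": 0.08, "MD9": 0.20}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    The defaults are the package's field-study preset: 175 complete
    participant-days on the default 48-slot grid with multitasking in just
    under 90% of slots and 24HR omitting simultaneous activities far more
    often than IAR.
    """

    n_participants: int = 175
    seed: int = 0
    grid: TimeslotGrid = field(default_factory=build_grid)
    catalog: ActivityCatalog = field(default_factory=build_default_catalog)
    sim_presence: Mapping[str, float] = field(default_factory=_default_sim_presence)
    division_weights: Mapping[str, float] = field(default_factory=_default_division_weights)
    persistence: float = 0.6
    p_second_foreground: float = 0.1
    error_models: Mapping[str, MethodErrorModel] = field(default_factory=_default_error_models)
    omission_unit: Literal["episode", "slot"] = "episode"
    reactivity_caregiving: float = 1.2
    reactivity_own_production: float = 0.75
    missing_slot_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for code, p in self.sim_presence.items():
            if code not in self.catalog or not self.catalog[code].simultaneous:
                raise ValueError(f"sim_presence key {code!r} is not a simultaneous activity")
            _check_prob(f"sim_presence[{code}]", p)
        for div, w in self.division_weights.items():
            if w < 0:
                raise ValueError(f"division weight for {div} must be >= 0")
            if not self._foreground_codes(div):
                raise ValueError(f"division {div} has no non-simultaneous aggregable activities")
        if sum(self.division_weights.values()) <= 0:
            raise ValueError("division weights must not all be zero")
        _check_prob("persistence", self.persistence)
        _check_prob("p_second_foreground", self.p_second_foreground)
        _check_prob("missing_slot_rate", self.missing_slot_rate)
        if self.omission_unit not in ("episode", "slot"):
            raise ValueError(f"unknown omission unit {self.omission_unit!r}")
        if self.reactivity_caregiving < 0 or self.reactivity_own_production < 0:
            raise ValueError("reactivity factors must be >= 0")
        unknown = set(self.error_models) - {"R24H", "IAR", "EII"}
        if unknown:
            raise ValueError(f"error models for unknown methods: {sorted(unknown)}")

    def _foreground_codes(self, division: str) -> tuple[str, ...]:
        return tuple(
            e.code
            for e in self.catalog
            if e.division == division and not e.simultaneous and not e.excluded_from_aggregation
        )

    def effective_sim_presence(self, day_type: str) -> dict[str, float]:
        """Per-slot simultaneous-activity probabilities, with observation-day reactivity."""
        probs = dict(self.sim_presence)
        if day_type == "observation" and self.reactivity_caregiving != 1.0:
            for code, p in probs.items():
                if self.catalog[code].division == "MD4":
                    probs[code] = min(1.0, p * self.reactivity_caregiving)
        return probs

    def effective_division_weights(self, day_type: str) -> dict[str, float]:
        weights = dict(self.division_weights)
        if day_type == "observation" and "MD2" in weights:
            weights["MD2"] = weights["MD2"] * self.reactivity_own_production
        total = sum(weights.values())
        return {d: w / total for d, w in weights.items()}


def field_preset(n_participants: int = 175, seed: int = 0, **overrides) -> SimulationConfig:
    """The field-study preset; keyword overrides replace individual fields."""
    return SimulationConfig(n_participants=n_participants, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Truth simulation


def _participant_rng(seed: int, pidx: int, *streams: int) -> np.random.Generator:
    # Stream-per-participant keying keeps cohorts reproducible when n changes.
    return np.random.default_rng([seed, pidx, *streams])


_DAY_STREAM = {"observation": 1, "non_observation": 2}
_METHOD_STREAM = {"R24H": 11, "IAR": 12, "EII": 13}


def _simulate_day(
    config: SimulationConfig, pidx: int, day_type: str
) -> tuple[frozenset[str], ...]:
    rng = _participant_rng(config.seed, pidx, _DAY_STREAM[day_type])
    grid = config.grid
    sim_probs = config.effective_sim_presence(day_type)
    weights = config.effective_division_weights(day_type)
    divisions = sorted(weights)
    w = np.array([weights[d] for d in divisions])

    def draw_foreground() -> str:
        division = divisions[int(rng.choice(len(divisions), p=w))]
        codes = config._foreground_codes(division)
        return codes[int(rng.integers(len(codes)))]

    slots: list[frozenset[str]] = []
    foreground = draw_foreground()
    for i in range(grid.n_slots):
        if i > 0 and rng.random() >= config.persistence:
            foreground = draw_foreground()
        acts = {foreground}
        if rng.random() < config.p_second_foreground:
            acts.add(draw_foreground())
        for code in sorted(sim_probs):
            if rng.random() < sim_probs[code]:
                acts.add(code)
        slots.append(frozenset(acts))
    return tuple(slots)


def simulate_truth(
    config: SimulationConfig,
    day_types: Sequence[str] = ("observation", "non_observation"),
) -> list[MethodRecord]:
    """Criterion-truth records (method OBS) for every participant and day type."""
    records = []
    for pidx in range(config.n_participants):
        pid = f"P{pidx + 1:04d}"
        for day_type in day_types:
            records.append(
                MethodRecord(
                    participant_id=pid,
                    method="OBS",
                    day_type=day_type,
                    slots=_simulate_day(config, pidx, day_type),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Degradation


def _episodes(slots: Sequence[frozenset[str]], code: str) -> list[tuple[int, int]]:
    """Maximal runs [start, end) of consecutive slots containing ``code``."""
    runs, start = [], None
    for i, s in enumerate(slots):
        if code in s and start is None:
            start = i
        elif code not in s and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(slots)))
    return runs


def degrade(
    truth: MethodRecord,
    method: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> MethodRecord:
    """Method-degraded version of a truth record.

    Simultaneous-activity episodes are omitted with q_sim; non-simultaneous
    episodes are omitted with q_act, merged across one-slot gaps with
    merge_prob, or displaced by one slot with shift_prob (slots shifted off
    the grid are lost).  With ``omission_unit="slot"`` each presence-slot is
    dropped independently instead of whole episodes.  Without an explicit
    merge probability the degraded record contains only activities present
    in truth in the same or an adjacent (shifted) slot.
    """
    if method not in _METHOD_STREAM:
        raise ValueError(f"method {method!r} has no error model (expected R24H/IAR/EII)")
    if not truth.is_complete:
        raise ValueError("degrade requires a complete truth record")
    model = config.error_models[method]
    if rng is None:
        pkey = zlib.crc32(truth.participant_id.encode())
        rng = _participant_rng(
            config.seed, pkey, _DAY_STREAM[truth.day_type], _METHOD_STREAM[method]
        )
    n = truth.n_slots
    new_slots: list[set[str]] = [set() for _ in range(n)]
    codes = sorted({c for s in truth.slots for c in s})
    for code in codes:
        simultaneous = config.catalog[code].simultaneous
        q = model.q_sim if simultaneous else model.q_act
        if config.omission_unit == "slot":
            for i in range(n):
                if code in truth.slots[i] and rng.random() >= q:
                    new_slots[i].add(code)
            continue
        runs = _episodes(truth.slots, code)
        kept: list[tuple[int, int]] = []
        for start, end in runs:
            if rng.random() < q:
                continue
            kept.append((start, end))
        if not simultaneous and model.merge_prob > 0.0:
            merged: list[tuple[int, int]] = []
            for run in kept:
                if merged and run[0] - merged[-1][1] == 1 and rng.random() < model.merge_prob:
                    merged[-1] = (merged[-1][0], run[1])
                else:
                    merged.append(run)
            kept = merged
        for start, end in kept:
            if not simultaneous and model.shift_prob > 0.0 and rng.random() < model.shift_prob:
                offset = 1 if rng.random() < 0.5 else -1
                start, end = start + offset, end + offset
            for i in range(max(start, 0), min(end, n)):
                new_slots[i].add(code)
    missing = frozenset(
        i for i in range(n) if config.missing_slot_rate and rng.random() < config.missing_slot_rate
    )
    for i in missing:  # a missing slot carries no usable content
        new_slots[i] = set()
    return MethodRecord(
        participant_id=truth.participant_id,
        method=method,
        day_type=truth.day_type,
        slots=tuple(frozenset(s) for s in new_slots),
        missing_slots=missing,
    )


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class SyntheticCohort:
    """All records of a simulated study plus the config that produced them.

    Criterion truth (OBS) is available for both day types in simulation —
    unlike the field design, where only one day is observed — which makes
    reactivity checks directly testable.
    """

    records: tuple[MethodRecord, ...]
    config: SimulationConfig

    def select(
        self, method: str | None = None, day_type: str | None = None
    ) -> list[MethodRecord]:
        return [
            r
            for r in self.records
            if (method is None or r.method == method)
            and (day_type is None or r.day_type == day_type)
        ]


def simulate_cohort(
    config: SimulationConfig,
    methods: Sequence[str] = ("R24H", "IAR", "EII"),
) -> SyntheticCohort:
    """Simulate truth and all degraded method records for every participant."""
    records: list[MethodRecord] = []
    for pidx in range(config.n_participants):
        pid = f"P{pidx + 1:04d}"
        for day_type in ("observation", "non_observation"):
            truth = MethodRecord(
                participant_id=pid,
                method="OBS",
                day_type=day_type,
                slots=_simulate_day(config, pidx, day_type),
            )
            records.append(truth)
            for method in methods:
                rng = _participant_rng(
                    config.seed, pidx, _DAY_STREAM[day_type], _METHOD_STREAM[method]
                )
                records.append(degrade(truth, method, config, rng=rng))
    return SyntheticCohort(records=tuple(records), config=config)


# ---------------------------------------------------------------------------
# Analytic oracle


def expected_bias(
    config: SimulationConfig,
    division: str,
    method: str = "R24H",
    day_type: str = "observation",
) -> float:
    """Closed-form expected credited-minute bias (criterion - degraded) for a division.

    Valid only in the analytically tractable regime: omission of
    simultaneous activities only (q_act = 0), no shifts, no merges, no slot
    missingness.  There, non-simultaneous credits cancel exactly between
    truth and degraded records, and each simultaneous activity contributes
    q_sim x n_slots x presence probability x slot_minutes, because episode-
    or slot-level omission with probability q retains each presence-slot
    with probability 1 - q in expectation.
    """
    model = config.error_models[method]
    offending = [
        f"{name}={getattr(model, name)}"
        for name in ("q_act", "shift_prob", "merge_prob")
        if getattr(model, name) != 0.0
    ]
    if config.missing_slot_rate:
        offending.append(f"missing_slot_rate={config.missing_slot_rate}")
    if offending:
        raise ValueError(
            "expected_bias requires the omission-only regime; offending features: "
            + ", ".join(offending)
        )
    probs = config.effective_sim_presence(day_type)
    total = 0.0
    for code, p in probs.items():
        if config.catalog[code].division == division:
            total += model.q_sim * config.grid.n_slots * p * config.grid.slot_minutes
    return total


# ---------------------------------------------------------------------------
# Camera-frame model


def _to_seconds(t: Union[datetime.time, str]) -> int:
    if isinstance(t, datetime.time):
        return t.hour * 3600 + t.minute * 60 + t.second
    parts = [int(p) for p in str(t).split(":")]
    if len(parts) == 2:
        parts.append(0)
    if len(parts) != 3:
        raise ValueError(f"cannot parse time of day {t!r}")
    h, m, s = parts
    return h * 3600 + m * 60 + s


def camera_frame_count(
    wear_start: Union[datetime.time, str],
    wear_end: Union[datetime.time, str],
    interval_seconds: int = 30,
) -> int:
    """Number of frames a fixed-interval wearable camera captures over a wear period."""
    if interval_seconds <= 0:
        raise ValueError("interval_seconds must be positive")
    start, end = _to_seconds(wear_start), _to_seconds(wear_end)
    if end <= start:
        raise ValueError("wear_end must be after wear_start")
    return (end - start) // interval_seconds
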