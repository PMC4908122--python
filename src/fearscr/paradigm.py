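"""Two-day differential fear-conditioning paradigm.

Day 1 carries a conditioning phase (two reinforced conditioned stimuli,
CS+E and CS+U, partially reinforced by an aversive unconditioned stimulus
at CS offset, plus a never-reinforced CS-) followed, after a short gap,
by an extinction phase in which only the CS+E and CS- are presented.
Day 2 is an extinction-recall phase with all three CS types and no US.

The conditioning phase presents the CS+E trials as a first block and the
CS+U trials as a second block ("the switch"), with CS- trials interleaved
throughout; this makes "the first CS- after the switch" — a trial excluded
from differential conditioning — well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, StructuralError

__all__ = [
    "Stimulus",
    "PhaseName",
    "PHASE_DAY",
    "TrialEvent",
    "ParadigmConfig",
    "Schedule",
    "ValidationReport",
    "SwitchInfo",
    "generate_schedule",
    "validate_events",
    "locate_switch",
]


class Stimulus(str, Enum):
    """Stimulus labels. The US is never scored as a conditioned stimulus."""

    CS_PLUS_E = "cs_plus_e"  # extinguished on day 1
    CS_PLUS_U = "cs_plus_u"  # not extinguished
    CS_MINUS = "cs_minus"    # never reinforced
    US = "us"                # aversive electric stimulation


CS_TYPES = (Stimulus.CS_PLUS_E, Stimulus.CS_PLUS_U, Stimulus.CS_MINUS)


class PhaseName(str, Enum):
    CONDITIONING = "conditioning"
    EXTINCTION = "extinction"
    RECALL = "recall"


#: Experimental day each phase belongs to.
PHASE_DAY = {
    PhaseName.CONDITIONING: 1,
    PhaseName.EXTINCTION: 1,
    PhaseName.RECALL: 2,
}


@dataclass(frozen=True)
class TrialEvent:
    """One stimulus presentation.

    ``index_within_type`` is the 1-based presentation order of this
    stimulus within its phase (US events are numbered among US events).
    """

    onset: float
    duration: float
    stimulus: Stimulus
    phase: PhaseName
    reinforced: bool = False
    index_within_type: int = 1

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def day(self) -> int:
        return PHASE_DAY[self.phase]


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial counts, timings and reinforcement structure of the paradigm.

    Defaults give 8 presentations of each CS+ with 5 reinforced
    (5/8 = 62.5% partial reinforcement), 16 CS- trials in conditioning,
    16 CS+E / 16 CS- in extinction and 8 of each CS type at recall.
    """

    n_csplus_each: int = 8
    n_reinforced_each: int = 5
    n_csminus_conditioning: int = 16
    n_csplusE_extinction: int = 16
    n_csminus_extinction: int = 16
    n_each_recall: int = 8
    cs_duration: float = 6.0
    us_duration: float = 0.5
    iti_range: tuple[float, float] = (12.0, 18.0)
    inter_phase_gap: float = 60.0
    seed: int = 0
    allow_no_reinforcement: bool = False

    def validate(self) -> None:
        counts = {
            "n_csplus_each": self.n_csplus_each,
            "n_csminus_conditioning": self.n_csminus_conditioning,
            "n_csplusE_extinction": self.n_csplusE_extinction,
            "n_csminus_extinction": self.n_csminus_extinction,
            "n_each_recall": self.n_each_recall,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.n_reinforced_each < 0:
            raise ConfigError(
                f"n_reinforced_each must be >= 0, got {self.n_reinforced_each}"
            )
        if self.n_reinforced_each == 0 and not self.allow_no_reinforcement:
            raise ConfigError(
                "n_reinforced_each = 0 requires allow_no_reinforcement=True "
                "(no-reinforcement control)"
            )
        if self.n_reinforced_each > self.n_csplus_each:
            raise ConfigError(
                "n_reinforced_each exceeds n_csplus_each "
                f"({self.n_reinforced_each} > {self.n_csplus_each})"
            )
        if self.cs_duration <= 0:
            raise ConfigError(f"cs_duration must be > 0, got {self.cs_duration}")
        if self.us_duration <= 0:
            raise ConfigError(f"us_duration must be > 0, got {self.us_duration}")
        lo, hi = self.iti_range
        if not (0 <= lo <= hi):
            raise ConfigError(f"iti_range must satisfy 0 <= min <= max, got {self.iti_range}")
        if self.inter_phase_gap < 0:
            raise ConfigError(f"inter_phase_gap must be >= 0, got {self.inter_phase_gap}")

    @property
    def reinforcement_fraction(self) -> float:
        return self.n_reinforced_each / self.n_csplus_each


@dataclass
class Schedule:
    """Ordered trial events per phase, on each day's own clock."""

    phases: dict[PhaseName, list[TrialEvent]]
    config: ParadigmConfig

    def events(self, phase: PhaseName) -> list[TrialEvent]:
        return self.phases[phase]

    def all_events(self) -> list[TrialEvent]:
        out: list[TrialEvent] = []
        for phase in (PhaseName.CONDITIONING, PhaseName.EXTINCTION, PhaseName.RECALL):
            out.extend(self.phases[phase])
        return out


def _interleave(primary: Sequence[Stimulus], fillers: Sequence[Stimulus]) -> list[Stimulus]:
    """Spread ``fillers`` as evenly as possible through ``primary``.

    Bresenham-style merge: the combined order is deterministic and, for
    equal counts, alternates primary/filler — so with the CS+E block
    before the CS+U block at least one filler follows the switch.
    """
    n_p, n_f = len(primary), len(fillers)
    order: list[Stimulus] = []
    i = j = 0
    # accumulate error against the ideal interleaving ratio
    while i < n_p or j < n_f:
        if j >= n_f:
            order.append(primary[i]); i += 1
        elif i >= n_p:
            order.append(fillers[j]); j += 1
        elif i * n_f <= j * n_p:
            order.append(primary[i]); i += 1
        else:
            order.append(fillers[j]); j += 1
    return order


def _reinforced_presentations(n_total: int, n_reinforced: int, rng: np.random.Generator) -> set[int]:
    """Pick which 1-based presentations are reinforced.

    The first presentation is excluded from the draw whenever possible
    (it is also excluded from analysis downstream); only if every
    presentation must be reinforced does the first one carry a US.
    """
    if n_reinforced == 0:
        return set()
    candidates = list(range(2, n_total + 1))
    if n_reinforced > len(candidates):
        chosen = {1}
        chosen.update(rng.choice(candidates, size=n_reinforced - 1, replace=False).tolist())
        return chosen
    return set(rng.choice(candidates, size=n_reinforced, replace=False).tolist())


def generate_schedule(config: ParadigmConfig) -> Schedule:
    """Generate the full 2-day trial schedule from a validated config.

    Onsets are seconds from each day's trace start; the day-1 clock is
    continuous across conditioning and extinction with
    ``config.inter_phase_gap`` seconds between them, while recall (day 2)
    restarts at zero. Inter-trial intervals are drawn uniformly from
    ``config.iti_range`` using ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    reinforced_e = _reinforced_presentations(config.n_csplus_each, config.n_reinforced_each, rng)
    reinforced_u = _reinforced_presentations(config.n_csplus_each, config.n_reinforced_each, rng)

    csplus_order = [Stimulus.CS_PLUS_E] * config.n_csplus_each + [Stimulus.CS_PLUS_U] * config.n_csplus_each
    cond_order = _interleave(csplus_order, [Stimulus.CS_MINUS] * config.n_csminus_conditioning)
    ext_order = _interleave(
        [Stimulus.CS_PLUS_E] * config.n_csplusE_extinction,
        [Stimulus.CS_MINUS] * config.n_csminus_extinction,
    )
    recall_primary = [Stimulus.CS_PLUS_E] * config.n_each_recall + [Stimulus.CS_PLUS_U] * config.n_each_recall
    recall_order = _interleave(recall_primary, [Stimulus.CS_MINUS] * config.n_each_recall)

    def build_phase(order: Iterable[Stimulus], phase: PhaseName, t0: float,
                    reinforced_idx: dict[Stimulus, set[int]]) -> tuple[list[TrialEvent], float]:
        events: list[TrialEvent] = []
        counters: dict[Stimulus, int] = {s: 0 for s in Stimulus}
        t = t0
        for stim in order:
            counters[stim] += 1
            k = counters[stim]
            reinforced = k in reinforced_idx.get(stim, set())
            ev = TrialEvent(onset=t, duration=config.cs_duration, stimulus=stim,
                            phase=phase, reinforced=reinforced, index_within_type=k)
            events.append(ev)
            end = ev.offset
            if reinforced:
                counters[Stimulus.US] += 1
                us = TrialEvent(onset=ev.offset, duration=config.us_duration,
                                stimulus=Stimulus.US, phase=phase, reinforced=False,
                                index_within_type=counters[Stimulus.US])
                events.append(us)
                end = us.offset
            t = end + rng.uniform(*config.iti_range)
        return events, t

    cond, t_end = build_phase(
        cond_order, PhaseName.CONDITIONING, 0.0,
        {Stimulus.CS_PLUS_E: reinforced_e, Stimulus.CS_PLUS_U: reinforced_u},
    )
    # t_end already includes one trailing ITI; start extinction after the gap
    # from the last event's offset.
    last_offset = max(ev.offset for ev in cond)
    ext, _ = build_phase(ext_order, PhaseName.EXTINCTION, last_offset + config.inter_phase_gap, {})
    recall, _ = build_phase(recall_order, PhaseName.RECALL, 0.0, {})

    return Schedule(
        phases={PhaseName.CONDITIONING: cond, PhaseName.EXTINCTION: ext, PhaseName.RECALL: recall},
        config=config,
    )


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)


def validate_events(events: Sequence[TrialEvent], config: ParadigmConfig | None = None) -> ValidationReport:
    """Check an event list against the paradigm invariants.

    Violations are reported as data, not raised: overlapping events,
    a US not locked to a reinforced CS+ offset, reinforced CS- trials,
    reinforcement outside conditioning, any US on day 2 or during
    extinction, and non-positive durations.
    """
    violations: list[str] = []
    if not events:
        raise StructuralError("empty event list")

    by_phase: dict[PhaseName, list[TrialEvent]] = {}
    for ev in events:
        by_phase.setdefault(ev.phase, []).append(ev)

    for phase, evs in by_phase.items():
        ordered = sorted(evs, key=lambda e: e.onset)
        if [e.onset for e in evs] != [e.onset for e in ordered]:
            violations.append(f"events not ordered by onset in {phase.value}")
        for ev in evs:
            if ev.onset < 0:
                violations.append(f"negative onset {ev.onset} in {phase.value}")
            if ev.duration <= 0:
                violations.append(f"non-positive duration for {ev.stimulus.value} at {ev.onset}")
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.onset < prev.offset - 1e-9:
                violations.append(
                    f"overlapping events in {phase.value}: {prev.stimulus.value}@{prev.onset} "
                    f"and {nxt.stimulus.value}@{nxt.onset}"
                )
            elif nxt.onset == prev.onset:
                violations.append(
                    f"overlapping events in {phase.value}: identical onsets at {nxt.onset}"
                )
        for i, ev in enumerate(ordered):
            if ev.stimulus is Stimulus.US:
                if phase is not PhaseName.CONDITIONING:
                    violations.append(f"US in {phase.value.upper()}")
                    continue
                prev = ordered[i - 1] if i > 0 else None
                if (prev is None or prev.stimulus not in
                        (Stimulus.CS_PLUS_E, Stimulus.CS_PLUS_U) or not prev.reinforced
                        or abs(prev.offset - ev.onset) > 1e-9):
                    violations.append(
                        f"US at {ev.onset} not locked to the offset of a reinforced CS+"
                    )
            elif ev.reinforced:
                if ev.stimulus is Stimulus.CS_MINUS:
                    violations.append(f"reinforced CS- at {ev.onset}")
                elif phase is not PhaseName.CONDITIONING:
                    violations.append(f"reinforced trial outside conditioning at {ev.onset}")

    return ValidationReport(passed=not violations, violations=violations)


@dataclass(frozen=True)
class SwitchInfo:
    """The first CS+U trial and the first CS- following it (if any)."""

    first_csplus_u: TrialEvent
    first_csminus_after: TrialEvent | None

    @property
    def has_post_switch_csminus(self) -> bool:
        return self.first_csminus_after is not None


def locate_switch(events: Sequence[TrialEvent]) -> SwitchInfo:
    """Find the block switch in a conditioning phase.

    Returns the first CS+U presentation and the first CS- whose onset
    exceeds it; ``first_csminus_after`` is None when no CS- follows the
    switch.
    """
    cond = sorted((e for e in events if e.phase is PhaseName.CONDITIONING), key=lambda e: e.onset)
    if not any(e.stimulus is Stimulus.CS_PLUS_E for e in cond):
        raise StructuralError("conditioning phase lacks CS+E trials")
    first_u = next((e for e in cond if e.stimulus is Stimulus.CS_PLUS_U), None)
    if first_u is None:
        raise StructuralError("conditioning phase lacks CS+U trials")
    first_minus = next(
        (e for e in cond if e.stimulus is Stimulus.CS_MINUS and e.onset > first_u.onset), None
    )
    return SwitchInfo(first_csplus_u=first_u, first_csminus_after=first_minus)
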