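"""Trough-to-peak scoring of event-locked skin-conductance responses.

A trial's response is the maximum conductance during the stimulus
interval minus the mean conductance over the 2 s immediately preceding
stimulus onset. Baseline subtraction makes the score reflect phasic
change beyond tonic level and slow drift. Traces are median-filtered
before scoring to suppress single-sample artifacts.

Subject-level quality control applies three criteria, each evaluated at
both visits:

* (a) data for the phases of interest were recorded at both visits and
  are free of obvious distortions (externally flagged);
* (b) the subject reacted to the US during conditioning (>= 0.05 µS);
* (c) the subject showed a conditioned response to the CS+ (>= 0.05 µS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage

from .errors import ScoringError, StructuralError
from .paradigm import PhaseName, Stimulus, TrialEvent

__all__ = [
    "ScrTrace",
    "TrialScore",
    "QcCriterion",
    "VisitScores",
    "QcDecision",
    "median_filter",
    "score_trial",
    "score_us_reactivity",
    "score_phase",
    "qc_subject",
    "BASELINE_WINDOW_S",
    "QC_THRESHOLD_US",
    "DEFAULT_MEDIAN_KERNEL_S",
    "DEFAULT_US_WINDOW_S",
]

BASELINE_WINDOW_S = 2.0
QC_THRESHOLD_US = 0.05
DEFAULT_MEDIAN_KERNEL_S = 0.5
DEFAULT_US_WINDOW_S = 6.0

_TIME_EPS = 1e-9


@dataclass
class ScrTrace:
    """Uniformly sampled skin-conductance trace (µS) for one subject-visit-phase."""

    sampling_rate: float
    start_time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ScoringError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ScoringError("trace needs at least 2 samples in one dimension")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) / self.sampling_rate


@dataclass(frozen=True)
class TrialScore:
    """Baseline, peak and response amplitude for one trial."""

    event: TrialEvent
    baseline: float
    peak: float
    score: float
    floored: bool = False


def median_filter(trace: ScrTrace, kernel_width: float = DEFAULT_MEDIAN_KERNEL_S) -> ScrTrace:
    """Running median over ``kernel_width`` seconds, reflected at the edges.

    The width is converted to samples and rounded up to the nearest odd
    count; a 1-sample kernel is the identity.
    """
    n = int(np.ceil(kernel_width * trace.sampling_rate))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    if n > trace.n_samples:
        raise ScoringError(
            f"median kernel of {n} samples exceeds trace length {trace.n_samples}"
        )
    if n == 1:
        filtered = trace.values.copy()
    else:
        filtered = scipy.ndimage.median_filter(trace.values, size=n, mode="reflect")
    return ScrTrace(trace.sampling_rate, trace.start_time, filtered)


def _window_indices(trace: ScrTrace, t_lo: float, t_hi: float,
                    closed_right: bool) -> tuple[int, int]:
    """Sample index range for [t_lo, t_hi) or [t_lo, t_hi]."""
    fs = trace.sampling_rate
    i_lo = int(np.ceil((t_lo - trace.start_time) * fs - _TIME_EPS * fs))
    if closed_right:
        i_hi = int(np.floor((t_hi - trace.start_time) * fs + _TIME_EPS * fs)) + 1
    else:
        i_hi = int(np.ceil((t_hi - trace.start_time) * fs - _TIME_EPS * fs))
    return i_lo, i_hi


def _score_windows(trace: ScrTrace, event: TrialEvent, base_lo: float, base_hi: float,
                   stim_lo: float, stim_hi: float, floor_at_zero: bool) -> TrialScore:
    b0, b1 = _window_indices(trace, base_lo, base_hi, closed_right=False)
    s0, s1 = _window_indices(trace, stim_lo, stim_hi, closed_right=True)
    if b0 < 0 or s1 > trace.n_samples:
        raise ScoringError(
            f"scoring window [{base_lo:.3f}, {stim_hi:.3f}] s out of trace bounds "
            f"[{trace.start_time:.3f}, {trace.end_time:.3f}] s for "
            f"{event.stimulus.value} at onset {event.onset:.3f}"
        )
    if b1 <= b0 or s1 <= s0:
        raise ScoringError(
            f"empty scoring window for {event.stimulus.value} at onset {event.onset:.3f}"
        )
    baseline = float(np.mean(trace.values[b0:b1]))
    peak = float(np.max(trace.values[s0:s1]))
    score = peak - baseline
    floored = False
    if floor_at_zero and score < 0:
        score, floored = 0.0, True
    return TrialScore(event=event, baseline=baseline, peak=peak, score=score, floored=floored)


def score_trial(trace: ScrTrace, event: TrialEvent, floor_at_zero: bool = True,
                baseline_window: float = BASELINE_WINDOW_S) -> TrialScore:
    """Score one CS trial: max over [onset, onset+duration] minus the
    mean over [onset - baseline_window, onset).

    The stimulus window is closed at both ends at sample resolution; the
    peak is the first sample attaining the maximum.
    """
    return _score_windows(
        trace, event,
        event.onset - baseline_window, event.onset,
        event.onset, event.onset + event.duration,
        floor_at_zero,
    )


def score_us_reactivity(trace: ScrTrace, us_event: TrialEvent,
                        response_window: float = DEFAULT_US_WINDOW_S,
                        floor_at_zero: bool = True,
                        baseline_window: float = BASELINE_WINDOW_S) -> TrialScore:
    """Score the unconditioned response: same rule as :func:`score_trial`
    but the peak is searched over [US onset, US onset + response_window].
    """
    if us_event.stimulus is not Stimulus.US:
        raise ScoringError(f"expected a US event, got {us_event.stimulus.value}")
    if us_event.phase is not PhaseName.CONDITIONING:
        raise ScoringError("US reactivity is defined for the conditioning phase")
    return _score_windows(
        trace, us_event,
        us_event.onset - baseline_window, us_event.onset,
        us_event.onset, us_event.onset + response_window,
        floor_at_zero,
    )


def score_phase(trace: ScrTrace, events: Sequence[TrialEvent], floor_at_zero: bool = True,
                median_kernel: float | None = DEFAULT_MEDIAN_KERNEL_S,
                us_window: float = DEFAULT_US_WINDOW_S) -> list[TrialScore]:
    """Median-filter a phase trace, then score every event in it.

    CS events are scored over their stimulus interval, US events over the
    US reactivity window. Filtering precedes scoring.
    """
    if not events:
        raise StructuralError("no events to score")
    filtered = median_filter(trace, median_kernel) if median_kernel else trace
    scores: list[TrialScore] = []
    for ev in events:
        if ev.stimulus is Stimulus.US:
            scores.append(score_us_reactivity(filtered, ev, us_window,
                                              floor_at_zero=floor_at_zero))
        else:
            scores.append(score_trial(filtered, ev, floor_at_zero=floor_at_zero))
    return scores


class QcCriterion(str, Enum):
    A_MISSING_OR_DISTORTED = "A_MISSING_OR_DISTORTED"
    B_NO_US_REACTIVITY = "B_NO_US_REACTIVITY"
    C_NO_CONDITIONED_RESPONSE = "C_NO_CONDITIONED_RESPONSE"


@dataclass
class VisitScores:
    """Per-visit material for the QC decision.

    ``available`` is an external data-quality flag: False marks the visit
    as missing or visibly distorted (criterion A); the package does not
    attempt to detect distortions itself.
    """

    us_scores: Sequence[float] = ()
    csplus_scores: Sequence[float] = ()
    available: bool = True


@dataclass
class QcDecision:
    subject_id: str
    include: bool
    failed_criteria: set[QcCriterion] = field(default_factory=set)
    detail: dict[str, list[str]] = field(default_factory=dict)  # visit -> failed criteria

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "include": self.include,
            "failed_criteria": sorted(c.value for c in self.failed_criteria),
            "detail": {v: sorted(cs) for v, cs in self.detail.items()},
        }


def qc_subject(subject_id: str, visits: Mapping[str, VisitScores],
               threshold: float = QC_THRESHOLD_US) -> QcDecision:
    """Apply the three inclusion criteria across all visits.

    A criterion failing at either visit fails overall; failures
    accumulate (a subject can fail several criteria). ``include`` is
    True iff no criterion failed at any visit.
    """
    failed: set[QcCriterion] = set()
    detail: dict[str, list[str]] = {}

    def mark(visit: str, crit: QcCriterion) -> None:
        failed.add(crit)
        detail.setdefault(visit, []).append(crit.value)

    for visit, vs in visits.items():
        if not vs.available:
            mark(visit, QcCriterion.A_MISSING_OR_DISTORTED)
            # unavailable data cannot rescue (b)/(c); evaluate what exists
        if vs.us_scores and max(vs.us_scores) < threshold:
            mark(visit, QcCriterion.B_NO_US_REACTIVITY)
        elif not vs.us_scores and vs.available:
            mark(visit, QcCriterion.B_NO_US_REACTIVITY)
        if vs.csplus_scores and max(vs.csplus_scores) < threshold:
            mark(visit, QcCriterion.C_NO_CONDITIONED_RESPONSE)
        elif not vs.csplus_scores and vs.available:
            mark(visit, QcCriterion.C_NO_CONDITIONED_RESPONSE)

    return QcDecision(subject_id=subject_id, include=not failed,
                      failed_criteria=failed, detail=detail)
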