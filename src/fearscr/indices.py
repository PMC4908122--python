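"""Derived endpoints: extinction retention, differential conditioning,
and the likelihood-weighted tract-FA summary.

The extinction retention index (ERI) expresses day-2 recall of the
extinguished CS+ as a percentage of maximal day-1 conditioned
responding, subtracted from 100:

    ERI = 100 - 100 * mean(sqrt(r1), sqrt(r2)) / max_j sqrt(c_j)

where r1, r2 are the responses to the first two CS+E recall trials and
c_j the conditioning-phase CS+E responses. The square root is applied
per trial score; since max of sqrt equals sqrt of max the reading only
affects the numerator, and the alternative (sqrt of the recall mean) is
available behind ``numerator_mode``.

Differential conditioning is the mean CS+ (E and U pooled) response
minus the mean CS- response during conditioning, excluding the first
presentation of each stimulus and the first CS- after the switch from
the CS+E block to the CS+U block.

The tract summary is the likelihood-weighted mean of per-voxel
fractional anisotropy along a reconstructed pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import AnalysisError
from .paradigm import Stimulus, locate_switch
from .scoring import TrialScore

__all__ = [
    "EriValue",
    "DifferentialConditioning",
    "TractSummary",
    "extinction_retention_index",
    "differential_conditioning",
    "weighted_fa",
]


@dataclass(frozen=True)
class EriValue:
    """ERI in percent, with its audit components (sqrt-µS scale)."""

    value: float
    numerator_recall_mean: float
    denominator_max_conditioning: float
    numerator_mode: str = "mean_of_sqrt"


def extinction_retention_index(
    conditioning_csplusE_scores: Sequence[float],
    recall_csplusE_scores: Sequence[float],
    numerator_mode: Literal["mean_of_sqrt", "sqrt_of_mean"] = "mean_of_sqrt",
) -> EriValue:
    """Compute the extinction retention index.

    Parameters
    ----------
    conditioning_csplusE_scores
        CS+E response amplitudes (µS, floored at 0) from the day-1
        conditioning phase; the maximum forms the denominator.
    recall_csplusE_scores
        CS+E recall amplitudes in presentation order; only the first two
        enter the numerator.
    numerator_mode
        ``"mean_of_sqrt"`` averages the square roots of the first two
        recall scores (default); ``"sqrt_of_mean"`` takes the square
        root of their mean.
    """
    cond = np.asarray(conditioning_csplusE_scores, dtype=float)
    recall = np.asarray(recall_csplusE_scores, dtype=float)
    if cond.size < 1:
        raise AnalysisError("ERI needs at least one conditioning CS+E score")
    if recall.size < 2:
        raise AnalysisError(
            f"ERI needs at least two recall CS+E trials, got {recall.size}"
        )
    if np.any(cond < 0) or np.any(recall < 0):
        raise AnalysisError("ERI requires scores floored at 0 (square-root transform)")
    denom = float(np.sqrt(np.max(cond)))
    if denom == 0.0:
        raise AnalysisError(
            "undefined ERI: maximal conditioning CS+E response is 0 (division by zero)"
        )
    r12 = recall[:2]
    if numerator_mode == "mean_of_sqrt":
        num = float(np.mean(np.sqrt(r12)))
    elif numerator_mode == "sqrt_of_mean":
        num = float(np.sqrt(np.mean(r12)))
    else:
        raise AnalysisError(f"unknown numerator_mode {numerator_mode!r}")
    value = 100.0 - 100.0 * num / denom
    return EriValue(value=value, numerator_recall_mean=num,
                    denominator_max_conditioning=denom, numerator_mode=numerator_mode)


@dataclass(frozen=True)
class DifferentialConditioning:
    value: float
    mean_csplus: float
    mean_csminus: float
    n_trials_used: dict[str, int]


def differential_conditioning(conditioning_scores: Sequence[TrialScore]) -> DifferentialConditioning:
    """Mean CS+ minus mean CS- response during conditioning.

    Exclusions: the first presentation of each of CS+E, CS+U and CS-,
    plus the first CS- after the switch between the CS+E and CS+U
    blocks. US events are ignored. Raw (untransformed) scores are used.
    """
    cs_scores = [s for s in conditioning_scores if s.event.stimulus is not Stimulus.US]
    if not cs_scores:
        raise AnalysisError("no CS trials to analyse")
    switch = locate_switch([s.event for s in cs_scores])
    excluded_minus_onset = (
        switch.first_csminus_after.onset if switch.first_csminus_after is not None else None
    )

    plus: list[float] = []
    minus: list[float] = []
    n_used = {"cs_plus_e": 0, "cs_plus_u": 0, "cs_minus": 0}
    for s in cs_scores:
        ev = s.event
        if ev.index_within_type == 1:
            continue
        if (ev.stimulus is Stimulus.CS_MINUS and excluded_minus_onset is not None
                and ev.onset == excluded_minus_onset):
            continue
        if ev.stimulus in (Stimulus.CS_PLUS_E, Stimulus.CS_PLUS_U):
            plus.append(s.score)
            n_used[ev.stimulus.value] += 1
        elif ev.stimulus is Stimulus.CS_MINUS:
            minus.append(s.score)
            n_used["cs_minus"] += 1
    if not plus:
        raise AnalysisError("no usable CS+ trials after exclusions")
    if not minus:
        raise AnalysisError("no usable CS- trials after exclusions")
    mean_plus = float(np.mean(plus))
    mean_minus = float(np.mean(minus))
    return DifferentialConditioning(
        value=mean_plus - mean_minus,
        mean_csplus=mean_plus,
        mean_csminus=mean_minus,
        n_trials_used=n_used,
    )


@dataclass(frozen=True)
class TractSummary:
    voxel_fa: np.ndarray
    voxel_weight: np.ndarray
    weighted_mean_fa: float


def weighted_fa(voxel_fa: Sequence[float], voxel_weight: Sequence[float]) -> TractSummary:
    """Likelihood-weighted mean FA along a tract.

    Each voxel's FA is weighted by the likelihood that the voxel belongs
    to the pathway; the summary is sum(w*FA)/sum(w).
    """
    fa = np.asarray(voxel_fa, dtype=float)
    w = np.asarray(voxel_weight, dtype=float)
    if fa.shape != w.shape or fa.ndim != 1:
        raise AnalysisError(
            f"FA and weight vectors must be 1-d and equal length, got {fa.shape} vs {w.shape}"
        )
    if fa.size == 0:
        raise AnalysisError("empty voxel table")
    if np.any(w < 0):
        raise AnalysisError("negative pathway likelihood weight")
    if np.any((fa < 0) | (fa > 1)):
        raise AnalysisError("FA values must lie in [0, 1]")
    total = float(np.sum(w))
    if total <= 0:
        raise AnalysisError("all pathway weights are zero")
    return TractSummary(voxel_fa=fa, voxel_weight=w,
                        weighted_mean_fa=float(np.sum(w * fa) / total))
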