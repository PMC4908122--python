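"""Synthetic electrodermal cohorts with programmable group-by-time structure.

The forward model for a trace is

    SC(t) = tonic + drift * t + noise(t) + sum_e  a_e * K(t - onset_e - latency)

with K a peak-normalized difference of exponentials (the canonical
phasic skin-conductance response shape) and per-event amplitudes a_e
determined by the stimulus, phase and visit:

* US events evoke ``us_amplitude``;
* CS+ trials in conditioning evoke the visit's conditioned-response
  amplitude (``cr_amplitude_pre``/``cr_amplitude_post``);
* CS+E trials in extinction decay exponentially across presentations
  (half-life 4 trials by default);
* CS+ trials at recall are the conditioned amplitude scaled by the
  visit's retention fraction — the quantity the extinction retention
  index is sensitive to;
* CS- trials evoke the orienting amplitude.

Non-responders receive US and CS+ amplitudes below the 0.05 µS QC
threshold, so they trip inclusion criteria (b) and (c).

Cohorts implement a difference-in-differences effect structure: the
control group's conditioned amplitude drops from pre to post by
``effect_cr_interaction`` while the trained group's is maintained, and
per-subject FA changes are coupled to the latent amplitude change via a
bivariate-normal construction targeting ``fa_scr_correlation``.
Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, StructuralError
from .paradigm import (ParadigmConfig, PhaseName, Schedule, Stimulus,
                       TrialEvent, generate_schedule)
from .scoring import ScrTrace

__all__ = [
    "PhasicWaveform",
    "SubjectParams",
    "CohortSpec",
    "Cohort",
    "synthesize_trace",
    "synthesize_cohort",
    "synthesize_questionnaires",
    "small_paradigm",
]

GROUPS = ("MBSR", "CONTROL")
VISITS = ("pre", "post")

#: Extinction-phase CS+ amplitude half-life, in trials.
EXTINCTION_HALFLIFE_TRIALS = 4.0

#: Amplitude (µS) assigned to US/CS+ events of non-responders; together
#: with the default noise level this keeps every scored response below
#: the 0.05 µS inclusion threshold.
NONRESPONDER_AMPLITUDE = 0.015

TRACE_TAIL_S = 10.0
TRACE_LEAD_S = 10.0


@dataclass(frozen=True)
class PhasicWaveform:
    """Peak-normalized difference-of-exponentials response kernel."""

    tau_rise: float = 0.75
    tau_decay: float = 3.0
    latency: float = 1.5

    def validate(self) -> None:
        if not (0 < self.tau_rise < self.tau_decay):
            raise ConfigError(
                f"need 0 < tau_rise < tau_decay, got {self.tau_rise}, {self.tau_decay}"
            )
        if self.latency < 0:
            raise ConfigError(f"latency must be >= 0, got {self.latency}")

    @property
    def time_to_peak(self) -> float:
        r, d = self.tau_rise, self.tau_decay
        return float(np.log(d / r) * r * d / (d - r))

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the kernel at times ``t`` (seconds after onset+latency)."""
        self.validate()
        t = np.asarray(t, dtype=float)
        raw = np.where(t >= 0, np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise), 0.0)
        tp = self.time_to_peak
        peak = np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise)
        return raw / peak

    @property
    def support(self) -> float:
        """Duration after which the kernel is negligible (< 1e-4 of peak)."""
        return self.latency + self.time_to_peak + 10.0 * self.tau_decay


@dataclass
class SubjectParams:
    """Latent per-subject generative parameters (amplitudes in µS)."""

    subject_id: str
    group: str
    tonic_level: float = 8.0
    tonic_drift: float = 0.0  # µS per minute
    noise_sd: float = 0.01
    us_amplitude: float = 0.8
    cr_amplitude_pre: float = 0.46
    cr_amplitude_post: float = 0.46
    orienting_amplitude: float = 0.15
    retention_fraction_pre: float = 0.2
    retention_fraction_post: float = 0.2
    responder: bool = True
    age: float = 40.0
    days_between_scans: float = 63.0
    practice_hours: float = float("nan")
    delta_fa_unc: float = 0.0
    fa_pre: float = 0.46

    def validate(self) -> None:
        if self.tonic_level <= 0:
            raise ConfigError(f"tonic_level must be > 0, got {self.tonic_level}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name in ("us_amplitude", "cr_amplitude_pre", "cr_amplitude_post",
                     "orienting_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("retention_fraction_pre", "retention_fraction_post"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

    def cr_amplitude(self, visit: str) -> float:
        return self.cr_amplitude_pre if visit == "pre" else self.cr_amplitude_post

    def retention_fraction(self, visit: str) -> float:
        return (self.retention_fraction_pre if visit == "pre"
                else self.retention_fraction_post)


@dataclass
class CohortSpec:
    """Cohort size, effect structure and generator conditions.

    Defaults mirror the study conditions: 23 subjects per group, a
    0.32 µS pre-to-post drop of the conditioned response in controls
    with the trained group maintained, retention-fraction changes that
    move the trained group's ERI from ~32% to ~63% against stable
    controls, FA changes of +0.008 (trained) / +0.002 (control) around
    0.46, an FA-change/CS+-change correlation of 0.42, and a 35%
    non-responder rate.
    """

    n_per_group: int = 23
    effect_cr_interaction: float = 0.32
    effect_eri_interaction: float = -0.35
    fa_scr_correlation: float = 0.42
    nonresponder_rate: float = 0.35
    sampling_rate: float = 10.0
    waveform: PhasicWaveform = field(default_factory=PhasicWaveform)
    seed: int = 0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    phases: tuple[PhaseName, ...] = (PhaseName.CONDITIONING, PhaseName.EXTINCTION,
                                     PhaseName.RECALL)
    # distribution conditions (medians/means and spreads)
    tonic_level_median: float = 8.0
    tonic_level_log_sd: float = 0.3
    tonic_drift_sd: float = 0.03        # µS/min
    noise_sd: float = 0.01              # µS
    # the unconditioned response scales with the subject's reactivity:
    # us_amplitude = cr_amplitude_pre * ratio.  Keeping the ratio well
    # above the worst-case baseline contamination from the decaying CS+
    # response makes every responder clear the 0.05 µS US criterion.
    us_cr_ratio_median: float = 3.0
    us_cr_ratio_log_sd: float = 0.2
    cr_amplitude_median: float = 0.46
    amplitude_log_sd: float = 0.5
    orienting_amplitude_median: float = 0.15
    cr_post_floor: float = 0.08
    cr_delta_sd: float = 0.10           # subject-level jitter of the post change
    retention_pre_mean: dict = field(default_factory=lambda: {"MBSR": 0.46, "CONTROL": 0.074})
    retention_control_delta: float = 0.03
    retention_sd: float = 0.12
    fa_pre_mean: float = 0.46
    fa_pre_sd: float = 0.03
    fa_delta_mean: dict = field(default_factory=lambda: {"MBSR": 0.008, "CONTROL": 0.002})
    fa_delta_sd: float = 0.01
    n_voxels: int = 40
    make_fa_tables: bool = True  # skip voxel tables in pure-SCR simulations
    age_mean: dict = field(default_factory=lambda: {"MBSR": 44.0, "CONTROL": 38.0})
    age_sd: float = 12.0
    days_between_mean: float = 63.0
    days_between_sd: float = 10.0
    practice_hours_median: float = 25.0
    practice_hours_log_sd: float = 0.4

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if not (0 <= self.nonresponder_rate < 1) and self.nonresponder_rate != 1.0:
            raise ConfigError(
                f"nonresponder_rate must lie in [0, 1], got {self.nonresponder_rate}"
            )
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if abs(self.fa_scr_correlation) > 1:
            raise ConfigError(
                f"|fa_scr_correlation| must be <= 1, got {self.fa_scr_correlation}"
            )
        self.waveform.validate()
        self.paradigm.validate()


def _event_amplitude(params: SubjectParams, event: TrialEvent, visit: str) -> float:
    if not params.responder and event.stimulus in (Stimulus.US, Stimulus.CS_PLUS_E,
                                                   Stimulus.CS_PLUS_U):
        return NONRESPONDER_AMPLITUDE
    if event.stimulus is Stimulus.US:
        return params.us_amplitude
    if event.stimulus is Stimulus.CS_MINUS:
        return params.orienting_amplitude
    # CS+ of either type
    cr = params.cr_amplitude(visit)
    if event.phase is PhaseName.CONDITIONING:
        return cr
    if event.phase is PhaseName.EXTINCTION:
        return cr * 0.5 ** ((event.index_within_type - 1) / EXTINCTION_HALFLIFE_TRIALS)
    # recall: conditioned response scaled by the visit's retention fraction
    return cr * params.retention_fraction(visit)


def synthesize_trace(params: SubjectParams, events: Sequence[TrialEvent], visit: str,
                     waveform: PhasicWaveform | None = None,
                     sampling_rate: float = 10.0,
                     seed: int | np.random.Generator = 0) -> ScrTrace:
    """Generate one subject-visit-phase trace from the forward model.

    The trace spans from 10 s before the first onset (clipped at the
    phase clock's zero only if events start at 0) to 10 s after the
    last event offset; drift is measured from the trace start.
    """
    if not events:
        raise StructuralError("cannot synthesize a trace without events")
    params.validate()
    wf = waveform or PhasicWaveform()
    wf.validate()
    if sampling_rate < 2.0:
        raise ConfigError(f"sampling_rate must be >= 2 Hz, got {sampling_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    phases = {e.phase for e in events}
    if len(phases) > 1:
        raise StructuralError(f"events span multiple phases: {sorted(p.value for p in phases)}")

    t0 = min(e.onset for e in events) - TRACE_LEAD_S
    t1 = max(e.offset for e in events) + TRACE_TAIL_S
    n = int(np.floor((t1 - t0) * sampling_rate)) + 1
    t = t0 + np.arange(n) / sampling_rate

    values = params.tonic_level + (params.tonic_drift / 60.0) * (t - t0)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=n)

    support = wf.support
    for ev in events:
        amp = _event_amplitude(params, ev, visit)
        if amp == 0.0:
            continue
        start = ev.onset + wf.latency
        i0 = max(0, int(np.floor((start - t0) * sampling_rate)))
        i1 = min(n, int(np.ceil((start + support - t0) * sampling_rate)) + 1)
        if i1 <= i0:
            continue
        values[i0:i1] += amp * wf.kernel(t[i0:i1] - start)

    return ScrTrace(sampling_rate=sampling_rate, start_time=float(t0), values=values)


def _lognormal(rng: np.random.Generator, median: float, log_sd: float, size: int) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, log_sd, size=size))


@dataclass
class Cohort:
    """Bundle of everything a synthetic study produces.

    ``traces`` maps (subject_id, visit, phase) to an (ScrTrace, events)
    pair; ``covariates`` is one row per subject; ``truth`` records the
    latent per-subject-visit amplitudes for parameter-recovery checks.
    """

    spec: CohortSpec
    subjects: list[SubjectParams]
    schedule: Schedule
    traces: dict[tuple[str, str, PhaseName], tuple[ScrTrace, list[TrialEvent]]]
    covariates: pd.DataFrame
    fa_tables: dict[tuple[str, str], pd.DataFrame]
    truth: pd.DataFrame

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def synthesize_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full two-group, two-visit cohort from the spec.

    The difference-in-differences structure: controls' conditioned
    amplitude at post is pre minus ``effect_cr_interaction`` (plus
    subject jitter, floored at ``cr_post_floor``); the trained group's
    is maintained (plus the same jitter). Retention fractions move by
    ``retention_control_delta`` in controls and additionally by
    ``effect_eri_interaction`` in the trained group. FA changes are
    drawn with correlation ``fa_scr_correlation`` against the latent
    CS+ amplitude change.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    total = 2 * n

    groups = np.array(["MBSR"] * n + ["CONTROL"] * n)
    ids = [f"sub-{i + 1:03d}" for i in range(total)]

    tonic = _lognormal(rng, spec.tonic_level_median, spec.tonic_level_log_sd, total)
    drift = rng.normal(0.0, spec.tonic_drift_sd, total)
    cr_pre = _lognormal(rng, spec.cr_amplitude_median, spec.amplitude_log_sd, total)
    us_amp = cr_pre * _lognormal(rng, spec.us_cr_ratio_median,
                                 spec.us_cr_ratio_log_sd, total)
    orient = _lognormal(rng, spec.orienting_amplitude_median, spec.amplitude_log_sd, total)
    jitter = rng.normal(0.0, spec.cr_delta_sd, total)
    drop = np.where(groups == "CONTROL", spec.effect_cr_interaction, 0.0)
    cr_post = np.maximum(cr_pre - drop + jitter, spec.cr_post_floor)

    rf_pre = np.clip(
        np.array([spec.retention_pre_mean[g] for g in groups])
        + rng.normal(0.0, spec.retention_sd, total), 0.01, 0.99)
    rf_delta = np.where(groups == "MBSR",
                        spec.retention_control_delta + spec.effect_eri_interaction,
                        spec.retention_control_delta)
    rf_post = np.clip(rf_pre + rf_delta + rng.normal(0.0, spec.retention_sd / 2, total),
                      0.01, 0.99)

    responder = rng.random(total) >= spec.nonresponder_rate

    age = np.array([rng.normal(spec.age_mean[g], spec.age_sd) for g in groups]).clip(18, 80)
    days = rng.normal(spec.days_between_mean, spec.days_between_sd, total).clip(7, None)
    practice = np.where(groups == "MBSR",
                        _lognormal(rng, spec.practice_hours_median,
                                   spec.practice_hours_log_sd, total),
                        np.nan)

    # FA change coupled to the latent CS+ amplitude change
    d_amp = cr_post - cr_pre
    sd = d_amp.std()
    z = (d_amp - d_amp.mean()) / sd if sd > 0 else np.zeros(total)
    r = spec.fa_scr_correlation
    eps = rng.normal(0.0, 1.0, total)
    fa_pre = rng.normal(spec.fa_pre_mean, spec.fa_pre_sd, total).clip(0.15, 0.85)
    d_fa = (np.array([spec.fa_delta_mean[g] for g in groups])
            + spec.fa_delta_sd * (r * z + np.sqrt(max(0.0, 1 - r * r)) * eps))

    subjects: list[SubjectParams] = []
    for i in range(total):
        subjects.append(SubjectParams(
            subject_id=ids[i], group=str(groups[i]),
            tonic_level=float(tonic[i]), tonic_drift=float(drift[i]),
            noise_sd=spec.noise_sd,
            us_amplitude=float(us_amp[i]),
            cr_amplitude_pre=float(cr_pre[i]), cr_amplitude_post=float(cr_post[i]),
            orienting_amplitude=float(orient[i]),
            retention_fraction_pre=float(rf_pre[i]),
            retention_fraction_post=float(rf_post[i]),
            responder=bool(responder[i]),
            age=float(age[i]), days_between_scans=float(days[i]),
            practice_hours=float(practice[i]),
            delta_fa_unc=float(d_fa[i]), fa_pre=float(fa_pre[i]),
        ))

    schedule = generate_schedule(spec.paradigm)

    traces: dict[tuple[str, str, PhaseName], tuple[ScrTrace, list[TrialEvent]]] = {}
    fa_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for subj in subjects:
        for visit in VISITS:
            for phase in spec.phases:
                events = schedule.events(phase)
                trace = synthesize_trace(subj, events, visit, spec.waveform,
                                         spec.sampling_rate, rng)
                traces[(subj.subject_id, visit, phase)] = (trace, list(events))
            if spec.make_fa_tables:
                fa_target = (subj.fa_pre if visit == "pre"
                             else subj.fa_pre + subj.delta_fa_unc)
                fa_tables[(subj.subject_id, visit)] = _voxel_table(
                    rng, fa_target, spec.n_voxels)

    covariates = pd.DataFrame({
        "subject_id": ids,
        "group": groups,
        "age": np.round(age, 1),
        "days_between_scans": np.round(days, 1),
        "practice_hours": practice,
    })

    truth = pd.DataFrame({
        "subject_id": ids,
        "group": groups,
        "responder": responder,
        "cr_amplitude_pre": cr_pre,
        "cr_amplitude_post": cr_post,
        "retention_fraction_pre": rf_pre,
        "retention_fraction_post": rf_post,
        "fa_pre": fa_pre,
        "delta_fa": d_fa,
    })

    return Cohort(spec=spec, subjects=subjects, schedule=schedule, traces=traces,
                  covariates=covariates, fa_tables=fa_tables, truth=truth)


def _voxel_table(rng: np.random.Generator, target_weighted_fa: float, n_voxels: int) -> pd.DataFrame:
    """Per-voxel FA + likelihood weights whose weighted mean hits the target."""
    w = rng.gamma(2.0, 1.0, n_voxels)
    fa = rng.normal(target_weighted_fa, 0.05, n_voxels)
    fa = fa + (target_weighted_fa - np.average(fa, weights=w))
    fa = np.clip(fa, 0.0, 1.0)
    return pd.DataFrame({
        "voxel_id": np.arange(1, n_voxels + 1),
        "fa": fa,
        "weight": w,
    })


QUESTIONNAIRE_PRE_MEANS = {"pss": 25.0, "ders": 80.0, "maas": 3.8}
QUESTIONNAIRE_PRE_SDS = {"pss": 6.0, "ders": 18.0, "maas": 0.9}


def synthesize_questionnaires(cohort: Cohort, effect_practice_slope: float = -0.3,
                              noise_sd: float = 4.0,
                              seed: int | None = None) -> pd.DataFrame:
    """Questionnaire totals (PSS, DERS, MAAS) per subject-visit.

    Pre scores are independent of practice; post scores for trained
    subjects are a linear function of total practice hours
    (``effect_practice_slope`` score-units per hour, same slope for each
    instrument) plus noise. Controls' post scores are pre plus noise.
    """
    spec = cohort.spec
    rng = np.random.default_rng(spec.seed + 104729 if seed is None else seed)
    rows = []
    for subj in cohort.subjects:
        pre_scores = {q: rng.normal(QUESTIONNAIRE_PRE_MEANS[q], QUESTIONNAIRE_PRE_SDS[q])
                      for q in QUESTIONNAIRE_PRE_MEANS}
        post_scores = {}
        for q in QUESTIONNAIRE_PRE_MEANS:
            if subj.group == "MBSR":
                if not np.isfinite(subj.practice_hours):
                    raise ConfigError(f"{subj.subject_id}: trained subject lacks practice hours")
                post = (QUESTIONNAIRE_PRE_MEANS[q]
                        + effect_practice_slope * subj.practice_hours)
            else:
                post = pre_scores[q]
            if noise_sd > 0:
                post += rng.normal(0.0, noise_sd)
            post_scores[q] = post
        rows.append({"subject_id": subj.subject_id, "visit": "pre", **pre_scores})
        rows.append({"subject_id": subj.subject_id, "visit": "post", **post_scores})
    return pd.DataFrame(rows)


def small_paradigm(seed: int = 0) -> ParadigmConfig:
    """A reduced schedule for simulation studies: 3 CS+ of each type
    (2 reinforced), 6 CS- in conditioning, 4 CS+E / 4 CS- in
    extinction, 2 of each type at recall, 4 s CS and short ITIs.
    Preserves the paradigm's structure at a fraction of the trace
    length."""
    return ParadigmConfig(
        n_csplus_each=3, n_reinforced_each=2, n_csminus_conditioning=6,
        n_csplusE_extinction=4, n_csminus_extinction=4, n_each_recall=2,
        cs_duration=4.0, us_duration=0.5, iti_range=(3.0, 5.0),
        inter_phase_gap=10.0, seed=seed,
    )
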