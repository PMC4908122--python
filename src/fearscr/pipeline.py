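"""End-to-end driver: write/read a study directory and run
score -> qc -> indices -> stats, leaving one CSV/JSON per stage plus a
manifest that suffices to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as fio
from .errors import AnalysisError, ConfigError, FearscrError, FormatError
from .indices import differential_conditioning, extinction_retention_index, weighted_fa
from .paradigm import PhaseName, Stimulus
from .scoring import (QC_THRESHOLD_US, VisitScores, qc_subject, score_phase)
from .stats import (MULTIPLICITY_CAVEAT, ChangeScoreAncova, TestResult,
                    baseline_difference, correlation, paired_t,
                    practice_regression)
from .synth import VISITS, Cohort

log = logging.getLogger("fearscr")

__all__ = ["write_cohort", "run_pipeline", "PipelineError", "Manifest",
           "score_cohort", "qc_from_scores", "endpoints_from_scores",
           "cohort_endpoints"]


class PipelineError(FearscrError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def write_cohort(cohort: Cohort, data_dir: str | Path,
                 questionnaires: pd.DataFrame | None = None) -> Path:
    """Materialize a synthetic cohort as a study directory."""
    root = Path(data_dir)
    for (subj, visit, phase), (trace, events) in sorted(cohort.traces.items()):
        stem = f"{subj}_visit-{visit}_phase-{phase.value}"
        fio.write_physio(trace, root / "physio" / f"{stem}_physio.tsv")
        fio.write_events(events, root / "events" / f"{stem}_events.tsv")
    for (subj, visit), table in sorted(cohort.fa_tables.items()):
        fio.write_voxel_table(table, root / "fa" / f"{subj}_visit-{visit}_fa.csv")
    fio.write_table(cohort.covariates, root / "covariates.csv")
    if questionnaires is not None:
        fio.write_table(questionnaires, root / "questionnaires.csv")
    return root


def _discover(root: Path) -> list[tuple[str, str, str]]:
    """(subject, visit, phase) triples present in the physio directory."""
    out = []
    for p in sorted((root / "physio").glob("*_physio.tsv")):
        stem = p.name[: -len("_physio.tsv")]
        subj, visit_part, phase_part = stem.split("_")
        out.append((subj, visit_part.removeprefix("visit-"),
                    phase_part.removeprefix("phase-")))
    if not out:
        raise FormatError(f"no physio files found under {root / 'physio'}")
    return out


def _score_rows(subj: str, visit: str, phase: str, scores) -> list[dict]:
    return [{
        "subject_id": subj, "visit": visit, "phase": phase,
        "trial_type": s.event.stimulus.value,
        "index_within_type": s.event.index_within_type,
        "onset": s.event.onset, "duration": s.event.duration,
        "reinforced": int(s.event.reinforced),
        "baseline_uS": s.baseline, "peak_uS": s.peak,
        "score_uS": s.score, "floored": int(s.floored),
    } for s in scores]


def _stage_score(root: Path, cfg: fio.PipelineConfig) -> pd.DataFrame:
    rows = []
    for subj, visit, phase in _discover(root):
        stem = f"{subj}_visit-{visit}_phase-{phase}"
        events_path = root / "events" / f"{stem}_events.tsv"
        if not events_path.exists():
            raise FormatError(f"missing events file {events_path}")
        trace = fio.read_physio(root / "physio" / f"{stem}_physio.tsv")
        events = fio.read_events(events_path)
        scores = score_phase(trace, events, floor_at_zero=cfg.floor_at_zero,
                             median_kernel=cfg.median_kernel or None,
                             us_window=cfg.us_window)
        rows.extend(_score_rows(subj, visit, phase, scores))
    return pd.DataFrame(rows)


def score_cohort(cohort: Cohort, median_kernel: float | None = 0.5,
                 us_window: float = 6.0, floor_at_zero: bool = True) -> pd.DataFrame:
    """Score every trace of an in-memory cohort (no disk round trip)."""
    rows = []
    for (subj, visit, phase), (trace, events) in sorted(cohort.traces.items()):
        scores = score_phase(trace, events, floor_at_zero=floor_at_zero,
                             median_kernel=median_kernel, us_window=us_window)
        rows.extend(_score_rows(subj, visit, phase.value, scores))
    return pd.DataFrame(rows)


def qc_from_scores(scores: pd.DataFrame, threshold: float = QC_THRESHOLD_US,
                   flags: dict | None = None) -> list:
    """Apply the three-criterion QC to a score table.

    ``flags`` maps (subject_id, visit) to an availability boolean;
    absent conditioning data for a visit also marks it unavailable.
    """
    flags = flags or {}
    decisions = []
    cond = scores[scores["phase"] == PhaseName.CONDITIONING.value]
    groups = {key: sub for key, sub in cond.groupby(["subject_id", "visit"], sort=False)}
    for subj in sorted(scores["subject_id"].unique()):
        visits = {}
        for visit in VISITS:
            sub = groups.get((subj, visit))
            if sub is None:
                visits[visit] = VisitScores(available=flags.get((subj, visit), False))
                continue
            tt = sub["trial_type"].to_numpy()
            sc = sub["score_uS"].to_numpy()
            visits[visit] = VisitScores(
                us_scores=sc[tt == Stimulus.US.value].tolist(),
                csplus_scores=sc[(tt == Stimulus.CS_PLUS_E.value)
                                 | (tt == Stimulus.CS_PLUS_U.value)].tolist(),
                available=flags.get((subj, visit), True),
            )
        decision = qc_subject(subj, visits, threshold=threshold)
        if not decision.include:
            log.info("QC exclusion %s: %s", subj,
                     sorted(c.value for c in decision.failed_criteria))
        decisions.append(decision)
    return decisions


def _stage_qc(scores: pd.DataFrame, root: Path, cfg: fio.PipelineConfig) -> list:
    flags = {}
    flags_path = root / "qc_flags.csv"
    if flags_path.exists():
        fdf = fio.read_table(flags_path)
        flags = {(r["subject_id"], r["visit"]): bool(r["available"])
                 for _, r in fdf.iterrows()}
    return qc_from_scores(scores, threshold=cfg.qc_threshold, flags=flags)


def _score_objects(group: pd.DataFrame):
    """Rebuild TrialScore objects from score-table rows (for indices)."""
    from .paradigm import TrialEvent
    from .scoring import TrialScore

    out = []
    for r in group.sort_values("onset").itertuples(index=False):
        ev = TrialEvent(onset=float(r.onset), duration=float(r.duration),
                        stimulus=Stimulus(r.trial_type),
                        phase=PhaseName(r.phase),
                        reinforced=bool(r.reinforced),
                        index_within_type=int(r.index_within_type))
        out.append(TrialScore(event=ev, baseline=float(r.baseline_uS),
                              peak=float(r.peak_uS), score=float(r.score_uS),
                              floored=bool(r.floored)))
    return out


def endpoints_from_scores(scores: pd.DataFrame, included: list[str],
                          fa_tables: dict[tuple[str, str], pd.DataFrame] | None = None,
                          eri_numerator_mode: str = "mean_of_sqrt") -> pd.DataFrame:
    """Per-subject-visit endpoints from a score table.

    Computes differential conditioning (with its CS+/CS- means), the
    ERI where conditioning and recall CS+E trials exist, and the
    weighted tract FA where a voxel table is supplied. Subjects with an
    undefined ERI (zero conditioning maximum) get NaN with a warning.
    """
    fa_tables = fa_tables or {}
    groups = {key: sub for key, sub in scores.groupby(["subject_id", "visit"], sort=False)}
    empty = scores.iloc[0:0]
    rows = []
    for subj in included:
        for visit in VISITS:
            sv = groups.get((subj, visit), empty)
            row: dict = {"subject_id": subj, "visit": visit}
            cond = sv[sv["phase"] == PhaseName.CONDITIONING.value]
            recall = sv[sv["phase"] == PhaseName.RECALL.value]
            if not cond.empty:
                dc = differential_conditioning(_score_objects(cond))
                row.update(diff_cond_uS=dc.value, mean_csplus_uS=dc.mean_csplus,
                           mean_csminus_uS=dc.mean_csminus)
            cond_e = cond[cond["trial_type"] == Stimulus.CS_PLUS_E.value]
            recall_e = recall[recall["trial_type"] == Stimulus.CS_PLUS_E.value]
            if not cond_e.empty and len(recall_e) >= 2:
                try:
                    eri = extinction_retention_index(
                        cond_e["score_uS"].to_numpy(),
                        recall_e.sort_values("onset")["score_uS"].to_numpy(),
                        numerator_mode=eri_numerator_mode)
                    row["eri_percent"] = eri.value
                except AnalysisError as exc:
                    log.warning("ERI undefined for %s/%s: %s", subj, visit, exc)
                    row["eri_percent"] = np.nan
            if (subj, visit) in fa_tables:
                vox = fa_tables[(subj, visit)]
                row["weighted_fa"] = weighted_fa(vox["fa"], vox["weight"]).weighted_mean_fa
            rows.append(row)
    if not rows:
        raise AnalysisError("no included subjects left after QC")
    return pd.DataFrame(rows)


def cohort_endpoints(cohort: Cohort, median_kernel: float | None = 0.5,
                     qc_threshold: float = QC_THRESHOLD_US,
                     eri_numerator_mode: str = "mean_of_sqrt") -> pd.DataFrame:
    """Score, QC and summarize an in-memory cohort to its endpoint table,
    merged with the covariates. The workhorse of the simulation studies."""
    scores = score_cohort(cohort, median_kernel=median_kernel)
    decisions = qc_from_scores(scores, threshold=qc_threshold)
    included = [d.subject_id for d in decisions if d.include]
    endpoints = endpoints_from_scores(scores, included, cohort.fa_tables,
                                      eri_numerator_mode)
    return endpoints.merge(cohort.covariates, on="subject_id", how="left")


def _stage_indices(scores: pd.DataFrame, included: list[str], root: Path,
                   cfg: fio.PipelineConfig) -> pd.DataFrame:
    fa_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for subj in included:
        for visit in VISITS:
            fa_path = root / "fa" / f"{subj}_visit-{visit}_fa.csv"
            if fa_path.exists():
                fa_tables[(subj, visit)] = fio.read_voxel_table(fa_path)
    return endpoints_from_scores(scores, included, fa_tables, cfg.eri_numerator_mode)


_ENDPOINTS = ["diff_cond_uS", "mean_csplus_uS", "mean_csminus_uS", "eri_percent",
              "weighted_fa"]


def _result_row(name: str, res: TestResult) -> dict:
    return {"analysis": name, "family": res.family, "statistic": res.statistic,
            "df1": res.df[0], "df2": res.df[1] if len(res.df) > 1 else np.nan,
            "p": res.pvalue, "effect_size": res.effect_size, "n": res.n}


def _stage_stats(endpoints: pd.DataFrame, covariates: pd.DataFrame,
                 questionnaires: pd.DataFrame | None,
                 cfg: fio.PipelineConfig) -> pd.DataFrame:
    merged = endpoints.merge(covariates, on="subject_id", how="left")
    covs = [c for c in cfg.covariates if c in merged.columns]
    rows = []
    for ep in _ENDPOINTS:
        if ep not in merged.columns or merged[ep].dropna().empty:
            continue
        data = merged.dropna(subset=[ep])
        try:
            model = ChangeScoreAncova.from_records(data, ep, covariates=covs)
            res = model.fit().as_test_result(f"group x time: {ep}")
            rows.append(_result_row(f"interaction_{ep}", res))
        except FearscrError as exc:
            log.warning("interaction on %s skipped: %s", ep, exc)
        for grp in sorted(data["group"].dropna().unique()):
            g = data[data["group"] == grp]
            pre = g[g["visit"] == "pre"].set_index("subject_id")[ep]
            post = g[g["visit"] == "post"].set_index("subject_id")[ep]
            common = pre.index.intersection(post.index)
            if len(common) >= 2:
                try:
                    res = paired_t(pre.loc[common], post.loc[common],
                                   description=f"paired t {grp} {ep}")
                    rows.append(_result_row(f"paired_t_{grp}_{ep}", res))
                except FearscrError as exc:
                    log.warning("paired t on %s/%s skipped: %s", grp, ep, exc)
        try:
            res = baseline_difference(data[data["visit"] == "pre"], ep, covariates=covs)
            rows.append(_result_row(f"baseline_{ep}", res))
        except FearscrError as exc:
            log.warning("baseline test on %s skipped: %s", ep, exc)

    # change-change correlation: delta weighted FA vs delta CS+ response
    if {"weighted_fa", "mean_csplus_uS"} <= set(merged.columns):
        wide = merged.pivot_table(index="subject_id",
                                  columns="visit",
                                  values=["weighted_fa", "mean_csplus_uS"],
                                  aggfunc="first")
        try:
            d_fa = wide[("weighted_fa", "post")] - wide[("weighted_fa", "pre")]
            d_cs = wide[("mean_csplus_uS", "post")] - wide[("mean_csplus_uS", "pre")]
            ok = d_fa.notna() & d_cs.notna()
            cov_tbl = covariates.set_index("subject_id").loc[ok[ok].index, list(covs)] \
                if covs else None
            res = correlation(d_cs[ok], d_fa[ok], partial_covariates=cov_tbl,
                              description="delta FA vs delta CS+")
            rows.append(_result_row("corr_dfa_dcsplus", res))
        except (FearscrError, KeyError) as exc:
            log.warning("delta-delta correlation skipped: %s", exc)

    if questionnaires is not None:
        qcols = [c for c in questionnaires.columns if c not in ("subject_id", "visit")]
        qm = questionnaires.merge(covariates, on="subject_id", how="left")
        for q in qcols:
            try:
                res = ChangeScoreAncova.from_records(qm.dropna(subset=[q]), q,
                                                     covariates=covs).fit() \
                    .as_test_result(f"group x time: {q}")
                rows.append(_result_row(f"interaction_{q}", res))
            except FearscrError as exc:
                log.warning("questionnaire interaction on %s skipped: %s", q, exc)
            trained = qm[(qm["group"] == "MBSR") & (qm["visit"] == "post")] \
                .dropna(subset=[q, "practice_hours"])
            if len(trained) >= 3:
                try:
                    res = practice_regression(trained[q], trained["practice_hours"],
                                              description=f"practice -> post {q}")
                    rows.append(_result_row(f"practice_{q}", res))
                except FearscrError as exc:
                    log.warning("practice regression on %s skipped: %s", q, exc)

    if not rows:
        raise AnalysisError("no statistical analysis could be run")
    return pd.DataFrame(rows)


@dataclass
class Manifest:
    config: dict
    seed: int
    version: str
    inputs: dict
    stage_rows: dict = field(default_factory=dict)
    excluded_subjects: dict = field(default_factory=dict)
    caveat: str = MULTIPLICITY_CAVEAT

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True) + "\n",
                        encoding="utf-8")


def run_pipeline(cfg: fio.PipelineConfig, stop_after: str | None = None) -> Manifest:
    """Execute score -> qc -> indices -> stats on a study directory.

    Each stage writes its CSV/JSON into ``cfg.out_dir``; any stage error
    aborts with :class:`PipelineError` naming the stage. Deterministic
    given identical inputs and config. ``stop_after`` truncates the run
    after the named stage (used by the per-stage CLI subcommands).
    """
    cfg.validate()
    if stop_after not in (None, "score", "qc", "indices", "stats"):
        raise ConfigError(f"unknown stage {stop_after!r}")
    root = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = Manifest(config=asdict(cfg), seed=cfg.seed, version=__version__,
                        inputs={"data_dir": str(root)})

    try:
        scores = _stage_score(root, cfg)
    except FearscrError as exc:
        raise PipelineError("score", exc) from exc
    fio.write_table(scores, out / "scores.csv")
    manifest.stage_rows["score"] = int(len(scores))
    if stop_after == "score":
        manifest.write(out / "manifest.json")
        return manifest

    try:
        decisions = _stage_qc(scores, root, cfg)
    except FearscrError as exc:
        raise PipelineError("qc", exc) from exc
    qc_df = pd.DataFrame([{
        "subject_id": d.subject_id, "include": int(d.include),
        "failed_criteria": ";".join(sorted(c.value for c in d.failed_criteria)),
    } for d in decisions])
    fio.write_table(qc_df, out / "qc.csv")
    (out / "qc.json").write_text(
        json.dumps([d.to_dict() for d in decisions], indent=1) + "\n", encoding="utf-8")
    included = [d.subject_id for d in decisions if d.include]
    manifest.stage_rows["qc"] = int(len(decisions))
    manifest.excluded_subjects = {
        d.subject_id: sorted(c.value for c in d.failed_criteria)
        for d in decisions if not d.include}
    if stop_after == "qc":
        manifest.write(out / "manifest.json")
        return manifest

    try:
        endpoints = _stage_indices(scores, included, root, cfg)
    except FearscrError as exc:
        raise PipelineError("indices", exc) from exc
    fio.write_table(endpoints, out / "endpoints.csv")
    manifest.stage_rows["indices"] = int(len(endpoints))
    if stop_after == "indices":
        manifest.write(out / "manifest.json")
        return manifest

    covariates = fio.read_table(root / "covariates.csv")
    qpath = root / "questionnaires.csv"
    questionnaires = fio.read_table(qpath) if qpath.exists() else None
    try:
        results = _stage_stats(endpoints, covariates, questionnaires, cfg)
    except FearscrError as exc:
        raise PipelineError("stats", exc) from exc
    fio.write_table(results, out / "results.csv")
    report = {
        "caveat": MULTIPLICITY_CAVEAT,
        "alpha": cfg.alpha,
        "df_convention": "interaction F has (1, n-k) df, k = model columns "
                         "(intercept + group + covariates); effect size is "
                         "partial eta^2 = SS_effect/(SS_effect+SS_error)",
        "results": results.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1) + "\n",
                                     encoding="utf-8")
    manifest.stage_rows["stats"] = int(len(results))

    manifest.write(out / "manifest.json")
    return manifest
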