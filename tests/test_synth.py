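import numpy as np
import pytest

from fearscr.errors import ConfigError, StructuralError
from fearscr.paradigm import ParadigmConfig, PhaseName, Stimulus, TrialEvent
from fearscr.pipeline import cohort_endpoints, score_cohort
from fearscr.scoring import score_phase
from fearscr.stats import practice_regression
from fearscr.synth import (CohortSpec, PhasicWaveform, SubjectParams,
                           small_paradigm, synthesize_cohort,
                           synthesize_questionnaires, synthesize_trace)


class TestPhasicWaveform:
    def test_kernel_peak_normalized_to_one(self):
        wf = PhasicWaveform()
        t = np.linspace(0, 30, 30001)
        assert wf.kernel(t).max() == pytest.approx(1.0, abs=1e-6)
        assert wf.kernel(np.array([wf.time_to_peak]))[0] == pytest.approx(1.0)

    def test_kernel_zero_before_onset(self):
        wf = PhasicWaveform()
        assert np.all(wf.kernel(np.array([-1.0, -0.01])) == 0.0)

    def test_invalid_time_constants(self):
        with pytest.raises(ConfigError):
            PhasicWaveform(tau_rise=3.0, tau_decay=0.75).validate()


def _cs_minus(onset, idx=1):
    return TrialEvent(onset=onset, duration=6.0, stimulus=Stimulus.CS_MINUS,
                      phase=PhaseName.CONDITIONING, index_within_type=idx)


class TestSynthesizeTrace:
    def test_single_event_noise_free_amplitude(self):
        params = SubjectParams("s", "MBSR", noise_sd=0.0, tonic_drift=0.0,
                               tonic_level=6.0, orienting_amplitude=0.3)
        tr = synthesize_trace(params, [_cs_minus(20.0)], "pre", sampling_rate=10.0)
        assert tr.values.max() - 6.0 == pytest.approx(0.3, rel=0.01)

    def test_nonresponder_scores_below_threshold(self):
        params = SubjectParams("s", "MBSR", responder=False, noise_sd=0.01)
        cfg = ParadigmConfig(seed=5)
        from fearscr.paradigm import generate_schedule
        events = generate_schedule(cfg).events(PhaseName.CONDITIONING)
        tr = synthesize_trace(params, events, "pre", sampling_rate=10.0, seed=3)
        scores = score_phase(tr, events)
        for s in scores:
            if s.event.stimulus in (Stimulus.US, Stimulus.CS_PLUS_E, Stimulus.CS_PLUS_U):
                assert s.score < 0.05

    def test_deterministic_given_seed(self):
        params = SubjectParams("s", "MBSR")
        ev = [_cs_minus(20.0)]
        a = synthesize_trace(params, ev, "pre", seed=9)
        b = synthesize_trace(params, ev, "pre", seed=9)
        assert np.array_equal(a.values, b.values)
        c = synthesize_trace(params, ev, "pre", seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_trace_covers_last_offset_plus_tail(self):
        tr = synthesize_trace(SubjectParams("s", "MBSR"), [_cs_minus(20.0)], "pre")
        assert tr.end_time >= 26.0 + 10.0 - 0.2

    def test_empty_events_rejected(self):
        with pytest.raises(StructuralError):
            synthesize_trace(SubjectParams("s", "MBSR"), [], "pre")

    def test_recall_amplitude_scaled_by_retention_fraction(self):
        params = SubjectParams("s", "MBSR", noise_sd=0.0, tonic_drift=0.0,
                               cr_amplitude_pre=0.4, retention_fraction_pre=0.25)
        ev = TrialEvent(onset=20.0, duration=6.0, stimulus=Stimulus.CS_PLUS_E,
                        phase=PhaseName.RECALL, index_within_type=1)
        tr = synthesize_trace(params, [ev], "pre")
        assert tr.values.max() - params.tonic_level == pytest.approx(0.1, rel=0.02)


class TestGeneratorScorerRoundTrip:
    def test_programmed_amplitudes_recovered_on_sparse_schedule(self):
        """With events separated enough that responses do not overlap,
        noise-free scoring recovers every programmed amplitude within
        the 2% kernel-discretization tolerance."""
        cfg = ParadigmConfig(n_csplus_each=3, n_reinforced_each=0,
                             allow_no_reinforcement=True,
                             n_csminus_conditioning=6, iti_range=(40.0, 50.0),
                             seed=2)
        from fearscr.paradigm import generate_schedule
        events = generate_schedule(cfg).events(PhaseName.CONDITIONING)
        params = SubjectParams("s", "MBSR", noise_sd=0.0, tonic_drift=0.0,
                               cr_amplitude_pre=0.46, orienting_amplitude=0.15)
        for fs in (8.0, 10.0):
            tr = synthesize_trace(params, events, "pre", sampling_rate=fs)
            for s in score_phase(tr, events, median_kernel=None):
                want = (0.15 if s.event.stimulus is Stimulus.CS_MINUS else 0.46)
                assert s.score == pytest.approx(want, rel=0.02)


class TestSynthesizeCohort:
    def test_bitwise_reproducible_from_seed(self):
        spec = CohortSpec(n_per_group=3, seed=77, paradigm=small_paradigm(),
                          phases=(PhaseName.CONDITIONING,))
        a = synthesize_cohort(spec)
        b = synthesize_cohort(spec)
        for key in a.traces:
            assert np.array_equal(a.traces[key][0].values, b.traces[key][0].values)
        assert a.covariates.equals(b.covariates)
        assert a.truth.equals(b.truth)

    def test_group_sizes_and_practice_hours(self):
        c = synthesize_cohort(CohortSpec(n_per_group=4, seed=1,
                                         paradigm=small_paradigm(),
                                         phases=(PhaseName.CONDITIONING,)))
        assert (c.covariates.group == "MBSR").sum() == 4
        assert (c.covariates.group == "CONTROL").sum() == 4
        mbsr = c.covariates[c.covariates.group == "MBSR"]
        ctrl = c.covariates[c.covariates.group == "CONTROL"]
        assert mbsr.practice_hours.notna().all()
        assert ctrl.practice_hours.isna().all()

    def test_all_nonresponders_fail_qc_with_b_or_c(self):
        from fearscr.pipeline import qc_from_scores
        spec = CohortSpec(n_per_group=3, seed=5, nonresponder_rate=1.0,
                          paradigm=small_paradigm(),
                          phases=(PhaseName.CONDITIONING,), make_fa_tables=False)
        scores = score_cohort(synthesize_cohort(spec))
        decisions = qc_from_scores(scores)
        assert all(not d.include for d in decisions)
        for d in decisions:
            codes = {c.value for c in d.failed_criteria}
            assert codes <= {"B_NO_US_REACTIVITY", "C_NO_CONDITIONED_RESPONSE"}
            assert codes

    def test_fa_tables_weighted_mean_tracks_truth(self):
        from fearscr.indices import weighted_fa
        spec = CohortSpec(n_per_group=3, seed=9, paradigm=small_paradigm(),
                          phases=(PhaseName.CONDITIONING,))
        c = synthesize_cohort(spec)
        truth = c.truth.set_index("subject_id")
        for (subj, visit), table in c.fa_tables.items():
            target = truth.loc[subj, "fa_pre"]
            if visit == "post":
                target += truth.loc[subj, "delta_fa"]
            got = weighted_fa(table["fa"], table["weight"]).weighted_mean_fa
            assert got == pytest.approx(target, abs=1e-6)

    def test_programmed_eri_structure_in_trained_group(self):
        """Scored ERI means land near the programmed retention levels:
        trained ~32% pre rising past 55% post, controls high throughout."""
        spec = CohortSpec(n_per_group=25, seed=31, nonresponder_rate=0.0,
                          noise_sd=0.005, make_fa_tables=False,
                          phases=(PhaseName.CONDITIONING, PhaseName.RECALL))
        ep = cohort_endpoints(synthesize_cohort(spec))
        m = ep.groupby(["group", "visit"])["eri_percent"].mean()
        assert 20 < m["MBSR", "pre"] < 45
        assert m["MBSR", "post"] > m["MBSR", "pre"] + 15
        assert abs(m["CONTROL", "post"] - m["CONTROL", "pre"]) < 15


class TestSynthesizeQuestionnaires:
    def _cohort(self, seed=3, n=6):
        return synthesize_cohort(CohortSpec(n_per_group=n, seed=seed, phases=(),
                                            make_fa_tables=False))

    def test_noise_free_slope_recovered_exactly(self):
        c = self._cohort()
        q = synthesize_questionnaires(c, effect_practice_slope=-0.4, noise_sd=0.0)
        post = q[q.visit == "post"].merge(c.covariates, on="subject_id")
        mbsr = post[post.group == "MBSR"]
        slope = np.polyfit(mbsr.practice_hours, mbsr.pss, 1)[0]
        assert slope == pytest.approx(-0.4, abs=1e-9)

    def test_null_slope_ci_covers_zero(self):
        covered = 0
        reps = 60
        for i in range(reps):
            c = self._cohort(seed=100 + i, n=12)
            q = synthesize_questionnaires(c, effect_practice_slope=0.0,
                                          noise_sd=5.0, seed=500 + i)
            post = q[q.visit == "post"].merge(c.covariates, on="subject_id")
            mbsr = post[post.group == "MBSR"]
            res = practice_regression(mbsr.pss, mbsr.practice_hours)
            covered += res.pvalue >= 0.05  # 95% CI covers 0 iff p >= alpha
        assert covered / reps >= 0.90

    def test_deterministic_given_seed(self):
        c = self._cohort()
        a = synthesize_questionnaires(c, seed=9)
        b = synthesize_questionnaires(c, seed=9)
        assert a.equals(b)

    def test_pre_scores_independent_of_practice(self):
        c = self._cohort(n=40)
        q = synthesize_questionnaires(c, effect_practice_slope=-1.0, noise_sd=0.0,
                                      seed=2)
        pre = q[q.visit == "pre"].merge(c.covariates, on="subject_id")
        mbsr = pre[pre.group == "MBSR"]
        r = np.corrcoef(mbsr.practice_hours, mbsr.pss)[0, 1]
        assert abs(r) < 0.4
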