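import numpy as np
import pytest
from scipy.stats import kstest

from tce_qsp.model import initialize_baseline, simulate
from tce_qsp.params import PB, TU
from tce_qsp.population import (
    AcceptanceEnvelope,
    NHLTumorParams,
    PerturbationSpec,
    TumorVariabilitySpec,
    VirtualSubject,
    accept_subject,
    apply_tumor,
    build_nhl_population,
    envelopes_from_study,
    generate_cohort,
    match_weights_to_waterfall,
    sample_candidate,
    translate_to_human,
    weighted_quantile,
)
from tce_qsp.reference import cyno_physiology, human_physiology
from tce_qsp.synthetic import ClinicalTargets, generate_nhl_targets


class TestSampleCandidate:
    def test_fold_one_returns_reference(self, ref_cyno, rng):
        spec = PerturbationSpec(folds={"tcell.k_prol": 1.0})
        cand = sample_candidate(ref_cyno, spec, rng)
        assert cand.model_dump() == ref_cyno.model_dump()

    def test_same_seed_identical_candidate(self, ref_cyno):
        spec = PerturbationSpec()
        a = sample_candidate(ref_cyno, spec, np.random.default_rng(4))
        b = sample_candidate(ref_cyno, spec, np.random.default_rng(4))
        assert a.model_dump() == b.model_dump()

    def test_draws_loguniform_within_three_fold(self, ref_cyno):
        spec = PerturbationSpec(folds={"cytokine.k_prod": 3.0})
        ref = ref_cyno.get("cytokine.k_prod")
        rng = np.random.default_rng(11)
        draws = np.array(
            [sample_candidate(ref_cyno, spec, rng).get("cytokine.k_prod")
             for _ in range(10_000)]
        )
        assert draws.min() >= ref / 3.0 and draws.max() <= ref * 3.0
        # log-uniform: log(draw/ref)/log(3) ~ Uniform(-1, 1)
        u = np.log(draws / ref) / np.log(3.0)
        assert kstest(u, "uniform", args=(-1.0, 2.0)).pvalue > 0.01

    def test_invalid_range_raises(self, ref_cyno, rng):
        spec = PerturbationSpec(folds={"cytokine.f_tiss": 25.0})  # can exceed 1
        with pytest.raises(Exception):
            for _ in range(200):
                sample_candidate(ref_cyno, spec, rng)


class TestAcceptance:
    @pytest.fixture(scope="class")
    def ref_traj_envelopes(self, ref_cyno, small_problem):
        traj = simulate(
            ref_cyno, small_problem.regimens[1.0], small_problem.forcings[1.0],
            t_end=14.0, settings=small_problem.settings,
        )
        times = np.arange(0.5, 14.0, 1.0)
        envs = []
        for analyte in ("CD8_count", "B_count", "IL6"):
            v = np.interp(times, traj.time, traj.observable(analyte))
            envs.append(
                AcceptanceEnvelope(analyte=analyte, dose_group=1.0, times=times,
                                   lower=v / 2.0, upper=v * 2.0)
            )
        return envs

    def test_reference_accepted_within_any_margin(self, ref_cyno, small_problem,
                                                  ref_traj_envelopes):
        ok, record = accept_subject(
            ref_cyno, ref_traj_envelopes, small_problem.regimens,
            small_problem.forcings, t_end=14.0,
        )
        assert ok
        assert all(frac == 1.0 for frac in record.values())

    def test_no_kill_candidate_rejected_by_depletion_envelope(
        self, ref_cyno, small_problem, ref_traj_envelopes
    ):
        weak = ref_cyno.replace({"drugs.mosunetuzumab.k_kill": 1e-15})
        ok, record = accept_subject(
            weak, ref_traj_envelopes, small_problem.regimens,
            small_problem.forcings, t_end=14.0,
        )
        assert not ok
        assert record["B_count@1.0"] < 0.8  # B cells never deplete

    def test_decision_equals_pointwise_recount(self, ref_cyno, small_problem,
                                               ref_traj_envelopes):
        cand = ref_cyno.replace({"tcell.k_prol": 1.1 * ref_cyno.tcell.k_prol})
        ok, record = accept_subject(
            cand, ref_traj_envelopes, small_problem.regimens,
            small_problem.forcings, t_end=14.0,
        )
        traj = simulate(
            cand, small_problem.regimens[1.0], small_problem.forcings[1.0],
            t_end=14.0, settings=small_problem.settings,
            extra_times=ref_traj_envelopes[0].times,
        )
        for env in ref_traj_envelopes:
            v = np.interp(env.times, traj.time, traj.observable(env.analyte))
            manual = np.mean((v >= env.lower) & (v <= env.upper))
            assert record[f"{env.analyte}@{env.dose_group}"] == pytest.approx(
                manual, abs=1e-9
            )
        assert ok == all(
            record[f"{e.analyte}@{e.dose_group}"] >= e.threshold
            for e in ref_traj_envelopes
        )

    def test_envelopes_from_study_cover_the_data(self, small_study):
        dataset, _ = small_study
        envs = envelopes_from_study(dataset, margin=1.2)
        assert {e.analyte for e in envs} == {"CD8_count", "pct_CD69", "B_count", "IL6"}
        for env in envs:
            sub = dataset.subset(analyte=env.analyte)
            v = sub.groupby("time_day")["value"].mean().to_numpy()
            assert np.all(v >= env.lower - 1e-9) and np.all(v <= env.upper + 1e-9)


class TestCohort:
    def test_fold_one_cohort_is_reference(self, ref_cyno, small_problem,
                                          small_study):
        dataset, _ = small_study
        envs = envelopes_from_study(dataset, margin=2.0)
        spec = PerturbationSpec(folds={"tcell.k_prol": 1.0})
        cohort, summary = generate_cohort(
            ref_cyno, spec, envs, small_problem.regimens, small_problem.forcings,
            n_target=1, max_draws=3, seed=0, t_end=14.0,
        )
        assert len(cohort) == 1
        got = cohort[0].parameters.model_dump()
        ref = ref_cyno.model_dump()
        got.pop("subject_id"), ref.pop("subject_id")
        assert got == ref
        assert summary["acceptance_rate"] == 1.0

    def test_cohort_bit_reproducible(self, ref_cyno, small_problem, small_study):
        dataset, _ = small_study
        envs = envelopes_from_study(dataset, margin=2.0)
        kw = dict(
            envelopes=envs, regimens=small_problem.regimens,
            forcings=small_problem.forcings, n_target=3, max_draws=20,
            seed=21, t_end=14.0,
        )
        c1, s1 = generate_cohort(ref_cyno, PerturbationSpec(), **kw)
        c2, s2 = generate_cohort(ref_cyno, PerturbationSpec(), **kw)
        assert s1 == s2
        for a, b in zip(c1, c2):
            assert a.parameters.model_dump() == b.parameters.model_dump()

    def test_members_satisfy_invariants_and_homeostasis(self, ref_cyno,
                                                        small_problem, small_study):
        dataset, _ = small_study
        envs = envelopes_from_study(dataset, margin=2.0)
        cohort, _ = generate_cohort(
            ref_cyno, PerturbationSpec(), envs, small_problem.regimens,
            small_problem.forcings, n_target=2, max_draws=20, seed=8, t_end=14.0,
        )
        for vs in cohort:
            subj = vs.parameters
            y0 = initialize_baseline(subj)  # re-validates equilibrium
            traj = simulate(subj, None, t_end=50.0,
                            settings=small_problem.settings)
            drift = np.abs(traj.states[-1] - y0) / np.maximum(y0, 1.0)
            assert drift.max() < 1e-4

    def test_impossible_envelopes_raise(self, ref_cyno, small_problem):
        env = AcceptanceEnvelope(
            analyte="IL6", dose_group=1.0, times=np.array([1.0]),
            lower=np.array([1e6]), upper=np.array([1e7]),
        )
        with pytest.raises(RuntimeError, match="widen"):
            generate_cohort(
                ref_cyno, PerturbationSpec(), [env], small_problem.regimens,
                small_problem.forcings, n_target=1, max_draws=3, seed=0,
                t_end=14.0,
            )


class TestTranslation:
    def test_identity_translation(self, ref_cyno):
        same = translate_to_human(ref_cyno, cyno_physiology(), subject_id="x")
        assert same.physiology == ref_cyno.physiology
        assert same.tcell == ref_cyno.tcell

    def test_baseline_concentrations_match_target_physiology(self, ref_cyno):
        human = translate_to_human(ref_cyno, human_physiology())
        y0 = initialize_baseline(human)
        phys = human_physiology()
        pb_ul = phys.volumes[PB] * 1e6
        # resting T concentration in PB equals the configured human value
        assert y0[0] / pb_ul == pytest.approx(phys.t_baseline[PB] / pb_ul)

    def test_total_body_b_cells_scale_by_configured_ratio(self, ref_cyno):
        human = translate_to_human(ref_cyno, human_physiology())
        cyno_total = sum(ref_cyno.physiology.b_baseline.values())
        human_total = sum(human.physiology.b_baseline.values())
        expected = sum(human_physiology().b_baseline.values())
        assert human_total == pytest.approx(expected)
        assert human_total / cyno_total == pytest.approx(expected / cyno_total)

    def test_missing_compartment_rejected(self, ref_cyno):
        chopped = human_physiology().model_dump()
        for key in ("volumes", "t_baseline", "b_baseline"):
            chopped[key].pop("BM", None)
        chopped["prob_baseline"] = 0.0
        from tce_qsp.params import Physiology

        with pytest.raises(ValueError, match="BM"):
            translate_to_human(ref_cyno, Physiology.model_validate(chopped))


class TestTumor:
    def test_apply_tumor_builds_dense_mass(self, ref_cyno):
        human = translate_to_human(ref_cyno, human_physiology())
        tum = NHLTumorParams(burden=2e10, doubling_time=40.0, bt_ratio=1e5,
                             t_access=1e-5)
        patient = apply_tumor(human, tum)
        phys = patient.physiology
        assert phys.tumor_baseline == 2e10
        assert phys.t_baseline[TU] == pytest.approx(2e5)
        assert patient.bcell.tumor_doubling_time == 40.0
        pf = patient.tcell.partition_frac
        assert pf["activated"][TU] == pytest.approx(1e-5)
        assert TU not in pf["resting"]  # only effectors infiltrate
        assert sum(pf["activated"].values()) == pytest.approx(1.0)

    def test_tumor_spec_sampling_within_ranges(self, rng):
        spec = TumorVariabilitySpec()
        for _ in range(100):
            t = spec.sample(rng)
            assert spec.burden[0] <= t.burden <= spec.burden[1]
            assert spec.doubling_time[0] <= t.doubling_time <= spec.doubling_time[1]
            assert spec.bt_ratio[0] <= t.bt_ratio <= spec.bt_ratio[1]
            assert spec.t_access[0] <= t.t_access <= spec.t_access[1]


class TestWeightMatching:
    def test_self_matching_recovers_target_masses(self, rng):
        pct = np.concatenate([np.full(30, -100.0), rng.uniform(-99, 150, 170)])
        targets = ClinicalTargets(waterfall=pct[rng.choice(200, 50, replace=False)])
        w, diag = match_weights_to_waterfall(pct, targets)
        assert np.allclose(diag["achieved_masses"], diag["target_masses"], atol=1e-9)
        assert w.sum() == pytest.approx(1.0)

    def test_responder_fraction_matches_within_5_points(self, rng):
        targets = generate_nhl_targets(n_patients=18, seed=3)
        pct = np.concatenate(
            [np.full(40, -100.0), rng.uniform(-99.0, 0.0, 80), rng.uniform(0, 200, 80)]
        )
        w, _ = match_weights_to_waterfall(pct, targets)
        achieved = w[pct <= -50.0].sum()
        assert abs(achieved - targets.responder_fraction) < 0.05

    def test_empty_bin_raises(self):
        targets = ClinicalTargets(waterfall=np.array([-100.0, -80.0, 20.0, 90.0]))
        pct = np.array([50.0, 60.0, 70.0])  # no CR, no PR candidates
        with pytest.raises(RuntimeError, match="bins"):
            match_weights_to_waterfall(pct, targets)

    def test_weighted_quantile_against_numpy_on_uniform_weights(self, rng):
        v = rng.normal(size=501)
        w = np.full(501, 1 / 501)
        got = weighted_quantile(v, w, [0.05, 0.5, 0.95])
        want = np.quantile(v, [0.05, 0.5, 0.95])
        # definitions differ at O(1/n) in probability space
        assert np.allclose(got, want, atol=0.05)


class TestNHLPopulation:
    @pytest.fixture(scope="class")
    def tiny_cohort(self, ref_cyno):
        # perturbed members spanning weak to strong effector function
        # (proliferation below/above the stimulated loss rate) stand in
        # for an accepted cohort
        subs = []
        for i, fac in enumerate([0.45, 0.7, 1.0, 1.3]):
            p = ref_cyno.replace({"tcell.k_prol": fac * ref_cyno.tcell.k_prol})
            subs.append(VirtualSubject(parameters=p.with_id(f"vc{i}"),
                                       accepted=True, record={}, lineage={}))
        return subs

    @pytest.fixture(scope="class")
    def small_population(self, tiny_cohort):
        from tce_qsp.pk import build_regimen

        targets = generate_nhl_targets(seed=3)
        return build_nhl_population(
            tiny_cohort, human_physiology(), TumorVariabilitySpec(), targets,
            build_regimen("blin_dlbcl_8wk"), n_out=48, seed=12,
        )

    def test_population_bit_reproducible(self, tiny_cohort, small_population):
        from tce_qsp.pk import build_regimen

        again = build_nhl_population(
            tiny_cohort, human_physiology(), TumorVariabilitySpec(),
            generate_nhl_targets(seed=3), build_regimen("blin_dlbcl_8wk"),
            n_out=48, seed=12,
        )
        assert np.array_equal(again.weights, small_population.weights)
        assert np.array_equal(again.pct_change, small_population.pct_change)

    def test_weighted_waterfall_sorted_and_bounded(self, small_population):
        wf = small_population.waterfall()
        assert np.all(np.diff(wf) <= 0)
        assert wf.min() >= -100.0

    def test_responder_fraction_matches_targets(self, small_population):
        diag = small_population.diagnostics
        assert abs(diag["achieved_responder_fraction"]
                   - diag["target_responder_fraction"]) < 0.05

    def test_members_keep_homeostasis_drug_free(self, small_population):
        from tce_qsp.model import SolverSettings

        subj = small_population.subjects[0]
        y0 = initialize_baseline(subj)
        traj = simulate(subj, None, t_end=50.0, settings=SolverSettings(rtol=1e-6))
        lay = traj.layout
        normal = np.delete(np.arange(lay.size), lay.i_tum)
        drift = np.abs(traj.states[-1, normal] - y0[normal]) / np.maximum(y0[normal], 1.0)
        assert drift.max() < 1e-4

    def test_jsonl_roundtrip(self, small_population, tmp_path):
        from tce_qsp.cli import _load_population

        path = tmp_path / "pop.jsonl"
        small_population.to_jsonl(path)
        back = _load_population(path)
        assert len(back) == len(small_population)
        assert np.allclose(back.weights, small_population.weights)
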