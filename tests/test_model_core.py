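import numpy as np
import pytest

from tce_qsp.model import (
    ConfigurationError,
    Model,
    SolverSettings,
    activation_signal,
    initialize_baseline,
    killing_rate,
    simulate,
)
from tce_qsp.params import SubjectParameters
from tce_qsp.pk import (
    DoseEvent,
    Regimen,
    TwoCompartmentForcing,
    ZeroForcing,
    build_regimen,
)
from tce_qsp.reference import (
    blinatumomab_pk_cyno,
    mosunetuzumab_pk_cyno,
    reference_cyno,
)

FAST = SolverSettings(rtol=1e-6)


def cyno_regimen(dose, t_end=None, **kw):
    kw.setdefault("body_weight_kg", 3.5)
    kw.setdefault("body_surface_m2", 0.25)
    reg = build_regimen("cyno_weeklyx4", dose_mg_per_kg=dose, **kw)
    if t_end is not None:
        reg = reg.model_copy(
            update={"events": tuple(e for e in reg.events if e.time <= t_end)}
        )
    return reg


def mosun_forcing(regimen):
    return TwoCompartmentForcing(mosunetuzumab_pk_cyno(), regimen)


class TestActivationSignal:
    def test_no_drug_no_activation(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        assert activation_signal(0.0, 1e9, 1e8, d) == 0.0

    def test_no_targets_no_activation(self, ref_cyno):
        # all CD20+ B depleted: the CD20/CD3 drug cannot trigger
        d = ref_cyno.drugs["mosunetuzumab"]
        assert activation_signal(50.0, 0.0, 1e8, d) == 0.0

    def test_half_maximum_at_ec50_with_saturating_ratio(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        got = activation_signal(d.ec50_act, 1e12, 1.0, d)  # r >> K_BT
        assert got == pytest.approx(d.vmax_max / 2.0, rel=1e-6)

    def test_matches_closed_form_over_six_decades(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        target_b, total_t = 4.2e8, 2.8e8
        r = target_b / total_t
        for conc in np.logspace(-2, 4, 25):
            expected = (d.vmax_max * r / (d.k_bt + r)) * conc / (d.ec50_act + conc)
            assert activation_signal(conc, target_b, total_t, d) == pytest.approx(expected)

    def test_monotone_in_conc_and_targets(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        concs = np.logspace(-3, 5, 30)
        vals = [activation_signal(c, 1e8, 1e8, d) for c in concs]
        assert np.all(np.diff(vals) >= 0)
        tgts = np.logspace(4, 10, 30)
        vals = [activation_signal(10.0, b, 1e8, d) for b in tgts]
        assert np.all(np.diff(vals) >= 0)

    def test_zero_t_cells_saturates_vmax(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        big = activation_signal(1e9, 1e9, 0.0, d)
        assert big == pytest.approx(d.vmax_max, rel=1e-3)

    def test_negative_inputs_rejected(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        with pytest.raises(ValueError):
            activation_signal(-1.0, 1e8, 1e8, d)


class TestKillingRate:
    def test_zero_cases(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        assert killing_rate(0.0, 1e8, 1e9, 0.28, d) == 0.0
        assert killing_rate(10.0, 0.0, 1e9, 0.28, d) == 0.0
        assert killing_rate(10.0, 1e8, 0.0, 0.28, d) == 0.0

    def test_formula(self, ref_cyno):
        d = ref_cyno.drugs["mosunetuzumab"]
        got = killing_rate(20.0, 1e8, 1e9, 0.28, d)
        expected = d.k_kill * 20.0 / (d.ec50_kill + 20.0) * (1e8 / 0.28) * 1e9
        assert got == pytest.approx(expected)

    def test_cd20_drug_spares_pro_b_cd19_drug_kills_them(self, ref_cyno):
        """The CD20/CD3 antibody cannot kill CD20- pro-B cells; the CD19/CD3
        BiTE can. The model RHS must respect the drug's target selector."""
        y0 = initialize_baseline(ref_cyno)
        m_mosun = Model(ref_cyno, "mosunetuzumab", disabled={"b_production"})
        m_blin = Model(ref_cyno, "blinatumomab", disabled={"b_production"})
        lay = m_mosun.layout
        y = y0.copy()
        y[lay.n : 2 * lay.n] = 1e7  # plant activated T everywhere

        class Const:
            breakpoints = ()
            def conc(self, t):
                return 100.0

        dy_mosun = m_mosun.rhs(0.0, y, Const(), ())
        dy_blin = m_blin.rhs(0.0, y, Const(), ())
        assert dy_mosun[lay.i_prob] == 0.0
        assert dy_blin[lay.i_prob] < 0.0


class TestBaselineEquilibrium:
    def test_derivatives_vanish_at_baseline(self, ref_cyno):
        m = Model(ref_cyno, "mosunetuzumab")
        y0 = m.baseline_state()
        dy = m.rhs(0.0, y0, ZeroForcing(), ())
        assert np.all(np.abs(dy) < 1e-9 * np.maximum(y0, 1.0))

    def test_homeostasis_100_days(self, ref_cyno):
        y0 = initialize_baseline(ref_cyno)
        traj = simulate(ref_cyno, None, t_end=100.0, settings=FAST)
        drift = np.abs(traj.states[-1] - y0) / np.maximum(y0, 1.0)
        assert drift.max() < 1e-4  # < 0.01%

    def test_empty_regimen_stays_at_baseline_throughout(self, ref_cyno):
        y0 = initialize_baseline(ref_cyno)
        traj = simulate(ref_cyno, None, t_end=30.0, settings=FAST)
        rel = np.abs(traj.states - y0) / np.maximum(y0, 1.0)
        assert rel.max() < 1e-5

    def test_tumor_grows_while_normal_pools_static(self):
        from tce_qsp.population import NHLTumorParams, apply_tumor, translate_to_human
        from tce_qsp.reference import human_physiology

        human = translate_to_human(reference_cyno(), human_physiology())
        patient = apply_tumor(
            human,
            NHLTumorParams(burden=1e10, doubling_time=30.0, bt_ratio=1e4, t_access=1e-4),
        )
        traj = simulate(patient, None, t_end=30.0, settings=FAST)
        tum = traj.tumor_cells()
        assert tum[-1] / tum[0] == pytest.approx(2.0, rel=1e-3)  # one doubling
        y0 = initialize_baseline(patient)
        lay = traj.layout
        normal = np.delete(np.arange(lay.size), lay.i_tum)
        rel = np.abs(traj.states[-1, normal] - y0[normal]) / np.maximum(y0[normal], 1.0)
        assert rel.max() < 1e-5

    def test_scale_invariance_of_concentrations(self, ref_cyno):
        """Doubling every baseline count and every volume leaves all
        concentration observables identical (the model is extensive)."""
        phys = ref_cyno.physiology
        scaled = SubjectParameters.model_validate(
            {
                **ref_cyno.model_dump(),
                "physiology": {
                    **phys.model_dump(),
                    "volumes": {k: 2 * v for k, v in phys.volumes.items()},
                    "serum_volume": 2 * phys.serum_volume,
                    "t_baseline": {k: 2 * v for k, v in phys.t_baseline.items()},
                    "b_baseline": {k: 2 * v for k, v in phys.b_baseline.items()},
                    "prob_baseline": 2 * phys.prob_baseline,
                },
            }
        )
        # absolute-rate thymic input must scale with the system
        scaled = scaled.replace({"tcell.k_thymus": 2 * ref_cyno.tcell.k_thymus})
        reg = cyno_regimen(0.1, t_end=10.0)
        f = mosun_forcing(reg)
        t1 = simulate(ref_cyno, reg, f, t_end=10.0, settings=FAST)
        t2 = simulate(scaled, reg, f, t_end=10.0, settings=FAST)
        for attr in ("pb_cd8_per_ul", "pb_b_per_ul", "pct_cd69", "il6"):
            a, b = getattr(t1, attr)(), getattr(t2, attr)()
            assert np.allclose(a, b, rtol=1e-4, atol=1e-8), attr

    def test_pro_b_balance_misconfiguration_detected(self, ref_cyno):
        bad = ref_cyno.replace({"bcell.k_gen_prob": 1e9})  # != k_mat * pB0
        with pytest.raises(ConfigurationError, match="pro-B generation vs. maturation"):
            initialize_baseline(bad)

    def test_resting_traffic_into_empty_tissue_detected(self, ref_cyno):
        dump = ref_cyno.model_dump()
        dump["physiology"]["t_baseline"]["SP"] = 0.0
        bad = SubjectParameters.model_validate(dump)
        with pytest.raises(ConfigurationError, match="resting"):
            initialize_baseline(bad)


class TestMechanismOracles:
    def test_trafficking_alone_conserves_t_cells(self, ref_cyno):
        keep = {"t_trafficking", "stress"}
        from tce_qsp.model import MECHANISMS

        reg = cyno_regimen(1.0, t_end=14.0)
        traj = simulate(
            ref_cyno, reg, mosun_forcing(reg), t_end=14.0, settings=FAST,
            disabled=MECHANISMS - keep,
        )
        for block in (traj.tr, traj.ta, traj.tp):
            tot = block.sum(axis=1)
            assert np.allclose(tot, tot[0], rtol=1e-6)
        btot = traj.b.sum(axis=1)
        assert np.allclose(btot, btot[0], rtol=1e-12)  # B untouched

    def test_tumor_growth_alone_is_exact_exponential(self):
        from tce_qsp.model import MECHANISMS
        from tce_qsp.population import NHLTumorParams, apply_tumor, translate_to_human
        from tce_qsp.reference import human_physiology

        dt_days = 25.0
        patient = apply_tumor(
            translate_to_human(reference_cyno(), human_physiology()),
            NHLTumorParams(burden=1e9, doubling_time=dt_days, bt_ratio=1e4, t_access=1e-4),
        )
        traj = simulate(
            patient, None, t_end=50.0,
            settings=SolverSettings(rtol=1e-9, atol=1e-3),
            disabled=MECHANISMS - {"tumor_growth"},
        )
        expected = 1e9 * 2.0 ** (traj.time / dt_days)
        assert np.allclose(traj.tumor_cells(), expected, rtol=1e-6)

    def test_il6_production_terms(self, ref_cyno):
        m = Model(ref_cyno, "mosunetuzumab")
        lay = m.layout
        y = m.baseline_state()
        conc = m.kpart * 100.0
        tr, ta, tp, b = lay.tr(y), lay.ta(y), lay.tp(y), lay.b(y)
        # no activated cells anywhere: no production
        sig = m._activation_vec(conc, b, tr + ta + tp)
        assert m.il6_production(conc, sig, np.zeros(lay.n)) == 0.0
        # hand-assembled formula: PB term + f_tiss * tissue terms
        ta_test = np.full(lay.n, 1e7)
        cy = ref_cyno.cytokine
        hand = cy.k_prod * (
            sig[m.i_pb] * 1e7
            + cy.f_tiss * sum(sig[i] * 1e7 for i in m.tissue_ix)
        )
        assert m.il6_production(conc, sig, ta_test) == pytest.approx(hand, rel=1e-12)
        # f_tiss = 0: only the PB term remains
        zero_tiss = ref_cyno.replace({"cytokine.f_tiss": 0.0})
        m2 = Model(zero_tiss, "mosunetuzumab")
        assert m2.il6_production(conc, sig, ta_test) == pytest.approx(
            cy.k_prod * sig[m.i_pb] * 1e7, rel=1e-12
        )

    def test_il6_relaxes_to_baseline_without_production(self, ref_cyno):
        from tce_qsp.model import MECHANISMS
        traj = simulate(
            ref_cyno, None, t_end=5.0, settings=FAST,
            disabled={"il6_production"},
        )
        assert np.allclose(traj.il6(), ref_cyno.cytokine.baseline, rtol=1e-6)

    def test_constant_production_closed_form(self, ref_cyno):
        """With constant production P and zero baseline the linear IL6 ODE
        has the closed form P/(V k_el) (1 - exp(-k_el t))."""
        from scipy.integrate import solve_ivp

        cy = ref_cyno.cytokine.model_copy(update={"baseline": 0.0})
        p_const = 5.0e4  # pg/day
        v_ml = ref_cyno.physiology.serum_volume * 1e3

        def rhs(t, y):
            return [p_const / v_ml - cy.k_el * y[0]]

        sol = solve_ivp(rhs, (0, 2), [0.0], rtol=1e-10, atol=1e-12,
                        t_eval=np.linspace(0, 2, 20))
        closed = p_const / (v_ml * cy.k_el) * (1 - np.exp(-cy.k_el * sol.t))
        assert np.allclose(sol.y[0], closed, rtol=1e-7)


def rk4_reference(model, y0, forcing, dose_times, t_end, h):
    """Independent fixed-step classical Runge-Kutta integrator."""
    n = int(round(t_end / h))
    t, y = 0.0, y0.copy()
    ts, ys = [0.0], [y0.copy()]
    for _ in range(n):
        k1 = model.rhs(t, y, forcing, dose_times)
        k2 = model.rhs(t + h / 2, y + h / 2 * k1, forcing, dose_times)
        k3 = model.rhs(t + h / 2, y + h / 2 * k2, forcing, dose_times)
        k4 = model.rhs(t + h, y + h * k3, forcing, dose_times)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        ts.append(t)
        ys.append(y.copy())
    return np.array(ts), np.array(ys)


class TestSolverFidelity:
    def test_reduced_model_matches_rk4_oracle(self, ref_cyno):
        """Two-compartment reduction (PB + spleen), deficit gates off:
        the adaptive solver agrees with an independent RK4 integrator."""
        dump = ref_cyno.model_dump()
        phys = dump["physiology"]
        for key in ("volumes", "t_baseline", "b_baseline"):
            phys[key] = {c: v for c, v in phys[key].items() if c in ("PB", "SP")}
        phys["prob_baseline"] = 0.0
        for s in dump["tcell"]["partition_frac"]:
            dump["tcell"]["partition_frac"][s] = {"SP": 1.0}
        reduced = SubjectParameters.model_validate(dump)
        disabled = {"thymus", "excess_apoptosis", "b_production", "b_migration",
                    "b_replenish", "b_deficit_prolif", "stress"}
        reg = Regimen(
            label="sd", drug="mosunetuzumab",
            events=(DoseEvent(time=0.0, amount=0.1, unit="mg_per_kg"),),
            body_weight_kg=3.5, body_surface_m2=0.25,
        )
        forcing = mosun_forcing(reg)
        traj = simulate(reduced, reg, forcing, t_end=2.0, disabled=disabled,
                        settings=SolverSettings(rtol=1e-10, atol=1e-6))
        model = Model(reduced, "mosunetuzumab", disabled=disabled)
        ts, ys = rk4_reference(model, model.baseline_state(), forcing,
                               reg.dose_times, 2.0, h=2e-4)
        oracle = np.vstack([np.interp(traj.time, ts, ys[:, j])
                            for j in range(ys.shape[1])]).T
        scale = np.maximum(np.abs(ys).max(axis=0), 1e-6)
        rel = np.abs(traj.states - oracle) / scale
        assert rel.max() < 1e-3  # 0.1%

    def test_tolerance_halving_stability(self, ref_cyno):
        reg = cyno_regimen(1.0, t_end=14.0)
        f = mosun_forcing(reg)
        t1 = simulate(ref_cyno, reg, f, t_end=14.0,
                      settings=SolverSettings(rtol=1e-8, atol=1e-3))
        t2 = simulate(ref_cyno, reg, f, t_end=14.0,
                      settings=SolverSettings(rtol=0.5e-8, atol=0.5e-3))
        for attr in ("pb_cd8_per_ul", "pct_cd69", "pb_b_per_ul", "il6"):
            a = getattr(t1, attr)()
            b = np.interp(t1.time, t2.time, getattr(t2, attr)())
            scale = max(np.abs(a).max(), 1e-9)
            assert np.abs(a - b).max() / scale < 1e-3, attr

    def test_states_remain_nonnegative(self, ref_cyno):
        for dose in (0.001, 1.0):
            reg = cyno_regimen(dose)
            traj = simulate(ref_cyno, reg, mosun_forcing(reg), t_end=28.0,
                            settings=FAST)
            assert traj.states.min() >= 0.0

    def test_events_outside_window_rejected(self, ref_cyno):
        reg = cyno_regimen(0.1)
        with pytest.raises(ValueError, match="within"):
            simulate(ref_cyno, reg, mosun_forcing(reg), t_end=10.0)


class TestStudyPhenomenology:
    """The hallmark in-vivo behaviors the reference virtual cyno reproduces."""

    @pytest.fixture(scope="class")
    def high_dose_traj(self, ref_cyno):
        reg = cyno_regimen(1.0)
        return simulate(ref_cyno, reg, mosun_forcing(reg), t_end=28.0, settings=FAST)

    def test_rapid_b_depletion(self, high_dose_traj):
        b = high_dose_traj.pb_b_per_ul()
        frac_24h = high_dose_traj.value_at(b, 1.0) / b[0]
        assert frac_24h < 0.05  # >95% depletion within 24 h of dose 1

    def test_t_cell_margination_then_rebound(self, high_dose_traj):
        cd8 = high_dose_traj.pb_cd8_per_ul()
        first_day = high_dose_traj.time <= 1.0
        assert cd8[first_day].min() < 0.8 * cd8[0]  # margination dip
        assert cd8.max() > 1.5 * cd8[0]  # tissue expansion re-entry

    def test_dose_monotone_first_peaks(self, ref_cyno):
        il6_peaks, cd69_peaks = [], []
        for dose in (0.001, 0.01, 0.1, 1.0):
            reg = Regimen(
                label="sd", drug="mosunetuzumab",
                events=(DoseEvent(time=0.0, amount=dose, unit="mg_per_kg"),),
                body_weight_kg=3.5, body_surface_m2=0.25,
            )
            traj = simulate(ref_cyno, reg, mosun_forcing(reg), t_end=2.0,
                            settings=FAST)
            il6_peaks.append(traj.il6().max())
            cd69_peaks.append(traj.pct_cd69().max())
        assert np.all(np.diff(il6_peaks) >= 0)
        assert np.all(np.diff(cd69_peaks) >= 0)

    def test_first_dose_phenomenon_with_depleted_b(self, ref_cyno, high_dose_traj):
        traj = high_dose_traj
        b = traj.pb_b_per_ul()
        assert traj.value_at(b, 7.0) / b[0] < 0.01  # >99% depleted at dose 2
        il6 = traj.il6()
        w1 = (traj.time >= 0) & (traj.time < 7)
        w2 = (traj.time >= 7) & (traj.time < 14)
        assert il6[w2].max() < 0.2 * il6[w1].max()

    def test_recurrent_peaks_with_b_recovery(self, ref_cyno):
        """Short weekly BiTE infusions at low dose let B cells partially
        recover between doses; cytokine peaks then recur only slightly
        reduced instead of collapsing after dose 1."""
        ev = tuple(
            DoseEvent(time=7.0 * i, amount=5.0, unit="ug_per_m2_per_day",
                      route="infusion", duration=2.0 / 24.0)
            for i in range(5)
        )
        reg = Regimen(label="blin_weekly", drug="blinatumomab", events=ev,
                      body_weight_kg=3.5, body_surface_m2=0.25)
        f = TwoCompartmentForcing(blinatumomab_pk_cyno(), reg)
        traj = simulate(ref_cyno, reg, f, t_end=35.0, settings=FAST)
        b = traj.pb_b_per_ul()
        assert traj.value_at(b, 7.0) / b[0] > 0.2  # partial recovery
        il6 = traj.il6()
        peaks = []
        for i in range(5):
            m = (traj.time >= 7 * i) & (traj.time < 7 * i + 7)
            peaks.append(il6[m].max())
        assert peaks[1] > 0.3 * peaks[0]
        assert min(peaks[1:]) > 0.25 * peaks[1]  # comparable recurrent peaks


class TestTrajectoryExport:
    def test_long_format_roundtrip(self, ref_cyno, tmp_path):
        traj = simulate(ref_cyno, None, t_end=2.0, settings=FAST)
        df = traj.to_frame()
        assert set(df.columns) == {"time_day", "compartment", "variable", "value", "units"}
        il6 = df[df["variable"] == "IL6"]["value"].to_numpy()
        assert np.allclose(il6, traj.il6())
        traj.export(tmp_path / "t.csv", tmp_path / "t.json")
        assert (tmp_path / "t.csv").exists() and (tmp_path / "t.json").exists()
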