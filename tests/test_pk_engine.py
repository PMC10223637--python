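import numpy as np
import pytest

from conftest import make_transfer
from lactopk.milk_transfer import derive_milk_transfer
from lactopk.pk_engine import (
    DoseEvent,
    MaternalPKParams,
    Regimen,
    Route,
    SimulationError,
    build_model,
    nca_auc_to_inf,
    nca_terminal_slope,
    simulate,
    simulate_to_steady_state,
)


class TestRegimen:
    @pytest.mark.parametrize(
        "text,dose,tau,n,route,dur",
        [
            ("1000mg q8h x15 po", 1000.0, 8.0, 15, Route.oral, 0.0),
            ("100mg q24h iv", 100.0, 24.0, 1, Route.iv_bolus, 0.0),
            ("500mg q12h x10 ivinf:1h", 500.0, 12.0, 10, Route.iv_infusion, 1.0),
            ("2.5mg q6.5h x2 po", 2.5, 6.5, 2, Route.oral, 0.0),
        ],
    )
    def test_grammar(self, text, dose, tau, n, route, dur):
        reg = Regimen.from_string(text)
        assert len(reg.events) == n
        assert reg.interval == tau
        ev = reg.events[0]
        assert (ev.amount, ev.route, ev.duration) == (dose, route, dur)

    @pytest.mark.parametrize("bad", ["1000 q8h po", "x3 100mg q8h po", "100mg po", ""])
    def test_bad_grammar_rejected(self, bad):
        with pytest.raises(ValueError):
            Regimen.from_string(bad)

    def test_daily_dose(self):
        assert Regimen.from_string("1000mg q8h x3 po").daily_dose == 3000.0

    def test_events_sorted(self):
        reg = Regimen(events=(DoseEvent(5.0, 10.0), DoseEvent(1.0, 20.0)))
        assert [e.time for e in reg.events] == [1.0, 5.0]

    def test_invalid_events(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 10.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, -5.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 5.0, Route.iv_infusion, duration=0.0)


class TestStructure:
    def test_state_count(self, neutral_probe):
        tr = make_transfer()
        iv = build_model(neutral_probe, MaternalPKParams(cl=5, vc=50), tr)
        assert iv.n_compartments == 2  # central + milk
        oral = build_model(
            neutral_probe, MaternalPKParams(cl=5, vc=50, ka=1.0), tr
        )
        assert oral.n_compartments == 3
        two = build_model(
            neutral_probe,
            MaternalPKParams(cl=5, vc=50, ka=1.0, peripherals=((30.0, 4.0),)),
            tr,
        )
        assert two.n_compartments == 4
        breast = build_model(
            neutral_probe, MaternalPKParams(cl=5, vc=50), tr,
            include_breast_tissue=True,
        )
        assert breast.n_compartments == 3
        assert "breast" in breast.labels

    def test_milk_inflow_scales_with_fu_plasma(self, caffeine_model):
        # dN_milk/dt inflow term is fu_plasma * CLsec * C_plasma
        A = caffeine_model.matrix()
        im = caffeine_model.index("milk")
        ic = caffeine_model.index("central")
        drug = caffeine_model.drug
        tr = caffeine_model.transfer
        expected = drug.fu_plasma * tr.clsec / 1000.0 / caffeine_model.pk.vc
        assert A[im, ic] == pytest.approx(expected)

    def test_decoupled_milk_stays_zero(self, iv_model):
        sim = simulate(iv_model, Regimen.single(100.0), 24.0, dt_out=0.5)
        assert np.all(sim.c_milk == 0.0)

    def test_oral_without_ka_fails(self, iv_model):
        with pytest.raises(SimulationError, match="ka"):
            simulate(iv_model, Regimen.single(100.0, Route.oral), 24.0)


class TestSimulate:
    def test_iv_bolus_closed_form(self, iv_model):
        d, cl, vc = 100.0, 5.0, 50.0
        sim = simulate(iv_model, Regimen.single(d), 24.0, dt_out=0.25)
        expected = (d / vc) * np.exp(-(cl / vc) * sim.times)
        np.testing.assert_allclose(sim.c_plasma, expected, rtol=1e-6)

    def test_zero_dose_all_zero(self, iv_model):
        sim = simulate(iv_model, Regimen.single(0.0), 12.0, dt_out=0.5)
        assert np.all(sim.states == 0.0)

    def test_expm_matches_lsoda(self, caffeine_model):
        reg = Regimen.periodic(100.0, 8.0, 3, Route.oral)
        a = simulate(caffeine_model, reg, 24.0, n_out=240, method="lsoda")
        b = simulate(caffeine_model, reg, 24.0, n_out=240, method="expm")
        np.testing.assert_allclose(a.c_plasma, b.c_plasma, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(a.c_milk, b.c_milk, rtol=1e-6, atol=1e-12)

    @pytest.mark.parametrize("method", ["lsoda", "expm"])
    def test_mass_balance_multidose_oral(self, caffeine_model, method):
        reg = Regimen.periodic(100.0, 8.0, 5, Route.oral)
        sim = simulate(caffeine_model, reg, 44.0, n_out=400, method=method)
        assert sim.mass_balance_error() < 1e-4

    def test_mass_balance_infusion(self, coupled_iv_model):
        reg = Regimen.single(200.0, Route.iv_infusion, duration=2.0)
        sim = simulate(coupled_iv_model, reg, 24.0, n_out=240)
        assert sim.mass_balance_error() < 1e-4
        # administered ramps linearly over the infusion
        assert sim.administered[-1] == pytest.approx(200.0)
        mid = np.interp(1.0, sim.times, sim.administered)
        assert mid == pytest.approx(100.0, rel=1e-6)

    def test_non_negative_states(self, caffeine_model):
        reg = Regimen.periodic(100.0, 8.0, 4, Route.oral)
        sim = simulate(caffeine_model, reg, 48.0, n_out=300)
        assert np.all(sim.states >= 0.0)

    def test_dose_proportionality(self, caffeine_model):
        reg1 = Regimen.periodic(100.0, 8.0, 3, Route.oral)
        reg2 = Regimen.periodic(200.0, 8.0, 3, Route.oral)
        s1 = simulate(caffeine_model, reg1, 24.0, n_out=200, method="expm")
        s2 = simulate(caffeine_model, reg2, 24.0, n_out=200, method="expm")
        np.testing.assert_allclose(2.0 * s1.c_plasma[1:], s2.c_plasma[1:], rtol=1e-9)
        np.testing.assert_allclose(2.0 * s1.c_milk[5:], s2.c_milk[5:], rtol=1e-9)

    def test_tolerance_refinement_stability(self, caffeine_model):
        reg = Regimen.periodic(100.0, 8.0, 3, Route.oral)
        coarse = simulate(caffeine_model, reg, 24.0, n_out=200, rtol=1e-8)
        fine = simulate(caffeine_model, reg, 24.0, n_out=200, rtol=5e-9, atol=5e-13)
        auc_c = np.trapezoid(coarse.c_plasma, coarse.times)
        auc_f = np.trapezoid(fine.c_plasma, fine.times)
        assert abs(auc_c / auc_f - 1.0) < 1e-3

    def test_milk_peak_lags_plasma_peak(self, caffeine_model):
        sim = simulate_to_steady_state(caffeine_model, (100.0, 8.0, Route.oral))
        t_plasma = sim.times[np.argmax(sim.c_plasma)]
        t_milk = sim.times[np.argmax(sim.c_milk)]
        assert t_milk >= t_plasma

    def test_oral_lag_shifts_profile(self, caffeine_config):
        from dataclasses import replace

        pk = replace(caffeine_config.maternal_pk, tlag=1.0)
        model = build_model(
            caffeine_config.physchem, pk, derive_milk_transfer(caffeine_config.physchem)
        )
        sim = simulate(model, Regimen.single(100.0, Route.oral), 12.0, dt_out=0.1)
        assert np.all(sim.c_plasma[sim.times < 0.99] == 0.0)
        assert sim.c_plasma[sim.times > 1.5].max() > 0.0


class TestSteadyState:
    def test_no_accumulation_when_tau_long(self, iv_model):
        # tau >> 5 half-lives (t1/2 ~ 6.9 h)
        sim = simulate_to_steady_state(iv_model, (100.0, 80.0, Route.iv_bolus))
        assert sim.ss_flag
        assert sim.n_cycles <= 3

    def test_accumulation_ratio_closed_form(self, iv_model):
        cl, vc, tau = 5.0, 50.0, 8.0
        k = cl / vc
        first = simulate(iv_model, Regimen.single(100.0), tau, n_out=400)
        auc1 = np.trapezoid(first.c_plasma, first.times)
        ss = simulate_to_steady_state(
            iv_model, (100.0, tau, Route.iv_bolus), n_out=400, ss_rtol=1e-6
        )
        auc_ss = np.trapezoid(ss.c_plasma, ss.times)
        assert auc_ss / auc1 == pytest.approx(1.0 / (1.0 - np.exp(-k * tau)), rel=1e-3)

    def test_linearity_at_steady_state(self, caffeine_model):
        s1 = simulate_to_steady_state(caffeine_model, (100.0, 8.0, Route.oral))
        s2 = simulate_to_steady_state(caffeine_model, (200.0, 8.0, Route.oral))
        np.testing.assert_allclose(2.0 * s1.c_milk, s2.c_milk, rtol=1e-6)

    def test_auc_mp_matches_closed_form(self, caffeine_model):
        sim = simulate_to_steady_state(
            caffeine_model, (100.0, 8.0, Route.oral), ss_rtol=1e-5
        )
        auc_p = np.trapezoid(sim.c_plasma, sim.times)
        auc_m = np.trapezoid(sim.c_milk, sim.times)
        assert auc_m / auc_p == pytest.approx(caffeine_model.transfer.mp_ss, rel=1e-2)

    def test_nonconvergence_flagged(self, iv_model):
        with pytest.warns(UserWarning, match="steady state"):
            sim = simulate_to_steady_state(
                iv_model, (100.0, 1.0, Route.iv_bolus), max_cycles=3
            )
        assert not sim.ss_flag
        assert sim.n_cycles == 3

    def test_accepts_periodic_regimen(self, iv_model):
        sim = simulate_to_steady_state(iv_model, Regimen.from_string("100mg q80h iv"))
        assert sim.ss_flag


class TestNCA:
    def test_exact_exponential_slope(self):
        t = np.linspace(0.0, 20.0, 11)
        c = 5.0 * np.exp(-0.2 * t)
        assert nca_terminal_slope(t, c, 4) == pytest.approx(0.2)

    def test_constant_concentration_rejected(self):
        t = np.linspace(0.0, 10.0, 6)
        with pytest.raises(ValueError, match="not decreasing"):
            nca_terminal_slope(t, np.full_like(t, 3.0))

    def test_nonpositive_rejected(self):
        t = np.linspace(0.0, 10.0, 6)
        c = np.array([1.0, 0.5, 0.2, 0.1, 0.0, 0.0])
        with pytest.raises(ValueError, match="positive"):
            nca_terminal_slope(t, c)

    def test_auc_to_inf_closed_form(self):
        t = np.linspace(0.0, 40.0, 2001)
        c0, lam = 8.0, 0.2
        c = c0 * np.exp(-lam * t)
        assert nca_auc_to_inf(t, c, 5) == pytest.approx(c0 / lam, rel=1e-3)
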