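import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beringmse import opmodel as om
from beringmse import synthetic as syn
from beringmse.recruitment import RecruitmentModel

from _oracles import advance_year_oracle, baranov_oracle, ssb_oracle


def flat_species(name="fish", n_ages=5, m=0.3):
    return om.SpeciesConfig(
        name=name,
        maturity=np.array([0.0, 0.5, 1.0, 1.0, 1.0][:n_ages]),
        selectivity=np.ones(n_ages),
        m1=np.full(n_ages, m),
        base_weight=np.linspace(0.2, 1.0, n_ages),
    )


class TestWeightAtAge:
    def test_zero_anomaly_is_baseline(self):
        cfg = flat_species()
        np.testing.assert_array_equal(om.weight_at_age(cfg, 0.0), cfg.base_weight)

    def test_multiplicative_linear_response(self):
        cfg = flat_species()
        cfg.thermal_weight_sens = -0.05
        np.testing.assert_allclose(om.weight_at_age(cfg, 2.0), 0.90 * cfg.base_weight)

    def test_floor_clamp_logged(self, caplog):
        cfg = flat_species()
        cfg.thermal_weight_sens = -0.5
        with caplog.at_level(logging.WARNING):
            w = om.weight_at_age(cfg, 10.0)
        np.testing.assert_allclose(w, om.WEIGHT_FLOOR * cfg.base_weight)
        assert any("clamped" in r.getMessage() for r in caplog.records)


class TestPredation:
    def test_empty_config_gives_zero(self):
        cfgs = {"a": flat_species("a"), "b": flat_species("b")}
        n = {sp: np.ones(5) for sp in cfgs}
        w = {sp: cfgs[sp].base_weight for sp in cfgs}
        m2 = om.predation_mortality(om.PredationConfig(), cfgs, n, w)
        for sp in cfgs:
            np.testing.assert_array_equal(m2[sp], 0.0)

    def test_single_predator_hand_value_and_homogeneity(self):
        cfgs = {"pred": flat_species("pred"), "prey": flat_species("prey")}
        n = {"pred": np.full(5, 10.0), "prey": np.ones(5)}
        w = {sp: np.ones(5) for sp in cfgs}
        pc = om.PredationConfig([om.PredationPair("pred", "prey", coef=0.002)])
        m2 = om.predation_mortality(pc, cfgs, n, w)
        np.testing.assert_allclose(m2["prey"], 0.002 * 50.0)
        n2 = {"pred": 2 * n["pred"], "prey": n["prey"]}
        m2_doubled = om.predation_mortality(pc, cfgs, n2, w)
        np.testing.assert_allclose(m2_doubled["prey"], 2 * m2["prey"])

    def test_unknown_pair_rejected(self):
        cfgs = {"a": flat_species("a")}
        pc = om.PredationConfig([om.PredationPair("a", "ghost", coef=0.1)])
        with pytest.raises(KeyError):
            om.predation_mortality(pc, cfgs, {"a": np.ones(5)}, {"a": np.ones(5)})


class TestBaranov:
    def test_zero_F_zero_catch(self):
        assert om.baranov_catch(np.ones(3), np.ones(3), np.ones(3), 0.0, np.full(3, 0.3)) == 0.0

    def test_closed_form_single_age(self):
        c = om.baranov_catch(
            np.array([1000.0]), np.array([1.0]), np.array([1.0]), 0.2, np.array([0.2])
        )
        assert c == pytest.approx(1000 * (1 - math.exp(-0.2)), rel=1e-12)
        assert c == pytest.approx(181.2692, abs=1e-4)

    def test_limit_takes_entire_biomass(self):
        n, w = np.array([10.0, 5.0]), np.array([1.0, 2.0])
        f = 1e4
        c = om.baranov_catch(n, w, np.ones(2), f, np.full(2, f))
        assert c == pytest.approx(float(np.sum(n * w)), rel=1e-6)

    @given(f1=st.floats(0.01, 2.0), f2=st.floats(0.01, 2.0))
    def test_monotone_in_F(self, f1, f2):
        n, w, s, m = np.full(4, 100.0), np.ones(4), np.ones(4), np.full(4, 0.25)
        c1 = om.baranov_catch(n, w, s, f1, m + s * f1)
        c2 = om.baranov_catch(n, w, s, f2, m + s * f2)
        assert (c1 < c2) == (f1 < f2) or f1 == f2

    def test_zero_Z_with_positive_F_guarded(self):
        with pytest.raises(ZeroDivisionError):
            om.baranov_catch(np.ones(1), np.ones(1), np.ones(1), 0.5, np.zeros(1))

    def test_matches_loop_oracle(self, rng):
        n = rng.uniform(1, 100, 6)
        w = rng.uniform(0.1, 2, 6)
        s = rng.uniform(0, 1, 6)
        f = 0.37
        z = rng.uniform(0.2, 0.6, 6) + s * f
        assert om.baranov_catch(n, w, s, f, z) == pytest.approx(
            baranov_oracle(n, w, s, f, z), rel=1e-12
        )


class TestSolveFFromCatch:
    n, w = np.full(5, 1000.0), np.linspace(0.5, 1.5, 5)
    s, m = np.ones(5), np.full(5, 0.3)

    def test_zero_target(self):
        assert om.solve_F_from_catch(self.n, self.w, self.s, self.m, 0.0) == 0.0

    def test_round_trip_inverse(self):
        f_true = 0.23
        c = om.baranov_catch(self.n, self.w, self.s, f_true, self.m + self.s * f_true)
        f = om.solve_F_from_catch(self.n, self.w, self.s, self.m, c)
        assert f == pytest.approx(f_true, abs=1e-8)

    def test_unattainable_target_capped(self, caplog):
        c_max = om.baranov_catch(self.n, self.w, self.s, om.F_MAX, self.m + self.s * om.F_MAX)
        with caplog.at_level(logging.WARNING):
            f = om.solve_F_from_catch(self.n, self.w, self.s, self.m, 1.01 * c_max)
        assert f == om.F_MAX
        assert any("exceeds attainable" in r.getMessage() for r in caplog.records)


def _toy_inputs(toy):
    cov = toy.forcing["persistence"].year_slice(2001)
    return toy.species_cfgs, toy.pred_cfg, toy.true_recruitment, cov


class TestAdvanceYear:
    def test_pure_exponential_survival(self, toy):
        cfgs, pred, models, cov = _toy_inputs(toy)
        state = om.initial_state(cfgs, cov, 2001)
        nxt = om.advance_year(state, cfgs, pred, cov, models)
        for sp, cfg in cfgs.items():
            m = cfg.m1[0]
            np.testing.assert_allclose(
                nxt.n[sp][1:-1], state.n[sp][:-2] * np.exp(-m), rtol=1e-12
            )

    def test_two_year_step_matches_oracle(self, toy):
        """3-species, 5-age toy stepped 2 years against the plain-loop
        spreadsheet oracle, including SSB-driven recruitment."""
        from beringmse.recruitment import predict_recruitment

        cfgs, pred, models, cov = _toy_inputs(toy)
        state = om.initial_state(cfgs, cov, 2001)
        expected = {sp: list(state.n[sp]) for sp in cfgs}
        for _ in range(2):
            prev_ssb = {
                sp: ssb_oracle(expected[sp], list(cfgs[sp].base_weight), list(cfgs[sp].maturity))
                for sp in cfgs
            }
            for sp, cfg in cfgs.items():
                rec = predict_recruitment(models[sp], prev_ssb[sp], cov)
                expected[sp] = advance_year_oracle(
                    expected[sp], list(cfg.base_weight), list(cfg.m1), list(cfg.maturity), rec
                )
            state = om.advance_year(state, cfgs, pred, cov, models)
        for sp in cfgs:
            np.testing.assert_allclose(state.n[sp], expected[sp], rtol=1e-9)

    def test_ssb_definition_invariant(self, toy):
        cfgs, pred, models, cov = _toy_inputs(toy)
        state = om.initial_state(cfgs, cov, 2001)
        for _ in range(3):
            state = om.advance_year(state, cfgs, pred, cov, models, f_applied={"pollock": 0.2})
            ssb = state.ssb(cfgs)
            for sp, cfg in cfgs.items():
                assert ssb[sp] == pytest.approx(
                    float(np.sum(cfg.maturity * state.n[sp] * state.w[sp])), rel=1e-9
                )
                assert np.all(state.n[sp] >= 0)
                assert np.all(state.z[sp] >= cfg.m1 - 1e-12)

    def test_zero_spawning_biomass_gives_zero_recruits(self, toy):
        cfgs, pred, models, cov = _toy_inputs(toy)
        state = om.initial_state(cfgs, cov, 2001)
        for sp in cfgs:
            state.n[sp][:] = 0.0
        nxt = om.advance_year(state, cfgs, pred, cov, models)
        for sp in cfgs:
            assert nxt.n[sp][0] == 0.0


class TestProjectUnfished:
    def test_F_zero_throughout_and_window_definition(self, study):
        pers = study.forcing["persistence"]
        traj, b0 = om.project_unfished(
            study.species_cfgs, study.pred_cfg, study.true_recruitment, pers
        )
        assert (traj.f == 0).all()
        sub = traj[(traj.year >= 2095) & (traj.year <= 2099)]
        for sp, expect in sub.groupby("species")["ssb"].mean().items():
            assert b0[sp] == pytest.approx(expect, rel=1e-12)

    def test_converges_to_equilibrium_under_constant_forcing(self, study):
        pers = study.forcing["persistence"]
        traj, _ = om.project_unfished(
            study.species_cfgs, study.pred_cfg, study.true_recruitment, pers
        )
        for sp, g in traj.groupby("species"):
            tail = g.sort_values("year")["ssb"].to_numpy()[-2:]
            assert abs(tail[1] - tail[0]) / tail[0] < 1e-6

    def test_window_outside_projection_rejected(self, study):
        with pytest.raises(ValueError):
            om.project_unfished(
                study.species_cfgs, study.pred_cfg, study.true_recruitment,
                study.forcing["persistence"], window=(2150, 2154),
            )
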