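import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beringmse import catchfn as cf
from beringmse import synthetic as syn


@pytest.fixture(scope="module")
def noiseless_history():
    params = syn.true_catch_function_params()
    params.tac_sd = 0.0
    params.catch_sd = 0.0
    return syn.make_quota_history(seed=0, params=params), params


class TestFit:
    def test_noiseless_recovery(self, noiseless_history):
        history, params = noiseless_history
        m = cf.fit_catch_functions(history)
        for sp in syn.SPECIES:
            assert m.tac_stage[sp].own_coef == pytest.approx(params.tac_own[sp], abs=1e-8)
            assert m.tac_stage[sp].intercept == pytest.approx(params.tac_intercept[sp], abs=1e-6)
            for o, g in params.tac_cross[sp].items():
                assert m.tac_stage[sp].cross_coefs[o] == pytest.approx(g, abs=1e-12)
            assert m.catch_stage[sp].own_coef == pytest.approx(params.catch_own[sp], abs=1e-8)

    def test_own_elasticity_recovered_under_noise(self):
        """With correlated lognormal noise at the generating magnitudes the
        TAC-stage own-log coefficient lands within +/-0.15 of truth in at
        least 90% of seeded replicates."""
        n_reps, hits = 200, 0
        for r in range(n_reps):
            history = syn.make_quota_history(seed=5000 + r)
            m = cf.fit_catch_functions(history)
            errs = [abs(m.tac_stage[sp].own_coef - 0.96) for sp in syn.SPECIES]
            hits += all(e <= 0.15 for e in errs)
        assert hits >= 0.90 * n_reps

    def test_short_history_rejected(self):
        history = syn.make_quota_history(seed=1, years=(2010, 2017))
        with pytest.raises(ValueError, match="12 years"):
            cf.fit_catch_functions(history)

    def test_constant_other_species_column_dropped(self, caplog):
        history = syn.make_quota_history(seed=2)
        for rec in history:
            rec.abc["arrowtooth"] = 1.2e5  # degenerate: no contrast in this regressor
        with caplog.at_level(logging.WARNING):
            m = cf.fit_catch_functions(history)
        assert m.tac_stage["pollock"].cross_coefs["arrowtooth"] == 0.0
        assert m.tac_stage["arrowtooth"].own_coef == 0.0
        assert any("constant column" in r.getMessage() for r in caplog.records)

    def test_residual_groupings_structure(self):
        m = cf.fit_catch_functions(syn.make_quota_history(seed=3))
        ind = m.resid_corr["independent"]["tac"]
        np.testing.assert_array_equal(ind, np.eye(len(m.species)))
        full = m.resid_corr["three_group"]["tac"]
        assert np.any(full != np.eye(len(m.species)))
        np.testing.assert_allclose(full, full.T)


class TestPredictTac:
    def test_identity_coefficients(self):
        m = cf.fit_catch_functions(syn.make_quota_history(seed=4))
        for sp in m.species:
            m.tac_stage[sp].intercept = 0.0
            m.tac_stage[sp].own_coef = 1.0
            m.tac_stage[sp].cross_coefs = {o: 0.0 for o in m.tac_stage[sp].cross_coefs}
            m.tac_stage[sp].indicator_coefs = {k: 0.0 for k in m.tac_stage[sp].indicator_coefs}
        abc = {"pollock": 1e6, "pcod": 3e5, "arrowtooth": 1e5}
        assert cf.predict_tac(m, abc) == pytest.approx(abc)

    def test_hand_computable_case(self):
        m = cf.fit_catch_functions(syn.make_quota_history(seed=4))
        sp = "pollock"
        m.tac_stage[sp].intercept = np.log(0.8)
        m.tac_stage[sp].own_coef = 1.0
        m.tac_stage[sp].cross_coefs = {o: 0.0 for o in m.tac_stage[sp].cross_coefs}
        m.tac_stage[sp].indicator_coefs = {k: 0.0 for k in m.tac_stage[sp].indicator_coefs}
        out = cf.predict_tac(m, {"pollock": 1e6, "pcod": 3e5, "arrowtooth": 1e5}, {"a80": 0.0, "afa": 0.0})
        assert out[sp] == pytest.approx(8e5, rel=1e-10)

    def test_prediction_clipped_to_abc(self, caplog):
        m = cf.fit_catch_functions(syn.make_quota_history(seed=4))
        sp = "arrowtooth"
        m.tac_stage[sp].intercept = np.log(2.0)
        m.tac_stage[sp].own_coef = 1.0
        m.tac_stage[sp].cross_coefs = {o: 0.0 for o in m.tac_stage[sp].cross_coefs}
        m.tac_stage[sp].indicator_coefs = {k: 0.0 for k in m.tac_stage[sp].indicator_coefs}
        with caplog.at_level(logging.WARNING):
            out = cf.predict_tac(m, {"pollock": 1e6, "pcod": 3e5, "arrowtooth": 1e5}, {"a80": 0.0, "afa": 0.0})
        assert out[sp] == 1e5
        assert any("exceeds ABC" in r.getMessage() for r in caplog.records)


class TestApplyCap:
    def test_below_cap_unchanged(self):
        tac = {"a": 1.0e6, "b": 0.5e6, "c": 0.1e6}
        assert cf.apply_cap(tac, 0.0, 2e6) == tac

    def test_hand_arithmetic_scaling(self):
        tac = {"a": 1.5e6, "b": 0.8e6, "c": 0.2e6}
        out = cf.apply_cap(tac, 0.0, 2e6)
        assert out == pytest.approx({"a": 1.2e6, "b": 0.64e6, "c": 0.16e6})
        assert sum(out.values()) == pytest.approx(2e6, abs=1e-6)

    @given(
        t=st.tuples(st.floats(1e3, 3e6), st.floats(1e3, 3e6), st.floats(1e3, 3e6)),
        exog=st.floats(0, 1.5e6),
    )
    def test_proportions_preserved_and_idempotent(self, t, exog):
        tac = dict(zip("abc", t))
        out = cf.apply_cap(tac, exog, 2e6)
        assert sum(out.values()) + exog <= 2e6 * (1 + 1e-12)
        if sum(tac.values()) + exog > 2e6:
            assert sum(out.values()) + exog == pytest.approx(2e6, rel=1e-12)
            for x, y in [("a", "b"), ("b", "c")]:
                assert out[x] / out[y] == pytest.approx(tac[x] / tac[y], rel=1e-12)
        again = cf.apply_cap(out, exog, 2e6)
        assert again == pytest.approx(out, rel=1e-12)

    def test_exogenous_exceeding_cap_rejected(self):
        with pytest.raises(cf.CapInfeasibleError):
            cf.apply_cap({"a": 1.0}, exogenous_other_tac=2.5e6, cap=2e6)


class TestPredictCatch:
    def test_scaled_identity(self):
        m = cf.fit_catch_functions(syn.make_quota_history(seed=4))
        for sp in m.species:
            m.catch_stage[sp].intercept = np.log(0.95)
            m.catch_stage[sp].own_coef = 1.0
            m.catch_stage[sp].cross_coefs = {o: 0.0 for o in m.catch_stage[sp].cross_coefs}
            m.catch_stage[sp].indicator_coefs = {k: 0.0 for k in m.catch_stage[sp].indicator_coefs}
        tac = {"pollock": 1e6, "pcod": 3e5, "arrowtooth": 1e5}
        out = cf.predict_catch(m, tac, {"a80": 0.0, "afa": 0.0})
        for sp in tac:
            assert out[sp] == pytest.approx(0.95 * tac[sp], rel=1e-10)

    def test_closure_indicator_lowers_catch(self):
        m = cf.fit_catch_functions(syn.make_quota_history(seed=4))
        sp = "pollock"
        m.catch_stage[sp].indicator_coefs["a80"] = -0.3
        tac = {"pollock": 1e6, "pcod": 3e5, "arrowtooth": 1e5}
        closed = cf.predict_catch(m, tac, {"a80": 1.0, "afa": 0.0})
        open_ = cf.predict_catch(m, tac, {"a80": 0.0, "afa": 0.0})
        assert closed[sp] < open_[sp]


class TestLooCv:
    def test_noiseless_history_zero_error(self, noiseless_history):
        history, _ = noiseless_history
        table = cf.loo_cv(history)
        ens = table[table.model == "ensemble"]
        assert (ens["sum_sq_pct_diff"] < 1e-12).all()

    def test_order_invariance(self):
        history = syn.make_quota_history(seed=6)
        t1 = cf.loo_cv(history)
        t2 = cf.loo_cv(history[::-1])
        pd.testing.assert_frame_equal(t1, t2)

    def test_beats_naive_baseline_on_typical_history(self):
        history = syn.make_quota_history(seed=7)
        table = cf.loo_cv(history).set_index(["model", "species"])
        for sp in syn.SPECIES:
            assert (
                table.loc[("ensemble", sp), "sum_sq_pct_diff"]
                < table.loc[("catch_eq_abc", sp), "sum_sq_pct_diff"]
            )
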