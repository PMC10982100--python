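"""Unit tests for the mechanistic reference models, noise model and
scenario registry."""

import io

import numpy as np
import pytest

from neuralpk.odeint import solve_rk4
from neuralpk.pk import (SCENARIO_NAMES, DoseRegimen, PKParams, PooledDataset,
                         add_proportional_error, central_index,
                         initial_condition, make_scenario, mechanistic_rhs,
                         simulate_reference, state_dim)

BASE = PKParams(kel=0.1, V=2.0)


class TestRhs:
    def test_onecomp_linear_elimination(self):
        reg = DoseRegimen(route="iv_bolus", d=1.0)
        dx = mechanistic_rhs("onecomp_iv", BASE, reg, [0.5], 0.0)
        assert dx[0] == pytest.approx(-0.05)

    def test_tmdd_receptor_baseline_is_stationary(self):
        p = PKParams(kel=0.1, kon=0.25, koff=0.01, ksyn=0.5, kdeg=0.25,
                     kint=0.1, V=2.0)
        reg = DoseRegimen(route="iv_bolus", d=0.0)
        state = [0.0, p.ksyn / p.kdeg, 0.0]  # no ligand, baseline receptor
        assert state[1] == 2.0
        dx = mechanistic_rhs("tmdd_iv", p, reg, state, 0.0)
        np.testing.assert_allclose(dx, 0.0, atol=1e-14)

    def test_zero_transits_match_first_order_absorption(self, rng):
        p0 = PKParams(kel=0.1, ka=0.2, V=2.0, ntr=0)
        reg = DoseRegimen(route="oral", d=5.0)
        for _ in range(20):
            depot, conc = rng.uniform(0, 5), rng.uniform(0, 2)
            dx = mechanistic_rhs("onecomp_po_transit", p0, reg,
                                 [depot, conc], 0.0)
            # plain first-order absorption: depot loses ka*A, central gains
            # ka*A/V and loses kel*C
            assert dx[0] == pytest.approx(-p0.ka * depot)
            assert dx[1] == pytest.approx(p0.ka * depot / p0.V - p0.kel * conc)

    def test_unknown_model_and_bad_state_rejected(self):
        reg = DoseRegimen(route="iv_bolus", d=1.0)
        with pytest.raises(ValueError, match="model_id"):
            mechanistic_rhs("threecomp", BASE, reg, [1.0], 0.0)
        with pytest.raises(ValueError, match="state length"):
            mechanistic_rhs("twocomp_iv", BASE, reg, [1.0], 0.0)

    def test_transit_chain_mass_balance(self):
        # d/dt(total amount) = -kel * xC * V along a nonnegative trajectory
        p = PKParams(kel=0.1, ka=0.2, ktr=0.1, ntr=4, V=2.0)
        reg = DoseRegimen(route="oral", d=5.0)
        state = np.array([3.0, 0.8, 0.5, 0.3, 0.1, 0.15])
        dx = mechanistic_rhs("onecomp_po_transit", p, reg, state, 0.0)
        total_rate = np.sum(dx[:-1]) + dx[-1] * p.V
        assert total_rate == pytest.approx(-p.kel * state[-1] * p.V)
        assert total_rate <= 0


class TestSimulate:
    def test_onecomp_matches_closed_form(self):
        reg = DoseRegimen(route="iv_bolus", d=1.0)
        times = np.linspace(0, 50, 40)
        conc = simulate_reference("onecomp_iv", BASE, reg, times)
        assert conc[0] == pytest.approx(0.5)
        np.testing.assert_allclose(conc, 0.5 * np.exp(-0.1 * times), atol=1e-6)

    def test_twocomp_matches_fixed_step_oracle(self):
        p = PKParams(kel=0.1, k12=0.2, k21=0.2, V=2.0)
        reg = DoseRegimen(route="iv_bolus", d=1.0)
        times = np.array([0.0, 5.0, 20.0, 50.0])
        conc = simulate_reference("twocomp_iv", p, reg, times)
        # independent oracle: classic RK4 at step 1e-3
        grid = np.arange(0, 50 + 1e-9, 1e-3)
        traj = solve_rk4(
            lambda x, t: mechanistic_rhs("twocomp_iv", p, reg, x, t),
            [0.5, 0.0], grid,
        )
        oracle = np.interp(times, grid, traj[:, 0])
        np.testing.assert_allclose(conc, oracle, atol=1e-4)

    @pytest.mark.parametrize(
        "model_id,params,route",
        [
            ("onecomp_iv", BASE, "iv_bolus"),
            ("twocomp_iv", PKParams(kel=0.1, k12=0.2, k21=0.2, V=2.0), "iv_bolus"),
            ("onecomp_po_transit",
             PKParams(kel=0.1, ka=0.2, ktr=0.1, ntr=4, V=2.0), "oral"),
        ],
    )
    def test_linear_models_dose_proportional(self, model_id, params, route):
        times = np.linspace(0, 50, 12)
        c1 = simulate_reference(model_id, params,
                                DoseRegimen(route=route, d=3.0), times)
        c2 = simulate_reference(model_id, params,
                                DoseRegimen(route=route, d=6.0), times)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-6, atol=1e-10)

    def test_infusion_derivative_drops_by_kin_over_V_at_tinf(self):
        reg = DoseRegimen.infusion(kin=1.0, tinf=6.0)
        eps = 1e-6
        before = mechanistic_rhs("onecomp_infusion", BASE, reg, [0.9], 6.0 - eps)
        after = mechanistic_rhs("onecomp_infusion", BASE, reg, [0.9], 6.0 + eps)
        assert before[0] - after[0] == pytest.approx(reg.kin / BASE.V)
        # concentration itself is continuous across tinf
        times = np.array([0.0, 6.0 - 1e-9, 6.0 + 1e-9])
        conc = simulate_reference("onecomp_infusion", BASE, reg, times)
        assert conc[1] == pytest.approx(conc[2], rel=1e-6)

    def test_tmdd_receptor_stays_at_baseline_without_ligand(self):
        p = PKParams(kel=0.1, kon=0.25, koff=0.01, ksyn=0.5, kdeg=0.25,
                     kint=0.1, V=2.0)
        reg = DoseRegimen(route="iv_bolus", d=0.0)
        times = np.linspace(0, 60, 20)
        conc = simulate_reference("tmdd_iv", p, reg, times)
        np.testing.assert_allclose(conc, 0.0, atol=1e-10)


class TestNoise:
    def test_zero_cv_is_identity(self):
        conc = np.array([1.0, 0.5, 0.1])
        np.testing.assert_array_equal(add_proportional_error(conc, 0.0, 1), conc)

    def test_seeded_reproducibility(self):
        conc = np.linspace(0.01, 1, 17)
        a = add_proportional_error(conc, 0.1, seed=42)
        b = add_proportional_error(conc, 0.1, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            add_proportional_error([1.0], -0.1, 0)

    def test_moments_match_proportional_error_model(self):
        n = 10_000
        draws = add_proportional_error(np.ones(n), 0.1, seed=7)
        se = 0.1 / np.sqrt(n)
        assert abs(draws.mean() - 1.0) < 3 * se
        rel_sd = np.std(draws - 1.0)
        assert abs(rel_sd - 0.1) / 0.1 < 0.05


class TestScenarios:
    def test_twocomp_scenario_doses(self):
        data, spec = make_scenario("twocomp_iv", seed=0)
        doses = sorted(data.df["dose"].unique())
        assert doses == [1.0, 10.0]
        assert len(data.group_ids) == 2
        assert [r.d for r in spec.test_regimens] == [5.0]

    def test_transit8_has_ten_sampling_times(self):
        data, _ = make_scenario("po_transit8", seed=0)
        for gid in data.group_ids:
            assert data.group(gid)["time"].nunique() == 10

    def test_overfit_noise_free_matches_closed_form(self):
        data, spec = make_scenario("overfit_onecomp", seed=3, cv=0.0)
        t = data.df["time"].to_numpy()
        np.testing.assert_allclose(
            data.df["conc"], 0.5 * np.exp(-0.1 * t), rtol=1e-7
        )

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("threecomp", seed=0)

    def test_registry_covers_all_named_scenarios(self):
        assert set(SCENARIO_NAMES) == {
            "overfit_onecomp", "interp_onecomp", "twocomp_iv", "po_plain",
            "po_transit4", "po_transit8", "infusion", "tmdd_iv", "tmdd_po",
        }

    def test_same_seed_same_dataset(self):
        a, _ = make_scenario("po_plain", seed=5)
        b, _ = make_scenario("po_plain", seed=5)
        assert a.to_csv_string() == b.to_csv_string()


class TestDatasetIO:
    def test_csv_round_trip(self):
        data, _ = make_scenario("infusion", seed=2)
        buf = io.StringIO()
        data.to_csv(buf)
        buf.seek(0)
        back = PooledDataset.from_csv(buf)
        assert back.to_csv_string() == data.to_csv_string()
        reg = back.regimen(back.group_ids[0])
        assert reg.route == "iv_infusion"
        assert reg.d == pytest.approx(reg.kin * reg.tinf)

    def test_negative_conc_warns_negative_dose_rejected(self):
        data, _ = make_scenario("overfit_onecomp", seed=1)
        df = data.df.copy()
        df.loc[0, "conc"] = -0.01
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.warns(UserWarning, match="negative concentrations"):
            PooledDataset.from_csv(buf)
        df.loc[0, "dose"] = -1.0
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(ValueError, match="dose"):
            with pytest.warns(UserWarning):
                PooledDataset.from_csv(buf)


class TestRegimen:
    def test_infusion_dose_consistency_enforced(self):
        with pytest.raises(ValueError, match="kin"):
            DoseRegimen(route="iv_infusion", d=5.0, kin=1.0, tinf=6.0)
        reg = DoseRegimen.infusion(kin=1.0, tinf=6.0)
        assert reg.d == 6.0

    def test_state_dims(self):
        assert state_dim("tmdd_iv", BASE) == 3
        assert state_dim("tmdd_po", BASE) == 4
        p = PKParams(ntr=8, V=2.0)
        assert state_dim("onecomp_po_transit", p) == 10
        assert central_index("onecomp_po_transit", p) == 9
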