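"""Unit tests for losses and the pooled training loop."""

import numpy as np
import pytest

from neuralpk.pk import make_scenario
from neuralpk.structures import build_node
from neuralpk.training import (TrainingConfig, cyclic_lr, dataset_loss,
                               init_logV_from_data, mse, train,
                               train_multistart, wmse)


class TestLosses:
    def test_perfect_fit_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert wmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed_two_point_values(self):
        # two time points, one replicate each: predictions (1, 2) against
        # observations (2, 4)
        assert mse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(2.5)
        assert wmse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(0.75)

    def test_mse_quadratic_homogeneity(self, rng):
        pred = rng.uniform(1, 2, 6)
        obs = rng.uniform(1, 2, 6)
        doubled = obs + 2 * (pred - obs)
        assert mse(doubled, obs) == pytest.approx(4 * mse(pred, obs))

    def test_wmse_joint_scaling_is_linear(self, rng):
        pred = rng.uniform(1, 2, 6)
        obs = rng.uniform(1, 2, 6)
        c = 3.7
        assert wmse(c * pred, c * obs) == pytest.approx(c * wmse(pred, obs))

    def test_wmse_rejects_nonpositive_observations(self):
        with pytest.raises(ValueError, match="nonpositive"):
            wmse([1.0], [0.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mse([1.0, 2.0], [1.0])


class TestSchedule:
    def test_cyclic_starts_at_ceiling_and_touches_floor(self):
        lrs = [cyclic_lr(e, 1e-3, 1e-6, 200) for e in range(400)]
        assert lrs[0] == pytest.approx(1e-3)
        assert min(lrs) == pytest.approx(1e-6, rel=0.05)
        assert lrs[200] == pytest.approx(1e-3)  # period 200


class TestTrain:
    @pytest.fixture(scope="class")
    def small_dataset(self):
        data, _ = make_scenario("overfit_onecomp", seed=11, cv=0.0)
        return data

    def test_seed_determinism_bit_identical(self, small_dataset):
        cfg = TrainingConfig(epochs=50, seed=5, h_max=2.0)
        fits = [
            train(build_node("separated", n_hid=5, seed=5), small_dataset, cfg)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0].loss_history,
                                      fits[1].loss_history)
        np.testing.assert_array_equal(fits[0].model.pack(),
                                      fits[1].model.pack())

    def test_loss_decreases_and_best_tracked(self, small_dataset):
        cfg = TrainingConfig(epochs=300, seed=3, h_max=2.0)
        fit = train(build_node("separated", n_hid=5, seed=3),
                    small_dataset, cfg)
        assert fit.loss_history[-1] <= fit.loss_history[0]
        assert fit.final_loss == fit.loss_history[fit.best_epoch]
        assert fit.final_loss == np.min(fit.loss_history)

    def test_route_incompatible_dataset_rejected(self, small_dataset):
        model = build_node("infusion", n_hid=4, seed=0)
        with pytest.raises(ValueError, match="iv_infusion"):
            train(model, small_dataset, TrainingConfig(epochs=10))

    def test_wmse_requires_positive_observations(self):
        data, _ = make_scenario("overfit_onecomp", seed=2)
        df = data.df.copy()
        df.loc[0, "conc"] = 0.0
        data.df = df
        model = build_node("separated", n_hid=4, seed=0)
        with pytest.raises(ValueError, match="positive"):
            train(model, data, TrainingConfig(loss="wmse", epochs=10))

    def test_trained_loss_matches_dataset_loss(self, small_dataset):
        cfg = TrainingConfig(epochs=200, seed=7, h_max=2.0)
        fit = train(build_node("separated", n_hid=5, seed=7),
                    small_dataset, cfg)
        recomputed = dataset_loss(fit.model, small_dataset, "mse", h_max=2.0)
        assert recomputed == pytest.approx(fit.final_loss, rel=1e-10)

    def test_multistart_returns_lowest_loss(self, small_dataset):
        cfg = TrainingConfig(epochs=100, seed=1, h_max=2.0)
        single = train_multistart(small_dataset, cfg, structure="separated",
                                  n_hid=5, restarts=1)
        double = train_multistart(small_dataset, cfg, structure="separated",
                                  n_hid=5, restarts=2)
        assert double.final_loss <= single.final_loss


class TestMechanismRecovery:
    def test_clean_five_point_fit_recovers_elimination_line(self):
        """On noise-free single-group data the model interpolates exactly
        and its derivative-state profile recovers the -kel*x mechanism
        over the sampled concentration range."""
        data, spec = make_scenario("overfit_onecomp", seed=31, cv=0.0)
        cfg = TrainingConfig(epochs=20_000, seed=31, h_max=2.0)
        fit = train_multistart(data, cfg, structure="separated", n_hid=20,
                               restarts=3)
        assert fit.final_loss < 1e-8
        from neuralpk.diagnostics import node_profile
        from neuralpk.pk import DoseRegimen

        prof = node_profile(fit.model, DoseRegimen(route="iv_bolus", d=1.0),
                            horizon=50.0)
        # slope of the learned derivative over the data's concentration range
        mask = (prof.conc > 0.05) & (prof.conc < 0.45)
        slope = np.polyfit(prof.conc[mask], prof.deriv[mask], 1)[0]
        assert slope == pytest.approx(-0.1, rel=0.10)

    def test_pooled_training_learns_cleaner_mechanism_than_single_replicate(self):
        """Residual errors average out under pooled training: the profile
        of an 8-replicate fit deviates from the true elimination line by a
        much smaller integrated error than a single-replicate fit."""
        from neuralpk.diagnostics import (compare_profiles, node_profile,
                                          reference_profile)
        from neuralpk.pk import DoseRegimen

        reg = DoseRegimen(route="iv_bolus", d=1.0)
        single, _ = make_scenario("overfit_onecomp", seed=41, cv=0.10)
        pooled_all, spec = make_scenario("interp_onecomp", seed=41, cv=0.10)
        pooled = pooled_all.subset(
            [g for g in pooled_all.group_ids if pooled_all.regimen(g).d == 1.0]
        )
        ref = reference_profile("onecomp_iv", spec.params, reg, horizon=50.0)
        devs = {}
        for tag, data in [("single", single), ("pooled", pooled)]:
            cfg = TrainingConfig(epochs=20_000, seed=41, h_max=2.0)
            fit = train_multistart(data, cfg, structure="separated",
                                   n_hid=20, restarts=3)
            prof = node_profile(fit.model, reg, horizon=50.0)
            devs[tag] = compare_profiles(prof, ref, (0.05, 0.45))["mean_abs"]
        assert devs["pooled"] < 0.5 * devs["single"]


class TestVolumeInit:
    def test_bolus_volume_read_from_first_concentration(self):
        data, _ = make_scenario("interp_onecomp", seed=4, cv=0.0)
        v0 = np.exp(init_logV_from_data(data))
        # earliest sample at t = 1: c = (d/V) e^{-0.1} so the crude read-off
        # overestimates V by about e^{0.1}
        assert v0 == pytest.approx(2.0 * np.exp(0.1), rel=1e-6)

    def test_infusion_volume_from_terminal_slope_and_plateau(self):
        # kel from the terminal log-linear slope, V from the concentration
        # at end of infusion; on clean data this lands near the true V = 2
        data, _ = make_scenario("infusion", seed=4, cv=0.0)
        v0 = np.exp(init_logV_from_data(data))
        assert v0 == pytest.approx(2.0, rel=0.15)
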