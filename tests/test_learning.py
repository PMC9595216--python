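import numpy as np
import pytest

from painchain import (
    HIDDEN_LABELS,
    OBS_LABELS,
    UNOBSERVED,
    ConditionalTable,
    CountSet,
    ObservationSchedule,
    PseudocountDistribution,
    batch_update,
    build_model,
    expected_counts,
    path_counts,
    preset_observer,
    propagate,
    run_learning,
    sample_generative,
)


def uniform_model(n_steps=20, nu=2.0):
    uni_h = PseudocountDistribution(HIDDEN_LABELS, (0.5, 0.5), nu)
    uni_o = PseudocountDistribution(OBS_LABELS, (0.5, 0.5), nu)
    return build_model(
        uni_h,
        ConditionalTable(HIDDEN_LABELS, (uni_h, uni_h)),
        ConditionalTable(HIDDEN_LABELS, (uni_o, uni_o)),
        n_steps,
    )


class TestExpectedCounts:
    def test_single_node_harmless(self):
        prior = PseudocountDistribution(HIDDEN_LABELS, (0.7, 0.3), 100.0)
        m = preset_observer("healthy").replace(prior=prior, n_steps=1)
        obs = ObservationSchedule(("harmless",))
        sweep = propagate(m, obs)
        counts = expected_counts(m, sweep, obs)
        q = 0.14 / 0.41
        assert counts.prior_counts == pytest.approx((q, 1 - q), abs=1e-10)
        assert counts.likelihood_counts[:, 1] == pytest.approx((q, 1 - q), abs=1e-10)
        assert counts.likelihood_counts[:, 0] == pytest.approx((0.0, 0.0))
        assert counts.transition_counts == pytest.approx(np.zeros((2, 2)))

    def test_all_unobserved_no_likelihood_counts(self, healthy):
        obs = ObservationSchedule((UNOBSERVED,) * 20)
        counts = expected_counts(healthy, propagate(healthy, obs), obs)
        assert counts.likelihood_counts == pytest.approx(np.zeros((2, 2)))

    def test_two_step_transition_counts_equal_pairwise(self, healthy):
        m = healthy.replace(n_steps=2)
        obs = ObservationSchedule(("noxious", "harmless"))
        sweep = propagate(m, obs)
        counts = expected_counts(m, sweep, obs)
        assert counts.transition_counts == pytest.approx(sweep.pairwise[0], abs=1e-12)

    def test_count_budgets(self, chronic):
        obs = ObservationSchedule(
            ("noxious",) * 5 + (UNOBSERVED,) * 8 + ("harmless",) * 7
        )
        counts = expected_counts(chronic, propagate(chronic, obs), obs)
        assert counts.prior_counts.sum() == pytest.approx(1.0, abs=1e-10)
        assert counts.transition_counts.sum() == pytest.approx(19.0, abs=1e-8)
        assert counts.likelihood_counts.sum() == pytest.approx(12.0, abs=1e-8)


class TestPathCounts:
    def test_indicator_counts(self, healthy):
        m = healthy.replace(n_steps=3)
        hidden = ("pain", "pain_free", "pain_free")
        obs = ObservationSchedule(("noxious", "harmless", UNOBSERVED))
        counts = path_counts(m, hidden, obs)
        assert counts.prior_counts == pytest.approx((1.0, 0.0))
        assert counts.transition_counts == pytest.approx(np.array([[0.0, 1.0], [0.0, 1.0]]))
        assert counts.likelihood_counts == pytest.approx(np.array([[1.0, 0.0], [0.0, 1.0]]))


class TestBatchUpdate:
    def test_prior_absorption(self, healthy):
        counts = CountSet((0.9, 0.1), np.zeros((2, 2)), np.zeros((2, 2)))
        updated = batch_update(healthy, counts)
        assert updated.prior.alpha == pytest.approx((20.9, 80.1), abs=1e-12)
        assert updated.prior.nu == pytest.approx(101.0)

    def test_zero_counts_identity(self, chronic):
        updated = batch_update(chronic, CountSet.zeros())
        assert updated.prior.lam == pytest.approx(chronic.prior.lam)
        assert updated.transition.mean_matrix() == pytest.approx(
            chronic.transition.mean_matrix()
        )

    def test_chronic_fully_noxious_sweep(self, chronic):
        # q(pain) ~= 1 at every node pushes ~20 noxious counts into the pain row
        counts = CountSet(
            (1.0, 0.0),
            np.array([[19.0, 0.0], [0.0, 0.0]]),
            np.array([[20.0, 0.0], [0.0, 0.0]]),
        )
        updated = batch_update(chronic, counts)
        pain_row = updated.likelihood.rows[0]
        assert pain_row.nu == pytest.approx(40.0)
        assert pain_row.lam[0] == pytest.approx(32 / 40)
        assert pain_row.lam[0] > 0.6

    def test_shape_mismatch_rejected(self, healthy):
        bad = CountSet(np.zeros(3), np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            batch_update(healthy, bad)


class TestRunLearning:
    def test_no_evidence_case(self, healthy):
        obs = ObservationSchedule((UNOBSERVED,) * 20)
        run = run_learning(healthy, [obs])
        assert run.trajectories[0] == pytest.approx(
            np.full(20, healthy.prior.lam[0]), abs=1e-10
        )
        assert run.final_model.prior.nu == pytest.approx(101.0)

    def test_empty_schedules_rejected(self, healthy):
        with pytest.raises(ValueError):
            run_learning(healthy, [])

    def test_chronic_mixed_flat(self, chronic):
        from painchain import observation_schedule

        run = run_learning(chronic, [observation_schedule("mixed", 20)] * 40)
        ranges = run.trajectories.max(axis=1) - run.trajectories.min(axis=1)
        assert np.all(ranges < 0.15)

    def test_healthy_all_noxious_learning_direction(self, healthy):
        obs = ObservationSchedule(("noxious",) * 20)
        run = run_learning(healthy, [obs] * 40)
        interior = run.trajectories[:, 1:-1].mean(axis=1)
        assert interior[-1] >= interior[0]

    def test_count_conservation(self, chronic):
        obs = ObservationSchedule(
            ("noxious",) * 3 + (UNOBSERVED,) * 10 + ("harmless",) * 7
        )
        n_trials, n_obs = 7, 10
        run = run_learning(chronic, [obs] * n_trials)
        final = run.final_model
        assert final.prior.nu == pytest.approx(100.0 + n_trials, abs=1e-8)
        trans_nu = sum(r.nu for r in final.transition.rows)
        assert trans_nu == pytest.approx(200.0 + n_trials * 19, abs=1e-7)
        lik_nu = sum(r.nu for r in final.likelihood.rows)
        assert lik_nu == pytest.approx(40.0 + n_trials * n_obs, abs=1e-7)

    def test_learn_false_keeps_model(self, healthy):
        obs = ObservationSchedule(("noxious",) * 20)
        run = run_learning(healthy, [obs] * 3, learn=False)
        assert run.final_model.prior.nu == 100.0
        assert run.trajectories[0] == pytest.approx(run.trajectories[2], abs=1e-15)

    def test_to_frame_shape(self, healthy):
        obs = ObservationSchedule((UNOBSERVED,) * 20)
        frame = run_learning(healthy, [obs] * 4).to_frame()
        assert len(frame) == 80
        assert list(frame.columns) == ["trial", "time_step", "q_pain", "free_energy"]
        assert frame["trial"].min() == 1 and frame["time_step"].max() == 20


class TestFreeEnergyDescent:
    @pytest.mark.parametrize("param", ["mean", "geometric"])
    def test_nonincreasing_on_fixed_data(self, param, chronic):
        from painchain import observation_schedule

        run = run_learning(
            chronic, [observation_schedule("mixed", 20)] * 50, parameterization=param
        )
        assert np.all(np.diff(run.free_energies) <= 1e-9)


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_healthy_preset(self, seed):
        truth = preset_observer("healthy")
        sequences = sample_generative(truth, seed, 200)
        model = uniform_model(n_steps=20, nu=2.0)
        for hidden, obs in sequences:
            counts = path_counts(model, hidden, ObservationSchedule(obs))
            model = batch_update(model, counts)
        assert np.max(
            np.abs(model.likelihood.mean_matrix() - truth.likelihood.mean_matrix())
        ) < 0.05
        assert np.max(
            np.abs(model.transition.mean_matrix() - truth.transition.mean_matrix())
        ) < 0.05
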