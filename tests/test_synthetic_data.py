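"""Generator contract: block structure, kernel fidelity, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import gogomarkov as gm
from gogomarkov import synthetic_data as sd
from conftest import small_config


def profile(pid="p01", gender="male", offset=0.0):
    return sd.ParticipantProfile(participant_id=pid, gender=gender, coffee=False, mood=1, rt_offset_ms=offset)


def flat_rt(anticipatory_rate=0.0, **kw):
    kwargs = dict(baseline_mean_ms={"2D": 450.0, "3D": 520.0, "AR": 620.0},
                  anticipatory_rate=anticipatory_rate, participant_offset_sd_ms=0.0)
    kwargs.update(kw)
    return sd.RTModel(**kwargs)


class TestGenerateBlock:
    def test_block_has_exactly_trials_per_block(self):
        config = sd.GeneratorConfig(seed=3)
        block = sd.generate_block(config, profile(), sd.AccuracyKernel.constant(0.9), flat_rt(), "2D")
        assert len(block) == 120
        assert list(block["trial_index"]) == list(range(1, 121))

    def test_perfect_kernel_yields_all_correct(self):
        config = small_config(seed=5)
        block = sd.generate_block(config, profile(), sd.AccuracyKernel.constant(1.0), flat_rt(), "3D")
        assert (block["correct"] == 1).all()
        assert (block["response_direction"] == block["stimulus_direction"]).all()

    def test_incorrect_trials_mismatch_stimulus(self):
        config = small_config(seed=5, trials_per_block=200)
        block = sd.generate_block(config, profile(), sd.AccuracyKernel.constant(0.5), flat_rt(), "2D")
        wrong = block[block["correct"] == 0]
        assert len(wrong) > 0
        assert (wrong["response_direction"] != wrong["stimulus_direction"]).all()

    def test_empirical_accuracy_matches_kernel(self):
        # binomial oracle: 10,000 trials at p=0.8 -> within 3 SE = 0.012
        config = sd.GeneratorConfig(trials_per_block=10_000, seed=11)
        block = sd.generate_block(config, profile(), sd.AccuracyKernel.constant(0.8), flat_rt(), "2D")
        assert abs(block["correct"].mean() - 0.8) < 0.012

    def test_conditional_accuracy_matches_order1_kernel(self):
        kernel = sd.AccuracyKernel(order=1, probs={(0,): 0.9, (1,): 0.6})
        config = sd.GeneratorConfig(trials_per_block=10_000, seed=12)
        block = sd.generate_block(config, profile(), kernel, flat_rt(), "2D")
        x = block["correct"].to_numpy()
        for prev, p_true in kernel.probs.items():
            follows = x[1:][x[:-1] == prev[0]]
            se = np.sqrt(p_true * (1 - p_true) / follows.size)
            assert abs(follows.mean() - p_true) < 3 * se

    def test_isi_within_configured_range(self):
        config = small_config(seed=1)
        block = sd.generate_block(config, profile(), sd.AccuracyKernel.constant(0.9), flat_rt(), "2D")
        assert block["isi_s"].between(*config.isi_range_s).all()

    def test_anticipatory_fraction_matches_rate(self):
        # all anticipatory draws fall below 200 ms; genuine RTs essentially never do
        config = sd.GeneratorConfig(trials_per_block=10_000, seed=13)
        block = sd.generate_block(config, profile(), sd.AccuracyKernel.constant(0.9),
                                  flat_rt(anticipatory_rate=0.05), "2D")
        frac = (block["rt_ms"] < 200).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 10_000)

    def test_unknown_environment_rejected(self):
        config = small_config()
        with pytest.raises(sd.ConfigurationError):
            sd.generate_block(config, profile(), sd.AccuracyKernel.constant(0.9), flat_rt(), "VR")

    def test_history_shift_applied_to_mean(self):
        # depth-1 shift: +80 ms after an error, huge n, tiny noise
        shift = {"2D": {(0, 0): 80.0, (0, 1): 80.0, (1, 0): 0.0, (1, 1): 0.0}}
        rt = flat_rt(history_shift_ms=shift, sd_ms=1.0)
        config = sd.GeneratorConfig(trials_per_block=5000, seed=21)
        block = sd.generate_block(config, profile(), sd.AccuracyKernel.constant(0.7), rt, "2D")
        x = block["correct"].to_numpy()
        r = block["rt_ms"].to_numpy()
        assert r[1:][x[:-1] == 0].mean() == pytest.approx(530.0, abs=1.0)
        assert r[1:][x[:-1] == 1].mean() == pytest.approx(450.0, abs=1.0)


class TestGenerateCohort:
    def test_default_cohort_shape(self, default_cohort):
        trials, profiles = default_cohort
        assert len(profiles) == 22
        assert sum(p.gender == "female" for p in profiles) == 6
        assert trials.groupby(["participant_id", "environment"]).ngroups == 66
        per_participant = trials.groupby("participant_id").size()
        assert (per_participant == 360).all()

    def test_empty_cohort(self):
        config = small_config(n_participants=0, n_female=0)
        kernels = {env: sd.AccuracyKernel.constant(0.9) for env in config.environments}
        trials, profiles = sd.generate_cohort(config, kernels, flat_rt())
        assert trials.empty and profiles == []

    def test_seed_determinism(self, small_cohort):
        config, kernels, rt_model, trials, profiles = small_cohort
        again, profiles2 = sd.generate_cohort(config, kernels, rt_model)
        pd.testing.assert_frame_equal(trials, again)
        assert profiles == profiles2

    def test_generation_order_invariance(self, small_cohort):
        # each block depends only on (seed, participant, environment)
        config, kernels, rt_model, trials, profiles = small_cohort
        for prof in reversed(profiles):
            for env in reversed(config.environments):
                block = sd.generate_block(config, prof, kernels[env], rt_model, env)
                expected = trials[(trials["participant_id"] == prof.participant_id)
                                  & (trials["environment"] == env)].reset_index(drop=True)
                pd.testing.assert_frame_equal(block, expected)

    def test_too_many_females_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(n_participants=4, n_female=5)

    def test_missing_kernel_rejected(self):
        config = small_config()
        with pytest.raises(sd.ConfigurationError):
            sd.generate_cohort(config, {"2D": sd.AccuracyKernel.constant(0.9)}, flat_rt())


class TestKernelAndDesign:
    def test_incomplete_kernel_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.AccuracyKernel(order=2, probs={(0, 0): 0.5, (0, 1): 0.5, (1, 1): 0.5})

    def test_probability_bounds_enforced(self):
        with pytest.raises(sd.ConfigurationError):
            sd.AccuracyKernel(order=0, probs={(): 1.2})

    def test_window_joint_matches_two_state_chain_closed_form(self):
        # stationary pi(V) of a 2-state chain: p(V|F) / (1 - p(V|V) + p(V|F))
        kernel = sd.AccuracyKernel(order=1, probs={(0,): 0.95, (1,): 0.78})
        joint = sd.window_joint(kernel, 1)
        pi_v = 0.95 / (1 - 0.78 + 0.95)
        assert joint[(1,)] == pytest.approx(pi_v, abs=1e-12)
        pair = sd.window_joint(kernel, 2)
        assert sum(pair.values()) == pytest.approx(1.0, abs=1e-12)
        assert pair[(1, 0)] == pytest.approx(pi_v * (1 - 0.78), abs=1e-12)

    @pytest.mark.parametrize("env,order", [("3D", 1), ("AR", 2)])
    def test_masked_shift_has_zero_marginal_covariance(self, defaults, env, order):
        # all lags below the target order carry no linear marginal association
        _, kernels, rt_model = defaults
        table = rt_model.history_shift_ms[env]
        cov = sd.window_covariance(kernels[env], order + 1)
        coef = np.array([table[tuple(1 if i == order - lag else 0 for i in range(order + 1))]
                         for lag in range(order + 1)])
        marginal = cov @ coef
        assert np.allclose(marginal[:order], 0.0, atol=1e-9)
        assert abs(marginal[order]) > 0
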