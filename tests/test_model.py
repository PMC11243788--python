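"""Attention primitives, GRU cell semantics, training loop and persistence."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgknee as ek
from emgknee.model import (GruAmConfig, KneeAngleGRU, alignment_score,
                           attention_weights, context_vector, forward_infer,
                           gru_baseline_config, gru_cell_np, init_params,
                           n_params)


class TestAlignmentScore:
    def test_zero_va_gives_zero(self):
        rng = np.random.default_rng(0)
        assert alignment_score(np.zeros(4), rng.random((3, 4)), rng.random((3, 4)),
                               rng.random(3), rng.random(3)) == 0.0

    def test_zero_projections_give_zero(self):
        assert alignment_score(np.ones(4), np.zeros((3, 4)), np.zeros((3, 4)),
                               np.ones(3), np.ones(3)) == 0.0

    def test_scalar_hand_value(self):
        # Va=1, Ua=0, Wa=1, h_j=0.5 -> tanh(0.5)
        s = alignment_score(np.array([1.0]), np.array([[0.0]]),
                            np.array([[1.0]]), np.array([0.0]), np.array([0.5]))
        assert s == pytest.approx(np.tanh(0.5))
        assert s == pytest.approx(0.46212, abs=1e-5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            alignment_score(np.ones(3), np.ones((2, 4)), np.ones((2, 4)),
                            np.ones(2), np.ones(2))


class TestAttentionWeights:
    def test_equal_scores_uniform(self):
        np.testing.assert_allclose(attention_weights([2.0] * 4), 0.25)

    def test_log_two_closed_form(self):
        np.testing.assert_allclose(attention_weights([0.0, np.log(2)]),
                                   [1 / 3, 2 / 3])

    def test_single_element(self):
        np.testing.assert_allclose(attention_weights([5.0]), [1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            attention_weights([1.0, np.inf])

    @settings(max_examples=50, deadline=None)
    @given(scores=st.lists(st.floats(-30, 30, allow_nan=False),
                           min_size=1, max_size=20))
    def test_weights_sum_to_one_and_positive(self, scores):
        w = attention_weights(scores)
        assert np.all(w > 0)
        assert w.sum() == pytest.approx(1.0)


class TestContextVector:
    def test_single_state(self):
        h = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(context_vector([1.0], h), h[0])

    def test_identical_states_convexity(self):
        h = np.tile([2.0, -1.0], (4, 1))
        np.testing.assert_allclose(context_vector([0.1, 0.2, 0.3, 0.4], h),
                                   [2.0, -1.0])

    def test_scalar_weighted_sum(self):
        assert context_vector([0.25, 0.75], np.array([[1.0], [3.0]]))[0] == 2.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            context_vector([0.5, 0.5], np.ones((3, 2)))

    @settings(max_examples=50, deadline=None)
    @given(m=st.integers(2, 8), h_dim=st.integers(1, 6),
           seed=st.integers(0, 1000))
    def test_convex_hull_and_permutation_invariance(self, m, h_dim, seed):
        rng = np.random.default_rng(seed)
        h = rng.standard_normal((m, h_dim))
        w = attention_weights(rng.standard_normal(m))
        c = context_vector(w, h)
        assert np.all(c <= h.max(axis=0) + 1e-12)
        assert np.all(c >= h.min(axis=0) - 1e-12)
        perm = rng.permutation(m)
        np.testing.assert_allclose(context_vector(w[perm], h[perm]), c)


class TestGruCell:
    def test_zero_weights_fixed_point(self):
        """With all weights and biases zero: z=r=1/2, n=0, h' = h/2."""
        H = 4
        p = {f"g_{k}{g}": np.zeros((H, H)) for k in "WU" for g in "zrn"}
        p = {"g_Wz": np.zeros((H, H)), "g_Uz": np.zeros((H, H)),
             "g_bz": np.zeros(H), "g_Wr": np.zeros((H, H)),
             "g_Ur": np.zeros((H, H)), "g_br": np.zeros(H),
             "g_Wn": np.zeros((H, H)), "g_Un": np.zeros((H, H)),
             "g_bn": np.zeros(H)}
        h = np.ones((1, H))
        for step in range(1, 4):
            h = gru_cell_np(p, "g", np.ones((1, H)), h)
            np.testing.assert_allclose(h, 0.5 ** step)

    def test_matches_hand_evaluated_scalar_cell(self):
        rng = np.random.default_rng(3)
        p = {f"g_{m}{g}": rng.standard_normal((1, 1)) for m in "WU" for g in "zrn"}
        p.update({f"g_b{g}": rng.standard_normal(1) for g in "zrn"})
        x, h = np.array([[0.3]]), np.array([[-0.2]])
        sig = lambda v: 1 / (1 + np.exp(-v))
        z = sig(x * p["g_Wz"] + h * p["g_Uz"] + p["g_bz"])
        r = sig(x * p["g_Wr"] + h * p["g_Ur"] + p["g_br"])
        n = np.tanh(x * p["g_Wn"] + (r * h) * p["g_Un"] + p["g_bn"])
        expected = (1 - z) * n + z * h
        np.testing.assert_allclose(gru_cell_np(p, "g", x, h), expected)


class TestEstimator:
    def test_output_shape_and_range(self, hv8_dataset, tiny_cfg):
        res = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=1)
        est = res.estimate_cycle(hv8_dataset.test_cycles[0])
        assert est.shape == (100,)
        assert est.min() >= res.stats.angle_min - 1e-9
        assert est.max() <= res.stats.angle_max + 1e-9

    def test_channel_mismatch_names_offenders(self, hv8_dataset, tiny_cfg):
        res = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=0)
        bad = hv8_dataset.drop_channel("RF").cycles[0]
        with pytest.raises(ValueError, match="RF"):
            res.estimate_cycle(bad)

    def test_zero_epochs_returns_initialized_model(self, hv8_dataset, tiny_cfg):
        res = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=0)
        assert res.n_epochs == 0
        assert res.history.empty
        expected = init_params(tiny_cfg, tiny_cfg.segment_window)
        for k, v in expected.items():
            np.testing.assert_array_equal(res.params[k], v)

    def test_identical_seeds_identical_fits(self, hv8_dataset, tiny_cfg):
        r1 = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=2)
        r2 = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=2)
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])

    def test_attention_weights_sum_to_one_at_every_decoder_step(
            self, hv8_dataset, tiny_cfg):
        """Instrumented forward: softmax normalization holds at every step."""
        from emgknee import _autodiff as ad
        recorded = []
        orig = ad.softmax

        def spy(a, axis=-1):
            out = orig(a, axis=axis)
            recorded.append(out.data.sum(axis=axis))
            return out
        ad.softmax = spy
        try:
            from emgknee.model import training_loss
            from emgknee._autodiff import Tensor
            from emgknee.gait import dataset_arrays
            X, Y = dataset_arrays(hv8_dataset.train_cycles[:2],
                                  hv8_dataset.stats, 20)
            P = {k: Tensor(v, requires_grad=True)
                 for k, v in init_params(tiny_cfg, 20).items()}
            training_loss(P, X, Y, tiny_cfg)
        finally:
            ad.softmax = orig
        assert len(recorded) == 100          # one per decoder step
        for s in recorded:
            np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_save_load_estimates_bit_identical(self, hv8_dataset, tiny_cfg,
                                               tmp_path):
        res = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=2)
        before = res.estimate_cycle(hv8_dataset.test_cycles[0])
        res.save(tmp_path / "model")
        loaded = ek.KneeAngleGRUResults.load(tmp_path / "model")
        after = loaded.estimate_cycle(hv8_dataset.test_cycles[0])
        np.testing.assert_array_equal(before, after)

    def test_summary_mentions_model_and_epochs(self, hv8_dataset, tiny_cfg):
        res = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=1)
        text = res.summary()
        assert "GRU-AM" in text
        assert "Epochs run:         1" in text


class TestBaseline:
    def test_param_count_difference_is_attention_block(self, tiny_cfg):
        H, A = tiny_cfg.hidden_size, tiny_cfg.attention_size
        p_am = init_params(tiny_cfg, 20)
        p_gru = init_params(gru_baseline_config(tiny_cfg), 20)
        assert n_params(p_am) - n_params(p_gru) == 2 * H * A + A

    def test_single_encoder_step_makes_variants_identical(self):
        """With M=1 the attention context equals h(M): same predictions."""
        cfg = GruAmConfig(hidden_size=6, attn_size=5, segment_window=20,
                          L=20, seed=1)
        rng = np.random.default_rng(0)
        X = rng.random((3, 1, 20))           # one channel, one time window
        p_am = init_params(cfg, 20)
        y_am = forward_infer(p_am, X, cfg)
        cfg_b = gru_baseline_config(cfg)
        p_gru = {k: v for k, v in p_am.items() if not k.startswith("att_")}
        y_gru = forward_infer(p_gru, X, cfg_b)
        np.testing.assert_allclose(y_am, y_gru, atol=1e-12)

    def test_baseline_trains_deterministically(self, hv8_dataset, tiny_cfg):
        cfg = gru_baseline_config(tiny_cfg)
        r1 = KneeAngleGRU(hv8_dataset, cfg).fit(max_epochs=2)
        r2 = KneeAngleGRU(hv8_dataset, cfg).fit(max_epochs=2)
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])


class TestTrainingLoop:
    def test_loss_decreases(self, hv8_dataset):
        cfg = GruAmConfig(hidden_size=16, attn_size=12, seed=0, rmse_stop=1.0)
        res = KneeAngleGRU(hv8_dataset, cfg).fit(max_epochs=15)
        first, last = res.history["loss"].iloc[0], res.history["loss"].iloc[-1]
        assert last < first

    def test_history_records_both_criteria(self, hv8_dataset, tiny_cfg):
        res = KneeAngleGRU(hv8_dataset, tiny_cfg).fit(max_epochs=2)
        assert list(res.history.columns) == ["epoch", "loss", "train_rmse_deg"]
        assert res.stop_reason in ("rmse", "max_epochs")

    def test_mse_loss_variant_runs(self, hv8_dataset):
        cfg = GruAmConfig(hidden_size=8, attn_size=6, seed=0, loss="mse")
        res = KneeAngleGRU(hv8_dataset, cfg).fit(max_epochs=2)
        assert res.n_epochs == 2

    def test_empty_training_set_rejected(self, hv8_dataset, tiny_cfg):
        from emgknee.gait import GaitCycleDataset
        empty = GaitCycleDataset(cycles=hv8_dataset.cycles,
                                 split=["test"] * len(hv8_dataset.cycles),
                                 stats=hv8_dataset.stats, train_frac=0.6)
        with pytest.raises(ValueError):
            KneeAngleGRU(empty, tiny_cfg)


class TestLearnability:
    def test_angle_as_scaled_envelope_copy_learned_below_5_deg(self, presets):
        """When the angle is a scaled copy of one channel's envelope, the
        trained estimator reconstructs held-out strides to < 5 deg RMSE."""
        from emgknee.io import AngleSeries
        trial = presets["shared6"].synthesize(n_strides=14, seed=3,
                                              noise_scale=0.05)
        rf = trial.emg.channels.index("RF")
        step = int(trial.emg.rate_hz / trial.angle.rate_hz)
        env_rf = trial.envelopes[::step, rf][:trial.angle.n_samples]
        angle = AngleSeries(rate_hz=trial.angle.rate_hz,
                            values=10.0 + 40.0 * env_rf)
        emg, ang = ek.align_streams(trial.emg, angle)
        cond = ek.condition(emg)
        cycles = [ek.time_normalize(c)
                  for c in ek.split_cycles(cond, ang, trial.events)]
        ds = ek.make_dataset(cycles, 0.6)
        cfg = GruAmConfig(hidden_size=32, attn_size=32, seed=1, rmse_stop=2.0)
        res = KneeAngleGRU(ds, cfg).fit(max_epochs=400)
        ev = res.evaluate(ds.test_cycles)
        assert ev["rmse"].mean() < 5.0
        assert ev["cc"].mean() > 0.9
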