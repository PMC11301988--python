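import numpy as np
import pandas as pd
import pytest

from metakinase.dataset import sample_episode
from metakinase.ilmc import TowerParams, loss_and_grad, loss_value
from metakinase.meta import (
    MetaConfig,
    _inner_trajectory,
    _meta_gradient_one_task,
    few_shot_adapt,
    inner_adapt,
    meta_step_arrays,
    meta_train,
    predict_new,
    rank_kinases,
)
from metakinase.ilmc import predict_proba
from metakinase.seeding import substream


@pytest.fixture
def task(tiny_batch):
    rng = np.random.default_rng(21)
    q = (rng.normal(size=(10, 2)), rng.normal(size=(10, 2)),
         (rng.random(10) < 0.5).astype(float))
    return tiny_batch, q


class TestInnerAdapt:
    def test_zero_lr_is_identity(self, tiny_params, tiny_batch):
        Xc, Xp, y = tiny_batch
        out = inner_adapt(tiny_params, Xc, Xp, y, inner_lr=0.0, inner_steps=4)
        assert np.array_equal(out.theta, tiny_params.theta)

    def test_zero_steps_is_identity(self, tiny_params, tiny_batch):
        Xc, Xp, y = tiny_batch
        out = inner_adapt(tiny_params, Xc, Xp, y, inner_lr=0.05, inner_steps=0)
        assert np.array_equal(out.theta, tiny_params.theta)

    def test_input_params_unmodified(self, tiny_params, tiny_batch):
        Xc, Xp, y = tiny_batch
        snapshot = tiny_params.theta.copy()
        inner_adapt(tiny_params, Xc, Xp, y, inner_lr=0.1, inner_steps=3)
        assert np.array_equal(tiny_params.theta, snapshot)

    def test_single_step_equals_explicit_gradient_step(self, tiny_params, tiny_batch):
        Xc, Xp, y = tiny_batch
        alpha = 0.05
        out = inner_adapt(tiny_params, Xc, Xp, y, alpha, 1, lambda_reg=1e-4)
        _, g = loss_and_grad(tiny_params.theta, tiny_params.arch, Xc, Xp, y, 1e-4)
        assert np.allclose(out.theta, tiny_params.theta - alpha * g, atol=1e-12)

    def test_empty_support_rejected(self, tiny_params):
        with pytest.raises(ValueError, match="empty"):
            inner_adapt(tiny_params, np.empty((0, 2)), np.empty((0, 2)), np.empty(0), 0.1, 1)


class TestMetaStep:
    def test_zero_outer_lr_keeps_params(self, tiny_params, task):
        cfg = MetaConfig(inner_lr=0.05, outer_lr=0.0, inner_steps=2)
        theta, _ = meta_step_arrays(
            tiny_params.theta.copy(), tiny_params.arch, [task], cfg
        )
        assert np.array_equal(theta, tiny_params.theta)

    def test_zero_inner_steps_reduces_to_query_gradient(self, tiny_params, task):
        cfg = MetaConfig(inner_lr=0.05, outer_lr=0.1, inner_steps=0)
        theta, _ = meta_step_arrays(
            tiny_params.theta.copy(), tiny_params.arch, [task], cfg
        )
        _, gq = loss_and_grad(
            tiny_params.theta, tiny_params.arch, *task[1], cfg.lambda_reg
        )
        assert np.allclose(theta, tiny_params.theta - 0.1 * gq, atol=1e-12)

    def test_first_equals_second_order_without_inner_steps(self, tiny_params, task):
        grads = {}
        for order in ("first", "second"):
            cfg = MetaConfig(inner_lr=0.05, inner_steps=0, order=order)
            _, grads[order] = _meta_gradient_one_task(
                tiny_params.theta, tiny_params.arch, task, cfg
            )
        assert np.array_equal(grads["first"], grads["second"])

    def test_second_order_matches_composite_finite_differences(self, tiny_params, task):
        cfg = MetaConfig(inner_lr=0.05, inner_steps=2, order="second", lambda_reg=1e-4)
        arch = tiny_params.arch
        _, g = _meta_gradient_one_task(tiny_params.theta, arch, task, cfg)

        def composite(theta):
            it = _inner_trajectory(
                theta, arch, *task[0], cfg.inner_lr, cfg.inner_steps, cfg.lambda_reg
            )
            return loss_value(it[-1], arch, *task[1], cfg.lambda_reg)

        h = 1e-5
        fd = np.array([
            (composite(tiny_params.theta + h * e) - composite(tiny_params.theta - h * e)) / (2 * h)
            for e in np.eye(tiny_params.theta.size)
        ])
        rel = np.abs(g - fd) / np.maximum(np.abs(fd), 1e-8)
        assert rel.max() < 1e-3

    def test_empty_query_rejected(self, tiny_params, tiny_batch):
        bad = (tiny_batch, (np.empty((0, 2)), np.empty((0, 2)), np.empty(0)))
        cfg = MetaConfig()
        with pytest.raises(ValueError, match="query"):
            meta_step_arrays(tiny_params.theta.copy(), tiny_params.arch, [bad], cfg)


class TestMetaTrain:
    def small_config(self, **kw):
        defaults = dict(
            inner_lr=0.01, outer_lr=0.01, inner_steps=2, outer_iterations=3,
            hidden=(8,), embedding_dim=4, seed=0,
        )
        defaults.update(kw)
        return MetaConfig(**defaults)

    def test_determinism(self, tiny_world):
        runs = [
            meta_train(
                tiny_world.split, tiny_world.compound_features,
                tiny_world.kinase_features, self.small_config(),
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0].theta, runs[1][0].theta)
        assert runs[0][1] == runs[1][1]

    def test_zero_outer_lr_returns_initialization(self, tiny_world):
        cfg = self.small_config(outer_lr=0.0)
        params, _ = meta_train(
            tiny_world.split, tiny_world.compound_features,
            tiny_world.kinase_features, cfg,
        )
        from metakinase.ilmc import TowerArch, init_params

        ref = init_params(
            TowerArch(tiny_world.compound_features.d, tiny_world.kinase_features.d,
                      (8,), 4),
            seed=cfg.seed,
        )
        assert np.array_equal(params.theta, ref.theta)

    def test_query_loss_decreases(self, tiny_world):
        cfg = self.small_config(outer_iterations=40, outer_lr=0.02)
        _, history = meta_train(
            tiny_world.split, tiny_world.compound_features,
            tiny_world.kinase_features, cfg,
        )
        assert np.mean(history[-10:]) < np.mean(history[:10])

    def test_infeasible_episode_sizes_named(self, tiny_world):
        cfg = self.small_config(n_support_per_class=80, n_query_per_class=80)
        with pytest.raises(ValueError, match="head task"):
            meta_train(
                tiny_world.split, tiny_world.compound_features,
                tiny_world.kinase_features, cfg,
            )


class TestFewShotAdapt:
    def adapt(self, tiny_world, cfg, kid=None):
        kid = kid or tiny_world.tail_kinases[0]
        from metakinase.ilmc import TowerArch, init_params

        meta_params = init_params(
            TowerArch(tiny_world.compound_features.d, tiny_world.kinase_features.d,
                      (8,), 4),
            seed=3,
        )
        return meta_params, few_shot_adapt(
            meta_params, kid, tiny_world.split.tail_support[kid],
            tiny_world.compound_features, tiny_world.kinase_features, cfg,
        )

    def test_zero_lr_keeps_meta_params(self, tiny_world):
        meta_params, adapted = self.adapt(tiny_world, MetaConfig(inner_lr=0.0))
        assert np.array_equal(adapted.params.theta, meta_params.theta)

    def test_adaptation_reduces_support_loss(self, tiny_world):
        cfg = MetaConfig(inner_lr=0.01, inner_steps=4)
        kid = tiny_world.tail_kinases[1]
        meta_params, adapted = self.adapt(tiny_world, cfg, kid)
        from metakinase.ilmc import pair_features

        Xc, Xp, y = pair_features(
            tiny_world.split.tail_support[kid],
            tiny_world.compound_features, tiny_world.kinase_features,
        )
        before = loss_value(meta_params.theta, meta_params.arch, Xc, Xp, y, cfg.lambda_reg)
        after = loss_value(adapted.params.theta, adapted.params.arch, Xc, Xp, y, cfg.lambda_reg)
        assert after <= before

    def test_uses_only_support_set(self, tiny_world):
        """Changing the tail test pairs cannot change the adapted parameters."""
        cfg = MetaConfig(inner_lr=0.01, inner_steps=2)
        kid = tiny_world.tail_kinases[0]
        _, a1 = self.adapt(tiny_world, cfg, kid)
        original_test = tiny_world.split.tail_test[kid]
        try:
            tiny_world.split.tail_test[kid] = original_test.iloc[:3]
            _, a2 = self.adapt(tiny_world, cfg, kid)
        finally:
            tiny_world.split.tail_test[kid] = original_test
        assert np.array_equal(a1.params.theta, a2.params.theta)

    def test_provenance_recorded(self, tiny_world):
        _, adapted = self.adapt(tiny_world, MetaConfig())
        assert adapted.provenance["support_fingerprint"]
        assert adapted.provenance["inner_steps"] == 4


class TestPrediction:
    def test_predict_new_delegates_to_forward_pass(self, tiny_world):
        from metakinase.ilmc import TowerArch, init_params
        from metakinase.meta import AdaptedModel

        kid = tiny_world.tail_kinases[0]
        params = init_params(
            TowerArch(tiny_world.compound_features.d, tiny_world.kinase_features.d,
                      (8,), 4),
            seed=9,
        )
        adapted = AdaptedModel(kid, params, {"meta_checkpoint": "x"})
        x_new = tiny_world.compound_features.matrix[0]
        expected = predict_proba(x_new, tiny_world.kinase_features.row(kid), params)
        assert predict_new(x_new, adapted, tiny_world.kinase_features) == expected
        assert predict_new(x_new, adapted, tiny_world.kinase_features.row(kid)) == expected

    def test_rank_kinases_order_and_ties(self, tiny_world):
        from metakinase.ilmc import TowerArch, init_params

        kids = tiny_world.kinase_features.ids[:4]
        params = init_params(
            TowerArch(tiny_world.compound_features.d, tiny_world.kinase_features.d,
                      (8,), 4),
            seed=11,
        )
        x_c = tiny_world.compound_features.matrix[5]
        ranking = rank_kinases(x_c, {k: params for k in kids}, tiny_world.kinase_features)
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)
        # matches sorting the individually computed scores (stable by id on ties)
        expected = sorted(
            ((k, predict_proba(x_c, tiny_world.kinase_features.row(k), params)) for k in kids),
            key=lambda t: (-t[1], t[0]),
        )
        assert ranking == expected
        top2 = rank_kinases(x_c, {k: params for k in kids}, tiny_world.kinase_features, top=2)
        assert top2 == expected[:2]

    def test_rank_requires_models(self, tiny_world):
        with pytest.raises(ValueError):
            rank_kinases(np.zeros(16), {}, tiny_world.kinase_features)
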