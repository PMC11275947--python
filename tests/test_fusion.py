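import numpy as np
import pytest

from genet.config import RunConfig
from genet.fusion import (
    RegressorParams,
    build_cross_feature_tensor,
    flatten_tensor,
    fusion_forward,
    fusion_loss_and_grads,
    train_genet,
    unflatten_tensor,
)
from genet.gcn_view import GCNParams, softmax


class TestCrossFeatureTensor:
    def test_one_hot_inputs_single_entry(self):
        e1 = np.array([0.0, 1.0, 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        T = build_cross_feature_tensor(e1, e2)
        assert T[1, 2] == 1.0 and T.sum() == 1.0

    def test_hand_computed_outer_product(self):
        T = build_cross_feature_tensor(np.array([0.5, 0.5]), np.array([0.2, 0.8]))
        assert np.allclose(T, [[0.1, 0.4], [0.1, 0.4]])

    def test_mass_conservation_for_simplex_inputs(self, rng):
        for _ in range(10):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            assert build_cross_feature_tensor(p, q).sum() == pytest.approx(1.0)

    def test_uniform_view_gives_proportional_rows(self, rng):
        c = 4
        q = rng.dirichlet(np.ones(c))
        T = build_cross_feature_tensor(np.full(c, 1 / c), q)
        for i in range(c):
            assert np.allclose(T[i], q / c)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_cross_feature_tensor(np.ones(2) / 2, np.ones(3) / 3)

    def test_batched_matches_per_sample(self, rng):
        P = rng.dirichlet(np.ones(3), size=6)
        Q = rng.dirichlet(np.ones(3), size=6)
        T = build_cross_feature_tensor(P, Q)
        for i in range(6):
            assert np.allclose(T[i], np.outer(P[i], Q[i]))


class TestFlatten:
    def test_row_major_order(self):
        assert flatten_tensor(np.array([[1.0, 2.0], [3.0, 4.0]])).tolist() == [1, 2, 3, 4]

    def test_flatten_unflatten_identity(self, rng):
        T = rng.normal(size=(7, 3, 3))
        assert np.array_equal(unflatten_tensor(flatten_tensor(T), 3), T)

    def test_single_class_is_length_one(self):
        assert flatten_tensor(np.array([[2.5]])).shape == (1,)


class TestFusionForward:
    def test_zero_weights_output_bias(self):
        params = RegressorParams(
            {"Wf0": np.zeros((4, 3)), "bf0": np.zeros(3),
             "Wf1": np.zeros((3, 1)), "bf1": np.array([1.25])}
        )
        assert fusion_forward(np.ones(4), params) == pytest.approx(1.25)

    def test_identity_hidden_summing_output(self):
        v = np.array([0.1, 0.4, 0.1, 0.4])
        params = RegressorParams(
            {"Wf0": np.eye(4), "bf0": np.zeros(4),
             "Wf1": np.ones((4, 1)), "bf1": np.zeros(1)}
        )
        assert fusion_forward(v, params) == pytest.approx(1.0)

    def test_linear_in_positive_region(self, rng):
        params = RegressorParams(
            {"Wf0": np.abs(rng.normal(size=(4, 5))), "bf0": np.ones(5),
             "Wf1": rng.normal(size=(5, 1)), "bf1": np.zeros(1)}
        )
        v1, v2 = np.abs(rng.normal(size=4)), np.abs(rng.normal(size=4))
        f = lambda v: fusion_forward(v, params)
        assert f(v1) + f(v2) == pytest.approx(f(v1 + v2) + f(np.zeros(4)), rel=1e-9)


def _tiny_instance(seed=0, n=5, d=4, h=6, c=3, fh=7):
    rng = np.random.default_rng(seed)
    X_tf = rng.normal(size=(n, d))
    X_hm = rng.normal(size=(n, d))
    A = rng.uniform(size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    y = rng.normal(size=n)
    mask = np.ones(n, bool)
    p_tf = GCNParams.init(rng, d, h, c)
    p_hm = GCNParams.init(rng, d, h, c)
    head = RegressorParams.init(rng, c, fh)
    return X_tf, X_hm, A, y, mask, p_tf, p_hm, head


def test_end_to_end_gradient_matches_finite_differences():
    """Backprop through head, tensor, softmaxes and both GCNs vs central FD."""
    X_tf, X_hm, A, y, mask, p_tf, p_hm, head = _tiny_instance()
    loss0, grads = fusion_loss_and_grads(
        X_tf, X_hm, A, A, y, mask, p_tf, p_hm, head
    )
    groups = {"tf": p_tf.weights, "hm": p_hm.weights, "head": head.weights}
    h_step = 1e-6
    for gname, weights in groups.items():
        for key, W in weights.items():
            g_num = np.zeros_like(W)
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = W[idx]
                W[idx] = orig + h_step
                lp, _ = fusion_loss_and_grads(X_tf, X_hm, A, A, y, mask, p_tf, p_hm, head)
                W[idx] = orig - h_step
                lm, _ = fusion_loss_and_grads(X_tf, X_hm, A, A, y, mask, p_tf, p_hm, head)
                W[idx] = orig
                g_num[idx] = (lp - lm) / (2 * h_step)
            g_bp = grads[gname][key].reshape(g_num.shape)
            denom = max(np.abs(g_num).max(), 1e-8)
            assert np.abs(g_bp - g_num).max() / denom < 1e-4, (gname, key)


def _small_training_setup(tiny_dataset, fast_config):
    from genet.pipeline import featurize_views
    from genet.simnet import build_similarity_graph
    from genet.train_eval import split_samples

    ds = tiny_dataset
    fm_tf, fm_hm, y = featurize_views(
        ds.peaks, ds.genes, ds.cell_lines, ds.expression, fast_config
    )
    g_tf = build_similarity_graph(fm_tf, fast_config.avg_degree)
    g_hm = build_similarity_graph(fm_hm, fast_config.avg_degree)
    masks = split_samples(len(y), fast_config.fractions, fast_config.seed)
    return fm_tf, fm_hm, g_tf, g_hm, y, masks


def test_train_genet_deterministic_given_seed(tiny_dataset, fast_config):
    fm_tf, fm_hm, g_tf, g_hm, y, masks = _small_training_setup(tiny_dataset, fast_config)
    out = [
        train_genet(
            fm_tf.values, fm_hm.values, g_tf.norm_adjacency, g_hm.norm_adjacency,
            y, masks.as_dict(), fast_config,
        )[1]
        for _ in range(2)
    ]
    assert np.array_equal(out[0], out[1])


def test_train_genet_predictions_finite_and_scaled(tiny_dataset, fast_config):
    fm_tf, fm_hm, g_tf, g_hm, y, masks = _small_training_setup(tiny_dataset, fast_config)
    model, yhat, history = train_genet(
        fm_tf.values, fm_hm.values, g_tf.norm_adjacency, g_hm.norm_adjacency,
        y, masks.as_dict(), fast_config,
    )
    assert yhat.shape == y.shape and np.isfinite(yhat).all()
    # predictions come back on the raw expression scale, not standardized
    assert np.abs(np.mean(yhat) - np.mean(y)) < 3 * np.std(y)
    assert len(history["val_mse"]) <= fast_config.epochs


def test_checkpoint_round_trip_preserves_predictions(
    tiny_dataset, fast_config, tmp_path
):
    from genet.fusion import GenetModel

    fm_tf, fm_hm, g_tf, g_hm, y, masks = _small_training_setup(tiny_dataset, fast_config)
    model, yhat, _ = train_genet(
        fm_tf.values, fm_hm.values, g_tf.norm_adjacency, g_hm.norm_adjacency,
        y, masks.as_dict(), fast_config,
    )
    model.save(str(tmp_path / "model.npz"))
    back = GenetModel.load(str(tmp_path / "model.npz"))
    yhat2 = back.predict(
        fm_tf.values, fm_hm.values, g_tf.norm_adjacency, g_hm.norm_adjacency
    )
    assert np.array_equal(yhat, yhat2)


def test_view_probabilities_stay_on_simplex_after_fusion_training(
    tiny_dataset, fast_config
):
    from genet.gcn_view import gcn_forward

    fm_tf, fm_hm, g_tf, g_hm, y, masks = _small_training_setup(tiny_dataset, fast_config)
    model, _, _ = train_genet(
        fm_tf.values, fm_hm.values, g_tf.norm_adjacency, g_hm.norm_adjacency,
        y, masks.as_dict(), fast_config,
    )
    X = model.x_scaler_tf.transform(fm_tf.values)
    _, P = gcn_forward(X, g_tf.norm_adjacency, model.params_tf)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
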