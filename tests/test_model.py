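"""Classifier numerics: conv layer, KAN layer, loss, training, counting."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

from kandel import _bspline
from kandel.alignio import AlignmentRecord, parse_cigar, segment_ops
from kandel.hetgraph import RELATIONS, batch_graphs, build_graph
from kandel.model import (
    ConfigError,
    DeletionNodeClassifier,
    ModelConfig,
    _backward,
    _forward,
    compute_loss,
    count_params,
    default_param_count,
    init_params,
    kan_forward,
    model_forward,
    rgcn_forward,
)
from conftest import random_multirelation_graph, rgcn_brute_force


# ----------------------------------------------------------- conv layer


def test_rgcn_self_term_identity():
    H = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
    params = {
        "W0": np.eye(3),
        **{f"W.{r}": np.zeros((3, 3)) for r in RELATIONS},
    }
    out = rgcn_forward(H, {r: np.zeros((0, 2), int) for r in RELATIONS}, params)
    assert np.allclose(out, H)


def test_rgcn_zero_weights():
    H = np.random.default_rng(1).normal(size=(5, 3))
    params = {
        "W0": np.zeros((3, 2)),
        **{f"W.{r}": np.zeros((3, 2)) for r in RELATIONS},
    }
    out = rgcn_forward(H, {RELATIONS[0]: np.array([[0, 1]])}, params)
    assert np.allclose(out, 0.0)


def test_rgcn_three_node_chain_hand_value():
    # chain 1-2-3 (0-indexed 0-1-2), scalar weights 1, H = (1,2,3):
    # node0: 2/1 + 1 = 3; node1: (1+3)/2 + 2 = 4; node2: 2/1 + 3 = 5
    H = np.array([[1.0], [2.0], [3.0]])
    edges = {
        RELATIONS[0]: np.array([[0, 1], [1, 0], [1, 2], [2, 1]]),
        RELATIONS[1]: np.zeros((0, 2), int),
        RELATIONS[2]: np.zeros((0, 2), int),
    }
    params = {
        "W0": np.array([[1.0]]),
        **{f"W.{r}": np.array([[1.0]]) for r in RELATIONS},
    }
    out = rgcn_forward(H, edges, params)
    assert np.allclose(out.ravel(), [3.0, 4.0, 5.0])


def test_rgcn_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(60):
        X, edges = random_multirelation_graph(rng, max_nodes=20, d=4)
        Wr = {r: rng.normal(size=(4, 3)) for r in RELATIONS}
        W0 = rng.normal(size=(4, 3))
        b = rng.normal(size=3)
        params = {"W0": W0, "b": b, **{f"W.{r}": W for r, W in Wr.items()}}
        got = rgcn_forward(X, edges, params)
        want = rgcn_brute_force(X, edges, Wr, W0, b)
        assert np.allclose(got, want, atol=1e-6)


# ------------------------------------------------------------ KAN layer


def test_bspline_basis_matches_scipy():
    G, k = 5, 3
    rng_range = (-2.0, 2.0)
    t = _bspline.knot_vector(rng_range, G, k)
    x = np.linspace(-2.0, 1.999, 97)
    B = _bspline.design_matrix(x, rng_range, G, k)
    Bp = _bspline.design_matrix_deriv(x, rng_range, G, k)
    for m in range(G + k):
        c = np.zeros(G + k)
        c[m] = 1.0
        ref = BSpline(t, c, k)
        assert np.allclose(B[:, m], ref(x), atol=1e-12)
        assert np.allclose(Bp[:, m], ref.derivative()(x), atol=1e-9)
    # partition of unity inside the grid range
    assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)


def test_bspline_interior_basis_peak_value():
    # the central cubic basis peaks at its middle knot with value from a
    # direct de Boor evaluation
    G, k = 5, 3
    t = _bspline.knot_vector((-2.0, 2.0), G, k)
    m = 4  # interior basis, support t[4..8], peak at t[6] = 0.4
    c = np.zeros(G + k)
    c[m] = 1.0
    peak_x = t[m + 2]
    expected = float(BSpline(t, c, k)(peak_x))
    got = _bspline.design_matrix(np.array([peak_x]), (-2.0, 2.0), G, k)[0, m]
    assert got == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(2.0 / 3.0)  # uniform cubic peak


def test_kan_zero_params_gives_zero():
    cfg = ModelConfig()
    nb = cfg.grid_size + cfg.spline_order
    params = {
        "base": np.zeros((2, 3)),
        "scale": np.zeros((2, 3)),
        "coef": np.zeros((2, 3, nb)),
    }
    X = np.random.default_rng(0).uniform(-2, 2, (7, 3))
    assert np.allclose(kan_forward(X, params, cfg), 0.0)


def test_kan_reduces_to_silu():
    cfg = ModelConfig()
    nb = cfg.grid_size + cfg.spline_order
    params = {
        "base": np.ones((1, 1)),
        "scale": np.ones((1, 1)),
        "coef": np.zeros((1, 1, nb)),
    }
    x = np.linspace(-1.9, 1.9, 11).reshape(-1, 1)
    out = kan_forward(x, params, cfg)
    silu = x / (1 + np.exp(-x))
    assert np.allclose(out, silu, atol=1e-12)


def test_kan_clamps_out_of_range_inputs():
    cfg = ModelConfig()
    nb = cfg.grid_size + cfg.spline_order
    rng = np.random.default_rng(3)
    params = {
        "base": rng.normal(size=(2, 2)),
        "scale": rng.normal(size=(2, 2)),
        "coef": rng.normal(size=(2, 2, nb)),
    }
    big = np.array([[10.0, -10.0]])
    edge = np.array([[2.0, -2.0]])
    assert np.allclose(
        kan_forward(big, params, cfg), kan_forward(edge, params, cfg)
    )


# --------------------------------------------------------------- forward


def _toy_graphs(n=6, seed=0):
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n):
        cigar = "100M80D100M" if rng.random() < 0.5 else "150M"
        r = AlignmentRecord(
            f"q{i}", 0, "chrI", int(rng.integers(0, 5000)), 60,
            parse_cigar(cigar),
        )
        g = build_graph(segment_ops(r), "chrI", f"q{i}")
        g.labels = np.array(
            [1 if nd.op_code == 2 else 0 for nd in g.nodes], dtype=np.int64
        )
        graphs.append(g)
    return graphs


def test_forward_probabilities_normalized():
    graphs = _toy_graphs()
    cfg = ModelConfig()
    params = init_params(cfg, np.random.default_rng(0))
    probs = model_forward(batch_graphs(graphs), params, cfg)
    assert probs.shape == (sum(g.n_nodes for g in graphs), 2)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((probs >= 0) & (probs <= 1))


def test_forward_permutation_equivariance():
    graphs = _toy_graphs(3, seed=5)
    batch = batch_graphs(graphs)
    cfg = ModelConfig()
    params = init_params(cfg, np.random.default_rng(1))
    probs = model_forward(batch, params, cfg)
    rng = np.random.default_rng(2)
    perm = rng.permutation(batch.n_nodes)
    inv = np.argsort(perm)
    batch2 = batch_graphs(graphs)
    batch2.X = batch.X[perm]
    batch2.edges = {
        rel: inv[E] if len(E) else E for rel, E in batch.edges.items()
    }
    probs2 = model_forward(batch2, params, cfg)
    assert np.allclose(probs2, probs[perm], atol=1e-9)


def test_batch_forward_equals_per_graph_forwards():
    graphs = _toy_graphs(5, seed=7)
    cfg = ModelConfig()
    params = init_params(cfg, np.random.default_rng(3))
    full = model_forward(batch_graphs(graphs), params, cfg)
    parts = np.concatenate(
        [model_forward(batch_graphs([g]), params, cfg) for g in graphs]
    )
    assert np.allclose(full, parts, atol=1e-6)


# ------------------------------------------------------------------ loss


def test_loss_hand_computed_example():
    probs = np.array([[0.8, 0.2], [0.4, 0.6]])
    labels = np.array([0, 1])
    loss = compute_loss(probs, labels, class_weight=0.7, l2=0.0)
    expected = -0.5 * (0.3 * np.log(0.8) + 0.7 * np.log(0.6))
    assert loss == pytest.approx(expected, abs=1e-12)
    assert loss == pytest.approx(0.2123, abs=1e-4)


def test_loss_zero_when_perfect_and_unregularized():
    probs = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert compute_loss(probs, np.array([0, 1]), l2=0.0) == pytest.approx(0.0)


def test_loss_regularizer_only():
    probs = np.array([[1.0, 0.0]])
    params = {"w": np.array([2.0, 0.0, 0.0])}  # ||W||^2 = 4
    loss = compute_loss(probs, np.array([0]), params, 0.9, l2=0.1)
    assert loss == pytest.approx(0.2, abs=1e-12)


def test_balanced_loss_is_half_unweighted_ce():
    rng = np.random.default_rng(0)
    p1 = rng.uniform(0.05, 0.95, 10)
    probs = np.stack([1 - p1, p1], axis=1)
    labels = rng.integers(0, 2, 10)
    w = compute_loss(probs, labels, class_weight=0.5, l2=0.0)
    p_true = probs[np.arange(10), labels]
    assert w == pytest.approx(0.5 * float(np.mean(-np.log(p_true))))


# ---------------------------------------------------------- gradients


@pytest.mark.parametrize("head", ["fc", "kan", "kan2", "kan_fc"])
def test_backward_matches_finite_differences(head):
    """Hand-written backprop agrees with central finite differences."""
    graphs = _toy_graphs(3, seed=11)
    batch = batch_graphs(graphs)
    cfg = ModelConfig(head=head, hidden1=5, hidden2=3)
    params = init_params(cfg, np.random.default_rng(4))
    labels = batch.labels

    probs, caches = _forward(batch, params, cfg)
    grads = _backward(probs, labels, caches, params, cfg)

    def loss_at() -> float:
        p, _ = _forward(batch, params, cfg)
        return compute_loss(p, labels, None, cfg.class_weight, 0.0)

    rng = np.random.default_rng(5)
    h = 1e-6
    for name, arr in params.items():
        flat = arr.ravel()
        idxs = rng.choice(flat.size, size=min(5, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + h
            up = loss_at()
            flat[i] = orig - h
            dn = loss_at()
            flat[i] = orig
            num = (up - dn) / (2 * h)
            ana = grads[name].ravel()[i]
            assert ana == pytest.approx(num, abs=5e-7), f"{name}[{i}]"


# ---------------------------------------------------------- training


def test_training_descends_and_is_deterministic():
    graphs = _toy_graphs(12, seed=1)
    est1 = DeletionNodeClassifier(epochs=300, seed=3).fit(graphs)
    est2 = DeletionNodeClassifier(epochs=300, seed=3).fit(graphs)
    assert est1.loss_history_[-1] < est1.loss_history_[0]
    assert abs(est1.loss_history_[-1] - est2.loss_history_[-1]) < 1e-8
    acc = (est1.predict(graphs) == np.concatenate(
        [g.labels for g in graphs]
    )).mean()
    assert acc > 0.9


def test_single_class_warns_but_trains():
    graphs = [g for g in _toy_graphs(8, seed=2) if g.labels.sum() == 0]
    assert graphs
    with pytest.warns(UserWarning):
        DeletionNodeClassifier(epochs=2, seed=0).fit(graphs)


def test_prediction_tie_break_and_shape():
    graphs = _toy_graphs(4, seed=8)
    est = DeletionNodeClassifier(epochs=2, seed=0).fit(graphs)
    probs = est.predict_proba(graphs)
    hard = est.predict(graphs)
    assert len(hard) == sum(g.n_nodes for g in graphs)
    # exact tie -> class 0 by the documented rule
    assert (np.array([0.5]) > np.array([0.5])).astype(int)[0] == 0
    assert np.all(hard == (probs[:, 1] > probs[:, 0]))


def test_scale_mismatch_rejected():
    graphs = _toy_graphs(2, seed=0)
    est = DeletionNodeClassifier(epochs=1, seed=0, length_scale=1e-2)
    with pytest.raises(ConfigError):
        est.fit(graphs)


def test_checkpoint_round_trip(tmp_path):
    graphs = _toy_graphs(4, seed=4)
    est = DeletionNodeClassifier(epochs=3, seed=1).fit(graphs)
    path = str(tmp_path / "model.json")
    est.save(path)
    est2 = DeletionNodeClassifier.load(path)
    assert np.allclose(
        est.predict_proba(graphs), est2.predict_proba(graphs)
    )
    assert est2.n_params_ == est.n_params_


# ----------------------------------------------------------- counting


def test_param_count_closed_forms():
    # conv1: 4*6*8+8; conv2: 4*8*4+4; KAN 4->4: 16*(2+G+k); FC: 4*2+2
    assert default_param_count() == 200 + 132 + 160 + 10 == 502
    rng = np.random.default_rng(0)
    counts = {
        "fc": 200 + 132 + 10,
        "kan": 200 + 132 + 80,
        "kan2": 200 + 132 + 160 + 80,
        "kan_fc": 502,
    }
    for head, want in counts.items():
        cfg = ModelConfig(head=head)
        assert count_params(init_params(cfg, rng)) == want
    fc_only = {"W": np.zeros((4, 2)), "b": np.zeros(2)}
    assert count_params(fc_only) == 10
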