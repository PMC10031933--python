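import numpy as np
import pytest

from netwarp import (
    Network,
    forman_ricci,
    make_prior_kernel,
    make_prior_vector,
    stationary_distribution,
    warp_with_curvature,
    warp_with_prior,
)
from netwarp.errors import InputError, NetwarpWarning
from netwarp.prior import SmoothedPrior, read_prior_set
from .conftest import random_connected_network


def uniform_weights(net):
    """K at beta=0 (every edge weight 1/2)."""
    return warp_with_curvature(net, forman_ricci(net), 0.0)


def test_prior_vector_uniform():
    net = Network(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
    phi = make_prior_vector(net, {"a", "b"}).phi
    assert np.allclose(phi, [0.5, 0.5, 0, 0])


def test_prior_vector_drops_missing_with_warning(path3):
    with pytest.warns(NetwarpWarning, match="x"):
        pv = make_prior_vector(path3, {"a", "x"})
    assert np.allclose(pv.phi, [1.0, 0, 0])


def test_prior_vector_disjoint_raises(path3):
    with pytest.raises(InputError, match="disjoint"):
        make_prior_vector(path3, {"x", "y"})


def test_empty_prior_raises(path3):
    with pytest.raises(InputError):
        make_prior_vector(path3, set())


def test_read_prior_set(tmp_path):
    f = tmp_path / "p.txt"
    f.write_text("# comment\nTP53\nKRAS # inline\n\n")
    assert read_prior_set(f) == {"TP53", "KRAS"}


def test_kernel_gamma_one_columns_equal_phi(path3):
    K = uniform_weights(path3)
    phi = make_prior_vector(path3, {"a"})
    P = make_prior_kernel(K, phi, 1.0).to_dense()
    for j in range(3):
        assert np.allclose(P[:, j], phi.phi)


def test_kernel_gamma_zero_is_column_normalized_K(path3):
    K = uniform_weights(path3)
    phi = make_prior_vector(path3, {"a"})
    P = make_prior_kernel(K, phi, 0.0).to_dense()
    Kd = K.K.toarray()
    assert np.allclose(P, Kd / Kd.sum(axis=0))


def test_kernel_hand_assembled_column(path3):
    # path a-b-c, beta=0, priors={a}, gamma=0.5: column b = (0.75, 0, 0.25)
    K = uniform_weights(path3)
    phi = make_prior_vector(path3, {"a"})
    P = make_prior_kernel(K, phi, 0.5).to_dense()
    assert np.allclose(P[:, 1], [0.75, 0.0, 0.25])


def test_kernel_columns_sum_to_one():
    rng = np.random.default_rng(2)
    net = random_connected_network(12, 0.25, rng)
    K = warp_with_curvature(net, forman_ricci(net), 0.5)
    phi = make_prior_vector(net, set(net.node_ids[:3]))
    for gamma in (0.0, 0.3, 0.7, 1.0):
        kernel = make_prior_kernel(K, phi, gamma)
        assert np.allclose(kernel.column_sums(), 1.0, atol=1e-14)
        assert np.allclose(kernel.to_dense().sum(axis=0), 1.0, atol=1e-14)


def test_kernel_isolated_node_pure_restart():
    net = Network(list("abc"), [("a", "b")])  # c isolated
    K = warp_with_curvature(net, forman_ricci(net), 0.0)
    phi = make_prior_vector(net, {"a"})
    with pytest.warns(NetwarpWarning, match="pure-restart"):
        kernel = make_prior_kernel(K, phi, 0.5)
    P = kernel.to_dense()
    assert np.allclose(P[:, 2], phi.phi)
    assert np.allclose(P.sum(axis=0), 1.0)


def test_kernel_isolated_node_gamma_zero_raises():
    net = Network(list("abc"), [("a", "b")])
    K = warp_with_curvature(net, forman_ricci(net), 0.0)
    phi = make_prior_vector(net, {"a"})
    with pytest.raises(InputError, match="dangling"):
        make_prior_kernel(K, phi, 0.0)


def test_kernel_apply_matches_dense():
    rng = np.random.default_rng(7)
    net = random_connected_network(10, 0.3, rng)
    K = warp_with_curvature(net, forman_ricci(net), 0.8)
    phi = make_prior_vector(net, set(net.node_ids[:2]))
    kernel = make_prior_kernel(K, phi, 0.4)
    v = rng.random(10)
    assert np.allclose(kernel.apply(v), kernel.to_dense() @ v, atol=1e-14)


def test_stationary_gamma_one_is_phi(path3):
    K = uniform_weights(path3)
    phi = make_prior_vector(path3, {"a"})
    pi = stationary_distribution(make_prior_kernel(K, phi, 1.0))
    assert np.allclose(pi.pi, phi.phi, atol=1e-12)


def test_stationary_two_node_hand_solve():
    # single edge, priors={a}, gamma=0.5: direct 2x2 solve oracle
    net = Network(["a", "b"], [("a", "b")])
    K = uniform_weights(net)
    phi = make_prior_vector(net, {"a"})
    kernel = make_prior_kernel(K, phi, 0.5)
    P = kernel.to_dense()
    # solve (P - I) pi = 0 with sum(pi) = 1 directly
    A = np.vstack([P - np.eye(2), np.ones(2)])
    b = np.array([0.0, 0.0, 1.0])
    expected, *_ = np.linalg.lstsq(A, b, rcond=None)
    power = stationary_distribution(kernel, method="power", tol=1e-14)
    direct = stationary_distribution(kernel, method="direct")
    assert np.allclose(power.pi, expected, atol=1e-10)
    assert np.allclose(direct.pi, expected, atol=1e-10)


def test_stationary_gamma_zero_matches_eigensolver():
    rng = np.random.default_rng(13)
    net = random_connected_network(15, 0.3, rng)  # chain has triangles w.h.p.
    K = warp_with_curvature(net, forman_ricci(net), 0.5)
    phi = make_prior_vector(net, {net.node_ids[0]})
    kernel = make_prior_kernel(K, phi, 0.0)
    pi = stationary_distribution(kernel, method="power", tol=1e-14)
    W = kernel.to_dense()
    vals, vecs = np.linalg.eig(W)
    lead = np.argmax(vals.real)
    expected = np.abs(vecs[:, lead].real)
    expected /= expected.sum()
    assert np.allclose(pi.pi, expected, atol=1e-8)


def test_stationary_power_matches_direct_solve():
    rng = np.random.default_rng(21)
    for seed in range(5):
        net = random_connected_network(14, 0.3, np.random.default_rng(seed))
        K = warp_with_curvature(net, forman_ricci(net), 0.6)
        phi = make_prior_vector(net, set(net.node_ids[:3]))
        kernel = make_prior_kernel(K, phi, 0.35)
        p1 = stationary_distribution(kernel, method="power", tol=1e-13)
        p2 = stationary_distribution(kernel, method="direct")
        assert np.abs(p1.pi - p2.pi).max() < 1e-10


def test_stationary_gamma_zero_disconnected_refused():
    net = Network(list("abcd"), [("a", "b"), ("c", "d")])
    K = uniform_weights(net)
    phi = make_prior_vector(net, {"a"})
    kernel = make_prior_kernel(K, phi, 0.0)
    with pytest.raises(InputError, match="disconnected"):
        stationary_distribution(kernel, method="power")


def test_stationary_gamma_zero_bipartite_refused(path3):
    K = uniform_weights(path3)
    phi = make_prior_vector(path3, {"a"})
    kernel = make_prior_kernel(K, phi, 0.0)
    with pytest.raises(InputError, match="bipartite"):
        stationary_distribution(kernel, method="power")


def test_stationary_positive_on_connected_graph():
    rng = np.random.default_rng(3)
    net = random_connected_network(20, 0.2, rng)
    K = warp_with_curvature(net, forman_ricci(net), 0.5)
    phi = make_prior_vector(net, {net.node_ids[0]})
    for gamma in (0.2, 0.5, 1.0):
        pi = stationary_distribution(make_prior_kernel(K, phi, gamma))
        assert pi.pi.sum() == pytest.approx(1.0, abs=1e-12)
        if gamma < 1.0:
            assert (pi.pi > 0).all()


def test_warp_with_prior_uniform_pi_scales_K(fig2):
    K = warp_with_curvature(fig2, forman_ricci(fig2), 0.5)
    n = fig2.n_nodes
    pi = SmoothedPrior(pi=np.full(n, 1.0 / n))
    a_star = warp_with_prior(K, pi).a_star.toarray()
    assert np.allclose(a_star, K.K.toarray() / n)


def test_warp_with_prior_indicator_pi(path3):
    K = uniform_weights(path3)
    pi = SmoothedPrior(pi=np.array([0.0, 1.0, 0.0]))
    a_star = warp_with_prior(K, pi).a_star.toarray()
    assert np.all(a_star[0] == 0) and np.all(a_star[2] == 0)
    assert a_star[1].sum() > 0


def test_asymmetry_ratio_law():
    rng = np.random.default_rng(8)
    net = random_connected_network(8, 0.4, rng)
    K = warp_with_curvature(net, forman_ricci(net), 0.7)
    phi = make_prior_vector(net, set(net.node_ids[:2]))
    pi = stationary_distribution(make_prior_kernel(K, phi, 0.5))
    a_star = warp_with_prior(K, pi).a_star.toarray()
    for u, v in net.edges:
        i, j = net.index_of(u), net.index_of(v)
        assert a_star[j, i] / a_star[i, j] == pytest.approx(pi.pi[j] / pi.pi[i], rel=1e-10)


def test_support_symmetry_with_positive_pi():
    rng = np.random.default_rng(9)
    net = random_connected_network(10, 0.3, rng)
    K = warp_with_curvature(net, forman_ricci(net), 0.5)
    phi = make_prior_vector(net, {net.node_ids[0]})
    pi = stationary_distribution(make_prior_kernel(K, phi, 0.5))
    a_star = warp_with_prior(K, pi).a_star.toarray()
    assert np.array_equal(a_star > 0, (a_star > 0).T)
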