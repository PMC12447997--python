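import itertools

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from treelfa import (
    DiagnosisMatrix,
    Hyperparams,
    ModelState,
    PhiPriors,
    RhoPriors,
    RunParamError,
    flat_tree,
    gibbs_train,
    init_state,
    log10_joint,
    make_tree,
    update_I,
    update_Z,
    update_rho,
)
from treelfa.gibbs_sampler import (
    indicator_conditional,
    phi_posterior_shapes,
    rho_transition_counts,
    sweep,
    z_full_conditional,
)
from treelfa.model_core import compute_z_sum


def make_state(Z, Phi, I, rho, K):
    Z = np.asarray(Z, dtype=np.int32)
    return ModelState(
        Phi=np.asarray(Phi, dtype=float),
        I=np.asarray(I, dtype=np.int8),
        rho=np.asarray(rho, dtype=float),
        Z=Z,
        Z_sum=compute_z_sum(Z, K),
    )


class TestZConditional:
    def test_hand_example(self):
        # other code assigned topic 2, alpha=(1,1), x=1, Phi=(0.5, 0.1):
        # P(z=1) = (0+1)*0.5 / ((0+1)*0.5 + (1+1)*0.1) = 5/7
        p = z_full_conditional(
            np.array([0.0, 1.0]), np.ones(2), np.array([0.5, 0.1]), x=1
        )
        assert p[0] == pytest.approx(5 / 7)
        assert p.sum() == pytest.approx(1.0)

    def test_k1_degenerate(self):
        p = z_full_conditional(np.array([3.0]), np.array([0.7]), np.array([0.2]), x=0)
        assert p == pytest.approx([1.0])


def exact_z_posterior(X, Phi, alpha):
    """Enumerate P(Z | X, Phi, alpha) over all K^(D*S) assignments."""
    D, S = X.shape
    K = Phi.shape[0]
    from scipy.special import gammaln

    states, probs = [], []
    A = alpha.sum()
    for flat in itertools.product(range(K), repeat=D * S):
        Z = np.array(flat).reshape(D, S)
        ln = 0.0
        for d in range(D):
            counts = np.bincount(Z[d], minlength=K)
            ln += gammaln(A) - gammaln(S + A)
            ln += (gammaln(counts + alpha) - gammaln(alpha)).sum()
            for s in range(S):
                phi = Phi[Z[d, s], s]
                ln += np.log(phi if X[d, s] else 1 - phi)
        states.append(flat)
        probs.append(ln)
    probs = np.exp(np.array(probs) - max(probs))
    return states, probs / probs.sum()


class TestUpdateZExactness:
    def test_empirical_law_matches_enumeration(self, tiny_data, tiny_tree):
        """Gibbs scan over Z alone has the enumerated collapsed posterior
        as its stationary law (Phi held fixed)."""
        X = tiny_data.values[:2]  # D=2, S=2
        data = DiagnosisMatrix(values=X, codes=tiny_data.codes)
        alpha = np.array([1.0, 0.6])
        Phi = np.array([[0.6, 0.3], [0.1, 0.8]])
        states, probs = exact_z_posterior(X, Phi, alpha)
        idx = {s: i for i, s in enumerate(states)}
        state = make_state([[0, 0], [0, 0]], Phi, np.zeros((2, 3)), [0.1, 0.5], K=2)
        rng = np.random.default_rng(5)
        n_sweeps = 40_000
        counts = np.zeros(len(states))
        for _ in range(n_sweeps):
            update_Z(state, data, alpha, rng)
            counts[idx[tuple(state.Z.ravel())]] += 1
        tv = 0.5 * np.abs(counts / n_sweeps - probs).sum()
        assert tv < 0.02

    def test_z_sum_consistency_after_update(self, small_sim):
        data, tree, _, cfg = small_sim
        state = init_state(data, tree, K=3, seed=0)
        update_Z(state, data, np.full(3, 0.2), np.random.default_rng(1))
        state.check()


class TestUpdatePhi:
    @pytest.mark.parametrize(
        "active,n1,n0,post_a,post_b,mean",
        [
            (0, 3, 7, 3.1, 507.0, 3.1 / 510.1),
            (1, 30, 70, 32.0, 74.0, 32 / 106),
            (0, 0, 0, 0.1, 500.0, 0.1 / 500.1),  # pure prior when unassigned
        ],
    )
    def test_posterior_shapes_closed_form(self, active, n1, n0, post_a, post_b, mean):
        priors = PhiPriors(0.1, 500, 2, 4)
        # one topic, one code; engineer counts via an explicit Z/X pair
        D = n1 + n0
        if D == 0:
            X = np.array([[0]])
            Z = np.array([[1]])  # assigned elsewhere -> no counts for topic 0
            K = 2
        else:
            X = np.array([[1]] * n1 + [[0]] * n0)
            Z = np.zeros((D, 1), dtype=np.int32)
            K = 1
        data = DiagnosisMatrix(values=X, codes=["D1"])
        tree = flat_tree(["D1"])
        tree.align_terminals(["D1"])
        state = make_state(Z, np.full((K, 1), 0.5), np.full((K, 2), active), [0.1, 0.5], K)
        state.I[:, 0] = 0  # root fixed
        a, b = phi_posterior_shapes(state, data, priors, tree)
        assert a[0, 0] == pytest.approx(post_a)
        assert b[0, 0] == pytest.approx(post_b)
        assert post_a / (post_a + post_b) == pytest.approx(mean, abs=1e-4)


def tiny_indicator_model():
    """Root -> C1 -> (D1, D2): 4 nodes, 1 topic, fixed Phi and rho."""
    tree = make_tree(1, 2)
    tree.align_terminals(["D1", "D2"])
    priors = PhiPriors(0.1, 500, 2, 4)
    Phi = np.array([[0.25, 0.02]])
    rho = np.array([0.2, 0.6])
    return tree, priors, Phi, rho


def exact_indicator_joint(tree, priors, Phi, rho):
    """P(I | Phi, rho) by enumerating all configurations of non-root nodes."""
    rho01, rho11 = rho
    n = tree.n_nodes
    configs = list(itertools.product([0, 1], repeat=n - 1))
    weights = []
    for cfg in configs:
        I = np.array((0,) + cfg)
        w = 1.0
        for node in range(1, n):
            p_act = rho11 if I[tree.parent_idx[node]] else rho01
            w *= p_act if I[node] else 1 - p_act
        for pos, node in enumerate(tree.terminal_node_idx):
            a, b = (priors.a1, priors.b1) if I[node] else (priors.a0, priors.b0)
            w *= beta_dist.pdf(Phi[0, pos], a, b)
        weights.append(w)
    weights = np.array(weights)
    return configs, weights / weights.sum()


class TestUpdateI:
    def test_absorbing_inactive_chain(self):
        tree, priors, Phi, _ = tiny_indicator_model()
        state = make_state([[0, 0]], Phi, np.zeros((1, 4)), [0.0, 0.6], K=1)
        # rho01 = 0: an inactive parent can never yield an active child,
        # whatever the likelihood says
        for node in range(1, 4):
            assert indicator_conditional(state, tree, priors, 0, node) == 0.0

    def test_two_node_hand_computation(self):
        # root -> single terminal, rho01=0.2, Phi=0.25: slab density
        # Beta(2,4) at 0.25 is 20*0.25*0.75^3 = 2.109; spike Beta(0.1,500)
        # density there ~ 0.75^499 scale -> P(I=1) ~ 1
        tree = flat_tree(["D1"])
        tree.align_terminals(["D1"])
        priors = PhiPriors(0.1, 500, 2, 4)
        state = make_state([[0]], [[0.25]], np.zeros((1, 2)), [0.2, 0.6], K=1)
        p1 = indicator_conditional(state, tree, priors, 0, 1)
        assert p1 == pytest.approx(1.0, abs=1e-10)
        act = 0.2 * beta_dist.pdf(0.25, 2, 4)
        inact = 0.8 * beta_dist.pdf(0.25, 0.1, 500)
        assert p1 == pytest.approx(act / (act + inact))

    def test_conditionals_match_enumeration(self):
        """Every single-site conditional equals the one derived from the
        enumerated joint, for every configuration of the other nodes."""
        tree, priors, Phi, rho = tiny_indicator_model()
        configs, probs = exact_indicator_joint(tree, priors, Phi, rho)
        joint = dict(zip(configs, probs))
        for cfg in configs:
            for node in range(1, 4):
                I = np.array((0,) + cfg, dtype=np.int8)
                state = make_state([[0, 0]], Phi, I[None, :], rho, K=1)
                got = indicator_conditional(state, tree, priors, 0, node)
                on = list(cfg)
                off = list(cfg)
                on[node - 1], off[node - 1] = 1, 0
                expected = joint[tuple(on)] / (joint[tuple(on)] + joint[tuple(off)])
                assert got == pytest.approx(expected, abs=1e-12)

    def test_gibbs_marginals_match_enumeration(self):
        tree, priors, Phi, rho = tiny_indicator_model()
        configs, probs = exact_indicator_joint(tree, priors, Phi, rho)
        exact_marg = np.zeros(3)
        for cfg, p in zip(configs, probs):
            exact_marg += np.array(cfg) * p
        state = make_state([[0, 0]], Phi, np.zeros((1, 4)), rho, K=1)
        rng = np.random.default_rng(3)
        n_sweeps = 20_000
        acc = np.zeros(3)
        for _ in range(n_sweeps):
            update_I(state, tree, priors, rng)
            acc += state.I[0, 1:]
        assert np.abs(acc / n_sweeps - exact_marg).max() < 0.02

    def test_root_never_resampled(self, small_sim):
        data, tree, _, _ = small_sim
        state = init_state(data, tree, K=2, seed=0)
        state.rho = np.array([0.5, 0.5])
        update_I(state, tree, PhiPriors(0.1, 500, 2, 4), np.random.default_rng(0))
        assert np.all(state.I[:, 0] == 0)
        with pytest.raises(ValueError):
            indicator_conditional(state, tree, PhiPriors(0.1, 500, 2, 4), 0, 0)


class TestUpdateRho:
    def test_hand_edge_count_on_example_tree(self, example_tree):
        # K=1 on the 20-edge example tree; C1, D1, D2 active:
        # c01=1 (root->C1), c00=16, c11=2 (C1->D1,D2), c10=1 (C1->D3)
        tree = example_tree
        tree.align_terminals([f"D{i}" for i in range(1, 16)])
        I = np.zeros((1, tree.n_nodes), dtype=np.int8)
        idx = {n: i for i, n in enumerate(tree.nodes)}
        for name in ("C1", "D1", "D2"):
            I[0, idx[name]] = 1
        state = make_state(np.zeros((1, 15), dtype=np.int32), np.full((1, 15), 0.1),
                           I, [0.1, 0.5], K=1)
        c = rho_transition_counts(state, tree)
        assert c[0, 1] == 1 and c[0, 0] == 16 and c[1, 1] == 2 and c[1, 0] == 1
        # posterior: rho01 ~ Beta(4, 36), rho11 ~ Beta(5, 4)
        priors = RhoPriors()
        draws = np.array([
            update_rho(state.copy(), tree, priors, np.random.default_rng(i)).rho
            for i in range(4000)
        ])
        se01 = np.sqrt(beta_dist.var(4, 36) / 4000)
        se11 = np.sqrt(beta_dist.var(5, 4) / 4000)
        assert abs(draws[:, 0].mean() - 4 / 40) < 3 * se01
        assert abs(draws[:, 1].mean() - 5 / 9) < 3 * se11

    def test_all_inactive_counts(self, example_tree):
        tree = example_tree
        tree.align_terminals([f"D{i}" for i in range(1, 16)])
        K = 3
        state = make_state(np.zeros((2, 15), dtype=np.int32),
                           np.full((K, 15), 0.1),
                           np.zeros((K, tree.n_nodes)), [0.1, 0.5], K=K)
        c = rho_transition_counts(state, tree)
        # E edges * K topics inactive->inactive transitions, nothing else
        assert c[0, 0] == 20 * K
        assert c[0, 1] == c[1, 0] == c[1, 1] == 0


class TestLog10Joint:
    def test_minimal_closed_form(self):
        data = DiagnosisMatrix(values=np.array([[1]]), codes=["D1"])
        tree = flat_tree(["D1"])
        tree.align_terminals(["D1"])
        priors = PhiPriors(0.1, 500, 2, 4)
        rho_p = RhoPriors()
        state = make_state([[0]], [[0.5]], np.zeros((1, 2)), [0.1, 0.5], K=1)
        hyper = Hyperparams(alpha=np.array([1.0]), phi_priors=priors, rho_priors=rho_p)
        got = log10_joint(state, data, hyper, tree)
        # independent composition of the five factors
        expected = (
            np.log10(0.5)  # data term; collapsed P(Z|alpha) term is log10(1)=0
            + beta_dist.logpdf(0.5, 0.1, 500) / np.log(10)  # P(Phi|I=0)
            + np.log10(1 - 0.1)  # P(I=0|root, rho01=0.1)
            + (beta_dist.logpdf(0.1, 3, 20) + beta_dist.logpdf(0.5, 3, 3)) / np.log(10)
        )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_strictly_negative(self, small_sim):
        data, tree, _, _ = small_sim
        state = init_state(data, tree, K=2, seed=0)
        hyper = Hyperparams(alpha=np.full(2, 0.1), phi_priors=PhiPriors(0.1, 500, 2, 4))
        assert log10_joint(state, data, hyper, tree) < 0

    def test_invariant_under_topic_relabeling(self, small_sim):
        data, tree, _, _ = small_sim
        state = init_state(data, tree, K=3, seed=2)
        rng = np.random.default_rng(0)
        priors = PhiPriors(0.1, 500, 2, 4)
        hyper = Hyperparams(alpha=np.array([0.3, 0.1, 0.5]), phi_priors=priors)
        sweep(state, data, tree, hyper, rng)
        base = log10_joint(state, data, hyper, tree)
        perm = np.array([2, 0, 1])  # new position j holds old topic perm[j]
        inv = np.argsort(perm)
        permuted = make_state(
            inv[state.Z], state.Phi[perm], state.I[perm], state.rho, K=3
        )
        hyper_p = Hyperparams(alpha=hyper.alpha[perm], phi_priors=priors)
        assert log10_joint(permuted, data, hyper_p, tree) == pytest.approx(base, rel=1e-12)


class TestGibbsTrain:
    @pytest.mark.parametrize(
        "burn_in,cycle,interval,expected",
        [(25, 50, 5, 5), (0, 1, 1, 1), (10, 50, 7, 5)],
    )
    def test_sample_count(self, small_sim, burn_in, cycle, interval, expected):
        data, tree, _, _ = small_sim
        state = init_state(data, tree, K=2, seed=0)
        res = gibbs_train(data, tree, state, np.full(2, 0.1),
                          burn_in=burn_in, cycle=cycle, interval=interval, seed=1)
        assert res.N_ps == expected == (cycle - burn_in) // interval
        assert len(res.L_all) == cycle
        for zs in res.Z_sum_samples:
            assert np.all(zs.sum(axis=1) == data.S)

    def test_burn_in_violation_raises_before_compute(self, small_sim):
        data, tree, _, _ = small_sim
        state = init_state(data, tree, K=2, seed=0)
        with pytest.raises(RunParamError, match="burn_in"):
            gibbs_train(data, tree, state, np.full(2, 0.1),
                        burn_in=50, cycle=50, interval=1)

    def test_state_consistent_after_sweeps(self, small_sim):
        data, tree, _, _ = small_sim
        state = init_state(data, tree, K=2, seed=0)
        res = gibbs_train(data, tree, state, np.full(2, 0.1),
                          burn_in=0, cycle=5, interval=1, seed=4)
        res.final_state.check()

    def test_converged_trace_fluctuates_without_trend(self, small_sim):
        """After convergence L_all moves up and down with no monotone
        drift: the two halves of the post-burn-in trace agree."""
        data, tree, _, _ = small_sim
        state = init_state(data, tree, K=2, seed=0)
        res = gibbs_train(data, tree, state, np.full(2, 0.1),
                          burn_in=100, cycle=300, interval=10, seed=5)
        tail = np.array(res.L_all[100:])
        first, second = tail[:100], tail[100:]
        assert np.sign(np.diff(tail)).std() > 0  # not monotone
        assert abs(first.mean() - second.mean()) < 3 * tail.std()
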