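"""Collapsed Gibbs sampler for treeLFA.

Topic weights theta are integrated out analytically, so a sweep updates
Z (topic assignments, collapsed conditional), Phi (conjugate Beta),
I (single-site Gibbs on the tree) and rho (conjugate Beta over edge
transition counts), in that order. The log10 joint density of the model
is recorded every sweep as the convergence trace L_all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

from .io_formats import (
    DiagnosisMatrix,
    RunConfig,
    RunParamError,
    TreeStructure,
    validate_run_params,
)
from .model_core import (
    PROB_EPS,
    Hyperparams,
    ModelState,
    PhiPriors,
    RhoPriors,
)

LN10 = np.log(10.0)


@dataclass
class GibbsResult:
    """Posterior samples from a fixed-alpha Gibbs run.

    N_ps = floor((cycle - burn_in)/interval) samples of Phi, I, rho and
    Z_sum are retained (full Z matrices are not kept; Z_sum suffices to
    approximate topic weights). L_all holds the per-sweep log10 joint.
    """

    Phi_samples: list[np.ndarray] = field(default_factory=list)
    I_samples: list[np.ndarray] = field(default_factory=list)
    rho_samples: list[np.ndarray] = field(default_factory=list)
    Z_sum_samples: list[np.ndarray] = field(default_factory=list)
    alpha: np.ndarray | None = None
    L_all: list[float] = field(default_factory=list)
    final_state: ModelState | None = None

    @property
    def N_ps(self) -> int:
        return len(self.Phi_samples)


# ---------------------------------------------------------------------------
# full conditionals
# ---------------------------------------------------------------------------

def z_full_conditional(
    z_sum_minus: np.ndarray, alpha: np.ndarray, phi_col: np.ndarray, x: int
) -> np.ndarray:
    """P(z = k | rest) for one (individual, code) site.

    Proportional to (count of topic k among the individual's other codes
    + alpha_k) times the Bernoulli likelihood Phi[k,s]^x (1-Phi[k,s])^(1-x).
    """
    lik = phi_col if x == 1 else 1.0 - phi_col
    p = (z_sum_minus + alpha) * lik
    return p / p.sum()


def update_Z(
    state: ModelState,
    data: DiagnosisMatrix,
    alpha: np.ndarray,
    rng: np.random.Generator,
) -> ModelState:
    """Resample every topic assignment (vectorized across individuals).

    Within one individual the sites are conditionally dependent through
    Z_sum, so codes are scanned systematically; across individuals the
    collapsed conditional factorizes, allowing one vectorized draw per
    code column.
    """
    X = data.values
    D, S, K = state.D, state.S, state.K
    Z, Z_sum, Phi = state.Z, state.Z_sum, state.Phi
    rows = np.arange(D)
    Z_sum_f = Z_sum.astype(np.float64)
    for s in range(S):
        z = Z[:, s]
        Z_sum_f[rows, z] -= 1.0  # one index per row: plain fancy indexing is safe
        lik = np.where(X[:, s, None] == 1, Phi[None, :, s], 1.0 - Phi[None, :, s])
        p = (Z_sum_f + alpha[None, :]) * lik
        c = np.cumsum(p, axis=1)
        u = rng.random(D) * c[:, -1]
        z_new = (c < u[:, None]).sum(axis=1).astype(np.int32)
        Z_sum_f[rows, z_new] += 1.0
        Z[:, s] = z_new
    state.Z_sum = Z_sum_f.astype(np.int32)
    return state


def phi_counts(state: ModelState, data: DiagnosisMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(n1, n0): per (topic, code), counts of assigned sites with x=1 / x=0."""
    K, S = state.K, state.S
    X = data.values
    n1 = np.zeros((K, S))
    n0 = np.zeros((K, S))
    for s in range(S):
        tot = np.bincount(state.Z[:, s], minlength=K)
        ones = np.bincount(state.Z[:, s], weights=X[:, s].astype(float), minlength=K)
        n1[:, s] = ones
        n0[:, s] = tot - ones
    return n1, n0


def phi_posterior_shapes(
    state: ModelState,
    data: DiagnosisMatrix,
    priors: PhiPriors,
    tree: TreeStructure,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior Beta shapes for every Phi[k,s] given Z and I."""
    n1, n0 = phi_counts(state, data)
    I_term = state.I[:, tree.terminal_node_idx]
    a, b = priors.shapes(I_term)
    return a + n1, b + n0


def update_Phi(
    state: ModelState,
    data: DiagnosisMatrix,
    priors: PhiPriors,
    tree: TreeStructure,
    rng: np.random.Generator,
) -> ModelState:
    """Conjugate update: Phi[k,s] ~ Beta(a_I + n1, b_I + n0)."""
    a, b = phi_posterior_shapes(state, data, priors, tree)
    state.Phi = np.clip(rng.beta(a, b), PROB_EPS, 1 - PROB_EPS)
    return state


def indicator_conditional(
    state: ModelState,
    tree: TreeStructure,
    priors: PhiPriors,
    k: int,
    node: int,
) -> float:
    """P(I[k, node] = 1 | everything else), exact single-site conditional.

    Combines the Markov prior from the parent, the transition likelihood
    of the node's children, and (for terminal codes) the Beta density of
    the current Phi under the slab vs spike prior.
    """
    if node == 0:
        raise ValueError("root indicator is fixed at 0 and never resampled")
    rho01, rho11 = state.rho
    parent_active = state.I[k, tree.parent_idx[node]]
    p_up = rho11 if parent_active else rho01
    with np.errstate(divide="ignore"):  # boundary rho values give -inf terms
        lp1 = np.log(p_up)
        lp0 = np.log1p(-p_up)
        kids = tree.children[node]
        if kids:
            n_act = int(state.I[k, kids].sum())
            n_in = len(kids) - n_act
            # n * log(p) with the convention 0 * -inf = 0
            lp1 += (n_act * np.log(rho11) if n_act else 0.0) + (
                n_in * np.log1p(-rho11) if n_in else 0.0
            )
            lp0 += (n_act * np.log(rho01) if n_act else 0.0) + (
                n_in * np.log1p(-rho01) if n_in else 0.0
            )
    term_pos = np.flatnonzero(tree.terminal_node_idx == node)
    if term_pos.size:
        s = int(term_pos[0])
        phi = state.Phi[k, s]
        lphi, l1mphi = np.log(phi), np.log1p(-phi)
        lp1 += (
            (priors.a1 - 1) * lphi
            + (priors.b1 - 1) * l1mphi
            - betaln(priors.a1, priors.b1)
        )
        lp0 += (
            (priors.a0 - 1) * lphi
            + (priors.b0 - 1) * l1mphi
            - betaln(priors.a0, priors.b0)
        )
    m = max(lp0, lp1)
    e1 = np.exp(lp1 - m)
    return float(e1 / (np.exp(lp0 - m) + e1))


def update_I(
    state: ModelState,
    tree: TreeStructure,
    priors: PhiPriors,
    rng: np.random.Generator,
) -> ModelState:
    """Single-site Gibbs over all (topic, non-root node) indicators.

    Nodes are scanned in topological order; the root stays 0 so that the
    Markov process runs from the root down and empty (all-inactive)
    topics remain representable.
    """
    K = state.K
    rho01, rho11 = float(state.rho[0]), float(state.rho[1])
    l_r01, l_r01c = np.log(rho01), np.log1p(-rho01)
    l_r11, l_r11c = np.log(rho11), np.log1p(-rho11)
    logPhi = np.log(state.Phi)
    log1mPhi = np.log1p(-state.Phi)
    lb0 = betaln(priors.a0, priors.b0)
    lb1 = betaln(priors.a1, priors.b1)
    # node index -> code position for terminals, -1 otherwise
    node_to_code = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_to_code[tree.terminal_node_idx] = np.arange(len(tree.terminals))
    u = rng.random((K, tree.n_nodes))
    I = state.I
    for k in range(K):
        Ik = I[k]
        for node in range(1, tree.n_nodes):
            par = Ik[tree.parent_idx[node]]
            lp1 = l_r11 if par else l_r01
            lp0 = l_r11c if par else l_r01c
            kids = tree.children[node]
            if kids:
                n_act = int(Ik[kids].sum())
                n_in = len(kids) - n_act
                lp1 += n_act * l_r11 + n_in * l_r11c
                lp0 += n_act * l_r01 + n_in * l_r01c
            s = node_to_code[node]
            if s >= 0:
                lp1 += (priors.a1 - 1) * logPhi[k, s] + (priors.b1 - 1) * log1mPhi[k, s] - lb1
                lp0 += (priors.a0 - 1) * logPhi[k, s] + (priors.b0 - 1) * log1mPhi[k, s] - lb0
            d = lp1 - lp0
            # P(I=1) = 1/(1+exp(-d))
            Ik[node] = u[k, node] < 1.0 / (1.0 + np.exp(-d))
    return state


def rho_transition_counts(state: ModelState, tree: TreeStructure) -> np.ndarray:
    """2x2 table c[p, i] of edge transitions (parent indicator p ->
    child indicator i) pooled over all topics and edges."""
    child_idx = np.arange(1, tree.n_nodes)
    par = state.I[:, tree.parent_idx[child_idx]]
    chd = state.I[:, child_idx]
    c = np.zeros((2, 2), dtype=np.int64)
    for p in (0, 1):
        for i in (0, 1):
            c[p, i] = int(((par == p) & (chd == i)).sum())
    return c


def update_rho(
    state: ModelState,
    tree: TreeStructure,
    priors: RhoPriors,
    rng: np.random.Generator,
) -> ModelState:
    """Conjugate update: rho01 ~ Beta(a01+c01, b01+c00),
    rho11 ~ Beta(a11+c11, b11+c10)."""
    c = rho_transition_counts(state, tree)
    rho01 = rng.beta(priors.a01 + c[0, 1], priors.b01 + c[0, 0])
    rho11 = rng.beta(priors.a11 + c[1, 1], priors.b11 + c[1, 0])
    state.rho = np.clip(np.array([rho01, rho11]), PROB_EPS, 1 - PROB_EPS)
    return state


# ---------------------------------------------------------------------------
# joint density
# ---------------------------------------------------------------------------

def _log_beta_pdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def log10_joint(
    state: ModelState,
    data: DiagnosisMatrix,
    hyper: Hyperparams,
    tree: TreeStructure,
) -> float:
    """log10 of P(X|Z,Phi) P(Z|alpha) P(Phi|I) P(I|rho,tree) P(rho).

    P(Z|alpha) is the collapsed Dirichlet-multinomial per individual
    (theta integrated out). This is the L_all trace quantity.
    """
    alpha = hyper.alpha
    K, S, D = state.K, state.S, state.D
    # data term from sufficient counts
    n1, n0 = phi_counts(state, data)
    ln = float(np.sum(n1 * np.log(state.Phi) + n0 * np.log1p(-state.Phi)))
    # collapsed Dirichlet-multinomial over Z, via a histogram of counts
    A = float(alpha.sum())
    ln += D * (gammaln(A) - gammaln(S + A) - float(gammaln(alpha).sum()))
    grid = np.arange(S + 1)
    for k in range(K):
        hist = np.bincount(state.Z_sum[:, k], minlength=S + 1)
        ln += float(hist @ gammaln(grid + alpha[k]))
    # P(Phi | I)
    I_term = state.I[:, tree.terminal_node_idx]
    a, b = hyper.phi_priors.shapes(I_term)
    ln += float(_log_beta_pdf(state.Phi, a, b).sum())
    # P(I | rho, tree): product over topics and edges
    c = rho_transition_counts(state, tree)
    rho01, rho11 = state.rho
    ln += (
        c[0, 0] * np.log1p(-rho01)
        + c[0, 1] * np.log(rho01)
        + c[1, 0] * np.log1p(-rho11)
        + c[1, 1] * np.log(rho11)
    )
    # P(rho)
    rp = hyper.rho_priors
    ln += float(_log_beta_pdf(np.array([rho01]), np.array([rp.a01]), np.array([rp.b01]))[0])
    ln += float(_log_beta_pdf(np.array([rho11]), np.array([rp.a11]), np.array([rp.b11]))[0])
    return ln / LN10


# ---------------------------------------------------------------------------
# sweep and sampling loop
# ---------------------------------------------------------------------------

def sweep(
    state: ModelState,
    data: DiagnosisMatrix,
    tree: TreeStructure,
    hyper: Hyperparams,
    rng: np.random.Generator,
) -> ModelState:
    """One full systematic Gibbs scan: Z, Phi, I, rho."""
    update_Z(state, data, hyper.alpha, rng)
    update_Phi(state, data, hyper.phi_priors, tree, rng)
    update_I(state, tree, hyper.phi_priors, rng)
    update_rho(state, tree, hyper.rho_priors, rng)
    return state


def gibbs_train(
    data: DiagnosisMatrix,
    tree: TreeStructure,
    init: ModelState,
    alpha: np.ndarray,
    burn_in: int,
    cycle: int,
    interval: int,
    seed: int | np.random.Generator = 0,
    hyper: Hyperparams | None = None,
) -> GibbsResult:
    """Run `cycle` sweeps with alpha fixed; after `burn_in`, keep one
    posterior sample every `interval` sweeps.

    Z itself is not retained in the samples; Z_sum is, from which topic
    weights are approximated downstream.
    """
    alpha = np.asarray(alpha, dtype=float)
    cfg = RunConfig(K=init.K, alpha0=alpha, burn_in=burn_in, cycle=cycle, interval=interval)
    violations = validate_run_params(cfg)
    if violations:
        raise RunParamError("; ".join(map(str, violations)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if hyper is None:
        from .model_core import priors_for_data

        hyper = Hyperparams(alpha=alpha, phi_priors=priors_for_data(data))
    state = init.copy()
    result = GibbsResult(alpha=alpha.copy())
    for t in range(1, cycle + 1):
        sweep(state, data, tree, hyper, rng)
        result.L_all.append(log10_joint(state, data, hyper, tree))
        if t > burn_in and (t - burn_in) % interval == 0:
            result.Phi_samples.append(state.Phi.copy())
            result.I_samples.append(state.I.copy())
            result.rho_samples.append(state.rho.copy())
            result.Z_sum_samples.append(state.Z_sum.copy())
    result.final_state = state
    return result
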