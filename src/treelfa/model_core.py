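"""Model parameters, priors and latent state for treeLFA.

treeLFA is a topic model for binary diagnosis matrices. Each individual
d carries a topic-weight vector theta_d ~ Dirichlet(alpha) (integrated
out during inference); each code s of individual d gets a topic
assignment z_{ds} ~ Categorical(theta_d) and the observation
x_{ds} ~ Bernoulli(Phi[z_{ds}, s]). Topics are sparsified by a
spike-and-slab prior: a binary indicator I[k, v] per topic and tree
node selects the inactive (spike, near-zero mean) or active (slab) Beta
prior for Phi, and the indicators themselves follow a Markov process
running from the root of the disease-code tree to the terminals, with
transition probabilities rho01 = P(child active | parent inactive) and
rho11 = P(child active | parent active).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DiagnosisMatrix, TreeStructure

# Numerical guard on sampled probabilities before Bernoulli likelihoods.
PROB_EPS = 1e-12

#: Lower bound enforced on every optimized Dirichlet entry.
ALPHA_FLOOR = 0.01


@dataclass(frozen=True)
class PhiPriors:
    """Beta shapes for code probabilities: (a0,b0) spike, (a1,b1) slab."""

    a0: float
    b0: float
    a1: float
    b1: float

    def __post_init__(self) -> None:
        if min(self.a0, self.b0, self.a1, self.b1) <= 0:
            raise ValueError("Beta shape parameters must be positive")

    def shapes(self, active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Elementwise (a, b) arrays selected by the indicator array."""
        active = np.asarray(active)
        return (
            np.where(active == 1, self.a1, self.a0),
            np.where(active == 1, self.b1, self.b0),
        )


@dataclass(frozen=True)
class RhoPriors:
    """Beta priors for the tree transition probabilities (rho01, rho11)."""

    a01: float = 3.0
    b01: float = 20.0
    a11: float = 3.0
    b11: float = 3.0

    def __post_init__(self) -> None:
        if min(self.a01, self.b01, self.a11, self.b11) <= 0:
            raise ValueError("Beta shape parameters must be positive")


@dataclass
class Hyperparams:
    """Dirichlet vector plus the fixed Beta priors."""

    alpha: np.ndarray
    phi_priors: PhiPriors
    rho_priors: RhoPriors = field(default_factory=RhoPriors)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1 or len(self.alpha) < 1:
            raise ValueError("alpha must be a nonempty vector")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha entries must be positive")

    @property
    def K(self) -> int:
        return len(self.alpha)


# Prevalence-adaptive spike/slab priors: (lower bound of range) -> priors.
# Chosen so inactive codes get near-zero probability while active codes
# stay clearly above the smallest prevalence in the data.
_PREVALENCE_PRIOR_TABLE = (
    (0.01, PhiPriors(0.1, 500.0, 2.0, 4.0)),
    (0.005, PhiPriors(0.1, 1000.0, 1.5, 3.0)),
    (0.0, PhiPriors(0.1, 4000.0, 1.2, 3.0)),
)


def select_phi_priors(min_prevalence: float) -> PhiPriors:
    """Pick the spike/slab Beta priors from the minimal code prevalence.

    Ranges: [0.01, 1) -> Beta(0.1,500)/Beta(2,4);
    [0.005, 0.01) -> Beta(0.1,1000)/Beta(1.5,3);
    (0, 0.005) -> Beta(0.1,4000)/Beta(1.2,3).
    """
    if not 0.0 < min_prevalence < 1.0:
        raise ValueError(
            f"min_prevalence must be in (0, 1), got {min_prevalence!r}"
        )
    for lower, priors in _PREVALENCE_PRIOR_TABLE:
        if min_prevalence >= lower:
            return priors
    raise AssertionError("unreachable")  # pragma: no cover


def priors_for_data(data: DiagnosisMatrix) -> PhiPriors:
    """Spike/slab priors from the data's minimal prevalence, clamped
    into (0, 1) so degenerate all-zero/all-one columns still resolve."""
    prev = float(data.prevalence().min())
    return select_phi_priors(min(max(prev, PROB_EPS), 1 - PROB_EPS))


@dataclass
class ModelState:
    """Current values of all latent variables.

    Phi is K x S (terminal codes only); I is K x n_nodes over the full
    tree with the root column fixed at 0; Z is D x S with 0-based topic
    indices internally (1-based in reports); Z_sum is the D x K count
    matrix with rows summing to S.
    """

    Phi: np.ndarray
    I: np.ndarray
    rho: np.ndarray
    Z: np.ndarray
    Z_sum: np.ndarray

    @property
    def K(self) -> int:
        return self.Phi.shape[0]

    @property
    def S(self) -> int:
        return self.Phi.shape[1]

    @property
    def D(self) -> int:
        return self.Z.shape[0]

    def copy(self) -> "ModelState":
        return ModelState(
            Phi=self.Phi.copy(),
            I=self.I.copy(),
            rho=self.rho.copy(),
            Z=self.Z.copy(),
            Z_sum=self.Z_sum.copy(),
        )

    def check(self) -> None:
        """Assert internal consistency (debug aid)."""
        assert self.Z_sum.shape == (self.D, self.K)
        assert np.all(self.Z_sum.sum(axis=1) == self.S), "Z_sum rows must sum to S"
        recon = np.zeros_like(self.Z_sum)
        for k in range(self.K):
            recon[:, k] = (self.Z == k).sum(axis=1)
        assert np.array_equal(recon, self.Z_sum), "Z_sum inconsistent with Z"
        assert np.all((self.rho > 0) & (self.rho < 1))
        assert np.all(self.I[:, 0] == 0), "root indicator must stay 0"


def compute_z_sum(Z: np.ndarray, K: int) -> np.ndarray:
    """Recompute the D x K assignment-count matrix from Z."""
    D = Z.shape[0]
    Z_sum = np.zeros((D, K), dtype=np.int32)
    for k in range(K):
        Z_sum[:, k] = (Z == k).sum(axis=1)
    return Z_sum


def init_state(
    data: DiagnosisMatrix,
    tree: TreeStructure,
    K: int,
    seed: int | np.random.Generator = 0,
) -> ModelState:
    """Initialize the chain: I all zero, rho=(0.1, 0.5), Z uniform over
    topics, Phi from the inactive (spike) Beta prior matching I=0."""
    if K < 1:
        raise ValueError("K must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    priors = priors_for_data(data)
    D, S = data.D, data.S
    Z = rng.integers(0, K, size=(D, S)).astype(np.int32)
    Phi = rng.beta(priors.a0, priors.b0, size=(K, S))
    Phi = np.clip(Phi, PROB_EPS, 1 - PROB_EPS)
    I = np.zeros((K, tree.n_nodes), dtype=np.int8)
    return ModelState(
        Phi=Phi,
        I=I,
        rho=np.array([0.1, 0.5]),
        Z=Z,
        Z_sum=compute_z_sum(Z, K),
    )
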