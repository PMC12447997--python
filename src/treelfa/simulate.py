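"""Generative simulator for treeLFA.

Draws binary diagnosis matrices from the model's own generative
process: per individual a topic-weight vector theta ~ Dirichlet(alpha),
per code a topic assignment z ~ Categorical(theta) and a diagnosis
x ~ Bernoulli(topics[z, s]). The default configuration reproduces the
worked example: 5,000 individuals, 15 codes under 5 internal nodes,
4 topics with disjoint active code sets at probability 0.3 and a
symmetric Dirichlet(0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DiagnosisMatrix, TreeStructure, tree_from_edges

ROOT_NAME = "root"


def make_tree(n_internal: int, children_per_internal: int) -> TreeStructure:
    """Three-layer tree: root -> C1..Cn -> D1..D(n*c) terminals."""
    if n_internal < 1 or children_per_internal < 1:
        raise ValueError("both counts must be at least 1")
    edges: list[tuple[str, str]] = []
    d = 0
    for i in range(1, n_internal + 1):
        edges.append((f"C{i}", ROOT_NAME))
        for _ in range(children_per_internal):
            d += 1
            edges.append((f"D{d}", f"C{i}"))
    return tree_from_edges(edges)


@dataclass
class SimConfig:
    """Simulation settings. Defaults reproduce the worked example."""

    D: int = 5000
    n_internal: int = 5
    children_per_internal: int = 3
    K: int = 4
    p_active: float = 0.3
    alpha_true: np.ndarray = field(default_factory=lambda: np.full(4, 0.1))
    # disjoint active blocks covering all 15 codes, the last aligned
    # with one tree branch (true sets are an implementation choice)
    active_sets: list[list[str]] = field(
        default_factory=lambda: [
            ["D1", "D2", "D3", "D4"],
            ["D5", "D6", "D7", "D8"],
            ["D9", "D10", "D11", "D12"],
            ["D13", "D14", "D15"],
        ]
    )
    seed: int = 0

    @property
    def S(self) -> int:
        return self.n_internal * self.children_per_internal

    @property
    def codes(self) -> list[str]:
        return [f"D{i}" for i in range(1, self.S + 1)]

    def __post_init__(self) -> None:
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        if len(self.alpha_true) != self.K:
            raise ValueError("alpha_true must have length K")
        if not 0.0 < self.p_active < 1.0:
            raise ValueError("p_active must be in (0, 1)")
        if len(self.active_sets) != self.K:
            raise ValueError("one active set per topic required")
        codes = set(self.codes)
        for s in self.active_sets:
            if not set(s) <= codes:
                raise ValueError("active sets must be subsets of the codes")


def make_topics(cfg: SimConfig) -> np.ndarray:
    """K x S topic matrix: p_active on each topic's active set, else 0."""
    topics = np.zeros((cfg.K, cfg.S))
    pos = {c: i for i, c in enumerate(cfg.codes)}
    for k, active in enumerate(cfg.active_sets):
        for code in active:
            topics[k, pos[code]] = cfg.p_active
    return topics


def simulate_data(
    topics: np.ndarray,
    alpha_true: np.ndarray,
    D: int,
    seed: int | np.random.Generator = 0,
    codes: list[str] | None = None,
) -> DiagnosisMatrix:
    """Draw a D-individual diagnosis matrix from the generative process."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    topics = np.atleast_2d(np.asarray(topics, dtype=float))
    alpha_true = np.asarray(alpha_true, dtype=float)
    K, S = topics.shape
    if codes is None:
        codes = [f"D{i}" for i in range(1, S + 1)]
    theta = rng.dirichlet(alpha_true, size=D)  # (D, K)
    c = np.cumsum(theta, axis=1)
    X = np.zeros((D, S), dtype=np.int8)
    for s in range(S):
        u = rng.random(D) * c[:, -1]
        z = (c < u[:, None]).sum(axis=1)
        X[:, s] = rng.random(D) < topics[z, s]
    return DiagnosisMatrix(values=X, codes=list(codes))


def simulate_example(
    cfg: SimConfig | None = None,
) -> tuple[DiagnosisMatrix, TreeStructure, np.ndarray, np.ndarray]:
    """Data, tree, generating topics and generating alpha for a config."""
    cfg = cfg or SimConfig()
    topics = make_topics(cfg)
    tree = make_tree(cfg.n_internal, cfg.children_per_internal)
    data = simulate_data(topics, cfg.alpha_true, cfg.D, cfg.seed, cfg.codes)
    tree.align_terminals(data.codes)
    return data, tree, topics, cfg.alpha_true.copy()
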