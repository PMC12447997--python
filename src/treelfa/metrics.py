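"""Topic-quality metrics: NPMI coherence and topic diversity."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import DiagnosisMatrix


@dataclass
class CooccurrenceTable:
    """Empirical marginal and pairwise co-presence frequencies."""

    P_i: np.ndarray  # (S,)
    P_ij: np.ndarray  # (S, S), symmetric, diagonal = P_i
    D: int

    @classmethod
    def from_data(cls, data: DiagnosisMatrix) -> "CooccurrenceTable":
        X = data.values.astype(float)
        return cls(P_i=X.mean(axis=0), P_ij=(X.T @ X) / data.D, D=data.D)


def npmi(P_i: float, P_j: float, P_ij: float) -> float:
    """Normalized pointwise mutual information of two codes.

    log(P_ij / (P_i P_j)) / (-log P_ij), in [-1, 1]: -1 for codes that
    never co-occur, 0 at independence, 1 for perfect co-occurrence.
    A zero marginal makes the score undefined: NaN is returned.
    """
    for name, p in (("P_i", P_i), ("P_j", P_j), ("P_ij", P_ij)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p!r}")
    if P_ij > min(P_i, P_j) + 1e-12:
        raise ValueError("P_ij cannot exceed min(P_i, P_j)")
    if P_i == 0.0 or P_j == 0.0:
        return math.nan
    if P_ij == 0.0:
        return -1.0
    if P_ij == P_i == P_j:
        return 1.0
    return math.log(P_ij / (P_i * P_j)) / (-math.log(P_ij))


def _top_codes(topic: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest-probability codes, ties by code order."""
    return np.argsort(-topic, kind="stable")[:n]


def topic_coherence(
    topics: np.ndarray, data: DiagnosisMatrix, top_n: int | None = None
) -> float:
    """Mean NPMI over code pairs within each topic's top codes.

    TC = (1/K) sum_k 1/(S'(S'-1)) sum_{i<j} f(c_i^k, c_j^k), where codes
    are ranked by probability within the topic and S' = top_n (all codes
    by default). Note the 1/(S'(S'-1)) constant together with the i<j
    sum halves the plain pair average. Pairs with an undefined NPMI
    (zero-prevalence code) are skipped with a warning.
    """
    topics = np.atleast_2d(np.asarray(topics, dtype=float))
    K, S = topics.shape
    if S != data.S:
        raise ValueError("topics and data must cover the same codes")
    n = S if top_n is None else int(top_n)
    if n < 2:
        raise ValueError("need at least two top codes per topic")
    table = CooccurrenceTable.from_data(data)
    total = 0.0
    skipped = 0
    for k in range(K):
        top = _top_codes(topics[k], n)
        acc = 0.0
        for a in range(n - 1):
            for b in range(a + 1, n):
                i, j = int(top[a]), int(top[b])
                f = npmi(table.P_i[i], table.P_i[j], table.P_ij[i, j])
                if math.isnan(f):
                    skipped += 1
                    continue
                acc += f
        total += acc / (n * (n - 1))
    if skipped:
        warnings.warn(
            f"{skipped} code pair(s) with a zero-prevalence code skipped in TC",
            stacklevel=2,
        )
    return total / K


def topic_diversity(topics: np.ndarray, N: int) -> float:
    """Fraction of unique codes among the top-N code lists of all topics.

    TD = U / (N K); 1 when all top lists are disjoint, 1/K when all K
    topics share one list.
    """
    topics = np.atleast_2d(np.asarray(topics, dtype=float))
    K, S = topics.shape
    if N < 1:
        raise ValueError("N must be at least 1")
    if N > S:
        raise ValueError(f"N={N} exceeds the number of codes {S}")
    unique: set[int] = set()
    for k in range(K):
        unique.update(int(i) for i in _top_codes(topics[k], N))
    return len(unique) / (N * K)
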