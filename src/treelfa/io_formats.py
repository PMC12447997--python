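"""Input formats for treeLFA: binary diagnosis matrices and disease-code trees.

Two plain-text inputs drive the model:

* a whitespace/tab-delimited binary matrix (individuals x disease codes)
  with a header row of code names, where 1 marks a diagnosis;
* a two-column child/parent table encoding a rooted hierarchy over the
  codes, with the literal name ``root`` as the (implicit) root node.

When no hierarchy is supplied a "flat" tree — every code a direct child
of the root — is used, which makes the prior non-informative over code
similarity ("flatLFA" behaviour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ROOT_NAME = "root"


class InputFormatError(ValueError):
    """Raised when the diagnosis matrix violates the binary-matrix contract."""


class TreeFormatError(ValueError):
    """Raised when the tree-structure table violates the hierarchy contract."""


class RunParamError(ValueError):
    """Raised when sampler/EM run parameters are inconsistent."""


@dataclass
class Violation:
    """One validation failure: a short rule identifier plus context."""

    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.detail}"


@dataclass
class DiagnosisMatrix:
    """D x S binary presence/absence matrix with ordered code names."""

    values: np.ndarray
    codes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.codes = list(self.codes)
        if self.values.ndim != 2:
            raise InputFormatError("diagnosis matrix must be two-dimensional")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise InputFormatError("diagnosis matrix must be at least 1x1")
        if self.values.shape[1] != len(self.codes):
            raise InputFormatError(
                f"{len(self.codes)} code names for {self.values.shape[1]} columns"
            )
        if len(set(self.codes)) != len(self.codes):
            raise InputFormatError("duplicate code names in header")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            d, s = np.argwhere(bad)[0]
            raise InputFormatError(
                f"entry at row {d + 1}, column {self.codes[s]!r} "
                f"({self.values[d, s]!r}) is not a binary integer"
            )
        self.values = self.values.astype(np.int8)

    @property
    def D(self) -> int:
        return self.values.shape[0]

    @property
    def S(self) -> int:
        return self.values.shape[1]

    def prevalence(self) -> np.ndarray:
        """Empirical marginal frequency of each code."""
        return self.values.mean(axis=0)


@dataclass
class TreeStructure:
    """Rooted tree over internal + terminal disease codes.

    ``nodes`` lists the root first, then the remaining nodes in a
    topological (parent-before-child) order. ``terminals`` are the codes
    that carry data; their order must match the diagnosis-matrix columns.
    """

    parent: dict[str, str]  # child -> parent, root excluded

    nodes: list[str] = field(init=False)
    terminals: list[str] = field(init=False)
    parent_idx: np.ndarray = field(init=False)  # per node, -1 for root
    children: list[list[int]] = field(init=False)
    terminal_node_idx: np.ndarray = field(init=False)  # code position -> node index

    def __post_init__(self) -> None:
        children_names = list(self.parent)
        if ROOT_NAME in children_names:
            raise TreeFormatError("'root' must not appear as a child (column 1)")
        parents = set(self.parent.values())
        if ROOT_NAME not in parents:
            raise TreeFormatError("no 'root' code among the parents (column 2)")
        for p in parents - {ROOT_NAME}:
            if p not in self.parent:
                raise TreeFormatError(
                    f"parent code {p!r} never appears as a child (column 1)"
                )
        # topological order by walking down from the root
        kids: dict[str, list[str]] = {ROOT_NAME: []}
        for c in children_names:
            kids.setdefault(c, [])
            kids.setdefault(self.parent[c], []).append(c)
        order, stack = [], [ROOT_NAME]
        while stack:
            v = stack.pop(0)
            order.append(v)
            stack.extend(kids[v])
        if len(order) != len(children_names) + 1:
            raise TreeFormatError("tree contains a cycle or unreachable nodes")
        self.nodes = order
        idx = {n: i for i, n in enumerate(order)}
        self.parent_idx = np.array(
            [-1 if n == ROOT_NAME else idx[self.parent[n]] for n in order],
            dtype=np.int64,
        )
        self.children = [[idx[c] for c in kids[n]] for n in order]
        self.terminals = [c for c in children_names if c not in parents]
        self.terminal_node_idx = np.array([idx[t] for t in self.terminals])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(c, p) for c, p in self.parent.items()]

    def align_terminals(self, codes: Sequence[str]) -> None:
        """Reorder ``terminals`` to match the diagnosis-matrix column order."""
        if set(self.terminals) != set(codes):
            raise TreeFormatError("terminal codes differ from data codes")
        idx = {n: i for i, n in enumerate(self.nodes)}
        self.terminals = list(codes)
        self.terminal_node_idx = np.array([idx[t] for t in self.terminals])


@dataclass
class RunConfig:
    """Run parameters shared by the Gibbs sampler and Gibbs-EM."""

    K: int
    alpha0: np.ndarray
    burn_in: int = 0
    cycle: int = 0
    interval: int = 1
    opt_N_1: int = 1
    cycle_1: int = 0
    opt_N_2: int = 1
    cycle_2: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha0 = np.asarray(self.alpha0, dtype=float)


def read_diagnosis_matrix(path: str | Path) -> DiagnosisMatrix:
    """Read a whitespace/tab-delimited binary matrix with a header row.

    Raises :class:`InputFormatError` (naming row and column) on any entry
    that is not an integer 0 or 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    codes = [str(c) for c in df.columns]
    raw = df.to_numpy()
    values = np.zeros(raw.shape, dtype=np.int8)
    for s, code in enumerate(codes):
        col = raw[:, s]
        ok = (col == "0") | (col == "1")
        if not ok.all():
            d = int(np.argmin(ok))
            raise InputFormatError(
                f"entry at row {d + 1}, column {code!r} ({col[d]!r}) "
                "is not a binary integer; the input is not a binary integer matrix"
            )
        values[:, s] = col == "1"
    mat = DiagnosisMatrix(values=values, codes=codes)
    zero = np.flatnonzero(mat.prevalence() == 0)
    if zero.size:
        warnings.warn(
            "codes with zero prevalence: "
            + ", ".join(codes[i] for i in zero)
            + " (the prior will dominate their topic probabilities)",
            stacklevel=2,
        )
    return mat


def write_diagnosis_matrix(data: DiagnosisMatrix, path: str | Path) -> None:
    """Write the matrix tab-separated with the code-name header row."""
    pd.DataFrame(data.values.astype(int), columns=data.codes).to_csv(
        path, sep="\t", index=False
    )


def read_tree_structure(
    path: str | Path, codes: Sequence[str] | None = None
) -> TreeStructure:
    """Read a two-column child/parent table into a validated tree.

    When ``codes`` is given the full rule set (terminal/data name match
    etc.) is enforced; structural rules are always enforced.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] != 2:
        raise TreeFormatError(f"expected two columns, found {df.shape[1]}")
    # a header row like "child parent" is tolerated if it is not itself an edge
    child, parent = df[0].tolist(), df[1].tolist()
    tree = tree_from_edges(list(zip(child, parent)))
    if codes is not None:
        violations = validate_tree(tree, codes)
        if violations:
            raise TreeFormatError("; ".join(map(str, violations)))
        tree.align_terminals(codes)
    return tree


def write_tree_structure(tree: TreeStructure, path: str | Path) -> None:
    """Write the child/parent edge table, tab-separated, no header."""
    pd.DataFrame(tree.edges).to_csv(path, sep="\t", index=False, header=False)


def tree_from_edges(edges: Sequence[tuple[str, str]]) -> TreeStructure:
    """Build a tree from (child, parent) pairs, rejecting duplicate children."""
    parent: dict[str, str] = {}
    for c, p in edges:
        if c in parent:
            raise TreeFormatError(
                f"column 1 contains repetitive disease codes: {c!r}"
            )
        parent[c] = p
    return TreeStructure(parent=parent)


def flat_tree(codes: Sequence[str]) -> TreeStructure:
    """Non-informative tree: every code a direct child of the root."""
    codes = list(codes)
    if not codes:
        raise TreeFormatError("cannot build a flat tree over zero codes")
    if len(set(codes)) != len(codes):
        raise TreeFormatError("duplicate codes")
    return tree_from_edges([(c, ROOT_NAME) for c in codes])


def validate_tree(tree: TreeStructure, codes: Sequence[str]) -> list[Violation]:
    """Check the six formatting rules relating the tree to the data codes.

    Returns an empty list on success, otherwise one :class:`Violation`
    per failed rule. Structural rules (single parent, acyclicity, root
    placement) are enforced at construction; this adds the cross-checks
    against the data codes.
    """
    v: list[Violation] = []
    codes = list(codes)
    terminals = set(tree.terminals)
    data_codes = set(codes)
    if terminals != data_codes:
        missing = sorted(terminals - data_codes) + sorted(data_codes - terminals)
        v.append(
            Violation(
                "terminal/data mismatch",
                "tree terminals and data codes should be exactly the same; "
                f"differing codes: {', '.join(missing)}",
            )
        )
    parents = set(tree.parent.values())
    overlap = (parents - {ROOT_NAME}) & data_codes
    if overlap:
        v.append(
            Violation(
                "parent among data codes",
                f"parent codes also appear as data codes: {', '.join(sorted(overlap))}",
            )
        )
    # rules below are guaranteed by construction but re-checked for defence
    if ROOT_NAME in tree.parent:
        v.append(Violation("root in column 1", "'root' appears as a child"))
    if ROOT_NAME not in parents:
        v.append(Violation("missing root", "no 'root' code in the 2nd column"))
    col1 = set(tree.parent)
    dangling = (parents - {ROOT_NAME}) - col1
    if dangling:
        v.append(
            Violation(
                "parent not in column 1",
                f"parent codes never defined as children: {', '.join(sorted(dangling))}",
            )
        )
    internal_in_col1 = col1 - terminals
    extra = internal_in_col1 - (parents - {ROOT_NAME})
    if extra:
        v.append(
            Violation(
                "parent sets differ",
                f"internal codes in column 1 never used as parents: {', '.join(sorted(extra))}",
            )
        )
    return v


def validate_run_params(cfg: RunConfig) -> list[Violation]:
    """Check sampler/EM parameter consistency; empty list means pass."""
    v: list[Violation] = []
    if len(cfg.alpha0) != cfg.K:
        v.append(
            Violation(
                "alpha length",
                f"topic number K={cfg.K} does not equal the length of the "
                f"alpha vector ({len(cfg.alpha0)})",
            )
        )
    if np.any(cfg.alpha0 <= 0):
        v.append(Violation("alpha positivity", "alpha entries must be positive"))
    if cfg.cycle and not cfg.burn_in < cfg.cycle:
        v.append(
            Violation(
                "burn-in bound",
                f"burn_in={cfg.burn_in} should be smaller than cycle={cfg.cycle}",
            )
        )
    if cfg.cycle and cfg.interval > cfg.cycle - cfg.burn_in:
        v.append(
            Violation(
                "interval bound",
                f"interval={cfg.interval} should not exceed cycle-burn_in="
                f"{cfg.cycle - cfg.burn_in}",
            )
        )
    if cfg.cycle and cfg.interval < 1:
        v.append(Violation("interval positivity", "interval must be >= 1"))
    for name in ("burn_in", "cycle", "opt_N_1", "cycle_1", "opt_N_2", "cycle_2"):
        if getattr(cfg, name) < 0:
            v.append(Violation("negative parameter", f"{name} must be nonnegative"))
    return v


def estimate_memory_kb(D: int, K: int, N_ps: int, S: int) -> int:
    """Posterior-sample storage estimate, M = 8*D*K*N_ps + 8*D*S*2.

    The first term is the stack of D x K topic-assignment count matrices
    across N_ps posterior samples, the second the two D x S matrices
    (input data and current topic assignment) held during inference.
    """
    for name, val in (("D", D), ("K", K), ("N_ps", N_ps), ("S", S)):
        if int(val) != val or val <= 0:
            raise ValueError(f"{name} must be a positive integer, got {val!r}")
    return 8 * D * K * N_ps + 8 * D * S * 2
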