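"""The predictive network: adjacency assembly and hub centrality.

Each fitted per-target model contributes one column of a directed
weighted adjacency matrix A: ``A[i, j]`` is the gain importance of
predictor dummy i in the model whose target is dummy j, so rows are
outgoing links ("i helps predict others") and columns incoming links.
No edge thresholding is applied.  Hub scores are the HITS hub vector:
the principal eigenvector of ``A @ A.T``, obtained by power iteration
and max-normalized so the strongest hub scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import EncodedMatrix


@dataclass
class PredictiveNetwork:
    """Directed weighted graph over dummy variables."""

    nodes: list[str]
    A: np.ndarray  # N x N, nonnegative; rows outgoing, columns incoming
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def edge_list(self) -> pd.DataFrame:
        """Non-zero edges as (source, target, weight), row-major order."""
        src, dst = np.nonzero(self.A)
        return pd.DataFrame(
            {
                "source_dummy": [self.nodes[i] for i in src],
                "target_dummy": [self.nodes[j] for j in dst],
                "weight": self.A[src, dst],
            }
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["source_dummy"], row["target_dummy"],
                       weight=float(row["weight"]))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


@dataclass
class HubScores:
    """Max-normalized principal eigenvector of ``A @ A.T``."""

    nodes: list[str]
    scores: np.ndarray
    eigenvalue: float
    iterations: int
    converged: bool

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.nodes, name="hub_score")


def build_adjacency(
    importances: dict[str, pd.Series],
    encoded: EncodedMatrix,
    normalize_columns: bool = True,
) -> PredictiveNetwork:
    """Place per-target importance vectors into the adjacency matrix.

    ``importances`` maps each non-skipped target dummy to a Series of
    gain importances indexed by predictor dummy name.  An importance
    vector that mentions any dummy from the target's own variable group
    trips the leakage sentinel and raises.  With ``normalize_columns``
    (default) every non-zero column is rescaled to sum to 1, so each
    fitted model contributes equal total edge weight.
    """
    nodes = list(encoded.columns)
    n = len(nodes)
    idx = {c: i for i, c in enumerate(nodes)}
    A = np.zeros((n, n))
    for target, vec in importances.items():
        j = encoded.column_index(target)
        banned = set(encoded.groups[encoded.group_of(target)])
        offenders = banned.intersection(vec.index)
        if offenders:
            raise ValueError(
                f"leakage: importance vector for {target!r} contains "
                f"same-group dummies {sorted(offenders)}"
            )
        for feat, imp in vec.items():
            if imp < 0:
                raise ValueError(f"negative importance for {feat!r}")
            if imp > 0:
                A[idx[feat], j] = imp
    if normalize_columns:
        col_sums = A.sum(axis=0)
        nz = col_sums > 0
        A[:, nz] /= col_sums[nz]
    return PredictiveNetwork(nodes=nodes, A=A,
                             groups={v: list(c) for v, c in encoded.groups.items()})


def hub_scores(
    net: PredictiveNetwork,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> HubScores:
    """Power iteration for the dominant eigenvector of ``M = A @ A.T``.

    Starts from the uniform positive vector; each iterate is divided by
    its maximum, and convergence is declared when successive normalized
    iterates differ by less than ``tol`` in max-norm.  By
    Perron-Frobenius the limit is nonnegative.  The zero matrix yields
    the all-zero score vector.
    """
    if np.any(net.A < 0):
        raise ValueError("adjacency must be nonnegative")
    M = net.A @ net.A.T
    n = len(net.nodes)
    v = np.ones(n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        w = M @ v
        mx = w.max()
        if mx <= 0.0:
            return HubScores(net.nodes, np.zeros(n), 0.0, iterations, True)
        w /= mx
        if np.max(np.abs(w - v)) < tol:
            v = w
            converged = True
            break
        v = w
    eigenvalue = float(v @ (M @ v) / (v @ v))
    return HubScores(net.nodes, v, eigenvalue, iterations, converged)


def rank_hubs(scores: HubScores, k: int) -> list[tuple[str, float]]:
    """Top-``k`` nodes by hub score, ties broken by node name ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(zip(scores.nodes, scores.scores),
                   key=lambda t: (-t[1], t[0]))
    return [(n, float(s)) for n, s in order[: min(k, len(order))]]


def hub_table(scores: HubScores) -> pd.DataFrame:
    """Full hub table: node, source variable, level, score, rank."""
    ranked = rank_hubs(scores, len(scores.nodes))
    rows = []
    for rank, (node, s) in enumerate(ranked, start=1):
        var, _, level = node.partition("=")
        rows.append((node, var, level, s, rank))
    return pd.DataFrame(
        rows, columns=["node", "variable", "level", "hub_score", "rank"]
    )
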