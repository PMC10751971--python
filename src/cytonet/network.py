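"""Signed Pearson correlation networks and eigenvector centrality.

A condition's network has one node per retained analyte and an edge for
every unordered analyte pair whose Pearson correlation magnitude strictly
exceeds a threshold (``r > 0.9`` "very strong" for the compression arms,
``r > 0.7`` "strong" for the pharmacological-activation arm). The sign of
the correlation is kept as an edge attribute, so inverse relationships
(e.g. LIF or IL-16 vs VEGFA in unloaded tissue) remain visible.

Node influence is scored by eigenvector centrality C_λ: the leading
eigenvector of the binary (unsigned) adjacency matrix, made non-negative
(Perron–Frobenius) and normalized by its maximum entry. The score lives
on [0, 1]: isolated nodes score 0 and the best-connected node scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import FilteredGroupMatrix

__all__ = [
    "CorrelationMatrix",
    "SignedNetwork",
    "CentralityTable",
    "pearson_matrix",
    "threshold_network",
    "eigenvector_centrality",
    "to_networkx",
    "write_edgelist_csv",
    "read_edgelist_csv",
    "write_graphml",
]

Pair = tuple[str, str]


def make_pair(a: str, b: str) -> Pair:
    """Canonical unordered analyte pair (sorted tuple)."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class CorrelationMatrix:
    """All-pairs Pearson correlations within one condition."""

    analytes: list[str]
    r: np.ndarray
    n: int
    source_condition: str | None = None

    def validate(self) -> None:
        p = len(self.analytes)
        if self.r.shape != (p, p):
            raise ValueError("correlation matrix shape does not match analytes")
        if np.max(np.abs(self.r - self.r.T)) > 1e-12:
            raise ValueError("correlation matrix not symmetric to 1e-12")
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-12:
            raise ValueError("correlation matrix diagonal is not 1")
        if self.n < 3:
            raise ValueError("n must be >= 3")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.analytes, columns=self.analytes)


@dataclass
class SignedNetwork:
    """Thresholded signed correlation network for one condition.

    ``edges`` maps each unordered analyte pair (sorted tuple) to its
    Pearson r; every edge satisfies ``|r| > r_min`` strictly. All retained
    analytes are kept as nodes, including isolates.
    """

    nodes: list[str]
    edges: dict[Pair, float]
    r_min: float
    source_condition: str | None = None

    def sign(self, pair: Pair) -> str:
        return "+" if self.edges[pair] > 0 else "-"

    @property
    def edge_pairs(self) -> set[Pair]:
        return set(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for p in self.edges if node in p)

    def validate(self) -> None:
        nodeset = set(self.nodes)
        for (a, b), r in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if (a, b) != make_pair(a, b):
                raise ValueError(f"edge pair {(a, b)!r} is not in canonical order")
            if not {a, b} <= nodeset:
                raise ValueError(f"edge {(a, b)!r} references unknown node")
            if abs(r) <= self.r_min:
                raise ValueError(f"edge {(a, b)!r} violates |r| > {self.r_min}: r={r}")


@dataclass
class CentralityTable:
    """Per-node eigenvector centrality C_λ on [0, 1]."""

    scores: dict[str, float]
    dominant_eigenvalue: float
    degenerate: bool = False

    def __getitem__(self, node: str) -> float:
        return self.scores[node]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"analyte": list(self.scores), "c_lambda": list(self.scores.values())}
        )


def pearson_matrix(
    matrix: FilteredGroupMatrix | pd.DataFrame,
    *,
    log10_transform: bool = False,
) -> CorrelationMatrix:
    """Sample Pearson correlation for every unordered analyte pair.

    ``log10_transform`` computes correlations on log10 concentrations
    instead of the raw pg/mL scale.
    """
    if isinstance(matrix, FilteredGroupMatrix):
        values = matrix.values
        source = matrix.group
    else:
        values = matrix
        source = None
    analytes = list(values.columns)
    x = values.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got {x.shape[0]}")
    sd = x.std(axis=0)
    zero = [a for a, s in zip(analytes, sd) if s == 0.0]
    if zero:
        raise ValueError(f"zero-variance analyte(s) reached pearson_matrix: {zero}")
    if log10_transform:
        x = np.log10(x)
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    out = CorrelationMatrix(analytes=analytes, r=r, n=x.shape[0], source_condition=source)
    out.validate()
    return out


def threshold_network(
    corr: CorrelationMatrix,
    r_min: float,
    *,
    source_condition: str | None = None,
) -> SignedNetwork:
    """Build the signed network with an edge wherever ``|r| > r_min``.

    The inequality is strict: a pair at exactly the threshold gets no
    edge. All analytes are kept as nodes, including isolates.
    """
    if not 0.0 < r_min < 1.0:
        raise ValueError(f"r_min must be in (0, 1), got {r_min}")
    corr.validate()
    edges: dict[Pair, float] = {}
    p = len(corr.analytes)
    for i in range(p):
        for j in range(i + 1, p):
            r = float(corr.r[i, j])
            if abs(r) > r_min:
                edges[make_pair(corr.analytes[i], corr.analytes[j])] = r
    return SignedNetwork(
        nodes=list(corr.analytes),
        edges=edges,
        r_min=r_min,
        source_condition=source_condition or corr.source_condition,
    )


def _adjacency(net: SignedNetwork) -> np.ndarray:
    idx = {a: i for i, a in enumerate(net.nodes)}
    a = np.zeros((len(net.nodes), len(net.nodes)))
    for (u, v) in net.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    return a


def _leading_scores(adj: np.ndarray) -> tuple[np.ndarray, float, bool]:
    w, v = np.linalg.eigh(adj)
    lam = float(w[-1])
    vec = np.abs(v[:, -1])
    degenerate = len(w) > 1 and (lam - float(w[-2])) < 1e-8 * max(1.0, abs(lam))
    vec[adj.sum(axis=0) == 0] = 0.0  # isolates score exactly 0
    if vec.max() > 0:
        vec = vec / vec.max()
    return vec, lam, degenerate


def eigenvector_centrality(
    net: SignedNetwork, *, per_component: bool = False
) -> CentralityTable:
    """Eigenvector centrality C_λ of the binary (unsigned) adjacency.

    The leading eigenvector is made non-negative and normalized by its
    maximum entry, so the best-connected node scores exactly 1 and an
    edgeless network scores all zeros. In a disconnected graph the global
    leading eigenvector localizes on the spectrally dominant component and
    other components score ≈ 0; ``per_component=True`` instead analyzes
    each connected component independently (each max-normalized within
    itself). If the top eigenvalue is (numerically) degenerate — e.g. two
    disjoint identical components — the deterministic symmetric
    eigen-solver's output is used and a degeneracy warning attached.
    """
    if not net.edges:
        return CentralityTable(
            scores={a: 0.0 for a in net.nodes}, dominant_eigenvalue=0.0
        )
    adj = _adjacency(net)
    if per_component:
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(net.edges)
        scores = {a: 0.0 for a in net.nodes}
        lam_max, degenerate = 0.0, False
        idx = {a: i for i, a in enumerate(net.nodes)}
        for comp in nx.connected_components(g):
            members = [a for a in net.nodes if a in comp]
            if len(members) == 1:
                continue
            sub = adj[np.ix_([idx[a] for a in members], [idx[a] for a in members])]
            vec, lam, deg = _leading_scores(sub)
            degenerate = degenerate or deg
            lam_max = max(lam_max, lam)
            for a, s in zip(members, vec):
                scores[a] = float(s)
    else:
        vec, lam_max, degenerate = _leading_scores(adj)
        scores = {a: float(s) for a, s in zip(net.nodes, vec)}
    if degenerate:
        warnings.warn(
            "dominant adjacency eigenvalue is degenerate; centrality of the "
            "tied components is solver-determined",
            RuntimeWarning,
            stacklevel=2,
        )
    return CentralityTable(
        scores=scores, dominant_eigenvalue=float(lam_max), degenerate=degenerate
    )


def edge_permutation_pvalues(
    matrix: FilteredGroupMatrix | pd.DataFrame,
    net: SignedNetwork,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    log10_transform: bool = False,
) -> dict[Pair, float]:
    """Optional two-sided permutation p-value per edge (off by default).

    Edges are defined by magnitude alone; this annotation estimates, for
    each edge, the fraction of row-permutations of one member whose |r|
    reaches the observed |r| (add-one estimator). Purely descriptive —
    no multiple-testing control is applied.
    """
    values = matrix.values if isinstance(matrix, FilteredGroupMatrix) else matrix
    x = values.to_numpy(dtype=float)
    if log10_transform:
        x = np.log10(x)
    cols = {a: i for i, a in enumerate(values.columns)}
    rng = np.random.default_rng(seed)
    out: dict[Pair, float] = {}
    for (a, b), r_obs in net.edges.items():
        xa, xb = x[:, cols[a]], x[:, cols[b]]
        count = 0
        for _ in range(n_permutations):
            rp = np.corrcoef(rng.permutation(xa), xb)[0, 1]
            count += abs(rp) >= abs(r_obs)
        out[(a, b)] = (count + 1) / (n_permutations + 1)
    return out


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def network_to_dataframe(net: SignedNetwork) -> pd.DataFrame:
    rows = [
        {"node_a": a, "node_b": b, "r": r, "sign": "+" if r > 0 else "-"}
        for (a, b), r in sorted(net.edges.items())
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "sign"])


def write_edgelist_csv(net: SignedNetwork, path: Path | str) -> None:
    network_to_dataframe(net).to_csv(path, index=False, encoding="utf-8")


def read_edgelist_csv(
    path: Path | str, *, r_min: float, nodes: list[str] | None = None,
    source_condition: str | None = None,
) -> SignedNetwork:
    df = pd.read_csv(path)
    edges = {
        make_pair(str(row.node_a), str(row.node_b)): float(row.r)
        for row in df.itertuples()
    }
    if nodes is None:
        seen: dict[str, None] = {}
        for a, b in edges:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        nodes = list(seen)
    return SignedNetwork(
        nodes=nodes, edges=edges, r_min=r_min, source_condition=source_condition
    )


def to_networkx(net: SignedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for (a, b), r in sorted(net.edges.items()):
        g.add_edge(a, b, r=float(r), sign="+" if r > 0 else "-")
    return g


def write_graphml(net: SignedNetwork, path: Path | str) -> None:
    nx.write_graphml(to_networkx(net), str(path))
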