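"""Edge-level comparison of condition networks.

Two condition networks are compared by edge identity — the unordered
analyte pair under canonical naming — yielding conserved, gained (only in
the second network), lost (only in the first), and sign-flipped edges
(present in both with opposite correlation sign, e.g. the LIF–VEGFA and
IL-16–VEGFA inversions that reverse between unloaded and statically
loaded tissue). Edge identity ignores r magnitude: a conserved edge may
change strength, and the strength delta is reported separately. Network
similarity is summarized by the Jaccard index of the edge-pair sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .network import CentralityTable, Pair, SignedNetwork, make_pair
from .panel_io import canonical_name

__all__ = ["NetworkDiff", "NodeDiff", "diff_networks", "node_neighborhood_change", "multi_compare", "MultiDiff"]


def _canonical_edges(net: SignedNetwork) -> dict[Pair, float]:
    out: dict[Pair, float] = {}
    for (a, b), r in net.edges.items():
        out[make_pair(canonical_name(a), canonical_name(b))] = r
    return out


@dataclass
class NetworkDiff:
    """Edge-set difference between two signed networks (A → B)."""

    label_a: str
    label_b: str
    conserved: set[Pair]
    gained: set[Pair]
    lost: set[Pair]
    sign_flipped: set[Pair]
    r_a: dict[Pair, float]
    r_b: dict[Pair, float]
    nodes: set[str]

    @property
    def jaccard(self) -> float:
        """|conserved| / |edge-pair union|; 1.0 when both edge sets are
        empty (identical emptiness)."""
        union = len(self.conserved) + len(self.gained) + len(self.lost)
        if union == 0:
            return 1.0
        return len(self.conserved) / union

    def strength_delta(self, pair: Pair) -> float:
        """r_B − r_A for a conserved edge."""
        return self.r_b[pair] - self.r_a[pair]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pair in sorted(self.conserved | self.gained | self.lost):
            status = (
                "conserved" if pair in self.conserved
                else "gained" if pair in self.gained
                else "lost"
            )
            ra = self.r_a.get(pair)
            rb = self.r_b.get(pair)
            rows.append(
                {
                    "node_a": pair[0],
                    "node_b": pair[1],
                    "status": status,
                    "r_a": ra,
                    "r_b": rb,
                    "sign_a": None if ra is None else ("+" if ra > 0 else "-"),
                    "sign_b": None if rb is None else ("+" if rb > 0 else "-"),
                    "sign_flipped": pair in self.sign_flipped,
                    "delta_r": None if ra is None or rb is None else rb - ra,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "node_a", "node_b", "status", "r_a", "r_b",
                "sign_a", "sign_b", "sign_flipped", "delta_r",
            ],
        )


def diff_networks(
    net_a: SignedNetwork,
    net_b: SignedNetwork,
    *,
    label_a: str | None = None,
    label_b: str | None = None,
) -> NetworkDiff:
    """Compare two condition networks edge-by-edge.

    Node sets may differ (per-condition filtering): edges over nodes
    absent from the other network still count as gained/lost. A
    sign-flipped edge is reported as conserved-with-flip, leaving its
    interpretation (preserved vs novel relationship) to the caller.
    """
    ea = _canonical_edges(net_a)
    eb = _canonical_edges(net_b)
    conserved = set(ea) & set(eb)
    gained = set(eb) - set(ea)
    lost = set(ea) - set(eb)
    sign_flipped = {p for p in conserved if (ea[p] > 0) != (eb[p] > 0)}
    nodes = {canonical_name(n) for n in net_a.nodes} | {
        canonical_name(n) for n in net_b.nodes
    }
    return NetworkDiff(
        label_a=label_a or net_a.source_condition or "A",
        label_b=label_b or net_b.source_condition or "B",
        conserved=conserved,
        gained=gained,
        lost=lost,
        sign_flipped=sign_flipped,
        r_a=ea,
        r_b=eb,
        nodes=nodes,
    )


@dataclass
class NodeDiff:
    """Restriction of a :class:`NetworkDiff` to edges incident to one node."""

    node: str
    conserved: set[Pair]
    gained: set[Pair]
    lost: set[Pair]
    sign_flipped: set[Pair]
    c_lambda_a: float | None = None
    c_lambda_b: float | None = None


def node_neighborhood_change(
    diff: NetworkDiff,
    node: str,
    *,
    centrality_a: CentralityTable | None = None,
    centrality_b: CentralityTable | None = None,
) -> NodeDiff:
    """Restrict a diff to the edges containing ``node``.

    Optionally attaches the node's C_λ in each network when centrality
    tables are supplied. The node must be a (canonical) analyte known to
    at least one of the compared networks.
    """
    node = canonical_name(node)
    if node not in diff.nodes:
        raise ValueError(f"unknown analyte {node!r} for diff {diff.label_a} vs {diff.label_b}")

    def restrict(pairs: set[Pair]) -> set[Pair]:
        return {p for p in pairs if node in p}

    return NodeDiff(
        node=node,
        conserved=restrict(diff.conserved),
        gained=restrict(diff.gained),
        lost=restrict(diff.lost),
        sign_flipped=restrict(diff.sign_flipped),
        c_lambda_a=None if centrality_a is None else centrality_a.scores.get(node),
        c_lambda_b=None if centrality_b is None else centrality_b.scores.get(node),
    )


@dataclass
class MultiDiff:
    """All pairwise diffs plus the edges conserved across every network."""

    pairwise: dict[tuple[str, str], NetworkDiff]
    conserved_all: set[Pair]


def multi_compare(networks: list[tuple[str, SignedNetwork]]) -> MultiDiff:
    """Diff every unordered pair of labelled networks.

    The all-conditions-conserved set is the intersection of all edge-pair
    sets (under canonical naming).
    """
    if len(networks) < 2:
        raise ValueError("multi_compare requires at least 2 networks")
    labels = [lab for lab, _ in networks]
    if len(set(labels)) != len(labels):
        raise ValueError("network labels must be unique")
    pairwise = {
        (la, lb): diff_networks(na, nb, label_a=la, label_b=lb)
        for (la, na), (lb, nb) in combinations(networks, 2)
    }
    conserved_all = set(_canonical_edges(networks[0][1]))
    for _, net in networks[1:]:
        conserved_all &= set(_canonical_edges(net))
    return MultiDiff(pairwise=pairwise, conserved_all=conserved_all)
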