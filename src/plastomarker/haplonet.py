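"""Simplified haplotype network over mutational-step distances.

A minimum-spanning network: the MST of the step matrix (Kruskal, with
deterministic lexicographic tie-breaking on node-pair labels) plus, at
``extra_edge_slack > 0``, any non-tree edge whose weight is within the
slack of the heaviest edge on the MST path between its endpoints. This is
a documented simplification of statistical-parsimony (TCS-style) networks:
the verifiable content is the step counts on edges, not the inferred
topology. Median (inferred) nodes are not introduced.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def build_network(steps: pd.DataFrame, extra_edge_slack: int = 0) -> nx.Graph:
    """Minimum-spanning network of a symmetric integer step matrix.

    Edges carry the ``steps`` weight; MST edges are flagged ``in_mst``.
    """
    if steps.empty:
        raise ValueError("empty step matrix")
    if list(steps.index) != list(steps.columns):
        raise ValueError("step matrix must have identical row and column labels")
    if not steps.equals(steps.T):
        raise ValueError("step matrix must be symmetric")
    nodes = sorted(steps.index)
    g = nx.Graph()
    g.add_nodes_from(nodes)

    edges = sorted(
        (int(steps.loc[a, b]), a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    )
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            g.add_edge(a, b, weight=w, in_mst=True)

    if extra_edge_slack > 0:
        mst = nx.Graph((a, b, d) for a, b, d in g.edges(data=True))
        for w, a, b in edges:
            if g.has_edge(a, b):
                continue
            path = nx.shortest_path(mst, a, b)
            bottleneck = max(
                mst[u][v]["weight"] for u, v in zip(path, path[1:])
            )
            if w <= bottleneck + extra_edge_slack:
                g.add_edge(a, b, weight=w, in_mst=False)
    return g


def to_dot(g: nx.Graph) -> str:
    lines = ["graph haplonet {"]
    for n in sorted(g.nodes):
        lines.append(f'  "{n}";')
    for a, b, d in sorted(g.edges(data=True)):
        style = "" if d.get("in_mst", True) else ", style=dashed"
        lines.append(f'  "{a}" -- "{b}" [label="{d["weight"]}"{style}];')
    lines.append("}")
    return "\n".join(lines)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))
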