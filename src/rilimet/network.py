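"""Per-group metabolite Pearson correlation networks.

Nodes are metabolites (annotated up/down/ns from a differential screen
when one is supplied); an undirected edge connects two metabolites when
|r| >= r_min (default 0.7) with two-sided p < alpha (default 0.05),
computed on pairwise-complete observations within the selected sample
group. Edge sign is the sign of r — the threshold is applied to |r| so
that strong negative relationships are kept. Exports target
Cytoscape-readable SIF and GraphML with bit-stable ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import SampleTable


@dataclass
class CorrelationNetwork:
    group: str
    nodes: dict                 # metabolite_id -> direction 'up'|'down'|'ns'
    edges: list                 # (m1, m2, r, p, sign) with m1 < m2
    r_min: float
    alpha: float
    excluded: list = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for m in sorted(self.nodes):
            g.add_node(m, direction=self.nodes[m])
        for m1, m2, r, p, sign in sorted(self.edges):
            g.add_edge(m1, m2, r=float(r), p=float(p), sign=sign)
        return g

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.edges,
                             columns=["m1", "m2", "r", "p", "sign"])
        return frame.set_index(["m1", "m2"])

    def to_dict(self) -> dict:
        return {"group": self.group, "r_min": self.r_min,
                "alpha": self.alpha, "nodes": self.nodes,
                "edges": [{"m1": a, "m2": b, "r": r, "p": p, "sign": s}
                          for a, b, r, p, s in self.edges],
                "excluded": self.excluded}


def correlation_network(table: SampleTable, dose_gy: float = None,
                        day: int = None, metabolites=None,
                        r_min: float = 0.7, alpha: float = 0.05,
                        diff=None, min_pairs: int = 4) -> CorrelationNetwork:
    """Build the correlation network for one sample group.

    ``dose_gy``/``day`` select study samples; ``metabolites`` restricts
    the node universe (e.g. the differential set); ``diff`` (a
    DiffResult) annotates node directions. Metabolites with fewer than
    ``min_pairs`` complete observations are excluded with a note.
    """
    sm = table.samples
    sel = table.study_mask()
    if dose_gy is not None:
        sel &= sm["dose_gy"] == dose_gy
    if day is not None:
        sel &= sm["day"] == day
    if sel.sum() < min_pairs:
        raise ValueError(f"fewer than {min_pairs} samples in the selected "
                         "group")
    ids = list(metabolites) if metabolites is not None \
        else table.measured_ids
    ids = [m for m in ids if m in table.abundance.columns]
    if len(ids) < 2:
        raise ValueError("need >= 2 metabolites")
    data = table.abundance.loc[sel, ids]

    excluded = []
    usable = []
    for m in ids:
        if data[m].notna().sum() >= min_pairs:
            usable.append(m)
        else:
            excluded.append(f"{m}: fewer than {min_pairs} complete "
                            "observations")
    edges = []
    for i, m1 in enumerate(usable):
        for m2 in usable[i + 1:]:
            pair = data[[m1, m2]].dropna()
            if len(pair) < min_pairs:
                continue
            r, p = sps.pearsonr(pair[m1], pair[m2])
            if np.isfinite(r) and abs(r) >= r_min and p < alpha:
                a, b = sorted((m1, m2))
                edges.append((a, b, float(r), float(p),
                              "+" if r > 0 else "-"))
    nodes = {}
    for m in usable:
        if diff is not None and m in diff.frame.index:
            if diff.frame.loc[m, "significant"]:
                nodes[m] = "up" if diff.frame.loc[m, "direction"] > 0 \
                    else "down"
            else:
                nodes[m] = "ns"
        else:
            nodes[m] = "ns"
    group = f"dose={dose_gy}, day={day}"
    return CorrelationNetwork(group=group, nodes=nodes,
                              edges=sorted(edges), r_min=r_min, alpha=alpha,
                              excluded=excluded)


def degree_stats(net: CorrelationNetwork):
    """Per-node degree and edge counts by sign; the handshake identity
    sum(degree) = 2 |edges| holds by construction."""
    degree = {m: 0 for m in net.nodes}
    counts = {"+": 0, "-": 0}
    for m1, m2, _, _, sign in net.edges:
        degree[m1] = degree.get(m1, 0) + 1
        degree[m2] = degree.get(m2, 0) + 1
        counts[sign] += 1
    return degree, counts


def export_network(net: CorrelationNetwork, path, format: str = "sif") \
        -> None:
    """Write the network for Cytoscape: SIF (``m1 pos|neg m2`` lines,
    isolated nodes as bare lines) or GraphML with r/p/sign edge
    attributes and node direction. Output ordering is bit-stable."""
    path = Path(path)
    if format == "sif":
        linked = set()
        lines = []
        for m1, m2, _, _, sign in sorted(net.edges):
            rel = "pos" if sign == "+" else "neg"
            lines.append(f"{m1}\t{rel}\t{m2}")
            linked.update((m1, m2))
        for m in sorted(net.nodes):
            if m not in linked:
                lines.append(m)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        g = net.to_networkx()
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
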