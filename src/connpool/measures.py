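"""Eight graph-theory nodal measures (CCA domain 2).

Computed on the binarized thresholded connectivity graph (an edge exists
wherever a signed weight survived thresholding): degree, clustering
coefficient, local efficiency, betweenness centrality, eigenvector
centrality, subgraph centrality, flow coefficient and k-core number.

Conventions, stated because the measures are only standard on binary
graphs: betweenness is unnormalized (raw geodesic counts, each unordered
pair counted once, fractional credit for tied geodesics); eigenvector
centrality is the nonnegative unit-norm principal eigenvector of the
largest connected component (zero elsewhere); subgraph centrality is the
diagonal of the matrix exponential of the adjacency; the flow coefficient
of node i is the fraction of neighbour pairs of i that are *not* directly
connected — the open 2-paths through i — which on a simple graph equals
1 - clustering(i); measures needing >= 2 neighbours are 0 below degree 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .connectome import CohortDataset, ConnectivityMatrix

__all__ = ["MEASURE_NAMES", "NodeMeasureMatrix", "compute_node_measures",
           "binarize", "cohort_measures"]

MEASURE_NAMES = [
    "degree", "clustering", "local_efficiency", "betweenness",
    "eigenvector", "subgraph", "flow", "kcore",
]


@dataclass
class NodeMeasureMatrix:
    values: np.ndarray  # (n, 8)
    measure_names: list[str]
    subject_id: str
    roi_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_labels,
                            columns=self.measure_names)


def binarize(cm: ConnectivityMatrix) -> np.ndarray:
    """0/1 adjacency: an edge wherever a (signed) weight was retained."""
    b = (np.abs(cm.values) > 0).astype(float)
    np.fill_diagonal(b, 0.0)
    return b


def _local_efficiency(graph: nx.Graph, node) -> float:
    neigh = list(graph.neighbors(node))
    if len(neigh) < 2:
        return 0.0
    sub = graph.subgraph(neigh)
    return nx.global_efficiency(sub)


def _eigenvector_centrality(b: np.ndarray, graph: nx.Graph) -> np.ndarray:
    n = b.shape[0]
    out = np.zeros(n)
    comp = max(nx.connected_components(graph), key=len)
    idx = np.array(sorted(comp))
    if len(idx) == 1:
        out[idx] = 1.0
        return out
    sub = b[np.ix_(idx, idx)]
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    # Perron-Frobenius: principal eigenvector of a connected nonnegative
    # matrix has one sign; orient it nonnegative
    if v.sum() < 0:
        v = -v
    v = np.abs(v)
    out[idx] = v / np.linalg.norm(v)
    return out


def compute_node_measures(cm: ConnectivityMatrix, weighted: bool = False) -> NodeMeasureMatrix:
    """n x 8 matrix of nodal graph measures for one subject.

    ``weighted=True`` swaps in weighted (absolute-weight) degree,
    clustering and local efficiency; the remaining measures stay binary.
    """
    if not cm.is_thresholded:
        raise ValueError("node measures require a thresholded matrix")
    b = binarize(cm)
    graph = nx.from_numpy_array(b)
    n = cm.n_nodes

    if weighted:
        wabs = np.abs(cm.values)
        wgraph = nx.from_numpy_array(wabs)
        degree = wabs.sum(axis=1)
        clustering = np.array([nx.clustering(wgraph, i, weight="weight")
                               for i in range(n)])
        inv = wgraph.copy()
        for u, v, d in inv.edges(data=True):
            d["distance"] = 1.0 / d["weight"]
        local_eff = np.zeros(n)
        for i in range(n):
            neigh = list(wgraph.neighbors(i))
            if len(neigh) < 2:
                continue
            sub = inv.subgraph(neigh)
            tot, cnt = 0.0, 0
            for u in sub.nodes:
                lengths = nx.single_source_dijkstra_path_length(sub, u, weight="distance")
                for v in sub.nodes:
                    if v != u:
                        tot += 1.0 / lengths[v] if v in lengths else 0.0
                        cnt += 1
            local_eff[i] = tot / cnt if cnt else 0.0
    else:
        degree = b.sum(axis=1)
        clustering = np.array([nx.clustering(graph, i) for i in range(n)])
        local_eff = np.array([_local_efficiency(graph, i) for i in range(n)])

    betweenness = np.array(list(
        nx.betweenness_centrality(graph, normalized=False).values()
    ))
    eigenvector = _eigenvector_centrality(b, graph)
    subgraph = np.diag(expm(b)).copy()
    deg_b = b.sum(axis=1)
    flow = np.where(deg_b >= 2,
                    1.0 - np.array([nx.clustering(graph, i) for i in range(n)]),
                    0.0)
    core = nx.core_number(graph)
    kcore = np.array([core[i] for i in range(n)], dtype=float)

    values = np.column_stack([
        degree, clustering, local_eff, betweenness,
        eigenvector, subgraph, flow, kcore,
    ])
    return NodeMeasureMatrix(values, list(MEASURE_NAMES), cm.subject_id,
                             list(cm.roi_labels))


def cohort_measures(ds: CohortDataset, weighted: bool = False) -> pd.DataFrame:
    """Long-format table: subject_id, roi, measure, value."""
    rows = []
    for cm in ds.matrices:
        nm = compute_node_measures(cm, weighted=weighted)
        for i, roi in enumerate(nm.roi_labels):
            for j, name in enumerate(nm.measure_names):
                rows.append({"subject_id": nm.subject_id, "roi": roi,
                             "measure": name, "value": nm.values[i, j]})
    return pd.DataFrame(rows)
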