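"""Thresholded weighted brain networks, centralities, and node classes.

Nodes are the 130 atlas parcels; an edge joins two parcels only when
their PLV is strictly larger than the shared threshold, keeping the
edge weight.  Isolated nodes are retained so every network has 130
nodes.  Two node metrics drive the four-way classification:

* activation (ERSP) — *hot spots* are the top 20% of nodes by ERS
  (floor(0.2 * 130) = 26 of 130);
* eigenvector centrality — *hubs* are the same number of top-ranked
  nodes by centrality.

Crossing the two memberships partitions nodes into hot hubs, non-hub
hot spots, cold hubs and non-hub cold nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import AtlasSpec
from .connectivity import PLVMatrix, ThresholdSpec

__all__ = [
    "BrainNetwork",
    "NODE_CLASSES",
    "build_network",
    "weighted_degree",
    "eigenvector_centrality",
    "classify_nodes",
    "write_pajek",
]

NODE_CLASSES = ("hot_hub", "non_hub_hot_spot", "cold_hub", "non_hub_cold_node")


@dataclass
class BrainNetwork:
    """An undirected weighted graph over the full atlas for one (band, group).

    ``atlas`` may be None for toy graphs, in which case nodes are the
    integer matrix indices.
    """

    graph: nx.Graph
    band: str
    group: str
    threshold: float
    atlas: AtlasSpec | None = None

    @property
    def nodes(self) -> tuple:
        if self.atlas is not None:
            return self.atlas.roi_labels
        return tuple(range(self.graph.number_of_nodes()))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> np.ndarray:
        """Weighted adjacency matrix in atlas node order."""
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, weight="weight")


def build_network(
    plv: PLVMatrix, thr: ThresholdSpec | float, atlas: AtlasSpec | None = None
) -> BrainNetwork:
    """Keep edges with PLV strictly above the threshold; no self-loops.

    All nodes are present regardless of isolation.  With ``atlas=None``
    nodes are integer indices (useful for toy matrices).
    """
    if atlas is not None and plv.n_rois != len(atlas):
        raise ValueError(
            f"PLV matrix has {plv.n_rois} ROIs but the atlas has {len(atlas)}"
        )
    labels = atlas.roi_labels if atlas is not None else tuple(range(plv.n_rois))
    threshold = thr.threshold if isinstance(thr, ThresholdSpec) else float(thr)
    g = nx.Graph(band=plv.band.name, group=plv.group, threshold=threshold)
    g.add_nodes_from(labels)
    iu, ju = np.triu_indices(plv.n_rois, k=1)
    keep = plv.values[iu, ju] > threshold
    g.add_weighted_edges_from(
        (labels[i], labels[j], float(plv.values[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    )
    return BrainNetwork(
        graph=g, band=plv.band.name, group=plv.group, threshold=threshold, atlas=atlas
    )


def weighted_degree(net: BrainNetwork) -> np.ndarray:
    """Sum of incident edge weights per node (0 for isolated nodes), atlas order."""
    deg = dict(net.graph.degree(weight="weight"))
    return np.array([deg[n] for n in net.nodes], dtype=float)


def eigenvector_centrality(
    net: BrainNetwork, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Leading eigenvector of the weighted adjacency, max-normalised to [0, 1].

    Computed by power iteration on the (possibly disconnected) graph;
    nodes outside the dominant component, and isolated nodes, converge
    to 0.  An edgeless network returns the all-zero vector with a
    warning.  Raises if the iteration does not converge.
    """
    a = net.adjacency()
    n = a.shape[0]
    if not a.any():
        warnings.warn("network has no edges; eigenvector centrality is all-zero", stacklevel=2)
        return np.zeros(n)
    # small diagonal shift: keeps the eigenvectors, breaks the +/- eigenvalue
    # tie of bipartite components that would stall plain power iteration
    mu = 1e-2 * float(a.sum(axis=1).max())
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + mu * x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise RuntimeError("power iteration collapsed to the zero vector")
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge within {max_iter} iterations "
            f"(residual {np.max(np.abs(a @ x / np.linalg.norm(a @ x) - x)):.2e})"
        )
    x = np.abs(x)  # Perron vector is nonnegative; strip sign noise
    x /= x.max()
    # nodes outside the dominant component decay geometrically but never
    # reach exact zero; clip numerical residue so they classify as
    # zero-centrality (never hubs)
    x[x < 1e-9] = 0.0
    return x


def _top_k(values: np.ndarray, k: int) -> set[int]:
    """Indices of the k largest values, ties broken by atlas order."""
    order = np.argsort(-np.asarray(values, dtype=float), kind="stable")
    return set(int(i) for i in order[:k])


def classify_nodes(
    ersp_by_node: np.ndarray,
    centrality_by_node: np.ndarray,
    top_frac: float = 0.2,
) -> np.ndarray:
    """Four-way node classification crossing hot-spot and hub membership.

    Hot spots are the top ``floor(top_frac * N)`` nodes by ERSP
    (strongest ERS first); hubs are the same number of nodes by
    eigenvector centrality, except that zero-centrality nodes (isolated,
    or all nodes of an edgeless network) are never hubs, so the hub set
    may be smaller.  Ties are broken by atlas order for determinism.
    """
    ersp_by_node = np.asarray(ersp_by_node, dtype=float)
    centrality_by_node = np.asarray(centrality_by_node, dtype=float)
    if ersp_by_node.shape != centrality_by_node.shape or ersp_by_node.ndim != 1:
        raise ValueError("ersp and centrality must be equal-length 1-D vectors")
    if not 0 < top_frac < 1:
        raise ValueError(f"top_frac must lie in (0, 1), got {top_frac}")
    n = ersp_by_node.size
    k = int(np.floor(top_frac * n))
    hot = _top_k(ersp_by_node, k)
    hub = {i for i in _top_k(centrality_by_node, k) if centrality_by_node[i] > 0}
    classes = np.empty(n, dtype=object)
    for i in range(n):
        if i in hot and i in hub:
            classes[i] = "hot_hub"
        elif i in hot:
            classes[i] = "non_hub_hot_spot"
        elif i in hub:
            classes[i] = "cold_hub"
        else:
            classes[i] = "non_hub_cold_node"
    return classes


def node_table(
    net: BrainNetwork,
    ersp_by_node: np.ndarray,
    top_frac: float = 0.2,
) -> pd.DataFrame:
    """Per-node attribute table: centralities, ERSP, and node class."""
    cent = eigenvector_centrality(net) if net.n_edges else np.zeros(len(net.nodes))
    classes = classify_nodes(ersp_by_node, cent, top_frac=top_frac)
    return pd.DataFrame(
        {
            "roi": net.nodes,
            "hemisphere": net.atlas.hemisphere,
            "system": net.atlas.system,
            "band": net.band,
            "group": net.group,
            "ersp": np.asarray(ersp_by_node, dtype=float),
            "weighted_degree": weighted_degree(net),
            "eigenvector_centrality": cent,
            "node_class": classes,
        }
    )


def write_pajek(net: BrainNetwork, path) -> None:
    """Export as a Pajek NET file (1-based vertices, weighted edges)."""
    nx.write_pajek(net.graph, path)
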