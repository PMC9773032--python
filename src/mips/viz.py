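"""Network layout, bicluster-exploded visualization, and GraphML export."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .bipartite import BipartiteGraph, Partition

__all__ = ["NetworkLayout", "layout_network", "annotate_network", "to_networkx", "write_graphml"]

logger = logging.getLogger(__name__)


@dataclass
class NetworkLayout:
    """Node coordinates after force-directed layout + cluster explosion.

    All nodes of one bicluster share the same radial displacement vector,
    so intra-cluster geometry is preserved while clusters separate.
    """

    coordinates: dict
    cluster_centroids: dict
    explode_radius: float


def to_networkx(graph: BipartiteGraph, partition: Partition | None = None) -> nx.Graph:
    g = nx.Graph()
    for i, pid in enumerate(graph.patient_ids):
        attrs = {"type": "patient", "degree": int(graph.patient_degrees[i])}
        if partition is not None:
            attrs["cluster"] = int(partition.patient_labels[i])
        g.add_node(pid, **attrs)
    for j, cid in enumerate(graph.comorbidity_ids):
        attrs = {"type": "comorbidity", "degree": int(graph.comorbidity_degrees[j])}
        if partition is not None:
            attrs["cluster"] = int(partition.comorbidity_labels[j])
        g.add_node(cid, **attrs)
    ii, jj = np.nonzero(graph.A)
    g.add_edges_from(
        (graph.patient_ids[i], graph.comorbidity_ids[j]) for i, j in zip(ii, jj)
    )
    return g


def layout_network(
    graph: BipartiteGraph,
    partition: Partition,
    explode_radius: float = 0.5,
    seed: int = 0,
) -> NetworkLayout:
    """Seeded Fruchterman-Reingold layout with exploded biclusters.

    After the force-directed pass, every cluster is translated radially
    outward from the global centroid along its own centroid direction by
    ``explode_radius``; ``explode_radius=0`` returns the raw layout.
    """
    g = to_networkx(graph, partition)
    pos = nx.spring_layout(g, seed=seed)
    coords = {node: np.asarray(p, dtype=float) for node, p in pos.items()}

    labels = {}
    for i, pid in enumerate(graph.patient_ids):
        labels[pid] = int(partition.patient_labels[i])
    for j, cid in enumerate(graph.comorbidity_ids):
        labels[cid] = int(partition.comorbidity_labels[j])

    global_centroid = np.mean(list(coords.values()), axis=0)
    centroids = {}
    for lab in sorted(set(labels.values())):
        members = [n for n, l in labels.items() if l == lab]
        centroids[lab] = np.mean([coords[n] for n in members], axis=0)

    if explode_radius != 0:
        for lab, centroid in centroids.items():
            direction = centroid - global_centroid
            norm = np.linalg.norm(direction)
            if norm < 1e-12:
                continue  # cluster sits on the centroid: nowhere to push
            shift = explode_radius * direction / norm
            for node, l in labels.items():
                if l == lab:
                    coords[node] = coords[node] + shift
            centroids[lab] = centroid + shift
    return NetworkLayout(
        coordinates={n: tuple(p) for n, p in coords.items()},
        cluster_centroids={lab: tuple(c) for lab, c in centroids.items()},
        explode_radius=explode_radius,
    )


def annotate_network(
    graph: BipartiteGraph,
    partition: Partition,
    layout: NetworkLayout,
    feature_report: pd.DataFrame,
    risk_table: pd.DataFrame | None = None,
    path=None,
):
    """Render the exploded network with per-bicluster annotations.

    Each bicluster's comorbidity labels are listed in descending order of
    their univariable odds ratio (shown in parentheses) and, when a risk
    table is supplied, the subgroup readmission risk is printed next to
    the bicluster (e.g. ``risk 19.6%``). Returns ``(figure, table)``
    where the table has one row per displayed comorbidity.
    """
    ors = dict(zip(feature_report["comorbidity"], feature_report["or_train"]))
    missing = [c for c in graph.comorbidity_ids if c not in ors]
    if missing:
        raise ValueError(f"no odds ratio available for displayed comorbidities: {missing}")

    risks = {}
    if risk_table is not None:
        for _, row in risk_table.iterrows():
            risks[int(row["subgroup"])] = row["risk"]

    fig, ax = plt.subplots(figsize=(9, 9))
    cmap = plt.get_cmap("tab10")
    coords = layout.coordinates

    ii, jj = np.nonzero(graph.A)
    for i, j in zip(ii, jj):
        p1 = coords[graph.patient_ids[i]]
        p2 = coords[graph.comorbidity_ids[j]]
        ax.plot([p1[0], p2[0]], [p1[1], p2[1]], color="0.85", lw=0.3, zorder=1)

    rows = []
    clusters = sorted(set(partition.patient_labels) | set(partition.comorbidity_labels))
    for lab in clusters:
        pmask = partition.patient_labels == lab
        cmask = partition.comorbidity_labels == lab
        if not pmask.any() and not cmask.any():
            warnings.warn(f"bicluster {lab} is empty; omitted from figure")
            continue
        color = cmap((lab - 1) % 10)
        pxy = np.array([coords[pid] for pid, m in zip(graph.patient_ids, pmask) if m])
        if len(pxy):
            ax.scatter(pxy[:, 0], pxy[:, 1], s=8, marker="o", color=color, zorder=2)
        cids = [cid for cid, m in zip(graph.comorbidity_ids, cmask) if m]
        members = sorted(cids, key=lambda c: -ors[c])
        for cid in members:
            xy = coords[cid]
            ax.scatter(*xy, s=60, marker="s", color=color, edgecolor="black", zorder=3)
            ax.annotate(f"{cid} ({ors[cid]:.1f})", xy, fontsize=7, zorder=4)
            rows.append(
                {"subgroup": lab, "comorbidity": cid, "odds_ratio": ors[cid]}
            )
        cx, cy = layout.cluster_centroids.get(lab, (np.nan, np.nan))
        label_txt = f"Subgroup-{lab}"
        if lab in risks and np.isfinite(risks[lab]):
            label_txt += f"\nrisk {100 * risks[lab]:.1f}%"
        ax.annotate(
            label_txt, (cx, cy), color="tab:blue", fontsize=10, fontweight="bold", zorder=5
        )
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    table = pd.DataFrame(rows)
    if risk_table is not None and not table.empty:
        table["risk"] = table["subgroup"].map(risks)
        table["risk_label"] = table["risk"].map(
            lambda r: f"{100 * r:.1f}%" if np.isfinite(r) else "undefined"
        )
    return fig, table


def write_graphml(
    graph: BipartiteGraph,
    partition: Partition,
    path,
    q: float | None = None,
    z: float | None = None,
    p: float | None = None,
) -> None:
    """GraphML export with node type/cluster/degree and graph-level stats."""
    g = to_networkx(graph, partition)
    if q is not None:
        g.graph["Q"] = float(q)
    if z is not None:
        g.graph["z"] = float(z)
    if p is not None:
        g.graph["P"] = float(p)
    nx.write_graphml(g, path)
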