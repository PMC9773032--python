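"""Bipartite patient-comorbidity networks and modularity biclustering.

The central quantity is Barber's bipartite modularity

    Q = (1/m) * sum_{i,j} (A_ij - k_i d_j / m) * delta(g_i, g_j)

where ``A`` is the n x d binary incidence matrix between patients and
comorbidities, ``k_i`` and ``d_j`` the two degree sequences, ``m`` the
edge count, and ``g`` a joint labelling of both node families. Q is the
fraction of edges falling within biclusters minus its expectation under a
degree-preserving random bipartite null; Q = 0 for the trivial one-cluster
partition and approaches 1 - 1/K for K equal, perfectly dense, disjoint
biclusters.

Maximisation uses BRIM-style alternating label sweeps (fix comorbidity
labels, optimally relabel every patient, then vice versa) from many
seeded random starts plus an agglomerative warm start; the number of
biclusters is emergent, never user-fixed. Significance comes from a
degree-preserving permutation test and replication from the Rand index of
the comorbidity labellings of two independent cohort halves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist
from scipy.special import comb

from .cohort import Cohort

__all__ = [
    "BipartiteGraph",
    "Partition",
    "BiclusterModel",
    "BiclusterResults",
    "ModularitySignificance",
    "ReplicationResult",
    "barber_modularity",
    "rand_index",
    "replication_test",
    "rewire_preserving_degrees",
]

logger = logging.getLogger(__name__)


@dataclass
class BipartiteGraph:
    """Patient x comorbidity incidence graph.

    Edge (i, j) present iff patient i carries comorbidity j. Patients with
    zero selected comorbidities must be removed upstream.
    """

    patient_ids: list
    comorbidity_ids: list
    A: np.ndarray  # (n, d) binary

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)
        if self.A.ndim != 2:
            raise ValueError("incidence matrix must be 2-D")
        if self.A.shape != (len(self.patient_ids), len(self.comorbidity_ids)):
            raise ValueError("incidence shape does not match node id lists")
        if self.m == 0:
            raise ValueError("empty graph: no patient-comorbidity edges")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]

    @property
    def patient_degrees(self) -> np.ndarray:
        return self.A.sum(axis=1).astype(np.int64)

    @property
    def comorbidity_degrees(self) -> np.ndarray:
        return self.A.sum(axis=0).astype(np.int64)

    @property
    def m(self) -> int:
        return int(self.A.sum())

    @classmethod
    def from_cohort(cls, cohort: Cohort, selected: Sequence[int] | None = None) -> "BipartiteGraph":
        """Build the case-only graph over the selected comorbidities."""
        X = cohort.X
        cols = cohort.comorbidity_cols
        if selected is not None:
            selected = list(selected)
            X = X[:, selected]
            cols = [cols[i] for i in selected]
        return cls(list(cohort.patient_ids), list(cols), X)


@dataclass
class Partition:
    """Joint bicluster assignment of patient and comorbidity nodes.

    Labels are integers in ``1..K`` shared between the two node families;
    a bicluster is a patient subgroup together with the comorbidities
    sharing its label.
    """

    patient_labels: np.ndarray
    comorbidity_labels: np.ndarray
    q: float = np.nan

    def __post_init__(self) -> None:
        self.patient_labels = np.asarray(self.patient_labels, dtype=np.int64)
        self.comorbidity_labels = np.asarray(self.comorbidity_labels, dtype=np.int64)

    @property
    def k(self) -> int:
        return len(np.unique(np.concatenate([self.patient_labels, self.comorbidity_labels])))

    def relabelled(self) -> "Partition":
        """Canonical 1..K labels ordered by first appearance on comorbidities."""
        joint = np.concatenate([self.comorbidity_labels, self.patient_labels])
        _, first = np.unique(joint, return_index=True)
        order = joint[np.sort(first)]
        mapping = {old: new for new, old in enumerate(order, start=1)}
        return Partition(
            np.array([mapping[v] for v in self.patient_labels]),
            np.array([mapping[v] for v in self.comorbidity_labels]),
            self.q,
        )


def barber_modularity(
    graph: BipartiteGraph,
    patient_labels: np.ndarray,
    comorbidity_labels: np.ndarray,
) -> float:
    """Evaluate bipartite modularity Q of a joint labelling, exactly.

    Rewrites the double sum per cluster c as
    ``(e_c - K_c * D_c / m) / m`` with ``e_c`` the edges inside c and
    ``K_c``, ``D_c`` the summed patient / comorbidity degrees in c.
    """
    gp = np.asarray(patient_labels)
    gc = np.asarray(comorbidity_labels)
    if gp.shape[0] != graph.n or gc.shape[0] != graph.d:
        raise ValueError("labelling does not cover all nodes")
    m = graph.m
    labels, gp_idx = np.unique(np.concatenate([gp, gc]), return_inverse=True)
    gp_i = gp_idx[: graph.n]
    gc_i = gp_idx[graph.n :]
    ii, jj = np.nonzero(graph.A)
    within = gp_i[ii] == gc_i[jj]
    e_c = np.bincount(gp_i[ii][within], minlength=len(labels))
    k_c = np.bincount(gp_i, weights=graph.patient_degrees, minlength=len(labels))
    d_c = np.bincount(gc_i, weights=graph.comorbidity_degrees, minlength=len(labels))
    return float(e_c.sum() / m - np.dot(k_c, d_c) / (m * m))


@dataclass
class ModularitySignificance:
    """Permutation test of optimized modularity against a degree-preserving null."""

    q_obs: float
    null_qs: np.ndarray
    n_perm: int
    seed: int
    null_model: str

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_qs))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_qs, ddof=1))

    @property
    def z(self) -> float:
        return (self.q_obs - self.null_mean) / self.null_sd

    @property
    def p_normal(self) -> float:
        return float(stats.norm.sf(self.z))

    @property
    def p_empirical(self) -> float:
        return (1 + int(np.sum(self.null_qs >= self.q_obs))) / (self.n_perm + 1)

    def summary(self) -> str:
        return (
            f"Q={self.q_obs:.3f}; null mean={self.null_mean:.3f} sd={self.null_sd:.3f} "
            f"({self.null_model} null, {self.n_perm} permutations); "
            f"z={self.z:.2f}; P_normal={self.p_normal:.2g}; P_empirical={self.p_empirical:.4g}"
        )


@dataclass
class ReplicationResult:
    """Rand-index agreement of two comorbidity labellings with a shuffle null."""

    ri: float
    null_ris: np.ndarray
    n_perm: int
    seed: int

    @property
    def z(self) -> float:
        sd = float(np.std(self.null_ris, ddof=1))
        return (self.ri - float(np.mean(self.null_ris))) / sd

    @property
    def p_empirical(self) -> float:
        return (1 + int(np.sum(self.null_ris >= self.ri))) / (self.n_perm + 1)

    def summary(self) -> str:
        return (
            f"RI={self.ri:.3f}; z={self.z:.2f}; P_empirical={self.p_empirical:.4g} "
            f"({self.n_perm} label shuffles)"
        )


def rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Rand index: fraction of item pairs treated concordantly.

    RI = (a + b) / C(n, 2) with ``a`` pairs co-clustered in both
    partitions and ``b`` pairs separated in both.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same item set")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_nij = comb(contingency, 2).sum()
    sum_ai = comb(contingency.sum(axis=1), 2).sum()
    sum_bj = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    return float((total + 2 * sum_nij - sum_ai - sum_bj) / total)


def replication_test(
    comorbidity_labels_train: Sequence,
    comorbidity_labels_repl: Sequence,
    comorbidity_ids_train: Sequence | None = None,
    comorbidity_ids_repl: Sequence | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> ReplicationResult:
    """Rand-index replication of comorbidity co-clustering across halves.

    The two halves share comorbidities but not patients, so agreement is
    measured on comorbidity nodes only. The null shuffles the replication
    half's labels over the comorbidities ``n_perm`` times.
    """
    if comorbidity_ids_train is not None or comorbidity_ids_repl is not None:
        if list(comorbidity_ids_train) != list(comorbidity_ids_repl):
            raise ValueError(
                "comorbidity node sets differ between halves; intersect and reorder first"
            )
    a = np.asarray(comorbidity_labels_train)
    b = np.asarray(comorbidity_labels_repl)
    ri_obs = rand_index(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t] = rand_index(a, rng.permutation(b))
    return ReplicationResult(ri=ri_obs, null_ris=null, n_perm=n_perm, seed=seed)


def rewire_preserving_degrees(
    graph: BipartiteGraph, rng: np.random.Generator, swaps_per_edge: int = 10
) -> BipartiteGraph:
    """Degree-preserving randomisation by double-edge swaps.

    Repeatedly picks two edges (i1, j1), (i2, j2) and exchanges their
    endpoints when the crossed edges are absent; both degree sequences are
    invariant by construction. The attempt budget is
    ``swaps_per_edge * m``.
    """
    ii, jj = np.nonzero(graph.A)
    m = len(ii)
    d = graph.d
    edges = set((ii * d + jj).tolist())
    ii = ii.copy()
    jj = jj.copy()
    n_attempts = swaps_per_edge * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    for e1, e2 in picks:
        i1, j1 = ii[e1], jj[e1]
        i2, j2 = ii[e2], jj[e2]
        if i1 == i2 or j1 == j2:
            continue
        k1 = i1 * d + j2
        k2 = i2 * d + j1
        if k1 in edges or k2 in edges:
            continue
        edges.remove(i1 * d + j1)
        edges.remove(i2 * d + j2)
        edges.add(k1)
        edges.add(k2)
        jj[e1], jj[e2] = j2, j1
    A = np.zeros_like(graph.A)
    A[ii, jj] = 1
    return BipartiteGraph(graph.patient_ids, graph.comorbidity_ids, A)


def _shuffle_rows(graph: BipartiteGraph, rng: np.random.Generator) -> BipartiteGraph:
    # cruder null: permute each patient's comorbidity vector independently
    # (preserves patient degrees only)
    A = graph.A.copy()
    for i in range(A.shape[0]):
        rng.shuffle(A[i])
    return BipartiteGraph(graph.patient_ids, graph.comorbidity_ids, A)


class BiclusterModel:
    """Bipartite modularity maximisation over a patient-comorbidity graph.

    ``fit`` runs BRIM-style alternating sweeps from ``restarts`` seeded
    random comorbidity labellings plus an agglomerative warm start (cutting
    a Jaccard-linkage dendrogram of comorbidity columns at every K), per
    connected component, and keeps the best-Q joint partition. The number
    of biclusters is whatever survives at the optimum.
    """

    def __init__(self, graph: BipartiteGraph):
        self.graph = graph

    # -- label sweeps ----------------------------------------------------
    @staticmethod
    def _sweep(
        A: np.ndarray,
        k: np.ndarray,
        dg: np.ndarray,
        m: int,
        gc: np.ndarray,
        n_labels: int,
        max_sweeps: int,
    ) -> tuple[np.ndarray, np.ndarray, bool]:
        """Alternate optimal relabelling until a fixed point (or cap)."""
        gp = np.zeros(A.shape[0], dtype=np.int64)
        converged = False
        A = A.astype(np.float64)
        for _ in range(max_sweeps):
            C = np.zeros((A.shape[1], n_labels))
            C[np.arange(A.shape[1]), gc] = 1.0
            d_c = dg @ C
            gp_new = np.argmax(A @ C - np.outer(k, d_c) / m, axis=1)
            P = np.zeros((A.shape[0], n_labels))
            P[np.arange(A.shape[0]), gp_new] = 1.0
            k_c = k @ P
            gc_new = np.argmax(A.T @ P - np.outer(dg, k_c) / m, axis=1)
            if np.array_equal(gp_new, gp) and np.array_equal(gc_new, gc):
                converged = True
                break
            gp, gc = gp_new, gc_new
        return gp, gc, converged

    def _warm_starts(self, A: np.ndarray) -> list[np.ndarray]:
        """Agglomerative comorbidity labellings at every cut 2..min(d,12)."""
        d = A.shape[1]
        if d < 3:
            return []
        dist = pdist(A.T.astype(bool), metric="jaccard")
        dist = np.nan_to_num(dist, nan=1.0)
        Z = linkage(dist, method="average")
        starts = []
        for kk in range(2, min(d, 12) + 1):
            starts.append(fcluster(Z, kk, criterion="maxclust") - 1)
        return starts

    def fit(
        self,
        restarts: int = 20,
        seed: int = 0,
        max_sweeps: int = 200,
        warm_start: bool = True,
    ) -> "BiclusterResults":
        g = self.graph
        rng = np.random.default_rng(seed)
        n_comp, comp = connected_components(
            _bipartite_block(g.A), directed=False, return_labels=True
        )
        comp_p, comp_c = comp[: g.n], comp[g.n :]

        gp_best = np.zeros(g.n, dtype=np.int64)
        gc_best = np.zeros(g.d, dtype=np.int64)
        any_nonconverged = False
        offset = 0
        k_all, d_all, m = g.patient_degrees, g.comorbidity_degrees, g.m
        for c in range(n_comp):
            pm = comp_p == c
            cm = comp_c == c
            if cm.sum() == 0 or pm.sum() == 0:
                # isolated nodes cannot occur post build (k_i >= 1) but be safe
                continue
            A = g.A[np.ix_(pm, cm)]
            k, dg = k_all[pm], d_all[cm]
            d_sub = A.shape[1]
            starts: list[np.ndarray] = []
            n_labels = d_sub
            for _ in range(restarts):
                starts.append(rng.integers(0, n_labels, size=d_sub))
            if warm_start:
                starts.extend(self._warm_starts(A))
            best_q = -np.inf
            best = None
            for gc0 in starts:
                gp1, gc1, conv = self._sweep(A, k, dg, m, np.asarray(gc0), n_labels, max_sweeps)
                any_nonconverged |= not conv
                q = _component_q(A, k, dg, m, gp1, gc1)
                if q > best_q + 1e-15:
                    best_q, best = q, (gp1, gc1)
            gp1, gc1 = best
            # compact component labels and shift into a disjoint range
            joint = np.concatenate([gp1, gc1])
            _, inv = np.unique(joint, return_inverse=True)
            gp_best[pm] = inv[: len(gp1)] + offset
            gc_best[cm] = inv[len(gp1) :] + offset
            offset += inv.max() + 1

        if any_nonconverged:
            logger.warning("label sweeps hit the max_sweeps cap; best-so-far partition returned")
        partition = Partition(gp_best + 1, gc_best + 1).relabelled()
        partition.q = barber_modularity(g, partition.patient_labels, partition.comorbidity_labels)
        return BiclusterResults(
            model=self,
            partition=partition,
            restarts=restarts,
            seed=seed,
            converged=not any_nonconverged,
        )


def _bipartite_block(A: np.ndarray):
    from scipy import sparse

    n, d = A.shape
    S = sparse.csr_matrix(A)
    return sparse.bmat([[None, S], [S.T, None]], format="csr")


def _component_q(A, k, dg, m, gp, gc) -> float:
    labels = np.unique(np.concatenate([gp, gc]))
    q = 0.0
    for lab in labels:
        pm = gp == lab
        cm = gc == lab
        e_c = A[np.ix_(pm, cm)].sum()
        q += e_c / m - (k[pm].sum() * dg[cm].sum()) / (m * m)
    return q


@dataclass
class BiclusterResults:
    """Best-Q joint partition found by :class:`BiclusterModel`."""

    model: BiclusterModel
    partition: Partition
    restarts: int
    seed: int
    converged: bool = True
    significance: ModularitySignificance | None = field(default=None, repr=False)

    @property
    def q(self) -> float:
        return self.partition.q

    @property
    def k(self) -> int:
        return self.partition.k

    def test_significance(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        null_model: str = "swap",
        restarts: int = 4,
        swaps_per_edge: int = 10,
    ) -> ModularitySignificance:
        """Permutation test of the optimized Q.

        Each permutation randomises the graph (degree-preserving ``swap``
        null by default; row-wise ``shuffle`` as the cruder alternative),
        re-optimises modularity with a reduced restart budget, and records
        the null optimum. Degree preservation is asserted for every swap
        permutation.
        """
        if n_perm < 20:
            raise ValueError("n_perm < 20 gives an unstable null sd; refuse to run")
        if null_model not in ("swap", "shuffle"):
            raise ValueError("null_model must be 'swap' or 'shuffle'")
        g = self.model.graph
        rng = np.random.default_rng(seed)
        null_qs = np.empty(n_perm)
        for t in range(n_perm):
            if null_model == "swap":
                g_null = rewire_preserving_degrees(g, rng, swaps_per_edge)
                assert np.array_equal(g_null.patient_degrees, g.patient_degrees)
                assert np.array_equal(g_null.comorbidity_degrees, g.comorbidity_degrees)
            else:
                g_null = _shuffle_rows(g, rng)
                assert np.array_equal(g_null.patient_degrees, g.patient_degrees)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = BiclusterModel(g_null).fit(restarts=restarts, seed=sub_seed)
            null_qs[t] = res.q
        sig = ModularitySignificance(
            q_obs=self.q, null_qs=null_qs, n_perm=n_perm, seed=seed, null_model=null_model
        )
        self.significance = sig
        return sig

    def comorbidity_labels_for(self, comorbidity_ids: Sequence) -> np.ndarray:
        """Labels reordered to a given comorbidity id sequence."""
        pos = {cid: i for i, cid in enumerate(self.model.graph.comorbidity_ids)}
        try:
            idx = [pos[c] for c in comorbidity_ids]
        except KeyError as err:
            raise ValueError(f"comorbidity {err} not in this graph") from err
        return self.partition.comorbidity_labels[idx]

    def to_frame(self):
        """Long-format partition table (node_id, type, cluster, degree)."""
        import pandas as pd

        g = self.model.graph
        return pd.DataFrame(
            {
                "node_id": list(g.patient_ids) + list(g.comorbidity_ids),
                "type": ["patient"] * g.n + ["comorbidity"] * g.d,
                "cluster": np.concatenate(
                    [self.partition.patient_labels, self.partition.comorbidity_labels]
                ),
                "degree": np.concatenate([g.patient_degrees, g.comorbidity_degrees]),
            }
        )

    def summary(self) -> str:
        lines = [
            "Bipartite modularity biclustering",
            f"  patients={self.model.graph.n}  comorbidities={self.model.graph.d}  "
            f"edges={self.model.graph.m}",
            f"  biclusters K={self.k}  Q={self.q:.4f}  "
            f"(restarts={self.restarts}, seed={self.seed})",
        ]
        if self.significance is not None:
            lines.append("  " + self.significance.summary())
        return "\n".join(lines)
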