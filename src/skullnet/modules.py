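"""Module detection: GTOM similarity → Ward.D2 → modularity-Q dendrogram cut.

Anatomical modules are found by hierarchical clustering of the generalized
topological overlap matrix (GTOM): two bones are similar when their (m-step)
neighborhoods overlap.  The dendrogram is built with the Ward.D2 criterion on
the dissimilarity 1 − overlap, and is cut at the number of clusters that
maximizes Newman–Girvan modularity Q.  The blocks of that cut are the
Q-modules and the attained Q is Q_max.  Each Q-module is then screened with a
one-sided Wilcoxon rank-sum test of its nodes' internal versus external
contact counts; modules whose internal connectivity significantly exceeds
their external connectivity are the S-modules.

Ward.D2 is implemented here via the Lance–Williams recurrence on squared
distances with a declared lexicographic tie-break, so that merge order — and
hence the recovered partition — is identical across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import SkullNetwork
from .stats import mann_whitney

__all__ = [
    "OverlapMatrix",
    "Dendrogram",
    "Partition",
    "ModuleReport",
    "topological_overlap",
    "ward_d2",
    "modularity_q",
    "cut_max_q",
    "s_module_test",
    "detect_modules",
]


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric topological-overlap similarity in [0, 1], unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    order: int = 1

    def dissimilarity(self) -> np.ndarray:
        """The standard clustering transform, 1 − overlap (zero diagonal)."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history in scipy linkage convention.

    Leaves are 0..N−1 in ``labels`` order; the cluster created by merge t
    has id N+t.  ``merges`` rows are (id_a, id_b, height, size).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> "Partition":
        """Partition induced by stopping after the first N−k merges."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}, got {k}")
        parent = list(range(n + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t, (a, b, _h, _s) in enumerate(self.merges[: n - k]):
            parent[find(a)] = parent[find(b)] = n + t
        roots: dict[int, int] = {}
        assignment: dict[str, int] = {}
        for i, lab in enumerate(self.labels):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots) + 1
            assignment[lab] = roots[r]
        return Partition(assignment=assignment)

    def to_newick(self) -> str:
        """Newick rendering with merge heights as branch lengths."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for t, (a, b, h, _s) in enumerate(self.merges):
            la = f"{rep[a]}:{h - height[a]:.6g}"
            lb = f"{rep[b]}:{h - height[b]:.6g}"
            rep[n + t] = f"({la},{lb})"
            height[n + t] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return rep[root] + ";"


@dataclass(frozen=True)
class Partition:
    """Node label → module id, ids contiguous 1..k."""

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"module ids must be contiguous 1..k, got {ids}")

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id: int) -> list[str]:
        return sorted(l for l, m in self.assignment.items() if m == module_id)

    def relabeled(self, mapping) -> "Partition":
        """Partition under a node-relabeling map (e.g. left/right mirror)."""
        return Partition(assignment={mapping(l): m for l, m in self.assignment.items()})


@dataclass(frozen=True)
class ModuleReport:
    """Full module-detection output for one specimen."""

    partition: Partition
    q_max: float
    p_values: dict[int, float]
    alpha: float
    dendrogram: Dendrogram

    @property
    def q_modules(self) -> int:
        return self.partition.k

    @property
    def s_modules(self) -> int:
        return sum(1 for p in self.p_values.values() if p < self.alpha)

    def summary(self) -> dict:
        return {
            "Q_modules": self.q_modules,
            "Q_max": self.q_max,
            "S_modules": self.s_modules,
            "alpha": self.alpha,
            "module_p_values": {str(m): p for m, p in sorted(self.p_values.items())},
        }


# ---------------------------------------------------------------------------
# GTOM
# ---------------------------------------------------------------------------

def topological_overlap(net: SkullNetwork, m: int = 1) -> OverlapMatrix:
    """Generalized topological overlap similarity of order ``m``.

    For m=1, overlap(i,j) = (|shared neighbors| + a_ij) / (min(k_i,k_j) + 1 − a_ij).
    For m>1 the same formula is applied to the m-step reachability graph
    (an edge wherever the original graph has a path of length ≤ m).
    """
    if m < 1:
        raise ValueError(f"GTOM order must be >= 1, got {m}")
    a = net.adjacency.astype(float)
    if m > 1:
        reach = a.copy()
        power = a.copy()
        for _ in range(m - 1):
            power = power @ a
            reach += power
        a = (reach > 0).astype(float)
        np.fill_diagonal(a, 0.0)
    shared = a @ a  # zero diagonal in a => entry ij counts common neighbors
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a) / denom
    t = np.where(denom > 0, t, 0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return OverlapMatrix(labels=tuple(net.labels), values=t, order=m)


# ---------------------------------------------------------------------------
# Ward.D2
# ---------------------------------------------------------------------------

def ward_d2(dissimilarity: np.ndarray, labels=None) -> Dendrogram:
    """Agglomerative clustering with the Ward.D2 criterion.

    Operates on the Lance–Williams recurrence over *squared* distances and
    reports merge heights on the distance scale (the hclust ward.D2
    convention).  Ties are broken toward the pair of clusters whose
    lexicographically smallest member labels sort first, making the merge
    order deterministic.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    if (d < 0).any():
        raise ValueError("dissimilarity must be nonnegative")
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    labels = tuple(labels)

    d2 = d.astype(float) ** 2
    active: dict[int, dict] = {
        i: {"size": 1, "min_label": labels[i]} for i in range(n)
    }
    # dist2[(a,b)] with a<b: current squared inter-cluster distance
    dist2: dict[tuple[int, int], float] = {
        (i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for (a, b), v in dist2.items():
            key = (
                v,
                min(active[a]["min_label"], active[b]["min_label"]),
                max(active[a]["min_label"], active[b]["min_label"]),
            )
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        dab2 = dist2[(a, b)]
        na, nb = active[a]["size"], active[b]["size"]
        new = {
            "size": na + nb,
            "min_label": min(active[a]["min_label"], active[b]["min_label"]),
        }
        merges.append((a, b, float(np.sqrt(dab2)), na + nb))
        del dist2[(a, b)]
        for c in list(active):
            if c in (a, b):
                continue
            nc = active[c]["size"]
            dac2 = dist2.pop((min(a, c), max(a, c)))
            dbc2 = dist2.pop((min(b, c), max(b, c)))
            # Ward.D2 Lance-Williams update on squared distances
            upd = ((na + nc) * dac2 + (nb + nc) * dbc2 - nc * dab2) / (na + nb + nc)
            dist2[(min(c, next_id), max(c, next_id))] = upd
        del active[a], active[b]
        active[next_id] = new
        next_id += 1
    return Dendrogram(labels=labels, merges=tuple(merges))


# ---------------------------------------------------------------------------
# modularity and the Q cut
# ---------------------------------------------------------------------------

def modularity_q(net: SkullNetwork, partition: Partition) -> float:
    """Newman–Girvan modularity Q = Σ_s [e_s/K − (d_s/2K)²]."""
    labels = net.labels
    missing = sorted(set(labels) - set(partition.assignment))
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    k_total = net.n_edges
    if k_total < 1:
        raise ValueError("modularity undefined for an edgeless network")
    deg = net.degree()
    idx = {l: i for i, l in enumerate(labels)}
    q = 0.0
    for s in range(1, partition.k + 1):
        mem = [idx[l] for l in partition.members(s)]
        sub = net.adjacency[np.ix_(mem, mem)]
        e_s = sub.sum() / 2.0
        d_s = deg[mem].sum()
        q += e_s / k_total - (d_s / (2.0 * k_total)) ** 2
    return float(q)


def cut_max_q(net: SkullNetwork, dendrogram: Dendrogram) -> tuple[Partition, float]:
    """Cut the dendrogram at the k (1..N) maximizing Q; ties go to smaller k."""
    best_part, best_q, best_k = None, -np.inf, None
    for k in range(1, dendrogram.n_leaves + 1):
        part = dendrogram.cut(k)
        q = modularity_q(net, part)
        if q > best_q + 1e-12:
            best_part, best_q, best_k = part, q, k
    return best_part, float(best_q)


# ---------------------------------------------------------------------------
# S-modules
# ---------------------------------------------------------------------------

def s_module_test(
    net: SkullNetwork,
    partition: Partition,
    alpha: float = 0.05,
    sidedness: str = "greater",
    dendrogram: Dendrogram | None = None,
) -> ModuleReport:
    """Wilcoxon rank-sum screen of internal vs external contacts per module.

    For each module, sample A is the per-node count of contacts to nodes
    inside the module and sample B the count to nodes outside; a module is
    an S-module when internal significantly exceeds external (one-sided by
    default).  Modules of size < 2 cannot be tested and are recorded as not
    significant with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    idx = {l: i for i, l in enumerate(net.labels)}
    a = net.adjacency
    p_values: dict[int, float] = {}
    for s in range(1, partition.k + 1):
        mem = [idx[l] for l in partition.members(s)]
        if len(mem) < 2:
            warnings.warn(
                f"module {s} of {net.specimen_id!r} has {len(mem)} node(s); "
                "rank-sum test skipped, recorded as not significant",
                stacklevel=2,
            )
            p_values[s] = 1.0
            continue
        inside = a[np.ix_(mem, mem)].sum(axis=1).astype(float)
        outside = (a[mem].sum(axis=1) - a[np.ix_(mem, mem)].sum(axis=1)).astype(float)
        res = mann_whitney(inside, outside, alternative=sidedness)
        p_values[s] = res.p
    if dendrogram is None:
        dendrogram = Dendrogram(labels=tuple(net.labels), merges=())
    q = modularity_q(net, partition)
    return ModuleReport(
        partition=partition,
        q_max=q,
        p_values=p_values,
        alpha=alpha,
        dendrogram=dendrogram,
    )


def detect_modules(
    net: SkullNetwork,
    m: int = 1,
    alpha: float = 0.05,
    sidedness: str = "greater",
) -> ModuleReport:
    """Full pipeline: GTOM(m) → Ward.D2 on 1−overlap → Q-max cut → S-test."""
    overlap = topological_overlap(net, m=m)
    dend = ward_d2(overlap.dissimilarity(), labels=overlap.labels)
    partition, q_max = cut_max_q(net, dend)
    report = s_module_test(net, partition, alpha=alpha, sidedness=sidedness, dendrogram=dend)
    assert abs(report.q_max - q_max) < 1e-12
    return report
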