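"""Per-network topology parameters.

Six statistics summarize each skull network and carry its biological
reading: node count N (bones/units), edge count K (contacts), density D
(morphological complexity), mean clustering coefficient C (anatomical
integration), mean shortest path length L (functional efficiency), and
degree heterogeneity H = sd(degree)/mean(degree) (anisomerism —
specialization among repeated parts).  Three module statistics
(Q-modules, Q_max, S-modules) are filled in from module detection.

Two numeric conventions are deliberately exposed because published values
depend on them: whether nodes of degree < 2 are excluded from the mean
clustering coefficient or counted as zero (``low_degree_rule``), and
whether H uses the sample (n−1) or population standard deviation
(``sd_rule``).  Defaults follow the R/igraph workflow these analyses
descend from: exclude, and sample sd.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .network import SkullNetwork

__all__ = [
    "ParameterVector",
    "PARAMETER_COLUMNS",
    "density",
    "clustering_coefficient",
    "mean_path_length",
    "heterogeneity",
    "compute_parameters",
    "parameter_table",
]

PARAMETER_COLUMNS = ["N", "K", "D", "C", "L", "H", "Q_modules", "Q_max", "S_modules"]


@dataclass(frozen=True)
class ParameterVector:
    """The nine per-specimen network statistics."""

    N: int
    K: int
    D: float
    C: float
    L: float
    H: float
    Q_modules: Optional[int] = None
    Q_max: Optional[float] = None
    S_modules: Optional[int] = None

    def as_dict(self) -> dict:
        return asdict(self)


def density(net: SkullNetwork) -> float:
    """Fraction of realized contacts out of all N(N−1)/2 possible pairs."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * net.n_edges / (n * (n - 1))


def clustering_coefficient(net: SkullNetwork, low_degree_rule: str = "exclude") -> float:
    """Mean local clustering coefficient.

    Per node i with degree k_i ≥ 2 the local coefficient is
    2·(edges among neighbors of i) / (k_i (k_i − 1)).  Nodes of degree < 2
    have no neighbor pairs; ``low_degree_rule`` controls whether they are
    dropped from the mean (``"exclude"``) or counted as 0 (``"zero"``).
    """
    if low_degree_rule not in ("exclude", "zero"):
        raise ValueError(f"unknown low_degree_rule {low_degree_rule!r}")
    g = net.to_networkx()
    local = nx.clustering(g)
    deg = dict(g.degree())
    if low_degree_rule == "exclude":
        vals = [local[v] for v in g if deg[v] >= 2]
        if not vals:
            raise ValueError("no node of degree >= 2 under rule 'exclude'")
    else:
        vals = [local[v] for v in g]
    return float(np.mean(vals))


def mean_path_length(net: SkullNetwork) -> float:
    """Mean breadth-first distance over all unordered node pairs.

    Disconnected networks are an error (no largest-component fallback):
    every real skull is connected, and a silent fallback would corrupt
    cross-specimen comparison.
    """
    g = net.to_networkx()
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(
            f"network {net.specimen_id!r} is disconnected; components: {comps}"
        )
    return float(nx.average_shortest_path_length(g))


def heterogeneity(net: SkullNetwork, sd_rule: str = "sample") -> float:
    """Coefficient of variation of the degree sequence, sd/mean."""
    if sd_rule not in ("sample", "population"):
        raise ValueError(f"unknown sd_rule {sd_rule!r}")
    deg = net.degree().astype(float)
    mean = deg.mean()
    if mean == 0:
        raise ValueError("heterogeneity undefined for an edgeless network")
    ddof = 1 if sd_rule == "sample" else 0
    return float(deg.std(ddof=ddof) / mean)


def compute_parameters(
    net: SkullNetwork,
    module_report=None,
    low_degree_rule: str = "exclude",
    sd_rule: str = "sample",
) -> ParameterVector:
    """All nine statistics for one network (module fields from the report)."""
    return ParameterVector(
        N=net.n_nodes,
        K=net.n_edges,
        D=density(net),
        C=clustering_coefficient(net, low_degree_rule),
        L=mean_path_length(net),
        H=heterogeneity(net, sd_rule),
        Q_modules=None if module_report is None else module_report.q_modules,
        Q_max=None if module_report is None else module_report.q_max,
        S_modules=None if module_report is None else module_report.s_modules,
    )


def parameter_table(vectors: dict[str, ParameterVector]) -> pd.DataFrame:
    """Assemble specimen_id → ParameterVector into the pooled analysis table."""
    df = pd.DataFrame({sid: v.as_dict() for sid, v in vectors.items()}).T
    df.index.name = "specimen_id"
    return df[PARAMETER_COLUMNS].astype(float)
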