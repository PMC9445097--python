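"""Synthetic skulls, clades, and traits with known ground truth.

Real inputs to the pipeline are bilaterally symmetric bone-contact networks,
a categorical trait table, and an ultrametric phylogeny.  The generators
here emulate exactly that statistical/topological structure — paired bones,
sagittally split midline bones, planted left/right × anterior/posterior
modules, Yule trees with Brownian trait evolution — without attempting any
anatomical realism.  Everything is seed-deterministic: the same config
produces byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .network import BoneNode, SkullNetwork, SIDE_LEFT, SIDE_RIGHT, SIDE_MIDLINE, \
    SIDE_SPLIT_LEFT, SIDE_SPLIT_RIGHT, mirror_label
from .modules import Partition
from .parameters import PARAMETER_COLUMNS

__all__ = [
    "SkullSimConfig",
    "CladeSimConfig",
    "SkullSimResult",
    "simulate_skull",
    "simulate_clade",
    "toy_skull_fixture",
    "TOY_SKULL_EXPECTED",
]


@dataclass(frozen=True)
class SkullSimConfig:
    """Recipe for one symmetric skull-like network.

    The left side is generated with ``n_modules_per_side`` planted modules
    (within-module edge probability ``p_within``, between ``p_between``),
    mirrored to the right, midline halves joined, sparse cross-midline edges
    added symmetrically, and bone pairs optionally fused.  Planted module
    ids are returned as ground truth (left modules 1..g, right g+1..2g).
    """

    n_bone_pairs: int = 14
    n_midline_bones: int = 2
    n_modules_per_side: int = 2
    p_within: float = 0.8
    p_between: float = 0.05
    p_cross_midline: float = 0.02
    fusion_rate: float = 0.0
    seed: int = 0
    max_bridge_edges: int = 64

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between", "p_cross_midline", "fusion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_bone_pairs + self.n_midline_bones < 2:
            raise ValueError("need at least 2 bones")
        if self.n_modules_per_side < 1:
            raise ValueError("need at least 1 module per side")


@dataclass(frozen=True)
class SkullSimResult:
    network: SkullNetwork
    planted: Partition
    n_bridges_added: int


def _left_labels(cfg: SkullSimConfig) -> tuple[list[str], list[str]]:
    paired = [f"b{i+1:02d}_L" for i in range(cfg.n_bone_pairs)]
    midline = [f"m{i+1:02d}_L" for i in range(cfg.n_midline_bones)]
    return paired, midline


def simulate_skull(config: SkullSimConfig) -> SkullSimResult:
    """Generate a connected, perfectly left-right symmetric skull network."""
    rng = np.random.default_rng(config.seed)
    paired, midline = _left_labels(config)
    left = paired + midline  # module blocks run over the combined left side
    n_left = len(left)
    module_of = {
        lab: 1 + (i * config.n_modules_per_side) // n_left
        for i, lab in enumerate(left)
    }

    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add(tuple(sorted((u, v))))

    # left side: planted modules
    for i in range(n_left):
        for j in range(i + 1, n_left):
            p = config.p_within if module_of[left[i]] == module_of[left[j]] else config.p_between
            if rng.random() < p:
                add(left[i], left[j])
    # mirror to the right
    for u, v in list(edges):
        add(mirror_label(u), mirror_label(v))
    # midline halves are always joined
    for m in midline:
        add(m, mirror_label(m))
    # sparse symmetric cross-midline contacts
    bases = [l[:-2] for l in left]
    for i in range(len(bases)):
        for j in range(i, len(bases)):
            if bases[i] == bases[j] and bases[j].startswith("m"):
                continue  # midline join already placed
            if rng.random() < config.p_cross_midline:
                add(f"{bases[i]}_L", f"{bases[j]}_R")
                add(f"{bases[j]}_L", f"{bases[i]}_R")

    # fusions: a bone pair collapses into one unsided unit
    fused: list[str] = []
    for lab in paired:
        if rng.random() < config.fusion_rate:
            fused.append(lab[:-2])
    for base in fused:
        l_lab, r_lab = f"{base}_L", f"{base}_R"
        new_edges = set()
        for u, v in edges:
            u2 = base if u in (l_lab, r_lab) else u
            v2 = base if v in (l_lab, r_lab) else v
            if u2 != v2:
                new_edges.add(tuple(sorted((u2, v2))))
        edges = new_edges

    labels = []
    for lab in paired:
        base = lab[:-2]
        if base in fused:
            labels.append(base)
        else:
            labels.extend([lab, mirror_label(lab)])
    for lab in midline:
        labels.extend([lab, mirror_label(lab)])

    nodes = []
    for lab in labels:
        if "_" not in lab:
            nodes.append(BoneNode(lab, lab, SIDE_MIDLINE))
        elif lab[:-2] in {m[:-2] for m in midline}:
            side = SIDE_SPLIT_LEFT if lab.endswith("_L") else SIDE_SPLIT_RIGHT
            nodes.append(BoneNode(lab, lab[:-2], side))
        else:
            side = SIDE_LEFT if lab.endswith("_L") else SIDE_RIGHT
            nodes.append(BoneNode(lab, lab[:-2], side))

    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    adj = np.zeros((n, n), dtype=int)
    for u, v in edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1

    # enforce connectivity with deterministic symmetric bridges
    import networkx as nx

    n_bridges = 0
    while True:
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from((u, v) for u, v in edges)
        comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
        if len(comps) == 1:
            break
        if n_bridges >= config.max_bridge_edges:
            raise RuntimeError("connectivity not achievable within retry budget")
        u, v = comps[0][0], comps[1][0]
        for a, b in ((u, v), (mirror_label(u), mirror_label(v))):
            if a != b:
                edges.add(tuple(sorted((a, b))))
                adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
        n_bridges += 1

    g_per_side = config.n_modules_per_side
    assignment = {}
    for lab in labels:
        if "_" not in lab:  # fused unit: keep its left module
            assignment[lab] = module_of[f"{lab}_L"]
        elif lab.endswith("_L"):
            assignment[lab] = module_of[lab]
        else:
            assignment[lab] = module_of[mirror_label(lab)] + g_per_side
    # fusion can empty a side's module; renumber ids to stay contiguous
    kept = sorted(set(assignment.values()))
    renum = {old: i + 1 for i, old in enumerate(kept)}
    assignment = {lab: renum[m] for lab, m in assignment.items()}
    net = SkullNetwork(
        specimen_id=f"sim{config.seed:05d}", nodes=nodes, adjacency=adj
    )
    return SkullSimResult(
        network=net, planted=Partition(assignment=assignment), n_bridges_added=n_bridges
    )


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeSimConfig:
    """Yule tree + Brownian continuous parameters + categorical traits."""

    n_taxa: int = 32
    birth_rate: float = 1.0
    bm_rates: dict = field(
        default_factory=lambda: {
            "N": 30.0, "K": 200.0, "D": 0.002, "C": 0.005, "L": 0.05,
            "H": 0.005, "Q_modules": 1.0, "Q_max": 0.005, "S_modules": 0.5,
        }
    )
    root_state: dict = field(
        default_factory=lambda: {
            "N": 44.0, "K": 100.0, "D": 0.11, "C": 0.40, "L": 2.4,
            "H": 0.38, "Q_modules": 5.0, "Q_max": 0.42, "S_modules": 2.0,
        }
    )
    categorical_rule: str = "clade"  # or "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be positive")
        if self.categorical_rule not in ("clade", "iid"):
            raise ValueError(f"unknown categorical rule {self.categorical_rule!r}")


class _SimNode:
    __slots__ = ("children", "birth", "length", "name")

    def __init__(self, birth: float):
        self.children: list["_SimNode"] = []
        self.birth = birth
        self.length = 0.0
        self.name = ""


def _yule_tree(n_taxa: int, rate: float, rng: np.random.Generator) -> _SimNode:
    """Pure-birth tree; all tips extant (ultrametric by construction)."""
    root = _SimNode(0.0)
    tips = [root]
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (rate * len(tips)))
        parent = tips.pop(rng.integers(len(tips)))
        parent.children = [_SimNode(t), _SimNode(t)]
        tips.extend(parent.children)
    t += rng.exponential(1.0 / (rate * len(tips)))  # grace period after last split
    for i, tip in enumerate(sorted(tips, key=lambda nd: nd.birth)):
        tip.name = f"t{i+1:03d}"
    _assign_lengths(root, t)
    # keep the root stem (time before the first split) so shared ancestry is
    # nonzero even for a two-tip cherry
    root.length = root.children[0].birth
    return root


def _assign_lengths(node: _SimNode, present: float) -> None:
    for ch in node.children:
        split = ch.children[0].birth if ch.children else present
        ch.length = split - ch.birth
        _assign_lengths(ch, present)


def _to_newick(node: _SimNode) -> str:
    if not node.children:
        return f"{node.name}:{node.length:.10f}"
    inner = ",".join(_to_newick(ch) for ch in node.children)
    return f"({inner}):{node.length:.10f}"


def _tips(node: _SimNode) -> list[_SimNode]:
    if not node.children:
        return [node]
    return [t for ch in node.children for t in _tips(ch)]


def simulate_clade(config: CladeSimConfig):
    """Simulate (PhyloTree, ParameterTable, TraitTable) over one clade.

    The global seed expands into independent substreams for tree shape,
    Brownian trait evolution, and categorical assignment, so each component
    can be regenerated on its own.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_bm, rng_cat = (np.random.default_rng(s) for s in ss.spawn(3))

    root = _yule_tree(config.n_taxa, config.birth_rate, rng_tree)
    tree = dendropy.Tree.get(data=_to_newick(root) + ";", schema="newick")
    tree.is_rooted = True

    # Brownian motion along the tree (root stem included), one independent
    # trait per parameter
    cols = [c for c in PARAMETER_COLUMNS if c in config.bm_rates]
    values: dict[str, dict[str, float]] = {}
    rates = np.array([config.bm_rates[c] for c in cols])

    def walk(node: _SimNode, state_above: np.ndarray) -> None:
        step = rng_bm.normal(0.0, np.sqrt(rates * max(node.length, 0.0)))
        state = state_above + step
        if not node.children:
            values[node.name] = dict(zip(cols, state))
            return
        for ch in node.children:
            walk(ch, state)

    walk(root, np.array([config.root_state[c] for c in cols], dtype=float))
    tip_names = sorted(values)
    params = pd.DataFrame([values[t] for t in tip_names], index=tip_names)[cols]
    params.index.name = "specimen_id"

    # categorical traits: one clade-linked binary, one iid binary, one 3-level
    tips = _tips(root)
    habitat = {t.name: "non-fossorial" for t in tips}
    if config.categorical_rule == "clade":
        target = max(2, len(tips) // 4)
        best, best_gap = None, None
        for node in _preorder(root):
            if node is root:
                continue
            sz = len(_tips(node))
            gap = abs(sz - target)
            if sz < len(tips) and (best_gap is None or gap < best_gap):
                best, best_gap = node, gap
        for t in _tips(best):
            habitat[t.name] = "fossorial"
    else:
        for t in tips:
            if rng_cat.random() < 0.25:
                habitat[t.name] = "fossorial"
    flag = {t.name: ("yes" if rng_cat.random() < 0.25 else "no") for t in tips}
    bar = {
        t.name: ("present", "incomplete", "absent")[rng_cat.integers(3)] for t in tips
    }
    traits = pd.DataFrame(
        {
            "habitat": [habitat[t] for t in tip_names],
            "clade_flag": [flag[t] for t in tip_names],
            "postorbital_bar": [bar[t] for t in tip_names],
        },
        index=tip_names,
    )
    traits.index.name = "specimen_id"
    return tree, params, traits


def _preorder(node: _SimNode):
    yield node
    for ch in node.children:
        yield from _preorder(ch)


# ---------------------------------------------------------------------------
# the hand-verified toy fixture
# ---------------------------------------------------------------------------

# Hand derivation (independent of the code under test):
#   nodes: midline splits m1, m2; bone pairs a, b, c  ->  N = 10
#   edges: m1_L-m1_R, m2_L-m2_R, and per side: m1-a, a-b, b-c, m2-a, m2-b,
#          m2-c  ->  K = 2 + 2*6 = 14
#   degrees: m1:2, m2:4, a:3, b:3, c:2 (each twice); sum 28  ->  D = 28/90
#   local clustering: m1 0, m2 2/6, a 1/3, b 2/3, c 1  ->  C = 2*(7/3)/10 = 7/15
#   pairwise distances sum (unordered) = 95 over 45 pairs  ->  L = 19/9
#   H: mean degree 2.8; sum of squared deviations 5.6
#      sample sd sqrt(5.6/9)  ->  H = 0.2817180687...
#      population sd sqrt(0.56) ->  H = 0.2672612419...
TOY_SKULL_EXPECTED = {
    "N": 10,
    "K": 14,
    "D": 28 / 90,
    "C": 7 / 15,
    "L": 19 / 9,
    "H_sample": np.sqrt(5.6 / 9) / 2.8,
    "H_population": np.sqrt(0.56) / 2.8,
}

_TOY_EDGES_LEFT = [
    ("m1_L", "a_L"), ("a_L", "b_L"), ("b_L", "c_L"),
    ("m2_L", "a_L"), ("m2_L", "b_L"), ("m2_L", "c_L"),
]


def toy_skull_fixture() -> SkullNetwork:
    """A 10-node, 14-edge miniature skull with hand-verified parameters.

    Two midline bones (split into joined halves) and three bone pairs; the
    left chain m1–a–b–c plus a hub m2 touching a, b, c, mirrored exactly on
    the right.  The constants in ``TOY_SKULL_EXPECTED`` were derived by hand
    (see comment above) and serve as the gold standard for the parameter
    pipeline.
    """
    labels = ["m1_L", "m1_R", "m2_L", "m2_R", "a_L", "a_R", "b_L", "b_R", "c_L", "c_R"]
    nodes = []
    for lab in labels:
        base = lab[:-2]
        if base in ("m1", "m2"):
            side = SIDE_SPLIT_LEFT if lab.endswith("_L") else SIDE_SPLIT_RIGHT
        else:
            side = SIDE_LEFT if lab.endswith("_L") else SIDE_RIGHT
        nodes.append(BoneNode(lab, base, side))
    idx = {l: i for i, l in enumerate(labels)}
    adj = np.zeros((10, 10), dtype=int)
    edges = [("m1_L", "m1_R"), ("m2_L", "m2_R")]
    edges += _TOY_EDGES_LEFT
    edges += [(mirror_label(u), mirror_label(v)) for u, v in _TOY_EDGES_LEFT]
    for u, v in edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1
    return SkullNetwork(specimen_id="toy", nodes=nodes, adjacency=adj, taxon="toy")
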