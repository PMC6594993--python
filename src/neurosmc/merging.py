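"""Trace refinement, node grouping, and tree construction.

Every neuron branch is typically traced several times; redundant traces
are collapsed in three steps.  (1) Mean-shift refinement: traces are
resampled to one-voxel spacing, then every node's position, radius and
correlation are iteratively replaced by the unweighted mean over the
nodes within its own initial radius (a flat kernel); links are untouched.
(2) Node grouping: a greedy pass repeatedly takes the ungrouped node with
the highest correlation, merges it with its ungrouped neighbors within
the grouping radius r_g into one group node (unweighted member means),
and projects all member links onto the group graph, preserving
connectivity.  (3) Tree construction: breadth-first traversal of the
group graph from the soma (or the highest-correlation group when no soma
was found) assigns parents, drops cycle-closing edges, keeps additional
connected components above a minimum size as extra roots, and prunes
single-node terminal branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .soma import SomaModel, SomaParams, extract_soma
from .seeds import SeedParams, extract_seeds
from .swc_io import NEURITE_TYPE, SOMA_TYPE, SwcNode, SwcTree, _resample_attrs
from .tracer import Trace, TracerParams, trace_all

__all__ = [
    "TraceNode",
    "GroupNode",
    "nodes_from_traces",
    "mean_shift_refine",
    "group_nodes",
    "build_tree",
    "reconstruct",
    "reconstruct_with_info",
]


@dataclass
class TraceNode:
    """Refinement currency: position, radius, correlation, neighbor links."""

    p: np.ndarray
    r: float
    c: float
    links: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(3)


@dataclass
class GroupNode:
    p: np.ndarray
    r: float
    c: float
    links: set[int] = field(default_factory=set)
    members: list[int] = field(default_factory=list)


def nodes_from_traces(
    traces: Sequence[Trace],
    step: float = 1.0,
    aspect: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[TraceNode]:
    """Flatten traces into one linked node set, resampled to ``step`` spacing.

    Radii and correlations are linearly interpolated along each trace;
    links form a bidirectional chain per trace.
    """
    nodes: list[TraceNode] = []
    for trace in traces:
        if len(trace) == 0:
            continue
        pts = np.stack([n.p for n in trace.nodes])
        attrs = np.array([[n.r, n.c] for n in trace.nodes])
        if len(pts) > 1:
            pts, attrs = _resample_attrs(pts, attrs, step, aspect)
        base = len(nodes)
        for i in range(len(pts)):
            links = set()
            if i > 0:
                links.add(base + i - 1)
            if i < len(pts) - 1:
                links.add(base + i + 1)
            nodes.append(TraceNode(pts[i], float(attrs[i, 0]), float(attrs[i, 1]), links))
    return nodes


def mean_shift_refine(
    nodes: Sequence[TraceNode],
    iterations: int = 5,
    aspect: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[TraceNode]:
    """Flat-kernel mean-shift of node estimates; links are preserved.

    Each iteration synchronously replaces every node's (p, r, c) by the
    unweighted mean over the nodes within distance r0 of it, where r0 is
    the node's initial radius.  Five iterations suffice in practice for
    radial trace alignment.
    """
    if not nodes:
        return []
    asp = np.asarray(aspect, dtype=float)
    P = np.stack([n.p for n in nodes])
    A = np.array([[n.r, n.c] for n in nodes])
    r0 = np.array([n.r for n in nodes])
    for _ in range(iterations):
        tree = cKDTree(P * asp)
        neighbor_lists = tree.query_ball_point(P * asp, r0)
        newP = np.empty_like(P)
        newA = np.empty_like(A)
        for i, idx in enumerate(neighbor_lists):
            newP[i] = P[idx].mean(axis=0)
            newA[i] = A[idx].mean(axis=0)
        P, A = newP, newA
    return [
        TraceNode(P[i], float(A[i, 0]), float(A[i, 1]), set(nodes[i].links))
        for i in range(len(nodes))
    ]


def group_nodes(
    nodes: Sequence[TraceNode],
    r_g: float = 2.0,
    aspect: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[GroupNode]:
    """Greedy correlation-ordered grouping of refined nodes.

    Repeatedly seeds a group at the ungrouped node with the highest
    correlation (ties toward the lower index), absorbs the ungrouped
    nodes within Euclidean distance r_g, and averages member fields
    (unweighted).  Member links are remapped to group indices; the
    resulting partition has P <= M groups and preserves every inter-node
    connection as an inter-group connection.
    """
    if r_g <= 0:
        raise ValueError("r_g must be > 0")
    m = len(nodes)
    if m == 0:
        return []
    asp = np.asarray(aspect, dtype=float)
    P = np.stack([n.p for n in nodes])
    c = np.array([n.c for n in nodes])
    tree = cKDTree(P * asp)
    # process in decreasing correlation, ties toward the lower index
    order = np.lexsort((np.arange(m), -c))
    assignment = np.full(m, -1, dtype=int)
    groups_members: list[list[int]] = []
    for i in order:
        if assignment[i] != -1:
            continue
        gid = len(groups_members)
        members = [
            j
            for j in sorted(tree.query_ball_point(P[i] * asp, r_g))
            if assignment[j] == -1
        ]
        for j in members:
            assignment[j] = gid
        groups_members.append(members)
    groups: list[GroupNode] = []
    for gid, members in enumerate(groups_members):
        pos = P[members].mean(axis=0)
        r = float(np.mean([nodes[j].r for j in members]))
        cc = float(np.mean([nodes[j].c for j in members]))
        links: set[int] = set()
        for j in members:
            for k in nodes[j].links:
                tgt = int(assignment[k])
                if tgt != gid:
                    links.add(tgt)
        groups.append(GroupNode(pos, r, cc, links, list(members)))
    # enforce symmetry of the projected links
    for gid, g in enumerate(groups):
        for tgt in g.links:
            groups[tgt].links.add(gid)
    return groups


def build_tree(
    groups: Sequence[GroupNode],
    soma: SomaModel | None = None,
    aspect: Sequence[float] = (1.0, 1.0, 1.0),
    min_component: int = 3,
    prune_single_terminals: bool = True,
) -> SwcTree:
    """Breadth-first conversion of the group graph into an SWC tree.

    The root is the soma node (linked to every group within soma radius +
    group radius of its center) or, if no soma was found, the group with
    the highest correlation.  BFS assigns each visited group its
    discoverer as parent; cycle-closing edges are dropped.  Unvisited
    components of at least ``min_component`` groups become additional
    roots; smaller ones and single-node terminal branches are discarded
    as likely false positives.
    """
    if len(groups) == 0:
        warnings.warn("no group nodes: returning empty tree")
        return SwcTree([], voxel_aspect=tuple(aspect))
    asp = np.asarray(aspect, dtype=float)
    n = len(groups)
    adjacency: list[set[int]] = [set(g.links) for g in groups]
    for i, g in enumerate(groups):
        for j in g.links:
            adjacency[j].add(i)

    swc_nodes: list[SwcNode] = []
    parent_of: dict[int, int] = {}  # group idx -> swc id of parent
    swc_id_of: dict[int, int] = {}
    next_id = 1
    visited = np.zeros(n, dtype=bool)

    def bfs(start_groups: list[int], root_swc_id: int) -> None:
        nonlocal next_id
        queue = list(start_groups)
        for g in start_groups:
            visited[g] = True
            parent_of[g] = root_swc_id
        while queue:
            g = queue.pop(0)
            swc_id_of[g] = next_id
            swc_nodes.append(
                SwcNode(
                    next_id,
                    NEURITE_TYPE,
                    groups[g].p,
                    max(groups[g].r, 1e-3),
                    parent_of[g],
                )
            )
            next_id += 1
            for nb in sorted(adjacency[g]):
                if not visited[nb]:
                    visited[nb] = True
                    parent_of[nb] = swc_id_of[g]
                    queue.append(nb)

    if soma is not None and soma.found:
        root_id = next_id
        swc_nodes.append(SwcNode(root_id, SOMA_TYPE, soma.center, soma.radius, -1))
        next_id += 1
        attached = [
            i
            for i, g in enumerate(groups)
            if np.linalg.norm((g.p - soma.center) * asp) <= soma.radius + g.r
        ]
        if attached:
            bfs(attached, root_id)
    else:
        corr = np.array([g.c for g in groups])
        start = int(np.lexsort((np.arange(n), -corr))[0])
        root_id = next_id
        swc_nodes.append(
            SwcNode(root_id, NEURITE_TYPE, groups[start].p, max(groups[start].r, 1e-3), -1)
        )
        swc_id_of[start] = root_id
        visited[start] = True
        next_id += 1
        children = [nb for nb in sorted(adjacency[start]) if not visited[nb]]
        bfs_children = []
        for nb in children:
            if not visited[nb]:
                bfs_children.append(nb)
        bfs(bfs_children, root_id)

    # remaining components become extra roots if large enough
    while not visited.all():
        remaining = np.nonzero(~visited)[0]
        # component of the highest-correlation remaining group
        corr = np.array([groups[i].c for i in remaining])
        start = int(remaining[np.lexsort((np.arange(len(remaining)), -corr))[0]])
        comp = [start]
        seen = {start}
        stack = [start]
        while stack:
            g = stack.pop()
            for nb in adjacency[g]:
                if nb not in seen and not visited[nb]:
                    seen.add(nb)
                    comp.append(nb)
                    stack.append(nb)
        if len(comp) >= min_component:
            root_id = next_id
            swc_nodes.append(
                SwcNode(
                    root_id,
                    NEURITE_TYPE,
                    groups[start].p,
                    max(groups[start].r, 1e-3),
                    -1,
                )
            )
            swc_id_of[start] = root_id
            visited[start] = True
            next_id += 1
            bfs([nb for nb in sorted(adjacency[start]) if not visited[nb]], root_id)
        else:
            for g in comp:
                visited[g] = True

    if prune_single_terminals and swc_nodes:
        children: dict[int, list[int]] = {}
        for node in swc_nodes:
            children.setdefault(node.parent, []).append(node.id)
        by_id = {node.id: node for node in swc_nodes}
        drop: set[int] = set()
        for node in swc_nodes:
            if node.id in children:
                continue  # not a leaf
            parent = node.parent
            if parent == -1:
                continue
            parent_node = by_id[parent]
            siblings = children.get(parent, [])
            parent_is_junction = len(siblings) >= 2 or parent_node.parent == -1
            if parent_is_junction:
                drop.add(node.id)
        swc_nodes = [node for node in swc_nodes if node.id not in drop]

    tree = SwcTree(swc_nodes, voxel_aspect=tuple(float(a) for a in asp))
    tree.validate()
    return tree


def reconstruct_with_info(
    volume: np.ndarray,
    soma_params: SomaParams | None = None,
    seed_params: SeedParams | None = None,
    tracer_params: TracerParams | None = None,
    r_g: float = 2.0,
    voxel_aspect: Sequence[float] = (1.0, 1.0, 1.0),
    rng_seed: int = 0,
    mean_shift_iterations: int = 5,
    min_component: int = 3,
    prune_single_terminals: bool = True,
) -> tuple[SwcTree, dict]:
    """Full reconstruction pipeline with per-stage counters.

    soma -> seeds -> SMC tracing -> one-voxel resampling -> mean-shift
    refinement -> grouping -> BFS tree.  Deterministic for a fixed
    ``rng_seed``.
    """
    soma_params = soma_params or SomaParams()
    seed_params = seed_params or SeedParams()
    tracer_params = tracer_params or TracerParams()
    rng = np.random.default_rng(rng_seed)
    vol = np.asarray(volume, dtype=float)

    soma = extract_soma(vol, soma_params, voxel_aspect)
    seeds = extract_seeds(vol, seed_params, voxel_aspect)
    info: dict = {"soma_found": soma.found, "n_seeds": len(seeds)}
    if not seeds:
        warnings.warn("no seeds found: returning empty tree")
        return SwcTree([], voxel_aspect=tuple(voxel_aspect)), info
    traces = trace_all(seeds, vol, tracer_params, rng)
    info["n_traces"] = len(traces)
    nodes = nodes_from_traces(traces, step=1.0, aspect=voxel_aspect)
    info["n_nodes"] = len(nodes)
    refined = mean_shift_refine(nodes, mean_shift_iterations, voxel_aspect)
    groups = group_nodes(refined, r_g, voxel_aspect)
    info["n_groups"] = len(groups)
    tree = build_tree(
        groups,
        soma,
        voxel_aspect,
        min_component=min_component,
        prune_single_terminals=prune_single_terminals,
    )
    info["n_output_nodes"] = len(tree)
    return tree, info


def reconstruct(volume: np.ndarray, **kwargs) -> SwcTree:
    """Reconstruct a neuron tree from an image stack (see
    :func:`reconstruct_with_info` for parameters)."""
    tree, _ = reconstruct_with_info(volume, **kwargs)
    return tree
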