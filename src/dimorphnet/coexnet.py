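"""Planar co-expression network construction and module discovery.

Gene-gene Spearman correlations are tested with the t approximation,
BH-filtered across all pairs, and the surviving edges — sorted by |rho|
descending with lexicographic tie-breaking so runs are bit-reproducible —
are inserted greedily into a planar maximally filtered graph (PMFG): an edge
is kept iff the graph stays planar, stopping once the planar bound of
3(n - 2) edges is reached. Modules are found by recursively splitting the
planar backbone with resolution-swept modularity communities, keeping every
accepted level as a nested hierarchy. Hubs ("key network drivers") are the
genes whose intramodular connectivity exceeds the module mean plus one
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_matrix",
    "correlation_edges",
    "build_pmfg",
    "Module",
    "ModuleHierarchy",
    "detect_modules",
    "ConnectivityProfile",
    "intramodular_connectivity",
    "nominate_knds",
    "l_layer_neighborhood",
]


def spearman_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """All-pairs Spearman rho for genes (rows) of a log-expression matrix."""
    ranks = stats.rankdata(matrix.to_numpy(dtype=float), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    return rho


def correlation_edges(
    matrix: pd.DataFrame,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Significant gene-gene Spearman edges, sorted for PMFG insertion.

    P-values use the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``
    with BH adjustment across all tested pairs; pairs involving a constant
    gene are dropped (count logged). Output columns: ``gene_a, gene_b, rho,
    p, q``, sorted by |rho| descending, ties lexicographic on the id pair.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation edges")
    genes = matrix.index.to_numpy()
    values = matrix.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        logger.info("correlation_edges: dropping %d constant genes",
                    int(constant.sum()))
    keep = ~constant
    rho = spearman_matrix(matrix.loc[keep])
    kept_genes = genes[keep]
    iu = np.triu_indices(len(kept_genes), k=1)
    r = np.clip(rho[iu], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    q = bh_adjust(p)
    edges = pd.DataFrame({
        "gene_a": kept_genes[iu[0]],
        "gene_b": kept_genes[iu[1]],
        "rho": r,
        "p": p,
        "q": q,
    })
    edges = edges[edges["q"] < fdr_max].copy()
    edges["abs_rho"] = edges["rho"].abs()
    edges = edges.sort_values(
        ["abs_rho", "gene_a", "gene_b"],
        ascending=[False, True, True], kind="mergesort",
    ).drop(columns="abs_rho").reset_index(drop=True)
    return edges


def build_pmfg(edges: pd.DataFrame, nodes: Iterable[str]) -> nx.Graph:
    """Planar maximally filtered graph from a weight-sorted edge list.

    Edges are inserted in the given order and kept iff the graph remains
    planar (certified by the combinatorial planarity test); insertion stops
    early at the planar edge bound 3(n - 2). Edge attribute ``weight`` is
    the signed correlation; connectivity computations use its magnitude.
    """
    G = nx.Graph()
    G.add_nodes_from(nodes)
    n = G.number_of_nodes()
    max_edges = max(0, 3 * (n - 2)) if n >= 3 else (1 if n == 2 else 0)
    for row in edges.itertuples(index=False):
        if G.number_of_edges() >= max_edges:
            break
        a, b = row.gene_a, row.gene_b
        if a == b or G.has_edge(a, b):
            continue
        G.add_edge(a, b, weight=float(row.rho))
        is_planar, _ = nx.check_planarity(G, counterexample=False)
        if not is_planar:
            G.remove_edge(a, b)
    return G


@dataclass
class Module:
    id: str
    parent: Optional[str]
    members: FrozenSet[str]
    depth: int


@dataclass
class ModuleHierarchy:
    """Nested modules on the planar backbone; the root holds every node."""

    modules: List[Module]

    @property
    def by_id(self) -> Dict[str, Module]:
        return {m.id: m for m in self.modules}

    def children(self, module_id: str) -> List[Module]:
        return [m for m in self.modules if m.parent == module_id]

    def nonroot(self) -> List[Module]:
        return [m for m in self.modules if m.parent is not None]

    def leaf_membership(self) -> Dict[str, str]:
        """Deepest module assignment per gene (root-only genes map to the
        root id)."""
        assign: Dict[str, Tuple[int, str]] = {}
        for m in self.modules:
            for g in m.members:
                if g not in assign or m.depth > assign[g][0]:
                    assign[g] = (m.depth, m.id)
        return {g: mid for g, (_, mid) in assign.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [(m.id, m.parent or "", m.depth, g)
                for m in self.modules for g in sorted(m.members)]
        return pd.DataFrame(rows, columns=["module_id", "parent_id",
                                           "scale", "gene_id"])


def _abs_weight_graph(G: nx.Graph, members: Iterable[str]) -> nx.Graph:
    # built explicitly in sorted order: subgraph views iterate their node
    # filter in set (hash) order, which would leak into seeded community
    # sweeps and break run-to-run determinism
    members = sorted(members)
    member_set = set(members)
    H = nx.Graph()
    H.add_nodes_from(members)
    for u in members:
        for v, d in G[u].items():
            if v in member_set and u < v:
                H.add_edge(u, v, weight=abs(d.get("weight", 1.0)))
    return H


def _cut_ratio(H: nx.Graph, children: Sequence[Set[str]]) -> float:
    """Mean |weight| of edges cut by the split divided by the mean |weight|
    inside the children (0 when nothing is cut)."""
    node2c = {n: i for i, c in enumerate(children) for n in c}
    cut, within = [], []
    for u, v, d in H.edges(data=True):
        cu, cv = node2c.get(u), node2c.get(v)
        if cu is None or cv is None:
            continue
        (within if cu == cv else cut).append(abs(d.get("weight", 1.0)))
    if not cut:
        return 0.0
    if not within:
        return np.inf
    return float(np.mean(cut) / np.mean(within))


def _merge_until_separated(H: nx.Graph, comms: List[Set[str]],
                           min_size: int,
                           separation_max: float) -> List[Set[str]]:
    """Agglomerate a community partition until every remaining pair of
    communities is only weakly connected.

    Two communities are merged while the mean |weight| of the edges between
    them reaches ``separation_max`` times the mean |weight| inside them;
    afterwards communities below ``min_size`` are absorbed into their most
    strongly attached neighbor. Splitting a homogeneous module leaves cuts
    as strong as the interiors, so it collapses back to one block; distinct
    modules held together only by weak spurious edges stay apart.
    """
    comms = [set(c) for c in comms]

    def mean_w(pairs):
        return float(np.mean(pairs)) if pairs else 0.0

    while len(comms) > 1:
        node2c = {n: i for i, c in enumerate(comms) for n in c}
        intra = [[] for _ in comms]
        inter: Dict[Tuple[int, int], List[float]] = {}
        for u, v, d in H.edges(data=True):
            w = abs(d.get("weight", 1.0))
            cu, cv = node2c[u], node2c[v]
            if cu == cv:
                intra[cu].append(w)
            else:
                inter.setdefault((min(cu, cv), max(cu, cv)), []).append(w)
        best_pair, best_ratio = None, separation_max
        for (i, j), ws in sorted(inter.items()):
            denom = mean_w(intra[i] + intra[j])
            ratio = np.inf if denom == 0 else mean_w(ws) / denom
            if ratio >= best_ratio:
                best_ratio, best_pair = ratio, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        comms[i] |= comms[j]
        del comms[j]

    # absorb undersized leftovers into their strongest neighbor
    changed = True
    while changed and len(comms) > 1:
        changed = False
        node2c = {n: i for i, c in enumerate(comms) for n in c}
        for i, c in enumerate(comms):
            if len(c) >= min_size:
                continue
            attach: Dict[int, float] = {}
            for n in c:
                for _, v, d in H.edges(n, data=True):
                    cv = node2c[v]
                    if cv != i:
                        attach[cv] = attach.get(cv, 0.0) \
                            + abs(d.get("weight", 1.0))
            if attach:
                target = max(sorted(attach), key=lambda k: attach[k])
                comms[target] |= c
                del comms[i]
                changed = True
                break
    return comms


def _best_split(H: nx.Graph, min_size: int, epsilon: float,
                resolutions: Sequence[float], seed: int,
                separation_max: float = 0.75
                ) -> Optional[List[Set[str]]]:
    """Most separating accepted partition of the induced subgraph, or None.

    Candidates are modularity communities at each resolution, agglomerated
    by ``_merge_until_separated``; a candidate needs >= 2 children of
    ``min_size``, weighted modularity >= ``epsilon`` and a cut-to-within
    mean |weight| ratio below ``separation_max``. Among candidates the one
    with the weakest cut wins.
    """
    if H.number_of_edges() == 0:
        return None
    best: Optional[List[Set[str]]] = None
    best_ratio = separation_max
    for res in resolutions:
        comms = nx.community.louvain_communities(
            H, weight="weight", resolution=res, seed=seed)
        merged = _merge_until_separated(H, [set(c) for c in comms],
                                        min_size, separation_max)
        big = [c for c in merged if len(c) >= min_size]
        if len(big) < 2:
            continue
        if nx.community.modularity(H, merged, weight="weight") < epsilon:
            continue
        ratio = _cut_ratio(H, big)
        if ratio < best_ratio:
            best_ratio = ratio
            # deterministic ordering: by smallest member id
            best = sorted(big, key=lambda c: min(c))
    return best


def detect_modules(
    network: nx.Graph,
    min_size: int = 10,
    max_depth: int = 5,
    epsilon: float = 0.001,
    resolutions: Sequence[float] = (0.3, 0.5, 1.0, 1.5, 2.0),
    separation_max: float = 0.75,
    seed: int = 0,
) -> ModuleHierarchy:
    """Multiscale module hierarchy by recursive modularity splitting.

    Connected components of at least ``min_size`` seed the root's children;
    each module is then recursively split (see ``_best_split``) until no
    split is accepted or ``max_depth`` is reached. Deterministic for a fixed
    seed.
    """
    root = Module(id="M0", parent=None,
                  members=frozenset(network.nodes), depth=0)
    modules = [root]
    counter = 1
    components = sorted((set(c) for c in nx.connected_components(network)),
                        key=lambda c: (-len(c), min(c)))
    queue: List[Tuple[Set[str], str, int]] = []
    for comp in components:
        if len(comp) >= min_size:
            mod = Module(id=f"M{counter}", parent="M0",
                         members=frozenset(comp), depth=1)
            counter += 1
            modules.append(mod)
            queue.append((comp, mod.id, 1))

    while queue:
        members, mod_id, depth = queue.pop(0)
        if depth >= max_depth or len(members) < 2 * min_size:
            continue
        H = _abs_weight_graph(network, members)
        split = _best_split(H, min_size, epsilon, resolutions, seed,
                            separation_max)
        if split is None:
            continue
        for child in split:
            mod = Module(id=f"M{counter}", parent=mod_id,
                         members=frozenset(child), depth=depth + 1)
            counter += 1
            modules.append(mod)
            queue.append((child, mod.id, depth + 1))
    return ModuleHierarchy(modules=modules)


@dataclass
class ConnectivityProfile:
    """Intramodular connectivity of one module on the planar backbone."""

    module_id: str
    k: pd.Series  # gene -> sum of |edge weight| to adjacent co-members
    mean_k: float
    sd_k: float

    @property
    def threshold(self) -> float:
        return self.mean_k + self.sd_k


def intramodular_connectivity(network: nx.Graph,
                              members: Iterable[str],
                              module_id: str = "") -> ConnectivityProfile:
    """Per-gene sum of |edge weight| to adjacent co-members, with the module
    mean, sample SD and hub threshold (mean + 1 SD)."""
    members = sorted(members)
    if len(members) < 2:
        raise ValueError(f"module {module_id or '?'} has < 2 members")
    absent = [g for g in members if g not in network]
    if absent:
        raise KeyError(f"module members missing from network: {absent[:5]}")
    member_set = set(members)
    k = {}
    for g in members:
        k[g] = sum(abs(d.get("weight", 1.0))
                   for _, h, d in network.edges(g, data=True)
                   if h in member_set)
    ks = pd.Series(k, name="k")
    sd = float(ks.std(ddof=1))
    return ConnectivityProfile(module_id=module_id, k=ks,
                               mean_k=float(ks.mean()), sd_k=sd)


def nominate_knds(profile: ConnectivityProfile) -> FrozenSet[str]:
    """Genes whose connectivity strictly exceeds the module mean + 1 SD."""
    return frozenset(profile.k.index[profile.k > profile.threshold])


def l_layer_neighborhood(network: nx.Graph, gene: str, L: int,
                         include_self: bool = False) -> FrozenSet[str]:
    """All nodes within unweighted shortest-path distance L of ``gene``
    (the gene itself excluded unless ``include_self``)."""
    if gene not in network:
        raise KeyError(f"gene {gene!r} not in network")
    if L < 0:
        raise ValueError("L must be >= 0")
    dist = nx.single_source_shortest_path_length(network, gene, cutoff=L)
    nodes = set(dist)
    if not include_self:
        nodes.discard(gene)
    return frozenset(nodes)
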