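"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chelate.electronics import ElectronicRecord
from chelate.features import FeatureTable, featurize_ligand
from chelate.structures import LigandStructure, MolecularGraph
from chelate.synth import SyntheticLigandSpec, make_ligand, make_ligand_pool


# ---------------------------------------------------------------------------
# graph helpers and oracles (independent of the implementation under test)


def mg(edges, n=None, elements=None) -> MolecularGraph:
    """MolecularGraph from an edge list; all-carbon unless elements given."""
    g = nx.Graph()
    nodes = set()
    for i, j in edges:
        nodes.update((i, j))
    if n is not None:
        nodes.update(range(n))
    for v in sorted(nodes):
        g.add_node(v, element=(elements or {}).get(v, "C"))
    g.add_edges_from(edges)
    return MolecularGraph(graph=g)


def brute_wiener(g: nx.Graph) -> int:
    """All-pairs BFS by hand."""
    total = 0
    nodes = list(g.nodes)
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if len(dist) != len(nodes):
            raise ValueError("disconnected")
        total += sum(dist.values())
    return total // 2


def brute_matchings(g: nx.Graph) -> int:
    """Count matchings by explicit enumeration over edge subsets."""
    edges = list(g.edges)

    def rec(i, used):
        if i == len(edges):
            return 1
        count = rec(i + 1, used)  # skip edge i
        u, v = edges[i]
        if u not in used and v not in used:
            count += rec(i + 1, used | {u, v})
        return count

    return rec(0, frozenset())


def brute_balaban(g: nx.Graph) -> float:
    from scipy.sparse.csgraph import shortest_path

    nodes = list(g.nodes)
    ix = {v: k for k, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges:
        A[ix[u], ix[v]] = A[ix[v], ix[u]] = 1
    D = shortest_path(A, unweighted=True)
    s = D.sum(axis=1)
    q = g.number_of_edges()
    mu = q - len(nodes) + 1
    return q / (mu + 1) * sum(1.0 / math.sqrt(s[ix[u]] * s[ix[v]]) for u, v in g.edges)


def brute_paths(g: nx.Graph, m: int) -> list[tuple]:
    """All m-edge simple paths via permutations of vertex tuples."""
    if m == 0:
        return [(v,) for v in g.nodes]
    out = set()
    for combo in itertools.permutations(g.nodes, m + 1):
        if all(g.has_edge(combo[k], combo[k + 1]) for k in range(m)):
            out.add(min(combo, combo[::-1]))
    return sorted(out)


def brute_chi(g: nx.Graph, m: int) -> float:
    deg = dict(g.degree())
    total = 0.0
    for path in brute_paths(g, m):
        prod = 1.0
        for v in path:
            prod *= deg[v]
        total += 1.0 / math.sqrt(prod)
    return total


def brute_kappa(g: nx.Graph, m: int) -> float:
    a = g.number_of_nodes()
    pm = len(brute_paths(g, m))
    if m == 1:
        return a * (a - 1) ** 2 / pm**2
    if m == 2:
        return (a - 1) * (a - 2) ** 2 / pm**2
    if a % 2 == 1:
        return (a - 1) * (a - 3) ** 2 / pm**2
    return (a - 3) * (a - 2) ** 2 / pm**2


def mc_union_volume(coords, radii, n_points, seed) -> tuple[float, float]:
    """Monte-Carlo union-of-spheres volume and its standard error."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    lo = (coords - radii[:, None]).min(axis=0)
    hi = (coords + radii[:, None]).max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    inside = np.zeros(n_points, dtype=bool)
    for c, r in zip(coords, radii):
        inside |= ((pts - c) ** 2).sum(axis=1) <= r * r
    box = float(np.prod(hi - lo))
    p = inside.mean()
    return box * p, box * math.sqrt(max(p * (1 - p), 1e-12) / n_points)


def connected_test_graphs():
    """All connected atlas graphs up to 7 vertices plus seeded 8-vertex samples."""
    from networkx.generators.atlas import graph_atlas_g

    graphs = [
        g for g in graph_atlas_g()[1:] if g.number_of_nodes() and nx.is_connected(g)
    ]
    rng = np.random.default_rng(2024)
    n8 = 0
    while n8 < 60:
        g = nx.gnp_random_graph(8, rng.uniform(0.2, 0.7), seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            graphs.append(g)
            n8 += 1
    return graphs


@pytest.fixture(scope="session")
def graphs():
    return connected_test_graphs()


# ---------------------------------------------------------------------------
# structure fixtures


def _c2_symmetric_structure() -> LigandStructure:
    """Hand-built, exactly mirror-symmetric N-C-C-N ligand (donors = N)."""
    atoms = [
        ("N", -0.73, 0.0, 0.0),
        ("N", 0.73, 0.0, 0.0),
        ("C", -0.76, 0.0, 1.45),
        ("C", 0.76, 0.0, 1.45),
        ("H", -1.25, 0.85, -0.35),
        ("H", 1.25, 0.85, -0.35),
        ("H", -1.25, -0.85, -0.35),
        ("H", 1.25, -0.85, -0.35),
        ("H", -1.35, -0.55, 2.05),
        ("H", 1.35, -0.55, 2.05),
        ("H", -1.05, 1.0, 1.70),
        ("H", 1.05, 1.0, 1.70),
    ]
    return LigandStructure(
        ligand_id="c2_fixture",
        symbols=[a[0] for a in atoms],
        coords=np.array([a[1:] for a in atoms]),
        donor_indices=(0, 1),
    )


@pytest.fixture
def c2_ligand() -> LigandStructure:
    return _c2_symmetric_structure()


@pytest.fixture(scope="session")
def en_ligand():
    """Plain ethylenediamine-like ligand from the synthetic generator."""
    struct, bond_orders, elec = make_ligand(SyntheticLigandSpec("en", ("h", "h"), seed=3))
    return struct, bond_orders, elec


@pytest.fixture(scope="session")
def bulky_ligand():
    """One bare arm, one tert-butyl arm: strongly asymmetric halves."""
    struct, bond_orders, elec = make_ligand(SyntheticLigandSpec("en", ("h", "tbu"), seed=5))
    return struct, bond_orders, elec


def featurize_entry(entry, **kwargs) -> pd.Series:
    struct, bond_orders, elec = entry
    rec = ElectronicRecord(struct.ligand_id, elec)
    return featurize_ligand(struct, bond_orders, rec, **kwargs)


@pytest.fixture(scope="session")
def small_pool_table() -> FeatureTable:
    """Featurized 8-ligand synthetic pool for modeling/PCA tests."""
    pool = make_ligand_pool(8, seed=11)
    return FeatureTable.from_vectors(
        {e[0].ligand_id: featurize_entry(e) for e in pool}
    )


@pytest.fixture(scope="session")
def bo_pool_table() -> FeatureTable:
    """Featurized 60-ligand synthetic pool for screening studies."""
    pool = make_ligand_pool(60, seed=7)
    return FeatureTable.from_vectors(
        {e[0].ligand_id: featurize_entry(e) for e in pool}
    )
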