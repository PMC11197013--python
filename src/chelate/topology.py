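"""Graph-topological descriptors of the molecular graph.

All indices here are functions of the bonded graph alone (plus, for the
valence and bond-order variants, element identities, attached-hydrogen
counts and explicit bond orders) and are therefore invariant under any
rigid transform of the coordinates and under vertex relabeling.

Conventions
-----------
* chi (molecular connectivity) and kappa (shape) indices follow Kier and
  Hall and are computed on the hydrogen-suppressed graph; the valence delta
  is (Zv - h) / (Z - Zv - 1) with Zv the valence-electron count, Z the
  atomic number and h the number of attached hydrogens.
* kappa order 3 uses the published alternate numerator for even heavy-atom
  counts: (A-1)(A-3)^2/P3^2 for odd A, (A-3)(A-2)^2/P3^2 for even A.
* the alpha-modified kappas replace A by A+alpha and Pm by Pm+alpha with
  alpha the sum over heavy atoms of (r_cov / r_Csp3 - 1).
* the flexibility index is a bond-rotatability score in [0,1]: terminal
  bonds contribute 0, ring bonds are damped (factor 0.3) and pi bond
  character attenuates linearly to 0 at bond order 2; the score is the mean
  contribution over heavy-heavy bonds.  It requires explicit bond orders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx

from .elements import ATOMIC_NUMBER, VALENCE_ELECTRONS, kier_alpha
from .structures import MolecularGraph

__all__ = [
    "wiener_index",
    "hosoya_z",
    "balaban_j",
    "chi_index",
    "kappa_index",
    "path_count",
    "flexibility_index",
    "simple_bond_indices",
    "read_bond_order_sidecar",
]

MAX_HOSOYA_EDGES = 64


def _require_connected(g: nx.Graph, what: str) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError(f"{what}: empty graph")
    if not nx.is_connected(g):
        raise ValueError(f"{what}: graph is disconnected")


def _pick(g: MolecularGraph | nx.Graph, hydrogen_suppressed: bool) -> nx.Graph:
    if isinstance(g, MolecularGraph):
        return g.hydrogen_suppressed if hydrogen_suppressed else g.graph
    return g


def wiener_index(g: MolecularGraph | nx.Graph, hydrogen_suppressed: bool = False) -> int:
    """Sum of shortest-path lengths over all unordered vertex pairs."""
    gr = _pick(g, hydrogen_suppressed)
    _require_connected(gr, "wiener_index")
    w = 0
    for _, dists in nx.all_pairs_shortest_path_length(gr):
        w += sum(dists.values())
    return w // 2


def hosoya_z(g: MolecularGraph | nx.Graph, hydrogen_suppressed: bool = False) -> int:
    """Number of matchings of the graph, including the empty matching."""
    gr = _pick(g, hydrogen_suppressed)
    if gr.number_of_edges() > MAX_HOSOYA_EDGES:
        raise ValueError(
            f"hosoya_z: {gr.number_of_edges()} edges exceeds the exact-count guard "
            f"({MAX_HOSOYA_EDGES})"
        )
    adj = {v: set(gr.neighbors(v)) for v in gr.nodes}
    memo: dict[frozenset, int] = {}

    def z(verts: frozenset) -> int:
        if len(verts) <= 1:
            return 1
        got = memo.get(verts)
        if got is not None:
            return got
        # split off the connected component of the smallest vertex
        v0 = min(verts)
        comp, stack = {v0}, [v0]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w in verts and w not in comp:
                    comp.add(w)
                    stack.append(w)
        if len(comp) < len(verts):
            res = z(frozenset(comp)) * z(verts - comp)
        else:
            # Z(G) = Z(G - v) + sum over edges (v,u) of Z(G - v - u)
            rest = verts - {v0}
            res = z(frozenset(rest))
            for u in adj[v0]:
                if u in verts:
                    res += z(frozenset(rest - {u}))
        memo[verts] = res
        return res

    return z(frozenset(adj))


def balaban_j(g: MolecularGraph | nx.Graph, hydrogen_suppressed: bool = False) -> float:
    """Distance-sum connectivity index J = q/(mu+1) sum_(ij) (s_i s_j)^-1/2."""
    gr = _pick(g, hydrogen_suppressed)
    _require_connected(gr, "balaban_j")
    q = gr.number_of_edges()
    if q == 0:
        raise ValueError("balaban_j: graph has no edges")
    n = gr.number_of_nodes()
    mu = q - n + 1
    s = {v: sum(d.values()) for v, d in nx.all_pairs_shortest_path_length(gr)}
    total = sum(1.0 / math.sqrt(s[i] * s[j]) for i, j in gr.edges)
    return q / (mu + 1.0) * total


# ---------------------------------------------------------------------------
# Kier-Hall connectivity and shape


def _paths_of_length(gr: nx.Graph, m: int) -> list[tuple]:
    """All simple paths with m edges, as vertex tuples, each counted once."""
    if m == 0:
        return [(v,) for v in gr.nodes]
    out = []

    def extend(path: tuple) -> None:
        if len(path) == m + 1:
            if path[0] < path[-1]:
                out.append(path)
            return
        for u in gr.neighbors(path[-1]):
            if u not in path:
                extend(path + (u,))

    for v in gr.nodes:
        extend((v,))
    return out


def path_count(g: MolecularGraph | nx.Graph, m: int) -> int:
    """Number of simple paths with m edges in the hydrogen-suppressed graph."""
    gr = _pick(g, True)
    return len(_paths_of_length(gr, m))


def _valence_delta(gr: nx.Graph, h_counts: dict[int, int]) -> dict[int, float]:
    out = {}
    for v, data in gr.nodes(data=True):
        el = data["element"]
        zv = VALENCE_ELECTRONS.get(el)
        z = ATOMIC_NUMBER.get(el)
        if zv is None or z is None:
            raise ValueError(f"no valence-electron data for element {el!r}")
        h = h_counts.get(v, 0)
        denom = z - zv - 1
        dv = (zv - h) / denom if denom > 0 else float(zv - h)
        if dv <= 0:
            raise ValueError(f"non-positive valence delta for atom {v} ({el}, {h} H)")
        out[v] = dv
    return out


def chi_index(g: MolecularGraph, m: int, valence: bool = False) -> float:
    """Kier-Hall molecular connectivity ^m chi (simple or valence).

    Sum over m-edge path subgraphs of the reciprocal square root of the
    product of vertex deltas; computed on the hydrogen-suppressed graph.
    """
    if not 0 <= m <= 6:
        raise ValueError("chi order must be in 0..6")
    gr = _pick(g, True)
    if valence:
        if not isinstance(g, MolecularGraph):
            raise TypeError("valence chi needs a MolecularGraph (hydrogen counts)")
        delta = _valence_delta(gr, g.hydrogen_counts())
    else:
        delta = dict(gr.degree())
    total = 0.0
    for path in _paths_of_length(gr, m):
        prod = 1.0
        for v in path:
            d = delta[v]
            if d <= 0:
                raise ValueError(f"zero-degree vertex {v} in a multi-vertex fragment")
            prod *= d
        total += 1.0 / math.sqrt(prod)
    return total


def kappa_index(g: MolecularGraph | nx.Graph, m: int, alpha: bool = False) -> float:
    """Kier shape index ^m kappa (m = 1..3), optionally alpha-modified."""
    if m not in (1, 2, 3):
        raise ValueError("kappa order must be 1, 2 or 3")
    gr = _pick(g, True)
    a = gr.number_of_nodes()
    if a < m + 1:
        raise ValueError(f"kappa order {m} needs at least {m + 1} heavy atoms")
    pm = len(_paths_of_length(gr, m))
    if pm == 0:
        raise ValueError(f"kappa_{m}: no paths of length {m}")
    al = 0.0
    if alpha:
        al = sum(kier_alpha(d["element"]) for _, d in gr.nodes(data=True))
    aa, pp = a + al, pm + al
    if pp <= 0:
        raise ValueError(f"kappa_{m}: alpha-corrected path count non-positive")
    if m == 1:
        return aa * (aa - 1.0) ** 2 / pp**2
    if m == 2:
        return (aa - 1.0) * (aa - 2.0) ** 2 / pp**2
    if a % 2 == 1:
        return (aa - 1.0) * (aa - 3.0) ** 2 / pp**2
    return (aa - 3.0) * (aa - 2.0) ** 2 / pp**2


# ---------------------------------------------------------------------------
# bond-order derived indices

RING_DAMPING = 0.3


def _heavy_edges_with_orders(g: MolecularGraph) -> list[tuple[int, int, float]]:
    gr = g.hydrogen_suppressed
    if g.bond_orders is None:
        raise ValueError("explicit bond orders are required but none were provided")
    out = []
    for i, j in gr.edges:
        key = frozenset((i, j))
        if key not in g.bond_orders:
            raise ValueError(f"missing bond order for edge ({i}, {j})")
        out.append((i, j, float(g.bond_orders[key])))
    return out


def flexibility_index(g: MolecularGraph) -> float:
    """Bond-rotatability score in [0, 1] (see module docstring)."""
    gr = g.hydrogen_suppressed
    edges = _heavy_edges_with_orders(g)
    if not edges:
        return 0.0
    ring_edges = set()
    for cyc in nx.cycle_basis(gr):
        for k in range(len(cyc)):
            ring_edges.add(frozenset((cyc[k], cyc[(k + 1) % len(cyc)])))
    deg = dict(gr.degree())
    total = 0.0
    for i, j, order in edges:
        if deg[i] <= 1 or deg[j] <= 1:
            continue  # terminal bond: not rotatable
        f = max(0.0, min(1.0, 2.0 - order))
        if frozenset((i, j)) in ring_edges:
            f *= RING_DAMPING
        total += f
    return total / len(edges)


def simple_bond_indices(
    g: MolecularGraph, donors: tuple[int, int] | None = None
) -> dict[str, float]:
    """Global and donor-local summaries of the explicit bond orders."""
    edges = _heavy_edges_with_orders(g)
    if not edges:
        raise ValueError("no heavy-heavy bonds with orders")
    orders = [o for _, _, o in edges]
    out = {
        "bo_global_sum": float(sum(orders)),
        "bo_global_mean": float(sum(orders) / len(orders)),
        "bo_global_max": float(max(orders)),
        "bo_global_min": float(min(orders)),
    }
    if donors is not None:
        for tag, d in zip(("donor_a", "donor_b"), donors):
            inc = [o for i, j, o in edges if d in (i, j)]
            out[f"bo_{tag}_sum"] = float(sum(inc)) if inc else 0.0
            out[f"bo_{tag}_mean"] = float(sum(inc) / len(inc)) if inc else 0.0
    return out


def read_bond_order_sidecar(path: str | Path) -> dict[str, dict[frozenset, float]]:
    """Read a bond-order table: ligand_id, atom_i, atom_j, order (0-based)."""
    out: dict[str, dict[frozenset, float]] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.replace(",", " ").split()
        if len(parts) != 4:
            raise ValueError(f"malformed bond-order line {ln!r}")
        lid, i, j, o = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if o <= 0:
            raise ValueError(f"non-positive bond order in line {ln!r}")
        out.setdefault(lid, {})[frozenset((i, j))] = o
    return out
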