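"""Topological indices against hand values and brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from chelate.structures import MolecularGraph
from chelate.topology import (
    balaban_j,
    chi_index,
    flexibility_index,
    hosoya_z,
    kappa_index,
    path_count,
    read_bond_order_sidecar,
    simple_bond_indices,
    wiener_index,
)

from conftest import brute_balaban, brute_chi, brute_kappa, brute_matchings, brute_paths, brute_wiener, mg


def path(n):
    return mg([(i, i + 1) for i in range(n - 1)], n=n)


def cycle(n):
    return mg([(i, (i + 1) % n) for i in range(n)])


class TestHandValues:
    def test_wiener(self):
        assert wiener_index(path(4)) == 10
        assert wiener_index(mg([], n=1)) == 0
        assert wiener_index(cycle(3)) == 3

    def test_hosoya(self):
        assert hosoya_z(path(4)) == 5
        assert hosoya_z(mg([], n=5)) == 1
        assert hosoya_z(cycle(6)) == 18

    def test_balaban(self):
        assert balaban_j(cycle(6)) == pytest.approx(2.0, abs=1e-12)
        assert balaban_j(path(2)) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            balaban_j(mg([(0, 1), (2, 3)]))

    def test_chi(self):
        star4 = mg([(0, 1), (0, 2), (0, 3), (0, 4)])
        assert chi_index(star4, 1) == pytest.approx(2.0, abs=1e-12)
        assert chi_index(path(2), 0) == pytest.approx(2.0, abs=1e-12)
        p5 = path(5)
        assert chi_index(p5, 2) == pytest.approx(brute_chi(p5.graph, 2), abs=1e-12)

    def test_kappa(self):
        assert kappa_index(path(5), 1) == pytest.approx(5.0, abs=1e-12)
        assert kappa_index(cycle(6), 1) == pytest.approx(6 * 25 / 36, abs=1e-12)
        assert kappa_index(path(5), 2) == pytest.approx(4.0, abs=1e-12)

    def test_kappa3_even_odd_convention(self):
        p6, p7 = path(6), path(7)
        # P3 of a path on n vertices is n - 3
        assert kappa_index(p7, 3) == pytest.approx(6 * 16 / 16, abs=1e-12)
        assert kappa_index(p6, 3) == pytest.approx(3 * 16 / 9, abs=1e-12)


class TestOracleSuite:
    def test_wiener_hosoya_balaban_vs_bruteforce(self, graphs):
        for g in graphs:
            m = mg(list(g.edges), n=g.number_of_nodes())
            assert wiener_index(m) == brute_wiener(g)
            assert hosoya_z(m) == brute_matchings(g)
            if g.number_of_edges():
                assert balaban_j(m) == pytest.approx(brute_balaban(g), rel=1e-10)

    def test_chi_kappa_vs_bruteforce(self, graphs):
        for g in graphs[::3]:
            if g.number_of_nodes() < 2:
                continue  # chi undefined on an isolated vertex (zero degree)
            m = mg(list(g.edges), n=g.number_of_nodes())
            for order in range(4):
                assert chi_index(m, order) == pytest.approx(
                    brute_chi(g, order), rel=1e-10
                ), f"chi{order} on {sorted(g.edges)}"
            a = g.number_of_nodes()
            for order in (1, 2, 3):
                if a >= order + 1 and brute_paths(g, order):
                    assert kappa_index(m, order) == pytest.approx(
                        brute_kappa(g, order), rel=1e-10
                    )

    def test_path_counts_vs_bruteforce(self, graphs):
        for g in graphs[::7]:
            m = mg(list(g.edges), n=g.number_of_nodes())
            for order in range(1, 5):
                assert path_count(m, order) == len(brute_paths(g, order))


class TestInvariance:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        base = nx.random_labeled_tree(9, seed=3)
        extra = nx.Graph(base)
        extra.add_edge(0, 8)
        for g in (base, extra):
            m0 = mg(list(g.edges), n=9)
            ref = (
                wiener_index(m0), hosoya_z(m0), balaban_j(m0),
                chi_index(m0, 2), kappa_index(m0, 2),
            )
            for _ in range(5):
                perm = rng.permutation(9)
                rel = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(9)})
                m1 = mg(list(rel.edges), n=9)
                got = (
                    wiener_index(m1), hosoya_z(m1), balaban_j(m1),
                    chi_index(m1, 2), kappa_index(m1, 2),
                )
                assert got == pytest.approx(ref, rel=1e-12)

    def test_kappa_alpha_zero_for_carbon_equals_plain(self):
        # alpha = sum(r_cov/r_Csp3 - 1) = 0 for an all-carbon skeleton
        g = path(6)
        for m_ord in (1, 2, 3):
            assert kappa_index(g, m_ord, alpha=True) == kappa_index(g, m_ord, alpha=False)

    def test_kappa_alpha_shifts_for_heteroatoms(self):
        g = mg([(0, 1), (1, 2), (2, 3)], elements={0: "N", 3: "O"})
        assert kappa_index(g, 1, alpha=True) != kappa_index(g, 1, alpha=False)

    def test_valence_chi_equals_simple_for_alkane(self):
        # all-carbon graph with valence delta = 4 - h = heavy degree
        full = nx.Graph()
        heavy = [0, 1, 2, 3]
        for v in heavy:
            full.add_node(v, element="C")
        full.add_edges_from([(0, 1), (1, 2), (2, 3)])
        hid = 4
        for v, nh in zip(heavy, (3, 2, 2, 3)):
            for _ in range(nh):
                full.add_node(hid, element="H")
                full.add_edge(v, hid)
                hid += 1
        g = MolecularGraph(graph=full)
        for m_ord in (0, 1, 2):
            assert chi_index(g, m_ord, valence=True) == pytest.approx(
                chi_index(g, m_ord, valence=False), rel=1e-12
            )


class TestBondOrderIndices:
    def _with_orders(self, edges, orders):
        g = mg(edges)
        g.bond_orders = {frozenset(e): o for e, o in zip(edges, orders)}
        return g

    def test_flexibility_star_is_zero(self):
        edges = [(0, 1), (0, 2), (0, 3), (0, 4)]
        g = self._with_orders(edges, [1, 1, 1, 1])
        assert flexibility_index(g) == 0.0

    def test_flexibility_orders_butane_above_isobutane(self):
        nbutane = self._with_orders([(0, 1), (1, 2), (2, 3)], [1, 1, 1])
        isobutane = self._with_orders([(0, 1), (0, 2), (0, 3)], [1, 1, 1])
        assert flexibility_index(nbutane) > flexibility_index(isobutane)

    def test_flexibility_ring_damped_below_chain(self):
        ring = self._with_orders([(i, (i + 1) % 6) for i in range(6)], [1] * 6)
        chain = self._with_orders([(i, i + 1) for i in range(5)], [1] * 5)
        assert flexibility_index(ring) < flexibility_index(chain)

    def test_flexibility_double_bond_rigid(self):
        single = self._with_orders([(0, 1), (1, 2), (2, 3)], [1, 1, 1])
        double = self._with_orders([(0, 1), (1, 2), (2, 3)], [1, 2, 1])
        assert flexibility_index(double) < flexibility_index(single)

    def test_missing_bond_order_names_edge(self):
        g = mg([(0, 1), (1, 2)])
        g.bond_orders = {frozenset((0, 1)): 1.0}
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            flexibility_index(g)

    def test_simple_indices(self):
        g = self._with_orders([(0, 1), (1, 2), (2, 3)], [1, 1, 1])
        out = simple_bond_indices(g, donors=(0, 3))
        assert out["bo_global_mean"] == 1.0
        g2 = self._with_orders([(0, 1), (1, 2)], [1.5, 1.0])
        out2 = simple_bond_indices(g2, donors=(0, 2))
        assert out2["bo_donor_a_mean"] == 1.5

    def test_no_orders_error(self):
        g = mg([(0, 1)])
        with pytest.raises(ValueError, match="bond order"):
            simple_bond_indices(g, donors=(0, 1))

    def test_sidecar_reader(self, tmp_path):
        p = tmp_path / "bo.tsv"
        p.write_text("# lig i j order\nL1 0 1 1.5\nL1 1 2 1\nL2 0 1 2\n")
        t = read_bond_order_sidecar(p)
        assert t["L1"][frozenset((0, 1))] == 1.5
        assert t["L2"][frozenset((0, 1))] == 2.0
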