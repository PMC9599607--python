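"""Body-bar framework construction and (6,6) pebble-game decomposition."""

import numpy as np
import pytest

from indelrig.fixtures import FixtureSpec, make_polyalanine, rigidity_matrix_oracle
from indelrig.interactions import detect_hydrogen_bonds, place_polar_hydrogens
from indelrig.rigidity import (
    BarPolicy,
    BodyBarFramework,
    ClusterSizeHistogram,
    RigidClusterDecomposition,
    build_framework,
    cluster_histogram,
    pebble_game_decompose,
)
from indelrig.structure_io import infer_covalent_bonds
from tests.conftest import random_framework


def _fw(n, edges):
    fw = BodyBarFramework(bodies=[(i,) for i in range(n)])
    for u, v, bars in edges:
        fw.add_bars(u, v, bars, "covalent-locked")
    return fw


class TestBuildFramework:
    def test_dipeptide_edges(self):
        st = make_polyalanine(FixtureSpec(kind="strand", length=2))
        bonds = infer_covalent_bonds(st)
        fw = build_framework(st, bonds)
        assert fw.n_bodies == st.n_atoms
        assert len(fw.edges) == len(bonds)
        by_bars = {6: 0, 5: 0}
        for _u, _v, bars, _o in fw.edges:
            by_bars[bars] += 1
        # locked: peptide, 2 pendant C=O, 2 pendant CB, pendant OXT, and
        # the N-terminal N-CA (N has no other neighbor) = 7; hinges: rest
        assert by_bars[6] == 7
        assert by_bars[5] == 3

    def test_hbond_adds_five_bar_edge(self, helix12):
        stp = place_polar_hydrogens(helix12)
        bonds = infer_covalent_bonds(stp)
        hbs = detect_hydrogen_bonds(stp, bonds=bonds)
        fw = build_framework(stp, bonds, hbs)
        hedges = [e for e in fw.edges if e[3] == "hbond"]
        assert len(hedges) == len(hbs)
        assert all(e[2] == 5 for e in hedges)

    def test_parallel_bars_capped_at_six(self):
        fw = _fw(2, [(0, 1, 5), (0, 1, 5)])
        capped = fw.capped_edges()
        assert sum(e[2] for e in capped) == 6

    def test_interaction_with_unknown_atom_rejected(self, tripeptide):
        from indelrig.interactions import HydrophobicContact
        bonds = infer_covalent_bonds(tripeptide)
        bogus = HydrophobicContact(idx_a=0, idx_b=tripeptide.n_atoms + 5,
                                   atom_a=tripeptide.atoms[0],
                                   atom_b=tripeptide.atoms[1], distance=3.0)
        with pytest.raises(ValueError, match="unknown atom"):
            build_framework(tripeptide, bonds, [], [bogus])


class TestPebbleGame:
    def test_single_body_single_cluster(self):
        fw = BodyBarFramework(bodies=[(7, 8, 9)])
        d = pebble_game_decompose(fw)
        assert d.clusters == [frozenset({7, 8, 9})]

    def test_six_bars_rigidify_pair(self):
        d = pebble_game_decompose(_fw(2, [(0, 1, 6)]))
        assert d.sizes == [2]

    def test_five_bars_leave_hinge(self):
        d = pebble_game_decompose(_fw(2, [(0, 1, 5)]))
        assert d.sizes == [1, 1]

    def test_triangle_of_three_bar_edges_flexible(self):
        # 9 bars total < 3*6 - 6 = 12 needed for collective rigidity
        d = pebble_game_decompose(_fw(3, [(0, 1, 3), (1, 2, 3), (0, 2, 3)]))
        assert d.sizes == [1, 1, 1]

    def test_triangle_of_four_bar_edges_rigid(self):
        # 12 independent bars on 3 bodies: exactly 6n-6
        d = pebble_game_decompose(_fw(3, [(0, 1, 4), (1, 2, 4), (0, 2, 4)]))
        assert d.sizes == [3]

    def test_rigidity_transmits_through_shared_body(self):
        d = pebble_game_decompose(_fw(3, [(0, 1, 6), (1, 2, 6)]))
        assert d.sizes == [3]

    def test_empty_framework_rejected(self):
        with pytest.raises(ValueError):
            pebble_game_decompose(BodyBarFramework(bodies=[]))

    def test_oracle_equivalence_on_random_frameworks(self):
        rng = np.random.default_rng(2024)
        for t in range(120):
            fw = random_framework(rng)
            pg = sorted(map(sorted, pebble_game_decompose(fw).clusters))
            orc = sorted(map(sorted, rigidity_matrix_oracle(fw, seed=t).clusters))
            assert pg == orc, f"framework {t}: {fw.edges}"

    def test_order_independence(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            fw = random_framework(rng)
            ref = sorted(map(sorted, pebble_game_decompose(fw).clusters))
            for _ in range(20):
                edges = list(fw.edges)
                rng.shuffle(edges)
                fw2 = BodyBarFramework(bodies=fw.bodies, edges=edges)
                assert sorted(map(sorted, pebble_game_decompose(fw2).clusters)) == ref

    def test_adding_bars_only_coarsens(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            fw = random_framework(rng)
            before = pebble_game_decompose(fw).clusters
            fw2 = BodyBarFramework(bodies=fw.bodies, edges=list(fw.edges))
            n = fw2.n_bodies
            u, v = rng.choice(n, size=2, replace=False)
            fw2.add_bars(int(u), int(v), int(rng.integers(1, 7)), "hbond")
            after = pebble_game_decompose(fw2).clusters
            for c in before:
                assert any(c <= c2 for c2 in after)

    def test_conservation_of_atoms(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            fw = random_framework(rng)
            d = pebble_game_decompose(fw)
            assert d.total_atoms == fw.n_bodies
            assert d.sizes == sorted(d.sizes, reverse=True)
            assert d.lcs >= d.slcs


class TestClusterHistogram:
    def test_counts_by_size(self):
        d = RigidClusterDecomposition(clusters=[
            frozenset(range(10)), frozenset(range(10, 15)),
            frozenset(range(15, 20)), frozenset({99}),
        ])
        h = cluster_histogram(d)
        assert h.counts == {10: 1, 5: 2, 1: 1}
        assert h.total_atoms == 21

    def test_single_cluster(self):
        d = RigidClusterDecomposition(clusters=[frozenset(range(7))])
        assert cluster_histogram(d).counts == {7: 1}

    def test_inconsistent_histogram_rejected(self):
        with pytest.raises(ValueError):
            ClusterSizeHistogram(counts={3: 1}, total_atoms=5)


class TestBarPolicy:
    def test_default_bar_counts(self):
        p = BarPolicy()
        assert (p.locked, p.hinge, p.hbond, p.hydrophobic) == (6, 5, 5, 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            BarPolicy(hydrophobic=0)
        with pytest.raises(ValueError):
            BarPolicy(locked=7)
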