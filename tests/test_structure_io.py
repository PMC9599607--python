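"""PDB parsing, writing, covalent-bond inference and sequence extraction."""

import numpy as np
import pytest

from indelrig.fixtures import FixtureSpec, make_polyalanine
from indelrig.structure_io import (
    Atom,
    BondClass,
    PDBFormatError,
    PDBParseError,
    Structure,
    chain_sequence,
    infer_covalent_bonds,
    read_pdb,
    write_pdb,
)


def _atom(serial, name, element, res_seq, coords, resname="ALA", alt="",
          chain="A", occ=1.0):
    return Atom(serial=serial, name=name, element=element, alt_loc=alt,
                chain_id=chain, res_seq=res_seq, i_code="",
                residue_name=resname, coords=coords, occupancy=occ)


class TestReadPdb:
    def test_polyalanine_fixture_atom_count(self, tripeptide):
        text = write_pdb(tripeptide)
        st = read_pdb(text)
        # 3 residues x (N, CA, C, O, CB) + terminal OXT
        assert st.n_atoms == 3 * 5 + 1
        assert st.chains == ["A"]

    def test_first_model_only(self, tripeptide):
        body = write_pdb(tripeptide).replace("END", "").rstrip()
        text = (
            "MODEL     1\n" + body + "\nENDMDL\n"
            "MODEL     2\n" + body + "\nENDMDL\nEND\n"
        )
        st = read_pdb(text)
        assert st.n_atoms == tripeptide.n_atoms

    def test_altloc_highest_occupancy_kept(self):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60  0.00           N\n"
            "ATOM      2  N  BALA A   1       1.000   0.000   0.000  0.40  0.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "END\n"
        )
        st = read_pdb(text)
        ns = [a for a in st.atoms if a.name == "N"]
        assert len(ns) == 1
        assert ns[0].alt_loc == "A"
        assert ns[0].coords[0] == pytest.approx(0.0)

    def test_altloc_occupancy_tie_prefers_a(self):
        text = (
            "ATOM      1  N  BALA A   1       1.000   0.000   0.000  0.50  0.00           N\n"
            "ATOM      2  N  AALA A   1       0.000   0.000   0.000  0.50  0.00           N\n"
            "END\n"
        )
        st = read_pdb(text)
        assert st.atoms[0].alt_loc == "A"

    def test_waters_excluded_by_default(self, tripeptide):
        text = write_pdb(tripeptide).replace(
            "END",
            "HETATM  999  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O\nEND",
        )
        assert read_pdb(text).n_atoms == tripeptide.n_atoms
        assert read_pdb(text, include_waters=True).n_atoms == tripeptide.n_atoms + 1

    def test_garbled_input_raises_with_line(self):
        with pytest.raises(PDBParseError, match="HELLO"):
            read_pdb("HELLO WORLD\nNOT A PDB\n")

    def test_empty_input_raises(self):
        with pytest.raises(PDBParseError):
            read_pdb("")


class TestWritePdb:
    def test_round_trip_identity(self, helix12):
        st = read_pdb(write_pdb(helix12))
        assert st.n_atoms == helix12.n_atoms
        for a, b in zip(helix12.atoms, st.atoms):
            assert (a.name, a.residue_name, a.res_seq) == (b.name, b.residue_name, b.res_seq)
            assert np.allclose(a.coords, b.coords, atol=5e-4)

    def test_empty_structure_rejected(self):
        with pytest.raises((PDBFormatError, ValueError)):
            write_pdb(Structure(atoms=[], source_id="x"))

    def test_out_of_range_coordinate_rejected(self):
        st = Structure(atoms=[_atom(1, "CA", "C", 1, (10000.0, 0.0, 0.0))])
        with pytest.raises(PDBFormatError):
            write_pdb(st)


class TestInferCovalentBonds:
    def test_dipeptide_template_and_peptide_bond(self):
        st = make_polyalanine(FixtureSpec(kind="strand", length=2))
        bonds = infer_covalent_bonds(st)
        idx = st.atom_index()
        c1 = idx[(("A", 1, ""), "C")]
        n2 = idx[(("A", 2, ""), "N")]
        assert bonds.bonds[frozenset((c1, n2))] is BondClass.LOCKED
        # per residue: N-CA, CA-C, C-O, CA-CB (4) + peptide + OXT
        assert len(bonds) == 2 * 4 + 1 + 1
        # graph connected within the chain
        adj = bonds.neighbors()
        seen, stack = set(), [0]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u])
        assert len(seen) == st.n_atoms

    def test_chain_break_gets_no_peptide_bond(self):
        st = make_polyalanine(FixtureSpec(kind="strand", length=2))
        shifted = []
        for a in st.atoms:
            x, y, z = a.coords
            if a.res_seq == 2:
                x += 30.0
            shifted.append(Atom(serial=a.serial, name=a.name, element=a.element,
                                alt_loc=a.alt_loc, chain_id=a.chain_id,
                                res_seq=a.res_seq, i_code=a.i_code,
                                residue_name=a.residue_name, coords=(x, y, z)))
        bonds = infer_covalent_bonds(st.with_atoms(shifted))
        idx = st.atom_index()
        pair = frozenset((idx[(("A", 1, ""), "C")], idx[(("A", 2, ""), "N")]))
        assert pair not in bonds.bonds

    def test_disulfide_detected_within_threshold(self):
        atoms = [
            _atom(1, "N", "N", 1, (0.0, 0.0, 0.0), "CYS"),
            _atom(2, "CA", "C", 1, (1.5, 0.0, 0.0), "CYS"),
            _atom(3, "CB", "C", 1, (2.0, 1.4, 0.0), "CYS"),
            _atom(4, "SG", "S", 1, (3.5, 1.8, 0.0), "CYS"),
            _atom(5, "N", "N", 9, (8.0, 0.0, 0.0), "CYS"),
            _atom(6, "CA", "C", 9, (6.5, 0.0, 0.0), "CYS"),
            _atom(7, "CB", "C", 9, (6.0, 1.4, 0.0), "CYS"),
            _atom(8, "SG", "S", 9, (5.5, 1.9, 0.0), "CYS"),
        ]
        bonds = infer_covalent_bonds(Structure(atoms=atoms))
        assert frozenset((3, 7)) in bonds.bonds  # SG-SG at 2.0 Å

    def test_pendant_and_ring_bonds_locked(self):
        st = make_polyalanine(FixtureSpec(kind="strand", length=3))
        bonds = infer_covalent_bonds(st)
        idx = st.atom_index()
        # C=O is pendant -> locked; N-CA is interior -> rotatable
        co = frozenset((idx[(("A", 1, ""), "C")], idx[(("A", 1, ""), "O")]))
        nca = frozenset((idx[(("A", 2, ""), "N")], idx[(("A", 2, ""), "CA")]))
        assert bonds.bonds[co] is BondClass.LOCKED
        assert bonds.bonds[nca] is BondClass.ROTATABLE


class TestChainSequence:
    def test_polyalanine_sequence(self, helix12):
        seq, keys = chain_sequence(helix12, "A")
        assert seq == "A" * 12
        assert keys[0] == ("A", 1, "")

    def test_insertion_code_ordering(self):
        atoms = [
            _atom(1, "CA", "C", 52, (0.0, 0.0, 0.0)),
            _atom(2, "CA", "C", 53, (8.0, 0.0, 0.0)),
            _atom(3, "CA", "C", 52, (4.0, 0.0, 0.0)),
        ]
        atoms[2] = Atom(serial=3, name="CA", element="C", alt_loc="",
                        chain_id="A", res_seq=52, i_code="A",
                        residue_name="GLY", coords=(4.0, 0.0, 0.0))
        seq, keys = chain_sequence(Structure(atoms=atoms), "A")
        assert keys == [("A", 52, ""), ("A", 52, "A"), ("A", 53, "")]
        assert seq == "AGA"

    def test_unknown_residue_is_x(self):
        atoms = [_atom(1, "CA", "C", 1, (0.0, 0.0, 0.0), resname="XYZ")]
        seq, _ = chain_sequence(Structure(atoms=atoms), "A")
        assert seq == "X"

    def test_missing_chain_lists_available(self, helix12):
        with pytest.raises(KeyError, match="A"):
            chain_sequence(helix12, "B")
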