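"""PDB structure reading/writing and covalent-bond inference.

The in-memory model is deliberately small: an ordered list of
:class:`Atom` records inside a :class:`Structure`, plus a :class:`BondSet`
classifying each covalent bond as a *rotatable* dihedral or a *locked*
constraint.  The atom count of a Structure is the normalization
denominator used downstream by the rigidity distance metrics, so parsing
must be deterministic: first model only, one conformer per atom.
"""

from __future__ import annotations

import enum
import logging
import math
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .templates import (
    RING_ATOMS,
    STANDARD_RESIDUES,
    THREE_TO_ONE,
    residue_bonds,
)

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)

PEPTIDE_BOND_MAX = 1.7    # Å, C(i)-N(i+1)
DISULFIDE_MAX = 2.3       # Å, SG-SG
FALLBACK_BOND_MAX = 1.9   # Å, heavy-atom distance fallback for unknown residues

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class PDBFormatError(ValueError):
    """Raised when a Structure cannot be serialized to fixed-width PDB."""


class BondClass(enum.Enum):
    ROTATABLE = "rotatable"
    LOCKED = "locked"


@dataclass(frozen=True)
class Atom:
    """One atom record; ``coords`` are Cartesian ångströms."""

    serial: int
    name: str
    element: str
    alt_loc: str
    chain_id: str
    res_seq: int
    i_code: str
    residue_name: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Structure:
    """Ordered atom list with chain bookkeeping."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.coords):
                raise ValueError(f"non-finite coordinates on atom {a.serial}")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residues(self) -> dict[ResidueKey, list[Atom]]:
        """Residues in order of first appearance -> their atoms."""
        out: dict[ResidueKey, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def atom_index(self) -> dict[tuple[ResidueKey, str], int]:
        return {(a.residue_key, a.name): i for i, a in enumerate(self.atoms)}

    def with_atoms(self, atoms: list[Atom]) -> "Structure":
        return Structure(atoms=list(atoms), source_id=self.source_id)


@dataclass
class BondSet:
    """Covalent bonds as unordered index pairs into ``structure.atoms``."""

    structure: Structure
    bonds: dict[frozenset[int], BondClass] = field(default_factory=dict)

    def add(self, i: int, j: int, cls: BondClass) -> None:
        if i == j:
            raise ValueError("self-bond")
        self.bonds[frozenset((i, j))] = cls

    def __len__(self) -> int:
        return len(self.bonds)

    def pairs(self) -> list[tuple[int, int, BondClass]]:
        out = [(min(p), max(p), c) for p, c in self.bonds.items()]
        out.sort()
        return out

    def neighbors(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.structure.n_atoms)}
        for p in self.bonds:
            i, j = tuple(p)
            adj[i].add(j)
            adj[j].add(i)
        return adj


def _looks_like_path(source: str | os.PathLike) -> bool:
    if isinstance(source, os.PathLike):
        return True
    return "\n" not in source and (os.path.exists(source) or source.endswith(".pdb"))


def read_pdb(
    source: str | os.PathLike,
    *,
    include_hetatm: bool = False,
    include_waters: bool = False,
) -> Structure:
    """Parse PDB text (or a path to it) into a :class:`Structure`.

    Only the first MODEL is read.  For alternate locations the
    highest-occupancy conformer is kept (ties broken toward conformer
    'A').  Waters and non-standard HETATM records are excluded unless the
    corresponding flag is set.
    """
    if _looks_like_path(source):
        with open(source) as fh:
            text = fh.read()
        label = os.path.splitext(os.path.basename(os.fspath(source)))[0]
    else:
        text = str(source)
        label = ""

    lines = text.splitlines()
    if not any(l.startswith(("ATOM", "HETATM")) for l in lines):
        offending = next((l for l in lines if l.strip()), "<empty input>")
        raise PDBParseError(f"no ATOM/HETATM records; first line: {offending!r}")

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise PDBParseError(str(exc)) from exc

    if len(st) == 0:
        raise PDBParseError("no models in input")
    if len(st) > 1:
        logger.info("multi-model file: reading model 1 of %d only", len(st))
    model = st[0]

    # Collect candidate atoms keyed by (residue_key, atom name), then
    # resolve alternate locations by occupancy.
    best: dict[tuple[ResidueKey, str], Atom] = {}
    order: list[tuple[ResidueKey, str]] = []
    serial = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            resname = res.name.strip()
            if het:
                if resname in _WATER_NAMES:
                    if not include_waters:
                        continue
                elif resname not in STANDARD_RESIDUES and not include_hetatm:
                    continue
            for at in res:
                serial += 1
                key: ResidueKey = (chain.name, res.seqid.num, res.seqid.icode.strip())
                atom = Atom(
                    serial=at.serial if at.serial > 0 else serial,
                    name=at.name.strip(),
                    element=at.element.name.upper(),
                    alt_loc=at.altloc.strip() if at.altloc != "\x00" else "",
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    i_code=res.seqid.icode.strip(),
                    residue_name=resname,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=at.occ,
                )
                k = (key, atom.name)
                if k not in best:
                    best[k] = atom
                    order.append(k)
                else:
                    cur = best[k]
                    if (atom.occupancy, -ord(atom.alt_loc or "Z")) > (
                        cur.occupancy, -ord(cur.alt_loc or "Z")
                    ):
                        best[k] = atom

    atoms = [best[k] for k in order]
    if not atoms:
        raise PDBParseError("no atoms retained after filtering")
    return Structure(atoms=atoms, source_id=label or st.name or "")


def write_pdb(structure: Structure) -> str:
    """Serialize to PDB v3.3 ATOM records (plus TER/END)."""
    if structure.n_atoms == 0:
        raise PDBFormatError("empty structure")
    out: list[str] = []
    prev_chain = None
    for i, a in enumerate(structure.atoms, start=1):
        if prev_chain is not None and a.chain_id != prev_chain:
            out.append("TER")
        prev_chain = a.chain_id
        x, y, z = a.coords
        for c in (x, y, z):
            if not (-999.999 <= c <= 9999.999):
                raise PDBFormatError(f"coordinate {c} outside fixed-width PDB range")
        name = a.name
        # PDB column rule: 1-char element names start in column 14.
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        out.append(
            f"ATOM  {i:5d} {name:<4s}{a.alt_loc or ' ':1s}{a.residue_name:>3s} "
            f"{a.chain_id[:1]:1s}{a.res_seq:4d}{a.i_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    out.append("END")
    return "\n".join(out) + "\n"


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.xyz - b.xyz))


def infer_covalent_bonds(structure: Structure) -> BondSet:
    """Build the covalent bond network and classify each bond.

    Intra-residue bonds come from standard-residue templates (distance
    fallback below 1.9 Å for unknown residues); peptide bonds C(i)-N(i+1)
    are added below 1.7 Å and disulfides SG-SG below 2.3 Å.  Locked
    bonds: peptide bonds, bonds inside ring systems, and bonds whose
    endpoint has no other neighbor (pendant atoms carry no rotational
    freedom of their own).  Everything else is a rotatable single bond.
    """
    bonds = BondSet(structure)
    residues = structure.residues()
    keys = list(residues)
    idx = {(a.residue_key, a.name): i for i, a in enumerate(structure.atoms)}

    peptide_pairs: set[frozenset[int]] = set()
    ring_pairs: set[frozenset[int]] = set()
    raw: set[frozenset[int]] = set()

    for key in keys:
        atoms = residues[key]
        resname = atoms[0].residue_name
        templ = residue_bonds(resname)
        names_here = {a.name for a in atoms}
        if templ:
            for n1, n2 in templ:
                if n1 in names_here and n2 in names_here:
                    raw.add(frozenset((idx[(key, n1)], idx[(key, n2)])))
            if "OXT" in names_here and "C" in names_here:
                raw.add(frozenset((idx[(key, "OXT")], idx[(key, "C")])))
            ring = RING_ATOMS.get(resname, frozenset())
            for n1, n2 in templ:
                if n1 in ring and n2 in ring and n1 in names_here and n2 in names_here:
                    ring_pairs.add(frozenset((idx[(key, n1)], idx[(key, n2)])))
        else:
            logger.warning("unknown residue %s %s: distance-fallback bonds", resname, key)
            heavy = [a for a in atoms if not a.is_hydrogen]
            for i, a in enumerate(heavy):
                for b in heavy[i + 1:]:
                    if _dist(a, b) < FALLBACK_BOND_MAX:
                        raw.add(frozenset((idx[(key, a.name)], idx[(key, b.name)])))
        # hydrogens: bond to nearest heavy atom in the residue
        for h in atoms:
            if not h.is_hydrogen:
                continue
            heavy = [a for a in atoms if not a.is_hydrogen]
            if not heavy:
                continue
            nearest = min(heavy, key=lambda a: _dist(a, h))
            if _dist(nearest, h) < 1.3:
                raw.add(frozenset((idx[(key, h.name)], idx[(key, nearest.name)])))

    # peptide bonds between consecutive residues of the same chain
    for k1, k2 in zip(keys, keys[1:]):
        if k1[0] != k2[0]:
            continue
        c = next((a for a in residues[k1] if a.name == "C"), None)
        n = next((a for a in residues[k2] if a.name == "N"), None)
        if c is not None and n is not None and _dist(c, n) < PEPTIDE_BOND_MAX:
            pair = frozenset((idx[(k1, "C")], idx[(k2, "N")]))
            raw.add(pair)
            peptide_pairs.add(pair)

    # disulfides
    sg = [i for i, a in enumerate(structure.atoms)
          if a.name == "SG" and a.residue_name == "CYS"]
    for ii, i in enumerate(sg):
        for j in sg[ii + 1:]:
            if _dist(structure.atoms[i], structure.atoms[j]) < DISULFIDE_MAX:
                raw.add(frozenset((i, j)))

    degree: dict[int, int] = {}
    for pair in raw:
        for i in pair:
            degree[i] = degree.get(i, 0) + 1

    for pair in raw:
        i, j = tuple(pair)
        if pair in peptide_pairs or pair in ring_pairs:
            cls = BondClass.LOCKED
        elif degree[i] == 1 or degree[j] == 1:
            cls = BondClass.LOCKED
        else:
            cls = BondClass.ROTATABLE
        bonds.add(i, j, cls)
    return bonds


def chain_sequence(structure: Structure, chain: str) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of a chain plus the parallel residue keys.

    Residues are ordered by (residue number, insertion code) with a blank
    insertion code sorting before 'A'.  Unknown residues map to 'X'.
    """
    if chain not in structure.chains:
        raise KeyError(
            f"chain {chain!r} not present; available: {structure.chains}"
        )
    keys = [k for k in structure.residues() if k[0] == chain]
    keys.sort(key=lambda k: (k[1], k[2]))
    residues = structure.residues()
    seq = "".join(
        THREE_TO_ONE.get(residues[k][0].residue_name, "X") for k in keys
    )
    return seq, keys
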