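"""Detection of the stabilizing interactions that brace a protein framework.

Two interaction classes contribute constraints on top of the covalent
network: hydrogen bonds, scored with the Mayo 12-10 energy function and
kept below an energy cutoff (default -1.0 kcal/mol), and hydrophobic
contacts between carbon/sulfur atoms within van-der-Waals range plus a
fudge distance (default 0.25 Å).  Both cutoffs are exposed so a run can
be matched to any external rigidity-tool configuration.

Because deposited structures usually lack hydrogens, a minimal internal
protonation step places backbone amide and side-chain polar hydrogens at
idealized geometry before donor search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import angle, place_atom, unit
from .structure_io import Atom, BondSet, Structure, infer_covalent_bonds

logger = logging.getLogger(__name__)

MAYO_V0 = 8.0      # kcal/mol well depth
MAYO_D0 = 2.8      # Å equilibrium donor-acceptor distance
DEFAULT_HBOND_CUTOFF = -1.0   # kcal/mol
DEFAULT_FUDGE = 0.25          # Å
PREFILTER_D_DA = 3.6          # Å
PREFILTER_THETA = 100.0       # degrees

VDW_RADII = {"C": 1.7, "S": 1.8}

# Donor/acceptor hybridization by (residue, atom name); backbone handled
# separately.  Hydroxyl groups are treated as sp3.
_SP3_DONOR_ATOMS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("LYS", "NZ")}
_SP3_ACCEPTOR_ATOMS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("HOH", "O")}


@dataclass(frozen=True)
class HydrogenBond:
    donor_idx: int
    hydrogen_idx: int
    acceptor_idx: int
    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    energy: float       # kcal/mol
    d_da: float         # Å donor-acceptor
    d_ha: float         # Å hydrogen-acceptor
    theta_dha: float    # degrees


@dataclass(frozen=True)
class HydrophobicContact:
    idx_a: int
    idx_b: int
    atom_a: Atom
    atom_b: Atom
    distance: float     # Å


def mayo_distance_term(d_da: float) -> float:
    """The 12-10 radial profile V0*(5(d0/d)^12 - 6(d0/d)^10); -V0 at d0."""
    if d_da <= 0:
        raise ValueError("d_DA must be positive")
    r = MAYO_D0 / d_da
    return MAYO_V0 * (5.0 * r**12 - 6.0 * r**10)


def angular_factor(
    theta_dha: float,
    phi: float | None = None,
    gamma: float = 0.0,
    donor_hyb: str = "sp2",
    acceptor_hyb: str = "sp2",
) -> float:
    """Angular modulation F in [0, 1] of the Mayo energy.

    ``theta_dha`` is the donor-H-acceptor angle (ideal 180°), ``phi`` the
    H-acceptor-base angle and ``gamma`` the out-of-plane deviation of the
    hydrogen from an sp2 acceptor plane, all in degrees.  The factor is
    cos²(dθ-type terms) damped by exp(-(π-θ)⁶), by donor/acceptor
    hybridization, and equals 1 at ideal geometry.
    """
    th = math.radians(theta_dha)
    if th <= math.pi / 2:
        return 0.0
    base = math.cos(math.pi - th) ** 2 * math.exp(-((math.pi - th) ** 6))
    if phi is None:
        return base
    ideal_phi = 109.5 if acceptor_hyb == "sp3" else 120.0
    dphi = abs(phi - ideal_phi)
    if acceptor_hyb == "sp2" and donor_hyb == "sp2":
        dev = max(dphi, abs(gamma))
    else:
        dev = dphi
    dev = min(dev, 90.0)
    return base * math.cos(math.radians(dev)) ** 2


def mayo_hbond_energy(
    d_da: float,
    theta_dha: float = 180.0,
    *,
    phi: float | None = None,
    gamma: float = 0.0,
    donor_hyb: str = "sp2",
    acceptor_hyb: str = "sp2",
    angular: float | None = None,
) -> float:
    """Hydrogen-bond energy in kcal/mol (negative = stabilizing).

    E = V0·{5(d0/d)^12 − 6(d0/d)^10}·F with V0 = 8 kcal/mol, d0 = 2.8 Å;
    F is ``angular`` if given, otherwise computed from the angles.
    """
    f = angular if angular is not None else angular_factor(
        theta_dha, phi, gamma, donor_hyb, acceptor_hyb
    )
    return mayo_distance_term(d_da) * f


def _donor_hyb(atom: Atom) -> str:
    return "sp3" if (atom.residue_name, atom.name) in _SP3_DONOR_ATOMS else "sp2"


def _acceptor_hyb(atom: Atom) -> str:
    return "sp3" if (atom.residue_name, atom.name) in _SP3_ACCEPTOR_ATOMS else "sp2"


def place_polar_hydrogens(structure: Structure) -> Structure:
    """Return a copy with idealized polar hydrogens added where missing.

    Adds backbone amide hydrogens (in the C(i-1)-N-CA plane opposite the
    bisector, N-H 1.01 Å; none at the N-terminus or proline) and
    side-chain hydrogens for N/O donors.  Existing hydrogens are kept.
    """
    bonds = infer_covalent_bonds(structure)
    adj = bonds.neighbors()
    atoms = list(structure.atoms)
    idx = structure.atom_index()
    residues = structure.residues()
    keys = list(residues)
    max_serial = max(a.serial for a in atoms)
    added: list[tuple[int, Atom]] = []  # (insert-after index, hydrogen)
    n_added = 0

    def has_h(i: int) -> bool:
        return any(atoms[j].is_hydrogen for j in adj[i])

    def mk(parent: Atom, name: str, pos: np.ndarray) -> Atom:
        nonlocal max_serial, n_added
        max_serial += 1
        n_added += 1
        return Atom(
            serial=max_serial, name=name, element="H", alt_loc="",
            chain_id=parent.chain_id, res_seq=parent.res_seq,
            i_code=parent.i_code, residue_name=parent.residue_name,
            coords=tuple(float(c) for c in pos),
        )

    for ridx, key in enumerate(keys):
        ratoms = residues[key]
        resname = ratoms[0].residue_name
        names = {a.name: a for a in ratoms}

        # backbone amide H
        if "N" in names and resname != "PRO":
            ni = idx[(key, "N")]
            prev_c = None
            if ridx > 0 and keys[ridx - 1][0] == key[0]:
                pk = keys[ridx - 1]
                pres = {a.name: a for a in residues[pk]}
                if "C" in pres and np.linalg.norm(
                    pres["C"].xyz - names["N"].xyz
                ) < 1.7:
                    prev_c = pres["C"]
            if prev_c is None:
                logger.debug("no amide H at chain start %s", key)
            elif not has_h(ni) and "CA" in names:
                n = names["N"].xyz
                h = n + 1.01 * unit(-(unit(prev_c.xyz - n) + unit(names["CA"].xyz - n)))
                added.append((idx[(key, "N")], mk(names["N"], "H", h)))

        # side-chain donors
        def present(nm: str) -> bool:
            return nm in names

        def add_if_missing(parent_nm: str, hname: str, pos: np.ndarray) -> None:
            pi = idx[(key, parent_nm)]
            if not has_h(pi):
                added.append((pi, mk(names[parent_nm], hname, pos)))

        try:
            if resname in ("SER", "THR", "TYR"):
                og = {"SER": "OG", "THR": "OG1", "TYR": "OH"}[resname]
                cb = {"SER": "CB", "THR": "CB", "TYR": "CZ"}[resname]
                ref = {"SER": "CA", "THR": "CA", "TYR": "CE1"}[resname]
                if present(og) and present(cb) and present(ref):
                    h = place_atom(names[ref].xyz, names[cb].xyz, names[og].xyz,
                                   0.96, 109.5, 180.0)
                    add_if_missing(og, "H" + og[1:], h)
            elif resname == "LYS" and present("NZ") and present("CE") and present("CD"):
                pi = idx[(key, "NZ")]
                if not has_h(pi):
                    for t, hn in ((60.0, "HZ1"), (180.0, "HZ2"), (300.0, "HZ3")):
                        h = place_atom(names["CD"].xyz, names["CE"].xyz,
                                       names["NZ"].xyz, 1.01, 109.5, t)
                        added.append((pi, mk(names["NZ"], hn, h)))
            elif resname == "ARG":
                if present("NE") and present("CZ") and present("CD"):
                    ne = names["NE"].xyz
                    h = ne + 1.01 * unit(-(unit(names["CD"].xyz - ne)
                                          + unit(names["CZ"].xyz - ne)))
                    add_if_missing("NE", "HE", h)
                for nh, hs in (("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))):
                    if present(nh) and present("CZ") and present("NE"):
                        pi = idx[(key, nh)]
                        if not has_h(pi):
                            for t, hn in zip((0.0, 180.0), hs):
                                h = place_atom(names["NE"].xyz, names["CZ"].xyz,
                                               names[nh].xyz, 1.01, 120.0, t)
                                added.append((pi, mk(names[nh], hn, h)))
            elif resname in ("ASN", "GLN"):
                nd = "ND2" if resname == "ASN" else "NE2"
                cg = "CG" if resname == "ASN" else "CD"
                od = "OD1" if resname == "ASN" else "OE1"
                if present(nd) and present(cg) and present(od):
                    pi = idx[(key, nd)]
                    if not has_h(pi):
                        for t, hn in zip((0.0, 180.0), ("HD21", "HD22")
                                         if resname == "ASN" else ("HE21", "HE22")):
                            h = place_atom(names[od].xyz, names[cg].xyz,
                                           names[nd].xyz, 1.01, 120.0, t)
                            added.append((pi, mk(names[nd], hn, h)))
            elif resname == "TRP" and all(present(x) for x in ("NE1", "CD1", "CE2")):
                ne = names["NE1"].xyz
                h = ne + 1.01 * unit(-(unit(names["CD1"].xyz - ne)
                                      + unit(names["CE2"].xyz - ne)))
                add_if_missing("NE1", "HE1", h)
            elif resname == "HIS" and all(present(x) for x in ("NE2", "CE1", "CD2")):
                # NE2-protonated tautomer by default; ND1 stays an acceptor
                ne = names["NE2"].xyz
                h = ne + 1.01 * unit(-(unit(names["CE1"].xyz - ne)
                                      + unit(names["CD2"].xyz - ne)))
                add_if_missing("NE2", "HE2", h)
        except ValueError:
            logger.warning("degenerate geometry; skipped protonation in %s %s",
                           resname, key)

    if not added:
        return structure.with_atoms(atoms)
    logger.info("placed %d polar hydrogens", n_added)
    out: list[Atom] = []
    by_parent: dict[int, list[Atom]] = {}
    for pi, h in added:
        by_parent.setdefault(pi, []).append(h)
    for i, a in enumerate(atoms):
        out.append(a)
        out.extend(by_parent.get(i, ()))
    return structure.with_atoms(out)


def _excluded(adj: dict[int, set[int]], i: int, j: int) -> bool:
    """True for 1-2 and 1-3 covalent neighbors."""
    if j in adj[i]:
        return True
    return bool(adj[i] & adj[j])


def detect_hydrogen_bonds(
    structure: Structure,
    energy_cutoff: float = DEFAULT_HBOND_CUTOFF,
    *,
    bonds: BondSet | None = None,
) -> list[HydrogenBond]:
    """Mayo-scored hydrogen bonds with energy ≤ ``energy_cutoff``.

    Donors are N/O atoms carrying a hydrogen; acceptors are O atoms and
    bare sp2 nitrogens.  Candidates are prefiltered by d_DA ≤ 3.6 Å and
    θ(D-H-A) ≥ 100°; the best hydrogen is used per donor-acceptor pair.
    Salt bridges qualify through the same rule.  Sorted by (donor serial,
    acceptor serial).
    """
    if bonds is None:
        bonds = infer_covalent_bonds(structure)
    adj = bonds.neighbors()
    atoms = structure.atoms

    donors: list[int] = []
    skipped_unprotonated = 0
    for i, a in enumerate(atoms):
        if a.element not in ("N", "O"):
            continue
        hs = [j for j in adj[i] if atoms[j].is_hydrogen]
        heavy = [j for j in adj[i] if not atoms[j].is_hydrogen]
        if hs:
            donors.append(i)
        elif a.element == "N" and len(heavy) < 3 and a.residue_name != "PRO":
            skipped_unprotonated += 1
    if skipped_unprotonated:
        # the N-terminal amide is deliberately left bare, so one skip per
        # chain is expected
        logger.info("%d potential N donors lack hydrogens; skipped",
                    skipped_unprotonated)

    acceptors = []
    for i, a in enumerate(atoms):
        if a.is_hydrogen:
            continue
        hs = [j for j in adj[i] if atoms[j].is_hydrogen]
        heavy = [j for j in adj[i] if not atoms[j].is_hydrogen]
        if a.element == "O" and len(hs) + len(heavy) <= 2:
            acceptors.append(i)
        elif a.element == "N" and not hs and len(heavy) <= 2:
            acceptors.append(i)
    if not donors or not acceptors:
        return []

    d_xyz = np.array([atoms[i].coords for i in donors])
    a_xyz = np.array([atoms[i].coords for i in acceptors])
    pairs = cKDTree(d_xyz).query_ball_tree(cKDTree(a_xyz), r=PREFILTER_D_DA)

    found: list[HydrogenBond] = []
    for di, alist in zip(donors, pairs):
        d_atom = atoms[di]
        for aj in alist:
            ai = acceptors[aj]
            if ai == di or _excluded(adj, di, ai):
                continue
            a_atom = atoms[ai]
            d_da = float(np.linalg.norm(d_atom.xyz - a_atom.xyz))
            if d_da < 0.5:
                continue
            base_heavy = sorted(j for j in adj[ai] if not atoms[j].is_hydrogen)
            best: HydrogenBond | None = None
            for hj in sorted(j for j in adj[di] if atoms[j].is_hydrogen):
                h_atom = atoms[hj]
                theta = angle(d_atom.xyz, h_atom.xyz, a_atom.xyz)
                if theta < PREFILTER_THETA:
                    continue
                phi = gamma = None
                if base_heavy:
                    b_atom = atoms[base_heavy[0]]
                    phi = angle(h_atom.xyz, a_atom.xyz, b_atom.xyz)
                    others = [j for j in adj[base_heavy[0]]
                              if j != ai and not atoms[j].is_hydrogen]
                    if others:
                        n = np.cross(a_atom.xyz - b_atom.xyz,
                                     atoms[others[0]].xyz - b_atom.xyz)
                        if np.linalg.norm(n) > 1e-9:
                            ah = h_atom.xyz - a_atom.xyz
                            s = np.dot(unit(n), unit(ah))
                            gamma = abs(math.degrees(math.asin(
                                np.clip(s, -1.0, 1.0))))
                e = mayo_hbond_energy(
                    d_da, theta, phi=phi, gamma=gamma or 0.0,
                    donor_hyb=_donor_hyb(d_atom),
                    acceptor_hyb=_acceptor_hyb(a_atom),
                )
                if e <= energy_cutoff and (best is None or e < best.energy):
                    best = HydrogenBond(
                        donor_idx=di, hydrogen_idx=hj, acceptor_idx=ai,
                        donor=d_atom, hydrogen=h_atom, acceptor=a_atom,
                        energy=e, d_da=d_da,
                        d_ha=float(np.linalg.norm(h_atom.xyz - a_atom.xyz)),
                        theta_dha=theta,
                    )
            if best is not None:
                found.append(best)
    found.sort(key=lambda hb: (hb.donor.serial, hb.acceptor.serial))
    return found


def detect_hydrophobic_contacts(
    structure: Structure,
    fudge: float = DEFAULT_FUDGE,
    *,
    bonds: BondSet | None = None,
) -> list[HydrophobicContact]:
    """Carbon/sulfur contact pairs within vdW range plus ``fudge`` Å.

    Pairs must come from different residues and not be covalent 1-2/1-3
    neighbors.  Ordering is deterministic by atom serial.
    """
    if bonds is None:
        bonds = infer_covalent_bonds(structure)
    adj = bonds.neighbors()
    atoms = structure.atoms
    cs = [i for i, a in enumerate(atoms) if a.element in VDW_RADII]
    if not cs:
        return []
    xyz = np.array([atoms[i].coords for i in cs])
    rmax = 2 * max(VDW_RADII.values()) + fudge
    tree = cKDTree(xyz)
    out: list[HydrophobicContact] = []
    for ii, jj in sorted(tree.query_pairs(r=rmax)):
        i, j = cs[ii], cs[jj]
        a, b = atoms[i], atoms[j]
        if a.residue_key == b.residue_key:
            continue
        if _excluded(adj, i, j):
            continue
        d = float(np.linalg.norm(a.xyz - b.xyz))
        if d <= VDW_RADII[a.element] + VDW_RADII[b.element] + fudge:
            i1, i2 = (i, j) if a.serial <= b.serial else (j, i)
            out.append(HydrophobicContact(
                idx_a=i1, idx_b=i2,
                atom_a=atoms[i1], atom_b=atoms[i2],
                distance=d,
            ))
    out.sort(key=lambda c: (c.atom_a.serial, c.atom_b.serial))
    return out
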