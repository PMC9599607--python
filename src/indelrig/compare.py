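"""Wildtype/mutant superposition and InDel-aware RMSD.

Sequences that differ by an insertion or deletion cannot be compared
atom-by-atom in file order, so residues are first paired by global
sequence alignment; the alignment's gap columns are the InDel sites.
All-atom RMSD is then computed over matched residues after an optimal
Kabsch superposition, and a local RMSD restricted to a residue window
around the InDel reports how much the modeled region itself moved,
measured in the globally superposed frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .structure_io import ResidueKey, Structure, chain_sequence

logger = logging.getLogger(__name__)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -5.0, -0.5
DEFAULT_WINDOW = 5  # residues on each side of an InDel site


@dataclass
class ResidueCorrespondence:
    """One-to-one, order-preserving residue pairing between two structures."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    gaps_a: list[ResidueKey] = field(default_factory=list)
    gaps_b: list[ResidueKey] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


def align_residues(a: Structure, b: Structure) -> ResidueCorrespondence:
    """Pair residues of two structures by global sequence alignment.

    Chains sharing an id are aligned together; otherwise chains are
    paired in order of appearance.  Gap columns give the unmatched
    (inserted/deleted) residues of either structure.
    """
    chains_a, chains_b = a.chains, b.chains
    if not chains_a or not chains_b:
        raise ValueError("structure without chains")
    shared = [c for c in chains_a if c in chains_b]
    if shared:
        chain_pairs = [(c, c) for c in shared]
    else:
        chain_pairs = list(zip(chains_a, chains_b))

    al = _aligner()
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    gaps_a: list[ResidueKey] = []
    gaps_b: list[ResidueKey] = []
    for ca, cb in chain_pairs:
        seq_a, keys_a = chain_sequence(a, ca)
        seq_b, keys_b = chain_sequence(b, cb)
        aln = al.align(seq_a, seq_b)[0]
        blocks_a, blocks_b = aln.aligned
        matched_a: set[int] = set()
        matched_b: set[int] = set()
        for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
            for off in range(ea - sa):
                ia, ib = sa + off, sb + off
                pairs.append((keys_a[ia], keys_b[ib]))
                matched_a.add(ia)
                matched_b.add(ib)
        gaps_a.extend(keys_a[i] for i in range(len(keys_a)) if i not in matched_a)
        gaps_b.extend(keys_b[i] for i in range(len(keys_b)) if i not in matched_b)
    if not pairs:
        raise ValueError("no alignable residues between structures")
    return ResidueCorrespondence(pairs=pairs, gaps_a=gaps_a, gaps_b=gaps_b)


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of B onto A.

    Returns (rotation R, translation t, rmsd) minimizing
    ||A − (B·Rᵀ + t)||; R is a proper rotation (det +1).
    """
    pa = np.asarray(coords_a, dtype=float)
    pb = np.asarray(coords_b, dtype=float)
    if pa.shape != pb.shape or pa.ndim != 2 or pa.shape[1] != 3:
        raise ValueError("coordinate arrays must both be n×3")
    n = pa.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    qa, qb = pa - ca, pb - cb
    h = qb.T @ qa
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    moved = qb @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((qa - moved) ** 2, axis=1))))
    return rot, t, rmsd


def _matched_coords(
    a: Structure,
    b: Structure,
    pairs: list[tuple[ResidueKey, ResidueKey]],
    include_hydrogens: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    res_a, res_b = a.residues(), b.residues()
    xa, xb, skipped = [], [], 0
    for ka, kb in pairs:
        atoms_a = {at.name: at for at in res_a[ka]
                   if include_hydrogens or not at.is_hydrogen}
        atoms_b = {at.name: at for at in res_b[kb]
                   if include_hydrogens or not at.is_hydrogen}
        common = sorted(set(atoms_a) & set(atoms_b))
        skipped += len(set(atoms_a) ^ set(atoms_b))
        for name in common:
            xa.append(atoms_a[name].coords)
            xb.append(atoms_b[name].coords)
    if skipped:
        logger.debug("%d atoms without a name match skipped", skipped)
    return np.array(xa, dtype=float), np.array(xb, dtype=float), skipped


def global_rmsd(
    a: Structure,
    b: Structure,
    corr: ResidueCorrespondence | None = None,
    *,
    include_hydrogens: bool = False,
) -> float:
    """All-atom RMSD (Å) over matched residues after Kabsch superposition."""
    if corr is None:
        corr = align_residues(a, b)
    xa, xb, _ = _matched_coords(a, b, corr.pairs, include_hydrogens)
    if len(xa) < 3:
        raise ValueError("fewer than 3 matched atoms")
    _, _, rmsd = kabsch_superpose(xa, xb)
    return rmsd


def local_rmsd(
    a: Structure,
    b: Structure,
    corr: ResidueCorrespondence | None = None,
    window: int = DEFAULT_WINDOW,
    residue_range: tuple[ResidueKey, ResidueKey] | None = None,
    *,
    local_fit: bool = False,
    include_hydrogens: bool = False,
) -> float:
    """RMSD (Å) restricted to residues near the InDel site.

    The site is taken from the correspondence gaps (or an explicit
    inclusive ``residue_range`` on structure A); matched residues within
    ``window`` positions of a gap enter the local set.  By default
    deviations are measured in the frame of the *global* superposition,
    so the value reflects how far the local region moved relative to the
    rest of the protein; ``local_fit`` re-superposes on the local set.
    """
    if corr is None:
        corr = align_residues(a, b)

    order_a: dict[ResidueKey, int] = {}
    for chain in a.chains:
        _, keys = chain_sequence(a, chain)
        for i, k in enumerate(keys):
            order_a[k] = i
    order_b: dict[ResidueKey, int] = {}
    for chain in b.chains:
        _, keys = chain_sequence(b, chain)
        for i, k in enumerate(keys):
            order_b[k] = i

    local_pairs: list[tuple[ResidueKey, ResidueKey]] = []
    if residue_range is not None:
        lo, hi = residue_range
        for ka, kb in corr.pairs:
            if ka[0] == lo[0] and (lo[1], lo[2]) <= (ka[1], ka[2]) <= (hi[1], hi[2]):
                local_pairs.append((ka, kb))
    else:
        if not corr.gaps_a and not corr.gaps_b:
            raise ValueError("no InDel site in correspondence and no explicit range")
        site_a = [order_a[k] for k in corr.gaps_a if k in order_a]
        site_b = [order_b[k] for k in corr.gaps_b if k in order_b]
        for ka, kb in corr.pairs:
            near_a = any(abs(order_a[ka] - s) <= window for s in site_a)
            near_b = any(abs(order_b[kb] - s) <= window for s in site_b)
            if near_a or near_b:
                local_pairs.append((ka, kb))
    if not local_pairs:
        raise ValueError("no matched residues in the local window")

    xa_all, xb_all, _ = _matched_coords(a, b, corr.pairs, include_hydrogens)
    if len(xa_all) < 3:
        raise ValueError("fewer than 3 matched atoms")
    xa_loc, xb_loc, _ = _matched_coords(a, b, local_pairs, include_hydrogens)
    if len(xa_loc) == 0:
        raise ValueError("no atoms in the local window")
    if local_fit:
        if len(xa_loc) < 3:
            raise ValueError("fewer than 3 local atoms for local fit")
        _, _, rmsd = kabsch_superpose(xa_loc, xb_loc)
        return rmsd
    rot, t, _ = kabsch_superpose(xa_all, xb_all)
    moved = xb_loc @ rot.T + t
    return float(np.sqrt(np.mean(np.sum((xa_loc - moved) ** 2, axis=1))))


def atom_serial_map(
    a: Structure, b: Structure, corr: ResidueCorrespondence
) -> dict[int, int]:
    """Map atom serials of B onto A across matched residues (by atom name)."""
    res_a, res_b = a.residues(), b.residues()
    out: dict[int, int] = {}
    for ka, kb in corr.pairs:
        names_a = {at.name: at.serial for at in res_a[ka]}
        for at in res_b[kb]:
            if at.name in names_a:
                out[at.serial] = names_a[at.name]
    return out
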