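"""Synthetic inputs for testing the pipeline without any downloads.

Provides ideal-geometry toy peptides (helix/strand/coil polyalanine),
Gaussian coordinate perturbation (a stand-in for the small structural
drift of a few energy-minimization steps), planted residue deletions,
random cluster-size histogram pairs, and a brute-force rigidity-matrix
oracle that independently decides generic body-bar rigidity for small
frameworks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import place_atom
from .rigidity import (
    BodyBarFramework,
    ClusterSizeHistogram,
    RigidClusterDecomposition,
)
from .structure_io import Atom, ResidueKey, Structure

# Ideal backbone internal coordinates (Å, degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
_D_C_N_CA_CB = -122.6   # improper fixing CB off the backbone plane

PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-119.0, 113.0)}


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "helix"          # helix | strand | coil
    length: int = 12             # residues
    seed: int = 0
    noise_sigma: float = 0.0     # Å

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be ≥ 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.kind not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown kind {self.kind!r}")


def make_polyalanine(spec: FixtureSpec) -> Structure:
    """Ideal-geometry polyalanine chain (N, CA, C, O, CB per residue + OXT).

    Helix uses φ = −57°, ψ = −47°; strand φ = −119°, ψ = 113°; coil
    draws per-residue torsions from broad allowed ranges using the
    spec's seed.  Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    if spec.kind == "coil":
        phis = rng.uniform(-150.0, -60.0, size=n)
        psis = rng.uniform(-70.0, 160.0, size=n)
    else:
        phi, psi = PHI_PSI[spec.kind]
        phis = np.full(n, phi)
        psis = np.full(n, psi)

    # first residue backbone in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])
    c0 = place_atom(dummy, n0, ca0, _B_CA_C, _A_N_CA_C, 150.0)

    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(n0, ca0, c0)]
    for i in range(1, n):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psis[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phis[i])
        backbone.append((n_i, ca_i, c_i))

    atoms: list[Atom] = []
    serial = 0

    def add(name: str, element: str, res: int, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(Atom(
            serial=serial, name=name, element=element, alt_loc="",
            chain_id="A", res_seq=res, i_code="", residue_name="ALA",
            coords=(float(pos[0]), float(pos[1]), float(pos[2])),
        ))

    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        res = i + 1
        o_i = place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psis[i] + 180.0)
        cb_i = place_atom(c_i, n_i, ca_i, _B_CA_CB, _A_N_CA_CB, _D_C_N_CA_CB)
        add("N", "N", res, n_i)
        add("CA", "C", res, ca_i)
        add("C", "C", res, c_i)
        add("O", "O", res, o_i)
        add("CB", "C", res, cb_i)
        if i == n - 1:
            oxt = place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psis[i])
            add("OXT", "O", res, oxt)

    st = Structure(atoms=atoms, source_id=f"poly-ALA-{spec.kind}-{n}")
    if spec.noise_sigma > 0:
        st = perturb_structure(st, spec.noise_sigma, spec.seed)
    return st


_HETERO_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
)  # no GLY (would orphan the CB) and no PRO (changes amide chemistry)


def make_heteropeptide(length: int, seed: int, kind: str = "helix") -> Structure:
    """Polyalanine-geometry backbone with a random residue labeling.

    Residue names are drawn uniformly without adjacent repeats, giving a
    sequence on which InDel sites are identifiable by alignment (a
    homopolymer has no unique gap placement).  Only backbone + CB atoms
    are present, so the labels affect sequence identity, not geometry.
    """
    st = make_polyalanine(FixtureSpec(kind=kind, length=length, seed=seed))
    rng = np.random.default_rng(seed)
    names: list[str] = []
    for _ in range(length):
        while True:
            pick = _HETERO_RESIDUES[int(rng.integers(len(_HETERO_RESIDUES)))]
            if not names or pick != names[-1]:
                names.append(pick)
                break
    new_atoms = []
    for a in st.atoms:
        new_atoms.append(Atom(
            serial=a.serial, name=a.name, element=a.element, alt_loc=a.alt_loc,
            chain_id=a.chain_id, res_seq=a.res_seq, i_code=a.i_code,
            residue_name=names[a.res_seq - 1], coords=a.coords,
            occupancy=a.occupancy,
        ))
    return Structure(atoms=new_atoms, source_id=f"hetero-{kind}-{length}")


def unambiguous_deletion_sites(
    structure: Structure, k: int, rng: np.random.Generator
) -> list[ResidueKey]:
    """Pick a random contiguous k-residue deletion with identifiable gaps.

    A deletion block whose flanking residues repeat the block's boundary
    letters admits more than one optimal alignment, so no planted-truth
    recovery is possible even in principle; such positions are rejected.
    """
    chain = structure.chains[0]
    keys = [key for key in structure.residues() if key[0] == chain]
    seq = [structure.residues()[key][0].residue_name for key in keys]
    n = len(keys)
    candidates = []
    for i in range(1, n - k):  # keep at least one flanking residue each side
        left_ok = seq[i - 1] != seq[i + k - 1]
        right_ok = (i + k >= n) or (seq[i] != seq[i + k])
        if left_ok and right_ok:
            candidates.append(i)
    if not candidates:
        raise ValueError("no unambiguous deletion site in this sequence")
    i = int(rng.choice(candidates))
    return keys[i: i + k]


def perturb_structure(structure: Structure, sigma: float, seed: int) -> Structure:
    """Add i.i.d. Gaussian noise (std ``sigma`` Å) to every coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    if sigma == 0:
        return structure.with_atoms(list(structure.atoms))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(structure.n_atoms, 3))
    new_atoms = []
    for a, d in zip(structure.atoms, noise):
        x, y, z = a.coords
        new_atoms.append(Atom(
            serial=a.serial, name=a.name, element=a.element, alt_loc=a.alt_loc,
            chain_id=a.chain_id, res_seq=a.res_seq, i_code=a.i_code,
            residue_name=a.residue_name,
            coords=(x + d[0], y + d[1], z + d[2]),
            occupancy=a.occupancy,
        ))
    return structure.with_atoms(new_atoms)


def delete_residues(structure: Structure, keys) -> Structure:
    """Remove whole residues; remaining numbering is left untouched."""
    keys = {tuple(k) for k in keys}
    present = set(structure.residues())
    unknown = keys - present
    if unknown:
        raise KeyError(f"residues not in structure: {sorted(unknown)}")
    kept = [a for a in structure.atoms if a.residue_key not in keys]
    return structure.with_atoms(kept)


def random_histogram_pair(
    seed: int, n_atoms: int, divergence: float
) -> tuple[ClusterSizeHistogram, ClusterSizeHistogram]:
    """A wildtype-like histogram and a variant at controlled divergence.

    Both histograms sum to ``n_atoms`` atoms.  ``divergence`` = 0 yields
    an identical pair; larger values apply proportionally more random
    split/merge moves to the variant's cluster list.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be ≥ 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    rem = n_atoms
    while rem > 0:
        s = min(rem, int(rng.geometric(0.08)))
        sizes.append(s)
        rem -= s

    mut = list(sizes)
    n_ops = int(round(divergence * max(1, len(sizes))))
    for _ in range(n_ops):
        if len(mut) > 1 and (len([s for s in mut if s > 1]) == 0 or rng.random() < 0.5):
            i, j = rng.choice(len(mut), size=2, replace=False)
            merged = mut[i] + mut[j]
            mut = [s for k, s in enumerate(mut) if k not in (i, j)] + [merged]
        else:
            splittable = [k for k, s in enumerate(mut) if s > 1]
            if not splittable:
                continue
            k = int(rng.choice(splittable))
            cut = int(rng.integers(1, mut[k]))
            mut = mut[:k] + mut[k + 1:] + [cut, mut[k] - cut]

    def to_hist(ss: list[int]) -> ClusterSizeHistogram:
        counts: dict[int, int] = {}
        for s in ss:
            counts[s] = counts.get(s, 0) + 1
        return ClusterSizeHistogram(counts=counts, total_atoms=n_atoms)

    return to_hist(sizes), to_hist(mut)


def _motion_space(framework: BodyBarFramework, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal basis of infinitesimal motions at a random placement.

    Each body b gets 6 motion coordinates (ω_b, v_b).  A bar between
    attachment points p, q on bodies u, v with direction d = (p−q)/|p−q|
    imposes (v_u + ω_u×p − v_v − ω_v×q)·d = 0, giving the row
    [p×d, d] at body u and −[q×d, d] at body v.
    """
    n = framework.n_bodies
    centers = rng.uniform(-5.0, 5.0, size=(n, 3))
    rows = []
    for u, v, bars, _origin in framework.capped_edges():
        for _ in range(bars):
            p = centers[u] + rng.uniform(-1.0, 1.0, size=3)
            q = centers[v] + rng.uniform(-1.0, 1.0, size=3)
            d = p - q
            nrm = np.linalg.norm(d)
            if nrm < 1e-9:
                d = rng.normal(size=3)
                nrm = np.linalg.norm(d)
            d = d / nrm
            row = np.zeros(6 * n)
            row[6 * u: 6 * u + 3] = np.cross(p, d)
            row[6 * u + 3: 6 * u + 6] = d
            row[6 * v: 6 * v + 3] -= np.cross(q, d)
            row[6 * v + 3: 6 * v + 6] -= d
            rows.append(row)
    if not rows:
        return np.eye(6 * n)
    r = np.array(rows)
    _u, s, vt = np.linalg.svd(r)
    tol = max(r.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
    tol = max(tol, 1e-8)
    null_mask = np.zeros(vt.shape[0], dtype=bool)
    null_mask[:len(s)] = s <= tol
    null_mask[len(s):] = True
    return vt[null_mask].T  # columns = kernel basis


def rigidity_matrix_oracle(
    framework: BodyBarFramework, seed: int = 0
) -> RigidClusterDecomposition:
    """Brute-force generic-rigidity decomposition for ≤ 12 bodies.

    Builds the body-bar rigidity matrix at two independent random
    placements; bodies u, v are mutually rigid iff every kernel motion
    assigns them the same rigid-body velocity (checked at both
    placements, guarding against non-generic accidents).
    """
    n = framework.n_bodies
    if n == 0:
        raise ValueError("empty framework")
    if n > 12:
        raise ValueError(f"oracle limited to 12 bodies, got {n}")
    rng = np.random.default_rng(seed)
    kernels = [_motion_space(framework, rng) for _ in range(2)]

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n):
        for v in range(u + 1, n):
            rigid = True
            for kern in kernels:
                diff = kern[6 * u: 6 * u + 6, :] - kern[6 * v: 6 * v + 6, :]
                if kern.shape[1] and np.abs(diff).max() > 1e-6:
                    rigid = False
                    break
            if rigid:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[rv] = ru

    groups: dict[int, set[int]] = {}
    for b in range(n):
        groups.setdefault(find(b), set()).add(b)
    clusters = []
    for members in groups.values():
        atoms: set[int] = set()
        for b in members:
            atoms.update(framework.bodies[b])
        clusters.append(frozenset(atoms))
    return RigidClusterDecomposition(clusters=clusters)
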