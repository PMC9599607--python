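"""Body-bar-hinge framework construction and (6,6) pebble-game rigidity.

The mechanical model treats every atom as a rigid body carrying 6
degrees of freedom.  Covalent bonds, hydrogen bonds and hydrophobic
contacts become multi-bar edges: a locked covalent bond contributes 6
bars (no relative motion), a rotatable bond is a hinge (5 bars, one
residual dihedral), a hydrogen bond 5 bars and a hydrophobic contact 2
bars.  Generic rigidity of such body-bar multigraphs is exactly
characterized by (6,6)-sparsity counts (every edge subset E' on bodies
V' has |E'| ≤ 6|V'| − 6), which the pebble game decides greedily: each
body starts with 6 pebbles (its free DOF) and a bar is independent iff
7 pebbles can be gathered on its endpoints.  After all bars are played,
two bodies are mutually rigid iff a hypothetical extra bar between them
would be redundant; maximal rigid clusters are the equivalence classes
of that relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .interactions import HydrogenBond, HydrophobicContact
from .structure_io import BondClass, BondSet, Structure

logger = logging.getLogger(__name__)

K = 6   # pebbles per body
L = 6   # pebbles that must remain on any spanning subgraph


@dataclass(frozen=True)
class BarPolicy:
    """Bars contributed per constraint type (each bar removes one DOF)."""

    locked: int = 6
    hinge: int = 5
    hbond: int = 5
    hydrophobic: int = 2

    def __post_init__(self) -> None:
        for name in ("locked", "hinge", "hbond", "hydrophobic"):
            v = getattr(self, name)
            if not 1 <= v <= 6:
                raise ValueError(f"bars for {name} must be in 1..6, got {v}")


@dataclass
class BodyBarFramework:
    """Multigraph of rigid bodies joined by bar-weighted edges.

    ``bodies[i]`` is the tuple of atom serials the body carries; edges
    are (u, v, bars, origin) with u < v body indices and 1 ≤ bars ≤ 6
    after capping parallel constraints.
    """

    bodies: list[tuple[int, ...]]
    edges: list[tuple[int, int, int, str]] = field(default_factory=list)

    @property
    def n_bodies(self) -> int:
        return len(self.bodies)

    def add_bars(self, u: int, v: int, bars: int, origin: str) -> None:
        if u == v:
            raise ValueError("self-edge")
        if not 1 <= bars <= 6:
            raise ValueError("bars must be in 1..6")
        u, v = min(u, v), max(u, v)
        self.edges.append((u, v, bars, origin))

    def capped_edges(self) -> list[tuple[int, int, int, str]]:
        """Edges with parallel bars between the same pair capped at 6."""
        total: dict[tuple[int, int], int] = {}
        out: list[tuple[int, int, int, str]] = []
        for u, v, bars, origin in self.edges:
            have = total.get((u, v), 0)
            room = 6 - have
            if room <= 0:
                logger.debug("dropping redundant bars %s-%s (%s): pair at cap",
                             u, v, origin)
                continue
            use = min(bars, room)
            if use < bars:
                logger.debug("capping %s-%s (%s) from %d to %d bars",
                             u, v, origin, bars, use)
            total[(u, v)] = have + use
            out.append((u, v, use, origin))
        return out


@dataclass
class RigidClusterDecomposition:
    """Partition of atoms into maximal rigid clusters."""

    clusters: list[frozenset[int]]   # atom serials per cluster

    def __post_init__(self) -> None:
        self.clusters = sorted(
            (frozenset(c) for c in self.clusters),
            key=lambda c: (-len(c), min(c)),
        )

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def total_atoms(self) -> int:
        return sum(self.sizes)

    @property
    def lcs(self) -> int:
        """Largest rigid cluster size (atoms)."""
        return self.sizes[0] if self.clusters else 0

    @property
    def slcs(self) -> int:
        """Second-largest rigid cluster size (0 if none)."""
        return self.sizes[1] if len(self.clusters) > 1 else 0

    @property
    def largest(self) -> frozenset[int]:
        return self.clusters[0]

    @property
    def second_largest(self) -> frozenset[int]:
        return self.clusters[1] if len(self.clusters) > 1 else frozenset()


@dataclass
class ClusterSizeHistogram:
    """Cluster-size spectrum: size (atoms) -> number of clusters."""

    counts: dict[int, int]
    total_atoms: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")
        if sum(i * c for i, c in self.counts.items()) != self.total_atoms:
            raise ValueError("histogram does not sum to total_atoms")

    def get(self, size: int) -> int:
        return self.counts.get(size, 0)

    @property
    def max_size(self) -> int:
        return max((i for i, c in self.counts.items() if c > 0), default=0)


def build_framework(
    structure: Structure,
    bonds: BondSet,
    hbonds: list[HydrogenBond] = (),
    contacts: list[HydrophobicContact] = (),
    policy: BarPolicy = BarPolicy(),
) -> BodyBarFramework:
    """Assemble the body-bar-hinge framework for a structure.

    Each atom is its own body.  Hydrogen bonds contribute bars between
    the hydrogen and the acceptor (the donor-hydrogen bond is already a
    locked covalent edge), hydrophobic contacts between the two heavy
    atoms.
    """
    n = structure.n_atoms
    fw = BodyBarFramework(bodies=[(a.serial,) for a in structure.atoms])
    for i, j, cls in bonds.pairs():
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bond references unknown atom index {i},{j}")
        bars = policy.locked if cls is BondClass.LOCKED else policy.hinge
        origin = "covalent-locked" if cls is BondClass.LOCKED else "covalent-hinge"
        fw.add_bars(i, j, bars, origin)
    for hb in hbonds:
        for idx in (hb.hydrogen_idx, hb.acceptor_idx):
            if not 0 <= idx < n:
                raise ValueError(f"hydrogen bond references unknown atom index {idx}")
        fw.add_bars(hb.hydrogen_idx, hb.acceptor_idx, policy.hbond, "hbond")
    for hc in contacts:
        for idx in (hc.idx_a, hc.idx_b):
            if not 0 <= idx < n:
                raise ValueError(f"contact references unknown atom index {idx}")
        fw.add_bars(hc.idx_a, hc.idx_b, policy.hydrophobic, "hydrophobic")
    return fw


class _PebbleGame:
    """(6,6) pebble game state on a body multigraph.

    ``out[u]`` maps v -> number of accepted bars currently oriented
    u → v; ``pebbles[u]`` is the number of free pebbles on u.
    """

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [K] * n
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]

    def _find_pebble(self, roots: tuple[int, ...]) -> bool:
        """Move one free pebble onto roots[0] by path reversal.

        DFS over oriented bars from roots[0]; vertices in ``roots`` may
        not donate their own pebbles.
        """
        root = roots[0]
        seen = [False] * self.n
        for r in roots:
            seen[r] = True
        parent: dict[int, int] = {}
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.out[u]:
                if seen[v]:
                    continue
                seen[v] = True
                parent[v] = u
                if self.pebbles[v] > 0:
                    # reverse the path root -> ... -> v
                    self.pebbles[v] -= 1
                    self.pebbles[root] += 1
                    while v != root:
                        u2 = parent[v]
                        self.out[u2][v] -= 1
                        if self.out[u2][v] == 0:
                            del self.out[u2][v]
                        self.out[v][u2] = self.out[v].get(u2, 0) + 1
                        v = u2
                    return True
                stack.append(v)
        return False

    def gather(self, u: int, v: int, target: int) -> int:
        """Gather up to ``target`` free pebbles onto {u, v}; return count."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if self.pebbles[u] < K and self._find_pebble((u, v)):
                continue
            if self.pebbles[v] < K and self._find_pebble((v, u)):
                continue
            break
        return self.pebbles[u] + self.pebbles[v]

    def try_insert_bar(self, u: int, v: int) -> bool:
        """Insert one bar u-v if independent; return acceptance."""
        if self.gather(u, v, L + 1) >= L + 1:
            if self.pebbles[u] == 0:
                u, v = v, u
            self.pebbles[u] -= 1
            self.out[u][v] = self.out[u].get(v, 0) + 1
            return True
        return False

    def mutually_rigid(self, u: int, v: int) -> bool:
        """True iff an additional bar between u and v would be redundant."""
        return self.gather(u, v, L + 1) <= L


def pebble_game_decompose(framework: BodyBarFramework) -> RigidClusterDecomposition:
    """Run the (6,6) pebble game and return maximal rigid clusters.

    Bars are played in deterministic (sorted-edge) order; the resulting
    decomposition is order-independent because independence defines a
    matroid on the bars.  Bodies u, v end up in one cluster iff no
    relative degree of freedom remains between them, tested as redundancy
    of a hypothetical extra bar; the mutual-rigidity relation is an
    equivalence, and rigid clusters are connected, so testing along
    edges suffices.
    """
    n = framework.n_bodies
    if n == 0:
        raise ValueError("empty framework")
    game = _PebbleGame(n)
    edges = framework.capped_edges()
    rejected = 0
    for u, v, bars, _origin in sorted(edges):
        for _ in range(bars):
            if not game.try_insert_bar(u, v):
                rejected += 1
    if rejected:
        logger.debug("%d redundant bars", rejected)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    seen_pairs: set[tuple[int, int]] = set()
    for u, v, _bars, _origin in edges:
        if (u, v) in seen_pairs:
            continue
        seen_pairs.add((u, v))
        if find(u) == find(v):
            continue
        if game.mutually_rigid(u, v):
            union(u, v)

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


def cluster_histogram(decomposition: RigidClusterDecomposition) -> ClusterSizeHistogram:
    """Count rigid clusters by size in atoms."""
    counts: dict[int, int] = {}
    for s in decomposition.sizes:
        counts[s] = counts.get(s, 0) + 1
    return ClusterSizeHistogram(counts=counts, total_atoms=decomposition.total_atoms)
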