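# Methods

## Overview

`indelrig` quantifies the structural impact of insertion/deletion (InDel)
mutations on proteins through rigidity analysis. A wildtype and a mutant
structure are each decomposed into maximal rigid clusters — sets of atoms
with no internal degrees of freedom under the covalent and non-covalent
constraint network — and the two decompositions are compared with the RDSM
and TLCCS metrics. Supporting stages provide InDel-aware residue alignment
and RMSD, and statistical tools for validating the metrics against mutant
fitness data.

## Mechanical model and the pebble game

Each atom is modeled as a rigid body with 6 degrees of freedom. Constraints
are multi-bar edges; each bar removes one relative DOF:

| constraint              | bars | rationale                                   |
|-------------------------|------|---------------------------------------------|
| locked covalent bond    | 6    | no relative motion (double/partial-double, ring, pendant) |
| rotatable covalent bond | 5    | a hinge: one dihedral survives              |
| hydrogen bond           | 5    | strong, directional; modeled as a hinge     |
| hydrophobic contact     | 2    | weak, slippery tether                       |

These are the conventional body-bar weights of the FIRST/KINARI tool
family; they are exposed as `BarPolicy` so a run can be matched to any
external configuration. Parallel bars between the same atom pair are
capped at 6 (more cannot be independent).

Generic rigidity of a body-bar multigraph is exactly characterized by
(6,6)-sparsity: a bar set is independent iff every sub-multigraph on
bodies V' has at most 6·|V'| − 6 bars. The pebble game decides this
greedily and correctly (the independent sets form a matroid, so greedy
insertion and the final decomposition are order-independent — a property
the tests check explicitly by permuting edge order). Each body holds 6
pebbles; a bar is accepted iff 7 pebbles can be gathered on its two
endpoints by reversing previously oriented bars. After all bars are
played, two bodies are mutually rigid iff a hypothetical extra bar
between them would be redundant (cannot gather 7 pebbles). Mutual
rigidity of bodies is transitive — a body has no internal DOF, so two
clusters sharing one are co-moving — and rigid clusters are connected,
so the partition is built by testing the relation along existing edges
and merging with union-find.

An independent oracle (`rigidity_matrix_oracle`, ≤ 12 bodies) builds the
body-bar rigidity matrix at two random generic placements: each bar
between attachment points p, q with direction d contributes the row
(p×d, d) / −(q×d, d); two bodies are mutually rigid iff every kernel
vector assigns them the same instantaneous screw motion. Generic
rigidity is placement-independent with probability 1; evaluating two
placements and a 1e-8 singular-value cutoff guard against non-generic
accidents. The oracle exists purely as ground truth for the pebble game
and shares no code with it.

## Interaction detection

Hydrogen bonds are scored with the Mayo 12-10 potential,
E = V0·(5(d0/d)¹² − 6(d0/d)¹⁰)·F, V0 = 8 kcal/mol, d0 = 2.8 Å (d is the
donor–acceptor distance), retained when E ≤ −1.0 kcal/mol. Candidates
are prefiltered at d_DA ≤ 3.6 Å and θ(D–H–A) ≥ 100°. The angular factor
F ∈ [0,1] multiplies cos²(π−θ)·exp(−(π−θ)⁶) by a hybridization-dependent
term in the H–acceptor–base angle φ (ideal 120° for sp2 acceptors,
109.5° for sp3) and, for sp2–sp2 pairs, the larger of the φ-deviation
and the out-of-plane deviation γ. This is a rationalized variant of the
published angular forms, constructed so that F = 1 exactly at ideal
geometry; since the reference tool's parameters for the original runs
are not published, the exact angular convention is a free choice here
and all cutoffs are configurable.

Deposited structures rarely include hydrogens, so a minimal internal
protonation step places backbone amide hydrogens in the C(i−1)–N–CA
plane opposite the bisector at 1.01 Å (none at the N-terminus or
proline, which is consistent with their chemistry) and side-chain polar
hydrogens at idealized torsions (hydroxyls 0.96 Å, N–H 1.01 Å; histidine
defaults to the NE2-protonated tautomer). Hydrophobic contacts join C/S
atoms of different residues within vdW sum (C 1.7 Å, S 1.8 Å) plus a
0.25 Å fudge, excluding 1-2/1-3 covalent neighbors.

Covalent bonds come from residue templates plus distance rules (peptide
C–N < 1.7 Å, disulfide SG–SG < 2.3 Å, unknown residues by < 1.9 Å heavy
atom fallback). A bond is *locked* when it is a peptide bond, lies in a
ring system, or ends in a single-neighbor (pendant) atom — a pendant
atom has no rotational freedom of its own; all other single bonds are
rotatable hinges.

## Comparison metrics

**RDSM** = Σ_i i·w(i)·(WT_i − Mut_i), where WT_i/Mut_i count rigid
clusters of exactly i atoms and w(x) = 1/(1+e^(−a·x+b)) weights large
clusters more (losing a large cluster matters more than reshuffling
small ones). Shipped variants: RDSM2 (a = 0.1, b = 5) and RDSM3
(a = 0.05, b = 5); others are user-configurable. The sum runs over the
union of sizes present in either histogram. Summation truncated at the
wildtype's largest cluster would silently drop any mutant cluster larger
than all wildtype clusters; the union rule is equivalent whenever that
does not happen and preserves exact antisymmetry
(RDSM(A,B) = −RDSM(B,A)), which the tests rely on. Normalized scores
divide by the wildtype's atom count so differently sized proteins are
comparable.

**TLCCS** compares only the top two clusters:
overlap = |LC_A ∩ map(LC_B)| / LCS_A,
penalty = (|LCS_A − LCS_B| + |SLCS_A − SLCS_B|) / LCS_A,
score = overlap / (1 + penalty), clamped to [0,1]. Identity gives
exactly 1; disjoint largest clusters give 0. Across an InDel pair the
atom correspondence comes from the residue alignment (unmatched atoms
count as non-overlapping). Scores at or below 0.5 are classified as a
significant rigidity impact. The printed source expression for this
score is typographically ambiguous; the adopted algebra is the unique
reading consistent with the identity-gives-1 behavior and the stated
interpretation, and the roles of the two arguments follow the
wildtype-first convention.

## Alignment and RMSD

Residues are paired per chain by global sequence alignment (match +1,
mismatch −1, gap open −5, gap extend −0.5, via Biopython's
`PairwiseAligner`); gap columns are the InDel sites. Global RMSD is the
all-atom (heavy atoms by default) RMSD over name-matched atoms of paired
residues after Kabsch superposition. Local RMSD restricts to matched
residues within ±5 (configurable) of a gap, *measured in the global
superposition frame*: re-fitting on the loop alone would hide a loop
that moved rigidly relative to the body of the protein, which is
precisely the displacement of interest; a `local_fit` flag provides the
alternative. The Kabsch implementation rejects fewer than 3 points and
collinear sets, and always returns a proper rotation.

## Statistical validation

For per-protein score triples X (wildtype vs experimental mutant), Y
(wildtype vs computational mutant), W (mutant vs mutant), the package
reports Spearman ρ(X, Y) and P(W < min(X, Y)) = P(D < 0) with
D = W − min(X, Y). The normal estimate Φ(−mean(D)/sd(D)) is the default
— a raw empirical fraction on a few dozen proteins is too granular to
produce the kind of non-multiple-of-1/n probabilities this analysis is
expected to yield — and the empirical fraction is always co-reported.
Pearson and Spearman coefficients come from `scipy.stats` with two-sided
p-values (t-distribution, n−2 df).

The shipped TEM-1 β-lactamase benchmark (`datasets.tem1_insertion_fitness`)
carries 10 single-residue insertion mutants of PDB 1ZG6 with
AMP-resistance fitness and published metric scores. In the published
table the TLCCS and RDSM1 column *headers* are transposed relative to
their contents; the dataset module names columns by content and documents
the evidence (the per-metric correlation row only reproduces under the
corrected assignment). The RDSM5 correlation is not recoverable from the
rounded printed scores (recomputation gives −0.12, not the printed
−0.254) and is therefore not asserted anywhere.

## Synthetic fixtures

All tests run from generated inputs. `make_polyalanine` builds
ideal-geometry backbones (helix φ = −57°, ψ = −47°; strand φ = −119°,
ψ = 113°; coil torsions drawn from broad allowed ranges) with standard
bond lengths/angles via NeRF internal-to-Cartesian placement; the helix
produces the expected i→i−4 backbone hydrogen-bond ladder when
protonated. `make_heteropeptide` relabels the backbone with a random
no-adjacent-repeat sequence so that planted InDel sites are identifiable
by alignment (a homopolymer admits no unique gap placement);
`unambiguous_deletion_sites` additionally rejects deletion blocks whose
flanking letters make the optimal alignment non-unique, because such
positions have no well-defined ground truth. Gaussian coordinate noise
(σ ≤ 0.05 Å in the robustness study) stands in for the small drift a few
hundred energy-minimization steps produce: the intent is a slight
perturbation without conformational change, which seeded noise achieves
without a molecular-dynamics dependency.

What the fixtures do *not* emulate: real side-chain packing, ligands,
waters, crystallographic disorder, and genuinely remodeled mutant
backbones (mutant generation by loop modeling is out of scope — the
package consumes already-built structures). Passing tests therefore
demonstrate correctness of the algorithms and metrics, not accuracy of
any particular published per-protein value that depends on externally
modeled coordinates and unpublished interaction parameters.

## Problem sizes and numerical choices

The validation runs use 12-residue helices (~60 atoms, ~72 after
protonation), 30-residue heteropeptides, 100-plus random frameworks of
≤ 8 bodies for oracle equivalence, and 50 seeded perturbation trials —
sizes chosen so the whole suite and the acceptance script run in
seconds while still exercising every code path at non-trivial scale.
Determinism: every stochastic step takes an explicit seed; pebble-game
iteration order is sorted so runs are bit-reproducible even though the
result is provably order-independent. Degenerate inputs (empty
structures, zero-variance vectors, collinear point sets, empty
decompositions) raise informative errors rather than returning NaN.

## Known limitations

- Interaction parameters (energy cutoff, bar counts, angular form) are
  defaults of the tool family, not a fit to any published table; per-pair
  published TLCCS/RMSD values additionally depend on externally modeled
  mutant coordinates and are not reproduction targets.
- Protonation is minimal and template-based; no optimization of hydrogen
  positions or histidine tautomer assignment.
- The rigidity model ignores ligands and waters by default (flags
  re-include HETATM records).
- The oracle is limited to 12 bodies by design; it is a test instrument,
  not an analysis path.
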