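"""Rigid-cluster comparison metrics between a wildtype and a mutant.

Two families are provided.  The RDSM (Rigidity Distance Similarity
Metric) compares the full cluster-size spectra:

    RDSM = Σ_i  i · w(i) · (WT_i − Mut_i)

where WT_i / Mut_i count rigid clusters of size i atoms and w is a
sigmoid weight that emphasizes large clusters; the shipped variants are
RDSM2 (w(x) = 1/(1+e^(−0.1x+5))) and RDSM3 (w(x) = 1/(1+e^(−0.05x+5))).
A term is positive where the wildtype has clusters the mutant lacks and
negative in the opposite case; optionally the sum is normalized by the
wildtype atom count so proteins of different size are comparable.

The TLCCS (Two Largest Cluster Comparison Score) compares only the two
largest clusters of each structure: the fraction of the first
structure's largest cluster recovered in the second's, damped by the
normalized size changes of the top two clusters.  It lives in [0, 1];
1 means no change, and values at or below 0.5 flag a significant
rigidity impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .rigidity import ClusterSizeHistogram, RigidClusterDecomposition

SIGNIFICANCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class WeightFunction:
    """Sigmoid cluster-size weight w(x) = 1 / (1 + exp(−a·x + b))."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("slope a must be positive")

    def __call__(self, x: float) -> float:
        z = -self.a * x + self.b
        if z > 700:
            return 0.0
        return 1.0 / (1.0 + math.exp(z))


def sigmoid_weight(a: float, b: float) -> WeightFunction:
    """Build a sigmoid weight; RDSM2 = (0.1, 5), RDSM3 = (0.05, 5)."""
    return WeightFunction(a=a, b=b)


@dataclass(frozen=True)
class RdsmConfig:
    label: str
    weight: WeightFunction
    normalize: bool = False


RDSM2 = RdsmConfig(label="RDSM2", weight=sigmoid_weight(0.1, 5.0))
RDSM3 = RdsmConfig(label="RDSM3", weight=sigmoid_weight(0.05, 5.0))
BUILTIN_VARIANTS: tuple[RdsmConfig, ...] = (RDSM2, RDSM3)


def rdsm_score(
    wt_hist: ClusterSizeHistogram,
    mut_hist: ClusterSizeHistogram,
    config: RdsmConfig = RDSM2,
) -> float:
    """Σ_i i·w(i)·(WT_i − Mut_i), summed over the union of sizes present.

    Summing over the union (rather than stopping at the wildtype's
    largest cluster) keeps the score antisymmetric and never discards a
    mutant cluster larger than any wildtype one.  With ``normalize`` the
    sum is divided by the wildtype's total atom count.
    """
    sizes = set(wt_hist.counts) | set(mut_hist.counts)
    w = config.weight
    total = sum(i * w(i) * (wt_hist.get(i) - mut_hist.get(i)) for i in sorted(sizes))
    if config.normalize:
        total /= wt_hist.total_atoms
    return total


def rdsm_suite(
    wt_hist: ClusterSizeHistogram,
    mut_hist: ClusterSizeHistogram,
    configs: tuple[RdsmConfig, ...] = BUILTIN_VARIANTS,
) -> dict[str, float]:
    """One RDSM score per configured variant, keyed by label."""
    if not configs:
        raise ValueError("at least one RDSM variant required")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate variant labels in {labels}")
    return {c.label: rdsm_score(wt_hist, mut_hist, c) for c in configs}


def tlccs_score(
    decomp_a: RigidClusterDecomposition,
    decomp_b: RigidClusterDecomposition,
    atom_map: dict[int, int] | None = None,
) -> float:
    """Two Largest Cluster Comparison Score in [0, 1].

    overlap = |LC_A ∩ map(LC_B)| / LCS_A;
    penalty = (|LCS_A − LCS_B| + |SLCS_A − SLCS_B|) / LCS_A;
    score   = overlap / (1 + penalty).

    ``atom_map`` maps atom serials of structure B onto structure A's
    (identity when omitted); unmatched atoms count as non-overlapping.
    """
    if not decomp_a.clusters or not decomp_b.clusters:
        raise ValueError("empty decomposition")
    lcs_a, slcs_a = decomp_a.lcs, decomp_a.slcs
    lcs_b, slcs_b = decomp_b.lcs, decomp_b.slcs
    largest_b = decomp_b.largest
    if atom_map is not None:
        mapped_b = {atom_map[s] for s in largest_b if s in atom_map}
    else:
        mapped_b = set(largest_b)
    overlap = len(decomp_a.largest & mapped_b) / lcs_a
    penalty = (abs(lcs_a - lcs_b) + abs(slcs_a - slcs_b)) / lcs_a
    score = overlap / (1.0 + penalty)
    return min(1.0, max(0.0, score))


def classify_impact(tlccs: float) -> str:
    """'significant' iff TLCCS ≤ 0.5, else 'not-significant'."""
    if not 0.0 <= tlccs <= 1.0:
        raise ValueError(f"TLCCS {tlccs} outside [0, 1]")
    return "significant" if tlccs <= SIGNIFICANCE_THRESHOLD else "not-significant"
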