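"""End-to-end wildtype/mutant comparison and batch validation.

``compare_pair`` chains the full pipeline — parse, protonate, detect
interactions, build the body-bar framework, pebble-game decompose,
score — and returns a :class:`ComparisonReport` holding every number
together with the parameters that produced it, so any reported score is
recomputable.  ``run_validation`` aggregates per-protein score triples
into the Spearman/P(D<0) summary and, when a fitness table is supplied,
the per-metric Pearson correlations.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from os import PathLike

from . import compare as cmp
from . import metrics as met
from .interactions import (
    DEFAULT_FUDGE,
    DEFAULT_HBOND_CUTOFF,
    detect_hydrogen_bonds,
    detect_hydrophobic_contacts,
    place_polar_hydrogens,
)
from .rigidity import (
    BarPolicy,
    ClusterSizeHistogram,
    RigidClusterDecomposition,
    build_framework,
    cluster_histogram,
    pebble_game_decompose,
)
from .stats import (
    ScoreTriple,
    metric_fitness_correlations,
    prob_w_below_min,
    spearman_rho,
)
from .structure_io import Structure, infer_covalent_bonds, read_pdb

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one comparison run."""

    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF   # kcal/mol
    fudge: float = DEFAULT_FUDGE                 # Å
    bars: BarPolicy = field(default_factory=BarPolicy)
    rdsm_variants: tuple[met.RdsmConfig, ...] = met.BUILTIN_VARIANTS
    protonate: bool = True
    include_hetatm: bool = False
    window: int = cmp.DEFAULT_WINDOW

    def params_dict(self) -> dict:
        return {
            "hbond_cutoff": self.hbond_cutoff,
            "fudge": self.fudge,
            "bars": asdict(self.bars),
            "rdsm_variants": {
                c.label: {"a": c.weight.a, "b": c.weight.b,
                          "normalize": c.normalize}
                for c in self.rdsm_variants
            },
            "protonate": self.protonate,
            "window": self.window,
        }

    @classmethod
    def from_toml(cls, path: str | PathLike) -> "PipelineConfig":
        """Load from a TOML file with [interactions], [bars],
        [rdsm.variants.<label>] and [compare] sections."""
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        inter = doc.get("interactions", {})
        bars = doc.get("bars", {})
        variants = []
        for label, v in doc.get("rdsm", {}).get("variants", {}).items():
            variants.append(met.RdsmConfig(
                label=label,
                weight=met.sigmoid_weight(v["a"], v["b"]),
                normalize=v.get("normalize", False),
            ))
        comp = doc.get("compare", {})
        return cls(
            hbond_cutoff=inter.get("hbond_cutoff", DEFAULT_HBOND_CUTOFF),
            fudge=inter.get("fudge", DEFAULT_FUDGE),
            bars=BarPolicy(**bars) if bars else BarPolicy(),
            rdsm_variants=tuple(variants) or met.BUILTIN_VARIANTS,
            protonate=inter.get("protonate", True),
            window=comp.get("window", cmp.DEFAULT_WINDOW),
        )


@dataclass
class StructureAnalysis:
    """Per-structure pipeline products."""

    structure: Structure
    n_hbonds: int
    n_contacts: int
    decomposition: RigidClusterDecomposition
    histogram: ClusterSizeHistogram


def analyze_structure(
    structure: Structure, config: PipelineConfig = PipelineConfig()
) -> StructureAnalysis:
    """Protonate, detect interactions, decompose into rigid clusters."""
    st = place_polar_hydrogens(structure) if config.protonate else structure
    bonds = infer_covalent_bonds(st)
    hbonds = detect_hydrogen_bonds(st, config.hbond_cutoff, bonds=bonds)
    contacts = detect_hydrophobic_contacts(st, config.fudge, bonds=bonds)
    fw = build_framework(st, bonds, hbonds, contacts, config.bars)
    decomp = pebble_game_decompose(fw)
    return StructureAnalysis(
        structure=st,
        n_hbonds=len(hbonds),
        n_contacts=len(contacts),
        decomposition=decomp,
        histogram=cluster_histogram(decomp),
    )


@dataclass
class ComparisonReport:
    """Everything one wildtype/mutant comparison produced."""

    label_wt: str
    label_mut: str
    n_atoms_wt: int
    n_atoms_mut: int
    n_hbonds: dict[str, int]
    n_contacts: dict[str, int]
    histogram_wt: dict[int, int]
    histogram_mut: dict[int, int]
    rdsm_raw: dict[str, float]
    rdsm_normalized: dict[str, float]
    tlccs: float
    impact: str
    global_rmsd: float
    local_rmsd: float | None
    gaps_wt: list
    gaps_mut: list
    parameters: dict

    TSV_FIELDS = ("label_wt", "label_mut", "global_rmsd", "local_rmsd",
                  "tlccs", "impact")

    def to_json(self) -> str:
        doc = asdict(self)
        doc["histogram_wt"] = {str(k): v for k, v in self.histogram_wt.items()}
        doc["histogram_mut"] = {str(k): v for k, v in self.histogram_mut.items()}
        return json.dumps(doc, indent=2, sort_keys=True)

    def tsv_row(self) -> str:
        vals = []
        for f in self.TSV_FIELDS:
            v = getattr(self, f)
            if isinstance(v, float):
                vals.append(f"{v:.6g}")
            else:
                vals.append("" if v is None else str(v))
        return "\t".join(vals)


def compare_structures(
    wt: Structure,
    mut: Structure,
    config: PipelineConfig = PipelineConfig(),
) -> ComparisonReport:
    """Full rigidity/RMSD comparison of two in-memory structures."""
    an_wt = analyze_structure(wt, config)
    an_mut = analyze_structure(mut, config)

    corr = cmp.align_residues(wt, mut)
    grmsd = cmp.global_rmsd(wt, mut, corr)
    try:
        lrmsd = cmp.local_rmsd(wt, mut, corr, window=config.window)
    except ValueError:
        lrmsd = None  # identical sequences: no InDel site

    raw = met.rdsm_suite(an_wt.histogram, an_mut.histogram, config.rdsm_variants)
    denom = an_wt.histogram.total_atoms
    normalized = {k: v / denom for k, v in raw.items()}

    amap = cmp.atom_serial_map(an_wt.structure, an_mut.structure, corr)
    tl = met.tlccs_score(an_wt.decomposition, an_mut.decomposition, amap)

    return ComparisonReport(
        label_wt=wt.source_id or "wt",
        label_mut=mut.source_id or "mut",
        n_atoms_wt=wt.n_atoms,
        n_atoms_mut=mut.n_atoms,
        n_hbonds={"wt": an_wt.n_hbonds, "mut": an_mut.n_hbonds},
        n_contacts={"wt": an_wt.n_contacts, "mut": an_mut.n_contacts},
        histogram_wt=dict(sorted(an_wt.histogram.counts.items())),
        histogram_mut=dict(sorted(an_mut.histogram.counts.items())),
        rdsm_raw=raw,
        rdsm_normalized=normalized,
        tlccs=tl,
        impact=met.classify_impact(tl),
        global_rmsd=grmsd,
        local_rmsd=lrmsd,
        gaps_wt=[list(k) for k in corr.gaps_a],
        gaps_mut=[list(k) for k in corr.gaps_b],
        parameters=config.params_dict(),
    )


def compare_pair(
    wt: str | PathLike,
    mut: str | PathLike,
    config: PipelineConfig | str | PathLike | None = None,
) -> ComparisonReport:
    """Compare two PDB files (paths or PDB text); see compare_structures."""
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_toml(config)
    st_wt = read_pdb(wt, include_hetatm=config.include_hetatm)
    st_mut = read_pdb(mut, include_hetatm=config.include_hetatm)
    return compare_structures(st_wt, st_mut, config)


def run_validation(
    triples_by_variant: dict[str, list[ScoreTriple]],
    fitness_table=None,
    fitness_column: str = "fitness",
) -> dict:
    """Spearman(X, Y) and P(W < min(X, Y)) per RDSM variant, plus the
    optional fitness correlation table.

    ``triples_by_variant`` maps an RDSM variant label to its per-protein
    (X, Y, W) triples; at least 3 triples are required per variant.
    """
    summary: dict = {"variants": {}}
    for label, triples in triples_by_variant.items():
        if len(triples) < 3:
            raise ValueError(
                f"variant {label!r}: need at least 3 triples, got {len(triples)}"
            )
        xs = [t.x for t in triples]
        ys = [t.y for t in triples]
        rho = spearman_rho(xs, ys)
        summary["variants"][label] = {
            "spearman_xy": rho.r,
            "spearman_p": rho.p,
            "p_w_below_min_normal": prob_w_below_min(triples, "normal"),
            "p_w_below_min_empirical": prob_w_below_min(triples, "empirical"),
            "n": len(triples),
        }
    if fitness_table is not None:
        corr = metric_fitness_correlations(fitness_table, fitness_column)
        summary["fitness_pearson"] = {
            k: {"r": v.r, "n": v.n, "p": v.p} for k, v in corr.items()
        }
    return summary
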