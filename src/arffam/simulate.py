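"""Synthetic-data generation with manifest-backed ground truth.

Every generator is a pure function of (parameters, seed). The study-like
preset emulates the study design this package models: an 11-member focal ARF
family (4 MR-composition activators, 3 CTD-bearing repressors, 3 CTD-less
repressors, 1 DBD-only protein; introns 1-13), 23 + 25 reference-species
homologs with seven planted focal/At cherries and none with Os, 27 promoters
of reproduction-related genes of which 16 carry planted AuxREs, and qRT-PCR
Ct tables (5 replicates, CpACTIN reference) with planted expression levels
per tissue / flower stage / sex type / fruit stage.

The evolved alignment uses a uniform-replacement (Jukes-Cantor-style) 20-letter
substitution model, so expected pairwise distances equal tree path lengths in
the small-rate limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genestruct import GeneModel
from .io import CtTable, DomainAnnotation, SequenceRecord, write_fasta
from .motifs import (
    MotifDefinition,
    MotifHit,
    PRESETS,
    PromoterRecord,
    compile_iupac,
    reverse_complement,
    scan_promoter,
)
from .phylo import Alignment, PhyloTree, TreeNode

__all__ = [
    "GeneSpec",
    "FamilyParams",
    "FamilyBundle",
    "FamilyManifest",
    "simulate_family",
    "evolve_alignment",
    "plant_motifs",
    "simulate_ct",
    "study_like_expression_levels",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one fixed codon per amino acid, for synthetic CDS construction
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}


@dataclass
class GeneSpec:
    """Planted ground truth for one focal gene."""

    name: str
    protein_id: str
    category: str
    has_ctd: bool
    introns: int
    length_aa: int
    strand: str
    cherry_partner: str | None  # reference leaf forming a planted cherry
    nearest_reference: str  # reference leaf deciding the assigned name


@dataclass
class FamilyParams:
    """Generator knobs; defaults are the study conditions being emulated."""

    alignment_length: int = 500
    mr_margin: float = 0.02  # minimum |freq(Q) - freq(P) - freq(G)| in the MR
    n_decoys: int = 3  # Aux/IAA-only decoy proteins
    promoter_length: int = 1500
    n_promoters: int = 27
    n_promoters_with_auxre: int = 16
    ct_noise_sd: float = 0.15  # cycles
    ct_n_reps: int = 5
    ct_baseline: float = 20.0
    reference_gene: str = "CpACTIN"
    cherry_tip: float = 0.03
    cherry_stem: float = 0.20
    singleton_tip: float = 0.25
    inner_branch: float = 0.08


@dataclass
class FamilyManifest:
    """Ground truth every pipeline stage must reproduce."""

    seed: int
    gene_specs: list[GeneSpec]
    decoy_ids: list[str]
    allow_list: set[str]
    cherries: list[tuple[str, str]]  # planted cross-species sister pairs
    tree_newick: str
    species_map: dict[str, str]
    mr_bounds: dict[str, tuple[int, int] | None]
    mr_margins: dict[str, float]
    promoter_hits: dict[str, list[MotifHit]]
    n_promoters_with_auxre: int
    expression_levels: dict[str, dict[str, dict[str, float]]]

    def genes_frame(self) -> pd.DataFrame:
        rows = []
        for spec in self.gene_specs:
            mr = self.mr_bounds[spec.protein_id]
            rows.append(
                {
                    "protein_id": spec.protein_id,
                    "name": spec.name,
                    "category": spec.category,
                    "has_ctd": spec.has_ctd,
                    "introns": spec.introns,
                    "length_aa": spec.length_aa,
                    "strand": spec.strand,
                    "cherry_partner": spec.cherry_partner or "",
                    "nearest_reference": spec.nearest_reference,
                    "mr_start": mr[0] if mr else 0,
                    "mr_end": mr[1] if mr else 0,
                    "mr_margin": self.mr_margins[spec.protein_id],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class FamilyBundle:
    """In-memory synthetic inputs plus their manifest."""

    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    gene_models: list[GeneModel]
    domains: list[DomainAnnotation]
    alignment: Alignment
    species_map: dict[str, str]
    promoters: list[PromoterRecord]
    ct_tables: dict[str, CtTable]
    true_tree: PhyloTree
    manifest: FamilyManifest


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_alignment(
    tree: PhyloTree | TreeNode,
    root_seq: str | None = None,
    length: int = 500,
    seed: int = 0,
) -> Alignment:
    """Evolve a gap-free protein alignment down a tree.

    Along a branch of length t (substitutions/site) each site changes with
    probability (19/20)(1 - exp(-20 t / 19)) to a uniformly chosen different
    residue — the 20-state Jukes-Cantor transition, whose expected p-distance
    between two leaves approaches their path length as t -> 0.
    """
    root = tree.root if isinstance(tree, PhyloTree) else tree
    rng = np.random.default_rng(seed)
    if root_seq is not None:
        if len(root_seq) == 0:
            raise ValueError("root sequence must be non-empty")
        codes = np.array([AA.index(a) for a in root_seq], dtype=np.int8)
    else:
        if length <= 0:
            raise ValueError("alignment length must be positive")
        codes = rng.integers(0, 20, length).astype(np.int8)

    records: list[SequenceRecord] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            records.append(
                SequenceRecord(node.name, "".join(AA[c] for c in seq), "protein")
            )
            return
        for child in node.children:
            p = (19.0 / 20.0) * (1.0 - np.exp(-20.0 * child.length / 19.0))
            mask = rng.random(len(seq)) < p
            mutated = seq.copy()
            if mask.any():
                shift = rng.integers(1, 20, int(mask.sum()))
                mutated[mask] = (mutated[mask] + shift) % 20
            descend(child, mutated)

    descend(root, codes)
    records.sort(key=lambda r: r.id)
    return Alignment(records)


# ---------------------------------------------------------------------------
# promoter planting


def plant_motifs(
    seq_len: int,
    plants: list[tuple[str, int, str]],
    motifs: list[MotifDefinition] | None = None,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
) -> tuple[str, list[MotifHit]]:
    """Uniform-background sequence carrying exactly the requested motif sites.

    ``plants`` lists (motif_id, 0-based position, strand). Background bases
    are resampled until scanning finds no match outside the planted windows,
    so planted counts are exact by construction. Returns the sequence and the
    realized hits (a planted window can legitimately satisfy more than one
    degenerate motif; all such hits are reported).
    """
    motifs = motifs if motifs is not None else PRESETS["methods"]
    by_id = {m.motif_id: m for m in motifs}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    windows: list[tuple[int, int]] = []
    for motif_id, pos, strand in plants:
        if motif_id not in by_id:
            raise ValueError(f"unknown motif id {motif_id!r}")
        k = len(by_id[motif_id].pattern)
        if not (0 <= pos <= seq_len - k):
            raise ValueError(f"planted position {pos} out of bounds")
        for ws, we in windows:
            if pos < we and ws < pos + k:
                raise ValueError("planted positions overlap")
        windows.append((pos, pos + k))

    seq = list("ACGT"[i] for i in rng.integers(0, 4, seq_len))
    planted_positions: set[int] = set()
    for motif_id, pos, strand in plants:
        concrete = sorted(compile_iupac(by_id[motif_id].pattern))
        word = concrete[rng.integers(0, len(concrete))]
        if strand == "-":
            word = reverse_complement(word)
        seq[pos : pos + len(word)] = list(word)
        planted_positions.update(range(pos, pos + len(word)))

    for _ in range(max_iter):
        hits = scan_promoter(PromoterRecord("tmp", "".join(seq)), motifs, "both")
        stray = [
            h
            for h in hits
            if (h.start, h.start + len(h.matched)) not in windows
        ]
        if not stray:
            final = "".join(seq)
            realized = scan_promoter(PromoterRecord("tmp", final), motifs, "both")
            return final, realized
        for h in stray:
            for i in range(h.start, h.start + len(h.matched)):
                if i not in planted_positions:
                    seq[i] = "ACGT"[rng.integers(0, 4)]
    raise ValueError(
        "could not build a motif-free background after "
        f"{max_iter} iterations; try a longer sequence"
    )


# ---------------------------------------------------------------------------
# Ct simulation


def simulate_ct(
    levels: dict[str, dict[str, float]],
    reference_gene: str = "CpACTIN",
    noise_sd: float = 0.15,
    n_reps: int = 5,
    baseline_ct: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> CtTable:
    """Ct table with planted relative expression levels.

    ``levels[gene][condition]`` is the planted target/reference ratio
    (2^-dCt). Reference Ct is drawn around ``baseline_ct``; target Ct is
    baseline - log2(level) plus Gaussian replicate noise. With noise_sd = 0
    the planted levels are recovered exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    for gene, conds in levels.items():
        for cond, level in conds.items():
            if level <= 0:
                raise ValueError(f"{gene}/{cond}: planted level must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = sorted({c for conds in levels.values() for c in conds})
    rows = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "gene": reference_gene,
                    "condition": cond,
                    "replicate": rep,
                    "ct": baseline_ct + rng.normal(0.0, noise_sd),
                }
            )
    for gene in sorted(levels):
        for cond, level in sorted(levels[gene].items()):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": baseline_ct - np.log2(level) + rng.normal(0.0, noise_sd),
                    }
                )
    df = pd.DataFrame(rows)
    df["ct"] = df["ct"].clip(lower=0.0)
    return CtTable(data=df, reference_gene=reference_gene)


# ---------------------------------------------------------------------------
# the study-like family preset


def _published_gene_specs() -> list[GeneSpec]:
    from .datasets import papaya_arf_table

    cherries = {"CpARF2", "CpARF3", "CpARF4", "CpARF5", "CpARF10", "CpARF16", "CpARF17"}
    specs = []
    for i, row in enumerate(papaya_arf_table().itertuples(index=False), 1):
        number = row.name.removeprefix("CpARF")
        at = f"AtARF{number}"
        specs.append(
            GeneSpec(
                name=row.name,
                protein_id=f"Cp_p{i:02d}",
                category=row.category,
                has_ctd=row.has_ctd,
                introns=row.introns,
                length_aa=row.length_aa,
                strand=row.strand,
                cherry_partner=at if row.name in cherries else None,
                nearest_reference=at,
            )
        )
    return specs


def _generic_gene_specs(n_focal: int, reference_prefix: str = "AtARF") -> list[GeneSpec]:
    cycle = ["activator", "repressor_with_CTD", "repressor_no_CTD"]
    specs = []
    for i in range(1, n_focal + 1):
        category = cycle[(i - 1) % 3]
        specs.append(
            GeneSpec(
                name=f"Gene{i}",
                protein_id=f"Cp_p{i:02d}",
                category=category,
                has_ctd=category in {"activator", "repressor_with_CTD"},
                introns=1 + (i - 1) % 13,
                length_aa=400 + 40 * ((i - 1) % 8),
                strand="+-"[i % 2],
                cherry_partner=f"{reference_prefix}{i}" if i % 2 == 1 else None,
                nearest_reference=f"{reference_prefix}{i}",
            )
        )
    return specs


_MR_TARGET = {
    # activator: glutamine/serine/leucine-rich middle region
    "activator": {"Q": 0.22, "S": 0.14, "L": 0.12, "P": 0.04, "G": 0.04},
    # repressor: serine/proline/glycine/leucine-rich middle region
    "repressor": {"Q": 0.05, "S": 0.16, "L": 0.12, "P": 0.13, "G": 0.13},
}


def _mr_probabilities(kind: str) -> np.ndarray:
    target = _MR_TARGET[kind]
    rest = (1.0 - sum(target.values())) / (20 - len(target))
    return np.array([target.get(a, rest) for a in AA])


def _sample_mr(rng: np.random.Generator, length: int, kind: str, margin: float) -> str:
    """MR segment whose realized Q - (P+G) margin has the right sign and size."""
    probs = _mr_probabilities(kind)
    want_positive = kind == "activator"
    for _ in range(200):
        seq = "".join(rng.choice(list(AA), size=length, p=probs))
        score = (seq.count("Q") - seq.count("P") - seq.count("G")) / length
        if want_positive and score >= margin:
            return seq
        if not want_positive and score <= -margin:
            return seq
    raise ValueError(f"could not realize MR margin {margin} at length {length}")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _build_architecture(
    spec: GeneSpec, rng: np.random.Generator, margin: float
) -> tuple[str, list[DomainAnnotation], tuple[int, int] | None, float]:
    """Protein sequence + domain annotations matching the planted category."""
    L = spec.length_aa
    dbd_start = 6
    if spec.category == "dbd_only":
        dbd_end = L
        seq = _random_peptide(rng, L)
        domains = [DomainAnnotation(spec.protein_id, "DBD", dbd_start, dbd_end, "synthetic")]
        return seq, domains, None, 0.0
    dbd_end = dbd_start + 109
    ctd_len = 90 if spec.has_ctd else 0
    mr_start, mr_end = dbd_end + 1, L - ctd_len
    kind = "activator" if spec.category == "activator" else "repressor"
    mr_seq = _sample_mr(rng, mr_end - mr_start + 1, kind, margin)
    realized = (mr_seq.count("Q") - mr_seq.count("P") - mr_seq.count("G")) / len(mr_seq)
    seq = (
        _random_peptide(rng, dbd_start - 1)
        + _random_peptide(rng, dbd_end - dbd_start + 1)
        + mr_seq
        + _random_peptide(rng, ctd_len)
    )
    domains = [
        DomainAnnotation(spec.protein_id, "DBD", dbd_start, dbd_end, "synthetic"),
        DomainAnnotation(
            spec.protein_id, "AUX_RESP", mr_start + 5, min(mr_start + 70, mr_end), "synthetic"
        ),
    ]
    if spec.has_ctd:
        domains.append(
            DomainAnnotation(spec.protein_id, "AUX_IAA", mr_end + 1, L, "synthetic")
        )
    return seq, domains, (mr_start, mr_end), realized


def _balanced_join(subtrees: list[TreeNode], inner: float) -> TreeNode:
    nodes = list(subtrees)
    while len(nodes) > 1:
        paired = []
        for i in range(0, len(nodes) - 1, 2):
            parent = TreeNode(length=inner, children=[nodes[i], nodes[i + 1]])
            paired.append(parent)
        if len(nodes) % 2:
            paired.append(nodes[-1])
        nodes = paired
    return nodes[0]


def _build_true_tree(
    specs: list[GeneSpec],
    reference_names: dict[str, list[str]],
    params: FamilyParams,
) -> tuple[PhyloTree, list[tuple[str, str]]]:
    """True tree with planted focal/reference cherries and no other
    cross-species cherries involving focal leaves."""
    used_refs: set[str] = set()
    units: list[TreeNode] = []
    cherries: list[tuple[str, str]] = []
    all_refs = [name for names in reference_names.values() for name in names]
    filler_pool = [
        r
        for r in all_refs
        if r not in {s.cherry_partner for s in specs}
        and r not in {s.nearest_reference for s in specs}
    ]
    filler_iter = iter(filler_pool)
    for spec in specs:
        if spec.cherry_partner is not None:
            if spec.cherry_partner not in all_refs:
                raise ValueError(f"cherry partner {spec.cherry_partner!r} not a reference leaf")
            used_refs.add(spec.cherry_partner)
            unit = TreeNode(
                length=params.cherry_stem,
                children=[
                    TreeNode(name=spec.protein_id, length=params.cherry_tip),
                    TreeNode(name=spec.cherry_partner, length=params.cherry_tip),
                ],
            )
            cherries.append(tuple(sorted((spec.protein_id, spec.cherry_partner))))
            units.append(unit)
        else:
            # focal leaf next to its naming reference, but never as a cherry:
            # the sibling subtree is (reference, filler)
            ref = spec.nearest_reference
            used_refs.add(ref)
            try:
                filler = next(filler_iter)
            except StopIteration:
                filler = None
            if ref in all_refs and filler is not None:
                used_refs.add(filler)
                sibling = TreeNode(
                    length=0.10,
                    children=[
                        TreeNode(name=ref, length=0.05),
                        TreeNode(name=filler, length=0.40),
                    ],
                )
                unit = TreeNode(
                    length=params.cherry_stem,
                    children=[
                        TreeNode(name=spec.protein_id, length=0.12),
                        sibling,
                    ],
                )
                units.append(unit)
            else:
                units.append(TreeNode(name=spec.protein_id, length=params.singleton_tip))
    for species, names in reference_names.items():
        remaining = [TreeNode(name=n, length=params.singleton_tip) for n in names if n not in used_refs]
        if remaining:
            sub = _balanced_join(remaining, params.inner_branch)
            sub.length = params.cherry_stem
            units.append(sub)
    root = _balanced_join(units, params.inner_branch)
    if len(root.children) == 2:
        # re-root as degree-3 by promoting the grandchildren of an internal child
        internal = next((c for c in root.children if not c.is_leaf), None)
        if internal is not None:
            other = next(c for c in root.children if c is not internal)
            other.length += internal.length
            root = TreeNode(children=[*internal.children, other])
    return PhyloTree(root), sorted(cherries)


def study_like_expression_levels() -> dict[str, dict[str, dict[str, float]]]:
    """Planted relative-expression levels (target/reference) for the four
    study-like Ct tables: tissues, flower stages, sex types, fruit stages."""
    genes = [
        "CpARF1", "CpARF2", "CpARF3", "CpARF4", "CpARF5", "CpARF6",
        "CpARF7", "CpARF10", "CpARF11", "CpARF16", "CpARF17",
    ]
    fruit_specific = {"CpARF2", "CpARF6", "CpARF10", "CpARF16", "CpARF17"}
    root_high = {"CpARF3", "CpARF5", "CpARF11"}
    low_in_vegetative = {
        "CpARF1", "CpARF2", "CpARF3", "CpARF6", "CpARF7", "CpARF16", "CpARF17",
    }
    tissues: dict[str, dict[str, float]] = {}
    for g in genes:
        base = 0.02 if g in low_in_vegetative else 0.3
        lv = {"leaf": base, "shoot": base, "root": 0.25, "flower": 0.25, "fruit": 0.25}
        if g in fruit_specific:
            lv = {"leaf": base, "shoot": base, "root": 0.05, "flower": 0.08, "fruit": 2.0}
        elif g == "CpARF1":
            lv = {"leaf": 0.02, "shoot": 0.02, "root": 0.2, "flower": 1.6, "fruit": 0.25}
        elif g in root_high:
            lv = {"leaf": lv["leaf"], "shoot": lv["shoot"], "root": 1.6, "flower": 0.2, "fruit": 0.2}
        tissues[g] = lv

    stages = [f"stage{i}" for i in range(1, 9)]
    flower: dict[str, dict[str, float]] = {}
    decreasing = {"CpARF1", "CpARF2", "CpARF4", "CpARF5", "CpARF10"}
    for g in genes:
        if g in decreasing:
            flower[g] = {s: 2.0 * 0.72 ** i for i, s in enumerate(stages)}
        elif g == "CpARF6":
            # rises through development: peak at stage 7, more-than-six-fold
            # above stage 1 by stage 8 (planted 8x, comfortably past the
            # six-fold mark given 5-replicate Ct noise)
            values = [0.4, 0.55, 0.8, 1.2, 1.8, 2.5, 3.5, 3.2]
            flower[g] = dict(zip(stages, values))
        elif g == "CpARF17":
            flower[g] = {s: 0.05 for s in stages}
        elif g == "CpARF3":
            flower[g] = {s: 0.5 for s in stages}
        else:
            flower[g] = {s: 0.6 for s in stages}

    male_dominant = {"CpARF3", "CpARF6", "CpARF11", "CpARF16", "CpARF17"}
    sex: dict[str, dict[str, float]] = {}
    for g in genes:
        if g in male_dominant:
            sex[g] = {"male": 2.0, "female": 0.3, "hermaphrodite": 0.7}
        elif g == "CpARF10":
            sex[g] = {"male": 0.01, "female": 0.4, "hermaphrodite": 1.5}
        elif g == "CpARF1":
            sex[g] = {"male": 0.2, "female": 1.6, "hermaphrodite": 0.6}
        elif g == "CpARF2":
            # eight-fold higher in male than female, but not >50% of the total
            sex[g] = {"male": 1.6, "female": 0.2, "hermaphrodite": 1.8}
        else:
            sex[g] = {"male": 0.5, "female": 0.5, "hermaphrodite": 0.5}

    fstages = [f"stage{i}" for i in range(1, 7)]
    fruit: dict[str, dict[str, float]] = {}
    for g in genes:
        if g == "CpARF1":
            fruit[g] = {s: 0.2 * 1.6 ** i for i, s in enumerate(fstages)}
        elif g in {"CpARF7", "CpARF11"}:
            fruit[g] = {s: 1.5 * 0.63 ** i for i, s in enumerate(fstages)}
        else:
            fruit[g] = {s: 0.5 for s in fstages}

    return {
        "tissues": tissues,
        "flower_stages": flower,
        "sex_types": sex,
        "fruit_stages": fruit,
    }


_PROMOTER_GENES = (
    [f"CpMADS{i}" for i in range(1, 8)]
    + [f"CpKNOX{i}" for i in range(1, 10)]
    + ["CpFT1", "CpFT2", "CpFT3", "CpLFY1"]
    + ["CpETR1", "CpETR2", "CpCTR1", "CpCTR2"]
    + ["CpACS1", "CpACS2", "CpACO1"]
)

# the 16 promoters that carry planted AuxREs in the study-like preset
_AUXRE_POSITIVE = [
    "CpMADS1", "CpMADS4", "CpMADS6",
    "CpKNOX2", "CpKNOX3", "CpKNOX5", "CpKNOX7", "CpKNOX8",
    "CpFT1", "CpLFY1",
    "CpETR1", "CpETR2",
    "CpACS1", "CpACS2", "CpACO1",
    "CpFT3",
]


def _simulate_promoters(
    rng: np.random.Generator, params: FamilyParams
) -> tuple[list[PromoterRecord], dict[str, list[MotifHit]]]:
    gene_set = list(_PROMOTER_GENES[: params.n_promoters])
    positive = [g for g in _AUXRE_POSITIVE if g in gene_set][
        : params.n_promoters_with_auxre
    ]
    if len(positive) < params.n_promoters_with_auxre:
        raise ValueError("n_promoters_with_auxre exceeds available promoter genes")
    promoters: list[PromoterRecord] = []
    hits: dict[str, list[MotifHit]] = {}
    motifs = PRESETS["methods"]
    for gene in gene_set:
        plants: list[tuple[str, int, str]] = []
        if gene in positive:
            n_sites = int(rng.integers(1, 5))
            positions: list[int] = []
            while len(positions) < n_sites:
                pos = int(rng.integers(0, params.promoter_length - 6))
                # keep planted windows well separated so background cleanup
                # around them always has free bases to resample
                if all(abs(pos - p) >= 12 for p in positions):
                    positions.append(pos)
            for pos in sorted(positions):
                motif_id = "AUX1" if rng.random() < 0.4 else "AUX2"
                strand = "+" if rng.random() < 0.5 else "-"
                plants.append((motif_id, pos, strand))
        seq, realized = plant_motifs(
            params.promoter_length, plants, motifs, seed=rng
        )
        promoters.append(PromoterRecord(gene, seq))
        hits[gene] = [
            MotifHit(gene, h.motif_id, h.start, h.strand, h.matched)
            for h in realized
        ]
    return promoters, hits


def _write_gff3(models: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.exons[0][0], m.exons[-1][1]
            fh.write(
                f"{m.contig}\tsynthetic\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID=gene_{m.gene_id}\n"
            )
            fh.write(
                f"{m.contig}\tsynthetic\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent=gene_{m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.contig}\tsynthetic\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def _gene_model_for(spec: GeneSpec, rng: np.random.Generator) -> GeneModel:
    cds_len = 3 * spec.length_aa
    n_exons = spec.introns + 1
    # partition cds_len into n_exons parts, each >= 3
    cuts = sorted(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    sizes = np.diff([0] + [3 * int(c) for c in cuts] + [cds_len])
    start = int(rng.integers(1000, 5000))
    exons = []
    pos = start
    for size in sizes:
        exons.append((pos, pos + int(size) - 1))
        pos += int(size) + int(rng.integers(80, 300))
    return GeneModel(
        gene_id=spec.protein_id,
        contig=f"ctg_{spec.protein_id}",
        strand=spec.strand,
        exons=exons,
        orf_len=cds_len,
    )


def simulate_family(
    n_focal: int = 11,
    n_reference: dict[str, int] | None = None,
    params: FamilyParams | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> FamilyBundle:
    """Generate the full synthetic input bundle plus its ground-truth manifest.

    Defaults emulate the modelled study: 11 focal genes with the published
    category/intron configuration, 23 At + 25 Os references, 7 planted
    focal/At cherries, 27 promoters (16 with AuxREs), and four Ct tables with
    5 replicates each. Fully deterministic given (parameters, seed).
    """
    params = params or FamilyParams()
    n_reference = n_reference if n_reference is not None else {"At": 23, "Os": 25}
    if n_focal + sum(n_reference.values()) < 3:
        raise ValueError("need at least 3 taxa in total")
    if not (0 < params.mr_margin < 1):
        raise ValueError("mr_margin must be in (0, 1)")
    seedseq = np.random.SeedSequence(seed)
    rng_arch, rng_tree, rng_prom, rng_ct, rng_aln = (
        np.random.default_rng(s) for s in seedseq.spawn(5)
    )

    if n_focal == 11:
        specs = _published_gene_specs()
    else:
        specs = _generic_gene_specs(n_focal)

    reference_names = {
        sp: [f"{sp}ARF{i}" for i in range(1, n + 1)] for sp, n in n_reference.items()
    }

    # --- proteins, domains, CDS, gene models
    proteins: list[SequenceRecord] = []
    cds: list[SequenceRecord] = []
    domains: list[DomainAnnotation] = []
    gene_models: list[GeneModel] = []
    mr_bounds: dict[str, tuple[int, int] | None] = {}
    mr_margins: dict[str, float] = {}
    allow_list: set[str] = set()
    for spec in specs:
        seq, doms, mr, margin = _build_architecture(spec, rng_arch, params.mr_margin)
        proteins.append(SequenceRecord(spec.protein_id, seq, "protein"))
        cds.append(
            SequenceRecord(
                spec.protein_id, "".join(_CODON[a] for a in seq), "dna"
            )
        )
        domains.extend(doms)
        mr_bounds[spec.protein_id] = mr
        mr_margins[spec.protein_id] = margin
        if spec.category == "dbd_only":
            allow_list.add(spec.protein_id)
        gene_models.append(_gene_model_for(spec, rng_arch))
    decoy_ids = []
    for i in range(1, params.n_decoys + 1):
        pid = f"Cp_iaa{i}"
        decoy_ids.append(pid)
        seq = _random_peptide(rng_arch, 200)
        proteins.append(SequenceRecord(pid, seq, "protein"))
        domains.append(DomainAnnotation(pid, "AUX_IAA", 100, 180, "synthetic"))

    # --- true tree and evolved alignment
    true_tree, cherries = _build_true_tree(specs, reference_names, params)
    aln_seed = int(rng_aln.integers(0, 2**31 - 1))
    alignment = evolve_alignment(true_tree, length=params.alignment_length, seed=aln_seed)
    species_map = {spec.protein_id: "Cp" for spec in specs}
    for sp, names in reference_names.items():
        species_map.update({n: sp for n in names})

    # --- promoters and Ct tables
    promoters, promoter_hits = _simulate_promoters(rng_prom, params)
    levels = study_like_expression_levels() if n_focal == 11 else {
        "tissues": {
            s.name: {"leaf": 0.2, "root": 1.0, "fruit": 0.5} for s in specs
        }
    }
    ct_tables = {
        name: simulate_ct(
            lv,
            reference_gene=params.reference_gene,
            noise_sd=params.ct_noise_sd,
            n_reps=params.ct_n_reps,
            baseline_ct=params.ct_baseline,
            seed=rng_ct,
        )
        for name, lv in levels.items()
    }

    manifest = FamilyManifest(
        seed=seed,
        gene_specs=specs,
        decoy_ids=decoy_ids,
        allow_list=allow_list,
        cherries=cherries,
        tree_newick=true_tree.to_newick(),
        species_map=species_map,
        mr_bounds=mr_bounds,
        mr_margins=mr_margins,
        promoter_hits=promoter_hits,
        n_promoters_with_auxre=sum(1 for h in promoter_hits.values() if h),
        expression_levels=levels,
    )
    bundle = FamilyBundle(
        proteins=proteins,
        cds=cds,
        gene_models=gene_models,
        domains=domains,
        alignment=alignment,
        species_map=species_map,
        promoters=promoters,
        ct_tables=ct_tables,
        true_tree=true_tree,
        manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: FamilyBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteins, outdir / "proteins.fasta")
    write_fasta(bundle.cds, outdir / "cds.fasta")
    write_fasta(bundle.alignment.records, outdir / "alignment.fasta")
    write_fasta(
        [SequenceRecord(p.gene_id, p.seq, "dna") for p in bundle.promoters],
        outdir / "promoters.fasta",
    )
    _write_gff3(bundle.gene_models, outdir / "genes.gff3")
    pd.DataFrame(
        [
            {
                "protein_id": d.protein_id,
                "accession": {"DBD": "PF02362", "AUX_RESP": "PF06507", "AUX_IAA": "PF02309"}[d.domain_id],
                "start": d.start,
                "end": d.end,
                "source": d.source,
            }
            for d in bundle.domains
        ]
    ).to_csv(outdir / "domains.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(bundle.species_map.items()), columns=["leaf", "species"]
    ).to_csv(outdir / "species_map.tsv", sep="\t", index=False)
    (outdir / "allow_list.txt").write_text(
        "".join(f"{pid}\n" for pid in sorted(bundle.manifest.allow_list))
    )
    for name, table in bundle.ct_tables.items():
        table.data.to_csv(outdir / f"ct_{name}.tsv", sep="\t", index=False)
    bundle.manifest.genes_frame().to_csv(
        outdir / "manifest_genes.tsv", sep="\t", index=False
    )
    (outdir / "true_tree.nwk").write_text(bundle.manifest.tree_newick + "\n")
    run_info = {
        "seed": bundle.manifest.seed,
        "n_focal": len(bundle.manifest.gene_specs),
        "n_promoters": len(bundle.promoters),
        "n_promoters_with_auxre": bundle.manifest.n_promoters_with_auxre,
        "cherries": ";".join(f"{a}|{b}" for a, b in bundle.manifest.cherries),
        "reference_gene": bundle.ct_tables[next(iter(bundle.ct_tables))].reference_gene,
    }
    (outdir / "manifest_run.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in run_info.items())
    )
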