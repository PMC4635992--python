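"""Gene-family member selection from domain architectures and naming by
nearest cross-species homolog.

The retention rule mirrors standard ARF-family curation: a member needs a B3
DNA-binding domain (DBD) plus an ARF (AUX_RESP) domain; proteins carrying
only the Aux/IAA domain belong to the Aux/IAA repressor family and are
excluded. DBD-only proteins are excluded by default but can be admitted via
an explicit allow-list (truncated yet genuine family members exist).
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

from .io import DomainAnnotation, SequenceRecord
from .phylo import PhyloTree

logger = logging.getLogger("arffam")

__all__ = [
    "CandidateGene",
    "NamingAssignment",
    "filter_arf_candidates",
    "dedupe_candidates",
    "assign_names",
]


@dataclass
class CandidateGene:
    protein_id: str
    domains: list[DomainAnnotation] = field(default_factory=list)
    status: str = "retained"  # "retained" | "excluded"
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in {"retained", "excluded"}:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "excluded") != bool(self.exclusion_reason):
            raise ValueError(
                f"{self.protein_id}: exclusion_reason must be set iff excluded"
            )


@dataclass
class NamingAssignment:
    protein_id: str
    assigned_name: str
    nearest_reference: str
    evidence: str  # "tree_cherry" | "min_distance"


def filter_arf_candidates(
    annotations: list[DomainAnnotation],
    allow_list: set[str] | None = None,
) -> list[CandidateGene]:
    """Retain proteins with >= 1 DBD and (>= 1 AUX_RESP or allow-list entry).

    Every protein in the annotation set gets a status and, if excluded, a
    reason (e.g. Aux/IAA-only architectures fail the DBD requirement).
    """
    if not annotations:
        raise ValueError("filter_arf_candidates: empty annotation set")
    allow_list = allow_list or set()
    per_protein: dict[str, list[DomainAnnotation]] = defaultdict(list)
    for ann in annotations:
        per_protein[ann.protein_id].append(ann)
    out: list[CandidateGene] = []
    for pid in sorted(per_protein):
        domains = sorted(per_protein[pid], key=lambda d: d.start)
        kinds = {d.domain_id for d in domains}
        if "DBD" not in kinds:
            out.append(
                CandidateGene(
                    pid, domains, "excluded", "no DBD domain (Aux/IAA-like architecture)"
                )
            )
        elif "AUX_RESP" not in kinds and pid not in allow_list:
            out.append(
                CandidateGene(
                    pid, domains, "excluded", "DBD only and not on allow-list"
                )
            )
        else:
            out.append(CandidateGene(pid, domains))
    return out


def dedupe_candidates(
    candidates: list[CandidateGene],
    sequences: list[SequenceRecord],
) -> list[CandidateGene]:
    """Collapse exact-duplicate protein sequences among retained candidates.

    The lexicographically smallest id is kept as the representative; the
    others are marked excluded as duplicates. Idempotent.
    """
    seqs = {r.id: r.seq for r in sequences}
    for cand in candidates:
        if cand.status == "retained" and cand.protein_id not in seqs:
            raise ValueError(f"candidate {cand.protein_id!r} lacks a sequence")
    by_seq: dict[str, str] = {}  # sequence -> representative id
    for cand in sorted(candidates, key=lambda c: c.protein_id):
        if cand.status != "retained":
            continue
        rep = by_seq.setdefault(seqs[cand.protein_id], cand.protein_id)
        if rep != cand.protein_id:
            cand.status = "excluded"
            cand.exclusion_reason = f"duplicate of {rep}"
            logger.info(
                "dedupe: %s collapsed into %s", cand.protein_id, rep
            )
    return candidates


_NUM_RE = re.compile(r"(\d+)")
_LETTERS = "bcdefghijklmnopqrstuvwxyz"


def assign_names(
    tree: PhyloTree,
    species_map: dict[str, str],
    reference_names: dict[str, str],
    name_prefix: str,
    focal_species: str | None = None,
) -> list[NamingAssignment]:
    """Name focal-species leaves after their nearest reference homolog.

    A focal leaf forming a cherry with a reference leaf takes that leaf's
    numeric suffix (evidence "tree_cherry"); otherwise the reference leaf at
    minimum patristic distance decides (evidence "min_distance"), with
    distance ties resolved toward the lowest-numbered reference name. Name
    collisions append a letter (b, c, ...) and are logged.
    """
    if not reference_names:
        raise ValueError("assign_names: no reference leaves supplied")
    leaves = tree.leaf_names
    if focal_species is None:
        ref_species = {species_map[l] for l in reference_names if l in species_map}
        focal = [
            l for l in leaves
            if l not in reference_names and species_map.get(l) not in ref_species
        ]
    else:
        focal = [l for l in leaves if species_map.get(l) == focal_species]
    cherry_partner: dict[str, str] = {}
    for a, b, _ in tree.cherries():
        if a in reference_names and b not in reference_names:
            cherry_partner[b] = a
        elif b in reference_names and a not in reference_names:
            cherry_partner[a] = b
    dm = tree.leaf_distances()
    idx = {lab: i for i, lab in enumerate(dm.labels)}

    def suffix(ref_leaf: str) -> str:
        m = _NUM_RE.search(reference_names[ref_leaf])
        return m.group(1) if m else reference_names[ref_leaf]

    assignments: list[NamingAssignment] = []
    used: dict[str, int] = {}
    for leaf in sorted(focal):
        if leaf in cherry_partner:
            ref, evidence = cherry_partner[leaf], "tree_cherry"
        else:
            ref = min(
                reference_names,
                key=lambda r: (
                    dm.d[idx[leaf], idx[r]],
                    (int(suffix(r)) if suffix(r).isdigit() else 10**9),
                    reference_names[r],
                ),
            )
            evidence = "min_distance"
        base = f"{name_prefix}{suffix(ref)}"
        n_seen = used.get(base, 0)
        used[base] = n_seen + 1
        name = base if n_seen == 0 else base + _LETTERS[n_seen - 1]
        if n_seen:
            logger.warning("assign_names: collision on %s -> %s", base, name)
        assignments.append(NamingAssignment(leaf, name, ref, evidence))
    return assignments
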