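"""IUPAC-degenerate AuxRE scanning of promoter sequences.

Auxin response elements are short degenerate hexamers; the canonical core is
AUX1 = TGTCTC and the relaxed variant AUX2 = TGTVYS (V = A/C/G, Y = C/T,
S = C/G). Hits are reported with 0-based offsets on the forward promoter
string — for a 1500-bp promoter, offset 0 is position -1500 relative to the
start codon. Reverse-strand hits are matches of a pattern's reverse
complement against the forward string, reported at their forward offset with
strand "-".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

__all__ = [
    "MotifDefinition",
    "PromoterRecord",
    "MotifHit",
    "IUPAC",
    "PRESETS",
    "compile_iupac",
    "reverse_complement",
    "scan_promoter",
    "promoter_summary",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class MotifDefinition:
    motif_id: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.motif_id}: empty pattern")
        self.pattern = self.pattern.upper()
        for ch in self.pattern:
            if ch not in IUPAC:
                raise ValueError(
                    f"{self.motif_id}: {ch!r} is not an IUPAC nucleotide code"
                )


#: Named motif presets. "methods" carries the canonical definitions
#: (AUX1=TGTCTC, AUX2=TGTVYS); "figure7" is an alternative published variant
#: (AUX1=TGTGTC; its AUX2 uses a non-IUPAC placeholder at position 4, read
#: here as N, the least restrictive code).
PRESETS: dict[str, list[MotifDefinition]] = {
    "methods": [
        MotifDefinition("AUX1", "TGTCTC"),
        MotifDefinition("AUX2", "TGTVYS"),
    ],
    "figure7": [
        MotifDefinition("AUX1", "TGTGTC"),
        MotifDefinition("AUX2", "TGTNYS"),
    ],
}


@dataclass
class PromoterRecord:
    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    start: int  # 0-based offset on the forward promoter string
    strand: str  # "+" | "-"
    matched: str  # the concrete promoter substring at [start, start+len)


def compile_iupac(pattern: str) -> set[str]:
    """Cartesian expansion of an IUPAC pattern into concrete sequences."""
    choices = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"{ch!r} is not an IUPAC nucleotide code")
        choices.append(IUPAC[ch])
    return {"".join(combo) for combo in product(*choices)}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_promoter(
    promoter: PromoterRecord,
    motifs: list[MotifDefinition] | None = None,
    strands: str = "both",
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches on a promoter.

    In "both" mode the reverse complement of each pattern is also matched
    against the forward string; such hits carry forward coordinates and
    strand "-". Output is sorted by (start, motif_id, strand).
    """
    if strands not in {"both", "forward_only"}:
        raise ValueError(f"unknown strand mode {strands!r}")
    if motifs is None:
        motifs = PRESETS["methods"]
    seq = promoter.seq
    hits: list[MotifHit] = []
    for motif in motifs:
        k = len(motif.pattern)
        searches = [("+", compile_iupac(motif.pattern))]
        if strands == "both":
            searches.append(
                ("-", {reverse_complement(s) for s in compile_iupac(motif.pattern)})
            )
        for strand, concrete in searches:
            for offset in range(len(seq) - k + 1):
                word = seq[offset : offset + k]
                if word in concrete:
                    hits.append(
                        MotifHit(promoter.gene_id, motif.motif_id, offset, strand, word)
                    )
    hits.sort(key=lambda h: (h.start, h.motif_id, h.strand))
    return hits


def promoter_summary(
    hits: list[MotifHit],
    gene_set: list[str],
) -> pd.DataFrame:
    """Per-gene motif counts: columns gene, n_AUX1-style count per motif id,
    and has_any; genes without hits appear as zero rows.

    ``df.attrs["n_with_any"]`` carries the family-level count of genes with
    at least one hit.
    """
    unknown = {h.gene_id for h in hits} - set(gene_set)
    if unknown:
        raise ValueError(f"hits for genes outside gene_set: {sorted(unknown)}")
    motif_ids = sorted({h.motif_id for h in hits}) or ["AUX1", "AUX2"]
    rows = []
    for gene in gene_set:
        counts = {
            f"n_{mid}": sum(
                1 for h in hits if h.gene_id == gene and h.motif_id == mid
            )
            for mid in motif_ids
        }
        rows.append({"gene": gene, **counts, "has_any": any(counts.values())})
    df = pd.DataFrame(rows)
    df.attrs["n_with_any"] = int(df["has_any"].sum()) if len(df) else 0
    return df


def hits_to_bed(hits: list[MotifHit]) -> pd.DataFrame:
    """BED-like export: 0-based half-open intervals on the promoter string."""
    return pd.DataFrame(
        [
            {
                "gene": h.gene_id,
                "start": h.start,
                "end": h.start + len(h.matched),
                "motif_id": h.motif_id,
                "strand": h.strand,
                "matched": h.matched,
            }
            for h in hits
        ],
        columns=["gene", "start", "end", "motif_id", "strand", "matched"],
    )
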