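"""Exon-intron gene structure: intron counts, drawing tracks, family summary.

Coordinates are 1-based inclusive throughout (GFF3 convention). Introns are
defined purely as the gaps between consecutive exons, so UTR introns count the
same as CDS introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneModel",
    "StructureTrack",
    "intron_count",
    "structure_track",
    "family_structure_table",
]


@dataclass
class GeneModel:
    """One gene locus: strand, ordered exons, and (optionally) its ORF length.

    Exons are stored in ascending genomic coordinates regardless of strand;
    transcript orientation is applied only when a drawing track is built.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    orf_len: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"{self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for start, end in self.exons:
            if start < 1:
                raise ValueError(f"{self.gene_id}: exon start {start} < 1")
            if end < start:
                raise ValueError(
                    f"{self.gene_id}: exon end {end} < start {start}"
                )
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = end

    @property
    def span(self) -> int:
        """Genomic span in bp, first exon start to last exon end."""
        return self.exons[-1][1] - self.exons[0][0] + 1


@dataclass
class StructureTrack:
    """Drawing track in transcript orientation: offset 0 = transcription start.

    ``boxes`` are (offset, length) exon boxes; ``segments`` are (offset,
    length) intron lines, interleaved as box, segment, box, ...
    """

    gene_id: str
    boxes: list[tuple[int, int]] = field(default_factory=list)
    segments: list[tuple[int, int]] = field(default_factory=list)


def intron_count(model: GeneModel) -> int:
    """Number of introns = number of exons - 1."""
    return len(model.exons) - 1


def structure_track(model: GeneModel) -> StructureTrack:
    """Exon boxes and intron segments in transcript orientation.

    Minus-strand models are reversed so the first box is the
    highest-coordinate exon; box lengths equal exon lengths and segment
    lengths equal intron lengths.
    """
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    track = StructureTrack(gene_id=model.gene_id)
    offset = 0
    prev: tuple[int, int] | None = None
    for start, end in exons:
        if prev is not None:
            if model.strand == "+":
                gap = start - prev[1] - 1
            else:
                gap = prev[0] - end - 1
            track.segments.append((offset, gap))
            offset += gap
        exon_len = end - start + 1
        track.boxes.append((offset, exon_len))
        offset += exon_len
        prev = (start, end)
    return track


def family_structure_table(models: list[GeneModel]) -> pd.DataFrame:
    """Per-gene structure summary: exon/intron counts and genomic span."""
    if not models:
        raise ValueError("family_structure_table: no gene models supplied")
    rows = [
        {
            "gene": m.gene_id,
            "n_exons": len(m.exons),
            "n_introns": intron_count(m),
            "span": m.span,
        }
        for m in models
    ]
    df = pd.DataFrame(rows)
    df.attrs["max_introns"] = int(df["n_introns"].max())
    df.attrs["min_introns"] = int(df["n_introns"].min())
    return df
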