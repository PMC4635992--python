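"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Bio.SeqIO, GFF3 through gffutils, tabular data through
pandas. GFF3/domain coordinates are kept 1-based inclusive end to end;
the only 0-based coordinates in the package are motif-hit offsets on
promoter strings (documented in :mod:`arffam.motifs`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .genestruct import GeneModel

logger = logging.getLogger("arffam")

__all__ = [
    "SequenceRecord",
    "DomainAnnotation",
    "CtTable",
    "PipelineConfig",
    "PFAM_DOMAIN_MAP",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_domain_table",
    "read_ct_table",
    "load_config",
]

# IUPAC nucleotide codes (degenerate allowed) and the 20 standard amino acids
# plus X (unknown) and "-" (alignment gap).
_DNA_ALPHABET = set("ACGTUNRYSWKMBDHV-")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")

#: Pfam accessions of the three family domains: B3 DNA-binding domain,
#: ARF (AUX_RESP) domain, and the Aux/IAA-shared C-terminal dimerization
#: domain. Version suffixes (e.g. PF02362.23) are accepted.
PFAM_DOMAIN_MAP: dict[str, str] = {
    "PF02362": "DBD",
    "PF06507": "AUX_RESP",
    "PF02309": "AUX_IAA",
}

DOMAIN_VOCABULARY = ("DBD", "AUX_RESP", "AUX_IAA")


@dataclass
class SequenceRecord:
    id: str
    seq: str
    moltype: str  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        if self.moltype not in {"dna", "protein"}:
            raise ValueError(f"{self.id}: unknown moltype {self.moltype!r}")
        self.seq = self.seq.upper()
        alphabet = _DNA_ALPHABET if self.moltype == "dna" else _PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"{self.id}: characters {sorted(bad)} not valid for "
                f"moltype {self.moltype}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DomainAnnotation:
    """A located domain on a protein, 1-based inclusive residue coordinates."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.domain_id not in DOMAIN_VOCABULARY:
            raise ValueError(
                f"{self.protein_id}: domain_id {self.domain_id!r} not in "
                f"{DOMAIN_VOCABULARY}"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.domain_id}: bad coordinates "
                f"{self.start}..{self.end}"
            )


@dataclass
class CtTable:
    """Long-format qRT-PCR cycle-threshold table.

    ``data`` has columns gene, condition, replicate, ct; ``reference_gene``
    names the internal-standard gene that must be present in every condition.
    """

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
        if (self.data["ct"] < 0).any():
            bad = self.data[self.data["ct"] < 0].iloc[0]
            raise ValueError(
                f"negative Ct value for {bad['gene']}/{bad['condition']}"
            )
        conditions = set(self.data["condition"])
        with_ref = set(
            self.data.loc[self.data["gene"] == self.reference_gene, "condition"]
        )
        lacking = sorted(conditions - with_ref)
        if lacking:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing for "
                f"conditions: {lacking}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.reference_gene})

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.data["condition"]))

    def ct_values(self, gene: str, condition: str) -> pd.Series:
        """Replicate Ct values for one gene x condition cell, replicate-indexed."""
        sub = self.data[
            (self.data["gene"] == gene) & (self.data["condition"] == condition)
        ]
        if sub.empty:
            raise KeyError(f"no Ct rows for gene={gene!r} condition={condition!r}")
        return sub.set_index("replicate")["ct"].sort_index()


@dataclass
class PipelineConfig:
    """Run-wide knobs; defaults mirror the study design this package models."""

    promoter_length: int = 1500
    bootstrap_reps: int = 1000
    sister_pair_min_support: float = 99.0
    fold_change_cutoff: float = 2.0
    reference_scale: float = 1000.0
    rng_seed: int = 0
    distance_model: str = "poisson"
    strands: str = "both"

    def __post_init__(self) -> None:
        for name in (
            "promoter_length",
            "bootstrap_reps",
            "fold_change_cutoff",
            "reference_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not (0 < self.sister_pair_min_support <= 100):
            raise ValueError("sister_pair_min_support must be in (0, 100]")


def read_fasta(path: str | Path, moltype: str) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Sequences are upper-cased; duplicate ids raise ValueError.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), moltype))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (one per mRNA) from a GFF3 file.

    Uses gffutils with an in-memory database. Exon features are preferred;
    CDS features are used for mRNAs without exon children. Exons must lie
    inside their parent span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parts = list(db.children(mrna, featuretype="exon"))
        if not parts:
            parts = list(db.children(mrna, featuretype="CDS"))
        if not parts:
            raise ValueError(f"{mrna.id}: mRNA without exon or CDS features")
        for part in parts:
            if part.start < mrna.start or part.end > mrna.end:
                raise ValueError(
                    f"{mrna.id}: exon {part.start}..{part.end} outside "
                    f"mRNA span {mrna.start}..{mrna.end}"
                )
        models.append(
            GeneModel(
                gene_id=mrna.id,
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=[(p.start, p.end) for p in parts],
            )
        )
    if not models:
        raise ValueError(f"no mRNA features found in {path}")
    return models


_ACCESSION_RE = re.compile(r"^(PF\d{5})")


def read_domain_table(
    path: str | Path,
    mapping: dict[str, str] | None = None,
) -> list[DomainAnnotation]:
    """Read a domain-scan TSV and map Pfam accessions to family domain ids.

    Expects a header with columns protein_id, accession, start, end (a
    ``source`` column is optional). Rows with accessions outside the mapping
    are dropped; the dropped count is logged.
    """
    if mapping is None:
        mapping = PFAM_DOMAIN_MAP
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "accession", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: unmappable domain-table layout, missing columns "
            f"{sorted(missing)}"
        )
    annotations: list[DomainAnnotation] = []
    dropped = 0
    for row in df.itertuples(index=False):
        m = _ACCESSION_RE.match(str(row.accession))
        accession = m.group(1) if m else str(row.accession)
        domain_id = mapping.get(accession)
        if domain_id is None:
            dropped += 1
            continue
        annotations.append(
            DomainAnnotation(
                protein_id=str(row.protein_id),
                domain_id=domain_id,
                start=int(row.start),
                end=int(row.end),
                source=str(getattr(row, "source", "")),
            )
        )
    if dropped:
        logger.info("read_domain_table: dropped %d unmapped rows", dropped)
    return annotations


def read_ct_table(path: str | Path, reference_gene: str) -> CtTable:
    """Read a long-format Ct table (gene, condition, replicate, ct)."""
    df = pd.read_csv(path, sep="\t")
    return CtTable(data=df, reference_gene=reference_gene)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat ``key = value`` config file; unknown keys warn, not fail."""
    known = {f: t for f, t in PipelineConfig.__annotations__.items()}
    values: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            logger.warning("config: unknown key %r ignored", key)
            continue
        target = known[key]
        if target == "int":
            values[key] = int(raw)
        elif target == "float":
            values[key] = float(raw)
        else:
            values[key] = raw
    return PipelineConfig(**values)  # type: ignore[arg-type]
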