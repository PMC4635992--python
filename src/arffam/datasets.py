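"""Bundled reference dataset: the literature-reported characterization of the
11-member auxin response factor (ARF) family of papaya (Carica papaya L.).

These are published per-gene values (locus, strand, ORF length, intron count,
protein length/mass/pI) and functional classifications (four MR-composition
activators, three CTD-bearing repressors, three CTD-truncated repressors, one
DBD-only protein). They serve as a worked example and as in-package inputs
for reproducing the family-level summary statistics.

Note: the published CpARF2 row is internally inconsistent (ORF 1855 nt is not
divisible by 3 yet 619 aa is printed; 1857 nt would match) — downstream code
surfaces this as a divisibility warning rather than silently fixing it.
"""

from __future__ import annotations

import pandas as pd

from .genestruct import GeneModel

__all__ = ["papaya_arf_table", "papaya_arf_gene_models"]

_ROWS = [
    # name, locus, contig, start, end, strand, orf_len, introns, aa, mw_kda, pi, category, has_ctd
    ("CpARF1", "evm.TU.supercontig_9.161", "supercontig_9", 969763, 974848, "-", 2094, 13, 698, 77.67, 7.18, "repressor_with_CTD", True),
    ("CpARF2", "evm.TU.contig_31756.1", "contig_31756", 3939, 7439, "+", 1855, 11, 619, 68.86, 7.12, "repressor_no_CTD", False),
    ("CpARF3", "evm.TU.supercontig_7.3", "supercontig_7", 132322, 138926, "-", 2022, 10, 674, 73.19, 7.01, "repressor_no_CTD", False),
    ("CpARF4", "evm.TU.supercontig_139.80", "supercontig_139", 638531, 645762, "-", 2439, 11, 813, 89.78, 6.58, "repressor_with_CTD", True),
    ("CpARF5", "evm.TU.supercontig_26.24", "supercontig_26", 231561, 267729, "-", 2814, 13, 938, 103.7, 5.16, "activator", True),
    ("CpARF6", "evm.TU.supercontig_17.53", "supercontig_17", 617715, 620541, "-", 933, 8, 311, 34.83, 9.03, "dbd_only", False),
    ("CpARF7", "evm.TU.supercontig_261.2", "supercontig_261", 2520, 11208, "-", 2649, 12, 883, 97.65, 5.52, "activator", True),
    ("CpARF10", "evm.TU.supercontig_65.4", "supercontig_65", 11160, 14085, "-", 1944, 4, 648, 71.54, 7.06, "activator", True),
    ("CpARF11", "evm.TU.supercontig_96.40", "supercontig_96", 684489, 688508, "+", 2064, 13, 688, 76.05, 6.66, "repressor_with_CTD", True),
    ("CpARF16", "evm.TU.supercontig_53.88", "supercontig_53", 584129, 586644, "-", 2091, 2, 697, 76.94, 6.57, "activator", True),
    ("CpARF17", "evm.TU.supercontig_49.122", "supercontig_49", 862531, 867248, "-", 1809, 1, 603, 66.22, 6.51, "repressor_no_CTD", False),
]

_COLUMNS = [
    "name", "locus", "contig", "start", "end", "strand", "orf_len",
    "introns", "length_aa", "mol_wt_kda", "pi", "category", "has_ctd",
]


def papaya_arf_table() -> pd.DataFrame:
    """Published characterization table of the papaya ARF family."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def papaya_arf_gene_models() -> list[GeneModel]:
    """Gene models consistent with the published loci and intron counts.

    Exact exon boundaries are not published; each model places introns+1
    equal-sized exons separated by equal gaps inside the published genomic
    span, which preserves locus, strand, span, and intron count — everything
    the structure summary uses.
    """
    models = []
    for row in papaya_arf_table().itertuples(index=False):
        n_exons = row.introns + 1
        span = row.end - row.start + 1
        exon_len = max(1, span // (2 * n_exons))
        step = span // n_exons if n_exons > 1 else span
        exons = []
        for i in range(n_exons):
            s = row.start + i * step
            e = min(s + exon_len - 1, row.end)
            exons.append((s, e))
        exons[-1] = (exons[-1][0], row.end)
        models.append(
            GeneModel(
                gene_id=row.name,
                contig=row.contig,
                strand=row.strand,
                exons=exons,
                orf_len=row.orf_len,
            )
        )
    return models
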