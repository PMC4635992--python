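"""Protein characterization: deduced length, molecular weight, isoelectric
point, middle-region composition, and activator/repressor classification.

ARF transcription factors carry an N-terminal B3-like DNA-binding domain
(DBD), a middle region (MR) whose amino-acid composition determines whether
the protein activates (Q/S/L-rich) or represses (S/P/G/L-rich) transcription,
and usually a C-terminal dimerization domain (CTD) shared with Aux/IAA
proteins. This module computes the per-protein physico-chemical table and the
MR-based classification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io import DomainAnnotation

__all__ = [
    "ProteinRecord",
    "MrComposition",
    "ArfClassification",
    "FamilySummary",
    "OrfDivisibilityError",
    "deduced_length",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "extract_mr",
    "classify_arf",
    "family_summary",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "PKA_BJELLQVIST",
    "PKA_EMBOSS",
]

CATEGORIES = ("activator", "repressor_with_CTD", "repressor_no_CTD", "dbd_only")


class OrfDivisibilityError(ValueError):
    """ORF nucleotide length not divisible by 3; carries the remainder."""

    def __init__(self, orf_len: int, remainder: int):
        self.orf_len = orf_len
        self.remainder = remainder
        super().__init__(
            f"ORF length {orf_len} nt is not divisible by 3 "
            f"(remainder {remainder})"
        )


@dataclass
class ProteinRecord:
    id: str
    aa_seq: str
    orf_len: int | None = None
    domains: list[DomainAnnotation] = field(default_factory=list)

    def domain(self, domain_id: str) -> DomainAnnotation | None:
        hits = [d for d in self.domains if d.domain_id == domain_id]
        return min(hits, key=lambda d: d.start) if hits else None

    @property
    def length_consistent(self) -> bool | None:
        """True when orf_len = 3 x protein length (stop codon excluded)."""
        if self.orf_len is None:
            return None
        return self.orf_len == 3 * len(self.aa_seq)


@dataclass
class MrComposition:
    """Middle-region bounds (1-based inclusive) and residue frequencies."""

    protein_id: str
    mr_start: int
    mr_end: int
    freq: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.protein_id}: MR frequencies sum to {total}, not 1"
            )

    @property
    def length(self) -> int:
        return self.mr_end - self.mr_start + 1


@dataclass
class ArfClassification:
    protein_id: str
    category: str
    rule_score: float
    has_ctd: bool
    source: str = "rule"  # "rule" | "override"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class FamilySummary:
    n_activators: int
    n_repressors: int
    n_ctd_truncated: int
    n_total: int
    activator_repressor_ratio: float | None
    ctd_truncated_pct: float


def deduced_length(orf_len: int, round_remainder: bool = False) -> int:
    """Deduced polypeptide length from ORF nucleotide length.

    Convention: the ORF length excludes the stop codon, so the protein has
    exactly orf_len / 3 residues (e.g. a 2814-nt ORF encodes 938 aa). A
    non-divisible length raises :class:`OrfDivisibilityError` unless
    ``round_remainder`` is set, in which case floor division applies.
    """
    if orf_len <= 0:
        raise ValueError(f"ORF length must be positive, got {orf_len}")
    remainder = orf_len % 3
    if remainder and not round_remainder:
        raise OrfDivisibilityError(orf_len, remainder)
    return orf_len // 3


# Average (isotope-abundance-weighted) residue masses in daltons, i.e. the
# amino-acid mass minus one water; a chain of n residues weighs
# sum(residues) + one water (18.0153 Da).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


def molecular_weight(aa_seq: str) -> float:
    """Average molecular weight in daltons of an unmodified polypeptide."""
    if not aa_seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(aa_seq, 1):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"non-standard residue {aa!r} at position {pos}"
            ) from None
    return total


# Bjellqvist pKa set (the one ExPASy-style pI calculators use): side chains,
# plus residue-specific N-terminal pKa values. Swappable via the pka_set
# argument of net_charge / isoelectric_point.
PKA_BJELLQVIST = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm_by_residue": {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
        "V": 7.44, "E": 7.7,
    },
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}

# Simpler EMBOSS-style alternative (no residue-specific termini).
PKA_EMBOSS = {
    "positive": {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
    "negative": {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    "nterm_by_residue": {},
    "cterm_by_residue": {},
}


def _ionizable_groups(aa_seq: str, pka_set: dict) -> list[tuple[float, int, int]]:
    """(pKa, count, sign) triples for a sequence; sign +1 basic, -1 acidic."""
    counts = Counter(aa_seq)
    pos, neg = pka_set["positive"], pka_set["negative"]
    nterm_pka = pka_set.get("nterm_by_residue", {}).get(aa_seq[0], pos["Nterm"])
    cterm_pka = pka_set.get("cterm_by_residue", {}).get(aa_seq[-1], neg["Cterm"])
    groups = [(nterm_pka, 1, +1), (cterm_pka, 1, -1)]
    for aa, pka in pos.items():
        if aa != "Nterm" and counts[aa]:
            groups.append((pka, counts[aa], +1))
    for aa, pka in neg.items():
        if aa != "Cterm" and counts[aa]:
            groups.append((pka, counts[aa], -1))
    return groups


def net_charge(aa_seq: str, pH: float, pka_set: dict | None = None) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Basic groups contribute +1/(1+10^(pH-pKa)) each; acidic groups
    contribute -1/(1+10^(pKa-pH)). The function is strictly decreasing
    in pH, so the isoelectric point is a unique root.
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    charge = 0.0
    for pka, count, sign in _ionizable_groups(aa_seq, pka_set or PKA_BJELLQVIST):
        if sign > 0:
            charge += count / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= count / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(
    aa_seq: str,
    pka_set: dict | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, found by bisection on [0, 14]."""
    pka_set = pka_set or PKA_BJELLQVIST
    lo, hi = 0.0, 14.0
    c_lo = net_charge(aa_seq, lo, pka_set)
    c_hi = net_charge(aa_seq, hi, pka_set)
    if c_lo < 0:  # all-acidic edge: charge already negative at pH 0
        return lo
    if c_hi > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(aa_seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def extract_mr(protein: ProteinRecord) -> MrComposition | None:
    """Middle region: residues strictly after the DBD end and strictly before
    the CTD (AUX_IAA domain) start, or the sequence end when no CTD exists.

    Returns None (absent-MR marker) when the DBD abuts the CTD or the
    sequence end.
    """
    dbd = protein.domain("DBD")
    if dbd is None:
        raise ValueError(f"{protein.id}: no DBD annotation, cannot locate MR")
    ctd = protein.domain("AUX_IAA")
    mr_start = dbd.end + 1
    mr_end = (ctd.start - 1) if ctd is not None else len(protein.aa_seq)
    if mr_start > mr_end:
        return None
    segment = protein.aa_seq[mr_start - 1 : mr_end]
    n = len(segment)
    freq = {aa: c / n for aa, c in sorted(Counter(segment).items())}
    return MrComposition(protein.id, mr_start, mr_end, freq)


def classify_arf(
    mr: MrComposition | None,
    has_ctd: bool,
    override: str | None = None,
    protein_id: str | None = None,
) -> ArfClassification:
    """Activator/repressor call from MR composition and CTD presence.

    Rule: the MR is activator-type iff freq(Q) > freq(P) + freq(G) — the
    minimal monotone separator between Q/S/L-rich activator MRs and
    S/P/G/L-rich (or G-rich) repressor MRs once the shared S/L terms cancel.
    Repressors split by CTD presence; a protein with neither MR nor CTD is
    dbd_only. An override bypasses the rule (source="override").
    """
    pid = protein_id or (mr.protein_id if mr else "<unknown>")
    if override is not None:
        if override not in CATEGORIES:
            raise ValueError(
                f"{pid}: override names unknown category {override!r}"
            )
        return ArfClassification(pid, override, float("nan"), has_ctd, "override")
    if mr is None:
        if has_ctd:
            # no MR but a CTD: composition rule cannot fire; treat as
            # repressor_with_CTD (a CTD-bearing protein is never dbd_only)
            return ArfClassification(pid, "repressor_with_CTD", 0.0, True)
        return ArfClassification(pid, "dbd_only", 0.0, False)
    score = mr.freq.get("Q", 0.0) - mr.freq.get("P", 0.0) - mr.freq.get("G", 0.0)
    if score > 0:
        category = "activator"
    else:
        category = "repressor_with_CTD" if has_ctd else "repressor_no_CTD"
    return ArfClassification(pid, category, score, has_ctd)


def family_summary(
    classifications: list[ArfClassification],
    dbd_only_policy: str = "count_as_repressor",
) -> FamilySummary:
    """Family-level counts: activator/repressor ratio and CTD-truncated %.

    dbd_only proteins enter the repressor denominator under the default
    policy (``count_as_repressor``) or are excluded from the ratio entirely
    (``exclude``); they always count as CTD-truncated. With zero repressors
    the ratio is None, not a number.
    """
    if not classifications:
        raise ValueError("family_summary: no classifications supplied")
    if dbd_only_policy not in {"count_as_repressor", "exclude"}:
        raise ValueError(f"unknown dbd_only_policy {dbd_only_policy!r}")
    counts = Counter(c.category for c in classifications)
    n_act = counts["activator"]
    n_rep = counts["repressor_with_CTD"] + counts["repressor_no_CTD"]
    if dbd_only_policy == "count_as_repressor":
        n_rep += counts["dbd_only"]
    n_total = len(classifications)
    n_truncated = sum(1 for c in classifications if not c.has_ctd)
    ratio = (n_act / n_rep) if n_rep > 0 else None
    return FamilySummary(
        n_activators=n_act,
        n_repressors=n_rep,
        n_ctd_truncated=n_truncated,
        n_total=n_total,
        activator_repressor_ratio=ratio,
        ctd_truncated_pct=100.0 * n_truncated / n_total,
    )
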