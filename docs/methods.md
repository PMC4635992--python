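# Methods

This note documents the models and conventions implemented in `arffam`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Family identification

Candidates are selected from an externally produced domain-annotation table
(InterProScan-style TSV mapped through Pfam accessions PF02362 → DBD,
PF06507 → AUX_RESP, PF02309 → AUX_IAA). The retention rule is: **≥ 1 DBD and
(≥ 1 AUX_RESP or an allow-list entry)**. Aux/IAA-only architectures fail the
DBD requirement and are excluded with a reason. DBD-only proteins are
excluded by default and admitted only via the allow-list: genuine but
severely truncated family members exist, yet admitting every stray B3 domain
would flood the family with RAV/B3-superfamily false positives. Homology
search and domain scanning themselves (BLAST/HMMER/InterProScan) are out of
scope; the package consumes their tabular output.

Exact duplicate sequences are collapsed to the lexicographically smallest id
(deterministic, idempotent). Naming follows the nearest reference-species
homolog: a focal leaf in a cherry with a reference leaf inherits that leaf's
numeric suffix; otherwise the minimum-patristic-distance reference decides,
with distance ties resolved toward the lowest-numbered reference and name
collisions disambiguated by appended letters.

## Protein characterization

**Deduced length.** The convention `length_aa = orf_len / 3` (stop codon not
counted in the ORF) is fixed because it reproduces the published anchor
values exactly (2814 → 938, 933 → 311). Non-divisible ORF lengths raise an
error carrying the remainder; callers may round explicitly. One row of the
bundled published table (ORF 1855 nt vs 619 aa) is internally inconsistent
and is deliberately surfaced as that error rather than silently repaired.

**Molecular weight** is the sum of average (isotope-weighted) residue masses
plus one water (18.0153 Da). The mass table is in
`arffam.protchar.AVERAGE_RESIDUE_MASS`; additivity
MW(s₁s₂) = MW(s₁) + MW(s₂) − 18.0153 holds to 10⁻⁶ Da and the values agree
with Biopython's independent average-mass computation to < 10⁻⁴ relative.

**Isoelectric point** is the unique root of the Henderson–Hasselbalch net
charge, found by bisection on pH ∈ [0, 14] to 10⁻⁴ pH. Basic groups
(N-terminus, K, R, H) contribute +1/(1+10^(pH−pKa)); acidic groups
(C-terminus, D, E, C, Y) contribute −1/(1+10^(pKa−pH)); the function is
strictly decreasing in pH so bisection cannot miss. The default pKa set is
the Bjellqvist table (the one ExPASy-style calculators use, including the
residue-specific N/C-terminal values); an EMBOSS-style set ships as an
alternative and any table of the same shape can be passed in. Because
published pI values depend on the (unnamed) tool that produced them,
two-decimal agreement with any particular published table is treated as
pKa-set-dependent; the package's own correctness is established against a
10⁻⁵-step pH grid scan and against Biopython inside its search bracket.

**MR classification.** The middle region is everything strictly after the
DBD end and strictly before the CTD (AUX_IAA domain) start, or the sequence
end when no CTD exists; an empty MR returns an absent marker. "Q/S/L-rich"
versus "S/P/G/L-rich" was never quantified in the literature this models, so
the classifier uses the minimal monotone separator consistent with those
descriptions once the shared S/L terms cancel: **activator iff
freq(Q) > freq(P) + freq(G)**. Repressors split into CTD-bearing and
CTD-truncated; a protein with neither MR nor CTD is `dbd_only`. An override
table bypasses the rule (flagged `source="override"`) so published
assignments are reproducible regardless of the rule's behaviour on edge
cases.

**Family summary.** The activator/repressor ratio counts `dbd_only` members
in the repressor denominator by default — the only reading under which the
published 11-member family gives 4/7 = 0.57 — with an `exclude` policy
available. CTD-truncated percentage counts every member lacking a CTD,
whatever its category. Zero repressors yield an undefined (None) ratio, not
a number.

## Gene structure

Introns are defined purely as gaps between consecutive exons (UTR introns
count; the modelled analyses do not distinguish CDS from UTR introns), so
`intron_count = n_exons − 1`. Drawing tracks are produced in transcript
orientation: minus-strand models are reversed so offset 0 is the
transcription start; box lengths equal exon lengths and segment lengths
intron lengths. GFF3 coordinates stay 1-based inclusive end to end.

## Phylogeny

Distances use **pairwise deletion**: per pair, p = mismatches / shared
ungapped columns; the Poisson correction −ln(1 − p) is the default model
(a common protein-distance default; the choice is configurable because the
modelled analysis names only "neighbor-joining"). Poisson is undefined at
p = 1 and errors with a pointer to p-distance.

**Neighbor joining** is the classic Saitou–Nei algorithm: join the pair
minimizing Q(i,j) = (m−2)d(i,j) − Rᵢ − Rⱼ; new distances
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2; branch lengths from the standard
formulas with negative estimates clamped to zero (logged). NJ
implementations differ in tie handling, so ties on Q are broken by the
lexicographically smallest (sorted) pair of cluster labels, a cluster's
label being its smallest leaf id — this makes trees reproducible, which the
bootstrap and the tests rely on. On additive matrices NJ is exact; the test
suite verifies this against an exhaustive-topology least-squares oracle for
≤ 6 taxa and by re-inducing input matrices.

**Bootstrap** is the standard Felsenstein procedure: columns resampled with
replacement, NJ per replicate, support of each *original-tree* bipartition =
percentage of replicates containing it (no consensus tree). Degenerate
replicates (no variation, or saturated Poisson distances) are skipped with a
log message. **Sister pairs** are cherries — two leaves joined to the same
internal node of the unrooted tree — whose leaves belong to different
species and whose separating-edge support meets the threshold (default
99 %). **Group assignment** roots the tree at its stored degree-3 node and
walks each unlabelled leaf rootward; the first ancestor containing reference
leaves decides (homogeneous → that group, mixed → `unplaced`). The arbitrary
rooting can only affect leaves whose placement is ambiguous anyway.

## Motif scanning

IUPAC patterns are Cartesian-expanded (V = A/C/G, Y = C/T, S = C/G, …) and
matched at every offset; overlapping hits are all reported. Default strand
mode is **both**, since AuxREs act on either strand and the modelled
protocol gives no strand convention; reverse-strand hits are matches of the
pattern's reverse complement against the forward string, reported at forward
offsets with strand "−". Coordinates are 0-based on the promoter string
(offset 0 = position −1500 for a 1500-bp promoter); BED export is 0-based
half-open. The canonical presets are AUX1 = TGTCTC and AUX2 = TGTVYS; an
alternative published variant set (AUX1 = TGTGTC, and an AUX2 whose fourth
position is a non-IUPAC placeholder, read here as N — the least restrictive
reading) ships as the `figure7` preset. Note TGTCTC itself matches TGTVYS,
so every AUX1 site is also an AUX2 site; summaries therefore count hits per
motif id and a per-gene `has_any` flag rather than assuming disjoint sets.

## Expression

ΔCt = ct_target − ct_reference is computed **per replicate index** (paired;
an unpaired mode uses the reference mean) and 2^−ΔΔCt uses the difference of
replicate-mean ΔCt values — i.e. a geometric replicate mean, which
coincides with the ratio of reference-scaled expressions whenever replicates
agree. Reference-scaled expression is scale × 2^−ΔCt per replicate, mean and
SD over replicates (scale default 1000: a target as abundant as the
reference reads 1000). Significance uses the fixed **2× rule**, boundary
inclusive (fold ≥ 2 up, ≤ 0.5 down); a Welch t-test on replicate ΔCt values
is available as secondary evidence only, since the modelled protocol defines
significance by the fold rule and does not name its test. Heatmap matrices
are row-anchored log2 ratios to the row maximum (row max exactly 0, all
entries ≤ 0); zeros get a pseudocount of 10⁻³ × the row's smallest positive
value, and an all-zero row errors with the gene name. Abundance shares and
tissue specificity use a 0.5 share threshold by default. Primer-efficiency
correction and multi-reference normalization are out of scope.

## Synthetic data

`simulate_family` is a pure function of (parameters, seed) — bundles are
byte-identical across runs. Its defaults are the study conditions the
package models: 11 focal genes with the published category/intron
configuration (4 activators, 3 + 3 repressors, 1 DBD-only admitted by
allow-list), 23 + 25 reference homologs, 7 planted focal/At cherries and no
focal/Os cherries, 27 promoters of reproduction-related genes with AuxREs
planted in 16, and four five-replicate Ct tables (tissues, 8 flower stages,
3 sex types, 6 fruit stages) with planted expression levels reflecting the
reported qualitative patterns. The flower-stage profile of the DBD-only gene
rises to 8× its stage-1 level by stage 8 (peaking at stage 7) — comfortably
past the more-than-six-fold mark so that five-replicate Ct noise (default
SD 0.15 cycles, a typical qPCR replicate spread) cannot drag the estimate
below it.

Protein evolution on the true tree uses a 20-state uniform-replacement
(Jukes–Cantor-style) model: per branch of length t each site changes with
probability (19/20)(1 − e^(−20t/19)), so expected p-distances equal path
lengths in the small-rate limit. Empirical substitution matrices (JTT etc.),
indels and alignment uncertainty are deliberately not modelled — the evolved
alignment is gap-free. Planted cherries use tip branches of 0.03 and stems
of 0.20 substitutions/site over 500 columns, which makes their bootstrap
support effectively 100 %.

MR composition is sampled from target frequency vectors (activator: Q 0.22,
S 0.14, L 0.12, P 0.04, G 0.04; repressor: Q 0.05, S 0.16, P 0.13, G 0.13,
L 0.12) and **resampled until the realized margin |f(Q) − f(P) − f(G)|
reaches the configured minimum (0.02)**, so classifier recovery of planted
labels is exact by construction rather than probabilistic. Promoter
backgrounds are uniform-composition (not GC-matched) and are locally
resampled until scanning finds no match outside the planted windows —
exactness beats realism for recovery tests. Ct tables draw reference Ct
around a baseline of 20 cycles and target Ct = baseline − log2(level), both
with Gaussian replicate noise.

Consequently, passing tests demonstrate that every pipeline stage recovers
its planted ground truth under the stated noise models; they do not
demonstrate robustness to real-data pathologies (alignment error, indels,
paralog misannotation, primer-efficiency drift, GC-biased promoter
composition).

## Problem sizes and numerics

Default analyses run on one CPU in seconds to tens of seconds: the 59-taxon,
500-column bootstrap does 1000 NJ replicates in roughly ten seconds; the
acceptance script completes in under a minute. Bisection tolerance for pI is
10⁻⁴ pH; distance matrices are symmetrized against float noise and NJ
tolerates triangle-inequality violations (they are only logged). Branch
lengths are clamped at zero rather than redistributed. The reported
activator/repressor ratio and CTD-truncated percentage are rounded to the
two printed figures (0.57, 36.4 %) only at the reporting boundary; internal
values stay exact fractions (4/7, 4/11).
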