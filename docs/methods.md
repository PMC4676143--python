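# Methods

This note documents the models and rules `spfam` implements, the
parameters that matter, the synthetic-data generator's scope, and the
numerical choices made where the design was genuinely open.

## Catalytic-triad detection and SP/SPH classification

Chymotrypsin-family proteases carry a His/Asp/Ser catalytic triad whose
residues sit in strongly conserved sequence contexts, conventionally
written TAAHC, DIAL and GDSGGP. Exact-string matching would miss real
family members, so each motif is a positional residue-class profile
anchored on the catalytic residue:

| motif | profile (anchor in bold) | default classes |
|-------|--------------------------|-----------------|
| His   | [ST]-[AG]-[AG]-**H**-C  | TAAHC-like      |
| Asp   | **D**-[IVLM]-[AG]-[LIVM] | DIAL-like      |
| Ser   | G-[DN]-**S**-G-[GS]-[PSA] | GDSGGP-like   |

A profile *hit* requires every non-anchor position to match its class;
the anchor itself is free, and the hit is *intact* iff the anchor holds
the catalytic residue. This two-level rule lets the scanner both find
intact triads and locate the degenerate motif of a homolog whose
catalytic residue has mutated away. The ambiguity code X matches no
position. Triads are assembled left to right with His < Asp < Ser
ordering, preferring intact components, with the His–Ser distance
bounded in [20, 300] residues; a protein is an SP iff at least one
assembled triad is complete, otherwise an SPH. The Tryp_SPc span is
estimated from the anchors (45 residues upstream of His — the
activation motif sits ~41 residues before the catalytic His in
chymotrypsinogen numbering — to 35 downstream of Ser).

## Clip-domain grammar

Clip domains are N-terminal regulatory modules with six conserved
cysteines forming three disulfides, Cys-5 and Cys-6 adjacent. Detection
enumerates six-cysteine placements in the region N-terminal to the
first catalytic domain that satisfy the spacing grammar (residues
strictly between consecutive cysteines):

* s12 ∈ [2, 10]; s23 = 5 (override available, e.g. [4, 6], for taxa
  outside the observed family); s34 ∈ [8, 26]; s45 ∈ [2, 20]
  (never reported in the source family; bounds chosen to cover both
  group geometries while keeping the span bound binding); s56 = 0;
* Cys-1..Cys-6 span (strictly-between count) ∈ [37, 55], the family
  range documented for insect clip domains.

Overlapping candidate placements are resolved leftmost-first,
non-overlapping, so a protein with two cassettes reports both. Group
assignment uses the Cys-3..Cys-4 spacing: group 1 for 8–17, group 2 for
22–26, otherwise unassigned (the gap between the ranges is real, not an
error). Widening any interval can only add placements, never remove
one (monotonicity, covered by a test).

## S1-pocket typing and activation sites

Substrate specificity is read at chymotrypsinogen-numbering positions
189, 216, 226. The numbering anchor is a packaged bovine
chymotrypsinogen A sequence (245 residues) with those positions
annotated in a JSON sidecar. A query domain is globally aligned to the
anchor (BLOSUM62; gap open 10, extend 0.5 — ClustalX-era defaults,
overridable) and the residues opposite the key positions are reported;
a gap reads as `-`, and a query covering < 50% of the reference is
unassigned with a warning. The pure classification rule is then:
trypsin iff (D189, G216, 226 ∈ {G,A,S}); chymotrypsin iff 189 ∈ {S,T,G}
with the same 216/226 constraint (the strictest reading of the
published rule — the chymotrypsin 216/226 constraints are not fully
enumerated anywhere, so anything looser is left to configuration);
otherwise "other".

Activation sites: the scanner looks for the motif family
`[IVLF]-[IVLN]-[GN]-G` (admitting the reported variants IVGG, IIGG,
IING and conservative neighbors) in a window from 30 residues upstream
of the domain start to 10 into it, keeping the match closest to the
domain start — zymogen activation cleaves immediately before the mature
domain, so proximity, not leftmost order, is the right tiebreak. The
preceding (P1) residue gives the cascade position: {R, K} terminal,
{L, H, S} penultimate, anything else unassigned.

## Tandem duplication and gene structure

Tandem duplication is a gene-count rule, not a distance rule: two
family genes on one scaffold are linked when at most `max_intervening`
(default 5) annotated genes lie strictly between their spans, counting
distinct gene ids of any family; clusters are connected runs of linked
pairs, singletons excluded. Homology defaults to family co-membership
(the inputs are already family members); an optional percent-identity
threshold over global alignment (default 40%) supports mixed gene sets.
Orientation is reported, not required — shared orientation within a
cluster is an observation, not part of the rule. Intron phase i is the
cumulative CDS length of exons 1..i mod 3, with exons taken in
transcription order (minus-strand genes reversed).

## Alignment, distances, trees

Pairwise global alignment delegates to Biopython's `PairwiseAligner`
(BLOSUM62, affine gaps: a gap of length L costs 10 + 0.5·(L−1));
tie-breaking among co-optimal alignments follows the engine's
deterministic canonical path order, and alignment *scores* — the
contract the oracle tests check — are tie-independent. The progressive
MSA builds a guide tree by average linkage over pairwise identity
distances (1 − pid/100) and merges profiles bottom-up with a
profile-profile Needleman–Wunsch over column frequency vectors (linear
gap cost 4 per column); every row de-gaps to its input sequence by
construction.

Percent identity uses the pairwise-deletion denominator (columns where
neither sequence is gapped); "similarity" additionally counts
substitutions within the groups {AVLIM}, {FWY}, {ST}, {KRH}, {DENQ},
{C}, {G}, {P}. Both modes exist because published similarity
percentages rarely state their measure.

Evolutionary distances use the Poisson correction d = −ln(1 − p) with p
the differing fraction over pairwise-deleted columns (gaps and X
excluded per pair); saturated pairs (p ≥ 1) are flagged infinite and
rejected by tree building, and a pair with no shared columns is a hard
error. Neighbor joining is the standard Saitou–Nei agglomeration with
the Q-criterion; taxa are sorted lexicographically on entry and exact Q
ties resolve to the smallest id pair, so topology is invariant to input
order. Negative branch-length estimates are clamped to zero with the
total deficit recorded on the tree. Bootstrap resamples alignment
columns with replacement (numpy generator seeded explicitly), recomputes
distance + NJ per replicate, and reports each original internal
bipartition's replicate frequency as a percentage; replicates whose
resampled columns saturate are skipped. Newick export labels supports
≥ 50% by default, matching the usual figure convention.

## Expression

log2 transformation maps RPKM > 0 to log2(RPKM) and RPKM = 0 to
*missing* — an unexpressed gene has no meaningful log abundance and is
rendered gray in the usual heat-map convention; missing stays missing.
Gene clustering is complete linkage over Euclidean distances computed
on mutually present columns and rescaled by (total/present) — the
Cluster 3.0 convention for missing data. Genes with all-missing rows
(silent everywhere) are excluded with a warning. "Expressed" means
RPKM strictly greater than a threshold whose default is 0; the
published counts never state their criterion, so the threshold is
explicit and configurable. qPCR normalisation averages replicate Ct
values per gene × sample and reports 2^(−ΔCt) against the housekeeping
reference (optionally 2^(−ΔΔCt) against a calibrator sample).

## Synthetic-data generator

The generator's defaults are the study conditions: 221 genes = 120 SP +
101 SPH; 38 trypsins and 8 chymotrypsins among the SPs; 10 clip-bearing
SPs and 3 clip-bearing SPHs, one SP with two clip domains (14 domains:
5 group 1, 9 group 2, sampled spans 43–53); activation-motif variants
IIGG/IING and unusual Tyr/Phe P1 residues planted at the trypsin
indices where they were observed; a scaffold layout with trypsin
clusters of sizes 5/5/4/4/2 (20 of 38 trypsins clustered) plus 31
further clusters — 36 clusters and 122 tandem genes, two clusters
sharing one scaffold; stage expression in three blocks (larva-high,
egg+pupa-high, adult-male-specific) over samples E, L1–L4, P, AM, AF
with 25 silent genes; tissue expressed-gene sets of sizes
161/148/130/140 whose union is exactly the 196 expressed genes.

Each protein is assembled from a domain template derived from the
packaged chymotrypsinogen anchor. Three constructions keep the truth
labels unambiguous, which is what makes exact-recovery testing sound:

* the template's Asp-motif context is set to an exact DIAL (the real
  bovine context, D-I-T-L, does not match the Asp profile — the
  template is a synthetic scaffold, the packaged reference stays real);
* linker/background residues are drawn from a fixed cysteine-free
  composition table, so the only cysteines upstream of the catalytic
  domain are planted clip cassettes;
* after assembly, unplanned intact matches of any catalytic-motif
  profile, unplanned located His-profile matches, and unplanned
  IVGG-like matches near the domain start are neutralised by a
  deterministic single-residue substitution.

SPH knockouts replace exactly one catalytic anchor with a recorded
residue; planted positions (motifs, pocket, activation, clip
cysteines) are never touched by the background mutation process
(default per-residue rate 0.05 on the domain). All randomness flows
from one integer seed through `numpy.random.default_rng`.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: hierarchical sequence evolution (members
diverge independently from one template, so phylogenies of the
synthetic family are star-like and bootstrap supports on deep edges are
legitimately low), signal peptides and propeptide processing, accessory
domains (LDLA/FRI/SR), nucleotide-level gene models, codon usage, and
read-level RNA-seq noise. Real families also contain members whose
motifs drift outside any fixed profile; sensitivity on real data is
bounded by the profile configuration, not by these tests.

## Numerical and design choices

* Coordinates are GFF 1-based inclusive at every interface; residue
  positions in annotations are 0-based half-open internally and
  reported as such in the clip span strings.
* The clip span bound applies to the strictly-between residue count;
  an inclusive-endpoint reading can be had by widening the configured
  interval by 2.
* NJ's Q matrix is evaluated on the upper triangle only: Q is
  mathematically symmetric but floating-point subtraction order makes
  the computed matrix asymmetric at the last ulp.
* Degenerate inputs fail loudly: duplicate FASTA ids, empty sequences,
  orphan CDS records, negative RPKM, ragged TSV rows, missing qPCR
  reference, infinite distances into NJ, < 3 taxa.
* Problem sizes used by the analysis scripts and acceptance run —
  221-gene family, 100 random 5–8-taxon additive matrices, 200
  bootstrap replicates in the phylogeny driver — are the package's own
  desk-scale defaults; the bootstrap default in the library remains
  1000 replicates.

## Known limitations

* The motif profiles encode one conservative reading of the conserved
  contexts; highly diverged true SPs can be missed (reported SPH), and
  the trypsin/chymotrypsin rule ignores pocket positions beyond
  189/216/226.
* The progressive MSA is a straightforward profile aligner without
  iterative refinement; for publication-grade alignments of real data
  a dedicated aligner is preferable, with the rest of the pipeline
  unchanged.
* Clip detection assumes the clip lies N-terminal to the catalytic
  domain; inter-domain clips in unusual architectures are out of scope.
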