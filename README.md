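# spfam

Annotation and expression analysis of insect serine-protease gene
families: serine proteases (SPs) and serine-protease homologs (SPHs).

Insect genomes carry large chymotrypsin-family (clan PA, S1) gene
families whose members act in digestion, development and innate
immunity. `spfam` re-implements the standard genome-wide workflow for
such a family as a single testable pipeline:

* **SP vs SPH classification** from the catalytic triad His/Asp/Ser,
  located by fuzzy profiles anchored in the conserved contexts
  `TAAHC`, `DIAL` and `GDSGGP`. A member with all three catalytic
  residues intact is an SP; any knockout makes it an SPH.
* **Clip-domain detection** by the six-cysteine spacing grammar
  (Cys-5/Cys-6 adjacent, Cys-2..Cys-3 spacing of 5, Cys-1..Cys-6 span
  37–55 residues), with group 1 vs group 2 assignment from the
  Cys-3..Cys-4 spacing (8–17 vs 22–26 residues).
* **Substrate-specificity typing** from the S1 pocket read at positions
  189/216/226 (chymotrypsinogen numbering, via global alignment to a
  packaged bovine chymotrypsinogen A anchor): Asp189 + Gly216 +
  Gly/Ala/Ser226 → trypsin; Ser/Thr/Gly at 189 → chymotrypsin.
* **Activation sites**: the IVGG-like motif at the mature N-terminus
  and its P1 residue, giving the cascade position (Arg/Lys = terminal,
  Leu/His/Ser = penultimate).
* **Tandem-duplication clusters**: neighboring family genes on one
  scaffold with ≤ 5 annotated genes between them, plus exon–intron
  structure with intron phases (cumulative CDS length mod 3).
* **Phylogenetics**: progressive MSA, Poisson-corrected distances
  d = −ln(1 − p) with pairwise deletion of gaps, Saitou–Nei
  neighbor joining, column-resampling bootstrap.
* **Expression**: log2-RPKM transformation (zeros → missing),
  hierarchical clustering with Euclidean distance and complete linkage,
  expressed-gene counts per sample, and qPCR ΔCt normalisation against
  a housekeeping gene.

A first-class synthetic-data generator (`spfam.synth`) builds families
with planted triads, pockets, clips, scaffold layouts and expression
blocks together with a ground-truth manifest, so every stage is
verifiable end to end without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
seed-fixed synthetic family and write their tables under `results/`:

```bash
python analysis/01_simulate_family.py
python analysis/02_annotate_family.py
python analysis/03_tandem_layout.py
python analysis/04_phylogenetics.py
python analysis/05_expression_profiles.py
```

which prints:

```
family: 221 genes = 120 SP + 101 SPH; 38 trypsins, 8 chymotrypsins; 13 clip-bearing genes with 14 clip domains
annotated 221 genes: 120 SP / 101 SPH, 38 trypsin, 8 chymotrypsin, 13 clip-bearing (14 clip domains)
label disagreements with the planted truth: 0
122 of 221 genes fall in 36 tandem clusters on 35 scaffolds
trypsins: 20/38 clustered (52.6%)
36/36 clusters structurally homogeneous
stage clustering: k=3 groups match the planted larva-high / egg+pupa / adult-male blocks (196 genes clustered, 25 silent genes excluded)
expressed genes per tissue: MG_L4=161, HD_L4=148, HD_AM=130, HD_AF=140; 196 of 221 genes expressed in at least one tissue
```

Reading the output: the generator plants a family at a realistic
genome-wide composition; the annotation stage recovers every planted
class, subtype, clip domain and activation call with zero errors; the
tandem rule finds exactly the planted clusters (52.6% of trypsins
clustered); and cutting the expression dendrogram at k = 3 separates
the three planted stage-expression groups, with silent (all-zero) genes
excluded as missing after the log2 transform.

The same stages are available as a CLI (`spfam annotate`, `spfam
layout`, `spfam phylo`, `spfam expr`, `spfam make-fixtures`) for use on
real FASTA/GFF3/TSV inputs; `scripts/supplementary_recompute.py`
applies the rules to an externally supplied family FASTA, gene-position
table and RPKM matrix.

## Layout

```
src/spfam/        library: seqio, domain_scan, specificity,
                  genome_layout, align_phylo, expression, synth,
                  pipeline, cli (+ packaged reference data)
analysis/         numbered drivers reproducing the study on synthetic data
tests/            pytest suite with independent oracles
scripts/          acceptance.py, supplementary_recompute.py
docs/methods.md   models, parameters, numerical choices, limitations
```
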