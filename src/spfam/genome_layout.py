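"""Tandem-duplication clusters and exon-intron structure.

Tandem duplication is called when neighboring homologous genes sit on a
single scaffold with at most five (configurable) annotated genes between
them; connected runs of such pairs form clusters.  Intron phases follow
the codon convention: phase of intron i = cumulative CDS length of the
exons upstream of it, mod 3.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align_phylo import AlignParams, global_align, percent_identity
from .seqio import GeneModel, ProteinRecord

__all__ = [
    "TandemCluster",
    "GeneStructure",
    "ConsistencyReport",
    "tandem_clusters",
    "intron_phases",
    "cluster_consistency",
]


@dataclass(frozen=True)
class TandemCluster:
    scaffold: str
    members: tuple[str, ...]              # gene ids ordered by start coordinate
    intervening_counts: tuple[int, ...]   # non-family genes between consecutive members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneStructure:
    gene_id: str
    exon_count: int
    intron_phases: tuple[int, ...]


def intron_phases(gene: GeneModel) -> GeneStructure:
    """Intron phases from exon lengths in transcription order."""
    phases = []
    cum = 0
    lengths = gene.exon_lengths
    for L in lengths[:-1]:
        cum += L
        phases.append(cum % 3)
    return GeneStructure(
        gene_id=gene.gene_id, exon_count=len(lengths), intron_phases=tuple(phases)
    )


def _count_between(
    left: GeneModel, right: GeneModel, others: list[GeneModel]
) -> int:
    """Distinct genes whose span lies strictly between two members' spans."""
    ids = {
        g.gene_id
        for g in others
        if g.start > left.end and g.end < right.start
    }
    return len(ids)


def tandem_clusters(
    family_genes: set[str],
    all_genes: list[GeneModel],
    max_intervening: int = 5,
    identity_threshold: float | None = None,
    sequences: dict[str, str] | None = None,
    params: AlignParams | None = None,
) -> list[TandemCluster]:
    """Find tandem-duplication clusters of family genes on scaffolds.

    Consecutive family genes on a scaffold are linked when the number of
    intervening non-family genes is <= max_intervening; clusters are
    connected runs of linked pairs (singletons excluded).  Homology
    defaults to family co-membership; passing ``identity_threshold``
    (percent) with a ``sequences`` map additionally requires that global
    percent identity between the pair meet the threshold.
    """
    by_id = {g.gene_id: g for g in all_genes}
    missing = family_genes - set(by_id)
    if missing:
        raise ValueError(f"family gene ids absent from gene models: {sorted(missing)}")
    if identity_threshold is not None and sequences is None:
        raise ValueError("identity_threshold requires a sequences map")

    def homologous(a: str, b: str) -> bool:
        if identity_threshold is None:
            return True
        aln = global_align(
            ProteinRecord(id=a, sequence=sequences[a]),
            ProteinRecord(id=b, sequence=sequences[b]),
            params,
        )
        return percent_identity(aln).iloc[0, 1] >= identity_threshold

    scaffolds: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        scaffolds.setdefault(g.scaffold, []).append(g)

    clusters: list[TandemCluster] = []
    for scaffold in sorted(scaffolds):
        genes = sorted(scaffolds[scaffold], key=lambda g: (g.start, g.gene_id))
        fam = [g for g in genes if g.gene_id in family_genes]
        non_fam = [g for g in genes if g.gene_id not in family_genes]
        run: list[str] = []
        counts: list[int] = []
        def flush() -> None:
            if len(run) >= 2:
                clusters.append(
                    TandemCluster(
                        scaffold=scaffold,
                        members=tuple(run),
                        intervening_counts=tuple(counts),
                    )
                )
            run.clear()
            counts.clear()
        for prev, cur in zip(fam, fam[1:]):
            between = _count_between(prev, cur, non_fam)
            linked = between <= max_intervening and homologous(prev.gene_id, cur.gene_id)
            if linked:
                if not run:
                    run.append(prev.gene_id)
                run.append(cur.gene_id)
                counts.append(between)
            else:
                flush()
        flush()
    return clusters


@dataclass(frozen=True)
class ConsistencyReport:
    """Structural homogeneity of a tandem cluster."""

    same_orientation: bool
    same_exon_count: bool
    same_intron_phases: bool
    mean_similarity: float | None


def cluster_consistency(
    cluster: TandemCluster,
    structures: dict[str, GeneStructure],
    orientations: dict[str, str],
    similarities: dict[frozenset, float] | None = None,
) -> ConsistencyReport:
    """Flag shared orientation / exon count / phase vector; report mean
    pairwise similarity when supplied."""
    members = cluster.members
    strands = {orientations[m] for m in members}
    exon_counts = {structures[m].exon_count for m in members}
    phase_vecs = {structures[m].intron_phases for m in members}
    mean_sim = None
    if similarities is not None:
        pairs = [
            frozenset((a, b))
            for i, a in enumerate(members)
            for b in members[i + 1:]
        ]
        vals = [similarities[p] for p in pairs]
        mean_sim = sum(vals) / len(vals) if vals else None
    return ConsistencyReport(
        same_orientation=len(strands) == 1,
        same_exon_count=len(exon_counts) == 1,
        same_intron_phases=len(phase_vecs) == 1,
        mean_similarity=mean_sim,
    )
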