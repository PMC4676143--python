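"""Stage orchestration: annotate, layout, phylo, expr.

Each function is a pure function of (inputs, config) and returns
in-memory results; the ``write_*`` helpers emit TSV/JSON/Newick files
with a provenance header (version, config hash, seed) so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align_phylo import (
    Alignment,
    AlignParams,
    DistanceMatrix,
    Tree,
    bootstrap_support,
    poisson_distance,
    progressive_msa,
)
from .domain_scan import (
    DEFAULT_GRAMMAR,
    ClipGrammar,
    classify_sp_sph,
    detect_clip_domains,
    find_triad_motifs,
)
from .expression import ClusterResult, expressed_counts, hcluster_genes, log2_transform
from .genome_layout import (
    TandemCluster,
    cluster_consistency,
    intron_phases,
    tandem_clusters,
)
from .seqio import ExpressionMatrix, GeneModel, ProteinRecord
from .specificity import find_activation_site, read_pocket

__all__ = [
    "RunConfig",
    "annotate",
    "layout",
    "phylo",
    "expr",
    "write_annotation",
    "write_layout",
]


@dataclass(frozen=True)
class RunConfig:
    grammar: ClipGrammar = DEFAULT_GRAMMAR
    align: AlignParams = AlignParams()
    max_intervening: int = 5
    bootstrap_replicates: int = 1000
    expression_threshold: float = 0.0
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"# spfam {__version__} config={config.hash()} seed={config.seed}\n"
    )


# ---------------------------------------------------------------------------
# annotate

def annotate(
    records: list[ProteinRecord], config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full per-gene annotation: SP/SPH class, triad status, clip domains
    and groups, S1-pocket subtype, activation site."""
    config = config or RunConfig()
    if not records:
        raise ValueError("no protein records to annotate")
    rows = []
    for rec in sorted(records, key=lambda r: r.id):
        triads = find_triad_motifs(rec)
        clips = detect_clip_domains(rec, triads, config.grammar)
        cls = classify_sp_sph(rec, triads, clips)
        status = triads[0].status if triads else (False, False, False)
        subtype = pocket = None
        if cls.cls == "SP":
            span = next(t for t in triads if t.complete).span
            call = read_pocket(rec, span=span, params=config.align)
            subtype = call.subtype
            pocket = (call.res189, call.res216, call.res226)
        act = (
            find_activation_site(rec, triads[0].span)
            if triads
            else None
        )
        rows.append(
            {
                "gene_id": rec.id,
                "class": cls.cls,
                "n_trypsp": cls.trypsp_count,
                "his_intact": status[0],
                "asp_intact": status[1],
                "ser_intact": status[2],
                "subtype": subtype,
                "res189": pocket[0] if pocket else None,
                "res216": pocket[1] if pocket else None,
                "res226": pocket[2] if pocket else None,
                "n_clips": len(clips),
                "clip_spans": ";".join(
                    f"{c.start}-{c.end}" for c in clips
                ) or None,
                "clip_groups": ";".join(c.group for c in clips) or None,
                "activation_motif": act.motif if act else None,
                "p1_residue": act.p1_residue if act else None,
                "cascade_position": act.cascade_position if act else None,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    summary = {
        "n_genes": len(table),
        "n_sp": int((table["class"] == "SP").sum()),
        "n_sph": int((table["class"] == "SPH").sum()),
        "n_trypsin": int((table["subtype"] == "trypsin").sum()),
        "n_chymotrypsin": int((table["subtype"] == "chymotrypsin").sum()),
        "n_clip_genes": int((table["n_clips"] > 0).sum()),
        "n_clip_domains": int(table["n_clips"].sum()),
    }
    return table, summary


def write_annotation(
    table: pd.DataFrame, summary: dict, out_dir: str | Path,
    config: RunConfig | None = None,
) -> None:
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "annotation.tsv", "w") as fh:
        fh.write(_header(config))
        table.to_csv(fh, sep="\t")
    (out / "annotation_summary.json").write_text(
        json.dumps({"config": config.hash(), "seed": config.seed, **summary}, indent=1)
    )


# ---------------------------------------------------------------------------
# layout

def layout(
    family_ids: set[str],
    models: list[GeneModel],
    config: RunConfig | None = None,
) -> tuple[list[TandemCluster], pd.DataFrame]:
    """Tandem clusters plus a per-cluster consistency report."""
    config = config or RunConfig()
    clusters = tandem_clusters(
        family_ids, models, max_intervening=config.max_intervening
    )
    by_id = {m.gene_id: m for m in models}
    rows = []
    for k, cl in enumerate(clusters, start=1):
        structures = {m: intron_phases(by_id[m]) for m in cl.members}
        orientations = {m: by_id[m].strand for m in cl.members}
        rep = cluster_consistency(cl, structures, orientations)
        rows.append(
            {
                "cluster": k,
                "scaffold": cl.scaffold,
                "size": len(cl),
                "members": ";".join(cl.members),
                "intervening": ";".join(map(str, cl.intervening_counts)),
                "same_orientation": rep.same_orientation,
                "same_exon_count": rep.same_exon_count,
                "same_intron_phases": rep.same_intron_phases,
            }
        )
    return clusters, pd.DataFrame(rows)


def write_layout(
    report: pd.DataFrame, out_dir: str | Path, config: RunConfig | None = None
) -> None:
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "tandem_clusters.tsv", "w") as fh:
        fh.write(_header(config))
        report.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phylo

def phylo(
    records: list[ProteinRecord],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Alignment, DistanceMatrix, Tree]:
    """MSA -> Poisson distances -> NJ tree with bootstrap supports."""
    config = config or RunConfig()
    if len(records) < 3:
        raise ValueError("phylogeny requires >= 3 sequences")
    aln = progressive_msa(records, config.align)
    dm = poisson_distance(aln)
    tree = bootstrap_support(
        aln, n_replicates=config.bootstrap_replicates, seed=config.seed
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aln.to_fasta(out / "alignment.afa")
        dm.to_phylip(out / "distances.phy")
        # supports below 50% are left unlabelled, as in the figures
        (out / "tree.nwk").write_text(
            tree.newick(with_support=True, min_support=50.0) + "\n"
        )
    return aln, dm, tree


# ---------------------------------------------------------------------------
# expr

def expr(
    matrix: ExpressionMatrix,
    config: RunConfig | None = None,
    k_groups: int | None = 3,
) -> dict:
    """log2 transform, hierarchical clustering, expressed-gene counts."""
    config = config or RunConfig()
    per_sample, any_count = expressed_counts(
        matrix, threshold=config.expression_threshold
    )
    result: dict = {
        "expressed_per_sample": per_sample,
        "expressed_any": any_count,
        "clustering": None,
        "groups": None,
    }
    logm = log2_transform(matrix)
    if len(matrix.samples) >= 2 and len(matrix.genes) >= 2:
        import warnings as _warnings
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                clustering = hcluster_genes(logm)
        except ValueError:
            # e.g. genes expressed in disjoint sample sets: no shared
            # present columns, distances undefined -> counts only
            return result
        result["clustering"] = clustering
        if k_groups:
            result["groups"] = clustering.cut(k_groups)
    return result
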