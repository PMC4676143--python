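"""The synthetic-family generator: determinism, invariants, recovery."""

import numpy as np
import pytest

from spfam import pipeline
from spfam.domain_scan import DEFAULT_GRAMMAR, detect_clip_domains, find_triad_motifs
from spfam.seqio import AA_ALPHABET
from spfam.synth import (
    FamilySpec,
    TruthManifest,
    default_cluster_plan,
    make_expression,
    make_family,
    make_scaffolds,
    write_fixtures,
)


def test_spec_invariants_enforced():
    with pytest.raises(ValueError, match="exceed n_sp"):
        FamilySpec(n_sp=10, n_trypsin=9, n_chymotrypsin=2)
    with pytest.raises(ValueError, match="clip-bearing"):
        FamilySpec(n_sp=5, n_sph=2, n_trypsin=1, n_chymotrypsin=1, n_clip_sp=6)
    with pytest.raises(ValueError, match="mutation_rate"):
        FamilySpec(mutation_rate=1.5)


def test_generator_is_seed_deterministic():
    spec = FamilySpec(n_sp=8, n_sph=5, n_trypsin=3, n_chymotrypsin=1,
                      n_clip_sp=2, n_clip_sph=1, seed=42)
    r1, m1 = make_family(spec)
    r2, m2 = make_family(spec)
    assert [x.sequence for x in r1] == [x.sequence for x in r2]
    assert m1.genes == m2.genes
    r3, _ = make_family(FamilySpec(n_sp=8, n_sph=5, n_trypsin=3,
                                   n_chymotrypsin=1, n_clip_sp=2,
                                   n_clip_sph=1, seed=43))
    assert [x.sequence for x in r3] != [x.sequence for x in r1]


def test_output_validates_against_seqio_invariants(small_family):
    records, manifest = small_family
    ids = [r.id for r in records]
    assert len(set(ids)) == len(ids)
    for r in records:
        assert set(r.sequence) <= AA_ALPHABET
        assert len(r.sequence) >= 50


def test_composition_matches_spec(full_family):
    _, manifest = full_family
    assert manifest.composition() == {
        "n_genes": 221, "n_sp": 120, "n_sph": 101,
        "n_trypsin": 38, "n_chymotrypsin": 8,
        "n_clip_genes": 13, "n_clip_domains": 14,
    }


def test_planted_clips_sampled_inside_grammar(full_family):
    _, manifest = full_family
    g = DEFAULT_GRAMMAR
    spans = []
    for truth in manifest.genes.values():
        for clip in truth.clips:
            c = clip.cys_positions
            s = [c[i + 1] - c[i] - 1 for i in range(5)]
            assert g.s12[0] <= s[0] <= g.s12[1]
            assert s[1] == 5
            assert s[4] == 0
            spans.append(c[5] - c[0] - 1)
    assert min(spans) >= 43 and max(spans) <= 53


def test_recovery_theorem_zero_mutation():
    """With mutation_rate = 0 and in-grammar spacings the full pipeline's
    annotations equal the manifest field for field."""
    spec = FamilySpec(n_sp=20, n_sph=15, n_trypsin=6, n_chymotrypsin=3,
                      n_clip_sp=4, n_clip_sph=2, n_double_clip=1,
                      mutation_rate=0.0, seed=77)
    records, manifest = make_family(spec)
    table, _ = pipeline.annotate(records)
    for gid, truth in manifest.genes.items():
        row = table.loc[gid]
        assert row["class"] == truth.cls
        if truth.cls == "SP":
            assert row["subtype"] == truth.subtype
            assert (row["res189"], row["res216"], row["res226"]) == truth.pocket
        assert row["n_clips"] == len(truth.clips)
        got_spans = row["clip_spans"].split(";") if row["clip_spans"] else []
        assert got_spans == [
            f"{c.cys_positions[0]}-{c.cys_positions[5]}" for c in truth.clips
        ]
        assert row["activation_motif"] == truth.activation_motif
        assert row["p1_residue"] == truth.p1
        assert row["cascade_position"] == truth.cascade


def test_single_sp_single_sph_specs():
    records, manifest = make_family(
        FamilySpec(n_sp=1, n_sph=0, n_trypsin=1, n_chymotrypsin=0,
                   n_clip_sp=0, n_clip_sph=0, n_double_clip=0, seed=7)
    )
    assert len(records) == 1
    table, summary = pipeline.annotate(records)
    assert summary["n_sp"] == 1 and summary["n_trypsin"] == 1

    records, manifest = make_family(
        FamilySpec(n_sp=0, n_sph=1, n_trypsin=0, n_chymotrypsin=0,
                   n_clip_sp=0, n_clip_sph=0, n_double_clip=0, seed=7)
    )
    truth = manifest.genes[records[0].id]
    assert truth.knocked in ("his", "asp", "ser")
    triads = find_triad_motifs(records[0])
    flags = dict(zip(("his", "asp", "ser"), triads[0].status))
    assert not flags[truth.knocked]


def test_scaffold_plan_boundary_cases(small_family):
    from spfam.genome_layout import tandem_clusters
    from spfam.synth import ClusterPlanEntry
    records, manifest = small_family
    ids = [r.id for r in records]
    # two members separated by 6 fillers -> no cluster
    plan = [ClusterPlanEntry("scX", (ids[0], ids[1]), (6,))]
    models = make_scaffolds(manifest, records, cluster_plan=plan)
    fam = set(ids)
    clusters = tandem_clusters(fam, models)
    assert all(set(c.members) != {ids[0], ids[1]} for c in clusters)
    # exactly 5 fillers -> cluster
    plan = [ClusterPlanEntry("scX", (ids[0], ids[1]), (5,))]
    models = make_scaffolds(manifest, records, cluster_plan=plan)
    clusters = tandem_clusters(fam, models)
    assert any(c.members == (ids[0], ids[1]) for c in clusters)


def test_default_plan_mirrors_observed_layout(full_family):
    _, manifest = full_family
    plan = default_cluster_plan(manifest)
    assert len(plan) == 36
    assert sum(len(e.members) for e in plan) == 122
    sizes = sorted((len(e.members) for e in plan), reverse=True)
    assert sizes[:5] == [5, 5, 4, 4, 4]
    # 35 distinct scaffolds: two clusters share one
    assert len({e.scaffold for e in plan}) == 35


def test_expression_matrices_deterministic_and_truthful(full_family):
    records, manifest = full_family
    stage1, tissue1 = make_expression(manifest)
    stage2, tissue2 = make_expression(manifest)
    assert stage1 == stage2 and tissue1 == tissue2
    blocks = manifest.expression["blocks"]
    assert set(blocks) == {r.id for r in records}
    silent = [g for g, b in blocks.items() if b == "silent"]
    assert (stage1.data.loc[silent] == 0).all().all()


def test_noiseless_expression_recovers_blocks_perfectly():
    spec = FamilySpec(n_sp=12, n_sph=8, n_trypsin=4, n_chymotrypsin=2,
                      n_clip_sp=2, n_clip_sph=1, seed=5)
    _, manifest = make_family(spec)
    stage, _ = make_expression(
        manifest, noise_sd=0.0, dropout_rate=0.0,
        tissue_sizes=(15, 12, 10, 11), n_expressed_any=18,
    )
    from spfam.expression import hcluster_genes, log2_transform
    with pytest.warns(UserWarning):
        result = hcluster_genes(log2_transform(stage))
    groups = result.cut(3)
    blocks = manifest.expression["blocks"]
    mapping = {}
    for gene, label in groups.items():
        mapping.setdefault(blocks[gene], set()).add(label)
    assert all(len(v) == 1 for v in mapping.values())


def test_fixture_bundle_and_manifest_round_trip(tmp_path):
    spec = FamilySpec(n_sp=6, n_sph=4, n_trypsin=2, n_chymotrypsin=1,
                      n_clip_sp=1, n_clip_sph=1, n_double_clip=1, seed=9)
    manifest = write_fixtures(tmp_path, spec)
    for name in ("family.faa", "family.gff3", "stages.tsv", "tissues.tsv",
                 "manifest.json"):
        assert (tmp_path / name).exists()
    back = TruthManifest.from_json(tmp_path / "manifest.json")
    assert back.genes == manifest.genes
    assert back.clusters == manifest.clusters
    from spfam.seqio import read_fasta
    records = read_fasta(tmp_path / "family.faa")
    assert [r.id for r in records] == sorted(manifest.genes)
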