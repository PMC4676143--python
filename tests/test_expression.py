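"""log2 transform, complete-linkage clustering, expressed counts, qPCR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spfam.expression import (
    expressed_counts,
    hcluster_genes,
    log2_transform,
    missing_euclidean,
    qpcr_relative_expression,
)
from spfam.seqio import ExpressionMatrix


def _matrix(values, genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def test_log2_transform_semantics():
    m = _matrix([[8, 1, 0], [np.nan, 2, 4]])
    out = log2_transform(m)
    assert out.data.iloc[0, 0] == 3.0
    assert out.data.iloc[0, 1] == 0.0
    assert np.isnan(out.data.iloc[0, 2])          # zero -> missing
    assert np.isnan(out.data.iloc[1, 0])          # missing stays missing
    assert out.data.iloc[1, 2] == 2.0


def test_log2_is_order_preserving():
    vals = np.array([0.5, 1.0, 2.0, 7.3, 100.0])
    out = log2_transform(_matrix([vals])).data.to_numpy().ravel()
    assert (np.diff(out) > 0).all()


def brute_force_complete_linkage(dist: np.ndarray):
    """Exhaustive oracle: repeatedly merge the pair of clusters with the
    smallest maximum pairwise distance; return (merged sets, heights)."""
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges, heights = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        heights.append(h)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges, heights


def _scipy_merges(genes, Z):
    idx = {i: frozenset([i]) for i in range(len(genes))}
    merges, heights = [], []
    for k, (a, b, h, _) in enumerate(Z):
        merged = idx[int(a)] | idx[int(b)]
        idx[len(genes) + k] = merged
        merges.append(merged)
        heights.append(h)
    return merges, heights


def test_identical_pair_merges_first():
    m = _matrix([[1, 2, 3], [1, 2, 3], [40, 50, 60]])
    result = hcluster_genes(m)
    merges, _ = _scipy_merges(result.genes, result.merge_tree)
    assert merges[0] == frozenset([0, 1])


def test_merge_sequence_matches_brute_force_oracle():
    """Complete linkage vs exhaustive oracle on random matrices <= 7 genes."""
    rng = np.random.default_rng(5)
    for trial in range(20):
        n = int(rng.integers(3, 8))
        values = rng.uniform(0, 10, size=(n, 5))
        m = _matrix(values)
        result = hcluster_genes(m)
        dist = missing_euclidean(m.data.sort_index().to_numpy())
        expected_merges, expected_heights = brute_force_complete_linkage(dist)
        got_merges, got_heights = _scipy_merges(result.genes, result.merge_tree)
        assert got_merges == expected_merges, trial
        assert np.allclose(got_heights, expected_heights)


def test_merge_heights_monotone(full_expression):
    manifest, stage, tissue = full_expression
    result = hcluster_genes(log2_transform(stage))
    heights = result.merge_heights()
    assert (np.diff(heights) >= -1e-9).all()


def test_missing_aware_distance_rescaling():
    # identical present values, one missing column: distance 0
    v = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 5.0]])
    d = missing_euclidean(v)
    assert d[0, 1] == 0.0
    # difference 3 on one shared column of three total -> sqrt(9 * 3/1)
    v = np.array([[np.nan, np.nan, 1.0], [4.0, 4.0, 4.0]])
    assert missing_euclidean(v)[0, 1] == pytest.approx(np.sqrt(27.0))


def test_all_missing_gene_excluded_with_warning():
    m = _matrix([[1, 2], [np.nan, np.nan], [5, 6]])
    with pytest.warns(UserWarning, match="all-missing"):
        result = hcluster_genes(m)
    assert result.excluded == ["g1"]
    assert result.genes == ["g0", "g2"]


def test_three_block_matrix_recovered_at_k3(full_expression):
    manifest, stage, tissue = full_expression
    logm = log2_transform(stage)
    with pytest.warns(UserWarning):
        result = hcluster_genes(logm)
    groups = result.cut(3)
    blocks = manifest.expression["blocks"]
    # group labels must be a relabelling of the planted blocks
    mapping = {}
    for gene, label in groups.items():
        mapping.setdefault(blocks[gene], set()).add(label)
    assert all(len(v) == 1 for v in mapping.values())
    assert len({next(iter(v)) for v in mapping.values()}) == 3


def test_expressed_counts_rules():
    m = _matrix([[0, 0], [0, 0]])
    per, any_c = expressed_counts(m)
    assert per.tolist() == [0, 0] and any_c == 0
    m = _matrix([[1.5, 0], [0.2, 0.2]])
    per, any_c = expressed_counts(m)
    assert per.tolist() == [2, 1] and any_c == 2
    # threshold at the max: nothing passes a strict inequality
    per, any_c = expressed_counts(m, threshold=1.5)
    assert per.tolist() == [0, 0] and any_c == 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(min_value=0, max_value=50), st.floats(min_value=0, max_value=50))
def test_expressed_counts_monotone_in_threshold(t1, t2):
    rng = np.random.default_rng(17)
    m = _matrix(rng.uniform(0, 40, size=(6, 4)))
    lo, hi = sorted([t1, t2])
    per_lo, any_lo = expressed_counts(m, threshold=lo)
    per_hi, any_hi = expressed_counts(m, threshold=hi)
    assert (per_hi <= per_lo).all() and any_hi <= any_lo


def test_planted_tissue_sets_recovered(full_expression):
    manifest, stage, tissue = full_expression
    per, any_c = expressed_counts(tissue)
    sets = manifest.expression["tissue_sets"]
    assert per.tolist() == [len(sets[s]) for s in tissue.samples]
    assert per.tolist() == [161, 148, 130, 140]
    assert any_c == 196


def _qpcr_table(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "Ct"])


def test_qpcr_relative_levels():
    table = _qpcr_table(
        [
            ("g1", "E", 1, 20.0), ("g1", "E", 2, 20.0),
            ("g2", "E", 1, 17.0),
            ("L32", "E", 1, 20.0),
        ]
    )
    rel = qpcr_relative_expression(table, reference_gene="L32")
    assert rel.loc["g1", "E"] == pytest.approx(1.0)       # Ct equal to reference
    assert rel.loc["g2", "E"] == pytest.approx(8.0)       # dCt = -3
    table2 = _qpcr_table([("g1", "E", 1, 23.0), ("L32", "E", 1, 20.0)])
    rel2 = qpcr_relative_expression(table2, reference_gene="L32")
    assert rel2.loc["g1", "E"] == pytest.approx(0.125)    # dCt = 3 -> 2^-3


def test_qpcr_missing_reference_is_error():
    table = _qpcr_table([("g1", "E", 1, 20.0), ("L32", "P", 1, 19.0), ("g1", "P", 1, 21.0)])
    with pytest.raises(ValueError, match="missing in samples"):
        qpcr_relative_expression(table, reference_gene="L32")


def test_qpcr_recovers_simulated_ratios():
    """Known expression ratios + Gaussian Ct noise: recovered within the
    noise envelope."""
    rng = np.random.default_rng(23)
    true_ratio = {"gA": 4.0, "gB": 0.25}
    rows = []
    for sample in ("E", "L4"):
        ref_ct = 20.0
        for rep in range(1, 7):
            rows.append(("L32", sample, rep, ref_ct + rng.normal(0, 0.1)))
            for g, ratio in true_ratio.items():
                ct = ref_ct - np.log2(ratio)
                rows.append((g, sample, rep, ct + rng.normal(0, 0.1)))
    rel = qpcr_relative_expression(_qpcr_table(rows), reference_gene="L32")
    for g, ratio in true_ratio.items():
        for sample in ("E", "L4"):
            assert rel.loc[g, sample] == pytest.approx(ratio, rel=0.25)
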