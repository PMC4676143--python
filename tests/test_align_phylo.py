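"""Alignment, Poisson distances, neighbor joining, bootstrap.

Independent oracles: a naive recursive affine-gap aligner for scores,
closed-form three-point branch lengths, additive matrices built from
random trees for NJ exactness, and scikit-bio's NJ for a library
cross-check.
"""

import math
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from spfam.align_phylo import (
    Alignment,
    AlignParams,
    DistanceMatrix,
    bootstrap_support,
    global_align,
    mean_pairwise,
    nj_tree,
    percent_identity,
    poisson_distance,
    progressive_msa,
)
from spfam.seqio import ProteinRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def naive_affine_score(a: str, b: str, open_=10.0, extend=0.5) -> float:
    """Independent recursion: best global score where a gap of length L
    costs open_ + (L-1)*extend.  Exponential-time 3-state recursion."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = extend if state == "ga" else open_
            best = max(best, -cost + rec(i + 1, j, "ga"))
        if j < len(b):
            cost = extend if state == "gb" else open_
            best = max(best, -cost + rec(i, j + 1, "gb"))
        return best

    return rec(0, 0, "m")


def test_identical_sequences_align_gap_free():
    rec = ProteinRecord(id="a", sequence="MKWVTFISLLLLFSSAYS")
    aln = global_align(rec, ProteinRecord(id="b", sequence=rec.sequence))
    assert aln.rows[0] == aln.rows[1] == rec.sequence
    assert percent_identity(aln).iloc[0, 1] == 100.0


def test_single_gap_alignment():
    aln = global_align(
        ProteinRecord(id="a", sequence="ACDE"), ProteinRecord(id="b", sequence="ACE")
    )
    assert aln.n_columns == 4
    assert sum(r.count("-") for r in aln.rows) == 1
    # de-gapping reproduces inputs
    assert aln.degapped(0) == "ACDE" and aln.degapped(1) == "ACE"


def test_alignment_score_matches_naive_oracle():
    rng = np.random.default_rng(42)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(50):
        a = "".join(rng.choice(letters, size=rng.integers(3, 13)))
        b = "".join(rng.choice(letters, size=rng.integers(3, 13)))
        got = global_align(
            ProteinRecord(id="a", sequence=a), ProteinRecord(id="b", sequence=b)
        ).score
        assert got == pytest.approx(naive_affine_score(a, b), abs=1e-9), (a, b)


def test_percent_identity_pairwise_deletion():
    aln = Alignment(ids=("a", "b"), rows=("AC-E", "ACDE"))
    assert percent_identity(aln).iloc[0, 1] == 100.0
    # 10 substitutions in 100 residues, gap-free
    base = ("ACDEFGHIKL" * 10)
    mutated = "W" * 10 + base[10:]
    aln = Alignment(ids=("a", "b"), rows=(base, mutated))
    assert percent_identity(aln).iloc[0, 1] == pytest.approx(90.0)


def test_similarity_counts_conservative_substitutions():
    aln = Alignment(ids=("a", "b"), rows=("IV", "VL"))   # both in {AVLIM}
    assert percent_identity(aln, mode="identity").iloc[0, 1] == 0.0
    assert percent_identity(aln, mode="similarity").iloc[0, 1] == 100.0
    assert mean_pairwise(percent_identity(aln, mode="similarity")) == 100.0


def test_poisson_distance_closed_form():
    ident = Alignment(ids=("a", "b"), rows=("ACDE", "ACDE"))
    assert poisson_distance(ident).get("a", "b") == 0.0
    base = "ACDEFGHIKL" * 10
    mutated = "W" * 10 + base[10:]          # p = 0.1
    d = poisson_distance(Alignment(ids=("a", "b"), rows=(base, mutated)))
    assert d.get("a", "b") == pytest.approx(-math.log(0.9), abs=1e-9)
    assert d.get("a", "b") == pytest.approx(0.10536, abs=1e-5)


def test_poisson_distance_pairwise_deletion_and_errors():
    # gapped columns excluded per pair
    aln = Alignment(ids=("a", "b"), rows=("AC-EF", "ACW-F"))
    # shared columns: 1,2,5 -> one diff (none: A=A, C=C, F=F) -> 0 diffs
    assert poisson_distance(aln).get("a", "b") == 0.0
    with pytest.raises(ValueError, match="no shared"):
        poisson_distance(Alignment(ids=("a", "b"), rows=("A-", "-A")))
    # saturated pair flagged infinite
    sat = poisson_distance(Alignment(ids=("a", "b"), rows=("AAAA", "CCCC")))
    assert sat.has_infinite


def test_poisson_monotone_and_bounded_below_by_p():
    for p in np.linspace(0.05, 0.95, 10):
        d = -math.log1p(-p)
        assert d >= p                        # Jensen
    diffs = [-math.log1p(-p) for p in np.linspace(0.0, 0.9, 10)]
    assert diffs == sorted(diffs)


# ---------------------------------------------------------------------------
# Neighbor joining

def test_three_taxon_closed_form():
    ids = ("a", "b", "c")
    m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = nj_tree(DistanceMatrix(ids=ids, matrix=m))
    dist = tree.leaf_distances()
    assert dist.loc["a", "b"] == pytest.approx(0.3, abs=1e-12)
    assert dist.loc["a", "c"] == pytest.approx(0.5, abs=1e-12)
    # closed form b_a = (d_ab + d_ac - d_bc) / 2
    (leaf_a,) = [l for l in tree.root.children if l.name == "a"]
    assert leaf_a.length == pytest.approx((0.3 + 0.5 - 0.6) / 2, abs=1e-12)


def random_additive_tree(n_taxa: int, rng) -> tuple[dict, np.ndarray, list]:
    """Random topology + positive branch lengths; returns path metric."""
    import itertools
    nodes = {f"t{i}": {} for i in range(n_taxa)}
    adj: dict = {name: [] for name in nodes}
    free = list(nodes)
    internal = 0
    while len(free) > 2:
        i, j = sorted(rng.choice(len(free), size=2, replace=False))
        a, b = free[j], free[i]
        new = f"n{internal}"; internal += 1
        adj[new] = []
        for leaf in (a, b):
            w = float(rng.uniform(0.05, 1.0))
            adj[new].append((leaf, w)); adj[leaf].append((new, w))
            free.remove(leaf)
        free.append(new)
    a, b = free
    w = float(rng.uniform(0.05, 1.0))
    adj[a].append((b, w)); adj[b].append((a, w))

    names = sorted(n for n in adj if n.startswith("t"))
    dist = np.zeros((len(names), len(names)))
    for i, src in enumerate(names):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for j, dst in enumerate(names):
            dist[i, j] = seen[dst]
    dist = (dist + dist.T) / 2.0      # remove float-order asymmetry
    return adj, dist, names


def test_nj_recovers_additive_matrices_exactly():
    """Path metric of the NJ tree equals the input on 100 random
    additive 5-8 taxon matrices (tolerance 1e-9)."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(5, 9))
        _, dist, names = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(ids=tuple(names), matrix=dist))
        got = tree.leaf_distances().loc[names, names].to_numpy()
        assert np.max(np.abs(got - dist)) < 1e-9


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(3)
    _, dist, names = random_additive_tree(6, rng)
    tree = nj_tree(DistanceMatrix(ids=tuple(names), matrix=dist))
    perm = rng.permutation(len(names))
    tree2 = nj_tree(
        DistanceMatrix(
            ids=tuple(names[i] for i in perm),
            matrix=dist[np.ix_(perm, perm)],
        )
    )
    assert tree.bipartitions() == tree2.bipartitions()
    assert tree.newick(with_support=False) == tree2.newick(with_support=False)


def test_nj_agrees_with_scikit_bio():
    """Independent library cross-check on topology."""
    import io
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(19)
    _, dist, names = random_additive_tree(7, rng)
    ours = nj_tree(DistanceMatrix(ids=tuple(names), matrix=dist))
    sk_tree = skbio_nj(SkbioDM(dist, ids=names))
    all_leaves = frozenset(names)
    ref = min(all_leaves)
    sk_splits = set()
    for node in sk_tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            sk_splits.add(side if ref not in side else all_leaves - side)
    assert ours.bipartitions() == sk_splits


def test_nj_rejects_degenerate_input():
    with pytest.raises(ValueError, match=">= 3"):
        nj_tree(DistanceMatrix(ids=("a", "b"), matrix=np.zeros((2, 2))))
    m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
    with pytest.raises(ValueError, match="infinite"):
        nj_tree(DistanceMatrix(ids=("a", "b", "c"), matrix=m))


# ---------------------------------------------------------------------------
# Progressive MSA

def test_msa_identical_sequences_gap_free():
    recs = [ProteinRecord(id=f"s{i}", sequence="MKWVTFISLL") for i in range(3)]
    aln = progressive_msa(recs)
    assert all(r == "MKWVTFISLL" for r in aln.rows)


def test_msa_degap_invariant_and_motif_block(small_family):
    records, _ = small_family
    subset = records[:6]
    aln = progressive_msa(subset)
    for i, rec in enumerate(aln.ids):
        src = next(r for r in subset if r.id == rec)
        assert aln.degapped(i) == src.sequence
    assert aln.n_columns >= max(len(r.sequence) for r in subset)
    # the planted His-motif context aligns into a single column block
    cols = {row.find("TAAHC") for row in aln.rows}
    cols.discard(-1)
    assert len(cols) == 1


# ---------------------------------------------------------------------------
# Bootstrap

def _clustered_alignment():
    """Two tight pairs, strongly (but not saturatedly) separated."""
    a = "ACDEFGHIKLMNPQRSTVWY" * 3
    b = a[:-1] + "W"
    c = "W" * 30 + a[30:]                      # 50% diverged from a
    d = c[:-2] + "AY"
    return Alignment(ids=("a", "b", "c", "d"), rows=(a, b, c, d))


def test_bootstrap_strong_signal_gives_full_support():
    tree = bootstrap_support(_clustered_alignment(), n_replicates=50, seed=1)
    supports = [n.support for n in tree.internal_edges() if n.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_zero_replicates_and_reproducibility():
    aln = _clustered_alignment()
    bare = bootstrap_support(aln, n_replicates=0, seed=1)
    assert all(n.support is None for n in bare.internal_edges())
    t1 = bootstrap_support(aln, n_replicates=30, seed=9)
    t2 = bootstrap_support(aln, n_replicates=30, seed=9)
    assert t1.newick() == t2.newick()


def test_bootstrap_invariant_to_row_order():
    aln = _clustered_alignment()
    perm = Alignment(
        ids=(aln.ids[2], aln.ids[0], aln.ids[3], aln.ids[1]),
        rows=(aln.rows[2], aln.rows[0], aln.rows[3], aln.rows[1]),
    )
    t1 = bootstrap_support(aln, n_replicates=40, seed=4)
    t2 = bootstrap_support(perm, n_replicates=40, seed=4)
    assert t1.newick() == t2.newick()
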