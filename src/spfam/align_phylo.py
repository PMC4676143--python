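"""Alignment, evolutionary distances and neighbor-joining phylogenetics.

Pairwise global alignment (BLOSUM62, affine gaps, ClustalX-era defaults)
drives percent identity/similarity, the S1-pocket readout and the guide
tree of a progressive profile MSA.  Evolutionary distances use the
Poisson correction d = -ln(1 - p) over pairwise-deleted columns (gap- or
X-bearing columns excluded per pair), trees come from Saitou-Nei
neighbor joining with deterministic lexicographic tie-breaking, and
branch supports from column-resampling bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .seqio import ProteinRecord

__all__ = [
    "AlignParams",
    "Alignment",
    "DistanceMatrix",
    "Node",
    "Tree",
    "global_align",
    "progressive_msa",
    "percent_identity",
    "poisson_distance",
    "nj_tree",
    "bootstrap_support",
    "SIMILARITY_GROUPS",
]

# Strong-conservation residue grouping used for "similarity" percentages.
SIMILARITY_GROUPS = (
    frozenset("AVLIM"),
    frozenset("FWY"),
    frozenset("ST"),
    frozenset("KRH"),
    frozenset("DENQ"),
    frozenset("C"),
    frozenset("G"),
    frozenset("P"),
)

_GROUP_OF: dict[str, int] = {}
for _gi, _g in enumerate(SIMILARITY_GROUPS):
    for _r in _g:
        _GROUP_OF[_r] = _gi

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA20)}


@dataclass(frozen=True)
class AlignParams:
    """Pairwise-alignment scoring: substitution matrix + affine gaps.

    A gap of length L costs gap_open + (L - 1) * gap_extend.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    msa_gap: float = 4.0      # linear per-column gap cost in profile merging


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows ('-' = gap) over an ordered id list."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")

    def to_clustal(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("CLUSTAL W multiple sequence alignment\n\n")
            width = max(len(i) for i in self.ids) + 2
            for start in range(0, self.n_columns, 60):
                for i, r in zip(self.ids, self.rows):
                    fh.write(f"{i:<{width}}{r[start:start + 60]}\n")
                fh.write("\n")


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    a: ProteinRecord, b: ProteinRecord, params: AlignParams | None = None
) -> Alignment:
    """Optimal global alignment of two proteins (deterministic first path)."""
    params = params or AlignParams()
    aligner = _aligner(params)
    alns = aligner.align(a.sequence, b.sequence)
    best = alns[0]
    return Alignment(
        ids=(a.id, b.id),
        rows=(str(best[0]), str(best[1])),
        score=float(best.score),
    )


# ---------------------------------------------------------------------------
# Percent identity / similarity

def percent_identity(alignment: Alignment, mode: str = "identity") -> pd.DataFrame:
    """Pairwise percent identity (or similarity) under pairwise deletion.

    Denominator per pair = columns where neither row has a gap;
    numerator = identical residue pairs (identity) or identical-or-same-
    conservation-group pairs (similarity).  X matches nothing.
    """
    if mode not in ("identity", "similarity"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(alignment.ids)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment.rows[i], alignment.rows[j]
            shared = hits = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                shared += 1
                if x == "X" or y == "X":
                    continue
                if x == y:
                    hits += 1
                elif mode == "similarity" and _GROUP_OF.get(x) == _GROUP_OF.get(y):
                    hits += 1
            pct = 100.0 * hits / shared if shared else float("nan")
            out[i, j] = out[j, i] = pct
    return pd.DataFrame(out, index=alignment.ids, columns=alignment.ids)


def mean_pairwise(matrix: pd.DataFrame) -> float:
    """Mean over all unordered distinct pairs."""
    vals = matrix.to_numpy()
    iu = np.triu_indices(len(matrix), k=1)
    return float(np.mean(vals[iu]))


# ---------------------------------------------------------------------------
# Poisson distances

@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray        # symmetric, zero diagonal; inf = saturated

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.array_equal(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.isfinite(m).all() and (m < 0).any():
            raise ValueError("distance matrix entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])

    @property
    def has_infinite(self) -> bool:
        return bool(np.isinf(self.matrix).any())

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.matrix[i])
                fh.write(f"{name:<12}{row}\n")


def poisson_distance(alignment: Alignment) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p), pairwise deletion.

    p is the fraction of differing residues over columns where neither
    sequence has a gap or X.  Saturated pairs (p >= 1) get infinity; a
    pair with zero shared columns is a hard error.
    """
    n = len(alignment.ids)
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    valid = [(r != b"-") & (r != b"X") for r in rows]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            shared = int(both.sum())
            if shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between "
                    f"{alignment.ids[i]!r} and {alignment.ids[j]!r}"
                )
            diffs = int((rows[i][both] != rows[j][both]).sum())
            p = diffs / shared
            d = float("inf") if p >= 1.0 else -math.log1p(-p)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=alignment.ids, matrix=m)


# ---------------------------------------------------------------------------
# Trees

@dataclass
class Node:
    """Tree node; ``length`` is the edge to the parent (None at the root)."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def _newick(self, with_support: bool, min_support: float | None) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            inner = ",".join(c._newick(with_support, min_support) for c in self.children)
            label = ""
            if with_support and self.support is not None:
                if min_support is None or self.support >= min_support:
                    label = f"{self.support:.0f}"
            body = f"({inner}){label}"
        if self.length is not None:
            body += f":{self.length:.6f}"
        return body

    def newick(self, with_support: bool = True, min_support: float | None = None) -> str:
        return self._newick(with_support, min_support) + ";"


@dataclass
class Tree:
    """Unrooted tree (root = trifurcation for >=3 taxa)."""

    root: Node
    clamped_negative_total: float = 0.0   # summed deficit of clamped NJ branches

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def newick(self, with_support: bool = True, min_support: float | None = None) -> str:
        return self.root.newick(with_support, min_support)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalised to the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset] = set()
        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                splits.add(side)
            return below
        walk(self.root)
        return splits

    def internal_edges(self) -> list[Node]:
        out = []
        def walk(node: Node) -> None:
            for c in node.children:
                if not c.is_leaf:
                    out.append(c)
                walk(c)
        walk(self.root)
        return out

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length matrix between leaves (for additivity checks)."""
        names = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(names)}
        m = np.zeros((len(names), len(names)))
        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            sides = []
            for c in node.children:
                d = {k: v + (c.length or 0.0) for k, v in walk(c).items()}
                sides.append(d)
                below.update(d)
            for a in range(len(sides)):
                for b in range(a + 1, len(sides)):
                    for la, da in sides[a].items():
                        for lb, db in sides[b].items():
                            m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = da + db
            return below
        walk(self.root)
        return pd.DataFrame(m, index=names, columns=names)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Taxa are processed in sorted-id order, and exact Q ties resolve to
    the lexicographically smallest id pair, so the topology is invariant
    to input order.  Negative branch-length estimates are clamped to 0
    and the total deficit recorded on the tree.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if dm.has_infinite:
        raise ValueError("distance matrix contains infinite (saturated) entries")
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    d = dm.matrix[np.ix_(order, order)].astype(float).copy()

    nodes: list[Node] = [Node(name=i) for i in ids]
    labels = list(ids)                  # min-leaf label per active cluster
    active = list(range(len(ids)))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(n, k=1)
        qmin = q[iu].min()         # upper triangle only: q may differ from
                                   # its transpose by rounding order
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                if q[ai, aj] == qmin:
                    la, lb = labels[active[ai]], labels[active[aj]]
                    key = (min(la, lb), max(la, lb))
                    if best is None or key < best[0]:
                        best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        bi = clamp(0.5 * dij + (r[ai] - r[aj]) / (2 * (n - 2)))
        bj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (n - 2))))
        nodes[i].length, nodes[j].length = bi, bj
        new = Node(children=[nodes[i], nodes[j]])
        # distances from the new cluster: reuse slot i
        for ak in range(n):
            k = active[ak]
            if k in (i, j):
                continue
            d_new = 0.5 * (d[i, k] + d[j, k] - dij)
            d[i, k] = d[k, i] = d_new
        nodes[i] = new
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    a, b, c = active
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, clamped_negative_total=clamped)


def bootstrap_support(
    alignment: Alignment, n_replicates: int = 1000, seed: int = 0
) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    Supports (% of replicates containing each original internal
    bipartition) are attached to internal edges of the tree built from
    the full alignment.  Replicates whose resampled columns yield a
    saturated or degenerate distance matrix are skipped.
    """
    base = nj_tree(poisson_distance(alignment))
    if n_replicates <= 0:
        return base
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    counts: dict[frozenset, int] = {bp: 0 for bp in base.bipartitions()}
    n_ok = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = tuple(r[cols].tobytes().decode() for r in rows)
        rep = Alignment(ids=alignment.ids, rows=rep_rows)
        try:
            tree = nj_tree(poisson_distance(rep))
        except ValueError:
            continue
        n_ok += 1
        reps = tree.bipartitions()
        for bp in counts:
            if bp in reps:
                counts[bp] += 1

    all_leaves = frozenset(alignment.ids)
    ref = min(all_leaves)

    def walk(node: Node, is_root: bool) -> frozenset:
        below = frozenset()
        if node.is_leaf:
            return frozenset([node.name])
        for c in node.children:
            below |= walk(c, False)
        if not is_root and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            if n_ok:
                node.support = 100.0 * counts.get(side, 0) / n_ok
        return below

    walk(base.root, True)
    return base


# ---------------------------------------------------------------------------
# Progressive MSA

def _profile_freq(rows: list[str], blosum: np.ndarray) -> np.ndarray:
    """Per-column residue-frequency matrix (L x 20); gaps and X weigh 0."""
    L = len(rows[0])
    f = np.zeros((L, 20))
    for r in rows:
        for i, ch in enumerate(r):
            k = _AA_INDEX.get(ch)
            if k is not None:
                f[i, k] += 1.0
    return f / len(rows)


def _blosum20(params: AlignParams) -> np.ndarray:
    sub = substitution_matrices.load(params.matrix)
    m = np.zeros((20, 20))
    for i, a in enumerate(_AA20):
        for j, b in enumerate(_AA20):
            m[i, j] = sub[a, b]
    return m


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], blosum: np.ndarray, gap: float
) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch over profile columns (linear gap cost)."""
    fa = _profile_freq(rows_a, blosum)
    fb = _profile_freq(rows_b, blosum)
    S = fa @ blosum @ fb.T
    la, lb = S.shape
    dp = np.zeros((la + 1, lb + 1))
    dp[:, 0] = -gap * np.arange(la + 1)
    dp[0, :] = -gap * np.arange(lb + 1)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)   # 0=diag 1=up(A col) 2=left(B col)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        diag = dp[i - 1, :-1] + S[i - 1]
        up = dp[i - 1, 1:] - gap
        row = dp[i]
        for j in range(1, lb + 1):
            left = row[j - 1] - gap
            best = diag[j - 1]
            move = 0
            if up[j - 1] > best:
                best, move = up[j - 1], 1
            if left > best:
                best, move = left, 2
            row[j] = best
            ptr[i, j] = move
    # traceback
    ops = []
    i, j = la, lb
    while i > 0 or j > 0:
        mv = ptr[i, j]
        if i > 0 and j > 0 and mv == 0:
            ops.append("M"); i -= 1; j -= 1
        elif i > 0 and mv == 1:
            ops.append("A"); i -= 1
        else:
            ops.append("B"); j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "A"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "B"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_msa(
    records: list[ProteinRecord], params: AlignParams | None = None
) -> Alignment:
    """Progressive profile alignment along a pairwise-identity guide tree.

    Pairwise identity distances (1 - pid/100 from global alignments)
    feed an average-linkage guide tree; profiles are merged bottom-up by
    profile-profile Needleman-Wunsch.  Row order follows the input.
    """
    params = params or AlignParams()
    if len(records) < 2:
        raise ValueError("progressive MSA requires >= 2 sequences")
    n = len(records)
    blosum = _blosum20(params)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], params)
            pid = percent_identity(aln).iloc[0, 1]
            cond.append(1.0 - pid / 100.0)
    Z = linkage(np.asarray(cond), method="average")

    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].sequence]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = profiles.pop(ia)
        idx_b, rows_b = profiles.pop(ib)
        out_a, out_b = _merge_profiles(rows_a, rows_b, blosum, params.msa_gap)
        profiles[n + step] = (idx_a + idx_b, out_a + out_b)
    (indices, rows), = profiles.values()
    ordered = sorted(zip(indices, rows))
    return Alignment(
        ids=tuple(records[i].id for i, _ in ordered),
        rows=tuple(r for _, r in ordered),
    )
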