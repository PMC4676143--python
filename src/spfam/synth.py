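"""Synthetic SP/SPH gene families with known ground truth.

Every pipeline stage is testable without downloads: this module builds
protein families with planted catalytic triads (intact for SPs, one
catalytic residue knocked out for SPHs), planted S1-pocket triples,
activation motifs, and clip cassettes sampled inside the detection
grammar; scaffold layouts with planted tandem clusters; and stage/tissue
RPKM matrices with block structure.  A TruthManifest records every
planted label and is the single source of truth for recovery tests.

Design notes.  Proteins are built on a domain template derived from the
packaged chymotrypsinogen scaffold: the Asp-motif context is set to an
exact DIAL, and any unplanned occurrence of the catalytic-motif profiles
is neutralised so truth labels stay unambiguous.  Linker/background
residues are drawn from a fixed cysteine-free composition table, so the
only cysteines upstream of the catalytic domain are planted clip
cassettes.  All randomness flows from a single integer seed through
numpy, so output is reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import domain_scan
from .domain_scan import DEFAULT_PROFILES, MotifProfile
from .seqio import (
    ExpressionMatrix,
    GeneModel,
    ProteinRecord,
    write_expression,
    write_fasta,
    write_gff,
)
from .specificity import load_reference

import pandas as pd

__all__ = [
    "FamilySpec",
    "GeneTruth",
    "ClipTruth",
    "ClusterPlanEntry",
    "TruthManifest",
    "make_family",
    "make_scaffolds",
    "make_expression",
    "default_cluster_plan",
    "write_fixtures",
]

# Background amino-acid composition (average protein composition with
# cysteine removed and renormalised); keeps planted cysteine topology
# unambiguous while avoiding a uniform-alphabet artefact.
_BG_FREQS = {
    "A": 0.078, "R": 0.051, "N": 0.043, "D": 0.053, "Q": 0.043,
    "E": 0.063, "G": 0.072, "H": 0.023, "I": 0.053, "L": 0.091,
    "K": 0.059, "M": 0.022, "F": 0.039, "P": 0.052, "S": 0.068,
    "T": 0.059, "W": 0.014, "Y": 0.032, "V": 0.066,
}
_BG_LETTERS = np.array(list(_BG_FREQS), dtype="U1")
_BG_P = np.array(list(_BG_FREQS.values()))
_BG_P = _BG_P / _BG_P.sum()

STAGE_SAMPLES = ("E", "L1", "L2", "L3", "L4", "P", "AM", "AF")
TISSUE_SAMPLES = ("MG_L4", "HD_L4", "HD_AM", "HD_AF")


def _bg(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BG_LETTERS, size=n, p=_BG_P))


# ---------------------------------------------------------------------------
# Domain template

# Template = chymotrypsinogen residues 16..245 (the catalytic domain,
# starting at the activation motif).  0-based indices into the template:
_T_OFFSET = 15           # template[0] = zymogen residue 16
_HIS_IDX = 57 - 16       # catalytic His
_ASP_IDX = 102 - 16
_SER_IDX = 195 - 16
_P189_IDX = 189 - 16
_P216_IDX = 216 - 16
_P226_IDX = 226 - 16
_MOTIF_IDX = 0           # activation motif occupies template[0:4]

_HIS_WIN = range(_HIS_IDX - 3, _HIS_IDX + 2)     # TAAHC context
_ASP_WIN = range(_ASP_IDX, _ASP_IDX + 4)         # DIAL context
_SER_WIN = range(_SER_IDX - 2, _SER_IDX + 4)     # GDSGGP context

_TEMPLATE_PROTECTED = (
    set(range(4))
    | set(_HIS_WIN) | set(_ASP_WIN) | set(_SER_WIN)
    | {_P189_IDX, _P216_IDX, _P226_IDX}
)


def _neutralize(seq: list[str], protected: set[int], profiles=DEFAULT_PROFILES) -> None:
    """Remove unplanned catalytic-motif matches in place.

    Intact matches of any profile, and located (anchor-degenerate)
    matches of the His profile, are broken by substituting Q/E at a
    non-protected position, unless the match overlaps a protected
    (planted) window.  Deterministic; loops until clean.
    """
    for _ in range(100):
        dirty = False
        s = "".join(seq)
        for prof in profiles.values():
            for hit in prof.hits(s):
                if not hit.intact and prof.name != "his":
                    continue
                window = range(hit.start, hit.start + len(prof))
                if any(i in protected for i in window):
                    continue
                # break the match at the first mutable position
                for i in window:
                    if i in protected:
                        continue
                    seq[i] = "Q" if seq[i] != "Q" else "E"
                    break
                dirty = True
        if not dirty:
            return
    raise RuntimeError("motif neutralisation did not converge")


_TEMPLATE_CACHE: list[str] | None = None


def _domain_template() -> list[str]:
    """Cleaned catalytic-domain scaffold (synthetic derivative of the
    packaged reference): exact DIAL planted at the Asp position, all
    unplanned motif matches neutralised."""
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        ref = load_reference()
        t = list(ref.sequence[_T_OFFSET:])
        t[_ASP_IDX:_ASP_IDX + 4] = list("DIAL")
        _neutralize(t, set(_TEMPLATE_PROTECTED))
        _TEMPLATE_CACHE = t
    return list(_TEMPLATE_CACHE)


# ---------------------------------------------------------------------------
# Specs and truth

@dataclass(frozen=True)
class FamilySpec:
    """Composition of a synthetic family (defaults mirror the analysed
    genome-wide family: 221 genes = 120 SP + 101 SPH, 38 trypsins,
    8 chymotrypsins, 13 clip-bearing genes carrying 14 clip domains)."""

    n_sp: int = 120
    n_sph: int = 101
    n_trypsin: int = 38
    n_chymotrypsin: int = 8
    n_clip_sp: int = 10
    n_clip_sph: int = 3
    n_double_clip: int = 1
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trypsin + self.n_chymotrypsin > self.n_sp:
            raise ValueError("trypsin + chymotrypsin counts exceed n_sp")
        if self.n_clip_sp > self.n_sp or self.n_clip_sph > self.n_sph:
            raise ValueError("clip-bearing counts exceed class counts")
        if self.n_double_clip > self.n_clip_sp:
            raise ValueError("double-clip count exceeds clip-SP count")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")

    @property
    def n_genes(self) -> int:
        return self.n_sp + self.n_sph


@dataclass(frozen=True)
class ClipTruth:
    cys_positions: tuple[int, int, int, int, int, int]
    group: str


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    cls: str                       # SP / SPH
    subtype: str | None            # trypsin / chymotrypsin / other (SP only)
    knocked: str | None            # his / asp / ser (SPH only)
    pocket: tuple[str, str, str] | None
    activation_motif: str
    p1: str
    cascade: str
    clips: tuple[ClipTruth, ...] = ()
    trypsp_count: int = 1


@dataclass
class TruthManifest:
    """Single source of truth for all recovery tests."""

    spec: FamilySpec
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)       # filled by make_scaffolds
    gene_layout: dict[str, dict] = field(default_factory=dict)
    expression: dict = field(default_factory=dict)           # filled by make_expression

    def composition(self) -> dict[str, int]:
        genes = self.genes.values()
        return {
            "n_genes": len(self.genes),
            "n_sp": sum(g.cls == "SP" for g in genes),
            "n_sph": sum(g.cls == "SPH" for g in genes),
            "n_trypsin": sum(g.subtype == "trypsin" for g in genes),
            "n_chymotrypsin": sum(g.subtype == "chymotrypsin" for g in genes),
            "n_clip_genes": sum(bool(g.clips) for g in genes),
            "n_clip_domains": sum(len(g.clips) for g in genes),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "genes": {k: asdict(v) for k, v in self.genes.items()},
            "clusters": self.clusters,
            "gene_layout": self.gene_layout,
            "expression": self.expression,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        man = cls(spec=FamilySpec(**raw["spec"]))
        for k, v in raw["genes"].items():
            clips = tuple(
                ClipTruth(cys_positions=tuple(c["cys_positions"]), group=c["group"])
                for c in v.pop("clips")
            )
            pocket = v.pop("pocket")
            man.genes[k] = GeneTruth(
                clips=clips,
                pocket=tuple(pocket) if pocket else None,
                **v,
            )
        man.clusters = raw["clusters"]
        man.gene_layout = raw["gene_layout"]
        man.expression = raw["expression"]
        return man


# Flavour: activation-motif variants among trypsins, mirroring the
# observed IIGG/IING variants and the unusual Tyr/Phe P1 residues
# (0-based trypsin index -> (motif, p1 or None for default)).
_TRYPSIN_FLAVOUR = {
    12: ("IING", None),
    13: ("IIGG", None),
    23: ("IIGG", None),
    25: ("IING", "Y"),
    27: ("IIGG", "F"),
    33: ("IIGG", "Y"),
}


def _sample_clip(rng: np.random.Generator, group: str) -> tuple[int, int, int, int]:
    """Spacings (s12, s23, s34, s45) inside the grammar with total
    Cys1..Cys6 span in [43, 53]."""
    s12 = int(rng.integers(2, 11))
    s23 = 5
    if group == "1":
        s34 = int(rng.integers(14, 18))
    else:
        s34 = int(rng.integers(22, 26))
    lo = max(2, 43 - 4 - s12 - s23 - s34)
    hi = min(20, 53 - 4 - s12 - s23 - s34)
    s45 = int(rng.integers(lo, hi + 1))
    return s12, s23, s34, s45


def _clip_cassette(rng, group: str) -> tuple[list[str], tuple[int, ...]]:
    s12, s23, s34, s45 = _sample_clip(rng, group)
    seq: list[str] = []
    pos = []
    for spacer in (s12, s23, s34, s45):
        pos.append(len(seq))
        seq.append("C")
        seq.extend(_bg(rng, spacer))
    pos.append(len(seq))
    seq.append("C")
    pos.append(len(seq))
    seq.append("C")
    return seq, tuple(pos)


def _build_protein(
    gene_id: str,
    cls: str,
    subtype: str | None,
    clip_groups: list[str],
    motif: str,
    p1: str,
    rng: np.random.Generator,
    mutation_rate: float,
) -> tuple[ProteinRecord, GeneTruth]:
    # --- N-terminal region: leader, clip cassettes, linker, P1
    pre: list[str] = list(_bg(rng, int(rng.integers(8, 21))))
    clip_abs: list[tuple[int, ...]] = []
    for k, group in enumerate(clip_groups):
        cassette, pos = _clip_cassette(rng, group)
        offset = len(pre)
        clip_abs.append(tuple(p + offset for p in pos))
        pre.extend(cassette)
        if k < len(clip_groups) - 1:
            pre.extend(_bg(rng, int(rng.integers(5, 13))))
    pre.extend(_bg(rng, int(rng.integers(12, 26))))
    pre.append(p1)

    # --- catalytic domain on the cleaned template
    dom = _domain_template()
    dom[0:4] = list(motif)
    protected = set(_TEMPLATE_PROTECTED)

    knocked = None
    if cls == "SPH":
        knocked = ["his", "asp", "ser"][int(rng.integers(0, 3))]
        idx, choices = {
            "his": (_HIS_IDX, "RQNY"),
            "asp": (_ASP_IDX, "NEGA"),
            "ser": (_SER_IDX, "AGNT"),
        }[knocked]
        dom[idx] = choices[int(rng.integers(0, len(choices)))]
        protected.add(idx)

    pocket = None
    if cls == "SP":
        gas = "GAS"
        if subtype == "trypsin":
            pocket = ("D", "G", gas[int(rng.integers(0, 3))])
        elif subtype == "chymotrypsin":
            stg = "STG"
            pocket = (stg[int(rng.integers(0, 3))], "G", gas[int(rng.integers(0, 3))])
        else:
            kne = "KNQE"
            pocket = (kne[int(rng.integers(0, 4))], "G", "G")
        dom[_P189_IDX] = pocket[0]
        dom[_P216_IDX] = pocket[1]
        dom[_P226_IDX] = pocket[2]

    # background divergence, never touching planted positions
    if mutation_rate > 0:
        for i in range(len(dom)):
            if i in protected:
                continue
            if rng.random() < mutation_rate:
                repl = str(rng.choice(_BG_LETTERS, p=_BG_P))
                if repl != dom[i]:
                    dom[i] = repl

    seq = pre + dom
    offset = len(pre)
    protected_abs = {i + offset for i in protected} | {offset - 1}
    for pos6 in clip_abs:
        protected_abs.update(pos6)
    _neutralize(seq, protected_abs)

    # keep the planted activation motif the unique match near the domain
    # start: break unplanned IVGG-like matches in the N-terminal region
    from .specificity import ACTIVATION_PATTERN
    for _ in range(50):
        window = "".join(seq[: offset + 4])
        stray = [
            m for m in ACTIVATION_PATTERN.finditer(window) if m.start() != offset
        ]
        if not stray:
            break
        for m in stray:
            for i in range(m.start(), m.start() + 4):
                if i not in protected_abs:
                    seq[i] = "Q" if seq[i] != "Q" else "E"
                    break
    _neutralize(seq, protected_abs)

    record = ProteinRecord(id=gene_id, sequence="".join(seq), gene_id=gene_id)
    if p1 in "RK":
        cascade = "terminal"
    elif p1 in "LHS":
        cascade = "penultimate"
    else:
        cascade = "unassigned"
    truth = GeneTruth(
        gene_id=gene_id,
        cls=cls,
        subtype=subtype,
        knocked=knocked,
        pocket=pocket,
        activation_motif=motif,
        p1=p1,
        cascade=cascade,
        clips=tuple(
            ClipTruth(cys_positions=pos, group=grp)
            for pos, grp in zip(clip_abs, clip_groups)
        ),
    )
    return record, truth


def make_family(spec: FamilySpec) -> tuple[list[ProteinRecord], TruthManifest]:
    """Generate the protein family and its truth manifest.

    Gene ids are g001..gNNN: trypsins first, then chymotrypsins, then
    other SPs (clip-bearing SPs lead this block), then SPHs (clip-
    bearing SPHs lead).  Clip-domain groups follow the observed mix:
    the double-clip gene carries two group-2 domains, the next five
    clip genes carry group-1 domains, the rest group 2.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = TruthManifest(spec=spec)
    records: list[ProteinRecord] = []

    n_other_sp = spec.n_sp - spec.n_trypsin - spec.n_chymotrypsin
    roles: list[tuple[str, str | None]] = (
        [("SP", "trypsin")] * spec.n_trypsin
        + [("SP", "chymotrypsin")] * spec.n_chymotrypsin
        + [("SP", "other")] * n_other_sp
        + [("SPH", None)] * spec.n_sph
    )

    # clip assignment: which genes carry clips, and the per-domain groups
    clip_plan: dict[int, list[str]] = {}
    first_other = spec.n_trypsin + spec.n_chymotrypsin
    group1_left = 5
    sp_slots = list(range(first_other, first_other + spec.n_clip_sp))
    sph_slots = list(range(spec.n_sp, spec.n_sp + spec.n_clip_sph))
    slot_iter = sp_slots + sph_slots
    for j, slot in enumerate(slot_iter):
        if j < spec.n_double_clip:
            clip_plan[slot] = ["2", "2"]
        elif group1_left > 0:
            clip_plan[slot] = ["1"]
            group1_left -= 1
        else:
            clip_plan[slot] = ["2"]

    for i, (cls, subtype) in enumerate(roles):
        gene_id = f"g{i + 1:03d}"
        motif, p1 = "IVGG", ("R", "K")[int(rng.integers(0, 2))]
        if subtype == "trypsin" and i in _TRYPSIN_FLAVOUR:
            motif, p1_override = _TRYPSIN_FLAVOUR[i]
            if p1_override:
                p1 = p1_override
        clip_groups = clip_plan.get(i, [])
        if clip_groups:
            # mirror the clip-bearing family's activation residues:
            # second clip gene penultimate (Leu), third/fourth unusual
            k = slot_iter.index(i)
            if k == 1:
                p1 = "L"
            elif k == 2:
                p1 = "Y"
            elif k == 3:
                p1 = "F"
        rec, truth = _build_protein(
            gene_id, cls, subtype, clip_groups, motif, p1, rng, spec.mutation_rate
        )
        records.append(rec)
        manifest.genes[gene_id] = truth
    return records, manifest


# ---------------------------------------------------------------------------
# Scaffold layouts

@dataclass(frozen=True)
class ClusterPlanEntry:
    scaffold: str
    members: tuple[str, ...]
    intervening: tuple[int, ...]         # filler genes between consecutive members
    phase_vector: tuple[int, ...] = (0, 1, 2)   # shared by all members
    strand: str = "+"


def default_cluster_plan(manifest: TruthManifest) -> list[ClusterPlanEntry]:
    """Planted layout mirroring the analysed genome: trypsin clusters of
    sizes 5/5/4/4/2 (20 of 38 trypsins clustered), plus 9 clusters of 4
    and 22 of 3 from the remaining genes — 36 clusters, 122 tandem
    genes, two clusters sharing one scaffold."""
    genes = list(manifest.genes.values())
    trypsins = [g.gene_id for g in genes if g.subtype == "trypsin"]
    others = [g.gene_id for g in genes if g.subtype != "trypsin"]
    plan: list[ClusterPlanEntry] = []
    cursor = 0
    rng = np.random.default_rng(manifest.spec.seed + 1)

    def take(pool: list[str], k: int, start: int) -> tuple[tuple[str, ...], int]:
        return tuple(pool[start:start + k]), start + k

    tryp_sizes = [5, 5, 4, 4, 2]
    phase_vecs = [(1, 2, 0), (0, 1, 2), (0, 1, 2), (0, 1, 2), (0, 1, 2)]
    sid = 1
    for size, pv in zip(tryp_sizes, phase_vecs):
        if cursor + size > len(trypsins):
            break
        members, cursor = take(trypsins, size, cursor)
        interv = tuple(int(rng.integers(0, 3)) for _ in range(size - 1))
        plan.append(ClusterPlanEntry(f"scaffold_{sid}", members, interv, pv))
        sid += 1

    ocursor = 0
    other_sizes = [4] * 9 + [3] * 22
    shared_scaffold = None
    for k, size in enumerate(other_sizes):
        if ocursor + size > len(others):
            break
        members, ocursor = take(others, size, ocursor)
        interv = tuple(int(rng.integers(0, 4)) for _ in range(size - 1))
        if k == len(other_sizes) - 1 and shared_scaffold is None and plan:
            scaffold = plan[-1].scaffold       # two clusters on one scaffold
            shared_scaffold = scaffold
        else:
            scaffold = f"scaffold_{sid}"
            sid += 1
        plan.append(ClusterPlanEntry(scaffold, members, interv, (0, 1, 2)))
    return plan


def _exon_lengths_for(total: int, phase_vector: tuple[int, ...]) -> tuple[int, ...]:
    """Exon lengths with the given intron-phase vector summing to total
    (total must be a multiple of 3)."""
    k = len(phase_vector) + 1
    if k == 1:
        return (total,)
    prev = 0
    residues = []
    for p in phase_vector:
        residues.append((p - prev) % 3)
        prev = p
    residues.append((-prev) % 3)
    m_total = (total - sum(residues)) // 3
    base = m_total // k
    ms = [base] * k
    for i in range(m_total - base * k):
        ms[i % k] += 1
    return tuple(3 * m + r for m, r in zip(ms, residues))


def make_scaffolds(
    manifest: TruthManifest,
    records: list[ProteinRecord],
    cluster_plan: list[ClusterPlanEntry] | None = None,
    intron_length: int = 200,
    intergenic: int = 2000,
    seed: int | None = None,
) -> list[GeneModel]:
    """Place family genes (plus filler genes) on scaffolds.

    Cluster members are laid down in plan order with the planned number
    of intervening filler genes; unplanned family genes get singleton
    scaffolds.  Exon structures realise the planned intron-phase
    vectors; CDS length is 3 * (protein length + 1).  Layout truth is
    recorded on the manifest.
    """
    rng = np.random.default_rng(manifest.spec.seed + 7 if seed is None else seed)
    if cluster_plan is None:
        cluster_plan = default_cluster_plan(manifest)
    lengths = {r.id: len(r.sequence) for r in records}
    planned = {m for e in cluster_plan for m in e.members}
    missing = planned - set(lengths)
    if missing:
        raise ValueError(f"cluster plan references unknown genes: {sorted(missing)}")

    models: list[GeneModel] = []
    fil_counter = 0
    manifest.clusters = []
    manifest.gene_layout = {}

    def add_gene(
        gene_id: str, scaffold: str, cursor: int, strand: str,
        phase_vector: tuple[int, ...],
    ) -> int:
        total = 3 * (lengths[gene_id] + 1)
        exon_lens = _exon_lengths_for(total, phase_vector)
        exons = []
        pos = cursor
        for L in exon_lens:
            exons.append((pos, pos + L - 1))
            pos += L + intron_length
        end = exons[-1][1]
        tx_exons = tuple(exons if strand == "+" else exons[::-1])
        models.append(
            GeneModel(
                gene_id=gene_id, scaffold=scaffold, start=cursor, end=end,
                strand=strand, exons=tx_exons,
            )
        )
        manifest.gene_layout[gene_id] = {
            "scaffold": scaffold,
            "strand": strand,
            "phase_vector": list(phase_vector),
            "exon_count": len(exon_lens),
            "cds_length": total,
            "cluster": None,
        }
        return end + intergenic

    def add_filler(scaffold: str, cursor: int) -> int:
        nonlocal fil_counter
        fil_counter += 1
        gid = f"fil{fil_counter:04d}"
        L = 300
        models.append(
            GeneModel(
                gene_id=gid, scaffold=scaffold, start=cursor,
                end=cursor + L - 1, strand="+", exons=((cursor, cursor + L - 1),),
            )
        )
        return cursor + L - 1 + intergenic

    scaffold_cursors: dict[str, int] = {}
    for cid, entry in enumerate(cluster_plan, start=1):
        cursor = scaffold_cursors.get(entry.scaffold, 1000)
        if entry.scaffold in scaffold_cursors:
            # second cluster on a shared scaffold: break the tandem run
            for _ in range(6):
                cursor = add_filler(entry.scaffold, cursor)
        for j, member in enumerate(entry.members):
            cursor = add_gene(
                member, entry.scaffold, cursor, entry.strand, entry.phase_vector
            )
            manifest.gene_layout[member]["cluster"] = cid
            if j < len(entry.members) - 1:
                for _ in range(entry.intervening[j]):
                    cursor = add_filler(entry.scaffold, cursor)
        scaffold_cursors[entry.scaffold] = cursor
        manifest.clusters.append(
            {
                "cluster_id": cid,
                "scaffold": entry.scaffold,
                "members": list(entry.members),
                "intervening": list(entry.intervening),
            }
        )

    singleton_sid = 1000
    for rec in records:
        if rec.id in planned:
            continue
        singleton_sid += 1
        scaffold = f"scaffold_{singleton_sid}"
        k = int(rng.integers(1, 6))
        phases = tuple(int(rng.integers(0, 3)) for _ in range(k - 1))
        strand = "+-"[int(rng.integers(0, 2))]
        cursor = add_gene(rec.id, scaffold, 1000, strand, phases)
        for _ in range(int(rng.integers(0, 3))):
            cursor = add_filler(scaffold, cursor)
    return models


# ---------------------------------------------------------------------------
# Expression matrices

_BLOCK_MEANS = {
    # RPKM pattern means per stage sample
    "larva_high":  {"E": 2, "L1": 120, "L2": 120, "L3": 120, "L4": 120, "P": 2, "AM": 2, "AF": 2},
    "egg_pupa":    {"E": 100, "L1": 2, "L2": 2, "L3": 2, "L4": 2, "P": 100, "AM": 2, "AF": 2},
    "adult_male":  {"E": 2, "L1": 2, "L2": 2, "L3": 2, "L4": 2, "P": 2, "AM": 150, "AF": 2},
    "silent":      {s: 0 for s in STAGE_SAMPLES},
}


def make_expression(
    manifest: TruthManifest,
    blocks: dict[str, str] | None = None,
    noise_sd: float = 0.4,
    dropout_rate: float = 0.02,
    tissue_sizes: tuple[int, int, int, int] = (161, 148, 130, 140),
    n_expressed_any: int = 196,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Stage and tissue RPKM matrices with planted block structure.

    Stage matrix: each gene follows its block's pattern mean times
    lognormal noise (sigma = noise_sd in natural log units); dropout
    zeros are injected at dropout_rate.  Tissue matrix: planted
    expressed-gene sets of the given sizes per tissue, whose union is
    exactly the n_expressed_any expressed genes (no dropout, so planted
    set sizes are recovered exactly).  Truth goes on the manifest.
    """
    rng = np.random.default_rng(
        manifest.spec.seed + 13 if seed is None else seed
    )
    gene_ids = sorted(manifest.genes)
    n = len(gene_ids)
    n_expressed = min(n_expressed_any, n)
    expressed = gene_ids[:n_expressed]
    silent = gene_ids[n_expressed:]

    if blocks is None:
        blocks = {}
        n_larva = int(round(0.46 * n_expressed))
        n_eggp = int(round(0.20 * n_expressed))
        for i, g in enumerate(expressed):
            if i < n_larva:
                blocks[g] = "larva_high"
            elif i < n_larva + n_eggp:
                blocks[g] = "egg_pupa"
            else:
                blocks[g] = "adult_male"
        for g in silent:
            blocks[g] = "silent"

    stage = np.zeros((n, len(STAGE_SAMPLES)))
    for i, g in enumerate(gene_ids):
        means = _BLOCK_MEANS[blocks[g]]
        for j, s in enumerate(STAGE_SAMPLES):
            mu = means[s]
            if mu <= 0:
                continue
            val = mu * float(np.exp(rng.normal(0.0, noise_sd)))
            if rng.random() < dropout_rate:
                val = 0.0
            stage[i, j] = val
    stage_m = ExpressionMatrix(
        pd.DataFrame(stage, index=gene_ids, columns=list(STAGE_SAMPLES))
    )

    # tissue inclusion: column sums = tissue_sizes, union = expressed set
    sizes = [min(s, n_expressed) for s in tissue_sizes]
    incl = {t: set() for t in TISSUE_SAMPLES}
    for t, size in zip(TISSUE_SAMPLES, sizes):
        chosen = rng.choice(len(expressed), size=size, replace=False)
        incl[t] = {expressed[i] for i in chosen}
    covered = set().union(*incl.values())
    uncovered = [g for g in expressed if g not in covered]
    mg = TISSUE_SAMPLES[0]
    for g in uncovered:
        coverage = {
            h: sum(h in incl[t] for t in TISSUE_SAMPLES) for h in incl[mg]
        }
        swap = max(coverage, key=lambda h: (coverage[h], h))
        if coverage[swap] < 2:
            raise RuntimeError("cannot satisfy tissue set sizes with full coverage")
        incl[mg].discard(swap)
        incl[mg].add(g)

    tissue = np.zeros((n, len(TISSUE_SAMPLES)))
    for i, g in enumerate(gene_ids):
        for j, t in enumerate(TISSUE_SAMPLES):
            if g in incl[t]:
                mu = 150.0 if t == mg else 8.0
                tissue[i, j] = mu * float(np.exp(rng.normal(0.0, noise_sd)))
    tissue_m = ExpressionMatrix(
        pd.DataFrame(tissue, index=gene_ids, columns=list(TISSUE_SAMPLES))
    )

    manifest.expression = {
        "blocks": dict(blocks),
        "tissue_sets": {t: sorted(incl[t]) for t in TISSUE_SAMPLES},
        "expressed_any": sorted(expressed),
        "noise_sd": noise_sd,
        "dropout_rate": dropout_rate,
    }
    return stage_m, tissue_m


# ---------------------------------------------------------------------------
# Fixture bundle

def write_fixtures(out_dir: str | Path, spec: FamilySpec | None = None) -> TruthManifest:
    """Emit FASTA + GFF3 + expression TSVs + manifest JSON for a spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or FamilySpec()
    records, manifest = make_family(spec)
    models = make_scaffolds(manifest, records)
    stage, tissue = make_expression(manifest)
    write_fasta(records, out / "family.faa")
    write_gff(models, out / "family.gff3")
    write_expression(stage, out / "stages.tsv")
    write_expression(tissue, out / "tissues.tsv")
    manifest.to_json(out / "manifest.json")
    return manifest
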