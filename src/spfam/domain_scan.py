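"""Catalytic-triad and clip-domain detection; SP vs SPH classification.

Serine proteases of the chymotrypsin (S1) family carry a His/Asp/Ser
catalytic triad embedded in the conserved contexts TAAHC, DIAL and
GDSGGP.  A family member with all three catalytic residues in place is a
serine protease (SP); one with any catalytic residue mutated away is a
serine-protease homolog (SPH).  Clip domains are N-terminal regulatory
modules with six conserved cysteines (Cys-5 and Cys-6 adjacent) whose
inter-cysteine spacings follow a tight grammar; the Cys-3..Cys-4 spacing
splits them into group 1 (8-17 residues) and group 2 (22-26 residues).

Motifs are located by fuzzy profiles anchored on the catalytic residue:
a profile *hit* requires every non-anchor position to match its residue
class (the anchor is free), and the hit is *intact* iff the anchor holds
the catalytic residue itself.  X never matches any position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqio import ProteinRecord

__all__ = [
    "MotifProfile",
    "MotifHit",
    "TriadResult",
    "ClipDomain",
    "ClipGrammar",
    "SpClass",
    "DEFAULT_PROFILES",
    "DEFAULT_GRAMMAR",
    "find_triad_motifs",
    "classify_sp_sph",
    "detect_clip_domains",
    "assign_clip_group",
]


@dataclass(frozen=True)
class MotifProfile:
    """A positional residue-class pattern anchored on one catalytic residue."""

    name: str
    positions: tuple[frozenset, ...]   # allowed residues per position
    anchor: int                        # index of the catalytic position
    anchor_residue: str                # the catalytic residue (H/D/S)

    def __len__(self) -> int:
        return len(self.positions)

    def hits(self, seq: str) -> list["MotifHit"]:
        """All positions where every non-anchor position matches.

        X never matches.  Hits are returned left to right.
        """
        out = []
        n, m = len(seq), len(self.positions)
        for i in range(n - m + 1):
            ok = True
            for j, allowed in enumerate(self.positions):
                if j == self.anchor:
                    continue
                if seq[i + j] not in allowed:
                    ok = False
                    break
            if ok:
                a = seq[i + self.anchor]
                out.append(
                    MotifHit(
                        name=self.name,
                        start=i,
                        matched=seq[i : i + m],
                        anchor_pos=i + self.anchor,
                        intact=(a == self.anchor_residue),
                    )
                )
        return out


def _p(spec: str) -> tuple[frozenset, ...]:
    """Parse 'A,[ST],C' style class lists into position sets."""
    out = []
    for tok in spec.split():
        tok = tok.strip("[]")
        out.append(frozenset(tok))
    return tuple(out)


# His motif: [ST]-[AG]-[AG]-H-C (anchor H), matching the TAAHC context.
# Asp motif: D-[IVLM]-[AG]-[LIVM] (anchor D), matching DIAL.
# Ser motif: G-[DN]-S-G-[GS]-[PSA] (anchor S), matching GDSGGP.
DEFAULT_PROFILES: dict[str, MotifProfile] = {
    "his": MotifProfile("his", _p("[ST] [AG] [AG] H C"), anchor=3, anchor_residue="H"),
    "asp": MotifProfile("asp", _p("D [IVLM] [AG] [LIVM]"), anchor=0, anchor_residue="D"),
    "ser": MotifProfile("ser", _p("G [DN] S G [GS] [PSA]"), anchor=2, anchor_residue="S"),
}

# Extent of a Tryp_SPc span relative to its catalytic anchors: the domain
# begins at the activation motif ~41 residues upstream of the catalytic
# His (chymotrypsinogen numbering: Ile16 vs His57) and ends shortly after
# the catalytic Ser.
SPAN_UPSTREAM_OF_HIS = 45
SPAN_DOWNSTREAM_OF_SER = 35
MAX_HIS_TO_SER = 300
MIN_HIS_TO_SER = 20


@dataclass(frozen=True)
class MotifHit:
    name: str
    start: int                # 0-based
    matched: str
    anchor_pos: int           # 0-based position of the catalytic residue
    intact: bool


@dataclass(frozen=True)
class TriadResult:
    """One Tryp_SPc span's catalytic machinery."""

    his: MotifHit | None
    asp: MotifHit | None
    ser: MotifHit | None
    span: tuple[int, int]     # 0-based half-open estimate of the domain extent

    @property
    def complete(self) -> bool:
        return all(h is not None and h.intact for h in (self.his, self.asp, self.ser))

    @property
    def status(self) -> tuple[bool, bool, bool]:
        """(H, D, S) intact flags."""
        return tuple(h is not None and h.intact for h in (self.his, self.asp, self.ser))


def _pick(hits: list[MotifHit], lo: int, hi: int) -> MotifHit | None:
    """First hit with anchor in (lo, hi), preferring intact hits."""
    window = [h for h in hits if lo < h.anchor_pos < hi]
    for h in window:
        if h.intact:
            return h
    return window[0] if window else None


def find_triad_motifs(
    protein: ProteinRecord,
    profiles: dict[str, MotifProfile] = DEFAULT_PROFILES,
) -> list[TriadResult]:
    """Locate catalytic-triad motifs, one TriadResult per Tryp_SPc span.

    Triads are assembled left to right with His < Asp < Ser ordering
    inside each span; intact components are preferred over located-but-
    mutated ones, so a spurious degenerate match never masks a genuine
    catalytic residue.  Multi-domain proteins yield multiple results.
    Absence of any assembleable triad yields an empty list.
    """
    seq = protein.sequence
    if len(seq) < 50:
        return []
    his_hits = profiles["his"].hits(seq)
    asp_hits = profiles["asp"].hits(seq)
    ser_hits = profiles["ser"].hits(seq)

    triads: list[TriadResult] = []
    cursor = -1
    # intact His anchors first, then located-but-mutated ones
    ordered_his = [h for h in his_hits if h.intact] + [h for h in his_hits if not h.intact]
    used_his: set[int] = set()
    while True:
        candidates = [
            h for h in ordered_his
            if h.anchor_pos > cursor and h.anchor_pos not in used_his
        ]
        hit = None
        for h in candidates:
            a = _pick(asp_hits, h.anchor_pos, h.anchor_pos + MAX_HIS_TO_SER)
            if a is None:
                continue
            s = _pick(
                ser_hits,
                a.anchor_pos,
                h.anchor_pos + MAX_HIS_TO_SER,
            )
            if s is None or s.anchor_pos - h.anchor_pos < MIN_HIS_TO_SER:
                continue
            hit = (h, a, s)
            break
        if hit is None:
            break
        h, a, s = hit
        span = (
            max(0, h.anchor_pos - SPAN_UPSTREAM_OF_HIS),
            min(len(seq), s.anchor_pos + SPAN_DOWNSTREAM_OF_SER),
        )
        triads.append(TriadResult(his=h, asp=a, ser=s, span=span))
        used_his.add(h.anchor_pos)
        cursor = s.anchor_pos
    triads.sort(key=lambda t: t.span[0])
    return triads


@dataclass(frozen=True)
class SpClass:
    """Family-member classification: SP iff >=1 complete catalytic triad."""

    cls: str                  # "SP" or "SPH"
    trypsp_count: int
    clip_count: int


def classify_sp_sph(
    protein: ProteinRecord,
    triads: list[TriadResult],
    clips: list["ClipDomain"] | None = None,
) -> SpClass:
    cls = "SP" if any(t.complete for t in triads) else "SPH"
    return SpClass(cls=cls, trypsp_count=len(triads), clip_count=len(clips or []))


# ---------------------------------------------------------------------------
# Clip domains

@dataclass(frozen=True)
class ClipGrammar:
    """Spacing bounds for the six-cysteine clip topology.

    Spacings count residues strictly between consecutive cysteines;
    ``span`` counts residues strictly between Cys-1 and Cys-6.
    """

    s12: tuple[int, int] = (2, 10)
    s23: tuple[int, int] = (5, 5)
    s34: tuple[int, int] = (8, 26)
    s45: tuple[int, int] = (2, 20)
    span: tuple[int, int] = (37, 55)
    group1_s34: tuple[int, int] = (8, 17)
    group2_s34: tuple[int, int] = (22, 26)


DEFAULT_GRAMMAR = ClipGrammar()


@dataclass(frozen=True)
class ClipDomain:
    cys_positions: tuple[int, int, int, int, int, int]   # 0-based, increasing
    group: str = "unassigned"                            # "1", "2", "unassigned"

    @property
    def spacings(self) -> tuple[int, int, int, int]:
        c = self.cys_positions
        return tuple(c[i + 1] - c[i] - 1 for i in range(4))

    @property
    def span(self) -> int:
        """Residues strictly between Cys-1 and Cys-6."""
        return self.cys_positions[5] - self.cys_positions[0] - 1

    @property
    def start(self) -> int:
        return self.cys_positions[0]

    @property
    def end(self) -> int:
        return self.cys_positions[5]


def assign_clip_group(clip: ClipDomain, grammar: ClipGrammar = DEFAULT_GRAMMAR) -> str:
    """Group 1 vs 2 by the Cys-3..Cys-4 spacing; gaps between the ranges
    stay unassigned."""
    s34 = clip.spacings[2]
    if grammar.group1_s34[0] <= s34 <= grammar.group1_s34[1]:
        return "1"
    if grammar.group2_s34[0] <= s34 <= grammar.group2_s34[1]:
        return "2"
    return "unassigned"


def _in(v: int, bounds: tuple[int, int]) -> bool:
    return bounds[0] <= v <= bounds[1]


def detect_clip_domains(
    protein: ProteinRecord,
    triads: list[TriadResult] | None = None,
    grammar: ClipGrammar = DEFAULT_GRAMMAR,
) -> list[ClipDomain]:
    """Find six-cysteine clip placements satisfying the spacing grammar.

    The search region runs from the N-terminus to the start of the first
    Tryp_SPc span (whole sequence if none), so a clip never overlaps a
    catalytic domain.  Overlapping candidate placements are resolved
    leftmost-first, non-overlapping.
    """
    seq = protein.sequence
    limit = len(seq)
    if triads:
        limit = min(t.span[0] for t in triads)
    cys = [i for i in range(limit) if seq[i] == "C"]

    candidates: list[tuple[int, ...]] = []
    for a, c1 in enumerate(cys):
        for b in range(a + 1, len(cys)):
            c2 = cys[b]
            if not _in(c2 - c1 - 1, grammar.s12):
                continue
            for c in range(b + 1, len(cys)):
                c3 = cys[c]
                if not _in(c3 - c2 - 1, grammar.s23):
                    continue
                for d in range(c + 1, len(cys)):
                    c4 = cys[d]
                    if not _in(c4 - c3 - 1, grammar.s34):
                        continue
                    for e in range(d + 1, len(cys)):
                        c5 = cys[e]
                        if not _in(c5 - c4 - 1, grammar.s45):
                            continue
                        c6 = c5 + 1
                        if c6 >= limit or seq[c6] != "C":
                            continue
                        if not _in(c6 - c1 - 1, grammar.span):
                            continue
                        candidates.append((c1, c2, c3, c4, c5, c6))
    candidates.sort()
    chosen: list[ClipDomain] = []
    last_end = -1
    for cand in candidates:
        if cand[0] > last_end:
            clip = ClipDomain(cys_positions=cand)
            clip = replace(clip, group=assign_clip_group(clip, grammar))
            chosen.append(clip)
            last_end = cand[5]
    return chosen
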