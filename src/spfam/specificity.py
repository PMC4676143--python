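"""Substrate-specificity and activation-site calls.

The S1 substrate-binding pocket of chymotrypsin-family proteases is read
out at positions 189, 216 and 226 (chymotrypsinogen numbering): Asp189
with Gly216 and Gly/Ala/Ser226 marks a trypsin; Ser/Thr/Gly at 189 (with
the canonical 216/226) marks a chymotrypsin.  The numbering anchor is a
packaged bovine chymotrypsinogen A sequence with those positions
annotated; query domains are globally aligned to it and the residues
opposite the key positions reported.

Zymogen activation cleaves immediately before a conserved IVGG-like
tetrapeptide; the residue preceding it (P1) places the protease in its
cascade: Arg/Lys = terminal, Leu/His/Ser = penultimate.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from importlib import resources

from .align_phylo import AlignParams, global_align
from .seqio import ProteinRecord, read_fasta

__all__ = [
    "PocketCall",
    "ActivationSite",
    "Reference",
    "load_reference",
    "read_pocket",
    "call_subtype",
    "find_activation_site",
    "TERMINAL_P1",
    "PENULTIMATE_P1",
    "ACTIVATION_PATTERN",
]

TERMINAL_P1 = frozenset("RK")
PENULTIMATE_P1 = frozenset("LHS")
# Admits the reported variants IVGG, IIGG, IING plus conservative neighbors.
ACTIVATION_PATTERN = re.compile(r"[IVLF][IVLN][GN]G")
ACTIVATION_WINDOW_UP = 30     # residues upstream of the domain start
ACTIVATION_WINDOW_DOWN = 10   # residues into the domain


@dataclass(frozen=True)
class Reference:
    """Numbering anchor: sequence plus 1-based annotated positions."""

    id: str
    sequence: str
    res189: int
    res216: int
    res226: int


def load_reference() -> Reference:
    pkg = resources.files("spfam.data")
    rec = read_fasta(str(pkg / "chymotrypsinogen_a.fasta"))[0]
    sites = json.loads((pkg / "chymotrypsinogen_a_sites.json").read_text())
    pocket = sites["s1_pocket"]
    return Reference(
        id=rec.id,
        sequence=rec.sequence,
        res189=pocket["res189"],
        res216=pocket["res216"],
        res226=pocket["res226"],
    )


_DEFAULT_REFERENCE: Reference | None = None


def _default_reference() -> Reference:
    global _DEFAULT_REFERENCE
    if _DEFAULT_REFERENCE is None:
        _DEFAULT_REFERENCE = load_reference()
    return _DEFAULT_REFERENCE


@dataclass(frozen=True)
class PocketCall:
    """Residues read out at S1-pocket positions ('-' = gap) plus subtype."""

    res189: str
    res216: str
    res226: str
    subtype: str              # trypsin / chymotrypsin / other / unassigned


def call_subtype(res189: str, res216: str, res226: str) -> str:
    """Pure rule on the (189, 216, 226) residue triple."""
    if res189 == "D" and res216 == "G" and res226 in "GAS":
        return "trypsin"
    if res189 in "STG" and res216 == "G" and res226 in "GAS":
        return "chymotrypsin"
    return "other"


def read_pocket(
    protein: ProteinRecord,
    span: tuple[int, int] | None = None,
    reference: Reference | None = None,
    params: AlignParams | None = None,
) -> PocketCall:
    """Align a Tryp_SPc span to the numbering anchor and read the S1 pocket.

    ``span`` is a 0-based half-open slice of the protein (default: whole
    sequence).  A gap opposite a key position reads as '-'.  If fewer
    than half the reference residues are covered by query residues the
    call is unassigned (with a warning).
    """
    ref = reference or _default_reference()
    params = params or AlignParams()
    lo, hi = span if span is not None else (0, len(protein.sequence))
    query = protein.sequence[lo:hi]
    aln = global_align(
        ProteinRecord(id="q", sequence=query),
        ProteinRecord(id="r", sequence=ref.sequence),
        params,
    )
    qrow, rrow = aln.rows
    readout: dict[int, str] = {}
    rpos = 0
    covered = 0
    for qc, rc in zip(qrow, rrow):
        if rc != "-":
            rpos += 1
            if qc != "-":
                covered += 1
            for key in (ref.res189, ref.res216, ref.res226):
                if rpos == key:
                    readout[key] = qc if qc != "-" else "-"
    if covered / len(ref.sequence) < 0.5:
        warnings.warn(
            f"{protein.id}: alignment covers <50% of the reference; "
            "pocket call unassigned"
        )
        return PocketCall("-", "-", "-", "unassigned")
    r189 = readout.get(ref.res189, "-")
    r216 = readout.get(ref.res216, "-")
    r226 = readout.get(ref.res226, "-")
    return PocketCall(r189, r216, r226, call_subtype(r189, r216, r226))


@dataclass(frozen=True)
class ActivationSite:
    motif: str | None         # the matched tetrapeptide, or None
    motif_start: int | None   # 0-based position in the protein
    p1_residue: str | None    # residue immediately preceding the motif
    cascade_position: str     # terminal / penultimate / unassigned


def find_activation_site(
    protein: ProteinRecord, span: tuple[int, int]
) -> ActivationSite:
    """Locate the IVGG-like activation motif near the Tryp_SPc start.

    Scans from 30 residues upstream of the span start to 10 residues
    into it and keeps the match whose start is closest to the span start
    (activation cleavage immediately precedes the mature domain).
    """
    seq = protein.sequence
    start = span[0]
    lo = max(0, start - ACTIVATION_WINDOW_UP)
    hi = min(len(seq), start + ACTIVATION_WINDOW_DOWN + 4)
    window = seq[lo:hi]
    best: tuple[int, int] | None = None   # (distance to span start, abs pos)
    for m in ACTIVATION_PATTERN.finditer(window):
        pos = lo + m.start()
        key = (abs(pos - start), pos)
        if best is None or key < best:
            best = key
    if best is None:
        return ActivationSite(None, None, None, "unassigned")
    pos = best[1]
    motif = seq[pos : pos + 4]
    p1 = seq[pos - 1] if pos > 0 else None
    if p1 in TERMINAL_P1:
        cascade = "terminal"
    elif p1 in PENULTIMATE_P1:
        cascade = "penultimate"
    else:
        cascade = "unassigned"
    return ActivationSite(motif, pos, p1, cascade)
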