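"""Paired Fv sequence handling: parsing, CDR delimitation, identity metrics.

The central objects are :class:`FvSequence` (a paired VH/VL record) and
:class:`CdrSet` (the six CDR spans). Two identity modes are exposed:

``full``
    global-alignment identity of the VH+VL concatenations — the metric under
    which an 80% threshold corresponds to 50 differences over a ~250-residue
    full-length pair;
``cdr6``
    the same identity computed on the concatenation of the six CDRs in fixed
    order H1,H2,H3,L1,L2,L3 — where 80% corresponds to 10 differences over a
    ~50-residue concatenation.

CDR delimitation follows Kabat spans located through the conserved framework
anchors (the intra-domain cysteines, the post-H1/L1 tryptophan and the
J-segment WGxG / FGxG motifs) rather than a full numbering scheme.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from ._align import global_alignment_columns, identity_fraction
from .errors import AlphabetError, AnnotationError, PairingError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

IdentityMode = Literal["full", "cdr6"]
Chain = Literal["H", "L"]

Span = tuple[int, int]

CDR_ORDER = ("H1", "H2", "H3", "L1", "L2", "L3")


def _validate_sequence(seq: str, what: str, allow_x: bool = False) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    allowed = AMINO_ACIDS | ({"X"} if allow_x else set())
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise AlphabetError(f"illegal character {ch!r} at position {i} in {what}")
    return seq


@dataclass(frozen=True)
class CdrSet:
    """Six half-open CDR spans, 0-based on their own chain."""

    h1: Span
    h2: Span
    h3: Span
    l1: Span
    l2: Span
    l3: Span

    def spans(self) -> dict[str, Span]:
        return {"H1": self.h1, "H2": self.h2, "H3": self.h3,
                "L1": self.l1, "L2": self.l2, "L3": self.l3}

    def chain_spans(self, chain: Chain) -> list[Span]:
        if chain == "H":
            return [self.h1, self.h2, self.h3]
        return [self.l1, self.l2, self.l3]

    def validate(self, vh: str, vl: str) -> None:
        for chain, seq in (("H", vh), ("L", vl)):
            prev_end = 0
            for start, end in self.chain_spans(chain):
                if not (0 <= start < end <= len(seq)):
                    raise AnnotationError(f"CDR span ({start},{end}) out of bounds on chain {chain}")
                if start < prev_end:
                    raise AnnotationError(f"overlapping CDR spans on chain {chain}")
                prev_end = end

    def cdr_sequences(self, vh: str, vl: str) -> dict[str, str]:
        out = {}
        for name, (start, end) in self.spans().items():
            seq = vh if name.startswith("H") else vl
            out[name] = seq[start:end]
        return out

    def cdr_concat(self, vh: str, vl: str) -> str:
        seqs = self.cdr_sequences(vh, vl)
        return "".join(seqs[name] for name in CDR_ORDER)

    def framework_mask(self, chain: Chain, length: int) -> list[bool]:
        """True for framework positions, False inside CDRs."""
        mask = [True] * length
        for start, end in self.chain_spans(chain):
            for i in range(start, min(end, length)):
                mask[i] = False
        return mask

    def in_cdr(self, chain: Chain, position: int) -> bool:
        return any(start <= position < end for start, end in self.chain_spans(chain))


@dataclass
class FvSequence:
    """A paired VH/VL amino-acid record."""

    id: str
    vh: str
    vl: str
    cdrs: CdrSet | None = None
    allow_x: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.vh = _validate_sequence(self.vh, f"{self.id} VH", self.allow_x)
        self.vl = _validate_sequence(self.vl, f"{self.id} VL", self.allow_x)

    def chain(self, chain: Chain) -> str:
        return self.vh if chain == "H" else self.vl

    def annotated(self) -> "FvSequence":
        if self.cdrs is None:
            return replace(self, cdrs=annotate_cdrs(self))
        return self

    def cdr_concat(self) -> str:
        if self.cdrs is None:
            raise ValueError(f"{self.id}: CDRs not annotated")
        return self.cdrs.cdr_concat(self.vh, self.vl)


@dataclass(frozen=True)
class GermlineAssignment:
    """Closest germline per chain, with the somatic substitutions."""

    vh_germline_id: str
    vl_germline_id: str
    vh_germline_seq: str
    vl_germline_seq: str
    vh_mutations: tuple[tuple[int, str, str], ...]
    vl_mutations: tuple[tuple[int, str, str], ...]

    @property
    def vh_mutation_count(self) -> int:
        return len(self.vh_mutations)

    @property
    def vl_mutation_count(self) -> int:
        return len(self.vl_mutations)

    def germline_seq(self, chain: Chain) -> str:
        return self.vh_germline_seq if chain == "H" else self.vl_germline_seq


@dataclass(frozen=True)
class IdentityHit:
    query_id: str
    db_id: str
    patent_id: str
    mode: IdentityMode
    identity: float


# ---------------------------------------------------------------------------
# FASTA I/O (">id|VH" / ">id|VL" pairing dialect)
# ---------------------------------------------------------------------------

def read_fv_fasta(path: str | Path, allow_x: bool = False) -> list[FvSequence]:
    """Read a paired-Fv FASTA panel.

    Headers must follow the ``>id|VH`` / ``>id|VL`` convention; every id needs
    exactly one chain of each role. Input order of first appearance is kept.
    """
    chains: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if "|" not in header:
            raise PairingError(f"header {header!r} lacks the '|VH'/'|VL' role tag")
        fv_id, role = header.rsplit("|", 1)
        role = role.upper()
        if role not in ("VH", "VL"):
            raise PairingError(f"header {header!r}: role must be VH or VL")
        if fv_id not in chains:
            chains[fv_id] = {}
            order.append(fv_id)
        if role in chains[fv_id]:
            raise PairingError(f"duplicate {role} record for id {fv_id!r}")
        chains[fv_id][role] = str(record.seq)
    panel = []
    for fv_id in order:
        roles = chains[fv_id]
        if set(roles) != {"VH", "VL"}:
            missing = {"VH", "VL"} - set(roles)
            raise PairingError(f"id {fv_id!r} is missing chain(s): {', '.join(sorted(missing))}")
        panel.append(FvSequence(fv_id, roles["VH"], roles["VL"], allow_x=allow_x))
    return panel


def write_fv_fasta(panel: Iterable[FvSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fv in panel:
            fh.write(f">{fv.id}|VH\n{fv.vh}\n>{fv.id}|VL\n{fv.vl}\n")


# ---------------------------------------------------------------------------
# CDR delimitation (Kabat spans via framework anchors)
# ---------------------------------------------------------------------------

_MIN_HEAVY_LEN = 90
_MIN_LIGHT_LEN = 80


def _first_index(seq: str, char: str, start: int, stop: int) -> int | None:
    idx = seq.find(char, start, stop)
    return idx if idx >= 0 else None


def heavy_anchor_positions(vh: str) -> dict[str, int]:
    """Locate the VH framework anchors: Cys22, Trp36, Cys92, J-segment WGxG."""
    if len(vh) < _MIN_HEAVY_LEN:
        raise AnnotationError(f"VH too short ({len(vh)} residues) to carry CDR anchors")
    c1 = _first_index(vh, "C", 10, 30)
    if c1 is None:
        raise AnnotationError("VH: first framework cysteine (Kabat 22) not found")
    w1 = _first_index(vh, "W", c1 + 10, c1 + 25)
    if w1 is None:
        raise AnnotationError("VH: post-CDR-H1 tryptophan (Kabat 36) not found")
    j = re.search(r"WG.G", vh[w1 + 30:])
    if j is None:
        raise AnnotationError("VH: J-segment WGxG motif not found")
    wg = w1 + 30 + j.start()
    c2 = vh.rfind("C", w1 + 30, wg - 3)
    if c2 < 0:
        raise AnnotationError("VH: second framework cysteine (Kabat 92) not found")
    return {"cys1": c1, "trp": w1, "cys2": c2, "jmotif": wg}


def light_anchor_positions(vl: str) -> dict[str, int]:
    """Locate the VL framework anchors: Cys23, Trp35, Cys88, J-segment FGxG."""
    if len(vl) < _MIN_LIGHT_LEN:
        raise AnnotationError(f"VL too short ({len(vl)} residues) to carry CDR anchors")
    c1 = _first_index(vl, "C", 10, 30)
    if c1 is None:
        raise AnnotationError("VL: first framework cysteine (Kabat 23) not found")
    w1 = _first_index(vl, "W", c1 + 5, c1 + 22)
    if w1 is None:
        raise AnnotationError("VL: post-CDR-L1 tryptophan (Kabat 35) not found")
    j = re.search(r"FG.G", vl[w1 + 22:])
    if j is None:
        raise AnnotationError("VL: J-segment FGxG motif not found")
    fg = w1 + 22 + j.start()
    c2 = vl.rfind("C", w1 + 22, fg - 1)
    if c2 < 0:
        raise AnnotationError("VL: second framework cysteine (Kabat 88) not found")
    return {"cys1": c1, "trp": w1, "cys2": c2, "jmotif": fg}


def anchor_positions(seq: str, chain: Chain) -> set[int]:
    """All positions a mutation must not touch for the spans to stay findable."""
    if chain == "H":
        a = heavy_anchor_positions(seq)
    else:
        a = light_anchor_positions(seq)
    return {a["cys1"], a["trp"], a["cys2"]} | set(range(a["jmotif"], a["jmotif"] + 4))


def annotate_cdrs(fv: FvSequence) -> CdrSet:
    """Delimit the six Kabat CDRs from the framework anchors.

    Heavy: H1 = [Cys22+9, Trp36), H2 = the 16 Kabat 50-65 positions starting
    14 after Trp36, H3 = [Cys92+3, WGxG). Light: L1 = [Cys23+1, Trp35),
    L2 = the 7 positions starting 15 after Trp35, L3 = [Cys88+1, FGxG).
    """
    ha = heavy_anchor_positions(fv.vh)
    la = light_anchor_positions(fv.vl)
    h1 = (ha["cys1"] + 9, ha["trp"])
    h2 = (ha["trp"] + 14, ha["trp"] + 30)
    h3 = (ha["cys2"] + 3, ha["jmotif"])
    l1 = (la["cys1"] + 1, la["trp"])
    l2 = (la["trp"] + 15, la["trp"] + 22)
    l3 = (la["cys2"] + 1, la["jmotif"])
    cdrs = CdrSet(h1=h1, h2=h2, h3=h3, l1=l1, l2=l2, l3=l3)
    cdrs.validate(fv.vh, fv.vl)
    return cdrs


# ---------------------------------------------------------------------------
# Identity metrics and nearest-neighbour searches
# ---------------------------------------------------------------------------

def _comparison_string(fv: FvSequence, mode: IdentityMode) -> str:
    if mode == "full":
        return fv.vh + fv.vl
    if mode == "cdr6":
        if fv.cdrs is None:
            raise ValueError(f"{fv.id}: cdr6 identity requires annotated CDRs")
        return fv.cdr_concat()
    raise ValueError(f"unknown identity mode {mode!r}")


def pairwise_identity(a: FvSequence, b: FvSequence, mode: IdentityMode = "full") -> float:
    """Global-alignment identity between two Fv records under the given mode."""
    sa, sb = _comparison_string(a, mode), _comparison_string(b, mode)
    if not sa or not sb:
        raise ValueError("empty comparison string")
    return identity_fraction(sa, sb)


def max_identity_search(query: FvSequence, db: Sequence, mode: IdentityMode = "full") -> IdentityHit:
    """Best database neighbour of `query`; ties broken by database order.

    Database records need `id`, `vh`, `vl` attributes (and annotated `cdrs`
    for mode=cdr6); a `source` or `patent_id` attribute is carried through.
    """
    if not db:
        raise ValueError("empty reference database")
    best: IdentityHit | None = None
    for record in db:
        rec_fv = record if isinstance(record, FvSequence) else FvSequence(
            record.id, record.vh, record.vl, cdrs=getattr(record, "cdrs", None))
        identity = pairwise_identity(query, rec_fv, mode)
        if best is None or identity > best.identity:
            patent = getattr(record, "patent_id", None) or getattr(record, "source", "")
            best = IdentityHit(query.id, record.id, patent or "", mode, identity)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Germline assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GermlineRecord:
    id: str
    chain: Chain
    seq: str


def read_germline_fasta(path: str | Path) -> list[GermlineRecord]:
    """Read a germline database FASTA with ``>name|IGHV``-style class tags."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if "|" not in header:
            raise PairingError(f"germline header {header!r} lacks a class tag")
        name, tag = header.rsplit("|", 1)
        chain: Chain = "H" if tag.upper().startswith("IGH") else "L"
        out.append(GermlineRecord(name, chain, _validate_sequence(str(record.seq), name)))
    return out


def _chain_mutations(query: str, germline: str) -> tuple[tuple[int, str, str], ...]:
    cols = global_alignment_columns(germline, query)
    muts = []
    for gi, qi in zip(cols[0].tolist(), cols[1].tolist()):
        if gi >= 0 and qi >= 0 and germline[gi] != query[qi]:
            muts.append((qi, germline[gi], query[qi]))
    return tuple(muts)


def assign_germline(fv: FvSequence, germlines: Sequence[GermlineRecord]) -> GermlineAssignment:
    """Closest germline per chain (global identity, first-in-db tie-break)."""
    per_chain: dict[Chain, GermlineRecord] = {}
    for chain in ("H", "L"):
        candidates = [g for g in germlines if g.chain == chain]
        if not candidates:
            raise ValueError(f"germline database has no {chain}-chain entries")
        query = fv.chain(chain)
        best, best_id = None, -1.0
        for g in candidates:
            identity = identity_fraction(query, g.seq)
            if identity > best_id:
                best, best_id = g, identity
        per_chain[chain] = best
    vh_g, vl_g = per_chain["H"], per_chain["L"]
    return GermlineAssignment(
        vh_germline_id=vh_g.id,
        vl_germline_id=vl_g.id,
        vh_germline_seq=vh_g.seq,
        vl_germline_seq=vl_g.seq,
        vh_mutations=_chain_mutations(fv.vh, vh_g.seq),
        vl_mutations=_chain_mutations(fv.vl, vl_g.seq),
    )
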