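"""Off-target prediction by CDR-similarity search against an annotated database.

The similarity of two antibodies is the length-weighted mean of the six
per-CDR global-alignment identities, on a 0-100 scale (weights are the
alignment lengths, so the long H3 dominates naturally). Database hits are
grouped per distinct target (best-scoring record kept), the query's own
intended target is excluded, and hits are tiered high (score >= 70, a
configurable policy) or medium, with the record's human / non-human species
class carried through.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from ._align import global_alignment_columns
from .fv import CDR_ORDER, CdrSet, FvSequence, annotate_cdrs

SpeciesClass = Literal["human", "non-human"]
Tier = Literal["high", "medium"]

HIGH_TIER_THRESHOLD = 70.0


@dataclass
class AntibodyRecord:
    """One reference-database antibody with its target annotation."""

    id: str
    vh: str
    vl: str
    target: str
    species: SpeciesClass
    source: str = ""
    cdrs: CdrSet | None = None

    def as_fv(self) -> FvSequence:
        return FvSequence(self.id, self.vh, self.vl, cdrs=self.cdrs)

    def annotated(self) -> "AntibodyRecord":
        if self.cdrs is None:
            self.cdrs = annotate_cdrs(self.as_fv())
        return self


@dataclass(frozen=True)
class OffTargetHit:
    target: str
    species: SpeciesClass
    score: float
    tier: Tier
    supporting_ids: tuple[str, ...]


def read_antibody_db(path: str | Path) -> list[AntibodyRecord]:
    """Read the reference database TSV (id, vh, vl, target, species, patent/source)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.lower() for c in df.columns]
    source_col = "patent" if "patent" in df.columns else "source"
    records = []
    for row in df.itertuples(index=False):
        species = getattr(row, "species", "human").lower()
        records.append(AntibodyRecord(
            id=row.id, vh=row.vh.upper(), vl=row.vl.upper(),
            target=row.target, species="human" if species == "human" else "non-human",
            source=getattr(row, source_col, ""),
        ))
    return records


def _cdr_identity(a: str, b: str) -> tuple[float, int]:
    """(identity, alignment length) for one CDR pair."""
    cols = global_alignment_columns(a, b)
    matches = 0
    for ia, ib in zip(cols[0].tolist(), cols[1].tolist()):
        if ia >= 0 and ib >= 0 and a[ia] == b[ib]:
            matches += 1
    return matches / cols.shape[1], cols.shape[1]


def cdr_similarity(a: FvSequence, b: FvSequence) -> float:
    """Length-weighted mean per-CDR identity on a 0-100 scale; symmetric."""
    if a.cdrs is None or b.cdrs is None:
        raise ValueError("both antibodies must carry annotated CDRs")
    seqs_a = a.cdrs.cdr_sequences(a.vh, a.vl)
    seqs_b = b.cdrs.cdr_sequences(b.vh, b.vl)
    weighted, total = 0.0, 0
    for name in CDR_ORDER:
        identity, length = _cdr_identity(seqs_a[name], seqs_b[name])
        weighted += identity * length
        total += length
    return 100.0 * weighted / total


def predict_offtargets(query: FvSequence, db: Sequence[AntibodyRecord],
                       self_target: str, min_score: float = 40.0,
                       high_threshold: float = HIGH_TIER_THRESHOLD) -> list[OffTargetHit]:
    """CDR-similarity hits grouped per distinct target, intended target excluded."""
    if not db:
        raise ValueError("empty reference database")
    if query.cdrs is None:
        raise ValueError("query must carry annotated CDRs")
    best: dict[str, tuple[float, SpeciesClass, list[str]]] = {}
    for record in db:
        if record.target == self_target:
            continue
        score = cdr_similarity(query, record.annotated().as_fv())
        if score < min_score:
            continue
        entry = best.get(record.target)
        if entry is None or score > entry[0]:
            best[record.target] = (score, record.species, [record.id])
        elif score == entry[0]:
            entry[2].append(record.id)
    hits = [
        OffTargetHit(target=target, species=species, score=score,
                     tier="high" if score >= high_threshold else "medium",
                     supporting_ids=tuple(ids))
        for target, (score, species, ids) in best.items()
    ]
    hits.sort(key=lambda h: (-h.score, h.target))
    return hits


def offtarget_profile(hits: Sequence[OffTargetHit]) -> dict[tuple[Tier, SpeciesClass], int]:
    """2x2 count table of hits by risk tier and target species class."""
    table: dict[tuple[Tier, SpeciesClass], int] = {
        (tier, species): 0
        for tier in ("high", "medium") for species in ("human", "non-human")
    }
    for hit in hits:
        table[(hit.tier, hit.species)] += 1
    return table
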