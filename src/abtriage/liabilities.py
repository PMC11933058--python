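"""Sequence-level developability: PTM liability motifs, CDR profile, humanness.

Motif classes scanned (liable residue is always the first residue of the
match): N-glycosylation sequons N-X-S/T and N-X-C, lysine glycation K-D/E,
asparagine deamidation N-G/S/D/T/H, aspartate isomerization D-G/S/N/T/H,
aspartate-proline cleavage, and the context-free single-residue oxidation /
hydrolysis liabilities M, W and C. A motif on its own proves nothing about
actual chemical modification; risk is modulated downstream by solvent
exposure and by conservation in the closest germline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from ._align import aligned_position_map
from .errors import DegenerateDistributionError
from .fv import Chain, FvSequence, GermlineAssignment

logger = logging.getLogger(__name__)

MotifClass = Literal[
    "n_glycosylation", "k_glycation", "n_deamidation", "d_isomerization",
    "dp_cleavage", "m_oxidation", "w_oxidation", "c_hydrolysis",
]

ExposureTier = Literal["low", "medium", "high"]

#: Formal side-chain charges at the implied neutral pH (His treated as 0).
RESIDUE_CHARGE: dict[str, float] = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


def _motif_patterns(n_glyc_no_proline: bool = False) -> list[tuple[str, re.Pattern]]:
    x = "[^P]" if n_glyc_no_proline else "[A-Z]"
    return [
        ("n_glycosylation", re.compile(f"(?=(N{x}[STC]))")),
        ("k_glycation", re.compile("(?=(K[DE]))")),
        ("n_deamidation", re.compile("(?=(N[GSDTH]))")),
        ("d_isomerization", re.compile("(?=(D[GSNTH]))")),
        ("dp_cleavage", re.compile("(?=(DP))")),
        ("m_oxidation", re.compile("(?=(M))")),
        ("w_oxidation", re.compile("(?=(W))")),
        ("c_hydrolysis", re.compile("(?=(C))")),
    ]


@dataclass(frozen=True)
class PtmSite:
    """One PTM-prone position on one Fv chain."""

    chain: Chain
    position: int
    motif_class: MotifClass
    matched_text: str
    in_cdr: bool
    germline_conserved: bool | None = None
    exposure: float | None = None
    exposure_tier: ExposureTier | None = None


@dataclass(frozen=True)
class CdrProfile:
    lengths: dict[str, int]
    charges: dict[str, float]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @property
    def total_charge(self) -> float:
        return sum(self.charges.values())


@dataclass(frozen=True)
class HumannessScore:
    chain: Chain
    score: float


@dataclass
class ReferenceDistribution:
    """A named benchmark distribution (e.g. from a clinical-stage panel)."""

    name: str
    values: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"reference distribution {self.name!r} needs >= 2 values")
        self.mean = float(arr.mean())
        self.sd = float(arr.std(ddof=1))

    def percentile_bounds(self, lo: float = 0.05, hi: float = 0.95) -> tuple[float, float]:
        arr = np.asarray(self.values, dtype=float)
        return float(np.quantile(arr, lo)), float(np.quantile(arr, hi))


def scan_sequence(seq: str, n_glyc_no_proline: bool = False,
                  ) -> list[tuple[int, str, str]]:
    """Scan one chain: (position, motif_class, matched_text) per site.

    Every position matching a motif class is reported once per class;
    overlapping motifs are all reported.
    """
    out = []
    for motif_class, pattern in _motif_patterns(n_glyc_no_proline):
        seen: set[int] = set()
        for m in pattern.finditer(seq):
            if m.start() in seen:
                continue
            seen.add(m.start())
            out.append((m.start(), motif_class, m.group(1)))
    out.sort()
    return out


def scan_ptm_motifs(fv: FvSequence, n_glyc_no_proline: bool = False) -> list[PtmSite]:
    """Scan both chains for all PTM liability motifs.

    Every position matching a motif class is reported once per class;
    overlapping motifs are all reported. Sites come back sorted by
    (chain, position, class).
    """
    if fv.cdrs is None:
        raise ValueError(f"{fv.id}: annotate CDRs before scanning (in_cdr labelling)")
    sites: list[PtmSite] = []
    for chain in ("H", "L"):
        seq = fv.chain(chain)
        for pos, motif_class, text in scan_sequence(seq, n_glyc_no_proline):
            sites.append(PtmSite(
                chain=chain,
                position=pos,
                motif_class=motif_class,  # type: ignore[arg-type]
                matched_text=text,
                in_cdr=fv.cdrs.in_cdr(chain, pos),
            ))
    sites.sort(key=lambda s: (s.chain, s.position, s.motif_class))
    return sites


def classify_exposure(site: PtmSite, rsa: float) -> PtmSite:
    """Attach the relative side-chain accessibility and its tier.

    Tiers partition [0, 1] with half-open bins: low (rsa <= 0.30),
    medium (0.30 < rsa <= 0.60), high (rsa > 0.60).
    """
    if not 0.0 <= rsa <= 1.0:
        raise ValueError(f"rsa {rsa} outside [0, 1]")
    if rsa <= 0.30:
        tier: ExposureTier = "low"
    elif rsa <= 0.60:
        tier = "medium"
    else:
        tier = "high"
    return replace(site, exposure=rsa, exposure_tier=tier)


def flag_germline_conserved(site: PtmSite, fv: FvSequence,
                            assignment: GermlineAssignment) -> PtmSite:
    """True iff the same motif class also matches the aligned germline position."""
    query = fv.chain(site.chain)
    germline = assignment.germline_seq(site.chain)
    posmap = aligned_position_map(query, germline)
    gpos = posmap.get(site.position)
    if gpos is None:
        logger.warning("%s %s%d: position falls in an insertion; motif treated as "
                       "not germline-conserved", fv.id, site.chain, site.position)
        return replace(site, germline_conserved=False)
    pattern = dict(_motif_patterns())[site.motif_class]
    conserved = any(m.start() == gpos for m in pattern.finditer(germline))
    return replace(site, germline_conserved=conserved)


def count_exposed_motifs(sites: Iterable[PtmSite], rsa_cutoff: float = 0.30,
                         include_glycation: bool = False) -> int:
    """Count sites with solvent accessibility above the cutoff.

    Lysine glycation sites are excluded from the headline figure by default
    (they are too numerous to be informative) but remain in the site list.
    """
    n = 0
    for site in sites:
        if site.exposure is None:
            raise ValueError("site lacks exposure; run classify_exposure first")
        if site.motif_class == "k_glycation" and not include_glycation:
            continue
        if site.exposure > rsa_cutoff:
            n += 1
    return n


def cdr_profile(fv: FvSequence) -> CdrProfile:
    """Length and net formal charge of each CDR (D/E = -1, K/R = +1, H = 0)."""
    if fv.cdrs is None:
        raise ValueError(f"{fv.id}: annotate CDRs before profiling")
    seqs = fv.cdrs.cdr_sequences(fv.vh, fv.vl)
    lengths = {name: len(s) for name, s in seqs.items()}
    charges = {name: sum(RESIDUE_CHARGE.get(ch, 0.0) for ch in s)
               for name, s in seqs.items()}
    return CdrProfile(lengths=lengths, charges=charges)


def _kmer_set(sequences: Iterable[str], k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i:i + k])
    return kmers


class HumanReference:
    """A k-mer containment reference built from human chain sequences."""

    def __init__(self, sequences: Iterable[str], k: int = 9):
        self.k = k
        self.kmers = _kmer_set(sequences, k)
        if not self.kmers:
            raise ValueError("human reference set yields no k-mers")


def humanness_score(chain_seq: str, human_ref: HumanReference | Iterable[str],
                    chain: Chain = "H", k: int = 9) -> HumannessScore:
    """Fraction of the chain's overlapping k-mers found in the human reference.

    The score is 1 for any member of the reference set, near 0 for a random
    sequence, and intermediate for humanized scaffolds carrying foreign CDRs.
    """
    ref = human_ref if isinstance(human_ref, HumanReference) else HumanReference(human_ref, k)
    if len(chain_seq) < ref.k:
        raise ValueError(f"chain shorter than k = {ref.k}")
    n_kmers = len(chain_seq) - ref.k + 1
    hits = sum(1 for i in range(n_kmers) if chain_seq[i:i + ref.k] in ref.kmers)
    return HumannessScore(chain=chain, score=hits / n_kmers)


def compare_to_reference(value: float, dist: ReferenceDistribution) -> tuple[float, float]:
    """z-score and empirical percentile of `value` against a benchmark panel."""
    if dist.sd == 0:
        raise DegenerateDistributionError(f"distribution {dist.name!r} has zero spread")
    z = (value - dist.mean) / dist.sd
    arr = np.asarray(dist.values, dtype=float)
    percentile = float(np.mean(arr <= value))
    return z, percentile
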