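"""Coarse-grained antibody-antigen interface scoring against a reference pose.

No docking is performed: each candidate Fv is rigidly superposed onto the
bound orientation of a reference antibody (least-squares fit of the aligned
framework representatives, proper rotation enforced), the facing centroid
pairs are extracted under a distance cutoff, and three scores are computed:

PCC  physico-chemical complementarity of the facing regions — the mean over
     facing pairs of (+1 both hydrophobic, +1 opposite charges, -1 same-sign
     charges, 0 otherwise, hydrophobic and charge terms summed per pair);
IR   the number of interacting region pairs;
C    the within-panel combination: mean of min-max-normalised PCC and IR.

The predicted epitope (target residues in contact) supports competition
prediction via Jaccard overlap of epitope maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._align import global_alignment_columns
from .errors import AlignmentError
from .surface import CoarseStructure, PatchThresholds

DEFAULT_INTERFACE_CUTOFF = 8.0


@dataclass
class ComplexPose:
    """An antibody placed on its target, with the rigid transform applied."""

    antibody: CoarseStructure
    target: CoarseStructure
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rmsd: float = 0.0
    target_id: str = "target"


@dataclass(frozen=True)
class EpitopeMap:
    target_id: str
    epitope: frozenset[tuple[str, int]]  # (chain, residue number) on the target
    paratope: frozenset[tuple[str, int]]


@dataclass(frozen=True)
class InterfaceScore:
    pcc: float  # NaN when there are no facing pairs
    ir: int
    facing_pairs: tuple[tuple[int, int], ...]
    epitope: EpitopeMap


def _kabsch(mobile: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of `mobile` onto `fixed` (proper rotation)."""
    mc, fc = mobile.mean(axis=0), fixed.mean(axis=0)
    h = (mobile - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = fc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return rotation, translation, rmsd


def _alignable_pairs(candidate: CoarseStructure, reference: CoarseStructure,
                     framework_only: bool = True) -> list[tuple[int, int]]:
    """Residue index pairs matched by per-chain sequence alignment."""
    cand_seqs = candidate.sequence_by_chain()
    ref_seqs = reference.sequence_by_chain()
    cand_offsets: dict[str, list[int]] = {}
    ref_offsets: dict[str, list[int]] = {}
    for i, r in enumerate(candidate.residues):
        cand_offsets.setdefault(r.chain, []).append(i)
    for i, r in enumerate(reference.residues):
        ref_offsets.setdefault(r.chain, []).append(i)
    pairs: list[tuple[int, int]] = []
    for chain in sorted(set(cand_seqs) & set(ref_seqs)):
        cols = global_alignment_columns(cand_seqs[chain], ref_seqs[chain])
        for ci, ri in zip(cols[0].tolist(), cols[1].tolist()):
            if ci >= 0 and ri >= 0:
                pairs.append((cand_offsets[chain][ci], ref_offsets[chain][ri]))
    return pairs


def align_onto_reference(candidate: CoarseStructure, reference_pose: ComplexPose,
                         min_alignable: int = 20) -> ComplexPose:
    """Superpose a candidate onto the reference antibody's bound orientation.

    Correspondences come from per-chain sequence alignment of the candidate
    against the reference antibody; the transform is the least-squares proper
    rotation of those representatives, and the reported RMSD is over the same
    positions.
    """
    pairs = _alignable_pairs(candidate, reference_pose.antibody)
    if len(pairs) < min_alignable:
        raise AlignmentError(
            f"only {len(pairs)} alignable positions (need >= {min_alignable})")
    cand_idx = [p[0] for p in pairs]
    ref_idx = [p[1] for p in pairs]
    rotation, translation, rmsd = _kabsch(candidate.coords[cand_idx],
                                          reference_pose.antibody.coords[ref_idx])
    moved = candidate.transformed(rotation, translation)
    return ComplexPose(antibody=moved, target=reference_pose.target,
                       rotation=rotation, translation=translation, rmsd=rmsd,
                       target_id=reference_pose.target_id)


def extract_interface(pose: ComplexPose,
                      cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                      ) -> tuple[list[tuple[int, int]], EpitopeMap]:
    """Facing centroid pairs and the residue-level epitope/paratope maps."""
    ab, tg = pose.antibody, pose.target
    if ab.centroids is None or tg.centroids is None:
        raise ValueError("both structures need centroids")
    ab_pos = np.array([c.position for c in ab.centroids])
    tg_pos = np.array([c.position for c in tg.centroids])
    d = cdist(ab_pos, tg_pos)
    pairs = [(int(i), int(j)) for i, j in np.argwhere(d <= cutoff)]
    facing_ab = {i for i, _ in pairs}
    facing_tg = {j for _, j in pairs}
    ab_coords, tg_coords = ab.coords, tg.coords

    epitope: set[tuple[str, int]] = set()
    for j in facing_tg:
        for ridx in tg.centroids[j].members:
            dmin = min(np.linalg.norm(tg_coords[ridx] - ab_pos[i]) for i in facing_ab)
            if dmin <= cutoff:
                r = tg.residues[ridx]
                epitope.add((r.chain, r.index))
    paratope: set[tuple[str, int]] = set()
    for i in facing_ab:
        for ridx in ab.centroids[i].members:
            dmin = min(np.linalg.norm(ab_coords[ridx] - tg_pos[j]) for j in facing_tg)
            if dmin <= cutoff:
                r = ab.residues[ridx]
                paratope.add((r.chain, r.index))
    emap = EpitopeMap(pose.target_id, frozenset(epitope), frozenset(paratope))
    return pairs, emap


def pcc_score(pose: ComplexPose, facing_pairs: Sequence[tuple[int, int]],
              thresholds: PatchThresholds) -> float:
    """Mean per-pair complementarity of the facing centroid pairs.

    Per pair: +1 if both centroids are hydrophobic (above the hydrophobicity
    moderate threshold), +1 for opposite-sign net charges, -1 for same-sign
    nonzero charges; the two terms are summed per pair and averaged.
    """
    if not facing_pairs:
        raise ValueError("PCC undefined with zero facing pairs")
    hydro_cut = thresholds.moderate["hydrophobicity"]
    total = 0.0
    for i, j in facing_pairs:
        ca = pose.antibody.centroids[i]
        ct = pose.target.centroids[j]
        term = 0.0
        if ca.property_value("hydrophobicity") > hydro_cut and \
           ct.property_value("hydrophobicity") > hydro_cut:
            term += 1.0
        qa, qt = ca.property_value("charge"), ct.property_value("charge")
        if qa * qt < 0:
            term += 1.0
        elif qa * qt > 0:
            term -= 1.0
        total += term
    return total / len(facing_pairs)


def ir_score(facing_pairs: Sequence[tuple[int, int]]) -> int:
    """Number of interacting (facing) region pairs."""
    return len(facing_pairs)


def merged_region_count(pose: ComplexPose,
                        facing_pairs: Sequence[tuple[int, int]],
                        merge_cutoff: float = 10.0) -> int:
    """Alternative IR reading: contiguous interface regions after merging
    facing pairs whose antibody-side centroids are adjacent."""
    if not facing_pairs:
        return 0
    ab_ids = sorted({i for i, _ in facing_pairs})
    pos = np.array([pose.antibody.centroids[i].position for i in ab_ids])
    d = cdist(pos, pos)
    n = len(ab_ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            if d[a, b] <= merge_cutoff:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    return len({find(i) for i in range(n)})


def _minmax(values: np.ndarray) -> np.ndarray:
    """Min-max normalisation; a spread-free panel maps to 0.5, NaN to 0."""
    out = np.full(values.shape, 0.5)
    finite = np.isfinite(values)
    if finite.any():
        lo, hi = values[finite].min(), values[finite].max()
        if hi > lo:
            out[finite] = (values[finite] - lo) / (hi - lo)
        else:
            out[finite] = 0.5
    out[~finite] = 0.0
    return out


def c_score(panel: Sequence[tuple[float, float]]) -> list[float]:
    """Per-candidate combined score: mean of min-max-normalised PCC and IR."""
    if len(panel) < 2:
        raise ValueError("C-score is panel-relative; need >= 2 candidates")
    pcc = np.array([p for p, _ in panel], dtype=float)
    ir = np.array([i for _, i in panel], dtype=float)
    combined = (_minmax(pcc) + _minmax(ir)) / 2.0
    return combined.tolist()


@dataclass(frozen=True)
class RankedCandidate:
    id: str
    c: float
    score: InterfaceScore
    rmsd: float


def rank_candidates(panel: Sequence[tuple[str, CoarseStructure]],
                    reference_pose: ComplexPose,
                    thresholds: PatchThresholds,
                    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                    ) -> tuple[list[RankedCandidate], list[str]]:
    """Full align -> interface -> PCC/IR -> panel C-score pipeline.

    Returns candidates ordered by decreasing C-score, plus the ids of any
    unalignable candidates (reported separately, not scored).
    """
    if not panel:
        raise ValueError("empty candidate panel")
    scored: list[tuple[str, InterfaceScore, float]] = []
    unalignable: list[str] = []
    for cand_id, structure in panel:
        try:
            pose = align_onto_reference(structure, reference_pose)
        except AlignmentError:
            unalignable.append(cand_id)
            continue
        pairs, emap = extract_interface(pose, cutoff)
        ir = ir_score(pairs)
        pcc = pcc_score(pose, pairs, thresholds) if ir > 0 else math.nan
        scored.append((cand_id, InterfaceScore(pcc, ir, tuple(pairs), emap), pose.rmsd))
    if len(scored) >= 2:
        combined = c_score([(s.pcc, float(s.ir)) for _, s, _ in scored])
    else:
        combined = [0.5] * len(scored)
    ranked = [RankedCandidate(cid, c, s, rmsd)
              for (cid, s, rmsd), c in zip(scored, combined)]
    ranked.sort(key=lambda r: (-r.c, r.id))
    return ranked, unalignable


def epitope_overlap(a: EpitopeMap, b: EpitopeMap,
                    competition_threshold: float = 0.25) -> tuple[float, bool]:
    """Jaccard overlap of two epitopes on the same target; competition flag."""
    if a.target_id != b.target_id:
        raise ValueError(f"epitope maps on different targets: "
                         f"{a.target_id!r} vs {b.target_id!r}")
    if not a.epitope and not b.epitope:
        return 0.0, False
    inter = len(a.epitope & b.epitope)
    union = len(a.epitope | b.epitope)
    overlap = inter / union
    return overlap, overlap >= competition_threshold
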