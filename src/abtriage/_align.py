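"""Internal global-alignment helpers shared by the sequence-facing modules.

Identity is the metric everywhere in this package (not similarity), so the
aligner scores match 1 / mismatch 0 with a linear gap penalty of -1 and the
identity fraction is read off the traceback as matches / alignment length
(gaps count against the denominator).
"""

from __future__ import annotations

import functools

import numpy as np
from Bio import Align


@functools.lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_alignment_columns(a: str, b: str) -> np.ndarray:
    """Align two sequences globally and return the column index map.

    Returns an integer array of shape (2, n_columns); entry -1 marks a gap,
    otherwise the 0-based position in the respective input sequence.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(a, b)[0]
    return np.asarray(alignment.indices)


def identity_fraction(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length, in [0, 1]."""
    cols = global_alignment_columns(a, b)
    ia, ib = cols[0], cols[1]
    aligned = (ia >= 0) & (ib >= 0)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    matches = int(np.sum(arr_a[ia[aligned]] == arr_b[ib[aligned]]))
    return matches / cols.shape[1]


def aligned_position_map(a: str, b: str) -> dict[int, int]:
    """Map positions of `a` to aligned positions of `b` (gap-aligned omitted)."""
    cols = global_alignment_columns(a, b)
    ia, ib = cols[0], cols[1]
    keep = (ia >= 0) & (ib >= 0)
    return dict(zip(ia[keep].tolist(), ib[keep].tolist()))
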