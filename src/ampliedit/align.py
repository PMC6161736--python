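"""Semi-global read-to-amplicon alignment.

Reads are aligned end-to-end (read global) against the amplicon (reference
local) under a fixed affine scheme: match +1, mismatch -1, and a gap of
length L costs -(3 + L) (open -3, extend -1).  Both read orientations are
tried and the better-scoring one kept.  Reads whose fraction of matching
bases falls below ``min_identity`` are rejected -- the analogue, for a
single-reference amplicon where multi-mapping MAPQ is undefined, of a
minimum-mapping-quality filter.

The dynamic programming itself is delegated to Bio.Align.PairwiseAligner,
configured to this exact scheme (checked against an independent
dynamic-programming oracle in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align, BiopythonDeprecationWarning

from .reference import AmpliconReference

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadAlignment:
    """One accepted alignment of an (oriented) read against the reference.

    ``ref_to_read[j]`` gives the index into ``read_seq`` of the base aligned
    at reference offset ``j``, or -1 where the read does not cover offset
    ``j`` with a base (gap or outside the aligned span).  ``read_seq`` is the
    read in aligned orientation; when ``orientation`` is "-" the caller must
    reverse its quality string to match.
    """

    score: float
    identity: float
    orientation: str
    read_seq: str
    ref_to_read: np.ndarray
    matches: int

    @property
    def mismatch_offsets(self) -> list[int]:
        return [
            j
            for j, i in enumerate(self.ref_to_read)
            if i >= 0 and self.read_seq[i] != self._ref_seq[j]
        ]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4  # first gap base: open(-3) + extend(-1)
    aligner.extend_gap_score = -1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonDeprecationWarning)
        # free end gaps on the reference side only (read stays global)
        aligner.query_end_gap_score = 0.0
    return aligner


@lru_cache(maxsize=1)
def _shared_aligner() -> Align.PairwiseAligner:
    return _make_aligner()


def alignment_score(read: str, reference_seq: str) -> float:
    """Optimal semi-global score of ``read`` against ``reference_seq`` (one orientation)."""
    return float(_shared_aligner().score(reference_seq, read))


def align_read(
    read: str,
    reference: AmpliconReference | str,
    min_identity: float = 0.8,
) -> ReadAlignment | None:
    """Align one read in both orientations; return the better, or None if rejected.

    Identity is the fraction of read bases matching the reference in the
    optimal alignment.  Orientation ties prefer the forward read.
    """
    ref_seq = reference.sequence if isinstance(reference, AmpliconReference) else reference
    if not read:
        raise ValueError("empty read")
    bad = set(read.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in read: {sorted(bad)}")
    read = read.upper()
    aligner = _shared_aligner()
    fwd_score = aligner.score(ref_seq, read)
    if fwd_score == len(read):  # perfect forward match; reverse cannot beat it
        rev_score = -np.inf
    else:
        rev_score = aligner.score(ref_seq, reverse_complement(read))
    rc = reverse_complement(read)
    if rev_score > fwd_score:
        oriented, orientation, score = rc, "-", rev_score
    else:
        oriented, orientation, score = read, "+", fwd_score
    aln = aligner.align(ref_seq, oriented)[0]
    ref_to_read = np.full(len(ref_seq), -1, dtype=np.int64)
    ref_arr = np.frombuffer(ref_seq.encode(), dtype="S1")
    read_arr = np.frombuffer(oriented.encode(), dtype="S1")
    matches = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        ref_to_read[t0:t1] = np.arange(q0, q1)
        matches += int((ref_arr[t0:t1] == read_arr[q0:q1]).sum())
    identity = matches / len(oriented)
    if identity < min_identity:
        return None
    out = ReadAlignment(
        score=float(score),
        identity=identity,
        orientation=orientation,
        read_seq=oriented,
        ref_to_read=ref_to_read,
        matches=matches,
    )
    out._ref_seq = ref_seq  # for mismatch introspection
    return out
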