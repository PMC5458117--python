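"""Per-pair consensus determination from the two in-read fragment copies.

The first copy and the reverse complement of the second are aligned to each
other without end gaps; the offset maximising exact matches wins and a pair
is rejected when the best overlap still carries more than one mismatch.  The
consensus takes the union of both aligned copies.  A base supported by both
copies gets the summed quality (capped at 93, the phred-33 ceiling); a base
seen in only one copy, or at the tolerated disagreeing position, is masked
with quality 2 so it can never contribute variant evidence downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import MASK_QUALITY, PHRED_MAX, SequenceRecord
from .preprocess import SplitResult
from .simulate import revcomp


@dataclass(eq=False)
class ConsensusRead:
    """The error-corrected fragment sequence (CS) for one read pair."""

    sequence: str
    qualities: np.ndarray
    dual_support: np.ndarray
    pair_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_masked(self) -> int:
        return int((~self.dual_support).sum())


@dataclass
class CopyAlignment:
    """End-gap-free placement of revcomp(copy 2) against copy 1.

    ``offset`` is the start of the reverse-complemented second copy in
    first-copy coordinates; ``mismatches`` are overlap positions (first-copy
    coordinates) where the copies disagree.
    """

    offset: int
    overlap_start: int
    overlap_end: int
    mismatches: tuple[int, ...]
    rc2: SequenceRecord

    @property
    def overlap(self) -> int:
        return self.overlap_end - self.overlap_start

    @property
    def n_matches(self) -> int:
        return self.overlap - len(self.mismatches)


def _mismatch_positions(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.flatnonzero(a != b)


def align_copies(
    target1: SequenceRecord,
    target2: SequenceRecord,
    max_mismatch: int = 1,
    min_overlap_bases: int = 30,
) -> CopyAlignment | None:
    """Align copy 1 against revcomp(copy 2); reject on >1 mismatch.

    The search is exact over all end-gap-free offsets but prunes offsets whose
    maximum possible overlap cannot beat the best match count already found;
    ties go to the smallest absolute offset (positive before negative).
    """
    a, b = target1.sequence, target2.sequence
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return None
    rc2 = SequenceRecord(
        target2.id,
        revcomp(b),
        None if target2.qualities is None else target2.qualities[::-1].copy(),
    )
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(rc2.sequence.encode("ascii"), dtype=np.uint8)

    def evaluate(d: int) -> tuple[int, int, int, np.ndarray]:
        lo = max(0, d)
        hi = min(la, d + lb)
        mism = _mismatch_positions(arr_a[lo:hi], arr_b[lo - d : hi - d]) + lo
        return lo, hi, hi - lo - mism.size, mism

    # offset 0 first: with near-identical copies it is almost always optimal
    best_d = 0
    best_lo, best_hi, best_matches, best_mism = evaluate(0)
    if rc2.sequence[: min(la, lb)] != a[: min(la, lb)]:  # not already perfect
        d = 0
        for step in range(1, la + lb):
            d = -d + 1 if d <= 0 else -d  # 1, -1, 2, -2, ...
            if abs(d) >= la + lb:
                break
            possible = min(la, d + lb) - max(0, d)
            if possible <= best_matches:
                if possible <= 0 and abs(d) >= max(la, lb):
                    break
                continue
            lo, hi, matches, mism = evaluate(d)
            if matches > best_matches:
                best_d, best_lo, best_hi, best_matches, best_mism = d, lo, hi, matches, mism
    overlap = best_hi - best_lo
    if overlap < min_overlap_bases or best_mism.size > max_mismatch:
        return None
    return CopyAlignment(
        offset=best_d,
        overlap_start=best_lo,
        overlap_end=best_hi,
        mismatches=tuple(int(p) for p in best_mism),
        rc2=rc2,
    )


def build_consensus(
    target1: SequenceRecord,
    target2: SequenceRecord,
    alignment: CopyAlignment,
    pair_id: str = "",
) -> ConsensusRead:
    """Union of the two aligned copies with summed/capped/masked qualities."""
    a, rc2 = target1, alignment.rc2
    la, lb, d = len(a), len(rc2), alignment.offset
    lo, hi = alignment.overlap_start, alignment.overlap_end
    start = min(0, d)
    end = max(la, d + lb)
    n = end - start
    q1 = a.qualities
    q2 = rc2.qualities

    seq = np.empty(n, dtype="<U1")  # filled per segment below
    qual = np.full(n, MASK_QUALITY, dtype=np.int16)
    dual = np.zeros(n, dtype=bool)

    a_arr = np.array(list(a.sequence))
    b_arr = np.array(list(rc2.sequence))
    # copy-1 overhangs and copy-2 overhangs (single support, masked)
    seq[0 - start : la - start] = a_arr
    if d < 0:
        seq[0 : lo - start] = b_arr[:lo - d]
    if d + lb > la:
        seq[la - start :] = b_arr[la - d :]
    # overlap: summed quality where the copies agree
    ov = slice(lo - start, hi - start)
    qual[ov] = np.minimum(PHRED_MAX, q1[lo:hi] + q2[lo - d : hi - d])
    dual[ov] = True
    # disagreeing positions: keep the higher-quality base, mask the quality
    for p in alignment.mismatches:
        i = p - start
        take2 = q2[p - d] > q1[p]
        seq[i] = b_arr[p - d] if take2 else a_arr[p]
        qual[i] = MASK_QUALITY
        dual[i] = False
    return ConsensusRead(
        sequence="".join(seq.tolist()),
        qualities=qual,
        dual_support=dual,
        pair_id=pair_id or target1.id.rsplit("/", 1)[0],
    )


def consensus_from_split(
    split: SplitResult,
    max_mismatch: int = 1,
    min_overlap_bases: int = 30,
) -> ConsensusRead | None:
    """Convenience: align + build for one split pair (``None`` on rejection)."""
    alignment = align_copies(
        split.target1, split.target2, max_mismatch, min_overlap_bases
    )
    if alignment is None:
        return None
    return build_consensus(split.target1, split.target2, alignment)
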