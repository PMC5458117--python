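"""Adaptor splitting and quality filtering of raw o2n read pairs.

Splitting removes the 5 leading primer bases from each mate and locates the
intermediate adaptor (forward orientation in read 1, reverse complement in
read 2).  Because fragments are longer than half a read minus the adaptor,
the adaptor usually appears only partially, as a prefix overlapping the read
end; matching therefore accepts suffix overlaps down to ``min_overlap`` bases
under a Hamming mismatch tolerance.  Quality filtering applies four rules in
order: trailing sub-20 trim, 4-base sliding-window cut, minimum length 36 and
minimum mean quality 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .formats import ReadPair, SequenceRecord
from .simulate import revcomp


@dataclass
class SplitResult:
    """Putative fragment copies recovered from one pair.

    ``adaptor_hit1``/``adaptor_hit2`` are offsets of the adaptor match within
    the post-prefix body of each mate (``None`` when no match was found, in
    which case the target is the full body remainder).
    """

    target1: SequenceRecord
    target2: SequenceRecord
    right_on: bool
    adaptor_hit1: int | None
    adaptor_hit2: int | None


def find_adaptor(
    body: str,
    adaptor: str,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
) -> int | None:
    """Locate the adaptor in ``body``; return the match start offset.

    Considers every end-gap-free placement, including suffix overlaps of at
    least ``min_overlap`` adaptor-prefix bases at the read end.  A placement
    with overlap ``ov`` tolerates ``ceil(max_mismatch_rate * ov)`` mismatches.
    The best match minimises the mismatch ratio, with ties broken toward the
    longer overlap and then the smaller offset.  Exact placements are found
    with C-speed string search; the tolerant Hamming scan only runs when no
    exact placement exists.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    la, lb = len(adaptor), len(body)
    if lb < min_overlap:
        return None
    # exact placements: full interior occurrences ...
    best_exact: tuple[int, int] | None = None  # (overlap, offset), overlap maximal
    pos = body.find(adaptor)
    if pos != -1:
        best_exact = (la, pos)
    # ... and exact suffix overlaps of the adaptor prefix at the read end
    if best_exact is None or best_exact[0] < min(la, lb):
        for ov in range(min(la, lb), min_overlap - 1, -1):
            if best_exact is not None and ov <= best_exact[0]:
                break
            if body.endswith(adaptor[:ov]):
                best_exact = (ov, lb - ov)
                break
    if best_exact is not None:
        return best_exact[1]
    # tolerant scan over all offsets (rare: only reads with adaptor errors)
    best: tuple[float, int, int] | None = None  # (ratio, -overlap, offset)
    for off in range(0, lb - min_overlap + 1):
        ov = min(la, lb - off)
        tol = ceil(max_mismatch_rate * ov)
        mism = 0
        window = body[off : off + ov]
        for x, y in zip(window, adaptor):
            if x != y:
                mism += 1
                if mism > tol:
                    break
        else:
            key = (mism / ov, -ov, off)
            if best is None or key < best:
                best = key
    return best[2] if best is not None else None


def split_o2n_read(
    pair: ReadPair,
    adaptor: str,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
    prefix_trim1: int = 5,
    prefix_trim2: int = 5,
) -> SplitResult | None:
    """Strip primer prefixes and cut each mate at its adaptor match.

    Returns ``None`` when either mate is shorter than 6 bases.  ``right_on``
    is true when the adaptor was located in at least one mate; for a mate
    without a match the target is its full post-prefix remainder.
    """
    r1, r2 = pair.read1, pair.read2
    if len(r1) < 6 or len(r2) < 6:
        return None
    body1 = r1.sequence[prefix_trim1:]
    body2 = r2.sequence[prefix_trim2:]
    hit1 = find_adaptor(body1, adaptor, min_overlap, max_mismatch_rate)
    hit2 = find_adaptor(body2, revcomp(adaptor), min_overlap, max_mismatch_rate)
    end1 = hit1 if hit1 is not None else len(body1)
    end2 = hit2 if hit2 is not None else len(body2)
    target1 = SequenceRecord(
        f"{pair.pair_id}/1",
        body1[:end1],
        r1.qualities[prefix_trim1 : prefix_trim1 + end1],
    )
    target2 = SequenceRecord(
        f"{pair.pair_id}/2",
        body2[:end2],
        r2.qualities[prefix_trim2 : prefix_trim2 + end2],
    )
    return SplitResult(
        target1=target1,
        target2=target2,
        right_on=hit1 is not None or hit2 is not None,
        adaptor_hit1=hit1,
        adaptor_hit2=hit2,
    )


def quality_filter(
    read: SequenceRecord,
    min_quality: int = 20,
    window: int = 4,
    min_length: int = 36,
) -> SequenceRecord | None:
    """Apply the four quality rules; return the trimmed read or ``None``.

    Rule order: (1) cut trailing bases below ``min_quality``; (2) scan 5'->3'
    with a ``window``-base sliding window and cut when the window mean drops
    below ``min_quality`` — the cut lands on the first individually sub-par
    base inside the failing window, so leading good bases of that window are
    kept; (3) discard reads shorter than ``min_length``; (4) discard reads
    whose mean quality is below ``min_quality``.  The trailing trim is
    re-applied after the window cut so the whole operation is idempotent.
    """
    q = read.qualities
    if q is None:
        raise ValueError("quality_filter requires per-base qualities")
    n = q.size
    if n and q.min() >= min_quality:  # fast path: nothing can trim
        return read if n >= min_length else None

    def _trail_trim(limit: int) -> int:
        keep = np.flatnonzero(q[:limit] >= min_quality)
        return int(keep[-1]) + 1 if keep.size else 0

    end = _trail_trim(n)
    if end >= window:
        sums = np.convolve(q[:end], np.ones(window, dtype=np.int64), mode="valid")
        bad = np.flatnonzero(sums < min_quality * window)
        if bad.size:
            cut = int(bad[0])
            while cut < end and q[cut] >= min_quality:
                cut += 1
            end = _trail_trim(cut)
    if end < min_length:
        return None
    if float(q[:end].mean()) < min_quality:
        return None
    if end == n:
        return read
    return SequenceRecord(read.id, read.sequence[:end], q[:end])
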