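"""Mapping consensus reads, alignment filtering, pileup and variant calling.

The internal mapper is a deliberately small ungapped k-mer seed aligner: the
upstream pipeline discards indel-containing alignments anyway, so an ungapped
placement search loses nothing the pipeline keeps.  Externally produced SAM
alignments can be ingested instead; they pass through the same filters.

A variant is called when its alternate allele is supported by at least
``min_cs`` consensus sequences with *distinct contexts* — differing mapped
start, length or sequence — and its allele fraction clears ``min_maf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .consensus import ConsensusRead
from .formats import SequenceRecord
from .simulate import revcomp


@dataclass(eq=False)
class AlignmentRecord:
    """A consensus read placed (ungapped) on the reference."""

    cs: ConsensusRead
    ref_id: str
    start: int
    strand: str
    mapq: int
    #: (ref position, ref base, cs base, cs quality), reference-oriented
    mismatches: list[tuple[int, str, str, int]]
    #: sequence/qualities re-oriented to the reference strand
    seq_oriented: str
    qual_oriented: np.ndarray
    usable_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.seq_oriented)

    @property
    def end(self) -> int:
        return self.start + len(self.seq_oriented)

    @property
    def context(self) -> tuple[int, int, str]:
        """Distinct-CS identity: (mapped start, length, sequence)."""
        return (self.start, len(self.seq_oriented), self.seq_oriented)


@dataclass(eq=False)
class AlleleObservation:
    count: int = 0
    forward: int = 0
    reverse: int = 0
    contexts: set = field(default_factory=set)
    qualities: list = field(default_factory=list)


@dataclass(eq=False)
class PileupColumn:
    """Per-position allele counts with distinct-context and strand detail."""

    ref_id: str
    position: int
    ref_base: str
    depth: int
    alleles: dict[str, AlleleObservation]


@dataclass(frozen=True)
class VariantCall:
    ref_id: str
    position: int
    ref_base: str
    alt_base: str
    support: int
    depth: int
    maf: float


class ReferenceIndex:
    """Exact-substring plus tiled k-mer seed index over one reference."""

    def __init__(self, reference: SequenceRecord, k: int = 15):
        self.ref_id = reference.id
        self.sequence = reference.sequence
        self.k = k
        self.array = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
        self._kmers: dict[str, list[int]] = {}
        seq = self.sequence
        for i in range(len(seq) - k + 1):
            self._kmers.setdefault(seq[i : i + k], []).append(i)

    def __len__(self) -> int:
        return len(self.sequence)

    def exact_occurrences(self, query: str) -> list[int]:
        hits = []
        pos = self.sequence.find(query)
        while pos != -1:
            hits.append(pos)
            pos = self.sequence.find(query, pos + 1)
        return hits

    def seed_candidates(self, query: str) -> set[int]:
        """Candidate start positions from non-overlapping tiled seeds.

        With ``s`` tiled seeds any placement carrying fewer than ``s``
        mismatches shares at least one exact seed, so for reads of >= 3k
        bases every placement within the mapper's mismatch budget is found.
        """
        k, L, lq = self.k, len(self.sequence), len(query)
        if lq < k:
            return set()
        offsets = list(range(0, lq - k + 1, k))
        if offsets[-1] != lq - k:
            offsets.append(lq - k)
        candidates: set[int] = set()
        for off in offsets:
            for pos in self._kmers.get(query[off : off + k], ()):
                start = pos - off
                if 0 <= start <= L - lq:
                    candidates.add(start)
        return candidates


def map_consensus(
    cs: ConsensusRead,
    index: ReferenceIndex,
    max_mismatches: int = 3,
) -> AlignmentRecord | None:
    """Place a consensus read on the reference (both strands, ungapped).

    mapq is 60 when the best placement is unique and beats the second best by
    at least 2 mismatches, otherwise 0; reads whose best placement still has
    more than ``max_mismatches`` mismatches are unmapped (``None``).
    """
    lq = len(cs.sequence)
    if lq == 0 or lq > len(index):
        return None
    oriented = {
        "+": (cs.sequence, cs.qualities),
        "-": (revcomp(cs.sequence), cs.qualities[::-1]),
    }
    scored: dict[tuple[str, int], int] = {}
    arrays: dict[str, np.ndarray] = {}
    for strand, (query, _) in oriented.items():
        qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        arrays[strand] = qarr
        candidates = set(index.exact_occurrences(query))
        candidates |= index.seed_candidates(query)
        for start in candidates:
            key = (strand, start)
            if key not in scored:
                diff = int((index.array[start : start + lq] != qarr).sum())
                scored[key] = diff
    if not scored:
        return None
    ranked = sorted(scored.items(), key=lambda kv: (kv[1], kv[0][1], kv[0][0]))
    (strand, start), best_mm = ranked[0]
    if best_mm > max_mismatches:
        return None
    second_mm = ranked[1][1] if len(ranked) > 1 else None
    mapq = 60 if (second_mm is None or second_mm - best_mm >= 2) else 0
    query, qual = oriented[strand]
    qarr = arrays[strand]
    mism_idx = np.flatnonzero(index.array[start : start + lq] != qarr)
    mismatches = [
        (start + int(i), index.sequence[start + int(i)], query[int(i)], int(qual[int(i)]))
        for i in mism_idx
    ]
    return AlignmentRecord(
        cs=cs,
        ref_id=index.ref_id,
        start=start,
        strand=strand,
        mapq=mapq,
        mismatches=mismatches,
        seq_oriented=query,
        qual_oriented=np.asarray(qual),
    )


def filter_and_trim(
    rec: AlignmentRecord,
    max_mismatches: int = 1,
    min_mapq: int = 25,
    min_base_quality: int = 50,
    edge_trim: int = 3,
    has_indel: bool = False,
) -> AlignmentRecord | None:
    """Apply the post-mapping filters; returns ``None`` when the CS is dropped.

    Drops indel-containing (ingested) alignments, low-mapq placements and
    alignments with more than ``max_mismatches`` mismatches *at usable
    bases*; masks bases below ``min_base_quality`` (which removes every
    single-copy-supported base, since those carry the quality-2 mask) and the
    ``edge_trim`` terminal bases on each side.
    """
    if has_indel or rec.mapq < min_mapq:
        return None
    n = len(rec.seq_oriented)
    if n <= 2 * edge_trim:
        return None
    usable = rec.qual_oriented >= min_base_quality
    usable[:edge_trim] = False
    usable[n - edge_trim :] = False
    countable = [m for m in rec.mismatches if usable[m[0] - rec.start]]
    if len(countable) > max_mismatches:
        return None
    rec.usable_mask = usable
    rec.mismatches = countable
    return rec


def pileup(
    records: Iterable[AlignmentRecord],
    index: ReferenceIndex,
    edge_trim: int = 3,
) -> list[PileupColumn]:
    """Accumulate filtered alignments into per-position allele columns.

    Every usable base contributes to exactly one column; reference-allele
    counts are derived from strand-resolved coverage so only non-reference
    observations need explicit bookkeeping (their distinct contexts, strands
    and qualities are collected per allele).
    """
    L = len(index)
    cov = {"+": np.zeros(L + 1, dtype=np.int64), "-": np.zeros(L + 1, dtype=np.int64)}
    alt_obs: dict[int, dict[str, AlleleObservation]] = {}
    for rec in records:
        usable = rec.usable_mask
        if usable is None:
            raise ValueError("pileup requires filtered records (run filter_and_trim)")
        n = len(rec.seq_oriented)
        diff = cov[rec.strand]
        diff[rec.start + edge_trim] += 1
        diff[rec.start + n - edge_trim] -= 1
        holes = np.flatnonzero(~usable[edge_trim : n - edge_trim]) + edge_trim
        for h in holes:
            diff[rec.start + int(h)] -= 1
            diff[rec.start + int(h) + 1] += 1
        for ref_pos, _ref_base, alt_base, quality in rec.mismatches:
            per_pos = alt_obs.setdefault(ref_pos, {})
            obs = per_pos.setdefault(alt_base, AlleleObservation())
            obs.count += 1
            if rec.strand == "+":
                obs.forward += 1
            else:
                obs.reverse += 1
            obs.contexts.add(rec.context)
            obs.qualities.append(quality)
    fwd = np.cumsum(cov["+"][:-1])
    rev = np.cumsum(cov["-"][:-1])
    total = fwd + rev
    columns: list[PileupColumn] = []
    covered = np.flatnonzero(total)
    for pos in covered:
        pos = int(pos)
        alleles = dict(alt_obs.get(pos, {}))
        alt_count = sum(o.count for o in alleles.values())
        alt_fwd = sum(o.forward for o in alleles.values())
        ref_base = index.sequence[pos]
        ref_obs = AlleleObservation(
            count=int(total[pos]) - alt_count,
            forward=int(fwd[pos]) - alt_fwd,
            reverse=int(rev[pos]) - (alt_count - alt_fwd),
        )
        alleles[ref_base] = ref_obs
        columns.append(
            PileupColumn(
                ref_id=index.ref_id,
                position=pos,
                ref_base=ref_base,
                depth=int(total[pos]),
                alleles=alleles,
            )
        )
    return columns


def call_variants(
    columns: Iterable[PileupColumn],
    min_cs: int = 1,
    min_maf: float = 0.0,
    exclude: set[int] | None = None,
) -> list[VariantCall]:
    """One call per (position, alt) clearing the distinct-CS and MAF filters."""
    if min_cs < 1:
        raise ValueError("min_cs must be >= 1")
    if not 0 <= min_maf < 1:
        raise ValueError("min_maf must lie in [0, 1)")
    calls: list[VariantCall] = []
    for col in columns:
        if exclude and col.position in exclude:
            continue
        for base, obs in col.alleles.items():
            if base == col.ref_base or base == "N" or obs.count == 0:
                continue
            support = len(obs.contexts)
            maf = obs.count / col.depth
            if support >= min_cs and maf >= min_maf:
                calls.append(
                    VariantCall(
                        ref_id=col.ref_id,
                        position=col.position,
                        ref_base=col.ref_base,
                        alt_base=base,
                        support=support,
                        depth=col.depth,
                        maf=maf,
                    )
                )
    return calls


def ingest_sam(path, index: ReferenceIndex) -> Iterator[AlignmentRecord]:
    """Read externally produced SAM alignments of consensus reads.

    Alignments with indel/clip CIGAR operations are yielded with mapq forced
    through the normal filters by flagging them; callers should pass records
    through :func:`filter_and_trim`, which drops them.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for seg in handle:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            has_indel = any(op in (1, 2) for op, _ in (seg.cigartuples or []))
            if any(op not in (0, 1, 2) for op, _ in (seg.cigartuples or [])):
                continue  # clips/pads unsupported in the ungapped model
            seq = seg.query_sequence.upper()
            qual = np.array(seg.query_qualities, dtype=np.int16)
            start = seg.reference_start
            strand = "-" if seg.is_reverse else "+"
            lq = len(seq)
            qarr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            if has_indel:
                mismatches: list[tuple[int, str, str, int]] = []
            else:
                mism_idx = np.flatnonzero(index.array[start : start + lq] != qarr)
                mismatches = [
                    (start + int(i), index.sequence[start + int(i)], seq[int(i)], int(qual[int(i)]))
                    for i in mism_idx
                ]
            if strand == "-":
                cs_seq, cs_qual = revcomp(seq), qual[::-1].copy()
            else:
                cs_seq, cs_qual = seq, qual.copy()
            cs = ConsensusRead(
                sequence=cs_seq,
                qualities=cs_qual,
                dual_support=cs_qual > 2,
                pair_id=seg.query_name or "",
            )
            rec = AlignmentRecord(
                cs=cs,
                ref_id=index.ref_id,
                start=start,
                strand=strand,
                mapq=seg.mapping_quality,
                mismatches=mismatches,
                seq_oriented=seq,
                qual_oriented=qual,
            )
            rec._has_indel = has_indel  # consumed by pipeline wrappers
            yield rec
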