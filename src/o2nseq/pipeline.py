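"""In-memory orchestration of the full pipeline and its run statistics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .calling import (
    AlignmentRecord,
    PileupColumn,
    ReferenceIndex,
    VariantCall,
    call_variants,
    filter_and_trim,
    map_consensus,
    pileup,
)
from .consensus import ConsensusRead, consensus_from_split
from .formats import ReadPair, SequenceRecord
from .preprocess import quality_filter, split_o2n_read
from .simulate import DEFAULT_ADAPTOR


@dataclass
class PipelineParams:
    """Tunables of the preprocess -> consensus -> call chain."""

    adaptor: str = DEFAULT_ADAPTOR
    min_overlap: int = 8
    max_mismatch_rate: float = 0.1
    prefix_trim1: int = 5
    prefix_trim2: int = 5
    min_quality: int = 20
    min_read_length: int = 36
    max_copy_mismatch: int = 1
    min_copy_overlap: int = 30
    seed_k: int = 15
    max_map_mismatches: int = 3
    max_cs_mismatches: int = 1
    min_mapq: int = 25
    min_base_quality: int = 50
    edge_trim: int = 3
    min_cs: int = 1
    min_maf: float = 0.0


@dataclass
class RunStats:
    n_pairs: int = 0
    n_rejected_short: int = 0
    n_right_on: int = 0
    n_quality_dropped: int = 0
    n_consensus: int = 0
    n_mapped: int = 0
    n_kept: int = 0
    raw_bases: int = 0
    usable_bases: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PipelineResult:
    stats: RunStats
    columns: list[PileupColumn]
    calls: list[VariantCall]
    index: ReferenceIndex

    @property
    def data_utilization(self) -> float:
        from .evaluate import data_utilization

        return data_utilization(self.stats.raw_bases, self.stats.usable_bases)

    def depth_vector(self):
        import numpy as np

        depths = np.zeros(len(self.index), dtype=np.int64)
        for col in self.columns:
            depths[col.position] = col.depth
        return depths


def consensus_stream(
    pairs: Iterable[ReadPair],
    params: PipelineParams,
    stats: RunStats,
) -> Iterator[ConsensusRead]:
    """Pairs -> split -> quality filter -> per-pair consensus."""
    for pair in pairs:
        stats.n_pairs += 1
        stats.raw_bases += len(pair.read1) + len(pair.read2)
        split = split_o2n_read(
            pair,
            params.adaptor,
            params.min_overlap,
            params.max_mismatch_rate,
            params.prefix_trim1,
            params.prefix_trim2,
        )
        if split is None:
            stats.n_rejected_short += 1
            continue
        if not split.right_on:
            continue
        stats.n_right_on += 1
        t1 = quality_filter(split.target1, params.min_quality, 4, params.min_read_length)
        t2 = quality_filter(split.target2, params.min_quality, 4, params.min_read_length)
        if t1 is None or t2 is None:
            stats.n_quality_dropped += 1
            continue
        split.target1, split.target2 = t1, t2
        cs = consensus_from_split(split, params.max_copy_mismatch, params.min_copy_overlap)
        if cs is None:
            continue
        stats.n_consensus += 1
        yield cs


def aligned_stream(
    consensus_reads: Iterable[ConsensusRead],
    index: ReferenceIndex,
    params: PipelineParams,
    stats: RunStats,
) -> Iterator[AlignmentRecord]:
    for cs in consensus_reads:
        rec = map_consensus(cs, index, params.max_map_mismatches)
        if rec is None:
            continue
        stats.n_mapped += 1
        rec = filter_and_trim(
            rec,
            params.max_cs_mismatches,
            params.min_mapq,
            params.min_base_quality,
            params.edge_trim,
            has_indel=getattr(rec, "_has_indel", False),
        )
        if rec is None:
            continue
        stats.n_kept += 1
        stats.usable_bases += int(rec.usable_mask.sum())
        yield rec


def run_from_pairs(
    pairs: Iterable[ReadPair],
    reference: SequenceRecord,
    params: PipelineParams | None = None,
    exclude: set[int] | None = None,
) -> PipelineResult:
    """Run the whole chain on an iterable of raw read pairs."""
    params = params or PipelineParams()
    stats = RunStats()
    index = ReferenceIndex(reference, params.seed_k)
    records = aligned_stream(consensus_stream(pairs, params, stats), index, params, stats)
    columns = pileup(records, index, params.edge_trim)
    calls = call_variants(columns, params.min_cs, params.min_maf, exclude)
    return PipelineResult(stats=stats, columns=columns, calls=calls, index=index)


def run_from_consensus(
    consensus_reads: Iterable[ConsensusRead],
    reference: SequenceRecord,
    params: PipelineParams | None = None,
    exclude: set[int] | None = None,
) -> PipelineResult:
    """Run mapping + calling on already-built consensus reads."""
    params = params or PipelineParams()
    stats = RunStats()
    index = ReferenceIndex(reference, params.seed_k)
    records = aligned_stream(consensus_reads, index, params, stats)
    columns = pileup(records, index, params.edge_trim)
    calls = call_variants(columns, params.min_cs, params.min_maf, exclude)
    return PipelineResult(stats=stats, columns=columns, calls=calls, index=index)


def write_summary(result: PipelineResult, path: str | Path, seed: int | None = None) -> dict:
    summary = {
        "seed": seed,
        "stats": result.stats.to_dict(),
        "n_columns": len(result.columns),
        "n_calls": len(result.calls),
        "data_utilization": result.data_utilization,
        "calls": [
            {
                "chrom": c.ref_id,
                "pos_1based": c.position + 1,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "support": c.support,
                "depth": c.depth,
                "maf": c.maf,
            }
            for c in result.calls
        ],
    }
    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary
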