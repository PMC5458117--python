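import numpy as np
import pytest

from o2nseq.calling import (
    AlignmentRecord,
    ReferenceIndex,
    call_variants,
    filter_and_trim,
    ingest_sam,
    map_consensus,
    pileup,
)
from o2nseq.consensus import ConsensusRead
from o2nseq.formats import SequenceRecord
from o2nseq.simulate import random_reference, revcomp


def _cs(seq, q=60, pair_id="cs"):
    quals = np.full(len(seq), q, dtype=np.int16) if np.isscalar(q) else np.asarray(q)
    return ConsensusRead(seq, quals, quals > 2, pair_id)


@pytest.fixture(scope="module")
def ref5k():
    return random_reference(5000, np.random.default_rng(77), "ref5k")


@pytest.fixture(scope="module")
def index5k(ref5k):
    return ReferenceIndex(ref5k)


class TestMapConsensus:
    def test_unique_exact_substring(self, ref5k, index5k):
        rec = map_consensus(_cs(ref5k.sequence[1000:1080]), index5k)
        assert rec is not None
        assert (rec.start, rec.strand, rec.mapq) == (1000, "+", 60)
        assert rec.mismatches == []

    def test_reverse_strand_placement(self, ref5k, index5k):
        rec = map_consensus(_cs(revcomp(ref5k.sequence[2000:2090])), index5k)
        assert rec is not None
        assert (rec.start, rec.strand) == (2000, "-")
        assert rec.seq_oriented == ref5k.sequence[2000:2090]

    def test_ambiguous_placement_gets_mapq_zero(self, rng):
        piece = random_reference(80, rng).sequence
        filler = random_reference(200, np.random.default_rng(5), "f").sequence
        ref = SequenceRecord("dup", piece + filler + piece)
        rec = map_consensus(_cs(piece), ReferenceIndex(ref))
        assert rec is not None and rec.mapq == 0

    def test_foreign_read_unmapped_vs_exhaustive_oracle(self, ref5k, index5k):
        rng = np.random.default_rng(123)
        foreign = random_reference(80, rng, "x").sequence
        assert map_consensus(_cs(foreign), index5k) is None
        # oracle: exhaustive ungapped scan of both strands
        ref_arr = np.frombuffer(ref5k.sequence.encode(), dtype=np.uint8)
        best = 80
        for query in (foreign, revcomp(foreign)):
            q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
            for start in range(len(ref_arr) - 80 + 1):
                best = min(best, int((ref_arr[start : start + 80] != q_arr).sum()))
        assert best > 3

    def test_one_mismatch_read_located(self, ref5k, index5k):
        seq = list(ref5k.sequence[3000:3080])
        seq[40] = "A" if seq[40] != "A" else "C"
        rec = map_consensus(_cs("".join(seq)), index5k)
        assert rec is not None and rec.start == 3000
        assert [m[0] for m in rec.mismatches] == [3040]


class TestFilterAndTrim:
    def test_two_usable_mismatches_dropped(self, ref5k, index5k):
        seq = list(ref5k.sequence[1000:1080])
        for pos in (30, 50):
            seq[pos] = "A" if seq[pos] != "A" else "C"
        rec = map_consensus(_cs("".join(seq)), index5k)
        assert filter_and_trim(rec) is None

    def test_edge_trim_leaves_interior_usable(self, ref5k, index5k):
        seq = list(ref5k.sequence[1000:1080])
        seq[40] = "A" if seq[40] != "A" else "C"
        rec = filter_and_trim(map_consensus(_cs("".join(seq)), index5k))
        assert rec is not None
        assert int(rec.usable_mask.sum()) == 80 - 6
        assert not rec.usable_mask[:3].any() and not rec.usable_mask[-3:].any()

    def test_masked_base_mismatch_not_counted(self, ref5k, index5k):
        seq = list(ref5k.sequence[1000:1080])
        q = np.full(80, 60, dtype=np.int16)
        for pos in (20, 44):  # two mismatches, one at a '#'-masked base
            seq[pos] = "A" if seq[pos] != "A" else "C"
        q[20] = 2
        rec = map_consensus(_cs("".join(seq), q), index5k)
        kept = filter_and_trim(rec)
        assert kept is not None
        assert [m[0] for m in kept.mismatches] == [1044]

    def test_low_mapq_dropped(self, ref5k, index5k):
        rec = map_consensus(_cs(ref5k.sequence[1000:1080]), index5k)
        rec.mapq = 0
        assert filter_and_trim(rec) is None

    def test_indel_flag_drops_record(self, ref5k, index5k):
        rec = map_consensus(_cs(ref5k.sequence[1000:1080]), index5k)
        assert filter_and_trim(rec, has_indel=True) is None


def _mapped(seqs, index, quals=None):
    out = []
    for i, seq in enumerate(seqs):
        q = None if quals is None else quals[i]
        rec = map_consensus(_cs(seq, 60 if q is None else q, f"cs{i}"), index)
        rec = filter_and_trim(rec)
        assert rec is not None
        out.append(rec)
    return out


class TestPileup:
    def test_identical_contexts_collapse(self, ref5k, index5k):
        seq = list(ref5k.sequence[1000:1080])
        seq[40] = alt = "A" if seq[40] != "A" else "C"
        records = _mapped(["".join(seq)] * 3, index5k)
        columns = pileup(records, index5k)
        col = next(c for c in columns if c.position == 1040)
        obs = col.alleles[alt]
        assert obs.count == 3 and len(obs.contexts) == 1

    def test_different_starts_are_distinct_contexts(self, ref5k, index5k):
        alt_pos = 1040
        seqs = []
        for start in (1000, 1005, 1010):
            seq = list(ref5k.sequence[start : start + 80])
            base = ref5k.sequence[alt_pos]
            seq[alt_pos - start] = alt = "A" if base != "A" else "C"
            seqs.append("".join(seq))
        columns = pileup(_mapped(seqs, index5k), index5k)
        col = next(c for c in columns if c.position == alt_pos)
        assert len(col.alleles[alt].contexts) == 3

    def test_depth_conservation_against_recount_oracle(self, ref5k, index5k):
        rng = np.random.default_rng(42)
        seqs = []
        for _ in range(60):
            start = int(rng.integers(0, 4900))
            length = int(rng.integers(60, 100))
            seqs.append(ref5k.sequence[start : start + length])
        records = _mapped(seqs, index5k)
        columns = pileup(records, index5k)
        total_depth = sum(col.depth for col in columns)
        assert total_depth == sum(int(r.usable_mask.sum()) for r in records)
        for col in columns:
            assert sum(o.count for o in col.alleles.values()) == col.depth

    def test_strand_counts_split(self, ref5k, index5k):
        fw = ref5k.sequence[1000:1080]
        records = _mapped([fw, revcomp(fw)], index5k)
        columns = pileup(records, index5k)
        col = next(c for c in columns if c.position == 1040)
        obs = col.alleles[col.ref_base]
        assert (obs.forward, obs.reverse) == (1, 1)


class TestCallVariants:
    def _columns_with_support(self, index5k, ref5k, n_contexts):
        alt_pos = 1040
        seqs = []
        for k in range(n_contexts):
            start = 1000 + 2 * k
            seq = list(ref5k.sequence[start : start + 80])
            base = ref5k.sequence[alt_pos]
            seq[alt_pos - start] = "A" if base != "A" else "C"
            seqs.append("".join(seq))
        return pileup(_mapped(seqs, index5k), index5k)

    def test_support_threshold_semantics(self, ref5k, index5k):
        columns = self._columns_with_support(index5k, ref5k, 3)
        assert len(call_variants(columns, min_cs=3)) == 1
        assert len(call_variants(columns, min_cs=4)) == 0

    def test_maf_threshold(self, ref5k, index5k):
        columns = self._columns_with_support(index5k, ref5k, 3)
        call = call_variants(columns, min_cs=1)[0]
        assert call.maf == 1.0  # only alt-carrying reads cover the site here
        assert call_variants(columns, min_cs=1, min_maf=0.5)

    def test_empty_columns_give_no_calls(self):
        assert call_variants([], min_cs=1) == []

    def test_monotone_nesting_over_levels(self, ref5k, index5k):
        columns = self._columns_with_support(index5k, ref5k, 5)
        previous = None
        for n in range(1, 7):
            keys = {(c.position, c.alt_base) for c in call_variants(columns, min_cs=n)}
            if previous is not None:
                assert keys <= previous
            previous = keys


class TestSamIngestion:
    def test_round_trip_through_sam(self, tmp_path, ref5k, index5k):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 5000, "SN": "ref5k"}]}
        path = tmp_path / "cs.sam"
        seq = ref5k.sequence[1000:1080]
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            a = pysam.AlignedSegment(out.header)
            a.query_name = "cs0"
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = 1000
            a.mapping_quality = 60
            a.cigarstring = "80M"
            a.query_qualities = pysam.qualitystring_to_array("~" * 80)
            a.flag = 0
            out.write(a)
            b = pysam.AlignedSegment(out.header)
            b.query_name = "cs1"
            b.query_sequence = seq
            b.reference_id = 0
            b.reference_start = 1000
            b.mapping_quality = 60
            b.cigarstring = "40M2D40M"
            b.query_qualities = pysam.qualitystring_to_array("~" * 80)
            b.flag = 0
            out.write(b)
        records = list(ingest_sam(path, index5k))
        kept = [
            filter_and_trim(r, has_indel=getattr(r, "_has_indel", False)) for r in records
        ]
        kept = [r for r in kept if r is not None]
        assert len(kept) == 1  # the 2D record is filtered out
        assert kept[0].start == 1000 and kept[0].mismatches == []
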