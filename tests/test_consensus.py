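import numpy as np
import pytest

from o2nseq.consensus import align_copies, build_consensus
from o2nseq.formats import MASK_QUALITY, SequenceRecord
from o2nseq.simulate import random_reference, revcomp


def _rec(seq, q=40, rid="t"):
    quals = np.full(len(seq), q) if np.isscalar(q) else np.asarray(q)
    return SequenceRecord(rid, seq, quals)


def _copy_pair(fragment, q1=40, q2=40):
    """target1 carries the fragment; target2 is its sequenced second copy."""
    return _rec(fragment, q1, "t1"), _rec(revcomp(fragment), q2, "t2")


def brute_force_align(a, b):
    """Oracle: score every end-gap-free offset of revcomp-free strings."""
    la, lb = len(a), len(b)
    best = None
    for d in range(-(lb - 1), la):
        lo, hi = max(0, d), min(la, d + lb)
        if hi <= lo:
            continue
        matches = sum(a[i] == b[i - d] for i in range(lo, hi))
        key = (-matches, abs(d), 0 if d >= 0 else 1)
        if best is None or key < best[0]:
            best = (key, d, hi - lo, (hi - lo) - matches)
    return best  # (key, offset, overlap, mismatches)


class TestAlignCopies:
    def test_identical_copies(self, rng):
        frag = random_reference(80, rng).sequence
        t1, t2 = _copy_pair(frag)
        aln = align_copies(t1, t2)
        assert aln is not None
        assert aln.offset == 0 and aln.mismatches == () and aln.overlap == 80

    def test_two_mismatches_rejected(self, rng):
        frag = random_reference(80, rng).sequence
        other = list(frag)
        for pos in (20, 60):
            other[pos] = "A" if frag[pos] != "A" else "C"
        t1, t2 = _rec(frag), _rec(revcomp("".join(other)))
        assert align_copies(t1, t2) is None

    def test_single_mismatch_tolerated(self, rng):
        frag = random_reference(80, rng).sequence
        other = frag[:40] + ("A" if frag[40] != "A" else "C") + frag[41:]
        aln = align_copies(_rec(frag), _rec(revcomp(other)))
        assert aln is not None and aln.mismatches == (40,)

    def test_truncated_second_copy(self, rng):
        frag = random_reference(80, rng).sequence
        aln = align_copies(_rec(frag), _rec(revcomp(frag[:45])))
        assert aln is not None
        assert aln.offset == 0 and aln.overlap == 45 and aln.mismatches == ()

    def test_overlap_below_minimum_rejected(self, rng):
        frag = random_reference(80, rng).sequence
        assert align_copies(_rec(frag), _rec(revcomp(frag[:20]))) is None

    @pytest.mark.parametrize("case_seed", range(30))
    def test_matches_brute_force_offset_oracle(self, case_seed):
        rng = np.random.default_rng(4000 + case_seed)
        la = int(rng.integers(36, 90))
        shift = int(rng.integers(0, 20))
        lb = int(rng.integers(36, 90))
        genome = random_reference(200, rng).sequence
        a = genome[:la]
        b_fw = genome[shift : shift + lb]
        if rng.random() < 0.5 and lb > 2:  # sprinkle a substitution
            pos = int(rng.integers(0, lb))
            b_fw = b_fw[:pos] + ("A" if b_fw[pos] != "A" else "C") + b_fw[pos + 1 :]
        aln = align_copies(_rec(a), _rec(revcomp(b_fw)), min_overlap_bases=10)
        key, offset, overlap, mismatches = brute_force_align(a, b_fw)
        if mismatches > 1 or overlap < 10:
            assert aln is None
        else:
            assert aln is not None
            assert (aln.offset, aln.overlap, len(aln.mismatches)) == (
                offset,
                overlap,
                mismatches,
            )


class TestBuildConsensus:
    def test_agreeing_base_quality_sums(self, rng):
        frag = random_reference(50, rng).sequence
        t1, t2 = _copy_pair(frag, q1=40, q2=40)
        cs = build_consensus(t1, t2, align_copies(t1, t2))
        assert cs.sequence == frag
        assert set(cs.qualities.tolist()) == {80}
        assert cs.dual_support.all()

    def test_quality_sum_caps_at_93(self, rng):
        frag = random_reference(50, rng).sequence
        t1, t2 = _copy_pair(frag, q1=60, q2=60)
        cs = build_consensus(t1, t2, align_copies(t1, t2))
        assert set(cs.qualities.tolist()) == {93}

    def test_single_covered_overhang_masked(self, rng):
        frag = random_reference(80, rng).sequence
        t1, t2 = _rec(frag), _rec(revcomp(frag[:45]))
        cs = build_consensus(t1, t2, align_copies(t1, t2))
        assert cs.sequence == frag
        assert (cs.qualities[:45] == 80).all()
        assert (cs.qualities[45:] == MASK_QUALITY).all()
        assert cs.n_masked == 80 - 45

    def test_disagreement_keeps_higher_quality_base_but_masks(self, rng):
        frag = random_reference(60, rng).sequence
        alt = "A" if frag[30] != "A" else "C"
        other = frag[:30] + alt + frag[31:]
        q2 = np.full(60, 50)
        t1 = _rec(frag, 40)
        t2 = _rec(revcomp(other), q2[::-1])
        cs = build_consensus(t1, t2, align_copies(t1, t2))
        assert cs.sequence[30] == alt  # copy 2 wins on quality
        assert cs.qualities[30] == MASK_QUALITY
        assert not cs.dual_support[30]
        assert cs.n_masked == 1

    def test_masked_count_equals_single_plus_mismatch_positions(self, rng):
        frag = random_reference(70, rng).sequence
        other = frag[:10] + ("A" if frag[10] != "A" else "C") + frag[11:60]
        t1, t2 = _rec(frag), _rec(revcomp(other))
        aln = align_copies(t1, t2)
        cs = build_consensus(t1, t2, aln)
        single = len(cs) - aln.overlap
        assert cs.n_masked == single + len(aln.mismatches)

    def test_consensus_length_bound(self, rng):
        for seed in range(10):
            case = np.random.default_rng(seed)
            genome = random_reference(150, case).sequence
            la, lb = int(case.integers(36, 80)), int(case.integers(36, 80))
            a, b = genome[:la], genome[: lb]
            aln = align_copies(_rec(a), _rec(revcomp(b)))
            if aln is None:
                continue
            cs = build_consensus(_rec(a), _rec(revcomp(b)), aln)
            assert len(cs) <= max(la, lb) + abs(aln.offset)


class TestErrorSuppression:
    def test_dual_support_error_rate_approaches_e_squared_over_three(self):
        """Coincident-error law: both copies must hit the same wrong base.

        With per-copy substitution rate e, a dual-supported consensus base is
        wrong only when both copies were misread to the same base, which
        happens at rate e^2/3.
        """
        e = 0.01
        rng = np.random.default_rng(99)
        genome = random_reference(5000, rng).sequence
        dual_bases = 0
        dual_errors = 0
        bases = np.array(list("ACGT"))
        for _ in range(30_000):
            flen = int(rng.integers(60, 121))
            start = int(rng.integers(0, 5000 - flen))
            frag = genome[start : start + flen]

            def corrupt(seq):
                arr = np.array(list(seq))
                hits = np.flatnonzero(rng.random(len(seq)) < e)
                for h in hits:
                    choices = bases[bases != arr[h]]
                    arr[h] = choices[rng.integers(3)]
                return "".join(arr)

            t1 = _rec(corrupt(frag), 30)
            t2 = _rec(revcomp(corrupt(frag)), 30)
            aln = align_copies(t1, t2)
            if aln is None or aln.offset != 0:
                continue
            cs = build_consensus(t1, t2, aln)
            if len(cs) != flen:
                continue
            dual = cs.dual_support
            truth = np.array(list(frag))
            obs = np.array(list(cs.sequence))
            dual_bases += int(dual.sum())
            dual_errors += int((obs[dual] != truth[dual]).sum())
        expected_rate = e**2 / 3
        expected = dual_bases * expected_rate
        sigma = np.sqrt(dual_bases * expected_rate)
        assert dual_bases > 1e6
        assert abs(dual_errors - expected) <= 3 * sigma
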