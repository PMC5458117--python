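"""Simulation of o2n-structured paired-end libraries.

An o2n molecule carries two tandem copies of one genomic fragment separated
by a fixed 62-base intermediate adaptor::

    5' [5-base primer][fragment][62-base adaptor][fragment][2-base tail] 3'

Sequencing 2 x ``read_length`` from both ends therefore reads each copy once,
so a per-pair consensus can cancel independent substitution errors.  The
generator emulates the gel-cut fragment window (60-120 bp by default),
2 x 125 bp sequencing, phred-driven substitution errors and strain mixtures
realised as independent per-molecule allele draws; a configurable fraction of
pairs are adaptor-free decoys standing in for non-right-on library molecules.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .formats import ReadPair, SequenceRecord, write_fastq

#: the 62-base blocking oligo used as the canonical intermediate adaptor
DEFAULT_ADAPTOR = "AGATCAGTCGTACGTGCTTACTCTCAATAGCAGCTTGTGGGCAGTCGGTGAACGACTGATCT"
#: the second-strand synthesis primer contributes 5 leading bases; the exact
#: oligo is not public, so a fixed synthetic 5-mer stands in for it
DEFAULT_PRIMER_PREFIX = "GACTG"
#: two bases left 3' of the dU nick site in the adaptor
DEFAULT_TAIL = "CT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_reference(length: int, rng: np.random.Generator, ref_id: str = "ref") -> SequenceRecord:
    """A uniform-random DNA reference (synthetic stand-in for a real genome)."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=length).tobytes().decode("ascii")
    return SequenceRecord(ref_id, seq)


@dataclass(frozen=True)
class TruthVariant:
    """A spiked minor allele: present in each molecule with ``allele_fraction``."""

    position: int
    ref_base: str
    alt_base: str
    allele_fraction: float

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base must differ from alt_base")
        if not 0 < self.allele_fraction <= 1:
            raise ValueError("allele_fraction must lie in (0, 1]")


@dataclass
class LibraryConfig:
    """Everything that determines one simulated library (plus the seed)."""

    reference: SequenceRecord
    variants: list[TruthVariant] = field(default_factory=list)
    n_pairs: int = 1000
    frag_min: int = 60
    frag_max: int = 120
    read_length: int = 125
    primer_prefix: str = DEFAULT_PRIMER_PREFIX
    intermediate_adaptor: str = DEFAULT_ADAPTOR
    tail: str = DEFAULT_TAIL
    quality: int = 30          # constant phred score of every sequenced base
    right_on_fraction: float = 1.0
    strand_flip: bool = True   # fragments drawn from either strand
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.primer_prefix) != 5:
            raise ValueError("primer_prefix must be 5 bases")
        if len(self.intermediate_adaptor) != 62:
            raise ValueError("intermediate adaptor must be 62 bases")
        if len(self.tail) != 2:
            raise ValueError("tail must be 2 bases")
        if self.frag_max > self.read_length - 1:
            raise ValueError("frag_max must be at most read_length - 1")
        if self.frag_min < 1 or self.frag_min > self.frag_max:
            raise ValueError("invalid fragment length window")
        if not 0 < self.right_on_fraction <= 1:
            raise ValueError("right_on_fraction must lie in (0, 1]")
        L = len(self.reference.sequence)
        for v in self.variants:
            if not 0 <= v.position < L:
                raise ValueError(f"variant position {v.position} outside reference")
            if self.reference.sequence[v.position] != v.ref_base:
                raise ValueError(f"variant at {v.position} does not match reference base")

    @property
    def error_rate(self) -> float:
        return 10 ** (-self.quality / 10)


def sample_haplotype(config: LibraryConfig, rng: np.random.Generator) -> str:
    """Draw one molecule-level haplotype of the whole reference.

    Each variant site carries the alternate base with probability
    ``allele_fraction``, independently per molecule and per site.
    """
    seq = config.reference.sequence
    if not config.variants:
        return seq
    chars = list(seq)
    for v in config.variants:
        if rng.random() < v.allele_fraction:
            chars[v.position] = v.alt_base
    return "".join(chars)


def make_o2n_molecule(fragment: str, config: LibraryConfig) -> str:
    """Assemble primer + fragment + adaptor + fragment + tail (same orientation)."""
    return (
        config.primer_prefix
        + fragment
        + config.intermediate_adaptor
        + fragment
        + config.tail
    )


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitute each base, independently, to a uniform different base."""
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        old = chars[pos]
        choices = [b for b in "ACGT" if b != old]
        chars[pos] = choices[rng.integers(3)]
    return "".join(chars)


def sequence_pair(
    molecule: str,
    config: LibraryConfig,
    rng: np.random.Generator,
    pair_id: str = "pair",
) -> ReadPair:
    """Sequence a molecule from both ends: read1 forward, read2 reverse strand."""
    if config.read_length < 36:
        raise ValueError("read_length must be at least 36")
    n = min(config.read_length, len(molecule))
    r1 = _inject_errors(molecule[:n], config.error_rate, rng)
    r2 = _inject_errors(revcomp(molecule[-n:]), config.error_rate, rng)
    qual = np.full(n, config.quality, dtype=np.int16)
    return ReadPair(
        SequenceRecord(f"{pair_id}/1", r1, qual.copy()),
        SequenceRecord(f"{pair_id}/2", r2, qual.copy()),
        pair_id,
    )


@dataclass
class MoleculeTruth:
    """What the simulator knows about one emitted pair."""

    pair_id: str
    right_on: bool
    start: int          # 0-based fragment start on the reference
    length: int
    strand: str         # '+' or '-'
    alleles: dict[int, str]  # position -> alt base carried by this molecule


def _sorted_variants(config: LibraryConfig) -> tuple[np.ndarray, list[TruthVariant]]:
    cached = getattr(config, "_variant_cache", None)
    if cached is None:
        ordered = sorted(config.variants, key=lambda v: v.position)
        cached = ([v.position for v in ordered], ordered)
        config._variant_cache = cached
    return cached


def _draw_fragment(
    config: LibraryConfig, rng: np.random.Generator, length: int | None = None
) -> tuple[int, int, str, dict[int, str], str]:
    """Draw (start, length, strand, alleles, fragment sequence) for one molecule."""
    L = len(config.reference.sequence)
    flen = int(rng.integers(config.frag_min, config.frag_max + 1)) if length is None else length
    start = int(rng.integers(0, L - flen + 1))
    frag = config.reference.sequence[start : start + flen]
    alleles: dict[int, str] = {}
    positions, ordered = _sorted_variants(config)
    lo = bisect_left(positions, start)
    hi = bisect_left(positions, start + flen)
    for v in ordered[lo:hi]:
        if rng.random() < v.allele_fraction:
            alleles[v.position] = v.alt_base
    if alleles:
        chars = list(frag)
        for pos, alt in alleles.items():
            chars[pos - start] = alt
        frag = "".join(chars)
    strand = "+"
    if config.strand_flip and rng.random() < 0.5:
        frag = revcomp(frag)
        strand = "-"
    return start, flen, strand, alleles, frag


def simulate_pairs(config: LibraryConfig) -> Iterator[tuple[ReadPair, MoleculeTruth]]:
    """Stream ``n_pairs`` read pairs with per-molecule truth records.

    Decoy (non-right-on) pairs are adaptor-free fragments of the reference
    sequenced at full read length from both ends.
    """
    rng = np.random.default_rng(config.seed)
    L = len(config.reference.sequence)
    qual = np.full(config.read_length, config.quality, dtype=np.int16)
    for i in range(config.n_pairs):
        pair_id = f"o2n:{i}"
        right_on = rng.random() < config.right_on_fraction
        if right_on:
            start, flen, strand, alleles, frag = _draw_fragment(config, rng)
            molecule = make_o2n_molecule(frag, config)
            n = min(config.read_length, len(molecule))
            r1 = _inject_errors(molecule[:n], config.error_rate, rng)
            r2 = _inject_errors(revcomp(molecule[-n:]), config.error_rate, rng)
        else:
            flen = min(2 * config.read_length, L)
            start = int(rng.integers(0, L - flen + 1))
            strand = "+"
            alleles = {}
            frag = config.reference.sequence[start : start + flen]
            n = config.read_length
            r1 = _inject_errors(frag[:n], config.error_rate, rng)
            r2 = _inject_errors(revcomp(frag[-n:]), config.error_rate, rng)
        q = qual[:n]
        pair = ReadPair(
            SequenceRecord(f"{pair_id}/1", r1, q),
            SequenceRecord(f"{pair_id}/2", r2, q),
            pair_id,
        )
        yield pair, MoleculeTruth(pair_id, right_on, start, flen, strand, alleles)


def truth_frame(truths: Sequence[MoleculeTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [t.pair_id for t in truths],
            "right_on": [int(t.right_on) for t in truths],
            "start": [t.start for t in truths],
            "length": [t.length for t in truths],
            "strand": [t.strand for t in truths],
            "alleles": [
                ",".join(f"{p}:{a}" for p, a in sorted(t.alleles.items())) for t in truths
            ],
        }
    )


def simulate_library(config: LibraryConfig, out_prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>_R1.fastq``, ``<prefix>_R2.fastq`` and ``<prefix>_truth.tsv``.

    Identical config + seed produces byte-identical files.
    """
    out_prefix = Path(out_prefix)
    r1s: list[SequenceRecord] = []
    r2s: list[SequenceRecord] = []
    truths: list[MoleculeTruth] = []
    for pair, truth in simulate_pairs(config):
        r1s.append(pair.read1)
        r2s.append(pair.read2)
        truths.append(truth)
    paths = {
        "r1": out_prefix.parent / (out_prefix.name + "_R1.fastq"),
        "r2": out_prefix.parent / (out_prefix.name + "_R2.fastq"),
        "truth": out_prefix.parent / (out_prefix.name + "_truth.tsv"),
    }
    write_fastq(r1s, paths["r1"])
    write_fastq(r2s, paths["r2"])
    truth_frame(truths).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_consensus_reads(
    config: LibraryConfig,
    n_reads: int,
    consensus_error_rate: float,
    consensus_quality: int = 60,
    rng: np.random.Generator | None = None,
):
    """Stream consensus-level reads directly (for very deep experiments).

    Fragments are drawn exactly as in the full simulator; each base then
    passes through the dual-copy error channel, i.e. it is substituted with
    probability ``consensus_error_rate`` (for a raw per-base error ``e`` the
    coincident-error rate is ``e**2 / 3``).  Returned objects are
    :class:`~o2nseq.consensus.ConsensusRead` with every base dual-supported,
    which makes million-read depths tractable without simulating and
    collapsing twice as many raw reads.
    """
    from .consensus import ConsensusRead

    if rng is None:
        rng = np.random.default_rng(config.seed)
    for i in range(n_reads):
        start, flen, strand, alleles, frag = _draw_fragment(config, rng)
        frag = _inject_errors(frag, consensus_error_rate, rng)
        qual = np.full(flen, min(consensus_quality, 93), dtype=np.int16)
        yield ConsensusRead(
            sequence=frag,
            qualities=qual,
            dual_support=np.ones(flen, dtype=bool),
            pair_id=f"cs:{i}",
        ), MoleculeTruth(f"cs:{i}", True, start, flen, strand, alleles)
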