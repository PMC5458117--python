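"""Phred-33 quality handling and the file formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere in this package; the
TSV/VCF writers emit 1-based positions and the readers convert back.  FASTQ
qualities are phred-33 with the conventional mask characters: ``'#'`` (score
2) marks a consensus base supported by a single copy and ``'~'`` (score 93)
is the encoding ceiling.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
PHRED_MAX = 93
#: quality assigned to single-copy-supported or disagreeing consensus bases
MASK_QUALITY = 2

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed records in any of the supported text formats."""


def phred33_decode(char: str) -> int:
    """Decode one phred-33 quality character to an integer score."""
    code = ord(char)
    if not 33 <= code <= 126:
        raise FormatError(f"character {char!r} outside printable phred-33 range")
    return code - PHRED_OFFSET


def phred33_encode(score: int) -> str:
    """Encode an integer phred score; scores above 93 clamp to ``'~'``."""
    if score < 0:
        raise FormatError(f"negative phred score {score}")
    return chr(min(int(score), PHRED_MAX) + PHRED_OFFSET)


def decode_quality_string(qual: str) -> np.ndarray:
    """Vectorised phred-33 decode of a FASTQ quality line."""
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    if arr.size and (arr.min() < 33 or arr.max() > 126):
        raise FormatError("quality string contains non-printable characters")
    return (arr.astype(np.int16) - PHRED_OFFSET).copy()


def encode_quality_array(qualities: np.ndarray) -> str:
    arr = np.asarray(qualities)
    if arr.size and arr.min() < 0:
        raise FormatError("negative phred score in quality array")
    clipped = np.minimum(arr, PHRED_MAX).astype(np.uint8) + PHRED_OFFSET
    return clipped.tobytes().decode("ascii")


@dataclass(eq=False)
class SequenceRecord:
    """A named DNA sequence with optional per-base phred scores.

    ``qualities`` is ``None`` for FASTA records; when present its length must
    equal the sequence length and every score must lie in [0, 93].
    """

    id: str
    sequence: str
    qualities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None:
            q = np.asarray(self.qualities, dtype=np.int16)
            if q.shape != (len(self.sequence),):
                raise FormatError(
                    f"record {self.id!r}: {len(self.sequence)} bases but "
                    f"{q.size} quality scores"
                )
            if q.size and (q.min() < 0 or q.max() > PHRED_MAX):
                raise FormatError(f"record {self.id!r}: phred score outside [0, 93]")
            self.qualities = q

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(eq=False)
class ReadPair:
    """The two mates of one paired-end read."""

    read1: SequenceRecord
    read2: SequenceRecord
    pair_id: str


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _pair_token(title: str) -> str:
    token = title.split()[0] if title.split() else title
    if len(token) > 2 and token[-2] == "/" and token[-1] in "12":
        token = token[:-2]
    return token


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line-record FASTQ file (phred-33)."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            if len(seq) != len(qual):
                raise FormatError(f"record {title!r}: sequence/quality length mismatch")
            yield SequenceRecord(title.split()[0], seq.upper(), decode_quality_string(qual))


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Yield mate pairs from two parallel FASTQ files, in file order."""
    sentinel = object()
    for r1, r2 in zip_longest(read_fastq(path1), read_fastq(path2), fillvalue=sentinel):
        if r1 is sentinel or r2 is sentinel:
            raise FormatError("paired FASTQ files have unequal record counts")
        id1, id2 = _pair_token(r1.id), _pair_token(r2.id)
        if id1 != id2:
            raise FormatError(f"mismatched pair ids {r1.id!r} / {r2.id!r}")
        yield ReadPair(r1, r2, id1)


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.qualities is None:
                raise FormatError(f"record {rec.id!r} has no qualities")
            handle.write(
                f"@{rec.id}\n{rec.sequence}\n+\n{encode_quality_array(rec.qualities)}\n"
            )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    with _open_text(path) as handle:
        return [
            SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# variant tables (TSV mirror of internal fields, and a minimal VCF 4.2 subset)
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=CS,Number=1,Type=Integer,Description="Distinct consensus-sequence support">\n'
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Usable consensus depth">\n'
    '##INFO=<ID=MAF,Number=1,Type=Float,Description="Allele fraction of the call">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)
_TSV_HEADER = "chrom\tpos_1based\tref\talt\tsupport\tdepth\tmaf\n"


def write_variants(calls: Iterable, path: str | Path, dialect: str = "tsv") -> None:
    """Write variant calls; ``dialect`` is ``"tsv"`` or ``"vcf-minimal"``.

    Internal 0-based positions are emitted 1-based in both dialects.
    """
    if dialect not in ("tsv", "vcf-minimal"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with _open_text(path, "wt") as handle:
        handle.write(_VCF_HEADER if dialect == "vcf-minimal" else _TSV_HEADER)
        for call in calls:
            if len(call.ref_base) != 1 or len(call.alt_base) != 1:
                raise FormatError("multi-base alleles are not supported")
            if dialect == "tsv":
                handle.write(
                    f"{call.ref_id}\t{call.position + 1}\t{call.ref_base}\t"
                    f"{call.alt_base}\t{call.support}\t{call.depth}\t{call.maf:.6g}\n"
                )
            else:
                handle.write(
                    f"{call.ref_id}\t{call.position + 1}\t.\t{call.ref_base}\t"
                    f"{call.alt_base}\t.\tPASS\t"
                    f"CS={call.support};DP={call.depth};MAF={call.maf:.6g}\n"
                )


def read_variants(path: str | Path, dialect: str = "tsv") -> list:
    """Read calls written by :func:`write_variants` (round-trip companion)."""
    from .calling import VariantCall  # local import avoids a module cycle

    calls: list[VariantCall] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if dialect == "tsv":
                chrom, pos, ref, alt, support, depth, maf = fields[:7]
            else:
                chrom, pos, _, ref, alt, _, _, info = fields[:8]
                kv = dict(item.split("=", 1) for item in info.split(";"))
                support, depth, maf = kv["CS"], kv["DP"], kv["MAF"]
            calls.append(
                VariantCall(
                    ref_id=chrom,
                    position=int(pos) - 1,
                    ref_base=ref,
                    alt_base=alt,
                    support=int(support),
                    depth=int(depth),
                    maf=float(maf),
                )
            )
    return calls


def read_sites_table(path: str | Path):
    """Read a gold-standard/exclusion site list.

    Expected columns: ``chrom, pos_1based, ref, alt, expected_af`` (extra
    columns pass through).  Adds a 0-based ``position`` column.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "pos_1based" not in df.columns:
        raise FormatError("site table lacks a pos_1based column")
    df["position"] = df["pos_1based"].astype(int) - 1
    return df


def write_sites_table(df, path: str | Path) -> None:
    out = df.drop(columns=[c for c in ("position",) if c in df.columns])
    out.to_csv(path, sep="\t", index=False)
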