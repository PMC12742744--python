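"""Genome ingestion: FASTA reading/writing, byte-range chunk planning, and merging.

This module is the local stand-in for the genome-preparation stage of the
pipeline: genomes arrive as (optionally gzip-compressed) FASTA, large files
are fetched in fixed-size byte-range portions that can be retrieved in any
order, and the portions are merged back into the original byte stream before
any parsing or indexing happens.  Chunking therefore operates on raw file
bytes; no biological unit can straddle a chunk boundary because extraction
only ever runs on the merged whole.
"""
from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence, Tuple

from Bio import SeqIO

#: default portion size for chunked fetches: 50 MB, binary (2**20 bytes/MB)
DEFAULT_CHUNK_BYTES = 50 * 2**20

ByteRange = Tuple[int, int]  # [start, end) byte offsets


class FastaError(ValueError):
    """Base class for FASTA ingestion failures."""


class MissingFileError(FastaError):
    """The requested FASTA file does not exist."""


class EmptyFastaError(FastaError):
    """The file parsed to zero sequence records."""


class HeaderOnlyError(FastaError):
    """A FASTA header was present with no sequence beneath it."""


class FetchPlanError(ValueError):
    """Invalid chunk-plan parameters."""


class MergeError(ValueError):
    """Base class for portion-merge failures."""


class MissingPortionError(MergeError):
    """A plan range has no corresponding portion."""


class DuplicatePortionError(MergeError):
    """The same plan range was supplied more than once."""


class PortionLengthError(MergeError):
    """A portion's byte length differs from its range size."""


# Normalization table: uppercase, U->T (RNA input), anything outside
# {A,C,G,T} becomes N.  Built once over the 8-bit range.
def _build_normalizer() -> dict[int, str]:
    table: dict[int, str] = {}
    for code in range(256):
        ch = chr(code).upper()
        if ch == "U":
            ch = "T"
        if ch not in "ACGTN":
            ch = "N"
        table[code] = ch
    return table


_NORMALIZE = _build_normalizer()
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U to T, and replace every other symbol with N."""
    return raw.translate(_NORMALIZE)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One normalized FASTA record."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("record identifier must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered collection of sequence records from one source."""

    records: tuple[SequenceRecord, ...]
    source_label: str

    def __post_init__(self) -> None:
        ids = [r.identifier for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record identifiers must be unique within an assembly")

    @property
    def total_bases(self) -> int:
        return sum(r.length for r in self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _open_maybe_gzip(path: Path) -> io.TextIOBase:
    # gzip sniffed by magic bytes so compressed assemblies "just work"
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: str | Path, source_label: str | None = None) -> GenomeAssembly:
    """Parse a (possibly gzipped) FASTA file into a normalized assembly.

    Sequences are uppercased, U is mapped to T, and any remaining non-ACGT
    symbol becomes N.  Raises :class:`MissingFileError`,
    :class:`EmptyFastaError` or :class:`HeaderOnlyError` for the respective
    malformed inputs.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(str(rec.seq))
            if not seq:
                raise HeaderOnlyError(f"record {rec.id!r} has a header but no sequence")
            records.append(SequenceRecord(identifier=rec.id, sequence=seq))
    if not records:
        raise EmptyFastaError(f"no FASTA records found in {path}")
    return GenomeAssembly(records=tuple(records), source_label=source_label or str(path))


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    """Write an assembly as plain FASTA with fixed line wrapping."""
    path = Path(path)
    with open(path, "wt") as out:
        for rec in assembly:
            out.write(f">{rec.identifier}\n")
            for i in range(0, rec.length, width):
                out.write(rec.sequence[i : i + width] + "\n")


@dataclass(frozen=True)
class FetchPlan:
    """A partition of ``[0, total_bytes)`` into contiguous byte ranges.

    Every range except possibly the last has size ``chunk_bytes``; a file no
    larger than one chunk yields a single range (the size threshold is a
    strict "larger than").
    """

    total_bytes: int
    chunk_bytes: int
    ranges: tuple[ByteRange, ...]

    def __post_init__(self) -> None:
        if self.total_bytes <= 0 or self.chunk_bytes <= 0:
            raise FetchPlanError("total_bytes and chunk_bytes must be positive")
        expected_start = 0
        for i, (start, end) in enumerate(self.ranges):
            if start != expected_start or end <= start:
                raise FetchPlanError("ranges must be sorted, contiguous and non-empty")
            if i < len(self.ranges) - 1 and end - start != self.chunk_bytes:
                raise FetchPlanError("every range but the last must span chunk_bytes")
            expected_start = end
        if expected_start != self.total_bytes:
            raise FetchPlanError("ranges must exactly cover [0, total_bytes)")

    def to_text(self) -> str:
        """One-range-per-line ``start<TAB>end`` serialization."""
        return "".join(f"{s}\t{e}\n" for s, e in self.ranges)

    @classmethod
    def from_text(cls, text: str) -> "FetchPlan":
        ranges = tuple(
            (int(a), int(b))
            for a, b in (line.split("\t") for line in text.splitlines() if line.strip())
        )
        if not ranges:
            raise FetchPlanError("empty plan text")
        # chunk size is recoverable from the first range (all but the last
        # range span exactly one chunk)
        chunk = ranges[0][1] - ranges[0][0]
        return cls(total_bytes=ranges[-1][1], chunk_bytes=chunk, ranges=ranges)


def plan_chunked_fetch(total_bytes: int, chunk_bytes: int = DEFAULT_CHUNK_BYTES) -> FetchPlan:
    """Partition a file of ``total_bytes`` into fetchable byte ranges.

    Files at or below ``chunk_bytes`` are fetched in one piece; larger files
    are split into ``ceil(total/chunk)`` contiguous ranges.
    """
    if total_bytes <= 0 or chunk_bytes <= 0:
        raise FetchPlanError("total_bytes and chunk_bytes must be positive")
    if total_bytes <= chunk_bytes:
        ranges: tuple[ByteRange, ...] = ((0, total_bytes),)
    else:
        starts = range(0, total_bytes, chunk_bytes)
        ranges = tuple((s, min(s + chunk_bytes, total_bytes)) for s in starts)
    return FetchPlan(total_bytes=total_bytes, chunk_bytes=chunk_bytes, ranges=ranges)


def split_bytes(data: bytes, plan: FetchPlan) -> list[tuple[ByteRange, bytes]]:
    """Cut a byte string into (range, portion) pairs following a plan."""
    if len(data) != plan.total_bytes:
        raise PortionLengthError("data length does not match plan total_bytes")
    return [((s, e), data[s:e]) for s, e in plan.ranges]


def merge_portions(plan: FetchPlan, portions: Iterable[tuple[ByteRange, bytes]]) -> bytes:
    """Reassemble portions (arriving in any order) into the original bytes."""
    by_range: dict[ByteRange, bytes] = {}
    for rng, chunk in portions:
        if rng in by_range:
            raise DuplicatePortionError(f"duplicate portion for range {rng}")
        by_range[rng] = chunk
    out = bytearray()
    for rng in plan.ranges:
        if rng not in by_range:
            raise MissingPortionError(f"missing portion for range {rng}")
        chunk = by_range.pop(rng)
        if len(chunk) != rng[1] - rng[0]:
            raise PortionLengthError(
                f"portion for range {rng} has length {len(chunk)}, expected {rng[1] - rng[0]}"
            )
        out.extend(chunk)
    if by_range:
        raise MergeError(f"portions supplied for ranges outside the plan: {sorted(by_range)}")
    return bytes(out)


class Fetcher(Protocol):
    """Contract for retrieving raw bytes of a genome source.

    Implementations exist for local files; a remote/accession fetcher is a
    pluggable extension point with the same two methods.
    """

    def size(self, source_label: str) -> int: ...

    def fetch(self, source_label: str, start: int, end: int) -> bytes: ...


class LocalFileFetcher:
    """Byte-range fetcher over local files (the default binding)."""

    def size(self, source_label: str) -> int:
        return Path(source_label).stat().st_size

    def fetch(self, source_label: str, start: int, end: int) -> bytes:
        with open(source_label, "rb") as handle:
            handle.seek(start)
            return handle.read(end - start)
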