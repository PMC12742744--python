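"""SpCas9 candidate target-site enumeration.

A candidate is a 23-nt footprint whose last two bases are the GG of the NGG
protospacer-adjacent motif (PAM): 20 spacer bases, one arbitrary base, then
GG.  Both strands are scanned; a reverse-strand site appears on the forward
strand as CC followed by 21 bases and is reported as its reverse complement
so that every emitted ``target23`` ends in GG.  All overlapping offsets are
reported — the usual regex behaviour of skipping past a match would silently
drop real sites — and any window containing N is excluded.

Coordinates are 0-based half-open on the forward strand; a reverse
candidate's ``start`` is the start of its forward-strand footprint (BED
convention).
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .genome_io import GenomeAssembly, SequenceRecord, reverse_complement

SITE_LENGTH = 23
SPACER_LENGTH = 20

# Lookahead groups make the scans overlapping: every offset is tested.
_FORWARD = re.compile(r"(?=([ACGT]{21}GG))")
_REVERSE = re.compile(r"(?=(CC[ACGT]{21}))")


@dataclass(frozen=True)
class CandidateGuide:
    """One CRISPR-Cas9 target site: 20-nt spacer + NGG PAM with coordinates."""

    target23: str
    record_id: str
    start: int
    strand: str

    def __post_init__(self) -> None:
        if len(self.target23) != SITE_LENGTH:
            raise ValueError("target23 must be 23 nt")
        if not self.target23.endswith("GG"):
            raise ValueError("target23 must end in GG")
        if "N" in self.target23:
            raise ValueError("target23 must not contain N")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @property
    def spacer20(self) -> str:
        return self.target23[:SPACER_LENGTH]

    @classmethod
    def from_spacer(
        cls, spacer20: str, record_id: str = "query", start: int = 0, strand: str = "+"
    ) -> "CandidateGuide":
        """Wrap a bare 20-nt spacer as a candidate with a canonical AGG PAM."""
        return cls(target23=spacer20 + "AGG", record_id=record_id, start=start, strand=strand)


def iter_candidates(record: SequenceRecord) -> Iterator[CandidateGuide]:
    """Yield every candidate in a record, sorted by (start, + before -)."""
    seq = record.sequence
    hits: list[tuple[int, int, str]] = []
    for m in _FORWARD.finditer(seq):
        hits.append((m.start(), 0, m.group(1)))
    for m in _REVERSE.finditer(seq):
        hits.append((m.start(), 1, reverse_complement(m.group(1))))
    hits.sort(key=lambda h: (h[0], h[1]))
    for start, rev, target in hits:
        yield CandidateGuide(
            target23=target, record_id=record.identifier, start=start, strand="-" if rev else "+"
        )


def extract_candidates(record: SequenceRecord) -> list[CandidateGuide]:
    """All SpCas9 candidates in a record (both strands, overlapping)."""
    return list(iter_candidates(record))


def count_sites(record: SequenceRecord) -> int:
    """Number of candidates in one record without materializing them."""
    seq = record.sequence
    fwd = sum(1 for _ in _FORWARD.finditer(seq))
    rev = sum(1 for _ in _REVERSE.finditer(seq))
    return fwd + rev


def count_genome_sites(assembly: GenomeAssembly) -> int:
    """Genome-wide candidate count, streamed record by record."""
    return sum(count_sites(rec) for rec in assembly)


def dedupe_spacers(candidates: Iterable[CandidateGuide]) -> dict[str, int]:
    """Collapse candidates to distinct spacer sequences with occurrence counts.

    Genome-wide indexing is per distinct spacer; the counts preserve how many
    loci share each sequence (a spacer occurring twice is penalized as an
    off-target of itself downstream).
    """
    return dict(Counter(c.spacer20 for c in candidates))


def genome_spacer_counts(assembly: GenomeAssembly) -> dict[str, int]:
    """Distinct spacer -> occurrence count over a whole assembly, streamed."""
    counts: Counter[str] = Counter()
    for rec in assembly:
        counts.update(c.spacer20 for c in iter_candidates(rec))
    return dict(counts)


def candidates_to_bed(candidates: Iterable[CandidateGuide]) -> str:
    """BED6 text: record, start, start+23, target23, placeholder score, strand."""
    return "".join(
        f"{c.record_id}\t{c.start}\t{c.start + SITE_LENGTH}\t{c.target23}\t0\t{c.strand}\n"
        for c in candidates
    )


def candidates_to_frame(candidates: Iterable[CandidateGuide]) -> pd.DataFrame:
    """Candidates as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "record_id": c.record_id,
                "start": c.start,
                "strand": c.strand,
                "target23": c.target23,
                "spacer20": c.spacer20,
            }
            for c in candidates
        ],
        columns=["record_id", "start", "strand", "target23", "spacer20"],
    )
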