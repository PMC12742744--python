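"""Synthetic genomes and gene sequences with controlled properties.

Everything the pipeline consumes can be generated here deterministically
from a seed, so every stage is testable without downloading real
assemblies:

* random genomes with controllable length and GC content, optionally with
  target sites "planted" at chosen positions and at exact Hamming distances
  from a reference spacer (for index-recall tests);
* artificial gene sequences that contain a *precise* number of candidate
  guides — the construction guarantees exactly one NGG site per block and
  no reverse-strand site anywhere, and the guarantee is checkable by the
  extractor itself.

The background model is i.i.d. bases with P(G)+P(C) = ``gc_fraction``; no
repeat structure is simulated by default (a tandem-repeat helper exists for
stress tests, since repetitive genomes concentrate many near-identical
spacers into the same index buckets).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome_io import GenomeAssembly, SequenceRecord, write_fasta

_BASES = np.array(list("ACGT"))
_SITE_LEN = 23  # planted footprint: 20-nt spacer + TGG


class FixtureError(ValueError):
    """Invalid fixture specification."""


@dataclass(frozen=True)
class PlantedSite:
    """A spacer to embed at a fixed position, mutated at ``mismatches`` bases."""

    spacer20: str
    position: int
    mismatches: int = 0


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic genome record."""

    length: int
    gc_fraction: float = 0.5
    seed: int = 0
    planted: tuple[PlantedSite, ...] = ()
    identifier: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise FixtureError("length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise FixtureError("gc_fraction must lie in [0, 1]")
        footprints = sorted((p.position, p.position + _SITE_LEN) for p in self.planted)
        for (s, e) in footprints:
            if s < 0 or e > self.length:
                raise FixtureError(f"planted site [{s}, {e}) falls outside the genome")
        for (_, e1), (s2, _) in zip(footprints, footprints[1:]):
            if s2 < e1:
                raise FixtureError("planted sites must not overlap")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def mutate_spacer(spacer20: str, mismatches: int, rng: np.random.Generator) -> str:
    """Return a spacer at *exactly* ``mismatches`` Hamming distance.

    Mutates that many distinct positions, each to a different base, and
    re-checks the distance by direct comparison before returning.
    """
    if not 0 <= mismatches <= len(spacer20):
        raise FixtureError("mismatch count out of range")
    out = list(spacer20)
    for pos in rng.choice(len(spacer20), size=mismatches, replace=False):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(len(alternatives)))]
    mutated = "".join(out)
    assert _hamming(spacer20, mutated) == mismatches
    return mutated


def generate_genome(spec: GenomeSpec) -> SequenceRecord:
    """Draw a random genome and write the planted sites into it.

    Each planted entry is written as its (mutated) spacer followed by
    ``TGG`` so the extractor recovers it as a forward candidate at the
    planted position.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=spec.length, p=probs)
    for plant in spec.planted:
        spacer = mutate_spacer(plant.spacer20, plant.mismatches, rng)
        site = spacer + "TGG"
        seq[plant.position : plant.position + _SITE_LEN] = list(site)
    return SequenceRecord(identifier=spec.identifier, sequence="".join(seq))


def plant_offtarget_family(
    spec: GenomeSpec, query_spacer: str, distances: list[int]
) -> GenomeSpec:
    """Augment a spec with one site at each exact distance from a query.

    Positions are assigned deterministically on a fixed stride, skipping any
    footprint already occupied; raises if the genome cannot host them all.
    """
    if any(not 0 <= d <= 20 for d in distances):
        raise FixtureError("distances must lie in [0, 20]")
    occupied = [(p.position, p.position + _SITE_LEN) for p in spec.planted]
    new_sites = list(spec.planted)
    pos = 0
    stride = _SITE_LEN + 7  # spacing between planted footprints
    for d in distances:
        while any(s < pos + _SITE_LEN and pos < e for s, e in occupied):
            pos += stride
        if pos + _SITE_LEN > spec.length:
            raise FixtureError("genome too small to host all planted sites")
        new_sites.append(PlantedSite(spacer20=query_spacer, position=pos, mismatches=d))
        occupied.append((pos, pos + _SITE_LEN))
        pos += stride
    return replace(spec, planted=tuple(new_sites))


# Separator-safe alphabet choices: when drawing an "exact guide" gene we
# forbid GG and CC dinucleotides everywhere except inside each block's PAM.
def _draw_base(prev: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if not (prev == "G" and b == "G") and not (prev == "C" and b == "C")]
    return choices[int(rng.integers(len(choices)))]


def generate_gene_with_exact_guides(n: int, seed: int = 0) -> str:
    """An artificial gene whose extracted candidate count is exactly ``n``.

    Construction: ``n`` blocks of ``spacer + TGG``, where every spacer (and
    every junction) is free of GG and CC dinucleotides.  Each block then
    contributes exactly one forward site (its PAM's GG, with 21 bases ahead
    of it) and the whole sequence has no CC, hence no reverse-strand site.
    ``n = 0`` yields a short GG/CC-free stretch with zero sites.
    """
    if n < 0:
        raise FixtureError("n must be non-negative")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    prev = "A"
    if n == 0:
        out = []
        for _ in range(50):
            b = _draw_base(prev, rng)
            out.append(b)
            prev = b
        return "".join(out)
    for _ in range(n):
        spacer = []
        for _ in range(20):
            b = _draw_base(prev, rng)
            spacer.append(b)
            prev = b
        parts.append("".join(spacer) + "TGG")
        prev = "G"  # blocks end in ...TGG; the next spacer must not start with G
    return "".join(parts)


def tandem_repeat_genome(
    unit_length: int, copies: int, gc_fraction: float = 0.5, seed: int = 0,
    identifier: str = "repeat",
) -> SequenceRecord:
    """A genome of exact tandem copies of one random unit (stress fixture)."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    unit = "".join(rng.choice(_BASES, size=unit_length, p=probs))
    return SequenceRecord(identifier=identifier, sequence=unit * copies)


def write_fixture(spec: GenomeSpec, fasta_path: str | Path) -> SequenceRecord:
    """Generate a genome, write it as FASTA plus a plain-text manifest.

    The sidecar ``<fasta>.manifest.txt`` records the spec and seed so the
    fixture can be regenerated byte-identically.
    """
    record = generate_genome(spec)
    fasta_path = Path(fasta_path)
    write_fasta(
        GenomeAssembly(records=(record,), source_label=str(fasta_path)), fasta_path
    )
    manifest = fasta_path.with_suffix(fasta_path.suffix + ".manifest.txt")
    lines = [
        f"length={spec.length}",
        f"gc_fraction={spec.gc_fraction}",
        f"seed={spec.seed}",
        f"identifier={spec.identifier}",
    ]
    for p in spec.planted:
        lines.append(f"planted={p.spacer20},{p.position},{p.mismatches}")
    manifest.write_text("\n".join(lines) + "\n")
    return record
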