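"""Off-target assessment via inverted signature slice lists (ISSL).

Every distinct 20-nt spacer in the genome is packed into a 40-bit integer
(2 bits per base, A=0 C=1 G=2 T=3, leftmost base most significant).  The
code is cut into ``num_slices`` fixed-width slices and, for each slice
position, a table maps the slice's bit signature to the list of spacers
carrying it.  With more slices than allowed mismatches, the pigeonhole
principle guarantees that any spacer within Hamming distance ``max_mm`` of
a query matches the query exactly in at least one slice, so gathering the
buckets for the query's signatures and verifying each candidate's full
Hamming distance recalls the complete neighbour set — no heuristics, no
missed sites.

Off-target risk is aggregated with the classical multiplicative-penalty
single-hit score: each off-target occurrence contributes
``100 * prod(1 - w_p)`` over its mismatched positions, and the specificity
of a guide is ``10000 / (100 + sum of hits)`` so a guide with no off-targets
scores 100 and every additional or closer off-target pushes the score down.
Two weight vectors are available: a uniform ``w_p = 0.5`` (every test value
is a closed form) and the experimentally derived position-dependent weights
in common use.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

SPACER_LENGTH = 20
CODE_BITS = 2 * SPACER_LENGTH  # 40-bit spacer codes

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

# Interleaved-bit mask used to fold a 2-bit-per-base XOR into one bit per
# mismatched base before popcount.
_ODD_BITS = np.uint64(0x5555555555555555)

#: uniform mismatch weights: every position penalizes half the signal
UNIFORM_WEIGHTS: tuple[float, ...] = (0.5,) * SPACER_LENGTH

#: position-dependent mismatch weights, 5' (PAM-distal, position 1) to 3'
#: (PAM-proximal, position 20); the widely used experimentally derived
#: vector of Hsu et al. 2013 (Nat Biotechnol 31:827-832).
LITERATURE_WEIGHTS: tuple[float, ...] = (
    0.000, 0.000, 0.014, 0.000, 0.000,
    0.395, 0.317, 0.000, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732,
    0.828, 0.615, 0.804, 0.685, 0.583,
)

_WEIGHT_MODES: dict[str, tuple[float, ...]] = {
    "uniform": UNIFORM_WEIGHTS,
    "literature": LITERATURE_WEIGHTS,
}


class EncodingError(ValueError):
    """Spacer contains a symbol outside {A,C,G,T}."""


class IndexConfigError(ValueError):
    """Invalid slice configuration or query bound."""


class IndexFormatError(ValueError):
    """Serialized index is corrupt or has an unknown layout."""


def encode_spacer(spacer20: str) -> int:
    """Pack a 20-nt spacer into its 40-bit integer code."""
    if len(spacer20) != SPACER_LENGTH:
        raise EncodingError(f"spacer must be {SPACER_LENGTH} nt, got {len(spacer20)}")
    value = 0
    for base in spacer20:
        code = _BASE_CODE.get(base)
        if code is None:
            raise EncodingError(f"cannot encode symbol {base!r}")
        value = (value << 2) | code
    return value


def decode_spacer(value: int) -> str:
    """Inverse of :func:`encode_spacer`."""
    if not 0 <= value < 4**SPACER_LENGTH:
        raise EncodingError(f"value out of range: {value}")
    bases = []
    for shift in range(CODE_BITS - 2, -2, -2):
        bases.append(_CODE_BASE[(value >> shift) & 3])
    return "".join(bases)


def hamming_distance(a: int, b: int) -> int:
    """Number of differing bases between two encoded spacers."""
    x = a ^ b
    return int(bin((x | (x >> 1)) & 0x5555555555555555).count("1"))


def mismatch_positions(a: int, b: int) -> frozenset[int]:
    """1-based mismatched positions (1 = PAM-distal/leftmost base)."""
    x = a ^ b
    positions = []
    for p in range(SPACER_LENGTH):
        shift = (SPACER_LENGTH - 1 - p) * 2
        if (x >> shift) & 3:
            positions.append(p + 1)
    return frozenset(positions)


@dataclass(frozen=True)
class SliceConfig:
    """Slice layout of the index: ``num_slices`` slices of equal width."""

    num_slices: int = 5

    def __post_init__(self) -> None:
        if self.num_slices <= 0 or SPACER_LENGTH % self.num_slices:
            raise IndexConfigError(
                f"num_slices must divide {SPACER_LENGTH}, got {self.num_slices}"
            )

    @property
    def slice_width_bases(self) -> int:
        return SPACER_LENGTH // self.num_slices

    def signature(self, value: int, slice_pos: int) -> int:
        """Bit signature of slice ``slice_pos`` (0 = leftmost) of a code."""
        w = self.slice_width_bases
        shift = (SPACER_LENGTH - (slice_pos + 1) * w) * 2
        return (value >> shift) & ((1 << (2 * w)) - 1)


@dataclass(frozen=True)
class EncodedSpacer:
    """A distinct indexed spacer with its genome-wide occurrence count."""

    value: int
    count: int

    @property
    def spacer(self) -> str:
        return decode_spacer(self.value)


@dataclass
class OffTargetResult:
    """Aggregate off-target verdict for one query spacer."""

    specificity: float
    neighbour_counts: dict[int, int]
    max_mm: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.specificity <= 100.0:
            raise ValueError("specificity must lie in [0, 100]")


_MAGIC = b"ISSLIDX1"
_VERSION = 1


class ISSLIndex:
    """Inverted-signature-slice-list index over all genome spacers.

    Built once per genome from the distinct-spacer occurrence counts, then
    queried per candidate.  Distinct spacers are stored sorted by encoded
    value; each of the ``num_slices`` tables maps a slice signature to the
    (sorted) indices of spacers carrying it, so every distinct spacer appears
    exactly once per table.
    """

    def __init__(
        self,
        config: SliceConfig,
        values: np.ndarray,
        counts: np.ndarray,
        slices: list[dict[int, np.ndarray]],
    ):
        self.config = config
        self.values = values
        self.counts = counts
        self.slices = slices

    @property
    def num_distinct(self) -> int:
        return int(self.values.size)

    @property
    def num_sites(self) -> int:
        return int(self.counts.sum())

    # -- construction ------------------------------------------------------

    @classmethod
    def build(
        cls, spacers: Mapping[str, int], config: SliceConfig | None = None
    ) -> "ISSLIndex":
        """Build the index from a distinct-spacer -> occurrence-count map."""
        config = config or SliceConfig()
        if not spacers:
            raise IndexConfigError("cannot build an index from zero spacers")
        pairs = sorted((encode_spacer(s), n) for s, n in spacers.items())
        for _, n in pairs:
            if n < 1:
                raise IndexConfigError("occurrence counts must be >= 1")
        values = np.array([v for v, _ in pairs], dtype=np.uint64)
        counts = np.array([n for _, n in pairs], dtype=np.int64)
        slices: list[dict[int, np.ndarray]] = []
        for p in range(config.num_slices):
            buckets: dict[int, list[int]] = {}
            for idx, (v, _) in enumerate(pairs):
                buckets.setdefault(config.signature(v, p), []).append(idx)
            slices.append(
                {sig: np.array(ix, dtype=np.uint32) for sig, ix in sorted(buckets.items())}
            )
        return cls(config=config, values=values, counts=counts, slices=slices)

    # -- queries -----------------------------------------------------------

    def query_neighbours(
        self, spacer20: str, max_mm: int = 4
    ) -> list[tuple[EncodedSpacer, int]]:
        """All indexed spacers within ``max_mm`` mismatches of the query.

        Exact recall requires ``num_slices >= max_mm + 1`` (pigeonhole);
        a looser bound is a configuration error, not a silent approximation.
        Results are sorted by (distance, encoded value).
        """
        if max_mm < 0:
            raise IndexConfigError("max_mm must be non-negative")
        if max_mm >= self.config.num_slices:
            raise IndexConfigError(
                f"exact recall needs num_slices > max_mm "
                f"({self.config.num_slices} slices, max_mm {max_mm})"
            )
        q = encode_spacer(spacer20)
        gathered = [
            table.get(self.config.signature(q, p))
            for p, table in enumerate(self.slices)
        ]
        gathered = [g for g in gathered if g is not None]
        if not gathered:
            return []
        cand = np.unique(np.concatenate(gathered))
        x = np.bitwise_xor(self.values[cand], np.uint64(q))
        mm = np.bitwise_count((x | (x >> np.uint64(1))) & _ODD_BITS)
        keep = mm <= max_mm
        hits = sorted(
            zip(mm[keep].tolist(), cand[keep].tolist()), key=lambda t: (t[0], self.values[t[1]])
        )
        return [
            (EncodedSpacer(value=int(self.values[i]), count=int(self.counts[i])), int(d))
            for d, i in hits
        ]

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the documented little-endian binary index file."""
        with open(path, "wb") as out:
            out.write(_MAGIC)
            out.write(
                struct.pack(
                    "<IIIQQ",
                    _VERSION,
                    self.config.num_slices,
                    self.config.slice_width_bases,
                    self.num_distinct,
                    self.num_sites,
                )
            )
            out.write(self.values.astype("<u8").tobytes())
            out.write(self.counts.astype("<i8").tobytes())
            for table in self.slices:
                out.write(struct.pack("<Q", len(table)))
                for sig in sorted(table):
                    ix = table[sig]
                    out.write(struct.pack("<QQ", sig, ix.size))
                    out.write(ix.astype("<u4").tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "ISSLIndex":
        with open(path, "rb") as handle:
            magic = handle.read(8)
            if magic != _MAGIC:
                raise IndexFormatError("not an ISSL index file")
            header_fmt = "<IIIQQ"
            version, num_slices, width, n_distinct, n_sites = struct.unpack(
                header_fmt, handle.read(struct.calcsize(header_fmt))
            )
            if version != _VERSION:
                raise IndexFormatError(f"unsupported index version {version}")
            config = SliceConfig(num_slices=num_slices)
            if config.slice_width_bases != width:
                raise IndexFormatError("slice width inconsistent with slice count")
            values = np.frombuffer(handle.read(8 * n_distinct), dtype="<u8").astype(np.uint64)
            counts = np.frombuffer(handle.read(8 * n_distinct), dtype="<i8").astype(np.int64)
            slices: list[dict[int, np.ndarray]] = []
            for _ in range(num_slices):
                (n_buckets,) = struct.unpack("<Q", handle.read(8))
                table: dict[int, np.ndarray] = {}
                for _ in range(n_buckets):
                    sig, n_ix = struct.unpack("<QQ", handle.read(16))
                    table[sig] = np.frombuffer(handle.read(4 * n_ix), dtype="<u4").astype(
                        np.uint32
                    )
                slices.append(table)
        index = cls(config=config, values=values, counts=counts, slices=slices)
        if index.num_distinct != n_distinct or index.num_sites != n_sites:
            raise IndexFormatError("index header totals do not match table contents")
        return index

    def dump_text(self) -> str:
        """Human-readable dump for debugging: spacer, count, per-slice sigs."""
        lines = [
            f"# slices={self.config.num_slices} width={self.config.slice_width_bases} "
            f"distinct={self.num_distinct} sites={self.num_sites}"
        ]
        for i in range(self.num_distinct):
            v = int(self.values[i])
            sigs = ",".join(
                str(self.config.signature(v, p)) for p in range(self.config.num_slices)
            )
            lines.append(f"{decode_spacer(v)}\t{int(self.counts[i])}\t{sigs}")
        return "\n".join(lines) + "\n"


def build_index(spacers: Mapping[str, int], config: SliceConfig | None = None) -> ISSLIndex:
    """Module-level convenience wrapper around :meth:`ISSLIndex.build`."""
    return ISSLIndex.build(spacers, config)


def hit_score(mismatch_pos: Iterable[int], weights: str | Sequence[float] = "uniform") -> float:
    """Single off-target hit penalty in [0, 100].

    ``100 * prod(1 - w_p)`` over the mismatched positions: a perfect match
    scores 100 (maximally dangerous duplicate) and every mismatch attenuates
    the hit by its positional weight.
    """
    w = _WEIGHT_MODES[weights] if isinstance(weights, str) else tuple(weights)
    if len(w) != SPACER_LENGTH:
        raise ValueError("weight vector must have 20 entries")
    score = 100.0
    for p in mismatch_pos:
        if not 1 <= p <= SPACER_LENGTH:
            raise ValueError(f"mismatch position out of range: {p}")
        score *= 1.0 - w[p - 1]
    return score


def specificity_score(
    query_spacer: str,
    neighbours: Sequence[tuple[EncodedSpacer, int]],
    weights: str | Sequence[float] = "uniform",
    max_mm: int = 4,
) -> OffTargetResult:
    """Aggregate neighbour hits into a guide specificity in [0, 100].

    Exactly one distance-0 occurrence of the query itself is the intended
    on-target site and is excluded; every other occurrence — including
    additional exact copies of the spacer elsewhere in the genome — counts
    as an off-target hit.  ``specificity = 10000 / (100 + sum(hit scores))``.
    """
    q = encode_spacer(query_spacer)
    neighbour_counts: dict[int, int] = {d: 0 for d in range(max_mm + 1)}
    total_hit = 0.0
    self_excluded = False
    for spacer, dist in neighbours:
        neighbour_counts[dist] = neighbour_counts.get(dist, 0) + spacer.count
        occurrences = spacer.count
        if dist == 0 and spacer.value == q and not self_excluded:
            occurrences -= 1  # the on-target site itself
            self_excluded = True
        if occurrences:
            positions = mismatch_positions(q, spacer.value)
            total_hit += occurrences * hit_score(positions, weights)
    specificity = 10000.0 / (100.0 + total_hit)
    return OffTargetResult(
        specificity=specificity, neighbour_counts=neighbour_counts, max_mm=max_mm
    )


def assess_offtarget(
    index: ISSLIndex,
    spacer20: str,
    max_mm: int = 4,
    weights: str | Sequence[float] = "uniform",
) -> OffTargetResult:
    """Query the index and aggregate the result for one candidate spacer."""
    neighbours = index.query_neighbours(spacer20, max_mm=max_mm)
    return specificity_score(spacer20, neighbours, weights=weights, max_mm=max_mm)
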