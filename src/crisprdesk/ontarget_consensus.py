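"""Consensus on-target filtering.

Each candidate is evaluated by three independent rule-based efficacy
methods and accepted when at least ``threshold`` of them vote yes
(majority 2-of-3 by default).  The three default methods are deliberately
simple, auditable sequence rules:

``g20``
    the PAM-proximal spacer base (position 20) is G — guides ending in G
    next to the PAM are preferentially active.
``composition``
    GC fraction of the spacer within [0.30, 0.70] and no TTTT run — extreme
    GC content impairs binding and poly-T terminates Pol III transcription.
``structure``
    no pair of non-overlapping spacer substrings of length >= 6 that are
    exact reverse complements (a self-hairpin would sequester the spacer).

All three are pure functions of the 23-nt target sequence; position and
strand never change a verdict.  Each method is pluggable behind the common
``(CandidateGuide) -> bool`` signature so alternative efficacy rules can be
substituted without touching the consensus logic; the defaults are this
package's stand-in rule set, not ports of any published scorer.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .genome_io import reverse_complement
from .site_extraction import CandidateGuide

MethodFn = Callable[[CandidateGuide], bool]

DEFAULT_CONSENSUS_THRESHOLD = 2

_HAIRPIN_STEM = 6  # minimum self-complementary stem length


def method_g20(candidate: CandidateGuide) -> bool:
    """True iff the PAM-proximal spacer base (position 20) is G."""
    return candidate.spacer20[19] == "G"


def method_composition(candidate: CandidateGuide) -> bool:
    """True iff spacer GC is in [0.30, 0.70] and it has no TTTT run."""
    spacer = candidate.spacer20
    gc = (spacer.count("G") + spacer.count("C")) / len(spacer)
    return 0.30 <= gc <= 0.70 and "TTTT" not in spacer


def method_structure(candidate: CandidateGuide) -> bool:
    """True iff the spacer has no self-complementary hairpin stem.

    A hairpin stem is a pair of non-overlapping substrings of length >= 6
    that are exact reverse complements.  Any longer stem contains a 6-nt
    stem whose intervals are still disjoint, so checking all 6-mer pairs is
    exhaustive.
    """
    spacer = candidate.spacer20
    n = len(spacer)
    k = _HAIRPIN_STEM
    for i in range(n - k + 1):
        stem = spacer[i : i + k]
        rc = reverse_complement(stem)
        for j in range(n - k + 1):
            if j + k <= i or j >= i + k:  # non-overlapping intervals
                if spacer[j : j + k] == rc:
                    return False
    return True


DEFAULT_METHODS: Mapping[str, MethodFn] = {
    "g20": method_g20,
    "composition": method_composition,
    "structure": method_structure,
}


@dataclass(frozen=True)
class OnTargetVerdict:
    """Per-method votes plus the consensus decision."""

    passes_g20: bool
    passes_composition: bool
    passes_structure: bool
    consensus_votes: int
    accepted: bool

    def __post_init__(self) -> None:
        votes = int(self.passes_g20) + int(self.passes_composition) + int(self.passes_structure)
        if votes != self.consensus_votes:
            raise ValueError("consensus_votes must equal the number of passing methods")


def consensus(
    passes_g20: bool,
    passes_composition: bool,
    passes_structure: bool,
    threshold: int = DEFAULT_CONSENSUS_THRESHOLD,
) -> OnTargetVerdict:
    """Combine three method votes under a configurable acceptance threshold."""
    votes = int(passes_g20) + int(passes_composition) + int(passes_structure)
    return OnTargetVerdict(
        passes_g20=passes_g20,
        passes_composition=passes_composition,
        passes_structure=passes_structure,
        consensus_votes=votes,
        accepted=votes >= threshold,
    )


def evaluate(
    candidate: CandidateGuide,
    methods: Mapping[str, MethodFn] = DEFAULT_METHODS,
    threshold: int = DEFAULT_CONSENSUS_THRESHOLD,
) -> OnTargetVerdict:
    """Run all three methods on a candidate and take the consensus.

    All methods always run (no short-circuiting) so every per-method vote is
    recorded for auditability even once the consensus is decided.
    """
    votes = {name: fn(candidate) for name, fn in methods.items()}
    return consensus(
        passes_g20=votes["g20"],
        passes_composition=votes["composition"],
        passes_structure=votes["structure"],
        threshold=threshold,
    )
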