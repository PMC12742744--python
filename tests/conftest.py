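"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (character-level
scans, string-comparison Hamming distances) kept independent of the package
code paths they check.
"""
from __future__ import annotations

import numpy as np
import pytest

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_extract(seq: str) -> list[tuple[int, str, str]]:
    """Brute-force both-strand scan testing every offset.

    Returns (start, strand, target23) sorted by (start, + before -).
    """
    out = []
    for i in range(max(len(seq) - 22, 0)):
        window = seq[i : i + 23]
        if "N" in window:
            continue
        if window[21] == "G" and window[22] == "G":
            out.append((i, "+", window))
        if window[0] == "C" and window[1] == "C":
            out.append((i, "-", naive_revcomp(window)))
    out.sort(key=lambda t: (t[0], 0 if t[1] == "+" else 1))
    return out


def naive_hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def naive_hamming_ball(
    spacer_counts: dict[str, int], query: str, max_mm: int
) -> set[tuple[str, int]]:
    """All indexed spacers within max_mm of the query, by direct comparison."""
    return {
        (s, naive_hamming(s, query))
        for s in spacer_counts
        if naive_hamming(s, query) <= max_mm
    }


def random_dna(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    bases = np.array(list("ACGTN"))
    p_acgt = (1.0 - n_prob) / 4
    probs = [p_acgt] * 4 + [n_prob]
    return "".join(rng.choice(bases, size=length, p=probs))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250930)


@pytest.fixture
def tmp_engine(tmp_path):
    """A fresh engine bound to a throwaway store and workdir."""
    from crisprdesk.config import PipelineConfig
    from crisprdesk.orchestrator import Engine, LocalStore

    def factory(config: PipelineConfig | None = None, name: str = "work") -> Engine:
        return Engine(LocalStore(), tmp_path / name, config=config)

    return factory
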