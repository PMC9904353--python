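"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

BASES = "ACGT"
COMP = str.maketrans("ACGT", "TGCA")


def revcomp_py(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def brute_count_kmers(reads, k):
    """Sliding-window dictionary oracle for canonical k-mer counting."""
    counts = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if any(c not in BASES for c in w):
                continue
            key = min(w, revcomp_py(w))
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_read_matches(motif, read, max_mismatches):
    """Exhaustive Hamming scan: does the read contain the motif (any strand)?"""
    k = len(motif)
    rc = revcomp_py(motif)
    for i in range(len(read) - k + 1):
        window = read[i : i + k]
        for pattern in (motif, rc):
            if sum(a != b for a, b in zip(window, pattern)) <= max_mismatches:
                return True
    return False


def brute_genome_proportion(motif, reads, max_mismatches):
    hits = sum(brute_read_matches(motif, r, max_mismatches) for r in reads)
    return hits / len(reads)


def brute_best_local_identity(query, reference, min_span):
    """All-diagonal, all-window oracle for ungapped local identity."""
    best = 0.0
    for ref in (reference, revcomp_py(reference)):
        for diag in range(-len(ref) + 1, len(query)):
            a_lo, a_hi = max(0, diag), min(len(query), diag + len(ref))
            if a_hi - a_lo < min_span:
                continue
            eq = [query[i] == ref[i - diag] for i in range(a_lo, a_hi)]
            for start in range(len(eq) - min_span + 1):
                best = max(best, sum(eq[start : start + min_span]) / min_span)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
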