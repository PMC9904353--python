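"""Canonical k-mer profiling and the genome-proportion statistic.

A repeat motif's *genome proportion* in an accession is the fraction of that
accession's shotgun reads containing at least one alignment of the motif (on
either strand) within a mismatch budget.  Comparing this statistic across
accessions of different ploidy is what exposes subgenome-specific repeats:
a repeat confined to one parental subgenome shows a proportion that scales
with that subgenome's dosage and collapses to ~0 in accessions lacking it.

K-mers are counted canonically (the lexicographic minimum of a window and
its reverse complement), the community convention for strand-agnostic
shotgun data.  The default motif length is 50, a length long enough to be
repeat-diagnostic yet directly usable as an oligonucleotide FISH probe.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _encode
from ._encode import revcomp
from .io import _open_text, as_sequence_list

DEFAULT_K = 50

__all__ = [
    "DEFAULT_K",
    "Motif",
    "KmerCounts",
    "KmerProfile",
    "MotifMatcher",
    "canonicalize",
    "revcomp",
    "count_kmers",
    "top_motifs",
    "genome_proportion",
    "matching_read_fraction",
    "consensus_read_fraction",
    "count_matching_reads",
    "best_local_identity",
]


def canonicalize(sequence: str) -> str:
    """Lexicographic minimum of a DNA string and its reverse complement.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    Raises ``ValueError`` on empty input or non-ACGT characters.
    """
    if not sequence:
        raise ValueError("cannot canonicalize an empty sequence")
    if any(c not in "ACGT" for c in sequence):
        raise ValueError(f"sequence contains non-ACGT characters: {sequence!r}")
    rc = revcomp(sequence)
    return sequence if sequence <= rc else rc


@dataclass(frozen=True)
class Motif:
    """A fixed-length repeat motif extracted from one accession's profile."""

    sequence: str
    source_accession: str = ""
    label: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("motif sequence must be non-empty")


def _motif_sequence(m) -> str:
    return m if isinstance(m, str) else m.sequence


class KmerCounts(Mapping):
    """Canonical k-mer -> count mapping backed by sorted packed arrays.

    Behaves like a read-only ``dict`` keyed by k-mer strings; lookups accept
    either strand (the query is canonicalized).  The packed representation
    keeps multi-million-entry profiles affordable.
    """

    __slots__ = ("k", "_hi", "_lo", "_counts")

    def __init__(self, k: int, hi: np.ndarray, lo: np.ndarray, counts: np.ndarray):
        self.k = k
        self._hi = hi
        self._lo = lo
        self._counts = counts

    @classmethod
    def from_dict(cls, k: int, data: Mapping) -> "KmerCounts":
        if not data:
            e = np.zeros(0, dtype=np.uint64)
            return cls(k, e, e.copy(), np.zeros(0, dtype=np.int64))
        hi = np.empty(len(data), dtype=np.uint64)
        lo = np.empty(len(data), dtype=np.uint64)
        counts = np.empty(len(data), dtype=np.int64)
        for i, (kmer, c) in enumerate(data.items()):
            h, l = _encode.pack_kmer(canonicalize(kmer), k)
            hi[i], lo[i], counts[i] = h, l, c
        order = np.lexsort((lo, hi))
        return cls(k, hi[order], lo[order], counts[order])

    def _find(self, kmer: str) -> int:
        if len(kmer) != self.k:
            return -1
        try:
            h, l = _encode.pack_kmer(canonicalize(kmer), self.k)
        except ValueError:
            return -1
        left = int(np.searchsorted(self._hi, np.uint64(h), side="left"))
        right = int(np.searchsorted(self._hi, np.uint64(h), side="right"))
        j = left + int(np.searchsorted(self._lo[left:right], np.uint64(l)))
        if j < right and self._lo[j] == l:
            return j
        return -1

    def __getitem__(self, kmer: str) -> int:
        j = self._find(kmer)
        if j < 0:
            raise KeyError(kmer)
        return int(self._counts[j])

    def __contains__(self, kmer) -> bool:
        return isinstance(kmer, str) and self._find(kmer) >= 0

    def __len__(self) -> int:
        return self._hi.size

    def __iter__(self):
        for i in range(self._hi.size):
            yield _encode.unpack_kmer(int(self._hi[i]), int(self._lo[i]), self.k)

    def items(self):
        for i in range(self._hi.size):
            yield (
                _encode.unpack_kmer(int(self._hi[i]), int(self._lo[i]), self.k),
                int(self._counts[i]),
            )

    def total(self) -> int:
        return int(self._counts.sum())

    def top_order(self) -> np.ndarray:
        """Indices sorted by count descending, ties lexicographic ascending."""
        return np.lexsort((self._lo, self._hi, -self._counts))

    def kmer_at(self, i: int) -> str:
        return _encode.unpack_kmer(int(self._hi[i]), int(self._lo[i]), self.k)

    def count_at(self, i: int) -> int:
        return int(self._counts[i])


@dataclass
class KmerProfile:
    """Canonical k-mer counts for one accession plus read/base tallies."""

    accession_id: str
    k: int
    counts: Mapping
    total_reads: int
    total_bases: int
    max_bases_used: int | None = None

    def to_tsv(self, path: str | Path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write(
                f"# accession={self.accession_id} k={self.k} "
                f"total_reads={self.total_reads} total_bases={self.total_bases} "
                f"max_bases_used={self.max_bases_used}\n"
            )
            for kmer, count in self.counts.items():
                fh.write(f"{kmer}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerProfile":
        meta = {}
        data = {}
        with _open_text(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for token in line[1:].split():
                        if "=" in token:
                            key, _, value = token.partition("=")
                            meta[key] = value
                    continue
                if not line:
                    continue
                kmer, count = line.split("\t")
                data[kmer] = int(count)
        k = int(meta.get("k", len(next(iter(data), ""))))
        cap = meta.get("max_bases_used", "None")
        return cls(
            accession_id=meta.get("accession", ""),
            k=k,
            counts=KmerCounts.from_dict(k, data),
            total_reads=int(meta.get("total_reads", 0)),
            total_bases=int(meta.get("total_bases", 0)),
            max_bases_used=None if cap == "None" else int(cap),
        )


def _count_kmers_python(reads: list[str], k: int) -> dict[str, int]:
    """Reference-style counting path for k beyond the packed-word limit."""
    counts: dict[str, int] = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            window = read[i : i + k]
            if any(c not in "ACGT" for c in window):
                continue
            key = canonicalize(window)
            counts[key] = counts.get(key, 0) + 1
    return counts


def count_kmers(
    read_source,
    k: int = DEFAULT_K,
    max_bases: int | None = None,
    accession_id: str = "",
    chunk_bases: int = 4_000_000,
) -> KmerProfile:
    """Count canonical k-mers over a read set, optionally capped at max_bases.

    Reads are consumed whole, in input order, until adding the next read
    would exceed ``max_bases``.  Windows containing non-ACGT characters are
    skipped; reads are never split and mates are counted independently.
    Empty input yields an empty profile with zero tallies.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(read_source, (str, Path)):
        from .io import iter_sequences

        read_iter: Iterable[str] = iter_sequences(read_source)
    else:
        read_iter = (r if isinstance(r, str) else r.sequence for r in read_source)

    total_reads = 0
    total_bases = 0
    batch: list[str] = []
    batch_bases = 0
    parts: list[tuple[np.ndarray, np.ndarray]] = []
    py_counts: dict[str, int] | None = {} if k > 64 else None

    def flush():
        nonlocal batch, batch_bases
        if not batch:
            return
        if py_counts is not None:
            for kmer, c in _count_kmers_python(batch, k).items():
                py_counts[kmer] = py_counts.get(kmer, 0) + c
        else:
            codes, _ = _encode.encode_concat(batch)
            hi, lo, valid = _encode.canonical_window_codes(codes, k)
            parts.append((hi[valid], lo[valid]))
        batch = []
        batch_bases = 0

    for read in read_iter:
        read = read.upper()
        if max_bases is not None and total_bases + len(read) > max_bases:
            break
        total_reads += 1
        total_bases += len(read)
        if len(read) >= k:
            batch.append(read)
            batch_bases += len(read)
            if batch_bases >= chunk_bases:
                flush()
    flush()

    if py_counts is not None:
        counts: Mapping = dict(sorted(py_counts.items()))
    elif parts:
        hi, lo, ct = _encode.aggregate_counts(
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
        counts = KmerCounts(k, hi, lo, ct)
    else:
        e = np.zeros(0, dtype=np.uint64)
        counts = KmerCounts(k, e, e.copy(), np.zeros(0, dtype=np.int64))

    return KmerProfile(
        accession_id=accession_id,
        k=k,
        counts=counts,
        total_reads=total_reads,
        total_bases=total_bases,
        max_bases_used=max_bases,
    )


def top_motifs(
    profile: KmerProfile,
    min_kmer_fraction: float | None = None,
    top_n: int | None = None,
) -> list[Motif]:
    """Most abundant canonical k-mers of a profile as Motif records.

    Exactly one of ``min_kmer_fraction`` (count / total window count) or
    ``top_n`` must be given.  Sorted by descending count; ties broken
    lexicographically.
    """
    if (min_kmer_fraction is None) == (top_n is None):
        raise ValueError("supply exactly one of min_kmer_fraction or top_n")
    if top_n is not None and top_n <= 0:
        raise ValueError("top_n must be positive")

    counts = profile.counts
    if isinstance(counts, KmerCounts):
        order = counts.top_order()
        total = counts.total()
        pairs = ((counts.kmer_at(i), counts.count_at(i)) for i in order)
    else:
        total = sum(counts.values())
        pairs = iter(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))

    out: list[Motif] = []
    for rank, (kmer, count) in enumerate(pairs, start=1):
        if top_n is not None and rank > top_n:
            break
        if min_kmer_fraction is not None and (total == 0 or count / total < min_kmer_fraction):
            break
        out.append(
            Motif(sequence=kmer, source_accession=profile.accession_id, label=f"m{rank}_{count}")
        )
    return out


class _SeedIndex:
    """Exact-seed lookup: packed seed code -> rows of payload arrays (CSR)."""

    def __init__(self, codes: np.ndarray, payload: tuple[np.ndarray, ...]):
        order = np.argsort(codes, kind="stable")
        codes = codes[order]
        self.payload = tuple(p[order] for p in payload)
        change = np.empty(codes.size, dtype=bool)
        if codes.size:
            change[0] = True
            np.not_equal(codes[1:], codes[:-1], out=change[1:])
        idx = np.flatnonzero(change)
        self.keys = codes[idx]
        self.starts = np.append(idx, codes.size)

    def lookup(self, window_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (window position, payload row) index pairs for every hit."""
        if self.keys.size == 0 or window_codes.size == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy()
        mask = np.isin(window_codes, self.keys)
        pos = np.flatnonzero(mask)
        if pos.size == 0:
            return pos, pos.copy()
        key_idx = np.searchsorted(self.keys, window_codes[pos])
        counts = self.starts[key_idx + 1] - self.starts[key_idx]
        total = int(counts.sum())
        rep = np.repeat(np.arange(pos.size), counts)
        base = np.repeat(self.starts[key_idx], counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        return pos[rep], base + within


@dataclass
class MatchResult:
    """Per-read match flags and per-motif alignment tallies for one scan."""

    read_mask: np.ndarray  # (n_reads, n_motifs) bool
    occurrences: np.ndarray  # (n_motifs,) distinct alignment starts
    n_reads: int
    total_bases: int
    k: int

    @property
    def read_fractions(self) -> np.ndarray:
        if self.n_reads == 0:
            raise ValueError("proportion undefined for an empty read set")
        return self.read_mask.sum(axis=0) / self.n_reads

    @property
    def base_fractions(self) -> np.ndarray:
        if self.total_bases == 0:
            raise ValueError("proportion undefined for an empty read set")
        return self.occurrences * self.k / self.total_bases


class MotifMatcher:
    """Mismatch-tolerant search of a motif set against read sets.

    Seeds with ``max_mismatches + 1`` disjoint exact seeds per strand
    (pigeonhole-complete: any alignment with <= max_mismatches substitutions
    leaves at least one seed intact), then verifies candidates with a full
    Hamming comparison.
    """

    def __init__(self, motifs: Sequence, max_mismatches: int = 2):
        sequences = [_motif_sequence(m).upper() for m in motifs]
        if not sequences:
            raise ValueError("motif set must be non-empty")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("all motifs must share one length")
        self.k = lengths.pop()
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.max_mismatches = max_mismatches
        self.sequences = sequences
        n_seeds = max_mismatches + 1
        self.seed_length = max(1, min(32, self.k // n_seeds))
        if self.seed_length * n_seeds > self.k:
            n_seeds = self.k // self.seed_length
        self._strand_codes = np.empty((len(sequences), 2, self.k), dtype=np.uint8)
        seed_codes: list[int] = []
        e_motif: list[int] = []
        e_strand: list[int] = []
        e_offset: list[int] = []
        for i, seq in enumerate(sequences):
            for strand, s in enumerate((seq, revcomp(seq))):
                codes = _encode.encode(s)
                if (codes >= _encode.SENTINEL).any():
                    raise ValueError(f"motif contains non-ACGT characters: {seq!r}")
                self._strand_codes[i, strand] = codes
                for p in range(n_seeds):
                    off = p * self.seed_length
                    hi, lo, _ = _encode.window_codes(
                        codes[off : off + self.seed_length], self.seed_length
                    )
                    seed_codes.append(int(lo[0]))
                    e_motif.append(i)
                    e_strand.append(strand)
                    e_offset.append(off)
        self._index = _SeedIndex(
            np.asarray(seed_codes, dtype=np.uint64),
            (
                np.asarray(e_motif, dtype=np.int64),
                np.asarray(e_strand, dtype=np.int64),
                np.asarray(e_offset, dtype=np.int64),
            ),
        )

    def scan(self, read_source, chunk_reads: int = 200_000) -> MatchResult:
        reads = as_sequence_list(read_source)
        n_motifs = len(self.sequences)
        mask = np.zeros((len(reads), n_motifs), dtype=bool)
        occurrences = np.zeros(n_motifs, dtype=np.int64)
        total_bases = 0
        k = self.k
        mm = self.max_mismatches
        for lo_i in range(0, len(reads), chunk_reads):
            chunk = [r.upper() for r in reads[lo_i : lo_i + chunk_reads]]
            total_bases += sum(len(r) for r in chunk)
            if not chunk:
                continue
            codes, starts = _encode.encode_concat(chunk)
            if codes.size < self.seed_length:
                continue
            _, wlo, valid = _encode.window_codes(codes, self.seed_length)
            pos, rows = self._index.lookup(wlo)
            keep = valid[pos]
            pos, rows = pos[keep], rows[keep]
            if pos.size == 0:
                continue
            motif = self._index.payload[0][rows]
            strand = self._index.payload[1][rows]
            astart = pos - self._index.payload[2][rows]
            ri = np.searchsorted(starts, pos, side="right") - 1
            read_start = starts[ri]
            read_end = starts[ri + 1] - 1
            ok = (astart >= read_start) & (astart + k <= read_end)
            motif, strand, astart, ri = motif[ok], strand[ok], astart[ok], ri[ok]
            if astart.size == 0:
                continue
            # collapse duplicate (alignment, motif, strand) candidates
            key = (astart * n_motifs + motif) * 2 + strand
            _, uniq = np.unique(key, return_index=True)
            motif, strand, astart, ri = motif[uniq], strand[uniq], astart[uniq], ri[uniq]
            for sub in range(0, astart.size, 500_000):
                sl = slice(sub, sub + 500_000)
                seg = codes[astart[sl, None] + np.arange(k)]
                mism = (seg != self._strand_codes[motif[sl], strand[sl]]).sum(axis=1)
                hit = mism <= mm
                mask[ri[sl][hit] + lo_i, motif[sl][hit]] = True
                # count alignment starts once per (start, motif) across strands
                hk = astart[sl][hit] * n_motifs + motif[sl][hit]
                hk_u, hk_m = np.unique(hk, return_index=True)
                np.add.at(occurrences, motif[sl][hit][hk_m], 1)
        return MatchResult(
            read_mask=mask,
            occurrences=occurrences,
            n_reads=len(reads),
            total_bases=total_bases,
            k=self.k,
        )


def genome_proportion(motif, read_source, max_mismatches: int = 2) -> float:
    """Fraction of reads containing the motif (either strand, <= mm subs)."""
    reads = as_sequence_list(read_source)
    if not reads:
        raise ValueError("genome proportion is undefined for zero reads")
    matcher = MotifMatcher([motif], max_mismatches=max_mismatches)
    return float(matcher.scan(reads).read_mask.any(axis=1).mean())


def matching_read_fraction(motifs: Sequence, read_source, max_mismatches: int = 2) -> float:
    """Fraction of reads matching at least one motif of a set (no double count)."""
    reads = as_sequence_list(read_source)
    if not reads:
        raise ValueError("proportion undefined for zero reads")
    matcher = MotifMatcher(motifs, max_mismatches=max_mismatches)
    return float(matcher.scan(reads).read_mask.any(axis=1).mean())


def consensus_read_fraction(
    consensus: str, read_source, k: int = DEFAULT_K, max_mismatches: int = 2
) -> float:
    """Fraction of reads containing any k-window of a family consensus."""
    windows = sorted({consensus[i : i + k] for i in range(len(consensus) - k + 1)})
    if not windows:
        raise ValueError("consensus shorter than k")
    return matching_read_fraction(windows, read_source, max_mismatches=max_mismatches)


def _diagonal_best_identity(
    rcodes: np.ndarray, ccodes: np.ndarray, diag: int, min_span: int
) -> float:
    """Best identity of any min_span window on one ungapped diagonal."""
    a_lo = max(0, diag)
    a_hi = min(rcodes.size, diag + ccodes.size)
    if a_hi - a_lo < min_span:
        return 0.0
    eq = (rcodes[a_lo:a_hi] == ccodes[a_lo - diag : a_hi - diag]).astype(np.int64)
    cs = np.cumsum(eq)
    wsum = cs[min_span - 1 :].copy()
    wsum[1:] -= cs[: cs.size - min_span]
    return float(wsum.max()) / min_span


def _consensus_seed_index(consensus: str, seed_len: int) -> tuple[_SeedIndex, list[np.ndarray]]:
    strands = [consensus, revcomp(consensus)]
    ccodes = [_encode.encode(s) for s in strands]
    seed_codes: list[np.ndarray] = []
    e_strand: list[np.ndarray] = []
    e_cpos: list[np.ndarray] = []
    for strand, codes in enumerate(ccodes):
        _, lo, valid = _encode.window_codes(codes, seed_len)
        pos = np.flatnonzero(valid)
        seed_codes.append(lo[pos])
        e_strand.append(np.full(pos.size, strand, dtype=np.int64))
        e_cpos.append(pos.astype(np.int64))
    index = _SeedIndex(
        np.concatenate(seed_codes) if seed_codes else np.zeros(0, dtype=np.uint64),
        (np.concatenate(e_strand), np.concatenate(e_cpos)),
    )
    return index, ccodes


class ConsensusSetMatcher:
    """Local ungapped matching of reads against several consensi at once.

    A read matches a consensus if some diagonal (either strand, anchored by
    an exact shared ``seed_length``-mer) carries a window of ``min_span``
    bases with identity >= ``min_identity``.  Encoding and seed lookup are
    shared across consensi, which matters when scoring several assembled
    contigs against the same large read set.
    """

    def __init__(
        self,
        consensi: Sequence[str],
        min_span: int = DEFAULT_K,
        seed_length: int = 12,
    ):
        if not consensi or any(not c for c in consensi):
            raise ValueError("empty consensus")
        self.consensi = [c.upper() for c in consensi]
        self.min_span = min_span
        self.seed_length = seed_length
        self._ccodes: list[tuple[np.ndarray, np.ndarray]] = []
        seed_parts, e_cons, e_strand, e_cpos = [], [], [], []
        for ci, consensus in enumerate(self.consensi):
            strands = (consensus, revcomp(consensus))
            pair = []
            for strand, s in enumerate(strands):
                codes = _encode.encode(s)
                pair.append(codes)
                _, lo, valid = _encode.window_codes(codes, seed_length)
                pos = np.flatnonzero(valid)
                seed_parts.append(lo[pos])
                e_cons.append(np.full(pos.size, ci, dtype=np.int64))
                e_strand.append(np.full(pos.size, strand, dtype=np.int64))
                e_cpos.append(pos.astype(np.int64))
            self._ccodes.append(tuple(pair))
        self._index = _SeedIndex(
            np.concatenate(seed_parts),
            (np.concatenate(e_cons), np.concatenate(e_strand), np.concatenate(e_cpos)),
        )

    def matching_reads(
        self, read_source, min_identity: float, chunk_reads: int = 200_000
    ) -> np.ndarray:
        """Boolean (n_reads, n_consensi) matrix of local-match verdicts."""
        if not 0.5 < min_identity <= 1.0:
            raise ValueError("min_identity must be in (0.5, 1]")
        threshold = min_identity - 1e-9
        reads = as_sequence_list(read_source)
        matched = np.zeros((len(reads), len(self.consensi)), dtype=bool)
        for lo_i in range(0, len(reads), chunk_reads):
            chunk = [r.upper() for r in reads[lo_i : lo_i + chunk_reads]]
            if not chunk:
                continue
            codes, starts = _encode.encode_concat(chunk)
            if codes.size < self.seed_length:
                continue
            _, wlo, valid = _encode.window_codes(codes, self.seed_length)
            pos, rows = self._index.lookup(wlo)
            keep = valid[pos]
            pos, rows = pos[keep], rows[keep]
            if pos.size == 0:
                continue
            cons = self._index.payload[0][rows]
            strand = self._index.payload[1][rows]
            cpos = self._index.payload[2][rows]
            ri = np.searchsorted(starts, pos, side="right") - 1
            diag = pos - starts[ri] - cpos
            quads = np.unique(np.stack([ri, cons, strand, diag], axis=1), axis=0)
            for r, ci, s, d in quads:
                if matched[int(r) + lo_i, ci]:
                    continue
                rstart = int(starts[r])
                rend = int(starts[r + 1]) - 1
                span = min(self.min_span, len(self.consensi[ci]))
                ident = _diagonal_best_identity(
                    codes[rstart:rend], self._ccodes[ci][int(s)], int(d), span
                )
                if ident >= threshold:
                    matched[int(r) + lo_i, ci] = True
        return matched


def count_matching_reads(
    consensus: str,
    read_source,
    min_identity: float,
    min_span: int = DEFAULT_K,
    seed_length: int = 12,
) -> int:
    """Count reads with a local ungapped match to a consensus.

    A read counts if its best local alignment to the consensus (either
    strand) covers at least ``min_span`` bases at identity >=
    ``min_identity``.  Non-increasing in ``min_identity``.
    """
    matcher = ConsensusSetMatcher([consensus], min_span=min_span, seed_length=seed_length)
    return int(matcher.matching_reads(read_source, min_identity)[:, 0].sum())


def best_local_identity(
    query: str, reference: str, min_span: int = DEFAULT_K, seed_length: int = 12
) -> float:
    """Best ungapped local identity between two sequences, either strand.

    Diagonals are anchored by exact shared ``seed_length``-mers; returns 0.0
    when no anchored diagonal offers a window of ``min_span`` bases.
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    query, reference = query.upper(), reference.upper()
    min_span = min(min_span, len(reference), len(query))
    index, ccodes = _consensus_seed_index(reference, min(seed_length, min_span))
    qcodes = _encode.encode(query)
    _, wlo, valid = _encode.window_codes(qcodes, min(seed_length, min_span))
    if wlo.size == 0:
        return 0.0
    pos, rows = index.lookup(wlo)
    keep = valid[pos]
    pos, rows = pos[keep], rows[keep]
    if pos.size == 0:
        return 0.0
    strand = index.payload[0][rows]
    diag = pos - index.payload[1][rows]
    best = 0.0
    for s, d in {(int(s), int(d)) for s, d in zip(strand, diag)}:
        best = max(best, _diagonal_best_identity(qcodes, ccodes[s], d, min_span))
        if best == 1.0:
            break
    return best
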