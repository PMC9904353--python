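"""Cross-accession screening for genome-specific repeats.

Two complementary discovery strategies operate on the motif x accession
genome-proportion matrix:

* **differential** — a motif is a candidate when its proportion in every
  target accession is at least ``ratio_min`` times the worst background
  proportion AND the background never exceeds ``background_max``
  (defaults: 100x and 0.01 %).  This finds repeats private to one genome
  in a polyploid, e.g. a subgenome contributed by an unsequenced parent.

* **shared** — motifs abundant in ALL target accessions are greedily
  assembled into contigs by exact suffix-prefix overlap; contigs whose
  proportion stays below ``background_max`` in every background accession
  are candidates, ranked by mean target proportion.  This reconstructs a
  repeat common to a group of polyploids but absent from the sampled
  diploids.

Candidates are finally screened for probe suitability (GC window,
homopolymer runs, telomere exclusion) so they can serve as FISH
oligonucleotide probes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filters import DEFAULT_TELOMERE_UNIT, gc_content, is_telomeric
from .io import _open_text, write_fasta
from .kmers import (
    DEFAULT_K,
    ConsensusSetMatcher,
    MotifMatcher,
    best_local_identity,
    canonicalize,
    revcomp,
    _motif_sequence,
)

__all__ = [
    "AbundanceMatrix",
    "ScreenConfig",
    "Contig",
    "Candidate",
    "CandidateSet",
    "ProbeReport",
    "RecoveryReport",
    "build_matrix",
    "strategy_differential",
    "strategy_shared",
    "assemble_greedy",
    "score_probe",
    "evaluate_recovery",
]


@dataclass
class AbundanceMatrix:
    """Motifs x accessions genome-proportion table (values in [0, 1])."""

    proportions: pd.DataFrame  # index: motif sequences, columns: accession ids
    method: str = "read_level"  # read_level | base_level

    def __post_init__(self):
        values = self.proportions.to_numpy()
        if np.isnan(values).any():
            raise ValueError("abundance matrix has missing cells")
        if ((values < 0) | (values > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def motifs(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.proportions.columns)

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with _open_text(path, "wt") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# method={self.method}\n")
            self.proportions.to_csv(fh, sep="\t", index_label="motif", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceMatrix":
        method = "read_level"
        with _open_text(path) as fh:
            lines = []
            for line in fh:
                if line.startswith("# method="):
                    method = line.strip().split("=", 1)[1]
                elif not line.startswith("#"):
                    lines.append(line)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col="motif")
        return cls(proportions=df, method=method)


@dataclass(frozen=True)
class ScreenConfig:
    """Accession roles and thresholds for the discovery strategies."""

    targets: tuple[str, ...]
    background: tuple[str, ...]
    target_min: float = 0.0005  # presence threshold for the shared strategy
    background_max: float = 0.0001  # the 0.01 % ceiling, strict
    ratio_min: float = 100.0

    def __post_init__(self):
        if set(self.targets) & set(self.background):
            raise ValueError("targets and background must be disjoint")
        if self.ratio_min <= 1:
            raise ValueError("ratio_min must exceed 1")
        if not self.targets or not self.background:
            raise ValueError("targets and background must both be non-empty")

    def to_dict(self) -> dict:
        return {
            "targets": list(self.targets),
            "background": list(self.background),
            "target_min": self.target_min,
            "background_max": self.background_max,
            "ratio_min": self.ratio_min,
        }


@dataclass(frozen=True)
class Contig:
    """A greedy-assembly product; members overlap exactly as recorded."""

    sequence: str
    member_motifs: tuple[str, ...]
    overlaps: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self):
        for m in self.member_motifs:
            if m not in self.sequence and revcomp(m) not in self.sequence:
                raise ValueError("contig member is not a substring of the contig")


@dataclass
class Candidate:
    sequence: str
    label: str
    kind: str  # motif | contig
    proportions: dict[str, float]
    score: float
    members: tuple[str, ...] = ()


@dataclass
class CandidateSet:
    strategy: str  # differential | shared
    config: ScreenConfig
    candidates: list[Candidate]

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, ((c.label, c.sequence) for c in self.candidates))

    def to_json(self, path: str | Path, header: Mapping | None = None) -> None:
        payload = {
            "strategy": self.strategy,
            "config": self.config.to_dict(),
            "candidates": [
                {
                    "label": c.label,
                    "kind": c.kind,
                    "sequence": c.sequence,
                    "score": c.score,
                    "proportions": c.proportions,
                    "members": list(c.members),
                }
                for c in self.candidates
            ],
        }
        if header:
            payload = {**dict(header), **payload}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def build_matrix(
    motifs: Sequence,
    read_sets: Mapping[str, Sequence],
    max_mismatches: int = 2,
    method: str = "read_level",
) -> AbundanceMatrix:
    """Genome proportion of every motif in every accession's read set."""
    sequences = [_motif_sequence(m) for m in motifs]
    if not sequences:
        raise ValueError("need at least one motif")
    if not read_sets:
        raise ValueError("need at least one accession")
    matcher = MotifMatcher(sequences, max_mismatches=max_mismatches)
    columns = {}
    for acc_id, reads in read_sets.items():
        result = matcher.scan(reads)
        if result.n_reads == 0:
            raise ValueError(f"accession {acc_id!r} has zero reads")
        columns[acc_id] = (
            result.read_fractions if method == "read_level" else result.base_fractions
        )
    df = pd.DataFrame(columns, index=sequences)
    return AbundanceMatrix(proportions=df, method=method)


def strategy_differential(matrix: AbundanceMatrix, config: ScreenConfig) -> CandidateSet:
    """Motifs enriched >= ratio_min-fold in targets over a quiet background.

    A zero background with a positive target minimum counts as accepted
    (ratio treated as infinite); the background ceiling is strict, matching
    the "< 0.01 % of the genome" convention.  Candidates are ranked by
    minimum target proportion, ties broken lexicographically.
    """
    df = matrix.proportions
    missing = (set(config.targets) | set(config.background)) - set(df.columns)
    if missing:
        raise ValueError(f"accessions absent from matrix: {sorted(missing)}")
    tmin = df[list(config.targets)].min(axis=1)
    bmax = df[list(config.background)].max(axis=1)
    ratio_ok = np.where(bmax > 0, tmin >= config.ratio_min * bmax, tmin > 0)
    accepted = df.index[(bmax < config.background_max) & ratio_ok]
    ranked = sorted(accepted, key=lambda m: (-tmin[m], m))
    candidates = [
        Candidate(
            sequence=m,
            label=f"motif_{i + 1}",
            kind="motif",
            proportions={acc: float(df.at[m, acc]) for acc in df.columns},
            score=float(tmin[m]),
        )
        for i, m in enumerate(ranked)
    ]
    return CandidateSet(strategy="differential", config=config, candidates=candidates)


# ---------------------------------------------------------------------------
# Greedy suffix-prefix assembly


class _AsmContig:
    __slots__ = ("seq", "members", "head", "tail")

    def __init__(self, seq: str, members: list[tuple[int, int, int]], head, tail):
        self.seq = seq
        self.members = members  # (motif index, orientation, offset)
        self.head = head  # (motif index, orientation) at the left end
        self.tail = tail

    @classmethod
    def singleton(cls, idx: int, seq: str) -> "_AsmContig":
        return cls(seq, [(idx, 0, 0)], (idx, 0), (idx, 0))

    def flipped(self, k: int) -> "_AsmContig":
        seq = revcomp(self.seq)
        members = [
            (idx, 1 - o, len(self.seq) - k - off) for idx, o, off in reversed(self.members)
        ]
        return _AsmContig(
            seq,
            members,
            (self.tail[0], 1 - self.tail[1]),
            (self.head[0], 1 - self.head[1]),
        )


def _overlap_edges(strands: list[tuple[str, str]], k: int, min_overlap: int):
    """Max exact suffix-prefix overlap for every oriented motif pair.

    Returned grouped by overlap length, descending; each edge is
    (i, oi, j, oj) meaning suffix of motif i (orientation oi) overlaps the
    prefix of motif j (orientation oj).
    """
    edges: dict[int, list[tuple[int, int, int, int]]] = {}
    seen: set[tuple[int, int, int, int]] = set()
    for t in range(k - 1, min_overlap - 1, -1):
        prefixes: dict[str, list[tuple[int, int]]] = {}
        for j, pair in enumerate(strands):
            for oj, s in enumerate(pair):
                prefixes.setdefault(s[:t], []).append((j, oj))
        for i, pair in enumerate(strands):
            for oi, s in enumerate(pair):
                for j, oj in prefixes.get(s[-t:], ()):
                    if i == j and oi == oj:
                        continue  # tandem self-overlap cannot merge a contig with itself
                    key = (i, oi, j, oj)
                    if key in seen:
                        continue
                    seen.add(key)
                    edges.setdefault(t, []).append(key)
    return edges


def assemble_greedy(motifs: Sequence, min_overlap: int | None = None) -> list[Contig]:
    """Greedy unitig-style assembly of equal-length motifs.

    Builds the exact suffix-prefix overlap graph in both orientations
    (overlap >= ``min_overlap``, default k // 2) and repeatedly merges the
    highest-overlap available pair; ties prefer the longer, then
    lexicographically smaller, merged sequence.  Every input motif ends up
    in exactly one contig; duplicates are collapsed with a warning.
    Deterministic.
    """
    raw = [_motif_sequence(m).upper() for m in motifs]
    sequences: list[str] = []
    seen_seq = set()
    for s in raw:
        if s in seen_seq:
            warnings.warn("duplicate motifs collapsed during assembly", stacklevel=2)
            continue
        seen_seq.add(s)
        sequences.append(s)
    if not sequences:
        return []
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("assembly input motifs must share one length")
    k = lengths.pop()
    if min_overlap is None:
        min_overlap = k // 2
    if not k > min_overlap >= k / 2:
        raise ValueError("require k > min_overlap >= k/2")

    strands = [(s, revcomp(s)) for s in sequences]
    edges_by_t = _overlap_edges(strands, k, min_overlap)

    contig_of = list(range(len(sequences)))  # motif index -> contig id
    contigs: dict[int, _AsmContig] = {
        i: _AsmContig.singleton(i, s) for i, s in enumerate(sequences)
    }

    def oriented(cid: int, motif: int, orient: int, end: str) -> _AsmContig | None:
        """Contig ``cid`` oriented so that (motif, orient) sits at ``end``."""
        c = contigs[cid]
        want = (motif, orient)
        anti = (motif, 1 - orient)
        if end == "tail":
            if c.tail == want:
                return c
            if c.head == anti:
                return c.flipped(k)
        else:
            if c.head == want:
                return c
            if c.tail == anti:
                return c.flipped(k)
        return None

    for t in sorted(edges_by_t, reverse=True):
        group = edges_by_t[t]
        while True:
            best = None  # (len(merged), merged, edge, left contig, right contig)
            for i, oi, j, oj in group:
                ci, cj = contig_of[i], contig_of[j]
                if ci == cj:
                    continue
                left = oriented(ci, i, oi, "tail")
                right = oriented(cj, j, oj, "head")
                if left is None or right is None:
                    continue
                merged = left.seq + right.seq[t:]
                key = (-len(merged), merged)
                if best is None or key < best[0]:
                    best = (key, (i, oi, j, oj), left, right)
            if best is None:
                break
            _, (i, oi, j, oj), left, right = best
            ci, cj = contig_of[i], contig_of[j]
            shift = len(left.seq) - t
            members = left.members + [
                (idx, o, off + shift) for idx, o, off in right.members
            ]
            new = _AsmContig(left.seq + right.seq[t:], members, left.head, right.tail)
            contigs[ci] = new
            del contigs[cj]
            for idx, _, _ in members:
                contig_of[idx] = ci

    out = []
    for c in contigs.values():
        rc = revcomp(c.seq)
        if rc < c.seq:
            c = c.flipped(k)
        members = sorted(c.members, key=lambda m: m[2])
        names = [sequences[idx] for idx, _, _ in members]
        overlaps = tuple(
            (names[a], names[a + 1], k - (members[a + 1][2] - members[a][2]))
            for a in range(len(members) - 1)
        )
        out.append(Contig(sequence=c.seq, member_motifs=tuple(names), overlaps=overlaps))
    out.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return out


def strategy_shared(
    target_motif_sets: Mapping[str, Sequence],
    read_sets: Mapping[str, Sequence],
    config: ScreenConfig,
    min_overlap: int | None = None,
    max_mismatches: int = 2,
    min_identity: float = 0.9,
) -> CandidateSet:
    """Assemble motifs shared by every target and screen contigs on background.

    Step 1 keeps motifs found (canonical identity) in all targets' abundant
    sets AND at proportion >= ``target_min`` in every target; step 2
    assembles them greedily; step 3 measures each contig's read proportion
    in every accession by local matching at ``min_identity``; step 4 accepts
    contigs whose background maximum stays below ``background_max``, ranked
    by mean target proportion.
    """
    if len(config.targets) < 2:
        raise ValueError("shared strategy needs at least two target accessions")
    missing = set(config.targets) - set(target_motif_sets)
    if missing:
        raise ValueError(f"missing motif sets for targets: {sorted(missing)}")
    canon_sets = []
    first_order: list[str] = []
    for acc in config.targets:
        canon = {canonicalize(_motif_sequence(m)) for m in target_motif_sets[acc]}
        canon_sets.append(canon)
        if acc == config.targets[0]:
            seen = set()
            for m in target_motif_sets[acc]:
                c = canonicalize(_motif_sequence(m))
                if c not in seen:
                    seen.add(c)
                    first_order.append(c)
    shared = [m for m in first_order if all(m in s for s in canon_sets)]
    if not shared:
        return CandidateSet(strategy="shared", config=config, candidates=[])

    matcher = MotifMatcher(shared, max_mismatches=max_mismatches)
    present = np.ones(len(shared), dtype=bool)
    for acc in config.targets:
        result = matcher.scan(read_sets[acc])
        if result.n_reads == 0:
            raise ValueError(f"accession {acc!r} has zero reads")
        present &= result.read_fractions >= config.target_min
    kept = [m for m, p in zip(shared, present) if p]
    if not kept:
        return CandidateSet(strategy="shared", config=config, candidates=[])

    contigs = assemble_greedy(kept, min_overlap=min_overlap)
    if not contigs:
        return CandidateSet(strategy="shared", config=config, candidates=[])
    accessions = list(config.targets) + list(config.background)
    contig_matcher = ConsensusSetMatcher([c.sequence for c in contigs])
    fractions = {}
    for acc in accessions:
        reads = read_sets[acc]
        if len(reads) == 0:
            raise ValueError(f"accession {acc!r} has zero reads")
        hits = contig_matcher.matching_reads(reads, min_identity=min_identity)
        fractions[acc] = hits.sum(axis=0) / len(reads)
    candidates = []
    for idx, contig in enumerate(contigs, start=1):
        proportions = {acc: float(fractions[acc][idx - 1]) for acc in accessions}
        bmax = max(proportions[acc] for acc in config.background)
        if bmax >= config.background_max:
            continue
        score = float(np.mean([proportions[acc] for acc in config.targets]))
        candidates.append(
            Candidate(
                sequence=contig.sequence,
                label=f"contig_{idx}",
                kind="contig",
                proportions=proportions,
                score=score,
                members=contig.member_motifs,
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.sequence))
    return CandidateSet(strategy="shared", config=config, candidates=candidates)


@dataclass(frozen=True)
class ProbeReport:
    sequence: str
    suitable: bool
    reasons: tuple[str, ...]
    gc: float
    max_homopolymer: int


def _max_homopolymer_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def score_probe(
    sequence: str,
    gc_bounds: tuple[float, float] = (0.35, 0.65),
    max_homopolymer: int = 6,
    telomere_unit: str = DEFAULT_TELOMERE_UNIT,
) -> ProbeReport:
    """Quick suitability screen for a FISH oligonucleotide probe candidate.

    Suitable iff GC lies within ``gc_bounds``, no homopolymer run exceeds
    ``max_homopolymer`` and the sequence is not telomeric.
    """
    if len(sequence) < 30:
        raise ValueError("probe candidates must be at least 30 bases")
    sequence = sequence.upper()
    reasons = []
    gc = gc_content(sequence)
    if not gc_bounds[0] <= gc <= gc_bounds[1]:
        reasons.append("gc_out_of_range")
    run = _max_homopolymer_run(sequence)
    if run > max_homopolymer:
        reasons.append("homopolymer")
    if is_telomeric(sequence, telomere_unit):
        reasons.append("telomeric")
    return ProbeReport(
        sequence=sequence,
        suitable=not reasons,
        reasons=tuple(reasons),
        gc=gc,
        max_homopolymer=run,
    )


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    f1: float
    recovered: frozenset
    flagged: bool = False  # True when precision defaults by convention


def evaluate_recovery(
    candidates: CandidateSet | Sequence,
    truth_consensus: Mapping[str, str],
    min_identity: float = 0.9,
    min_span: int = DEFAULT_K,
) -> RecoveryReport:
    """Family-level precision/recall of a candidate set against planted truth.

    A family is recovered when some candidate matches its consensus at
    >= ``min_identity`` over >= ``min_span`` bases (either strand).  An
    empty candidate set reports recall 0 and, by convention, precision 1.0
    with ``flagged=True``.
    """
    if not truth_consensus:
        raise ValueError("ground truth is empty")
    items = candidates.candidates if isinstance(candidates, CandidateSet) else list(candidates)
    sequences = [c.sequence if isinstance(c, Candidate) else _motif_sequence(c) for c in items]
    if not sequences:
        return RecoveryReport(
            precision=1.0, recall=0.0, f1=0.0, recovered=frozenset(), flagged=True
        )
    recovered = set()
    matched = 0
    for seq in sequences:
        hit = False
        for fam, consensus in truth_consensus.items():
            if best_local_identity(seq, consensus, min_span=min_span) >= min_identity:
                recovered.add(fam)
                hit = True
        matched += hit
    precision = matched / len(sequences)
    recall = len(recovered) / len(truth_consensus)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return RecoveryReport(
        precision=precision, recall=recall, f1=f1, recovered=frozenset(recovered)
    )
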