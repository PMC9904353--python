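"""Exclusion filters applied to abundant motifs before any comparison.

Four classes of abundant k-mers are uninformative for genome discrimination
and are removed up front: the plant telomeric repeat (TTTAGGG)n, motifs with
homology to ribosomal DNA or plastid genomes (organellar reads are abundant
in shotgun data regardless of ploidy), sequencing-adapter carry-over, and
motifs of extreme GC content (homopolymer-like artefacts).  Precedence when
several apply: telomeric > rdna > plastid > adapter > gc_extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import write_tsv
from .kmers import Motif, canonicalize, revcomp

LIBRARY_ORDER = ("rdna", "plastid", "adapter")

DEFAULT_TELOMERE_UNIT = "TTTAGGG"


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases; raises on empty or non-ACGT input."""
    if not sequence:
        raise ValueError("gc_content of empty sequence")
    sequence = sequence.upper()
    if any(c not in "ACGT" for c in sequence):
        raise ValueError("sequence contains non-ACGT characters")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def is_telomeric(
    sequence: str,
    unit: str = DEFAULT_TELOMERE_UNIT,
    min_cover: float = 0.8,
) -> bool:
    """True when the sequence is covered by tandem-telomere motif copies.

    Coverage counts positions under occurrences of any cyclic rotation of
    the unit or of its reverse complement; rotation invariance is what makes
    the detector phase-agnostic for k-mers cut out of an (TTTAGGG)n array.
    """
    sequence = sequence.upper()
    if len(sequence) < len(unit):
        raise ValueError("sequence shorter than telomere unit")
    covered = [False] * len(sequence)
    patterns = set(_rotations(unit.upper())) | set(_rotations(revcomp(unit.upper())))
    for pat in patterns:
        start = sequence.find(pat)
        while start != -1:
            for i in range(start, start + len(pat)):
                covered[i] = True
            start = sequence.find(pat, start + 1)
    return sum(covered) / len(sequence) >= min_cover


def load_fasta_library(path: str | Path) -> list[str]:
    """Read a contaminant reference library from FASTA."""
    from .io import iter_sequences

    return list(iter_sequences(path))


@dataclass
class FilterConfig:
    """Thresholds and reference libraries for the motif exclusion step."""

    telomere_unit: str = DEFAULT_TELOMERE_UNIT
    telomere_min_cover: float = 0.8
    gc_low: float = 0.2
    gc_high: float = 0.8
    contaminant_libraries: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed_length: int = 25

    def __post_init__(self):
        if not self.telomere_unit:
            raise ValueError("telomere_unit must be non-empty")
        if not 0 <= self.gc_low < self.gc_high <= 1:
            raise ValueError("require 0 <= gc_low < gc_high <= 1")
        unknown = set(self.contaminant_libraries) - set(LIBRARY_ORDER)
        if unknown:
            raise ValueError(f"unknown contaminant library names: {sorted(unknown)}")
        self._library_kmers: dict[str, frozenset[str]] = {}
        for name in LIBRARY_ORDER:
            seqs = self.contaminant_libraries.get(name, ())
            kmers: set[str] = set()
            for seq in seqs:
                seq = seq.upper()
                for i in range(len(seq) - self.seed_length + 1):
                    window = seq[i : i + self.seed_length]
                    if all(c in "ACGT" for c in window):
                        kmers.add(canonicalize(window))
            self._library_kmers[name] = frozenset(kmers)

    def to_dict(self) -> dict:
        return {
            "telomere_unit": self.telomere_unit,
            "telomere_min_cover": self.telomere_min_cover,
            "gc_low": self.gc_low,
            "gc_high": self.gc_high,
            "seed_length": self.seed_length,
            "contaminant_libraries": {
                name: list(seqs) for name, seqs in self.contaminant_libraries.items()
            },
        }


def homology_flag(
    sequence: str,
    config_or_libraries,
    seed_length: int | None = None,
) -> str | None:
    """First contaminant library sharing an exact seed-length-mer, or None.

    Libraries are tried in the fixed order rdna -> plastid -> adapter.
    Matching is canonical (either strand).  An empty library set flags
    nothing.
    """
    if isinstance(config_or_libraries, FilterConfig):
        config = config_or_libraries
        if seed_length is not None and seed_length != config.seed_length:
            config = FilterConfig(
                telomere_unit=config.telomere_unit,
                telomere_min_cover=config.telomere_min_cover,
                gc_low=config.gc_low,
                gc_high=config.gc_high,
                contaminant_libraries=config.contaminant_libraries,
                seed_length=seed_length,
            )
    else:
        config = FilterConfig(
            contaminant_libraries=config_or_libraries,
            seed_length=seed_length if seed_length is not None else 25,
        )
    sequence = sequence.upper()
    s = config.seed_length
    query = {
        canonicalize(sequence[i : i + s])
        for i in range(len(sequence) - s + 1)
        if all(c in "ACGT" for c in sequence[i : i + s])
    }
    for name in LIBRARY_ORDER:
        if query & config._library_kmers.get(name, frozenset()):
            return name
    return None


@dataclass(frozen=True)
class FilterVerdict:
    motif: Motif
    kept: bool
    reason: str  # telomeric | rdna | plastid | adapter | gc_extreme | kept

    def __post_init__(self):
        if (self.reason == "kept") != self.kept:
            raise ValueError("reason must be 'kept' iff kept is True")


def apply_filters(motifs: Iterable, config: FilterConfig) -> list[FilterVerdict]:
    """Classify each motif as kept or excluded, preserving input order.

    Reasons are exhaustive and exclusive, assigned with precedence
    telomeric > rdna > plastid > adapter > gc_extreme.  Idempotent on the
    kept subset.
    """
    verdicts: list[FilterVerdict] = []
    for m in motifs:
        motif = m if isinstance(m, Motif) else Motif(sequence=m)
        seq = motif.sequence.upper()
        if len(seq) >= len(config.telomere_unit) and is_telomeric(
            seq, config.telomere_unit, config.telomere_min_cover
        ):
            reason = "telomeric"
        else:
            reason = homology_flag(seq, config)
            if reason is None:
                gc = gc_content(seq)
                if gc < config.gc_low or gc > config.gc_high:
                    reason = "gc_extreme"
        if reason is None:
            verdicts.append(FilterVerdict(motif=motif, kept=True, reason="kept"))
        else:
            verdicts.append(FilterVerdict(motif=motif, kept=False, reason=reason))
    return verdicts


def kept_motifs(verdicts: Sequence[FilterVerdict]) -> list[Motif]:
    return [v.motif for v in verdicts if v.kept]


def verdicts_to_tsv(
    path: str | Path, verdicts: Sequence[FilterVerdict], header_lines: Sequence[str] = ()
) -> None:
    write_tsv(
        path,
        ((v.motif.sequence, v.kept, v.reason) for v in verdicts),
        columns=("motif", "kept", "reason"),
        header_lines=header_lines,
    )
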