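"""Plain-text I/O: FASTA/FASTQ readers and the pipeline's TSV writers.

All writers emit LF line endings.  FASTQ output uses a fixed quality of "I"
for every base, since no quality model is simulated.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn"}
_FASTQ_EXT = {".fq", ".fastq"}


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="ascii" if "t" in mode else None)
    return open(path, mode, newline="\n" if "w" in mode else None)


def _sequence_format(path: Path) -> str:
    suffixes = path.suffixes
    ext = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else path.suffix
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path.name!r}")


def iter_sequences(path: str | Path) -> Iterator[str]:
    """Yield upper-case sequence strings from a FASTA/FASTQ(.gz) file."""
    path = Path(path)
    fmt = _sequence_format(path)
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            yield str(record.seq).upper()


def as_sequence_list(read_source) -> list[str]:
    """Normalise a read source into a list of sequence strings.

    Accepts a FASTA/FASTQ path, an iterable of strings, or an iterable of
    objects exposing a ``sequence`` attribute (e.g. simulated reads).
    """
    if isinstance(read_source, (str, Path)):
        return list(iter_sequences(read_source))
    out = []
    for item in read_source:
        out.append(item if isinstance(item, str) else item.sequence)
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_tsv(
    path: str | Path,
    rows: Iterable[Sequence],
    columns: Sequence[str],
    header_lines: Sequence[str] = (),
) -> None:
    """Write a TSV with ``#``-prefixed provenance lines and a column header."""
    with _open_text(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
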