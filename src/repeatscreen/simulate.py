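"""Synthetic diploid/allopolyploid genomes, shotgun reads and flow histograms.

The generator emulates the study design of a comparative repeatome screen:
several accessions share a set of ancestral ("shared") repeat families,
individual subgenomes carry genome-specific families at realistic genome
proportions (0.01 %-2 %), telomeric (TTTAGGG)n arrays account for roughly
0.1 % of reads, and organellar/rDNA-like contamination is injected at the
read level.  Allopolyploid accessions are expressed as a dosage multiset of
subgenome labels (e.g. RRDD), so odd ploidies (RRDDB, ...) are expressible.

Everything is driven by one master seed; each stochastic stage draws from a
stream derived from it, so identical seeds give byte-identical output.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _encode
from .flow import FlowHistogram

PAIR_GAP = 50  # inner gap between paired reads; fragment = 2*read_length + gap

FAMILY_CLASSES = (
    "shared",
    "genome_specific",
    "telomeric",
    "rdna_like",
    "plastid_like",
    "gc_extreme",
)
CONTAMINANT_CLASSES = ("rdna_like", "plastid_like")


class InfeasibleSpecError(ValueError):
    """Planted repeat content cannot fit into the declared subgenome."""


@dataclass(frozen=True)
class RepeatFamily:
    """One planted repeat family and how it is laid out in the genome."""

    name: str
    consensus: str
    copy_number: int
    divergence: float = 0.0
    layout: str = "dispersed"  # tandem | dispersed
    subgenome_scope: tuple[str, ...] = ()
    family_class: str = "shared"

    def __post_init__(self):
        if any(c not in "ACGT" for c in self.consensus):
            raise ValueError(f"family {self.name}: consensus must be A/C/G/T only")
        if not 50 <= len(self.consensus) <= 5000:
            raise ValueError(f"family {self.name}: unit length must be in [50, 5000]")
        if self.copy_number < 1:
            raise ValueError(f"family {self.name}: copy_number must be positive")
        if not 0 <= self.divergence <= 0.3:
            raise ValueError(f"family {self.name}: divergence must be in [0, 0.3]")
        if self.layout not in ("tandem", "dispersed"):
            raise ValueError(f"family {self.name}: unknown layout {self.layout!r}")
        if self.family_class not in FAMILY_CLASSES:
            raise ValueError(f"family {self.name}: unknown class {self.family_class!r}")
        if self.family_class == "telomeric":
            unit = "TTTAGGG"
            if len(self.consensus) % len(unit) or self.consensus != unit * (
                len(self.consensus) // len(unit)
            ):
                raise ValueError(
                    f"family {self.name}: telomeric consensus must be concatenated "
                    f"{unit} units"
                )

    @property
    def unit_length(self) -> int:
        return len(self.consensus)

    @property
    def is_contaminant(self) -> bool:
        return self.family_class in CONTAMINANT_CLASSES


@dataclass(frozen=True)
class SimSpec:
    """Full description of a simulated study: genomes, accessions, reads."""

    subgenomes: tuple[tuple[str, int], ...]
    accessions: tuple[tuple[str, tuple[str, ...]], ...]
    families: tuple[RepeatFamily, ...] = ()
    read_length: int = 150
    coverage: float = 10.0
    error_rate: float = 0.001
    paired: bool = True
    contaminant_read_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        labels = {label for label, _ in self.subgenomes}
        if len(labels) != len(self.subgenomes):
            raise ValueError("duplicate subgenome labels")
        for label, length in self.subgenomes:
            if length <= 0:
                raise ValueError(f"subgenome {label}: non-positive length")
        for acc_id, dosage in self.accessions:
            if not dosage:
                raise ValueError(f"accession {acc_id}: dosage multiset is empty")
            missing = set(dosage) - labels
            if missing:
                raise ValueError(f"accession {acc_id}: unknown subgenomes {sorted(missing)}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if not 0 <= self.contaminant_read_fraction < 1:
            raise ValueError("contaminant_read_fraction must be in [0, 1)")
        for fam in self.families:
            if not fam.is_contaminant and set(fam.subgenome_scope) - labels:
                raise ValueError(
                    f"family {fam.name}: scope outside declared subgenomes"
                )

    def subgenome_length(self, label: str) -> int:
        return dict(self.subgenomes)[label]

    def dosage(self, accession_id: str) -> tuple[str, ...]:
        return dict(self.accessions)[accession_id]


@dataclass
class FamilyAccessionTruth:
    copies: int
    expected_base_fraction: float
    expected_read_fraction: float


@dataclass
class GroundTruth:
    """Simulator manifest: what was planted, where, and what to expect.

    ``expected_base_fraction`` is copy_number x unit_length over genome
    length (dosage-weighted); ``expected_read_fraction`` is the overlap-aware
    probability that a read contains at least one full k-window of the
    family, the quantity the read-level genome-proportion statistic
    estimates.
    """

    k_ref: int
    realized_copies: dict[str, dict[str, int]] = field(default_factory=dict)
    placements: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    per_accession: dict[str, dict[str, FamilyAccessionTruth]] = field(default_factory=dict)
    total_reads: dict[str, int] = field(default_factory=dict)
    subgenome_base_fraction: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k_ref": self.k_ref,
            "realized_copies": self.realized_copies,
            "placements": self.placements,
            "per_accession": {
                acc: {
                    fam: {
                        "copies": t.copies,
                        "expected_base_fraction": t.expected_base_fraction,
                        "expected_read_fraction": t.expected_read_fraction,
                    }
                    for fam, t in fams.items()
                }
                for acc, fams in self.per_accession.items()
            },
            "total_reads": self.total_reads,
            "subgenome_base_fraction": self.subgenome_base_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls(k_ref=payload["k_ref"])
        truth.realized_copies = payload["realized_copies"]
        truth.placements = {
            fam: {sg: [tuple(b) for b in blocks] for sg, blocks in sgs.items()}
            for fam, sgs in payload["placements"].items()
        }
        truth.per_accession = {
            acc: {
                fam: FamilyAccessionTruth(**t) for fam, t in fams.items()
            }
            for acc, fams in payload["per_accession"].items()
        }
        truth.total_reads = payload["total_reads"]
        truth.subgenome_base_fraction = payload["subgenome_base_fraction"]
        return truth


@dataclass
class SimRead:
    """A simulated read plus its generation labels (origin, mate, class)."""

    name: str
    sequence: str
    subgenome: str
    mate: int = 0  # 0 = unpaired, 1/2 = mate flags
    is_contaminant: bool = False

    @property
    def fastq_id(self) -> str:
        suffix = f"/{self.mate}" if self.mate else ""
        return f"{self.name}{suffix} sg={self.subgenome}" + (
            " contaminant" if self.is_contaminant else ""
        )


def _stream(seed: int, stage: int, key: str = "") -> np.random.Generator:
    """Deterministic per-stage RNG stream derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, stage, zlib.crc32(key.encode())])


def _place_blocks(
    occupied: list[tuple[int, int]], length: int, n_blocks: int, block_len: int,
    rng: np.random.Generator, family: str,
) -> list[tuple[int, int]]:
    """Choose non-overlapping (start, length) blocks by rejection sampling."""
    placed = []
    import bisect

    for _ in range(n_blocks):
        if block_len > length:
            raise InfeasibleSpecError(f"family {family}: block longer than subgenome")
        for _attempt in range(2000):
            start = int(rng.integers(0, length - block_len + 1))
            i = bisect.bisect_right(occupied, (start, length + 1))
            ok = True
            if i > 0 and occupied[i - 1][0] + occupied[i - 1][1] > start:
                ok = False
            if ok and i < len(occupied) and occupied[i][0] < start + block_len:
                ok = False
            if ok:
                occupied.insert(i, (start, block_len))
                placed.append((start, block_len))
                break
        else:
            raise InfeasibleSpecError(
                f"family {family}: could not place a {block_len}-base block "
                f"(subgenome too crowded)"
            )
    return placed


def _mutated_copy(
    consensus_codes: np.ndarray, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    copy = consensus_codes.copy()
    if divergence > 0:
        mask = rng.random(copy.size) < divergence
        n = int(mask.sum())
        if n:
            copy[mask] = (copy[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return copy


def build_genomes(spec: SimSpec, k_ref: int = 50) -> tuple[dict[str, str], GroundTruth]:
    """Construct subgenome sequences with planted repeats and the manifest.

    Background is uniform-random A/C/G/T; tandem families occupy one
    contiguous array, dispersed families independent non-overlapping
    positions; every copy carries independent substitutions at the family's
    divergence rate.  Contaminant-class families are NOT embedded (they are
    emitted as reads by :func:`simulate_reads`, mirroring organellar reads
    in shotgun data).  Deterministic for a given spec seed.
    """
    truth = GroundTruth(k_ref=k_ref)
    genomes: dict[str, str] = {}

    for sg_index, (label, length) in enumerate(spec.subgenomes):
        fams = [
            f
            for f in spec.families
            if not f.is_contaminant and label in f.subgenome_scope
        ]
        planted_total = sum(f.copy_number * f.unit_length for f in fams)
        if planted_total > length:
            raise InfeasibleSpecError(
                f"subgenome {label}: planted repeat length {planted_total} exceeds "
                f"declared length {length}"
            )
        rng = _stream(spec.seed, 11, label)
        arr = rng.integers(0, 4, size=length, dtype=np.uint8)
        occupied: list[tuple[int, int]] = []
        for fam in fams:
            unit = _encode.encode(fam.consensus)
            if fam.layout == "tandem":
                blocks = _place_blocks(
                    occupied, length, 1, fam.copy_number * fam.unit_length, rng, fam.name
                )
                start = blocks[0][0]
                for c in range(fam.copy_number):
                    arr[start + c * fam.unit_length : start + (c + 1) * fam.unit_length] = (
                        _mutated_copy(unit, fam.divergence, rng)
                    )
            else:
                blocks = _place_blocks(
                    occupied, length, fam.copy_number, fam.unit_length, rng, fam.name
                )
                for start, blen in blocks:
                    arr[start : start + blen] = _mutated_copy(unit, fam.divergence, rng)
            truth.realized_copies.setdefault(fam.name, {})[label] = fam.copy_number
            truth.placements.setdefault(fam.name, {})[label] = blocks
        genomes[label] = _encode.decode(arr)

    _fill_expected_fractions(spec, truth, k_ref)
    return genomes, truth


def _fill_expected_fractions(spec: SimSpec, truth: GroundTruth, k_ref: int) -> None:
    rl = spec.read_length
    flen = 2 * rl + PAIR_GAP if spec.paired else rl
    cf = spec.contaminant_read_fraction
    lengths = dict(spec.subgenomes)
    for acc_id, dosage in spec.accessions:
        weights = {}
        for label in dosage:
            weights[label] = weights.get(label, 0) + lengths[label]
        total_weight = sum(weights.values())
        total_bases = sum(lengths[label] for label in dosage)
        truth.subgenome_base_fraction[acc_id] = {
            label: lengths[label] * dosage.count(label) / total_bases
            for label in sorted(set(dosage))
        }
        acc_truth: dict[str, FamilyAccessionTruth] = {}
        for fam in spec.families:
            if fam.is_contaminant:
                continue
            copies = sum(
                truth.realized_copies.get(fam.name, {}).get(label, 0) for label in dosage
            )
            if copies == 0:
                continue
            base_fraction = (
                sum(
                    fam.copy_number * fam.unit_length
                    for label in dosage
                    if label in truth.realized_copies.get(fam.name, {})
                )
                / total_bases
            ) * (1 - cf)
            read_fraction = 0.0
            for label in sorted(set(dosage)):
                blocks = truth.placements.get(fam.name, {}).get(label, [])
                if not blocks:
                    continue
                valid = sum(max(0, blen + rl - 2 * k_ref + 1) for _, blen in blocks)
                p_sg = lengths[label] * dosage.count(label) / total_weight
                read_fraction += p_sg * valid / (lengths[label] - flen + 1)
            read_fraction *= 1 - cf
            acc_truth[fam.name] = FamilyAccessionTruth(
                copies=copies,
                expected_base_fraction=base_fraction,
                expected_read_fraction=read_fraction,
            )
        truth.per_accession[acc_id] = acc_truth


def _emit_unit_reads(
    frag: np.ndarray, rl: int, paired: bool, error_rate: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Turn a fragment code matrix into per-unit read code matrices."""
    if paired:
        read1 = frag[:, :rl].copy()
        read2 = 3 - frag[:, : frag.shape[1] - rl - 1 : -1]
        reads = [read1, read2.copy()]
    else:
        reads = [frag.copy()]
    if error_rate > 0:
        for mat in reads:
            mask = rng.random(mat.shape) < error_rate
            n = int(mask.sum())
            if n:
                mat[mask] = (mat[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return reads


def _matrix_to_strings(mat: np.ndarray) -> list[str]:
    blob = _encode._BASES[mat].tobytes().decode("ascii")
    rl = mat.shape[1]
    return [blob[i * rl : (i + 1) * rl] for i in range(mat.shape[0])]


def simulate_reads(
    genomes: Mapping[str, str],
    dosage: Sequence[str],
    spec: SimSpec,
    accession_id: str = "acc",
    truth: GroundTruth | None = None,
    chunk_units: int = 50_000,
) -> list[SimRead]:
    """Shotgun reads for one accession at the spec's coverage and geometry.

    Fragment starts are uniform, subgenome choice is proportional to dosage
    x length, strands are flipped with probability 1/2, substitution errors
    are i.i.d. at ``error_rate`` and contaminant reads are injected at
    ``contaminant_read_fraction``.  Deterministic under the spec seed.
    """
    if not dosage:
        raise ValueError("dosage must be non-empty")
    for label in dosage:
        if label not in genomes:
            raise ValueError(f"dosage references unknown subgenome {label!r}")
    rl = spec.read_length
    flen = 2 * rl + PAIR_GAP if spec.paired else rl
    lengths = {label: len(genomes[label]) for label in set(dosage)}
    if any(flen > L for L in lengths.values()):
        raise ValueError("read/fragment length exceeds a subgenome length")

    total_bases = spec.coverage * sum(lengths[label] for label in dosage)
    reads_per_unit = 2 if spec.paired else 1
    n_units = max(1, round(total_bases / (rl * reads_per_unit)))
    n_cont_units = round(spec.contaminant_read_fraction * n_units)
    pools = _contaminant_pools(spec, flen)
    if not pools:
        n_cont_units = 0
    n_genomic = n_units - n_cont_units

    rng = _stream(spec.seed, 13, accession_id)
    labels = sorted(set(dosage))
    weights = np.array([lengths[l] * dosage.count(l) for l in labels], dtype=float)
    probs = weights / weights.sum()
    per_label = rng.multinomial(n_genomic, probs)

    out: list[SimRead] = []
    counter = 0

    def emit(source_codes: np.ndarray, n: int, origin: str, contaminant: bool):
        nonlocal counter
        L = source_codes.size
        for lo in range(0, n, chunk_units):
            m = min(chunk_units, n - lo)
            starts = rng.integers(0, L - flen + 1, size=m)
            frag = source_codes[starts[:, None] + np.arange(flen)]
            flip = rng.random(m) < 0.5
            if flip.any():
                frag[flip] = 3 - frag[flip][:, ::-1]
            mats = _emit_unit_reads(frag, rl, spec.paired, spec.error_rate, rng)
            strings = [_matrix_to_strings(mat) for mat in mats]
            for u in range(m):
                name = f"{accession_id}_{counter:08d}"
                counter += 1
                if spec.paired:
                    out.append(SimRead(name, strings[0][u], origin, 1, contaminant))
                    out.append(SimRead(name, strings[1][u], origin, 2, contaminant))
                else:
                    out.append(SimRead(name, strings[0][u], origin, 0, contaminant))

    for label, n in zip(labels, per_label):
        emit(_encode.encode(genomes[label]), int(n), label, False)

    if n_cont_units:
        pool_names = sorted(pools)
        pool_weights = np.array([pools[name][1] for name in pool_names], dtype=float)
        per_pool = rng.multinomial(n_cont_units, pool_weights / pool_weights.sum())
        for name, n in zip(pool_names, per_pool):
            emit(pools[name][0], int(n), name, True)

    if truth is not None:
        truth.total_reads[accession_id] = len(out)
    return out


def _contaminant_pools(spec: SimSpec, flen: int) -> dict[str, tuple[np.ndarray, int]]:
    pools = {}
    for fam in spec.families:
        if fam.is_contaminant:
            reps = max(1, math.ceil(flen / fam.unit_length) + 1)
            pools[fam.name] = (_encode.encode(fam.consensus * reps), fam.copy_number)
    return pools


def simulate_accessions(
    spec: SimSpec, k_ref: int = 50
) -> tuple[dict[str, str], dict[str, list[SimRead]], GroundTruth]:
    """Build genomes then reads for every accession in the spec."""
    genomes, truth = build_genomes(spec, k_ref=k_ref)
    reads = {
        acc_id: simulate_reads(genomes, dosage, spec, accession_id=acc_id, truth=truth)
        for acc_id, dosage in spec.accessions
    }
    return genomes, reads, truth


def simulate_histogram(
    standard_peak_position: float,
    sample_ploidy_multiple: float,
    cv: float,
    n_events: int,
    debris_fraction: float = 0.05,
    seed: int = 0,
    n_bins: int = 512,
    g2_fraction: float = 0.10,
) -> FlowHistogram:
    """Synthetic PI-fluorescence histogram for a sample of given ploidy.

    The G0/G1 peak is Gaussian with mean ``standard_peak_position x
    multiple / 2`` and sd ``cv x mean``; a G2 peak sits at twice that mean
    with ``g2_fraction`` of events, and debris forms an exponentially
    decaying low-fluorescence tail.
    """
    if not 0 < cv <= 0.2:
        raise ValueError("cv must be in (0, 0.2]")
    if n_events < 1000:
        raise ValueError("n_events must be >= 1000")
    if not 0 <= debris_fraction < 0.5:
        raise ValueError("debris_fraction must be in [0, 0.5)")
    if not 0 <= g2_fraction <= 0.15:
        raise ValueError("g2_fraction must be in [0, 0.15]")
    rng = _stream(seed, 17, f"flow:{sample_ploidy_multiple}")
    mean = standard_peak_position * sample_ploidy_multiple / 2
    n_debris = round(debris_fraction * n_events)
    n_g2 = round(g2_fraction * (n_events - n_debris))
    n_main = n_events - n_debris - n_g2
    main = rng.normal(mean, cv * mean, size=n_main)
    g2 = rng.normal(2 * mean, cv * 2 * mean, size=n_g2)
    debris = rng.exponential(mean / 3, size=n_debris)
    values = np.abs(np.concatenate([main, g2, debris]))
    upper = 2 * mean * (1 + 6 * cv)
    return FlowHistogram.from_events(values, n_bins=n_bins, upper=upper)
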