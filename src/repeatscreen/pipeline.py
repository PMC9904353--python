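"""End-to-end orchestration: subsample -> count -> filter -> screen -> report.

The per-accession ``max_bases`` cap (default 2e7) is this pipeline's
desk-scale analogue of analysing a fixed-size subset of each accession's
raw sequencing run, so that accessions of different depth are compared on
equal footing.  The cap is applied by uniform reservoir subsampling (mates
kept together) before any counting or matching.

Every output file carries the tool version, a hash of the configuration and
the master seed, and the run log records per-stage bookkeeping (reads
consumed, motifs surviving each filter) so a run can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .filters import FilterConfig, apply_filters, kept_motifs, load_fasta_library, verdicts_to_tsv
from .io import write_tsv
from .kmers import DEFAULT_K, KmerProfile, Motif, canonicalize, count_kmers, top_motifs
from .screen import (
    AbundanceMatrix,
    CandidateSet,
    ProbeReport,
    RecoveryReport,
    ScreenConfig,
    build_matrix,
    evaluate_recovery,
    score_probe,
    strategy_differential,
    strategy_shared,
)

logger = logging.getLogger("repeatscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def subsample_reads(read_source, max_bases: int, seed: int) -> list:
    """Uniform reservoir sample of whole reads totalling <= max_bases.

    Mate pairs (consecutive reads flagged mate 1/2 with a shared name) are
    kept or dropped together.  Input no larger than the cap passes through
    unchanged; otherwise the sample is returned in original read order.
    Deterministic under ``seed``.
    """
    if max_bases <= 0:
        raise ValueError("max_bases must be positive")
    units: list[list] = []
    pending = None
    for read in read_source:
        mate = getattr(read, "mate", 0)
        if pending is not None:
            if mate == 2 and getattr(read, "name", None) == getattr(pending, "name", None):
                units.append([pending, read])
                pending = None
                continue
            units.append([pending])
            pending = None
        if mate == 1:
            pending = read
        else:
            units.append([read])
    if pending is not None:
        units.append([pending])
    if not units:
        return []

    def unit_bases(unit) -> int:
        return sum(len(r) if isinstance(r, str) else len(r.sequence) for r in unit)

    m = max(1, max_bases // unit_bases(units[0]))
    if len(units) <= m:
        return [r for unit in units for r in unit]
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 29])
    reservoir: list[tuple[int, list]] = [(i, u) for i, u in enumerate(units[:m])]
    for i in range(m, len(units)):
        j = int(rng.integers(0, i + 1))
        if j < m:
            reservoir[j] = (i, units[i])
    reservoir.sort(key=lambda t: t[0])
    return [r for _, unit in reservoir for r in unit]


@dataclass
class AccessionInput:
    """One accession: reads from files or in memory, and its screen role."""

    id: str
    role: str  # target | background
    files: tuple[str, ...] = ()
    reads: Sequence | None = None

    def __post_init__(self):
        if self.role not in ("target", "background"):
            raise ValueError(f"accession {self.id}: role must be target or background")

    def load(self) -> list:
        if self.reads is not None:
            return list(self.reads)
        out = []
        from .io import iter_sequences

        for path in self.files:
            out.extend(iter_sequences(path))
        return out


@dataclass
class PipelineConfig:
    accessions: tuple[AccessionInput, ...]
    strategy: str = "differential"  # differential | shared
    k: int = DEFAULT_K
    max_bases: int = 20_000_000
    top_n: int = 2500
    max_mismatches: int = 2
    min_overlap: int | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    target_min: float = 0.0005
    background_max: float = 0.0001
    ratio_min: float = 100.0
    output_dir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [a.id for a in self.accessions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate accession ids")
        if self.strategy not in ("differential", "shared"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        targets = [a.id for a in self.accessions if a.role == "target"]
        background = [a.id for a in self.accessions if a.role == "background"]
        if not targets or not background:
            raise ValueError("need at least one target and one background accession")
        if self.strategy == "shared" and len(targets) < 2:
            raise ValueError("shared strategy needs at least two target accessions")
        for acc in self.accessions:
            if acc.reads is None:
                if not acc.files:
                    raise ValueError(f"accession {acc.id}: no reads and no files")
                for path in acc.files:
                    if not Path(path).exists():
                        raise ValueError(f"accession {acc.id}: missing file {path}")
        # ScreenConfig construction re-checks disjointness of the role sets
        self.screen_config()

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            targets=tuple(a.id for a in self.accessions if a.role == "target"),
            background=tuple(a.id for a in self.accessions if a.role == "background"),
            target_min=self.target_min,
            background_max=self.background_max,
            ratio_min=self.ratio_min,
        )

    def to_dict(self) -> dict:
        return {
            "accessions": [
                {"id": a.id, "role": a.role, "files": list(a.files)}
                for a in self.accessions
            ],
            "strategy": self.strategy,
            "k": self.k,
            "max_bases": self.max_bases,
            "top_n": self.top_n,
            "max_mismatches": self.max_mismatches,
            "min_overlap": self.min_overlap,
            "filters": self.filters.to_dict(),
            "target_min": self.target_min,
            "background_max": self.background_max,
            "ratio_min": self.ratio_min,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        accessions = tuple(
            AccessionInput(
                id=entry["id"], role=entry["role"], files=tuple(entry.get("files", ()))
            )
            for entry in data.get("accessions", ())
        )
        filt = data.get("filters", {})
        libraries = {
            name: load_fasta_library(p) for name, p in filt.pop("libraries", {}).items()
        }
        filters = FilterConfig(contaminant_libraries=libraries, **filt)
        screen = data.get("screen", {})
        return cls(
            accessions=accessions,
            strategy=data.get("strategy", "differential"),
            k=data.get("k", DEFAULT_K),
            max_bases=data.get("max_bases", 20_000_000),
            top_n=data.get("top_n", 2500),
            max_mismatches=data.get("max_mismatches", 2),
            min_overlap=data.get("min_overlap"),
            filters=filters,
            target_min=screen.get("target_min", 0.0005),
            background_max=screen.get("background_max", 0.0001),
            ratio_min=screen.get("ratio_min", 100.0),
            output_dir=data.get("output_dir"),
            seed=data.get("seed", 0),
            log_level=data.get("log_level", "INFO"),
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    reads: dict[str, list]
    profile_summaries: dict[str, dict]
    verdicts: dict[str, list]
    matrix: AbundanceMatrix | None
    candidates: CandidateSet
    probes: list[ProbeReport]
    recovery: RecoveryReport | None
    output_dir: Path | None


def _header_lines(config: PipelineConfig) -> list[str]:
    return [
        f"repeatscreen {__version__}",
        f"config_hash={config.config_hash()} seed={config.seed}",
    ]


def run_pipeline(
    config: PipelineConfig,
    truth: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Execute the full screen and write the report bundle.

    Stages: subsample -> count -> top_motifs -> apply_filters -> screen
    (differential matrix or shared assembly) -> probe scoring -> optional
    recovery evaluation against a {family: consensus} truth mapping.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    logger.setLevel(config.log_level)
    outdir = Path(config.output_dir) if config.output_dir else None
    file_handler = None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        file_handler = logging.FileHandler(outdir / "run.log", mode="w")
        file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(file_handler)
    stage = "validate"
    try:
        config.validate()
        screen_config = config.screen_config()
        logger.info(
            "run start: strategy=%s seed=%d config=%s",
            config.strategy,
            config.seed,
            config.config_hash(),
        )

        stage = "subsample"
        reads: dict[str, list] = {}
        for acc in config.accessions:
            t0 = time.time()
            raw = acc.load()
            sub_seed = (config.seed * 1_000_003 + zlib.crc32(acc.id.encode())) & 0x7FFFFFFF
            reads[acc.id] = subsample_reads(raw, config.max_bases, sub_seed)
            logger.info(
                "subsample %s: %d of %d reads kept (%.1fs)",
                acc.id,
                len(reads[acc.id]),
                len(raw),
                time.time() - t0,
            )
            del raw

        stage = "count"
        target_ids = list(screen_config.targets)
        motif_sets: dict[str, list[Motif]] = {}
        profile_summaries: dict[str, dict] = {}
        for acc_id in target_ids:
            t0 = time.time()
            profile = count_kmers(reads[acc_id], k=config.k, accession_id=acc_id)
            motifs = top_motifs(profile, top_n=config.top_n)
            profile_summaries[acc_id] = {
                "total_reads": profile.total_reads,
                "total_bases": profile.total_bases,
                "distinct_kmers": len(profile.counts),
                "window_count": profile.counts.total()
                if hasattr(profile.counts, "total")
                else sum(profile.counts.values()),
            }
            motif_sets[acc_id] = motifs
            logger.info(
                "count %s: %d reads, %d distinct %d-mers, top %d extracted (%.1fs)",
                acc_id,
                profile.total_reads,
                profile_summaries[acc_id]["distinct_kmers"],
                config.k,
                len(motifs),
                time.time() - t0,
            )
            del profile

        stage = "filter"
        verdicts: dict[str, list] = {}
        kept_sets: dict[str, list[Motif]] = {}
        for acc_id in target_ids:
            v = apply_filters(motif_sets[acc_id], config.filters)
            verdicts[acc_id] = v
            kept_sets[acc_id] = kept_motifs(v)
            tally: dict[str, int] = {}
            for item in v:
                tally[item.reason] = tally.get(item.reason, 0) + 1
            logger.info("filter %s: %s", acc_id, tally)

        stage = "screen"
        matrix = None
        if config.strategy == "differential":
            seen: set[str] = set()
            motifs: list[str] = []
            for acc_id in target_ids:
                for m in kept_sets[acc_id]:
                    c = canonicalize(m.sequence)
                    if c not in seen:
                        seen.add(c)
                        motifs.append(c)
            if not motifs:
                raise ValueError("no motifs survived filtering")
            matrix = build_matrix(motifs, reads, max_mismatches=config.max_mismatches)
            candidates = strategy_differential(matrix, screen_config)
        else:
            candidates = strategy_shared(
                kept_sets,
                reads,
                screen_config,
                min_overlap=config.min_overlap,
                max_mismatches=config.max_mismatches,
            )
        logger.info("screen: %d candidates", len(candidates.candidates))

        stage = "probe"
        probes = [score_probe(c.sequence) for c in candidates.candidates]

        stage = "evaluate"
        recovery = None
        if truth is not None:
            recovery = evaluate_recovery(candidates, truth)
            logger.info(
                "recovery: precision=%.3f recall=%.3f f1=%.3f",
                recovery.precision,
                recovery.recall,
                recovery.f1,
            )

        stage = "write"
        if outdir:
            header = _header_lines(config)
            for acc_id, v in verdicts.items():
                verdicts_to_tsv(outdir / f"verdicts_{acc_id}.tsv", v, header_lines=header)
            if matrix is not None:
                matrix.to_tsv(outdir / "matrix.tsv", header_lines=header)
            candidates.to_fasta(outdir / "candidates.fasta")
            candidates.to_json(
                outdir / "candidates.json",
                header={"tool": f"repeatscreen {__version__}",
                        "config_hash": config.config_hash(),
                        "seed": config.seed},
            )
            write_tsv(
                outdir / "probes.tsv",
                (
                    (c.label, p.sequence[:60], p.suitable, ";".join(p.reasons) or "-",
                     f"{p.gc:.3f}", p.max_homopolymer)
                    for c, p in zip(candidates.candidates, probes)
                ),
                columns=("label", "sequence", "suitable", "reasons", "gc", "max_homopolymer"),
                header_lines=header,
            )
        return PipelineResult(
            config=config,
            reads=reads,
            profile_summaries=profile_summaries,
            verdicts=verdicts,
            matrix=matrix,
            candidates=candidates,
            probes=probes,
            recovery=recovery,
            output_dir=outdir,
        )
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    finally:
        if file_handler:
            logger.removeHandler(file_handler)
            file_handler.close()
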