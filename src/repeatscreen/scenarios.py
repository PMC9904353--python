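"""Ready-made synthetic study designs exercising the screen end to end.

Two scenarios mirror the situations the comparative screen is built for:

* ``differential_scenario`` — two diploid accessions (RR, DD) and one
  allotetraploid (RRZZ) whose Z subgenome, contributed by an unsampled
  parent, carries a private satellite at 1 % of Z (0.5 % of the tetraploid's
  reads).  The differential strategy should pull out exactly that family.

* ``shared_scenario`` — four polyploid accessions sharing a B subgenome
  absent from the two sequenced diploids; the shared strategy should
  assemble the B-specific satellite into the top-ranked contig.

Both plant, on top of a uniform-random background: two ancestral satellites
shared by all subgenomes (0.2 % and 0.08 %), a telomeric (TTTAGGG)n array
sized to ~0.1 % of reads, a GC-extreme family, and rDNA-like/plastid-like
contaminant pools injected as 1 % of reads.  Subgenomes default to 2 Mb at
10x coverage with 150-b paired reads and a 0.1 % per-base error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _encode
from .filters import FilterConfig
from .pipeline import AccessionInput, PipelineConfig, PipelineResult, run_pipeline
from .simulate import GroundTruth, RepeatFamily, SimSpec, simulate_accessions

# Standard Illumina TruSeq adapter read-through sequences (public).
ILLUMINA_ADAPTERS = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA",
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT",
)


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _encode.decode(rng.choice(4, size=n, p=p).astype(np.uint8))


@dataclass
class Scenario:
    """A simulation spec bundled with its screen configuration and truth."""

    spec: SimSpec
    filters: FilterConfig
    roles: dict[str, str]  # accession id -> target | background
    strategy: str
    truth_families: dict[str, str]  # family name -> consensus (screen targets)


def _base_families(
    rng: np.random.Generator,
    scope: tuple[str, ...],
    subgenome_length: int,
) -> tuple[list[RepeatFamily], dict[str, str]]:
    """Families planted in every scenario, scaled to the subgenome length."""

    def copies(fraction: float, unit: int) -> int:
        return max(2, round(fraction * subgenome_length / unit))

    sat1 = _random_dna(rng, 300)
    sat2 = _random_dna(rng, 200)
    gc_rich = _random_dna(rng, 150, gc=0.9)
    rdna = _random_dna(rng, 3000, gc=0.55)
    plastid = _random_dna(rng, 5000, gc=0.38)
    telomere_units = copies(0.001, 56) * 8  # consensus of 8 units, ~0.1 % of bases
    families = [
        RepeatFamily("shared_sat1", sat1, copies(0.002, 300), 0.01, "tandem", scope, "shared"),
        RepeatFamily("shared_sat2", sat2, copies(0.0008, 200), 0.01, "dispersed", scope, "shared"),
        RepeatFamily(
            "telomere", "TTTAGGG" * 8, max(2, telomere_units // 8), 0.0, "tandem", scope,
            "telomeric",
        ),
        RepeatFamily("gc_rich", gc_rich, copies(0.0008, 150), 0.0, "dispersed", scope,
                     "gc_extreme"),
        RepeatFamily("rdna_unit", rdna, 2, 0.0, "dispersed", (), "rdna_like"),
        RepeatFamily("plastid_frag", plastid, 3, 0.0, "dispersed", (), "plastid_like"),
    ]
    references = {"rdna": rdna, "plastid": plastid}
    return families, references


def _filter_config(references: Mapping[str, str]) -> FilterConfig:
    return FilterConfig(
        contaminant_libraries={
            "rdna": [references["rdna"]],
            "plastid": [references["plastid"]],
            "adapter": list(ILLUMINA_ADAPTERS),
        }
    )


def differential_scenario(seed: int, subgenome_length: int = 2_000_000) -> Scenario:
    """Diploids RR and DD vs allotetraploid RRZZ with a Z-private satellite."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 7])
    scope = ("R", "D", "Z")
    families, references = _base_families(rng, scope, subgenome_length)
    z_specific = _random_dna(rng, 400)
    families.append(
        RepeatFamily(
            "z_specific", z_specific,
            max(2, round(0.01 * subgenome_length / 400)),
            0.01, "tandem", ("Z",), "genome_specific",
        )
    )
    spec = SimSpec(
        subgenomes=(("R", subgenome_length), ("D", subgenome_length), ("Z", subgenome_length)),
        accessions=(
            ("UR", ("R", "R")),
            ("UD", ("D", "D")),
            ("UX", ("R", "R", "Z", "Z")),
        ),
        families=tuple(families),
        contaminant_read_fraction=0.01,
        seed=seed,
    )
    return Scenario(
        spec=spec,
        filters=_filter_config(references),
        roles={"UR": "background", "UD": "background", "UX": "target"},
        strategy="differential",
        # tandem satellites are circular: doubling the monomer lets
        # unit-junction k-mers align when matching against the truth
        truth_families={"z_specific": z_specific * 2},
    )


def shared_scenario(seed: int, subgenome_length: int = 2_000_000) -> Scenario:
    """Four B-carrying tetraploids vs two diploids lacking the B subgenome."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 8])
    scope = ("R", "D", "B")
    families, references = _base_families(rng, scope, subgenome_length)
    b_specific = _random_dna(rng, 400)
    families.append(
        RepeatFamily(
            "b_specific", b_specific,
            max(2, round(0.01 * subgenome_length / 400)),
            0.01, "tandem", ("B",), "genome_specific",
        )
    )
    targets = ("UB1", "UB2", "UB3", "UB4")
    spec = SimSpec(
        subgenomes=(("R", subgenome_length), ("D", subgenome_length), ("B", subgenome_length)),
        accessions=tuple(
            [(t, ("R", "R", "B", "B")) for t in targets]
            + [("UR", ("R", "R")), ("UD", ("D", "D"))]
        ),
        families=tuple(families),
        contaminant_read_fraction=0.01,
        seed=seed,
    )
    roles = {t: "target" for t in targets}
    roles.update({"UR": "background", "UD": "background"})
    return Scenario(
        spec=spec,
        filters=_filter_config(references),
        roles=roles,
        strategy="shared",
        truth_families={"b_specific": b_specific * 2},
    )


def run_scenario(
    scenario: Scenario,
    output_dir=None,
    **config_overrides,
) -> tuple[PipelineResult, GroundTruth]:
    """Simulate the scenario's accessions and run the screen on them."""
    genomes, reads, truth = simulate_accessions(scenario.spec)
    del genomes
    accessions = tuple(
        AccessionInput(id=acc_id, role=scenario.roles[acc_id], reads=acc_reads)
        for acc_id, acc_reads in reads.items()
    )
    config = PipelineConfig(
        accessions=accessions,
        strategy=scenario.strategy,
        filters=scenario.filters,
        output_dir=output_dir,
        seed=scenario.spec.seed,
        **config_overrides,
    )
    result = run_pipeline(config, truth=scenario.truth_families)
    return result, truth
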