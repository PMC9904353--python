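"""Simulate a small allopolyploid study with planted repeat families.

Builds two diploids (RR, DD) and an allotetraploid (RRZZ) whose Z subgenome
carries a private satellite, then prints what was planted and what fraction
of each accession's reads the simulator expects that family to occupy.
"""

from repeatscreen.scenarios import differential_scenario
from repeatscreen.simulate import simulate_accessions

scenario = differential_scenario(seed=1, subgenome_length=200_000)
genomes, reads, truth = simulate_accessions(scenario.spec)

print(f"subgenomes: {', '.join(f'{k} ({len(v):,} bp)' for k, v in genomes.items())}")
for acc_id, acc_reads in reads.items():
    print(f"accession {acc_id}: {len(acc_reads):,} reads "
          f"(dosage {''.join(scenario.spec.dosage(acc_id))})")

print("\nexpected read fraction of each planted family (per accession):")
for acc_id, fams in truth.per_accession.items():
    row = ", ".join(f"{name}={t.expected_read_fraction:.4%}" for name, t in sorted(fams.items()))
    print(f"  {acc_id}: {row}")

print("\nThe z_specific family should appear only in RRZZ (accession UX): its")
print("read fraction there is the 'genome proportion' the screen estimates.")
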