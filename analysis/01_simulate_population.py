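#!/usr/bin/env python
"""Simulate the phage/host universe used by the downstream analyses.

Generates a population of 2,000 phages (30% infecting spore-forming hosts)
carrying 20 planted spore-host-enriched genes (carriage 0.2 vs 0.02) and
200 null genes (carriage 0.05), and writes the four input tables under
results/population/.
"""

from pathlib import Path

from sporeamg.synthetic_data import GeneSpec, PopulationSpec, generate_population

OUT = Path("results/population")
SEED = 20230

enriched = tuple(GeneSpec(f"KE{i:04d}", 0.2, 0.02) for i in range(20))
nulls = tuple(GeneSpec(f"KN{i:04d}", 0.05, 0.05, is_sporulation=False) for i in range(200))
spec = PopulationSpec(
    n_phages=2000, frac_spore_host=0.3, gene_specs=enriched + nulls, seed=SEED
)

tables = generate_population(spec)
tables.write(OUT)

spore_ids = set(tables.hosts.host_id[tables.hosts.is_spore_former])
n_spore = int(tables.phages.host_id.isin(spore_ids).sum())
print(f"wrote {OUT}/: {len(tables.phages)} phages ({n_spore} with spore-forming hosts),")
print(f"  {len(tables.annotations)} gene detections across {len(tables.truth)} genes")
print(f"  planted enriched genes: {int((tables.truth.label == 'enriched').sum())}")
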