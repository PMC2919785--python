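"""Detect autozygous segments with the two-state HMM and run SNP QC.

Plants known autozygous tracts (with 0.5% genotyping error) into an
outbred panel, recovers them with the forward-backward scan, summarizes
runs of homozygosity, and applies the heterozygosity-in-autozygosity
filter that flags badly clustering SNPs.
"""

import numpy as np

from breedmap.autozygosity import (
    autozygosity_scan,
    filter_snps_by_het_in_auto,
    roh_summary,
)
from breedmap.simulate import (
    PlantedSegment,
    SimConfig,
    plant_autozygosity,
    sample_genotypes_hwe,
    simulate_breed_frequencies,
)

cfg = SimConfig(n_breeds=1, dogs_per_breed=20, n_markers=3000, breed_F=0.0, seed=5)
truth = simulate_breed_frequencies(cfg)
g = sample_genotypes_hwe(cfg, truth)

planted = [
    PlantedSegment(str(ind), "chr1", 10_000_000, 14_000_000)
    for ind in g.individual_ids[:8]
]
g = plant_autozygosity(g, planted, error_rate=0.005, seed=6)

# corrupt one marker inside the tracts, as a segmental duplication would:
# heterozygous calls where the genome is identical by descent
tract_markers = np.flatnonzero(
    (g.map.chromosome == "chr1")
    & (g.map.position_bp >= 10_000_000)
    & (g.map.position_bp <= 14_000_000)
)
bad = tract_markers[len(tract_markers) // 2]  # mid-tract, solidly covered
g.genotypes[:4, bad] = 1

scan = autozygosity_scan(g)
summary = roh_summary(scan.segments, marker_map=g.map)
carriers = summary[summary["n_gt_1000000bp"] > 0]
print(f"called {len(scan.segments)} autozygous segments in {g.n_individuals} dogs")
print(f"{len(carriers)} dogs carry a ROH > 1 Mb (8 were planted with one)")
print(f"mean genome fraction autozygous among carriers: "
      f"{carriers['genome_fraction'].mean():.3f}")

qc = filter_snps_by_het_in_auto(g, scan.segments, max_het_rate=0.10)
print(f"SNP QC: {len(qc.excluded_ids)} markers excluded for >10% heterozygosity")
print("  inside autozygous tracts (a genotyping-artifact signature);")
print(f"  {int((qc.table['status'] == 'untested').sum())} markers untested (no coverage)")
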