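"""Simulate an F2 intercross litter and look at what the simulator emits.

An F2 embryo is the offspring of two F1 hybrids of two inbred strains
("B" = reference, "9" = alternate).  Each chromosome is a recombinant
mosaic of the two strains; at catalog sites (positions where the strains
carry fixed different alleles) the diplotype determines the expected
variant allele fraction (0, 0.5, or 1 in a euploid genome).
"""

import numpy as np

from hybridscar import (
    GenomeModel, SimConfig, StrainCatalog, sample_reads, simulate_litter,
    substream,
)
from hybridscar.cross import litter_table

genome = GenomeModel.example()            # 3 chromosomes x 100 Mb, 1 Morgan each
cfg = SimConfig(mean_depth=80.0, base_error_rate=0.001, seed=5)
catalog = StrainCatalog.random(genome, 5000, substream(5, "catalog"))

embryos = simulate_litter(genome, cfg, n_embryos=8)
print(litter_table(embryos).to_string(index=False))
n_dko = sum(e.is_dko for e in embryos)
print(f"\n{n_dko}/8 embryos are double knockouts "
      f"(expected fraction 1/16 before lethality)")

alive = [e for e in embryos if e.alive_at["E12.5"]]
ad = sample_reads(alive, catalog, cfg)
vaf = ad.vaf()
print(f"\nread matrix: {ad.n_sites} catalog sites x {len(ad.samples)} embryos")
print(f"first embryo mean VAF {np.nanmean(vaf[:, 0]):.3f} "
      "(mixture of hom-ref ~0, het ~0.5, hom-alt ~1 sites)")
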