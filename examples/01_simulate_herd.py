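"""Simulate a synthetic herd and inspect its structure.

Builds the default desk-scale herd (~400 animals over 3 generations,
2,500 SNPs on five 40-Mb chromosomes, one trait with h2 = 0.30) and prints
the quantities a breeder would check first: pedigree depth, marker panel,
realized heritability, and the phenotype table.
"""

import gsel

cfg = gsel.default_config(seed=1)
herd = gsel.simulate_herd(cfg)

ped = herd.pedigree
print(f"animals: {ped.n} ({int(ped.is_founder.sum())} founders, "
      f"{cfg.n_generations} generations)")
print(f"SNPs: {herd.genotypes.n_snps} on {cfg.n_chromosomes} chromosomes")
print(f"QTL: {len(herd.qtl_indices)} (drawn from the marker panel)")
print(f"target h2: {cfg.target_h2}, realized h2: {herd.realized_h2[0]:.3f}")
print("\nphenotypes (y = mu + contemporary group + dam age + BV + e):")
print(herd.phenotypes.head())

# the herd can be persisted in standard text formats
# (PLINK .ped/.map needs integer dosages, i.e. no mean imputation yet)
from gsel.io import write_dosage_csv, write_pedigree_csv  # noqa: E402

write_dosage_csv(herd.genotypes, "/tmp/herd_dosage.csv")
write_pedigree_csv(herd.pedigree, "/tmp/herd_pedigree.csv")
print("\nwrote /tmp/herd_dosage.csv (+ .snps.csv map) and /tmp/herd_pedigree.csv")
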