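"""Draw a synthetic clonal breeding trial and summarize its design.

The generator mirrors a structured conifer progeny test: 13 parents mated
into 9 full-sib families (some sharing a parent), 165 cloned progeny, each
clone planted as 16-50 ramets across 16 sites, genotyped at unlinked
biallelic SNPs descending from the founders by Mendelian gene dropping.
"""

from clonalgp import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_markers=1000)
data = simulate_dataset(cfg, seed=1)

ped = data.pedigree
fams = ped.families()
print(f"pedigree records : {len(ped)} ({len(ped.founders())} founders, "
      f"{len(ped.offspring())} cloned progeny)")
print(f"full-sib families: {len(fams)}, sizes "
      f"{sorted(len(v) for v in fams.values())}")
print(f"phenotype records: {len(data.phenotypes)} trees on "
      f"{data.phenotypes['site_id'].nunique()} sites")
print(f"markers          : {data.genotypes.n_markers}, "
      f"missing calls {100 * data.genotypes.mask.mean():.2f}%")
print(f"true h2 (tree)   : {cfg.h2:.2f}  "
      f"(sigma2_a={cfg.sigma2_a}, sigma2_e={cfg.sigma2_e})")
tbv = data.truth.breeding_values
print(f"true breeding values: var {tbv.var():.3f} across clones "
      f"(target sigma2_a = {cfg.sigma2_a}; family structure shrinks it slightly)")
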