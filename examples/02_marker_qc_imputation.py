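"""Marker QC on a raw array draw, then compare imputation methods.

Raw-marker mode plants monomorphic and high-missing loci among the
informative ones; the filter removes monomorphic loci first, then loci with
more than 15% missing calls.  The four imputation methods are then judged
by the mean accuracy of the GEBVs they lead to - the practical question a
breeder cares about.
"""

from clonalgp import (
    SimulationConfig,
    build_numerator_relationship,
    filter_markers,
    imputation_accuracy_comparison,
    missing_fraction,
    recode_to_minor,
    simulate_dataset,
)

cfg = SimulationConfig(
    n_markers=800, n_monomorphic=150, n_high_missing=50, missing_rate=0.012
)
data = simulate_dataset(cfg, seed=2)

geno, _ = recode_to_minor(data.genotypes)
filtered, report = filter_markers(geno, max_missing=0.15)
print(f"raw markers        : {report.n_raw}")
print(f"monomorphic removed: {report.n_monomorphic}")
print(f"high-missing (>15%): {report.n_high_missing}")
print(f"informative        : {report.n_informative}")
print(f"missing calls left : {100 * missing_fraction(filtered):.2f}% "
      "(to be imputed)")

A = build_numerator_relationship(data.pedigree).submatrix(filtered.clone_ids)
table = imputation_accuracy_comparison(filtered, data.phenotypes, A, seed=2)
print("\nGEBV accuracy by imputation method (reliability-based, mean over clones):")
print(table[["method", "mean_accuracy", "mean_se"]].round(4).to_string(index=False))
print("\nAt ~1% missingness the choice of imputation method barely moves "
      "the accuracy of genomic predictions.")
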