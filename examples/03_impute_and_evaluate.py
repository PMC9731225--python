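"""Mask a cohort to an array, impute it and score the result.

Held-out samples are reduced to their array-typed genotypes, imputed with
the Li-Stephens haplotype-copying model against their own population's
reference panel, and compared with the withheld truth per allele-frequency
bin: aggregated R^2 (dosage-vs-truth correlation) and % well-imputed
(model-internal estimated r^2 >= 0.8).
"""

from imputebench import (
    LSParams,
    QCThresholds,
    apply_qc_cascade,
    design_array,
    evaluate,
    impute,
    mask_to_array,
    split_reference_target,
)
from imputebench.scenarios import standard_sim_config, simulate_populations

panels = simulate_populations(standard_sim_config(seed=1))
panel = panels["POPA"]

reference, truth = split_reference_target(panel, n_target=50, seed=1)
reference, _ = apply_qc_cascade(reference, thresholds=QCThresholds(min_external_datasets=0))
array = design_array(reference, target_density=60, design_pop="POPA")

geno, mask_log = mask_to_array(truth, array)
print(f"array: {len(array)} sites; genotype panel keeps {geno.n_sites} "
      f"({mask_log.below_maf_floor} below the 1% MAF floor)")

typed = truth.subset_sites(truth.site_keys().get_indexer(geno.site_keys()))
dosages, _ = impute(typed, reference, LSParams(), panel_id="POPA")

report = evaluate(dosages, truth)
cols = ["bin", "n_sites", "mean_r2", "sd_r2", "n_imputed", "pct_well_imputed"]
print(report.table[cols].round(3).to_string(index=False))
print(f"overall mean aggregated R^2: {report.overall_mean_r2:.3f}")
# mean_r2 is accuracy against withheld truth; pct_well_imputed is what a
# real study would see without truth -- the model's own confidence.
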