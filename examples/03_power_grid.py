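"""Operating characteristics on a small simulation grid.

Runs a reduced polygenic scenario (10% causal variants, two disease
heritability levels, rG in {0, 0.5, 1}), ranks regions by the r0 = 0
p-value, and reports AUC for two definitions of a true colocalization
(|rG| >= 0.5, |rG| >= 0.8) plus the null calibration at the boundary.
"""

from hdlc import (
    SimScenario,
    auc_by_threshold,
    null_calibration,
    run_scenario,
    scores_from_pvalues,
)

scenario = SimScenario(
    M=200, ld_rho=0.9, architecture=0.10, h1_sq_grid="top-snp",
    h2_sq_grid=(0.01, 0.1), rg_grid=(0.0, 0.5, 1.0),
    N1=30_000, N2=300_000, n_replicates=40, mode="direct", seed=2024,
)
records = run_scenario(scenario, r0_list=(0.0, 0.5))
records["score"] = scores_from_pvalues(records["pvalue"], records["lambda"])

auc = auc_by_threshold(records, [0.5, 0.8], group_cols=["r0", "true_h2_sq"])
print(auc.to_string(index=False))
# Each row: discrimination of truly-colocalized regions (|rG| >= threshold)
# from the rest when ranking by the test's p-value at that r0.

# Null calibration is a statement about the model itself, so check it on
# an infinitesimal (all-causal) scenario where the ensemble rG is also the
# realized per-replicate correlation; with 10% causal variants the realized
# effect correlation scatters around its ensemble value, which is genuine
# signal, not miscalibration.
null_scn = SimScenario(
    M=200, ld_rho=0.9, architecture=1.0, h1_sq_grid=(0.05,),
    h2_sq_grid=(0.05,), rg_grid=(0.5,), N1=100_000, N2=100_000,
    n_replicates=200, mode="direct", seed=2025,
)
boundary = run_scenario(null_scn, r0_list=(0.5,))
cal = null_calibration(boundary)
print(
    f"\nboundary null (true rG = r0 = 0.5, infinitesimal): "
    f"zero-Lambda mass = {cal['zero_mass_fraction']:.2f} (theory: 0.50), "
    f"rejection at 5% = {cal['rejection_rates'][0.05]:.3f}"
)
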