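"""Generate a synthetic brain cohort and estimate its cell-type proportions.

Builds purified reference profiles for neurons, astrocytes,
oligodendrocytes, and microglia, simulates a case/control bulk cohort with
planted proportion shifts (neuronal loss, astrocytosis), deconvolves the
bulk samples with marker-constrained semi-supervised NMF, and compares the
estimates to the known truth.
"""

from cortexmix import (
    SyntheticCohortSpec,
    SyntheticConfig,
    marker_panel_from_config,
    reference_panel_from_profiles,
    rmse,
    simulate_bulk_cohort,
    simulate_reference_profiles,
    ssnmf_deconvolve,
)

config = SyntheticConfig(seed=42)  # 4 cell types, 50 markers each, noise sigma 0.2
profiles, labels = simulate_reference_profiles(config)
panel = reference_panel_from_profiles(profiles, labels)
markers = marker_panel_from_config(config)

spec = SyntheticCohortSpec(n_cases=30, n_controls=30, seed=42)
bulk, truth, metadata = simulate_bulk_cohort(profiles, labels, spec)

result = ssnmf_deconvolve(bulk, panel, markers)
print(f"deconvolved {len(result.proportions)} samples "
      f"({result.iterations} iterations, converged={result.converged})")
print("first three estimates vs truth (rows sum to 1):")
print(result.proportions.head(3).round(3))
print(truth.head(3).round(3))
print(f"RMSE vs known proportions: {rmse(result.proportions, truth):.4f}")
print("Lower RMSE means the marker-anchored factorization recovers the "
      "planted cellular composition of each bulk sample more accurately.")
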