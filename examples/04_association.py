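"""Associate estimated cell proportions with disease status.

Simulates a case/control cohort with a planted neuronal decrease (-0.17)
and astrocytic increase (+0.23), deconvolves the bulk expression, fits one
linear model per cell type with technical covariates, and pools two
studies by fixed-effect meta-analysis.
"""

from cortexmix import (
    SyntheticCohortSpec,
    SyntheticConfig,
    fit_association,
    marker_panel_from_config,
    meta_analyze,
    reference_panel_from_profiles,
    simulate_bulk_cohort,
    simulate_reference_profiles,
    ssnmf_deconvolve,
)

config = SyntheticConfig(seed=42)
profiles, labels = simulate_reference_profiles(config)
panel = reference_panel_from_profiles(profiles, labels)
markers = marker_panel_from_config(config)

results = []
for study_seed in (1, 2):
    spec = SyntheticCohortSpec(n_cases=60, n_controls=60, seed=study_seed)
    bulk, truth, metadata = simulate_bulk_cohort(profiles, labels, spec)
    props = ssnmf_deconvolve(bulk, panel, markers).proportions
    res = fit_association(props, metadata, "neuron", "status", covariates=["RIN", "PMI"])
    print(f"study {study_seed}: neuron effect (case vs control) "
          f"beta={res.effect:+.3f}, SE={res.std_error:.3f}, p={res.p_value:.2e}, n={res.n}")
    results.append(res)

pooled = meta_analyze(results)
print(f"meta-analysis: beta={pooled.effect:+.3f}, SE={pooled.std_error:.3f}, "
      f"p={pooled.p_value:.2e}")
print("A negative beta is the planted neuronal-loss signal; pooling two "
      "studies shrinks the standard error by about 1/sqrt(2).")
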