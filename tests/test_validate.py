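"""Validation harness: RMSE scoring, chimeric design, read allocation,
donor hold-out benchmarking, gene dropout, and LOOCV accuracy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cortexmix.exceptions import ConfigurationError, DataError
from cortexmix.synthetic import (
    SyntheticConfig,
    marker_panel_from_config,
    reference_panel_from_profiles,
    simulate_read_pools,
    simulate_reference_profiles,
)
from cortexmix.validate import (
    PAPER_RANGES,
    allocate_reads,
    build_chimeric_design,
    gene_dropout_robustness,
    loocv_accuracy,
    pool_chimeric_library,
    rmse,
    run_chimeric_validation,
)


class TestRmse:
    def test_identical_matrices_score_zero(self, crossfree):
        assert rmse(crossfree["truth"], crossfree["truth"]) == 0.0

    def test_hand_evaluated_single_row(self):
        est = pd.DataFrame([[0.5, 0.5]], columns=["A", "B"])
        tru = pd.DataFrame([[0.3, 0.7]], columns=["A", "B"])
        assert rmse(est, tru) == pytest.approx(0.2, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((5, 4)), rng.random((5, 4))
        assert rmse(a, b) == pytest.approx(rmse(b, a))

    def test_label_mismatch_raises(self, crossfree):
        truth = crossfree["truth"].rename(columns={"neuron": "NEURON?"})
        with pytest.raises(DataError, match="mismatch"):
            rmse(crossfree["truth"], truth)


class TestAllocateReads:
    @given(
        st.lists(st.floats(0.001, 1.0), min_size=2, max_size=6),
        st.integers(1, 10**6),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_for_any_simplex_vector(self, raw, total):
        p = np.asarray(raw) / np.sum(raw)
        counts = allocate_reads(p, total)
        assert counts.sum() == total
        assert (counts >= 0).all()
        # largest-remainder never deviates from the real-valued share by >= 1
        assert np.abs(counts - p * total).max() < 1.0

    def test_exact_when_divisible(self):
        assert (allocate_reads(np.array([0.5, 0.25, 0.25]), 400_000) ==
                np.array([200_000, 100_000, 100_000])).all()


class TestChimericDesign:
    def test_components_respect_quoted_ranges(self):
        design = build_chimeric_design(n_distributions=32, repeats=5, seed=3)
        for k, ct in enumerate(design.cell_types):
            lo, hi = PAPER_RANGES[ct]
            col = design.distributions[:, k]
            assert (col >= lo - 1e-12).all() and (col <= hi + 1e-12).all()

    def test_same_seed_reproduces_design(self):
        a = build_chimeric_design(seed=9, repeats=2)
        b = build_chimeric_design(seed=9, repeats=2)
        assert np.array_equal(a.distributions, b.distributions)

    def test_infeasible_ranges_show_sums(self):
        bad = {"A": (0.6, 0.9), "B": (0.5, 0.8)}
        with pytest.raises(ConfigurationError, match="infeasible"):
            build_chimeric_design(ranges=bad, repeats=1)

    def test_supplied_vector_outside_range_names_index(self):
        vectors = np.array([[0.5, 0.3, 0.15, 0.05]])  # neuron 0.5 > 0.36
        with pytest.raises(ConfigurationError, match="distribution 0"):
            build_chimeric_design(vectors=vectors, repeats=1)

    def test_supplied_vectors_used_verbatim(self):
        vectors = np.array([[0.2, 0.5, 0.26, 0.04], [0.1, 0.4, 0.45, 0.05]])
        design = build_chimeric_design(vectors=vectors, repeats=3)
        assert design.source == "supplied"
        assert np.array_equal(design.distributions, vectors)
        assert design.n_tasks == 6


class TestPoolChimericLibrary:
    def test_single_type_library_equals_donor_pool(self):
        pools = {
            "A": np.array(["g1"] * 60 + ["g2"] * 40),
            "B": np.array(["g3"] * 100),
        }
        sample, truth = pool_chimeric_library(
            pools, [1.0, 0.0], total_reads=100, mode="reads", seed=0
        )
        assert sample.sum() == 100
        assert sample.get("g1", 0) == 60 and sample.get("g2", 0) == 40
        assert truth["A"] == 1.0

    def test_read_counts_sum_exactly(self):
        rng = np.random.default_rng(0)
        pools = {ct: rng.choice([f"g{i}" for i in range(20)], 5000) for ct in "ABCD"}
        sample, _ = pool_chimeric_library(
            pools, [0.33, 0.22, 0.28, 0.17], total_reads=4000, mode="reads", seed=1
        )
        assert int(sample.sum()) == 4000

    def test_expression_mode_roundtrip_recovers_truth(self, crossfree):
        from cortexmix.deconv import ssnmf_deconvolve

        donors = {ct: crossfree["panel"].expression[f"{ct}_1"] for ct in crossfree["truth"].columns}
        p = [0.3, 0.4, 0.25, 0.05]
        sample, truth = pool_chimeric_library(donors, p, mode="expression")
        bulk = sample.to_frame("mix")
        res = ssnmf_deconvolve(bulk, crossfree["panel"], crossfree["markers"])
        assert np.abs(res.proportions.loc["mix"] - truth).max() < 0.01

    def test_small_pool_sampled_with_replacement_warns(self):
        pools = {"A": np.array(["g1"] * 10), "B": np.array(["g2"] * 10)}
        with pytest.warns(UserWarning, match="replacement"):
            sample, _ = pool_chimeric_library(pools, [0.5, 0.5], total_reads=100, mode="reads")
        assert int(sample.sum()) == 100


class TestRunChimericValidation:
    def test_oracle_engine_scores_zero(self, noisy_panel, noisy_markers):
        design = build_chimeric_design(n_distributions=4, repeats=2, seed=5)
        truth_iter = iter(design.distributions.tolist() * design.repeats)

        def oracle(bulk, panel, markers):
            return pd.DataFrame(
                [next(truth_iter)], index=bulk.columns, columns=list(design.cell_types)
            )

        res = run_chimeric_validation(noisy_panel, noisy_markers, design, engine=oracle, seed=5)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_crossfree_donors_near_exact(self, crossfree):
        design = build_chimeric_design(n_distributions=8, repeats=2, seed=2)
        res = run_chimeric_validation(crossfree["panel"], crossfree["markers"], design, seed=2)
        assert res.rmse <= 0.01

    def test_error_grows_with_donor_noise(self, crossfree):
        # on a crosstalk-free panel the pooled error is driven by donor
        # noise alone and rises with sigma on a fixed noise draw
        signature = crossfree["signature"]
        rng = np.random.default_rng(7)
        base = pd.DataFrame(
            {f"{ct}_{r}": signature[ct] for ct in signature.columns for r in (1, 2, 3)}
        )
        labels = pd.Series({c: c.rsplit("_", 1)[0] for c in base.columns})
        z = rng.normal(0.0, 1.0, base.shape)
        design = build_chimeric_design(n_distributions=8, repeats=3, seed=7)
        errors = []
        for sigma in (0.0, 0.1, 0.2, 0.4):
            noisy = base * np.exp(sigma * z)
            panel = reference_panel_from_profiles(noisy, labels)
            errors.append(
                run_chimeric_validation(panel, crossfree["markers"], design, seed=7).rmse
            )
        assert all(b >= a - 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[0] <= 0.01 < errors[-1]

    def test_holdout_impossible_with_single_donor(self, noisy_markers):
        cfg = SyntheticConfig(noise_sigma=0.2, n_replicates=1, seed=7)
        expr, labels = simulate_reference_profiles(cfg)
        panel = reference_panel_from_profiles(expr, labels)
        design = build_chimeric_design(n_distributions=2, repeats=1, seed=0)
        with pytest.raises(DataError, match="holdout"):
            run_chimeric_validation(panel, noisy_markers, design, holdout=True)

    def test_read_mode_matches_expression_mode_closely(self, noisy_panel, noisy_markers):
        design = build_chimeric_design(n_distributions=4, repeats=1, total_reads=50_000, seed=4)
        pools = simulate_read_pools(noisy_panel.expression, pool_size=60_000, seed=4)
        res_reads = run_chimeric_validation(
            noisy_panel, noisy_markers, design, mode="reads", read_pools=pools, seed=4
        )
        res_expr = run_chimeric_validation(noisy_panel, noisy_markers, design, seed=4)
        assert abs(res_reads.rmse - res_expr.rmse) < 0.02


class TestGeneDropout:
    def test_summary_matches_per_gene_vector(self, noisy_panel):
        small = SyntheticConfig(n_genes=60, n_markers_per_type=5, n_replicates=3, seed=7)
        expr, labels = simulate_reference_profiles(small)
        panel = reference_panel_from_profiles(expr, labels)
        markers = marker_panel_from_config(small)
        design = build_chimeric_design(n_distributions=4, repeats=2, seed=1)
        per_gene, summary = gene_dropout_robustness(panel, markers, design, seed=1)
        assert summary["n_genes"] == len(per_gene) == len(markers.genes)
        assert summary["mean"] == pytest.approx(per_gene.mean())
        assert summary["sd"] == pytest.approx(per_gene.std(ddof=1))
        assert (per_gene >= 0).all()

    def test_sole_marker_of_a_type_skipped_with_warning(self):
        cfg = SyntheticConfig(n_genes=40, n_markers_per_type=1, n_replicates=2, seed=3)
        expr, labels = simulate_reference_profiles(cfg)
        panel = reference_panel_from_profiles(expr, labels)
        markers = marker_panel_from_config(cfg)
        design = build_chimeric_design(n_distributions=2, repeats=1, seed=0)
        with pytest.warns(UserWarning, match="single marker"):
            per_gene, summary = gene_dropout_robustness(panel, markers, design, seed=0)
        assert summary["n_genes"] == 0


class TestLoocvAccuracy:
    def test_noiseless_crossfree_panel_near_perfect(self, crossfree):
        res = loocv_accuracy(crossfree["panel"], crossfree["markers"])
        assert res.mean_accuracy >= 0.99
        assert res.rmse_one_hot <= 0.01

    def test_reports_one_row_per_sample(self, noisy_panel, noisy_markers):
        res = loocv_accuracy(noisy_panel, noisy_markers)
        assert set(res.proportions.index) == set(noisy_panel.sample_ids)
        assert np.allclose(res.proportions.sum(axis=1), 1.0, atol=1e-6)
        assert res.sd_accuracy >= 0.0

    def test_single_sample_type_rejected(self, noisy_panel, noisy_markers):
        drop = [s for s in noisy_panel.sample_ids if noisy_panel.labels[s] == "microglia"][1:]
        panel = noisy_panel.drop_samples(drop)
        with pytest.raises(DataError, match="microglia"):
            loocv_accuracy(panel, noisy_markers)
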