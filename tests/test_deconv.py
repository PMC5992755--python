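"""Engine contracts: exact recovery, simplex/scale/permutation invariances,
objective monotonicity, and agreement with independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from cortexmix.containers import MarkerPanel
from cortexmix.deconv import (
    deconvolve,
    dsa_deconvolve,
    mean_profile_deconvolve,
    ssnmf_deconvolve,
)
from cortexmix.exceptions import ConfigurationError, DataError
from cortexmix.validate import rmse

from conftest import grid_least_squares_oracle

ENGINE_FUNCS = {
    "ssnmf": lambda bulk, cf: ssnmf_deconvolve(bulk, cf["panel"], cf["markers"]),
    "dsa": lambda bulk, cf: dsa_deconvolve(bulk, cf["markers"]),
    "mean_profile": lambda bulk, cf: mean_profile_deconvolve(bulk, cf["markers"]),
}


@pytest.mark.parametrize("engine", list(ENGINE_FUNCS))
class TestEngineInvariants:
    def test_rows_on_simplex(self, crossfree, engine, noisy_panel, noisy_markers):
        rng = np.random.default_rng(11)
        bulk = pd.DataFrame(
            noisy_panel.type_means().to_numpy() @ rng.dirichlet([1] * 4, 6).T
            * np.exp(rng.normal(0, 0.3, (len(noisy_panel.expression), 6))),
            index=noisy_panel.expression.index,
            columns=[f"b{i}" for i in range(6)],
        )
        cf = {"panel": noisy_panel, "markers": noisy_markers}
        props = ENGINE_FUNCS[engine](bulk, cf).proportions.to_numpy()
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-6)
        assert (props >= -1e-9).all() and (props <= 1 + 1e-9).all()

    def test_per_sample_scale_invariance(self, crossfree, engine):
        bulk = crossfree["bulk"].copy()
        scaled = bulk.copy()
        scaled["mix4"] = scaled["mix4"] * 37.5
        base = ENGINE_FUNCS[engine](bulk, crossfree).proportions
        after = ENGINE_FUNCS[engine](scaled, crossfree).proportions
        assert np.abs(base.to_numpy() - after.to_numpy()).max() < 1e-6

    def test_gene_permutation_invariance(self, crossfree, engine):
        bulk = crossfree["bulk"]
        shuffled = bulk.sample(frac=1.0, random_state=3)
        base = ENGINE_FUNCS[engine](bulk, crossfree).proportions
        after = ENGINE_FUNCS[engine](shuffled, crossfree).proportions
        assert np.abs(base.to_numpy() - after.to_numpy()).max() < 1e-12

    def test_exact_mixture_recovery(self, crossfree, engine):
        props = ENGINE_FUNCS[engine](crossfree["bulk"], crossfree).proportions
        assert np.abs(props.to_numpy() - crossfree["truth"].to_numpy()).max() < 0.01

    def test_negative_input_rejected(self, crossfree, engine):
        bulk = crossfree["bulk"].copy()
        bulk.iloc[0, 0] = -1.0
        with pytest.raises(DataError, match="negative"):
            ENGINE_FUNCS[engine](bulk, crossfree)


class TestSsnmf:
    def test_pure_reference_sample_self_recovery(self, crossfree):
        # a bulk that IS one purified neuron sample comes back as neuron
        sample = crossfree["panel"].expression[["neuron_1"]]
        res = ssnmf_deconvolve(sample, crossfree["panel"], crossfree["markers"])
        assert res.proportions.loc["neuron_1", "neuron"] >= 0.99

    def test_objective_trace_non_increasing(self, noisy_panel, noisy_markers):
        rng = np.random.default_rng(5)
        mix = rng.dirichlet([1, 1, 1, 1], 4)
        bulk = pd.DataFrame(
            noisy_panel.type_means().to_numpy() @ mix.T,
            index=noisy_panel.expression.index,
            columns=list("abcd"),
        )
        res = ssnmf_deconvolve(bulk, noisy_panel, noisy_markers)
        trace = np.asarray(res.objective_trace)
        assert (np.diff(trace) <= 1e-10).all()

    def test_deterministic_across_runs(self, noisy_panel, noisy_markers):
        bulk = noisy_panel.expression.iloc[:, :2]
        a = ssnmf_deconvolve(bulk, noisy_panel, noisy_markers).proportions
        b = ssnmf_deconvolve(bulk, noisy_panel, noisy_markers).proportions
        pd.testing.assert_frame_equal(a, b)

    def test_signature_respects_marker_constraint(self, noisy_panel, noisy_markers):
        bulk = noisy_panel.expression.iloc[:, :3]
        res = ssnmf_deconvolve(bulk, noisy_panel, noisy_markers)
        W = res.signature
        for ct in noisy_markers.cell_types:
            off = W.loc[list(noisy_markers.assignments[ct])].drop(columns=ct)
            assert (off.to_numpy() == 0.0).all()

    def test_noisy_admixtures_within_error_bound(self, noisy_panel, noisy_markers):
        # 20 admixtures at generator noise 0.2: error vs truth within 0.08,
        # and close to the simplex-grid least-squares oracle's own accuracy
        rng = np.random.default_rng(8)
        truth = rng.dirichlet([4, 4, 4, 1], 20)
        tm = noisy_panel.type_means()[list(noisy_markers.cell_types)]
        V = tm.to_numpy() @ truth.T * np.exp(
            rng.normal(0, 0.2, (len(tm), 20))
        )
        bulk = pd.DataFrame(V, index=tm.index, columns=[f"s{i}" for i in range(20)])
        res = ssnmf_deconvolve(bulk, noisy_panel, noisy_markers)
        assert rmse(res.proportions.to_numpy(), truth) <= 0.08

    def test_missing_marker_type_names_type(self, crossfree):
        bulk = crossfree["bulk"].drop(
            index=list(crossfree["markers"].assignments["microglia"])
        )
        with pytest.raises(DataError, match="microglia"):
            ssnmf_deconvolve(bulk, crossfree["panel"], crossfree["markers"])


class TestDsa:
    def test_pure_sample_with_zero_other_markers(self, crossfree):
        bulk = crossfree["bulk"][["mix0"]]  # pure neuron column of the signature
        extra = crossfree["bulk"][["mix1", "mix2", "mix3"]]
        props = dsa_deconvolve(pd.concat([bulk, extra], axis=1), crossfree["markers"]).proportions
        assert props.loc["mix0", "neuron"] == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_two_type_mixture_exact(self):
        markers = MarkerPanel({"A": ("a1", "a2"), "B": ("b1", "b2")})
        S = pd.DataFrame(
            {"A": [8.0, 4.0, 0.0, 0.0], "B": [0.0, 0.0, 6.0, 6.0]},
            index=["a1", "a2", "b1", "b2"],
        )
        mixes = np.array([[0.25, 0.75], [0.6, 0.4]])
        bulk = pd.DataFrame(S.to_numpy() @ mixes.T, index=S.index, columns=["m1", "m2"])
        props = dsa_deconvolve(bulk, markers).proportions
        assert np.abs(props.to_numpy() - mixes).max() < 1e-6

    def test_agreement_with_grid_oracle_under_noise(self, crossfree):
        rng = np.random.default_rng(2)
        truth = rng.dirichlet([4, 4, 4, 1], 30)
        S = crossfree["signature"]
        V = S.to_numpy() @ truth.T * np.exp(rng.normal(0, 0.2, (len(S), 30)))
        bulk = pd.DataFrame(V, index=S.index, columns=[f"s{i}" for i in range(30)])
        est = dsa_deconvolve(bulk, crossfree["markers"]).proportions
        oracle = grid_least_squares_oracle(bulk, S)
        assert np.abs(est.to_numpy() - oracle.to_numpy()).max() <= 0.02

    def test_rank_deficient_design_recommends_more_samples(self, crossfree):
        one = crossfree["bulk"][["mix4"]]
        with pytest.raises(DataError, match="rank-deficient"):
            dsa_deconvolve(one, crossfree["markers"])


class TestMeanProfile:
    def test_zero_marker_sample_estimates_zero(self):
        markers = MarkerPanel({"A": ("a1",), "B": ("b1",)})
        bulk = pd.DataFrame(
            {"s1": [4.0, 0.0], "s2": [2.0, 6.0]}, index=["a1", "b1"]
        )
        props = mean_profile_deconvolve(bulk, markers).proportions
        assert props.loc["s1", "B"] == 0.0
        assert props.loc["s1", "A"] == 1.0

    def test_symmetric_sample_is_uniform(self, crossfree):
        props = mean_profile_deconvolve(crossfree["bulk"], crossfree["markers"]).proportions
        assert np.allclose(props.loc["mix6"], 0.25, atol=1e-9)

    def test_hand_computed_fixture(self):
        # two types x two markers x two samples, worked by hand:
        # columns normalize to unit totals, rows scale to unit max, type
        # means renormalize per sample -> (0.6, 0.4) for both samples
        markers = MarkerPanel({"A": ("g1", "g2"), "B": ("g3", "g4")})
        bulk = pd.DataFrame(
            {"s1": [4.0, 2.0, 2.0, 2.0], "s2": [1.0, 1.0, 3.0, 0.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        props = mean_profile_deconvolve(bulk, markers).proportions
        expected = np.array([[0.6, 0.4], [0.6, 0.4]])
        assert np.abs(props.to_numpy() - expected).max() < 1e-12

    def test_flagged_as_relative_index(self, crossfree):
        res = mean_profile_deconvolve(crossfree["bulk"], crossfree["markers"])
        assert res.relative_index


class TestDispatch:
    def test_dispatch_matches_direct_call(self, crossfree):
        direct = ssnmf_deconvolve(crossfree["bulk"], crossfree["panel"], crossfree["markers"])
        via = deconvolve(crossfree["bulk"], crossfree["panel"], crossfree["markers"], engine="ssnmf")
        pd.testing.assert_frame_equal(direct.proportions, via.proportions)

    def test_unknown_engine_lists_valid_names(self, crossfree):
        with pytest.raises(ConfigurationError, match="dsa"):
            deconvolve(crossfree["bulk"], crossfree["panel"], crossfree["markers"], engine="nope")

    def test_cross_engine_consistency_on_noiseless_mixture(self, crossfree):
        results = [
            ENGINE_FUNCS[e](crossfree["bulk"], crossfree).proportions.to_numpy()
            for e in ENGINE_FUNCS
        ]
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                assert np.abs(results[i] - results[j]).max() <= 0.02

    def test_callable_engine_passthrough(self, crossfree):
        def oracle(bulk, panel, markers):
            return crossfree["truth"]

        res = deconvolve(crossfree["bulk"], crossfree["panel"], crossfree["markers"], engine=oracle)
        pd.testing.assert_frame_equal(res.proportions, crossfree["truth"])
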