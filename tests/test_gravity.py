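"""Flow-table assembly, mixed-effects gravity fits, and AIC selection."""

import numpy as np
import pandas as pd
import pytest

from chorusnet.genotypes import GeneticDistanceMatrix
from chorusnet.gravity import (
    GravityModel,
    aic,
    bandwidth_selection,
    build_flow_table,
    fit_gravity,
    model_selection,
)
from chorusnet.synthetic import simulate_flow_table


def pair_design(n_sites=18, seed=0, cols=("x1", "x2")):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        for j in range(n_sites):
            if i != j:
                rows.append({"origin": f"s{i}", "destination": f"s{j}",
                             **{c: rng.normal() for c in cols}})
    return pd.DataFrame(rows)


def toy_inputs(n_sites=4, seed=0):
    rng = np.random.default_rng(seed)
    sites = [f"s{k}" for k in range(n_sites)]
    d = rng.uniform(0.2, 0.8, (n_sites, n_sites))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    dps = GeneticDistanceMatrix(sites, d, {s: 10 for s in sites})
    at = pd.DataFrame({"pratio_at": rng.uniform(0.2, 0.6, n_sites)}, index=sites)
    pairs = [(a, b) for i, a in enumerate(sites) for b in sites[i + 1:]]
    bet = pd.DataFrame(
        {"srr_bet": rng.uniform(0.1, 0.9, len(pairs))},
        index=pd.MultiIndex.from_tuples(pairs),
    )
    dist = pd.DataFrame(rng.uniform(300, 3000, (n_sites, n_sites)), index=sites, columns=sites)
    dist = (dist + dist.T) / 2
    return dps, at, bet, dist


class TestBuildFlowTable:
    def test_ordered_pair_count(self):
        dps, at, bet, dist = toy_inputs(18)
        flow = build_flow_table(dps, at, bet, dist)
        assert len(flow) == 18 * 17
        assert flow.groupby("origin").size().eq(17).all()

    def test_zero_genetic_distance_gives_zero_response(self):
        dps, at, bet, dist = toy_inputs(3)
        dps.matrix[:] = 0.0
        flow = build_flow_table(dps, at, bet, dist)
        np.testing.assert_allclose(flow["ln_T"], 0.0, atol=1e-12)

    def test_complete_differentiation_floored_with_warning(self):
        dps, at, bet, dist = toy_inputs(3)
        dps.matrix[0, 1] = dps.matrix[1, 0] = 1.0
        with pytest.warns(UserWarning, match="floor"):
            flow = build_flow_table(dps, at, bet, dist, epsilon=1e-6)
        got = flow.set_index(["origin", "destination"]).loc[("s0", "s1"), "ln_T"]
        assert got == pytest.approx(np.log(1e-6))

    def test_missing_covariate_names_site_and_variable(self):
        dps, at, bet, dist = toy_inputs(3)
        at.loc["s1", "pratio_at"] = np.nan
        with pytest.raises(ValueError, match="pratio_at.*s1"):
            build_flow_table(dps, at, bet, dist)

    def test_node_metric_role_switch(self):
        dps, at, bet, dist = toy_inputs(3)
        fo = build_flow_table(dps, at, bet, dist, node_metric_role="origin")
        fd = build_flow_table(dps, at, bet, dist, node_metric_role="destination")
        a = fo.set_index(["origin", "destination"])["pratio_at"]
        b = fd.set_index(["origin", "destination"])["pratio_at"]
        assert a[("s0", "s1")] == b[("s1", "s0")]


class TestGravityModel:
    def test_boundary_case_matches_ols(self):
        d = pair_design(seed=1)
        flow = simulate_flow_table(d, [-0.5, 0.3], sigma_u=0.0, sigma_e=0.05, seed=2)
        m = GravityModel(["x1", "x2"]).fit(flow)
        X = np.column_stack([np.ones(len(flow)), flow[["x1", "x2"]]])
        beta, *_ = np.linalg.lstsq(X, flow["ln_T"], rcond=None)
        np.testing.assert_allclose(m.coef_.to_numpy(), beta, atol=1e-6)

    def test_record_order_invariance(self):
        d = pair_design(seed=3)
        flow = simulate_flow_table(d, [0.4, -0.2], sigma_u=0.1, sigma_e=0.05, seed=4)
        m1 = GravityModel(["x1", "x2"]).fit(flow)
        shuffled = flow.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m2 = GravityModel(["x1", "x2"]).fit(shuffled)
        np.testing.assert_allclose(m1.coef_.to_numpy(), m2.coef_.to_numpy(), atol=1e-8)
        assert m1.loglik_ == pytest.approx(m2.loglik_, abs=1e-6)

    def test_parameter_recovery_within_3_se(self):
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            d = pair_design(seed=100 + rep)
            flow = simulate_flow_table(d, [-0.5, 0.3], sigma_u=0.1, sigma_e=0.05,
                                       seed=200 + rep, intercept=1.0)
            m = GravityModel(["x1", "x2"]).fit(flow)
            se = m.standard_errors().to_numpy()
            ok = np.all(np.abs(m.coef_.to_numpy() - [1.0, -0.5, 0.3]) <= 3 * se)
            hits += bool(ok)
        assert hits >= n_rep - 1

    def test_variance_components_recovered_roughly(self):
        d = pair_design(n_sites=25, seed=5)
        flow = simulate_flow_table(d, [0.2, -0.4], sigma_u=0.3, sigma_e=0.1, seed=6)
        m = GravityModel(["x1", "x2"]).fit(flow)
        assert m.sigma_u2_ == pytest.approx(0.09, rel=0.8)
        assert m.sigma_e2_ == pytest.approx(0.01, rel=0.4)

    def test_rank_deficient_design_rejected(self):
        d = pair_design(seed=7)
        d["x3"] = d["x1"] * 2.0
        flow = simulate_flow_table(d, [0.1, 0.1, 0.1], sigma_u=0.0, sigma_e=0.1, seed=8)
        with pytest.raises(ValueError, match="rank deficient"):
            GravityModel(["x1", "x2", "x3"]).fit(flow)

    def test_affine_rescaling_rescales_coefficient(self):
        d = pair_design(seed=9)
        flow = simulate_flow_table(d, [0.5, -0.3], sigma_u=0.1, sigma_e=0.05, seed=10)
        m1 = GravityModel(["x1", "x2"]).fit(flow)
        flow2 = flow.copy()
        flow2["x1"] = 3.0 * flow2["x1"] + 2.0
        m2 = GravityModel(["x1", "x2"]).fit(flow2)
        assert m2.loglik_ == pytest.approx(m1.loglik_, abs=1e-6)
        assert m2.coef_["x1"] == pytest.approx(m1.coef_["x1"] / 3.0, abs=1e-6)
        assert m2.coef_["x2"] == pytest.approx(m1.coef_["x2"], abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        # independent implementation check: statsmodels MixedLM (ML) on
        # well-conditioned data with a substantial origin variance
        import statsmodels.api as sm

        d = pair_design(n_sites=12, seed=30)
        flow = simulate_flow_table(d, [0.6, -0.4], sigma_u=0.5, sigma_e=0.2, seed=31,
                                   intercept=0.7)
        m = GravityModel(["x1", "x2"]).fit(flow)
        exog = sm.add_constant(flow[["x1", "x2"]])
        ref = sm.MixedLM(flow["ln_T"], exog, groups=flow["origin"]).fit(reml=False)
        np.testing.assert_allclose(m.coef_.to_numpy(), ref.fe_params.to_numpy(), atol=1e-5)
        assert m.loglik_ == pytest.approx(ref.llf, abs=1e-4)
        assert m.sigma_e2_ == pytest.approx(ref.scale, rel=1e-3)
        assert m.sigma_u2_ == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3)
        np.testing.assert_allclose(
            m.standard_errors().to_numpy(), ref.bse_fe.to_numpy(), rtol=1e-3
        )

    def test_sklearn_param_protocol(self):
        m = GravityModel(["x1"], aic_convention="printed_k")
        assert m.get_params()["aic_convention"] == "printed_k"
        m.set_params(aic_convention="full")
        assert m.aic_convention == "full"
        with pytest.raises(ValueError):
            m.set_params(bogus=1)

    def test_predict_uses_fixed_effects(self):
        d = pair_design(seed=11)
        flow = simulate_flow_table(d, [1.0, 0.0], sigma_u=0.0, sigma_e=0.0, seed=12)
        m = fit_gravity(flow, ["x1", "x2"])
        np.testing.assert_allclose(m.predict(flow), flow["ln_T"], atol=1e-6)


class TestAic:
    def test_tuple_arithmetic(self):
        assert aic((4, -6.04)) == pytest.approx(20.08)
        assert aic((5, -5.39)) == pytest.approx(20.78)

    def test_conventions_differ_by_fixed_offset(self):
        d = pair_design(seed=13)
        flow = simulate_flow_table(d, [0.3, 0.2], sigma_u=0.1, sigma_e=0.1, seed=14)
        m = GravityModel(["x1", "x2"]).fit(flow)
        # full counts intercept + 2 variance components on top of the slopes
        assert aic(m, "full") - aic(m, "printed_k") == pytest.approx(6.0)


class TestSelection:
    def test_single_candidate_tops_table(self):
        d = pair_design(seed=15)
        flow = simulate_flow_table(d, [0.5, 0.0], sigma_u=0.05, sigma_e=0.1, seed=16)
        flow = flow.rename(columns={"x1": "distance", "x2": "z"})
        sel = model_selection(flow, {"only": ["distance", "z"]})
        assert sel.table.iloc[0]["delta_aic"] == 0.0
        assert sel.table.iloc[0]["top_set"]
        assert "null_distance" in set(sel.table["model"])

    def test_identical_specs_tie_break_by_name(self):
        d = pair_design(seed=17)
        flow = simulate_flow_table(d, [0.5, 0.1], sigma_u=0.05, sigma_e=0.1, seed=18)
        flow = flow.rename(columns={"x1": "distance", "x2": "z"})
        sel = model_selection(flow, {"b_twin": ["distance", "z"], "a_twin": ["distance", "z"]})
        ranked = sel.table[sel.table["model"].str.endswith("twin")]
        assert list(ranked["model"]) == ["a_twin", "b_twin"]
        assert ranked["aic"].nunique() == 1

    def test_true_model_lands_in_top_set(self):
        wins = 0
        n_rep = 8
        for rep in range(n_rep):
            d = pair_design(seed=300 + rep, cols=("distance", "z1", "z2"))
            flow = simulate_flow_table(d, [-0.6, 0.5, 0.0], sigma_u=0.05,
                                       sigma_e=0.05, seed=400 + rep)
            sel = model_selection(
                flow,
                {"true": ["distance", "z1"], "extra": ["distance", "z1", "z2"]},
            )
            top = set(sel.top_models["model"])
            wins += "true" in top
        assert wins >= n_rep - 1

    def test_noise_predictor_never_hurts_loglik(self):
        d = pair_design(seed=19, cols=("distance", "noise"))
        flow = simulate_flow_table(d, [-0.5, 0.0], sigma_u=0.1, sigma_e=0.05, seed=20)
        base = GravityModel(["distance"]).fit(flow)
        bigger = GravityModel(["distance", "noise"]).fit(flow)
        assert bigger.loglik_ >= base.loglik_ - 1e-6
        assert aic(bigger, "printed_k") >= aic(base, "printed_k") - 2.0 - 1e-6


class TestBandwidthSelection:
    def test_identical_tables_pick_smallest_bandwidth(self):
        d = pair_design(seed=21)
        flow = simulate_flow_table(d, [0.3, -0.2], sigma_u=0.05, sigma_e=0.1, seed=22)
        bw, table = bandwidth_selection({bw: flow for bw in (30.0, 60.0, 120.0, 240.0)},
                                        ["x1", "x2"])
        assert bw == 30.0
        assert table["aic"].nunique() == 1

    def test_generating_bandwidth_usually_selected(self):
        wins = 0
        n_rep = 8
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            d = pair_design(seed=600 + rep, cols=("distance", "srr_bet"))
            flow30 = simulate_flow_table(d, [-0.4, 0.8], sigma_u=0.0, sigma_e=0.05,
                                         seed=700 + rep)
            tables = {30.0: flow30}
            for bw in (60.0, 120.0, 240.0):
                blurred = flow30.copy()
                blurred["srr_bet"] = blurred["srr_bet"] + rng.normal(0, 0.5, len(blurred))
                tables[bw] = blurred
            bw, _ = bandwidth_selection(tables, ["distance", "srr_bet"])
            wins += bw == 30.0
        assert wins >= n_rep // 2 + 1

    def test_single_bandwidth_trivial(self):
        d = pair_design(seed=23)
        flow = simulate_flow_table(d, [0.1, 0.1], sigma_u=0.0, sigma_e=0.1, seed=24)
        bw, _ = bandwidth_selection({60.0: flow}, ["x1", "x2"])
        assert bw == 60.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bandwidth_selection({}, ["x1"])
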