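import numpy as np
import pandas as pd
import pytest

from phylopest import (
    ModelSpec,
    build_design,
    curve_envelope,
    draw_sources,
    fit_logistic,
    pairwise_distances,
    run_resampling,
    screen_interaction,
    simulate_tree,
)
from phylopest.errors import FitError
from phylopest.regression import _design_arrays, _fit_arrays
from phylopest.simulate import GeneratorConfig, simulate_pests

from conftest import incidence_from_hosts
from oracles import binom_loglik, grid_max_loglik


def design_frame(x1, s, n_known=2):
    return pd.DataFrame(
        {
            "pest_id": "P1",
            "source_genus": "A",
            "target_genus": "B",
            "S": s,
            "PD": 10 ** np.asarray(x1) - 1,
            "x1": x1,
            "n_known": n_known,
        }
    )


class TestModelSpec:
    def test_predictor_sets_strictly_nested(self):
        p1, p2, p3 = (set(ModelSpec(m).predictors) for m in ("M1", "M2", "M3"))
        assert p1 < p2 < p3

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("M4")


class TestDrawSources:
    def test_uniform_over_hosts(self):
        inc = incidence_from_hosts({"P1": ["A", "B"]}, ["A", "B", "C"])
        rng = np.random.default_rng(0)
        freq = np.mean([draw_sources(inc, rng)["P1"] == "A" for _ in range(10000)])
        assert freq == pytest.approx(0.5, abs=0.015)

    def test_single_host_pest_rejected(self):
        inc = incidence_from_hosts({"P1": ["A"]}, ["A", "B"])
        with pytest.raises(FitError):
            draw_sources(inc, np.random.default_rng(0))

    def test_deterministic_given_seed(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, _ = tiny_dataset
        elig = filter_multihost(incidence)
        a = draw_sources(elig, np.random.default_rng(42))
        b = draw_sources(elig, np.random.default_rng(42))
        assert a == b


class TestBuildDesign:
    def test_one_pest_three_genera_gives_two_rows(self, three_tip_tree):
        inc = incidence_from_hosts({"P1": ["A", "B"]}, ["A", "B", "C"])
        dm = pairwise_distances(three_tip_tree)
        design = build_design(inc, {"P1": "A"}, dm)
        assert len(design) == 2
        assert set(design["target_genus"]) == {"B", "C"}
        assert design.set_index("target_genus")["S"].to_dict() == {"B": 1, "C": 0}

    def test_x1_is_log10_pd_plus_one(self, three_tip_tree):
        inc = incidence_from_hosts({"P1": ["A", "B"]}, ["A", "B", "C"])
        dm = pairwise_distances(three_tip_tree)
        design = build_design(inc, {"P1": "A"}, dm)
        np.testing.assert_allclose(design["x1"], np.log10(design["PD"] + 1))
        assert (design["PD"] > 0).all()

    def test_positive_rows_per_pest_equal_n_known_minus_one(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, distances = tiny_dataset
        elig = filter_multihost(incidence)
        sources = draw_sources(elig, np.random.default_rng(1))
        design = build_design(elig, sources, distances)
        per_pest = design.groupby("pest_id")[["S", "n_known"]].agg(
            S=("S", "sum"), n_known=("n_known", "first")
        )
        assert (per_pest["S"] == per_pest["n_known"] - 1).all()

    def test_source_never_among_targets(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, distances = tiny_dataset
        elig = filter_multihost(incidence)
        sources = draw_sources(elig, np.random.default_rng(2))
        design = build_design(elig, sources, distances)
        assert not (design["source_genus"] == design["target_genus"]).any()

    def test_non_host_source_rejected(self, three_tip_tree):
        inc = incidence_from_hosts({"P1": ["A", "B"]}, ["A", "B", "C"])
        dm = pairwise_distances(three_tip_tree)
        with pytest.raises(FitError):
            build_design(inc, {"P1": "C"}, dm)


class TestFitLogistic:
    def test_saturated_two_point_closed_form(self):
        design = design_frame(x1=[1, 1, 1, 1, 2, 2, 2, 2], s=[1, 1, 1, 0, 1, 0, 0, 0])
        fit = fit_logistic(design, ModelSpec("M1"))
        assert fit.converged and not fit.separated
        assert fit.params[0] == pytest.approx(3 * np.log(3), abs=1e-5)
        assert fit.params[1] == pytest.approx(-2 * np.log(3), abs=1e-5)

    def test_degenerate_response_rejected(self):
        design = design_frame(x1=[1.0, 2.0], s=[1, 1])
        with pytest.raises(FitError, match="degenerate"):
            fit_logistic(design, ModelSpec("M1"))

    def test_loglik_beats_grid_oracle(self):
        rng = np.random.default_rng(5)
        x1 = rng.uniform(0, 2.5, size=200)
        p = 1 / (1 + np.exp(-(2.0 - 1.5 * x1)))
        s = (rng.random(200) < p).astype(int)
        design = design_frame(x1=x1, s=s)
        fit = fit_logistic(design, ModelSpec("M1"))
        X = np.column_stack([np.ones_like(x1), x1])
        ll_fit = binom_loglik(s, X, fit.params)
        assert ll_fit >= grid_max_loglik(s, X, fit.params) - 1e-6

    def test_separation_flagged(self):
        x1 = np.array([0.0, 0.2, 0.4, 1.6, 1.8, 2.0])
        s = np.array([1, 1, 1, 0, 0, 0])
        fit = fit_logistic(design_frame(x1=x1, s=s), ModelSpec("M1"))
        assert fit.separated


class TestRunResampling:
    def test_single_run_summary_has_zero_width_ci(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, distances = tiny_dataset
        elig = filter_multihost(incidence)
        summary, runs = run_resampling(elig, distances, ModelSpec("M1"), n_runs=1, seed=3)
        ok = summary.table.dropna(subset=["median"])
        assert (ok["ci_low"] == ok["median"]).all()
        assert (ok["ci_high"] == ok["median"]).all()

    def test_reproducible_from_seed(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, distances = tiny_dataset
        elig = filter_multihost(incidence)
        s1, r1 = run_resampling(elig, distances, ModelSpec("M1"), n_runs=3, seed=9)
        s2, r2 = run_resampling(elig, distances, ModelSpec("M1"), n_runs=3, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_quantile_ordering(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, distances = tiny_dataset
        elig = filter_multihost(incidence)
        summary, _ = run_resampling(elig, distances, ModelSpec("M1"), n_runs=8, seed=1)
        ok = summary.table.dropna(subset=["median"])
        assert (ok["ci_low"] <= ok["median"]).all()
        assert (ok["median"] <= ok["ci_high"]).all()

    def test_unfiltered_incidence_rejected(self, tiny_dataset, three_tip_tree):
        inc = incidence_from_hosts({"P1": ["A"], "P2": ["A", "B"]}, ["A", "B", "C"])
        dm = pairwise_distances(three_tip_tree)
        with pytest.raises(FitError, match="filter_multihost"):
            run_resampling(inc, dm, ModelSpec("M1"), n_runs=1, seed=0)

    def test_unknown_group_rejected(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, distances = tiny_dataset
        elig = filter_multihost(incidence)
        with pytest.raises(ValueError, match="algae"):
            run_resampling(elig, distances, ModelSpec("M1"), n_runs=1, seed=0,
                           groups=["algae"])


class TestTrueSourceRecovery:
    """With the generating source known, the fit recovers the simulation truth.

    This isolates the design-construction + ML machinery from the extra
    variability (and attenuation) introduced by random source redraws.
    """

    def test_slope_recovered_from_true_sources(self):
        b0, b1 = 4.3961, -3.3249
        tree = simulate_tree(210, 160.0, seed=np.random.default_rng([21, 0]))
        cfg = GeneratorConfig(
            n_genera=210, root_age=160.0, n_pests={"fungi": 300},
            coefficients={"fungi": (b0, b1)}, sigma_b=0.0, seed=21,
        )
        records, truth = simulate_pests(tree, cfg, rng=np.random.default_rng([21, 1]))
        from phylopest import collapse_to_genus, filter_multihost

        elig = filter_multihost(collapse_to_genus(records, tree.tip_labels))
        dm = pairwise_distances(tree)
        sources = {p: truth["pests"][p]["source"] for p in elig.pests}
        fit = fit_logistic(build_design(elig, sources, dm), ModelSpec("M1"))
        assert fit.converged
        assert fit.params[1] == pytest.approx(b1, rel=0.10)


class TestCurveEnvelope:
    @staticmethod
    def runs_frame(coefs):
        rows = []
        for i, c in enumerate(coefs):
            rows.append({"run": i, "group": "fungi", "converged": True,
                         "separated": False, **c})
        return pd.DataFrame(rows)

    def test_null_model_gives_flat_half(self):
        runs = self.runs_frame([{"b0": 0.0, "b1": 0.0}])
        env = curve_envelope(runs, ModelSpec("M1"), grid_step=5, max_pd=100)
        np.testing.assert_allclose(env.table["q50"], 0.5)

    def test_negative_slope_gives_decreasing_median_curve(self):
        runs = self.runs_frame([{"b0": 3.0, "b1": -2.5}])
        env = curve_envelope(runs, ModelSpec("M1"), grid_step=5, max_pd=300)
        assert (np.diff(env.table["q50"]) < 0).all()

    def test_hand_computed_point(self):
        runs = self.runs_frame([{"b0": 2.0, "b1": -1.0}])
        env = curve_envelope(runs, ModelSpec("M1"), grid_step=9, max_pd=9)
        at9 = env.table[env.table["pd"] == 9.0]["q50"].iloc[0]
        assert at9 == pytest.approx(0.7311, abs=1e-4)

    def test_grid_uses_requested_step(self):
        runs = self.runs_frame([{"b0": 1.0, "b1": -1.0}])
        env = curve_envelope(runs, ModelSpec("M1"), grid_step=5, max_pd=20)
        np.testing.assert_allclose(env.table["pd"], [0, 5, 10, 15, 20])

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValueError):
            curve_envelope(pd.DataFrame(), ModelSpec("M1"))

    def test_m2_requires_n_known(self):
        runs = self.runs_frame([{"b0": 1.0, "b1": -1.0, "b2": 0.05}])
        with pytest.raises(ValueError, match="n_known"):
            curve_envelope(runs, ModelSpec("M2"), grid_step=5, max_pd=20)


class TestScreenInteraction:
    def test_single_run_flags_low_replication(self, tiny_dataset):
        from phylopest import filter_multihost

        *_, incidence, distances = tiny_dataset
        elig = filter_multihost(incidence)
        report = screen_interaction(elig, distances, n_runs=1, seed=0)
        assert report["low_replication"].all()
        assert set(report.columns) >= {"interaction_median", "ci_low", "ci_high",
                                       "significant", "recommended_model"}

    def test_heterogeneity_detected_as_positive_interaction(self):
        """Pest-level intercept spread induces a real distance x breadth
        interaction under source resampling, which the screen detects."""
        seed = 104
        tree = simulate_tree(210, 160.0, seed=np.random.default_rng([seed, 0]))
        cfg = GeneratorConfig(
            n_genera=210, root_age=160.0, n_pests={"fungi": 300},
            coefficients={"fungi": (4.3961, -3.3249)}, sigma_b=1.0, seed=seed,
        )
        records, _ = simulate_pests(tree, cfg, rng=np.random.default_rng([seed, 1]))
        from phylopest import collapse_to_genus, filter_multihost

        elig = filter_multihost(collapse_to_genus(records, tree.tip_labels))
        dm = pairwise_distances(tree)
        report = screen_interaction(elig, dm, n_runs=40, seed=seed)
        row = report.iloc[0]
        assert row["significant"] and row["interaction_median"] > 0
        assert row["recommended_model"] == "M3"
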