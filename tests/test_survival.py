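"""KM/log-rank, Cox fits, BH adjustment, meta-analysis, gene screen."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from gctme import synthetic
from gctme.survival import (
    cox_fit,
    fdr_adjust,
    km_logrank,
    meta_fixed,
    prognostic_gene_screen,
)


def logrank_oracle(times, events, grp):
    """Observed-minus-expected log-rank chi-square from first principles."""
    from scipy import stats

    times, events, grp = map(np.asarray, (times, events, grp))
    O = E = V = 0.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        d = ((times == t) & (events == 1)).sum()
        n = at.sum()
        n1 = (at & (grp == 0)).sum()
        O += ((times == t) & (events == 1) & (grp == 0)).sum()
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, stats.chi2.sf(chi2, 1)


class TestKmLogrank:
    def test_hand_worked_six_subject_example(self):
        """Group A dies at {1,2,3}, group B at {4,5,6}: the statistic matches
        the observed-minus-expected table computed from scratch."""
        surv = pd.DataFrame(
            {"os_time": [1, 2, 3, 4, 5, 6], "os_event": 1},
            index=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.index)
        curves, chi2, p = km_logrank(groups, surv)
        o_chi2, o_p = logrank_oracle(surv["os_time"], surv["os_event"],
                                     (groups == "A").astype(int) ^ 1)
        assert chi2 == pytest.approx(o_chi2, rel=1e-9)
        assert p == pytest.approx(o_p, rel=1e-9)
        assert chi2 == pytest.approx(5.0516605166, rel=1e-8)

    def test_identical_groups_give_p_one(self):
        base = pd.DataFrame({"os_time": [1.0, 2.0, 3.0], "os_event": [1, 1, 0]})
        surv = pd.concat([base, base], ignore_index=True)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.index)
        _, chi2, p = km_logrank(groups, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_km_curves_non_increasing_and_label_swap_invariant(self):
        rng = np.random.default_rng(0)
        surv = pd.DataFrame(
            {"os_time": rng.exponential(5, 40), "os_event": rng.integers(0, 2, 40)}
        )
        surv.loc[surv.index[:5], "os_event"] = 1
        groups = pd.Series(rng.choice(["x", "y"], 40), index=surv.index)
        curves, _, p1 = km_logrank(groups, surv)
        for c in curves.values():
            assert (np.diff(c.iloc[:, 0]) <= 1e-12).all()
        _, _, p2 = km_logrank(groups.map({"x": "y", "y": "x"}), surv)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_power_under_strong_effect(self):
        """Simulated hazard ratio 3, n = 400: p < 0.001 in nearly all reps."""
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(50 + rep)
            grp = pd.Series(rng.integers(0, 2, 400))
            hazard = 0.1 * np.exp(np.log(3) * grp)
            T = rng.exponential(1 / hazard)
            C = rng.exponential(50, size=400)
            surv = pd.DataFrame(
                {"os_time": np.minimum(T, C), "os_event": (T <= C).astype(int)}
            )
            _, _, p = km_logrank(grp.map({0: "lo", 1: "hi"}), surv)
            hits += p < 0.001
        assert hits >= int(0.95 * reps)

    def test_single_group_rejected(self):
        surv = pd.DataFrame({"os_time": [1, 2], "os_event": [1, 1]})
        with pytest.raises(ValueError):
            km_logrank(pd.Series(["A", "A"], index=surv.index), surv)


class TestCoxFit:
    def test_three_subject_brute_force_likelihood(self):
        """Partial-likelihood maximum matches a 1-D grid-search oracle."""
        df = pd.DataFrame(
            {"os_time": [1.0, 2.0, 3.0], "os_event": [1, 1, 1],
             "x": [0.0, 2.0, 1.0]}
        )
        res = cox_fit(df, ["x"])

        x = df["x"].to_numpy()

        def negll(b):
            # risk sets by event order: {0,1,2}, {1,2}, {2}
            return -(
                b * x[0] - np.log(np.exp(b * x).sum())
                + b * x[1] - np.log(np.exp(b * x[1:]).sum())
            )

        grid = np.linspace(-5, 5, 200001)
        oracle = grid[np.argmin([negll(b) for b in grid])]
        assert res.loc["x", "beta"] == pytest.approx(oracle, abs=1e-4)

    def test_null_coverage(self):
        """beta = 0: the 95% CI covers HR = 1 in about 95% of replicates."""
        cover = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            x = pd.Series(rng.normal(size=120))
            sv = synthetic.simulate_survival(
                x, synthetic.SimSurvivalConfig(beta_stem=0.0, censor_rate=0.02,
                                               seed=2000 + rep),
            )
            res = cox_fit(sv.assign(score=x), ["score"])
            cover += res.loc["score", "CI_low"] <= 1.0 <= res.loc["score", "CI_high"]
        assert 0.90 * reps <= cover <= 0.99 * reps

    def test_planted_continuous_effect_recovered(self):
        rng = np.random.default_rng(11)
        x = pd.Series(rng.normal(size=1000))
        sv = synthetic.simulate_survival(
            x, synthetic.SimSurvivalConfig(beta_stem=-0.105, baseline_hazard=0.1,
                                           censor_rate=0.02, seed=12),
        )
        res = cox_fit(sv.assign(score=x), ["score"])
        assert 0.85 <= res.loc["score", "HR"] <= 0.95

    def test_negated_covariate_inverts_hr(self):
        rng = np.random.default_rng(13)
        x = pd.Series(rng.normal(size=200))
        sv = synthetic.simulate_survival(
            x, synthetic.SimSurvivalConfig(beta_stem=0.4, seed=14)
        )
        r1 = cox_fit(sv.assign(v=x), ["v"])
        r2 = cox_fit(sv.assign(v=-x), ["v"])
        assert r1.loc["v", "HR"] == pytest.approx(1 / r2.loc["v", "HR"], rel=1e-6)

    def test_multivariate_stage_reference_level(self):
        rng = np.random.default_rng(15)
        n = 300
        stage = rng.choice(["I", "II", "III", "IV"], size=n)
        x = pd.Series(rng.normal(size=n))
        sv = synthetic.simulate_survival(
            x, synthetic.SimSurvivalConfig(beta_stem=0.3, seed=16)
        )
        df = sv.assign(score=x, stage=stage, age=rng.normal(60, 8, n))
        res = cox_fit(df, ["score", "stage", "age"], mode="multivariate")
        assert {"stage_II", "stage_III", "stage_IV"} <= set(res.index)
        assert "stage_I" not in res.index  # level I is the reference

    def test_too_few_events_rejected(self):
        df = pd.DataFrame(
            {"os_time": [1.0, 2.0, 3.0], "os_event": [1, 0, 0],
             "a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]}
        )
        with pytest.raises(ValueError):
            cox_fit(df, ["a", "b"], mode="multivariate")


class TestFdrAdjust:
    def test_hand_computed_bh(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestMetaFixed:
    def test_hand_computed_two_study_example(self):
        m = meta_fixed([-0.1, -0.2], [0.1, 0.2])
        assert m.pooled_beta == pytest.approx(-0.12, abs=1e-12)
        assert m.pooled_se == pytest.approx(np.sqrt(1 / 125.0), rel=1e-9)
        assert m.pooled_se == pytest.approx(0.0894, abs=5e-5)

    def test_identical_studies_shrink_se_by_sqrt2(self):
        m = meta_fixed([0.3, 0.3], [0.15, 0.15])
        assert m.pooled_beta == pytest.approx(0.3)
        assert m.pooled_se == pytest.approx(0.15 / np.sqrt(2))

    def test_equal_se_reduces_to_mean(self):
        betas = [0.1, -0.4, 0.25]
        m = meta_fixed(betas, [0.2] * 3)
        assert m.pooled_beta == pytest.approx(np.mean(betas))

    def test_dominant_study_limit(self):
        m = meta_fixed([0.5, -3.0], [1e-4, 10.0])
        assert m.pooled_beta == pytest.approx(0.5, abs=1e-3)

    def test_single_study_passthrough(self):
        m = meta_fixed([0.2], [0.1])
        assert m.pooled_beta == pytest.approx(0.2)
        assert "single study" in m.note

    def test_matches_statsmodels_fixed_effects(self):
        """Cross-check pooled estimate/SE against statsmodels' combiner."""
        rng = np.random.default_rng(2)
        betas = rng.normal(0, 0.3, size=5)
        ses = rng.uniform(0.05, 0.3, size=5)
        m = meta_fixed(betas, ses)
        sm = combine_effects(betas, ses**2)
        df = sm.summary_frame()
        assert m.pooled_beta == pytest.approx(df.loc["fixed effect", "eff"], rel=1e-9)
        assert m.pooled_se == pytest.approx(df.loc["fixed effect", "sd_eff"], rel=1e-9)

    def test_pooled_se_not_above_best_study(self):
        m = meta_fixed([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert m.pooled_se <= 0.1

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([0.1], [0.0])


def synth_cohorts(beta_planted, n_cohorts=4, n=300, n_null=5, seed=0):
    """Cohorts with one planted prognostic gene among null genes."""
    genes = ["planted"] + [f"null{i}" for i in range(n_null)]
    cohorts = {}
    for c in range(n_cohorts):
        rng = np.random.default_rng(seed * 1000 + c)
        expr = pd.DataFrame(
            rng.normal(size=(len(genes), n)), index=genes,
            columns=[f"c{c}s{i}" for i in range(n)],
        )
        x = expr.loc["planted"]
        sv = synthetic.simulate_survival(
            x,
            synthetic.SimSurvivalConfig(
                beta_stem=beta_planted, baseline_hazard=0.1,
                censor_rate=0.02, seed=seed * 1000 + 500 + c,
            ),
        )
        clinical = sv.copy()
        clinical["age"] = rng.normal(62, 9, n)
        cohorts[f"cohort{c}"] = (expr, clinical)
    return cohorts, genes


class TestPrognosticGeneScreen:
    def test_planted_risk_gene_selected(self):
        cohorts, genes = synth_cohorts(beta_planted=0.4, seed=1)
        res = prognostic_gene_screen(cohorts, genes, direction="risk")
        assert res.loc["planted", "selected"]
        assert res.loc["planted", "meta_p"] < 1e-5
        assert res.loc["planted", "meta_HR"] > 1

    def test_null_genes_not_selected(self):
        cohorts, genes = synth_cohorts(beta_planted=0.4, n_null=20, seed=2)
        res = prognostic_gene_screen(cohorts, genes, direction="risk")
        nulls = res.drop(index="planted")
        assert not nulls["selected"].any()

    def test_two_of_four_insufficient_at_k3(self):
        """A gene significant in only 2 of 4 cohorts fails min_cohorts=3."""
        cohorts, genes = synth_cohorts(beta_planted=0.5, seed=3)
        # null out the planted effect in two cohorts by shuffling expression
        for name in ["cohort2", "cohort3"]:
            expr, clin = cohorts[name]
            rng = np.random.default_rng(9)
            expr.loc["planted"] = rng.permutation(expr.loc["planted"].to_numpy())
        res = prognostic_gene_screen(cohorts, genes, direction="risk",
                                     min_cohorts=3)
        assert res.loc["planted", "n_cohorts_significant"] <= 2
        assert not res.loc["planted", "selected"]

    def test_protective_direction_filter(self):
        cohorts, genes = synth_cohorts(beta_planted=-0.4, seed=4)
        res = prognostic_gene_screen(cohorts, genes, direction="protective")
        assert res.loc["planted", "selected"]
        assert res.loc["planted", "meta_HR"] < 1
        # the same gene must fail the opposite direction
        res_risk = prognostic_gene_screen(cohorts, genes, direction="risk")
        assert not res_risk.loc["planted", "selected"]
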