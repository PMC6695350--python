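import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import gammaln

import dielgate as dg
from dielgate.core import ValidationError
from dielgate.de import (
    DesignSpec,
    build_design_matrix,
    fit_and_test,
    make_design,
)


def _nb_nll(beta, y, X, offset, alpha):
    """Independent NB log-likelihood used as brute-force oracle."""
    mu = np.exp(X @ beta + offset)
    size = 1.0 / alpha
    ll = (
        gammaln(y + size)
        - gammaln(size)
        - gammaln(y + 1)
        + size * np.log(size / (size + mu))
        + y * np.log(mu / (size + mu))
    )
    return -ll.sum()


class TestDesigns:
    def test_contrast_width_checked(self):
        with pytest.raises(ValidationError, match="width"):
            DesignSpec("x", ["a", "b"], {"c": np.array([1.0, 0.0, 0.0])})

    def test_analysis2_design_is_cell_means(self, strong_sim):
        cm, _ = strong_sim
        X = build_design_matrix(cm.samples, make_design("analysis2"))
        assert X.sum(axis=1).tolist() == [1.0] * cm.n_samples
        assert X.sum(axis=0).tolist() == [4.0, 4.0, 4.0, 4.0]

    def test_analysis3_interaction_column(self, strong_sim):
        cm, _ = strong_sim
        X = build_design_matrix(cm.samples, make_design("analysis3"))
        pm_heat = (
            (cm.samples["time"] == "PM") & (cm.samples["condition"] == "heat")
        ).to_numpy(float)
        assert np.array_equal(X[:, 3], pm_heat)

    def test_unknown_analysis_rejected(self):
        with pytest.raises(ValidationError, match="unknown analysis"):
            make_design("analysis9")


class TestDispersions:
    def test_poisson_counts_estimated_near_zero(self):
        cfg = dg.SimulationConfig(
            n_genes=1000,
            archetype_proportions={"null": 1.0},
            dispersion_log_mean=(np.log(1e-9), 1e-12),
            seed=2,
        )
        cm, _ = dg.simulate_experiment(cfg)
        alpha = dg.estimate_dispersions(cm)
        assert np.median(alpha) <= 0.01

    def test_alpha_point_two_recovered_within_band(self):
        cfg = dg.SimulationConfig(
            n_genes=1000,
            archetype_proportions={"null": 1.0},
            dispersion_log_mean=(np.log(0.2), 1e-12),
            seed=2,
        )
        cm, _ = dg.simulate_experiment(cfg)
        alpha = dg.estimate_dispersions(cm)
        assert 0.1 <= np.median(alpha) <= 0.4

    def test_constant_within_group_counts_at_floor_raw(self, tiny_counts):
        counts = pd.DataFrame(
            {"s1": [5, 9], "s2": [5, 9], "s3": [7, 2], "s4": [7, 2]},
            index=["g1", "g2"],
        )
        samples = tiny_counts.samples.copy()
        samples["time"] = ["AM", "AM", "PM", "PM"]
        samples["condition"] = ["control", "control", "control", "control"]
        cm = dg.CountMatrix(counts, samples)
        # no shrinkage: zero within-group variance drives raw MoM to the floor
        alpha = dg.estimate_dispersions(cm, shrink_weight=0.0)
        assert (alpha <= 1e-8).all()

    def test_single_replicate_needs_fixed_alpha(self):
        cfg = dg.SimulationConfig(n_genes=20, seed=0)
        _, truth = dg.simulate_experiment(cfg)
        circ = dg.simulate_circadian_replicate(
            truth, pd.Series(True, index=truth.index), cfg
        )
        with pytest.raises(ValidationError, match="replicates"):
            dg.estimate_dispersions(circ)
        alpha = dg.estimate_dispersions(circ, fixed_alpha=0.05)
        assert (alpha == 0.05).all()


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(dg.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert dg.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(dg.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagated_and_excluded(self):
        out = dg.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        # m = 2 tests only
        assert np.allclose(out[[0, 2]], [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            dg.bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        adj = dg.bh_adjust(p)
        assert ((adj >= p - 1e-12) & (adj <= 1 + 1e-12)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, expected, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(dg.bh_adjust(p), expected)


class TestFitAndTest:
    def test_identical_groups_give_null_results(self, tiny_counts):
        counts = pd.DataFrame(
            {
                "s1": [20, 7],
                "s2": [20, 7],
                "s3": [20, 7],
                "s4": [20, 7],
            },
            index=["g1", "g2"],
        )
        samples = tiny_counts.samples.copy()
        samples["time"] = ["AM"] * 4
        samples["condition"] = ["control", "control", "heat", "heat"]
        cm = dg.CountMatrix(counts, samples)
        res = fit_and_test(
            cm, make_design("analysis1_AM"), fixed_alpha=0.05
        )["heat_vs_control"]
        assert np.allclose(res.table["log2FC"], 0.0, atol=1e-8)
        assert (res.table["p"] > 0.99).all()

    def test_lfc_matches_bruteforce_mle(self):
        """Oracle equivalence on a 20-gene fixture: IRLS estimates agree
        with generic numerical NB likelihood maximization to 1e-4 relative."""
        cfg = dg.SimulationConfig(n_genes=20, seed=3)
        cm, _ = dg.simulate_experiment(cfg)
        factors = dg.size_factors(cm)
        disp = dg.estimate_dispersions(cm, factors)
        design = make_design("analysis2")
        res = fit_and_test(cm, design, factors=factors, dispersions=disp)
        X = build_design_matrix(cm.samples, design)
        offset = np.log(factors.to_numpy())
        Y = cm.counts.to_numpy(float)
        c = design.contrasts["AMheat_vs_AMctrl"]
        for i in range(cm.n_genes):
            b0 = np.full(4, np.log(Y[i].mean() + 0.5))
            opt = minimize(
                _nb_nll,
                b0,
                args=(Y[i], X, offset, disp.iloc[i]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            expected = (opt.x @ c) / np.log(2)
            observed = res["AMheat_vs_AMctrl"].table["log2FC"].iloc[i]
            assert observed == pytest.approx(expected, rel=1e-4, abs=1e-6)

    def test_interaction_centered_for_parallel_significant_for_gated(self):
        """Simulation with known truth: cat17 genes (equal AM/PM response)
        produce interaction estimates centered on zero, cat13 genes
        (AM-only) produce significant interactions at strong effects."""
        # up/down-balanced mixture keeps median-of-ratios normalization
        # composition-neutral within every group
        cfg = dg.SimulationConfig(
            n_genes=800,
            archetype_proportions={
                "cat17": 0.1, "cat18": 0.1, "cat13": 0.1, "cat14": 0.1,
                "null": 0.6,
            },
            seed=9,
        )
        cm, truth = dg.simulate_experiment(cfg)
        cm = dg.filter_low_counts(cm, 10)
        truth = truth.loc[cm.genes]
        de3 = dg.run_analysis3(cm)
        parallel = truth["archetype"].isin(["cat17", "cat18"]).to_numpy()
        am_only = truth["archetype"].isin(["cat13", "cat14"]).to_numpy()
        assert abs(de3.table.loc[parallel, "log2FC"].mean()) < 0.15
        sig = de3.table["padj"] < 0.05
        assert sig[am_only].mean() >= 0.8
        assert sig[parallel].mean() <= 0.1

    def test_contrast_direction_equivariance(self, strong_sim):
        cm, _ = strong_sim
        factors = dg.size_factors(cm)
        disp = dg.estimate_dispersions(cm, factors)
        design = make_design("analysis2")
        flipped = DesignSpec(
            "analysis2",
            design.coef_names,
            {"AMctrl_vs_AMheat": -design.contrasts["AMheat_vs_AMctrl"]},
        )
        fwd = fit_and_test(cm, design, factors=factors, dispersions=disp)[
            "AMheat_vs_AMctrl"
        ]
        rev = fit_and_test(cm, flipped, factors=factors, dispersions=disp)[
            "AMctrl_vs_AMheat"
        ]
        assert np.allclose(fwd.table["log2FC"], -rev.table["log2FC"])
        assert np.allclose(fwd.table["p"].dropna(), rev.table["p"].dropna())

    def test_power_monotone_in_effect_size(self):
        rates = []
        for lfc in (0.5, 1.0, 2.0):
            cfg = dg.SimulationConfig(
                n_genes=500,
                archetype_proportions={"cat17": 0.3, "null": 0.7},
                heat_log2fc=lfc,
                seed=12,
            )
            cm, _ = dg.simulate_experiment(cfg)
            cm = dg.filter_low_counts(cm, 10)
            res = dg.run_analysis2(cm)["AMheat_vs_AMctrl"]
            rates.append((res.table["padj"] < 0.05).mean())
        assert rates[0] < rates[1] <= rates[2]

    def test_analysis1_analysis2_agree_on_strong_effects(self, strong_sim, strong_de):
        """The per-time model and the four-group model differ only in
        variance pooling; their AM heat calls agree on >= 90% of
        strong-effect genes."""
        cm, truth = strong_sim
        th = dg.Thresholds()
        sig1 = strong_de["de1"]["AM"].significant(th)
        sig2 = strong_de["de2"]["AMheat_vs_AMctrl"].significant(th)
        strong = truth["heat_am_log2fc"].abs() >= 2.0
        agree = (sig1 == sig2)[strong.to_numpy()]
        assert agree.mean() >= 0.90


def test_agrees_with_independent_nb_engine():
    """Cross-check against an independent negative-binomial DE engine:
    per-time log2 fold changes correlate near-perfectly and the dual-
    threshold significance calls coincide on simulated data."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    cfg = dg.SimulationConfig(n_genes=300, seed=5)
    cm, _ = dg.simulate_experiment(cfg)
    cm = dg.filter_low_counts(cm, 10)
    am = cm.subset_samples(cm.samples["time"] == "AM")
    dds = DeseqDataSet(
        counts=am.counts.T, metadata=am.samples, design="~condition", quiet=True
    )
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "heat", "control"], quiet=True)
    stats.summary()
    mine = dg.run_analysis1(cm)["AM"]
    merged = mine.table.join(
        stats.results_df, how="inner", lsuffix="_mine", rsuffix="_ref"
    )
    r = np.corrcoef(merged["log2FC"], merged["log2FoldChange"])[0, 1]
    assert r > 0.99
    th = dg.Thresholds()
    calls_ref = (merged["padj_ref"] < th.padj_cut) & (
        merged["log2FoldChange"].abs() > th.lfc_cut
    )
    agreement = (mine.significant(th).loc[merged.index] == calls_ref).mean()
    assert agreement >= 0.95


def test_type_one_error_controlled_on_null_simulation():
    """All-null simulation: raw p < 0.05 fraction stays near nominal."""
    cfg = dg.SimulationConfig(
        n_genes=5000, archetype_proportions={"null": 1.0}, seed=7
    )
    cm, _ = dg.simulate_experiment(cfg)
    cm = dg.filter_low_counts(cm, 10)
    res = dg.run_analysis1(cm)
    for time in ("AM", "PM"):
        frac = (res[time].table["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09
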