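"""Trajectory models, sequential tests, classification, arrest-time conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kodep import (
    InsertionTrajectory,
    aggregate_insertions,
    classify_library,
    classify_trajectory,
    estimate_k0,
    fit_trajectory_models,
    log_relative_abundance,
    overabundance_from_arrest,
    simulate_library_from_truth,
)
from kodep.tfnseq import informative_fractions, stage_pvalues

TIMES = np.arange(0.0, 24.1, 2.0)


def _fits(y, k0, **kw):
    return fit_trajectory_models(TIMES, y, k0, **kw)


class TestLogRelativeAbundance:
    def test_constant_ratio_gives_zero(self):
        traj = InsertionTrajectory("g", TIMES, np.full(13, 50.0), np.full(13, 1000.0))
        _, y, _ = log_relative_abundance(traj)
        assert np.allclose(y, 0.0)

    def test_halving_counts_decline_by_ln2(self):
        counts = 4096.0 / 2 ** np.arange(6)
        traj = InsertionTrajectory("g", TIMES[:6], counts, np.full(6, 10**6))
        _, y, _ = log_relative_abundance(traj, pseudocount=0.0)
        assert np.allclose(np.diff(y), -np.log(2))

    def test_all_zero_counts_unclassifiable(self):
        traj = InsertionTrajectory("g", TIMES, np.zeros(13), np.full(13, 1000.0))
        assert not traj.classifiable

    def test_no_effect_gene_stays_near_zero_at_depth(self, k0):
        """Binomial noise at depth 1e6 keeps |y| small for a neutral gene."""
        truth = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)],
                              "class": "no_effect", "slope": np.nan,
                              "arrest_time_h": np.nan})
        counts = simulate_library_from_truth(truth, TIMES, 10**6, k0, seed=0)
        mat = counts.drop(columns="gene_id").to_numpy(dtype=float)
        ok = 0
        for row in mat:
            traj = InsertionTrajectory("g", TIMES, row, mat.sum(axis=0))
            _, y, _ = log_relative_abundance(traj)
            ok += np.abs(y).max() < 0.05
        assert ok >= 95


class TestModelFits:
    def test_noiseless_breakpoint_identified(self, k0):
        y = -k0 * np.clip(TIMES - 4.0, 0, None)
        fits = _fits(y, k0)
        assert fits.arrest_time == pytest.approx(4.0, abs=1e-4)
        assert fits.rss["overabundant"] < 1e-12

    def test_flat_data_all_models_degenerate(self, k0):
        fits = _fits(np.zeros(13), k0)
        assert all(r < 1e-12 for r in fits.rss.values())
        assert fits.slope == pytest.approx(0.0, abs=1e-9)

    def test_grid_refinement_matches_fine_grid_oracle(self, k0):
        """Breakpoint from grid+refine vs exhaustive 1-ms grid, noiseless."""
        rng = np.random.default_rng(42)
        fine = np.arange(0.0, TIMES[-1] + 1e-9, 0.001)
        for _ in range(100):
            T_true = rng.uniform(0.5, 20.0)
            y = -k0 * np.clip(TIMES - T_true, 0, None)
            fits = _fits(y, k0)
            # brute-force oracle: profile the intercept at every fine-grid T
            rss_fine = []
            for T in fine:
                x = -k0 * np.clip(TIMES - T, 0, None)
                r = y - x
                rss_fine.append(np.sum((r - r.mean()) ** 2))
            T_oracle = fine[int(np.argmin(rss_fine))]
            assert abs(fits.arrest_time - T_oracle) < 0.01

    @given(st.lists(st.floats(-5, 5), min_size=13, max_size=13))
    @settings(max_examples=50, deadline=None)
    def test_nesting_against_the_constant_model(self, ys):
        """M1 and M2 both contain M0, so neither can fit worse than it."""
        fits = _fits(np.array(ys), float(np.log(2)))
        assert fits.rss["sufficient"] <= fits.rss["no_effect"] + 1e-9
        assert fits.rss["overabundant"] <= fits.rss["no_effect"] + 1e-9


class TestClassification:
    def test_flat_trajectory_is_no_effect(self, k0):
        """A neutral (recF-like) gene with pure sampling noise is no-effect."""
        rng = np.random.default_rng(2)
        y = rng.normal(0, 0.03, 13)
        out = classify_trajectory(_fits(y, k0), k0)
        assert out.model == "no_effect"

    def test_immediate_decline_is_sufficient(self, k0):
        """dnaA-like immediate arrest: slope k0 from t=0, overabundance 1.0."""
        rng = np.random.default_rng(1)
        y = -k0 * TIMES + rng.normal(0, 0.05, 13)
        out = classify_trajectory(_fits(y, k0), k0)
        assert out.model == "sufficient"
        assert out.log10_o == 0.0

    def test_ftsN_scale_recovery(self, k0):
        """True log10 o = 2.6 at depth 1e5: recovered within 0.2 in >=90% of runs."""
        T_true = 2.6 * np.log(10) / k0
        n_ok = 0
        n_runs = 50
        for seed in range(n_runs):
            truth = pd.DataFrame({
                "gene_id": [f"bg{i}" for i in range(99)] + ["ftsN"],
                "class": ["no_effect"] * 99 + ["overabundant"],
                "slope": np.nan,
                "arrest_time_h": [np.nan] * 99 + [T_true],
            })
            counts = simulate_library_from_truth(truth, TIMES, 10**5, k0, seed=seed)
            res = classify_library(counts, k0=k0, normalization="none")
            row = res.set_index("gene_id").loc["ftsN"]
            if row["class"] == "overabundant" and abs(row["log10_o"] - 2.6) < 0.2:
                n_ok += 1
        assert n_ok >= 0.9 * n_runs

    def test_unclassifiable_with_too_few_nonzero_fractions(self, k0):
        counts = pd.DataFrame({"gene_id": ["g"],
                               **{f"t_{t:g}": [0] for t in TIMES}})
        counts.loc[0, "t_0"] = 10
        big = pd.concat([counts] * 1 + [
            pd.DataFrame({"gene_id": [f"f{i}"],
                          **{f"t_{t:g}": [100] for t in TIMES}})
            for i in range(5)
        ], ignore_index=True)
        res = classify_library(big, k0=k0, normalization="none")
        assert res.set_index("gene_id").loc["g", "class"] == "unclassifiable"

    def test_boundary_small_T_estimates_near_zero(self, k0):
        """As true T -> 0 the estimated log10 o approaches 0 when called
        overabundant, and otherwise the gene lands in the sufficient class."""
        rng = np.random.default_rng(7)
        for T_true in (0.0, 0.2):
            y = -k0 * np.clip(TIMES - T_true, 0, None) + rng.normal(0, 0.05, 13)
            out = classify_trajectory(_fits(y, k0), k0)
            assert out.model in ("sufficient", "overabundant")
            log10_o = out.log10_o if np.isfinite(out.log10_o) else 0.0
            assert log10_o < 0.25


class TestInformativeFractions:
    def test_trailing_zeros_censored_after_first(self):
        counts = np.array([50, 20, 5, 1, 0, 0, 0])
        mask = informative_fractions(counts)
        assert mask.tolist() == [True] * 5 + [False] * 2

    def test_interior_zero_kept(self):
        counts = np.array([50, 0, 5, 1, 0, 0])
        assert informative_fractions(counts).tolist() == [True] * 5 + [False]


class TestConversions:
    @pytest.mark.parametrize("k0_,T,expected", [
        (np.log(2), 0.0, 1.0),
        (np.log(2), 2.0, 4.0),
    ])
    def test_overabundance_from_arrest(self, k0_, T, expected):
        assert overabundance_from_arrest(k0_, T) == pytest.approx(expected)

    def test_dnaN_arrest_time_maps_to_log10_o_1p5(self):
        """T = 4.983 h at k0 = ln2/h inverts to the dnaN-scale log10 o = 1.5."""
        o = overabundance_from_arrest(np.log(2), 4.983)
        assert np.log10(o) == pytest.approx(1.5, abs=0.001)

    def test_negative_arrest_time_rejected(self):
        with pytest.raises(ValueError):
            overabundance_from_arrest(np.log(2), -1.0)


class TestEstimateK0:
    def test_config_passthrough(self):
        assert estimate_k0(k0=0.9) == (0.9, "config")

    def test_spikein_recovery(self):
        t = np.arange(0, 12.1, 2.0)
        totals = 1e6 * np.exp(0.85 * t)
        k0_hat, source = estimate_k0(times=t, absolute_totals=totals)
        assert source == "spike-in"
        assert k0_hat == pytest.approx(0.85, rel=0.02)

    def test_no_path_raises(self):
        with pytest.raises(ValueError):
            estimate_k0()


class TestAggregation:
    def test_insertions_summed_per_gene(self):
        df = pd.DataFrame({
            "gene_id": ["a", "a", "b"],
            "position": [10, 200, 5],
            "strand": ["+", "-", "+"],
            "t_0": [1, 2, 3], "t_2": [4, 5, 6], "t_4": [0, 1, 0], "t_6": [1, 0, 2],
        })
        out = aggregate_insertions(df)
        assert out.set_index("gene_id").loc["a"].tolist() == [3, 9, 1, 1]


class TestLibraryTypeI:
    def test_stage1_false_positive_rate_controlled(self, k0):
        """Raw stage-1 rejections on a pure-null library stay below 1.5*alpha."""
        truth = pd.DataFrame({"gene_id": [f"g{i}" for i in range(400)],
                              "class": "no_effect", "slope": np.nan,
                              "arrest_time_h": np.nan})
        counts = simulate_library_from_truth(truth, TIMES, 10**5, k0, seed=17)
        res = classify_library(counts, k0=k0, multiple_testing="none",
                               normalization="none")
        rate = (res["class"] != "no_effect").mean()
        assert rate <= 1.5 * 0.05
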