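"""Dilution reconstruction, growth rates, arrest detection, overabundance."""

import numpy as np
import pytest

from kodep import (
    CellTrack,
    LineageSimConfig,
    LineageTree,
    analyze_lineage,
    areal_growth_rate,
    detect_arrest,
    dilution_concentration,
    fitness_landscape,
    fluorescence_dilution_check,
    overabundance_from_lineage,
    simulate_lineage,
    total_area_series,
)
from kodep.lineage import ROOT_SENTINEL, aggregate_growth_rate


class TestDilutionConcentration:
    @pytest.mark.parametrize("C0,V0,V,expected", [
        (1.0, 1.0, 1.0, 1.0),
        (1.0, 1.0, 2.0, 0.5),
        (2.0, 1.0, 8.0, 0.25),
    ])
    def test_values(self, C0, V0, V, expected):
        assert dilution_concentration(C0, V0, np.array([V]))[0] == expected

    def test_rejects_nonpositive_volumes(self):
        with pytest.raises(ValueError):
            dilution_concentration(1.0, 0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            dilution_concentration(1.0, 1.0, np.array([-2.0]))


class TestArealGrowthRate:
    def test_exact_exponential(self):
        t = np.arange(0, 3.01, 0.1)
        track = CellTrack(0, ROOT_SENTINEL, t, 2.0 * np.exp(0.7 * t))
        k = areal_growth_rate(track, window=5)
        assert np.allclose(k, 0.7, atol=1e-9)

    def test_constant_area_zero_rate(self):
        t = np.arange(0, 1.01, 0.1)
        track = CellTrack(0, ROOT_SENTINEL, t, np.full(t.size, 3.0))
        assert np.allclose(areal_growth_rate(track, window=3), 0.0, atol=1e-12)

    def test_short_track_rejected(self):
        track = CellTrack(0, ROOT_SENTINEL, [0.0, 0.1], [1.0, 1.1])
        with pytest.raises(ValueError):
            areal_growth_rate(track, window=5)

    def test_noisy_simulation_mean_rate_near_k0(self, k0):
        """Per-cell mean areal rates scatter around k0 under 10% rate noise."""
        tree = simulate_lineage(LineageSimConfig(
            o_true=np.inf, t_max=4.0, growth_noise_cv=0.1, seed=4))
        means = [areal_growth_rate(tr, window=5).mean()
                 for tr in tree.tracks.values() if tr.n_samples >= 5]
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - k0) < 3 * max(se, 0.01)


class TestTotalAreaSeries:
    def test_single_cell(self):
        t = np.arange(0, 1.01, 0.1)
        a = np.exp(t)
        tree = LineageTree({0: CellTrack(0, ROOT_SENTINEL, t, a)}, [0])
        times, totals = total_area_series(tree)
        assert np.allclose(times, t) and np.allclose(totals, a)

    def test_continuous_across_division(self, clean_lineage_o4, k0):
        """Conserved division keeps the total-area series exactly exponential."""
        times, totals = total_area_series(clean_lineage_o4)
        growing = times <= 2.0
        assert np.allclose(totals[growing], totals[0] * np.exp(k0 * times[growing]),
                           rtol=1e-9)

    def test_matches_simulator_bookkeeping(self):
        tree = simulate_lineage(LineageSimConfig(
            o_true=8.0, t_max=5.0, growth_noise_cv=0.1,
            division_asymmetry_cv=0.1, seed=6))
        grid, internal = tree.meta["internal_totals"]
        times, totals = total_area_series(tree)
        assert np.allclose(times, grid[: times.size])
        assert np.allclose(totals, internal[: times.size], rtol=1e-9)

    def test_inconsistent_parentage_rejected(self):
        with pytest.raises(ValueError, match="unknown parent"):
            LineageTree({1: CellTrack(1, 99, [0.0], [1.0])}, [])


class TestDetectArrest:
    def test_constant_growth_never_arrests(self, k0):
        t = np.arange(0, 10, 0.2)
        assert detect_arrest(t, np.full(t.size, k0), k0) is None

    def test_step_to_zero_detected_at_step(self, k0):
        t = np.arange(0, 10, 0.2)
        k = np.where(t < 4.0, k0, 0.0)
        T = detect_arrest(t, k, k0, frac=0.5)
        assert T == pytest.approx(4.0, abs=0.2)

    def test_invalid_k0(self):
        with pytest.raises(ValueError):
            detect_arrest(np.arange(3.0), np.zeros(3), k0=0.0)


class TestOverabundance:
    def test_no_growth_gives_unity(self):
        tree = simulate_lineage(LineageSimConfig(o_true=1.0, t_max=1.0, seed=0))
        res = overabundance_from_lineage(tree, T=0.0)
        assert res.o_elongation == pytest.approx(1.0)

    def test_quadrupled_area_gives_four(self, clean_lineage_o4):
        res = overabundance_from_lineage(clean_lineage_o4, T=2.0)
        assert res.o_elongation == pytest.approx(4.0, rel=1e-9)

    def test_dnaA_like_septation_is_one(self):
        """Four progenitors arresting without division: o_septation = 1."""
        tree = simulate_lineage(LineageSimConfig(
            o_true=1.0, t_max=1.0, n_progenitors=4, seed=0))
        times, _ = total_area_series(tree)
        res = overabundance_from_lineage(tree, T=times[-1])
        assert res.n_progenitors == 4 and res.n_cells == 4
        assert res.o_septation == pytest.approx(1.0)
        assert res.log10_o_septation == pytest.approx(0.0)

    def test_elongation_consistent_with_arrest_time(self, clean_lineage_o4, k0):
        """o_elongation = exp(k0 T) within one sampling step of growth."""
        res, _ = analyze_lineage(clean_lineage_o4, k0=k0)
        assert res.arrest_time is not None
        one_step = np.exp(k0 * 0.1)
        ratio = res.o_elongation / np.exp(k0 * res.arrest_time)
        assert 1 / one_step - 1e-9 <= ratio <= one_step + 1e-9

    def test_monotone_in_arrest_time(self, clean_lineage_o4):
        times, _ = total_area_series(clean_lineage_o4)
        os = [overabundance_from_lineage(clean_lineage_o4, float(t)).o_elongation
              for t in times[::5]]
        assert np.all(np.diff(os) >= -1e-12)


class TestFitnessLandscape:
    def test_step_landscape_zero_noise(self, k0):
        tree = simulate_lineage(LineageSimConfig(o_true=8.0, t_max=5.0, seed=1))
        land = fitness_landscape(tree, k0=k0)
        high = land.rel_abundance > 1.2 / 8.0
        frac_growing = (land.growth_rate[high] > 0.5 * k0).mean()
        assert frac_growing > 0.95
        low = land.rel_abundance < 1 / 8.0 / 1.2
        assert np.all(land.growth_rate[low] < 0.5 * k0)

    def test_sufficient_landscape_collapses(self):
        tree = simulate_lineage(LineageSimConfig(o_true=1.0, t_max=1.0, seed=0))
        land = fitness_landscape(tree, k0=np.log(2))
        assert land.rel_abundance.min() > 0.8

    def test_arrest_abundance_recovers_threshold(self, k0):
        """Fitted arrest abundance near 1/o_true across seeds despite noise."""
        o_true = 6.0
        rels = []
        for seed in range(20):
            tree = simulate_lineage(LineageSimConfig(
                o_true=o_true, t_max=6.0, growth_noise_cv=0.1,
                division_asymmetry_cv=0.1, n_progenitors=3, seed=seed))
            land = fitness_landscape(tree, k0=k0)
            assert land.arrest_rel_abundance is not None
            rels.append(land.arrest_rel_abundance)
        assert np.median(rels) == pytest.approx(1 / o_true, rel=0.15)


class TestFluorescenceDilution:
    def test_conserved_protein_fits_dilution_model(self, clean_lineage_o4):
        chk = fluorescence_dilution_check(clean_lineage_o4)
        assert chk.rel_rms < 1e-6
        assert chk.n_arrested > 0 and chk.arrested_max_drift < 1e-9

    def test_synthesis_control_breaks_the_fit(self):
        """Injected synthesis is a negative control: deviation grows with time."""
        tree = simulate_lineage(LineageSimConfig(
            o_true=np.inf, t_max=4.0, synthesis_rate=0.3, seed=1))
        chk = fluorescence_dilution_check(tree)
        assert chk.rel_rms > 0.05

    def test_missing_fluorescence_rejected(self):
        t = np.arange(0, 1.01, 0.1)
        tree = LineageTree({0: CellTrack(0, ROOT_SENTINEL, t, np.exp(t))}, [0])
        with pytest.raises(ValueError, match="fluorescence"):
            fluorescence_dilution_check(tree)


class TestRecovery:
    def test_murA_scale_overabundance_recovered(self, k0):
        """Imaging-scale recovery at log10 o = 1.1 with 10% growth noise."""
        recs = []
        for seed in range(20):
            tree = simulate_lineage(LineageSimConfig(
                o_true=10**1.1, t_max=6.5, growth_noise_cv=0.1,
                division_asymmetry_cv=0.1, n_progenitors=3, seed=seed))
            res, _ = analyze_lineage(tree, k0=k0)
            assert res.arrest_time is not None
            recs.append(np.log10(res.o_elongation))
        assert abs(np.median(recs) - 1.1) < 0.1

    def test_unbounded_lineage_never_arrests(self, k0):
        tree = simulate_lineage(LineageSimConfig(
            o_true=np.inf, t_max=5.0, growth_noise_cv=0.1, seed=3))
        t, k = aggregate_growth_rate(tree)
        assert detect_arrest(t, k, k0=k0) is None
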