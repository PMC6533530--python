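import numpy as np
import pandas as pd
import pytest

from mycogrid import quantgen, spatial, synth
from mycogrid.spatial import HCModelConfig, SDWModelConfig
from conftest import small_config

# light optimizer for repeated small-scale refits: slope/field estimates are
# insensitive to high-precision smoothing parameters
_LIGHT = {"grid": np.logspace(-3, 3, 7), "sweeps": 1,
          "nm": {"maxfev": 30, "xatol": 1e-2, "fatol": 1e-2}}
_MED = {"grid": np.logspace(-4, 4, 9), "sweeps": 1,
        "nm": {"maxfev": 60, "xatol": 1e-3, "fatol": 1e-4}}


def _toy(**kw):
    base = dict(n_varieties=100, subgroup_sizes={"A": 34, "B": 33, "C": 33},
                n_checks=2, n_runs=2, rows=10, cols=12, n_snps=120, n_chrom=4)
    base.update(kw)
    return small_config(**base)


def _sdw_cfg():
    return SDWModelConfig(spline_k=5, optimizer=_LIGHT)


class TestSDWModel:
    def test_null_coupling_slopes_cover_zero(self):
        # zero coupling, no field, neighbor variation dominated by variety
        # effects: the regime where the Wald approximation is reliable (the
        # simultaneity of neighbor-mean covariates otherwise makes the SEs
        # anti-conservative; see the methods note)
        covered = total = 0
        for seed in range(20):
            exp = synth.simulate_experiment(
                _toy(rho=(0.0, 0.0, 0.0), spatial_sd_log=0.0,
                     variety_sd_log=0.4, sdw_resid_sd_log=0.15), seed=seed)
            sf = spatial.fit_sdw_model(exp.plants, _sdw_cfg())
            for _, row in sf.slopes.iterrows():
                total += 1
                covered += abs(row["slope"]) <= 2 * row["se"]
        assert covered / total >= 0.9

    def test_treatment_ordering_recovered(self):
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(_toy(), seed=seed)
            sf = spatial.fit_sdw_model(exp.plants, _sdw_cfg())
            s = sf.slopes.set_index("treatment")["slope"]
            hits += s["Control"] < s["RP"] < s["RP+AM"]
        assert hits >= 18

    def test_absent_field_shrinks_smooth_edf(self):
        exp = synth.simulate_experiment(
            _toy(spatial_sd_log=0.0, rho=(0.0, 0.0, 0.0)), seed=0)
        sf = spatial.fit_sdw_model(exp.plants, _sdw_cfg())
        smooth = [k for k in sf.fit.edf if k.startswith("s(")][0]
        # null space is 4-dimensional (1 aliased with the intercept)
        assert sf.fit.edf[smooth] < 8

    def test_dropped_rows_counted(self):
        exp = synth.simulate_experiment(_toy(missing_rate=0.1), seed=0)
        sf = spatial.fit_sdw_model(exp.plants, _sdw_cfg())
        assert sf.n_dropped > 0
        assert sf.fit.n_obs + sf.n_dropped == len(exp.plants)

    def test_backward_selection_prunes_null_interactions(self):
        exp = synth.simulate_experiment(_toy(), seed=1)
        cfg = SDWModelConfig(spline_k=5, optimizer=_LIGHT,
                             all_interactions=True, select_fixed=True)
        sf = spatial.fit_sdw_model(exp.plants, cfg)
        # no interaction structure in the generator: most extras should go
        assert len(sf.pruned_terms) >= 5
        assert "treatment:neigh_sdw_g" not in sf.pruned_terms

    def test_sar_coupling_monotone_in_estimated_slope(self):
        means = []
        for rho in (0.0, 0.1, 0.2):
            slopes = []
            for seed in range(20):
                exp = synth.simulate_experiment(_toy(rho=(rho,) * 3), seed=seed)
                sf = spatial.fit_sdw_model(exp.plants, _sdw_cfg())
                slopes.append(sf.slopes["slope"].mean())
            means.append(np.mean(slopes))
        assert means[0] < means[1] < means[2]


class TestScopeSelection:
    # the spatial trend must dominate for the scope question to be answerable
    # at toy scale; the neighbor-mean covariate is excluded because it acts as
    # a per-block-adaptive field estimate and absorbs the trend being tested
    _KW = dict(spatial_sd_log=0.4, sdw_resid_sd_log=0.15, variety_sd_log=0.2,
               gxt_sd_log=0.05, rho=(0.0, 0.0, 0.0))

    def _config(self):
        return SDWModelConfig(spline_k=5, optimizer=_MED, include_neighbor=False)

    def test_common_truth_selects_common(self):
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(
                _toy(spatial_scope="common", **self._KW), seed=seed)
            chosen, _ = spatial.select_spatial_structure(
                exp.plants, config=self._config())
            hits += chosen == "common"
        assert hits >= 18

    def test_per_block_truth_selects_per_block(self):
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(
                _toy(spatial_scope="per_block", **self._KW), seed=seed)
            chosen, _ = spatial.select_spatial_structure(
                exp.plants, config=self._config())
            hits += chosen == "per_block"
        assert hits >= 18

    def test_single_box_tie_prefers_common(self):
        exp = synth.simulate_experiment(_toy(), seed=3)
        one_box = exp.plants[exp.plants["run"] == 1]
        chosen, tab = spatial.select_spatial_structure(
            one_box, candidates=("common", "per_box"), config=_sdw_cfg())
        assert chosen == "common"
        assert tab["delta_bic"].abs().max() < 1e-3  # identical fits


class TestHCModel:
    def test_mrf_improves_bic_under_car_field(self):
        # a strong, smooth CAR field (alpha near 1) that dominates the nugget
        # noise: the regime where one observation per lattice cell carries
        # enough information for BIC to support the field
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(
                _toy(car_alpha=0.99, car_sd=16.0, hc_resid_sd=3.0,
                     n_intersections=400), seed=seed)
            with_ = spatial.fit_hc_model(exp.plants,
                                         HCModelConfig(optimizer=_LIGHT))
            without = spatial.fit_hc_model(
                exp.plants, HCModelConfig(include_mrf=False, optimizer=_LIGHT))
            hits += with_.fit.bic < without.fit.bic
        assert hits >= 18

    def test_independent_noise_shrinks_mrf_edf(self):
        exp = synth.simulate_experiment(
            _toy(car_alpha=0.0, car_sd=0.0), seed=4)
        hf = spatial.fit_hc_model(exp.plants)
        mrf = [k for k in hf.fit.edf if k.startswith("s(")][0]
        n_blocks = exp.plants.loc[exp.plants.hyphae_pct.notna(), "block"].nunique()
        assert hf.fit.edf[mrf] < n_blocks + 10

    def test_focal_slope_recovered_within_two_se(self):
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(_toy(), seed=seed)
            hf = spatial.fit_hc_model(exp.plants, HCModelConfig(optimizer=_LIGHT))
            row = hf.terms.set_index("term").loc["sdw_g"]
            truth = exp.truth.config["hc_focal_slope"]
            hits += abs(row["estimate"] - truth) <= 2 * row["se"]
        assert hits >= 18


class TestAdditiveVsInteractive:
    def test_additive_truth_rarely_favors_interactive(self):
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(_toy(), seed=seed)
            daic, _, _ = spatial.compare_additive_interactive(
                exp.plants, optimizer=_LIGHT)
            hits += daic >= -2.0
        assert hits >= 16

    def test_strong_interaction_favors_interactive(self):
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(
                _toy(hc_interaction_slope=9000.0, hc_resid_sd=4.0), seed=seed)
            daic, _, _ = spatial.compare_additive_interactive(
                exp.plants, optimizer=_LIGHT)
            hits += daic < -2.0
        assert hits >= 16

    def test_deterministic_repeat(self):
        exp = synth.simulate_experiment(_toy(), seed=9)
        d1, *_ = spatial.compare_additive_interactive(exp.plants, optimizer=_LIGHT)
        d2, *_ = spatial.compare_additive_interactive(exp.plants, optimizer=_LIGHT)
        assert d1 == d2


class TestCorrection:
    def test_subtract_nothing_returns_raw(self):
        exp = synth.simulate_experiment(_toy(), seed=0)
        hf = spatial.fit_hc_model(exp.plants, HCModelConfig(optimizer=_LIGHT))
        table, _ = spatial.prepare_hc_table(exp.plants)
        res = spatial.spatially_correct(hf.fit, table, subtract=[])
        assert np.allclose(res.data[res.corrected_col], table["hyphae_pct"])

    def test_unknown_term_rejected(self):
        exp = synth.simulate_experiment(_toy(), seed=0)
        hf = spatial.fit_hc_model(exp.plants, HCModelConfig(optimizer=_LIGHT))
        table, _ = spatial.prepare_hc_table(exp.plants)
        with pytest.raises(KeyError):
            spatial.spatially_correct(hf.fit, table, subtract=["no_such_term"])

    def test_grand_mean_preserved_by_centering(self):
        exp = synth.simulate_experiment(_toy(), seed=1)
        hf = spatial.fit_hc_model(exp.plants, HCModelConfig(optimizer=_LIGHT))
        table, _ = spatial.prepare_hc_table(exp.plants)
        res = spatial.spatially_correct(hf.fit, table)
        assert res.data[res.corrected_col].mean() == pytest.approx(
            table["hyphae_pct"].mean(), abs=1e-8)

    def test_ledger_reproduces_correction_exactly(self):
        exp = synth.simulate_experiment(_toy(), seed=2)
        hf = spatial.fit_hc_model(exp.plants, HCModelConfig(optimizer=_LIGHT))
        table, _ = spatial.prepare_hc_table(exp.plants)
        res = spatial.spatially_correct(hf.fit, table)
        recon = (table["hyphae_pct"].to_numpy()
                 - res.subtracted.to_numpy().sum(axis=1))
        assert np.abs(recon - res.data[res.corrected_col].to_numpy()).max() < 1e-10

    def test_variety_r2_improves_under_spatial_field(self):
        hits = 0
        for seed in range(20):
            exp = synth.simulate_experiment(
                _toy(car_alpha=0.9, car_sd=12.0), seed=seed)
            hf = spatial.fit_hc_model(exp.plants, HCModelConfig(optimizer=_LIGHT))
            table, _ = spatial.prepare_hc_table(exp.plants)
            res = spatial.spatially_correct(hf.fit, table)
            raw = quantgen.oneway_partition(table["hyphae_pct"], table["variety"])
            cor = quantgen.oneway_partition(res.data[res.corrected_col],
                                            table["variety"])
            hits += cor.shares["group"] > raw.shares["group"]
        assert hits >= 18

    def test_correction_idempotent(self):
        exp = synth.simulate_experiment(_toy(car_sd=10.0), seed=5)
        hf = spatial.fit_hc_model(exp.plants, HCModelConfig(optimizer=_LIGHT))
        table, _ = spatial.prepare_hc_table(exp.plants)
        res = spatial.spatially_correct(hf.fit, table)
        nuis1 = res.subtracted.var()

        plants2 = exp.plants.copy()
        # prepare_hc_table preserves the original row index, so assignment
        # aligns corrected values back onto the plant table directly
        plants2.loc[res.data.index, "hyphae_pct"] = \
            res.data[res.corrected_col].clip(0, 100)

        hf2 = spatial.fit_hc_model(plants2, HCModelConfig(optimizer=_LIGHT))
        table2, _ = spatial.prepare_hc_table(plants2)
        res2 = spatial.spatially_correct(hf2.fit, table2)
        nuis2 = res2.subtracted.var()
        for term in ("s(cell,mrf):block",):
            assert nuis2[term] < 0.05 * max(nuis1[term], 1e-9) + 1e-6
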