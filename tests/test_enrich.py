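"""Matched controls, block bootstrap, enrichment ORs, frost, dispersion."""

import numpy as np
import pandas as pd
import pytest

from seasonscan.datamodel import Role
from seasonscan.enrich import (block_sample, dispersion_test, enrichment_or,
                               frost_overshoot, match_controls,
                               matching_key_frame, threshold_sweep_enrichment)
from seasonscan.scan import seasonal_scan
from seasonscan.synth import TruthConfig, simulate_study, simulate_truth


def toy_keys(n, rng, n_strata=5):
    return pd.DataFrame({"chrom": rng.choice(["2L", "2R"], n),
                         "stratum": rng.integers(0, n_strata, n)})


class TestMatchControls:
    def test_every_focal_matched_when_pool_mirrors_focal(self, rng):
        keys = pd.DataFrame({"chrom": ["2L"] * 100,
                             "stratum": [1] * 100})
        focal = np.zeros(100, bool)
        focal[:20] = True
        cs = match_controls(keys, focal, n_sets=50, seed=1)
        assert len(cs.focal_idx) == 20 and len(cs.dropped_focal) == 0
        assert cs.control_idx.shape == (20, 50)
        # controls come from the pool, never the focal set
        assert not np.isin(cs.control_idx, np.flatnonzero(focal)).any()

    def test_unique_stratum_focal_is_dropped(self, rng):
        keys = pd.DataFrame({"stratum": [1, 1, 1, 2]})
        focal = np.array([True, False, False, True])
        cs = match_controls(keys, focal, n_sets=10, seed=2)
        assert cs.dropped_focal.tolist() == [3]
        assert cs.focal_idx.tolist() == [0]

    def test_controls_match_focal_keys_exactly(self, rng):
        n = 600
        keys = toy_keys(n, rng)
        focal = np.zeros(n, bool)
        focal[rng.choice(n, 60, replace=False)] = True
        cs = match_controls(keys, focal, n_sets=40, seed=3)
        for f_row, c_rows in zip(cs.focal_idx, cs.control_idx):
            assert (keys.iloc[c_rows]["chrom"] ==
                    keys.iloc[f_row]["chrom"]).all()
            assert (keys.iloc[c_rows]["stratum"] ==
                    keys.iloc[f_row]["stratum"]).all()

    def test_all_dropped_is_an_error(self):
        keys = pd.DataFrame({"stratum": [1, 2]})
        with pytest.raises(ValueError):
            match_controls(keys, np.array([True, False]), n_sets=5, seed=4)

    def test_key_frame_rounding(self, null_study):
        _, table, metas = null_study
        kf = matching_key_frame(table,
                                freq_samples=[metas[0].sample_id],
                                keys=("chrom", "recomb_rate", "freq"))
        assert set(kf.columns) == {"chrom", "recomb_rate", "freq"}
        assert (np.abs(kf["freq"] * 20 - np.round(kf["freq"] * 20))
                < 1e-9).all()


class TestBlockSample:
    def test_distinct_windows_keep_all_focal(self):
        pos = np.arange(10) * 60_000
        subsets = block_sample(["2L"] * 10, pos, n_boot=20, seed=5)
        assert subsets.shape == (20, 10)
        assert (np.sort(subsets, axis=1) == np.arange(10)).all()

    def test_single_window_yields_singletons(self):
        pos = np.arange(100) * 10
        subsets = block_sample(["2L"] * 100, pos, n_boot=50, seed=6)
        assert subsets.shape == (50, 1)

    def test_subset_size_equals_occupied_windows(self, rng):
        pos = rng.integers(0, 5_000_000, 300)
        chroms = rng.choice(["2L", "3R"], 300)
        windows = {(c, p // 50_000) for c, p in zip(chroms, pos)}
        subsets = block_sample(chroms, pos, n_boot=10, seed=7)
        assert subsets.shape[1] == len(windows)


class TestEnrichmentOr:
    def setup_tables(self, rng, n=3000, n_focal=250):
        chroms = rng.choice(["2L", "2R"], n)
        pos = rng.choice(20_000_000, n, replace=False)
        keys = pd.DataFrame({"chrom": chroms,
                             "stratum": rng.integers(0, 4, n)})
        focal = np.zeros(n, bool)
        focal[rng.choice(n, n_focal, replace=False)] = True
        return chroms, pos, keys, focal

    def test_null_centered_with_nominal_coverage(self):
        """Status-independent predicate: E within 3 SD of 0 and the 95% CI
        covers 0 in at least 90% of replicates."""
        covered, centred = 0, 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            chroms, pos, keys, focal = self.setup_tables(rng, n=1500,
                                                         n_focal=150)
            pred = (rng.random(1500) < 0.3).astype(float)
            cs = match_controls(keys, focal, n_sets=80, seed=r)
            res = enrichment_or(pred, cs, chroms, pos, n_boot=80, seed=r)
            covered += res.ci_low <= 0.0 <= res.ci_high
            centred += abs(res.e_value) <= 3 * res.sd
        assert covered >= 90
        assert centred >= 90

    def test_planted_odds_ratio_recovered(self, rng):
        chroms, pos, keys, focal = self.setup_tables(rng)
        pred = np.where(focal, rng.random(len(focal)) < 0.4,
                        rng.random(len(focal)) < 0.2).astype(float)
        cs = match_controls(keys, focal, n_sets=150, seed=8)
        res = enrichment_or(pred, cs, chroms, pos, n_boot=150, seed=9)
        expect = np.log2((0.4 / 0.6) / (0.2 / 0.8))
        assert res.ci_low < expect < res.ci_high
        assert res.p < 0.01

    def test_swapping_focal_and_control_negates_e(self, rng):
        n = 2000
        chroms = np.array(["2L"] * n)
        pos = rng.choice(20_000_000, n, replace=False)
        keys = pd.DataFrame({"k": np.zeros(n, dtype=int)})
        group_a = np.zeros(n, bool)
        group_a[: n // 2] = True
        pred = np.where(group_a, rng.random(n) < 0.35,
                        rng.random(n) < 0.2).astype(float)
        res_a = enrichment_or(pred, match_controls(keys, group_a, 100, 10),
                              chroms, pos, n_boot=100, seed=11)
        res_b = enrichment_or(pred, match_controls(keys, ~group_a, 100, 10),
                              chroms, pos, n_boot=100, seed=11)
        assert res_a.e_value == pytest.approx(-res_b.e_value,
                                              abs=3 * res_a.sd)

    def test_invariant_to_row_order_and_chrom_names(self, rng):
        chroms, pos, keys, focal = self.setup_tables(rng, n=1200,
                                                     n_focal=120)
        pred = np.where(focal, rng.random(1200) < 0.4,
                        rng.random(1200) < 0.2).astype(float)
        cs = match_controls(keys, focal, n_sets=120, seed=12)
        res = enrichment_or(pred, cs, chroms, pos, n_boot=120, seed=13)

        perm = rng.permutation(1200)
        keys2 = keys.iloc[perm].reset_index(drop=True)
        keys2["chrom"] = keys2["chrom"].map({"2L": "chrA", "2R": "chrB"})
        cs2 = match_controls(keys2, focal[perm], n_sets=120, seed=14)
        res2 = enrichment_or(pred[perm], cs2, keys2["chrom"].to_numpy(),
                             pos[perm], n_boot=120, seed=15)
        assert res2.e_value == pytest.approx(res.e_value, abs=3 * res.sd)

    def test_missing_predicate_excluded_not_fatal(self, rng):
        chroms, pos, keys, focal = self.setup_tables(rng, n=1000,
                                                     n_focal=100)
        pred = (rng.random(1000) < 0.3).astype(float)
        pred[rng.random(1000) < 0.2] = np.nan
        cs = match_controls(keys, focal, n_sets=60, seed=16)
        res = enrichment_or(pred, cs, chroms, pos, n_boot=60, seed=17)
        assert np.isfinite(res.e_value)


class TestThresholdSweep:
    def gwas_study(self, concordance, seed):
        cfg = TruthConfig(n_snps=4000, frac_seasonal=0.1,
                          gwas_concordance=concordance, seed=seed)
        truth = simulate_truth(cfg)
        table, metas = simulate_study(truth, cfg)
        seas = (truth["class"] == "seasonal").to_numpy()
        # concordance: GWAS direction agrees with the spring-favoured allele
        want = np.where(truth["amplitude"].to_numpy() > 0, 1, -1)
        concordant = (table.df["gwas_direction"].to_numpy() == want)
        score = -np.log10(table.df["gwas_p"].to_numpy())
        keys = matching_key_frame(table, keys=("chrom",))
        cs = match_controls(keys, seas, n_sets=100, seed=seed + 1)
        return table, seas, concordant, score, cs

    def test_coin_flip_concordance_is_null(self):
        table, seas, conc, score, cs = self.gwas_study(0.5, seed=41)
        out = threshold_sweep_enrichment(
            score, cs, [0.0, 0.5, 1.0], table.df["chrom"], table.df["pos"],
            concordant=conc, n_boot=100, seed=42)
        assert (np.abs(out["e_value"]) < 3 * out["sd"]).all()

    def test_planted_concordance_detected(self):
        table, seas, conc, score, cs = self.gwas_study(0.75, seed=43)
        out = threshold_sweep_enrichment(
            score, cs, [0.0, 0.5], table.df["chrom"], table.df["pos"],
            concordant=conc, n_boot=100, seed=44)
        assert (out["e_value"] > 0).all()
        assert out["ci_low"].iloc[0] > 0

    def test_threshold_above_all_scores_is_missing(self):
        table, seas, conc, score, cs = self.gwas_study(0.5, seed=45)
        out = threshold_sweep_enrichment(
            score, cs, [1e9], table.df["chrom"], table.df["pos"],
            concordant=conc, n_boot=50, seed=46)
        assert bool(out["missing"].iloc[0])


class TestFrostOvershoot:
    def test_pure_noise_with_matching_is_calibrated(self, frost_null_study):
        """Exchangeable focal SNPs on null data (no frost effect): the
        matched-control overshoot comparison is centred at zero."""
        _, table, metas = frost_null_study
        rng = np.random.default_rng(51)
        focal = np.zeros(len(table), bool)
        focal[rng.choice(len(table), 300, replace=False)] = True
        ps, pc, res = frost_overshoot(table, focal, metas, n_sets=150,
                                      n_boot=150, seed=51)
        assert res.ci_low <= 0.0 <= res.ci_high
        assert abs(ps - pc) < 0.05

    def test_matching_removes_regression_to_mean(self, frost_null_study):
        """Focal SNPs picked for above-typical observed pre-frost
        displacement on pure-noise data: without the displacement match
        the controls overshoot too often (regression to the mean) and E is
        pushed negative; the match removes that bias."""
        _, table, metas = frost_null_study
        pre = table.freqs("PA_2011_fall")
        long_ids = [m.sample_id for m in metas
                    if m.role is Role.PENNSYLVANIA_SERIES and m.year < 2011]
        disp = np.abs(pre - table.freq_matrix(long_ids).mean(axis=1))
        lo, hi = np.quantile(disp, [0.75, 0.95])
        band = np.flatnonzero((disp >= lo) & (disp < hi))
        rng = np.random.default_rng(52)
        focal = np.zeros(len(table), bool)
        focal[rng.choice(band, 300, replace=False)] = True
        _, _, matched = frost_overshoot(table, focal, metas, n_sets=150,
                                        n_boot=150, seed=52)
        _, _, unmatched = frost_overshoot(table, focal, metas, n_sets=150,
                                          n_boot=150, seed=52,
                                          match_on_displacement=False)
        assert matched.ci_low <= 0.0 <= matched.ci_high
        assert matched.e_value > unmatched.e_value + 0.1

    def test_planted_frost_response_detected(self):
        from seasonscan.synth import frost_study_plan
        cfg = TruthConfig(n_snps=5000, frac_seasonal=0.08, frost_shift=0.8,
                          sampling_plan=frost_study_plan(), seed=53)
        truth = simulate_truth(cfg)
        table, metas = simulate_study(truth, cfg)
        seas = (truth["class"] == "seasonal").to_numpy()
        ps, pc, res = frost_overshoot(table, seas, metas, n_sets=150,
                                      n_boot=150, seed=54)
        assert ps > pc
        assert res.ci_low > 0

    def test_missing_frost_sample_is_an_error(self, null_study):
        _, table, metas = null_study
        mask = np.zeros(len(table), bool)
        mask[:50] = True
        with pytest.raises(ValueError, match="frost_post"):
            frost_overshoot(table, mask, metas)


class TestDispersionTest:
    def windows(self, counts, rng, window=1000):
        n = len(counts) * window
        chroms = np.repeat("2L", n)
        rec = np.abs(rng.normal(2.0, 0.4, n))
        mask = np.zeros(n)
        for i, c in enumerate(counts):
            mask[i * window: i * window + min(int(c), window)] = 1
        return mask, chroms, rec

    def test_poisson_null_ratio_near_one(self, rng):
        counts = rng.poisson(3.5, 400)
        mask, chroms, rec = self.windows(counts, rng)
        ratio, p = dispersion_test(mask, chroms, rec)
        assert 0.8 < ratio < 1.25
        assert p > 0.01

    def test_planted_overdispersion_magnitude_recovered(self, rng):
        """Counts with Var = 2.3 * mean: ratio ~ 2.3 and the one-sided test
        rejects."""
        lam, ratio_true = 3.5, 2.3
        shape = lam / (ratio_true - 1.0)
        counts = rng.negative_binomial(shape, shape / (shape + lam), 400)
        mask, chroms, rec = self.windows(counts, rng)
        ratio, p = dispersion_test(mask, chroms, rec)
        assert 1.7 < ratio < 3.0
        assert p < 0.01

    def test_rejection_rate_on_planted_overdispersion(self):
        lam, ratio_true, hits = 3.5, 2.3, 0
        shape = lam / (ratio_true - 1.0)
        for r in range(20):
            rng = np.random.default_rng(600 + r)
            counts = rng.negative_binomial(shape, shape / (shape + lam), 400)
            mask, chroms, rec = self.windows(counts, rng)
            _, p = dispersion_test(mask, chroms, rec)
            hits += p < 0.05
        assert hits >= 19

    def test_covariate_absorbs_heterogeneity(self, rng):
        """Window rates driven entirely by the recombination covariate:
        after the Poisson GLM the dispersion ratio returns to ~1."""
        nwin, window = 400, 1000
        rec_win = rng.uniform(0.5, 4.0, nwin)
        lam = np.exp(0.2 + 0.5 * rec_win)
        counts = rng.poisson(lam)
        mask = np.zeros(nwin * window)
        for i, c in enumerate(counts):
            mask[i * window: i * window + min(int(c), window)] = 1
        chroms = np.repeat("2L", nwin * window)
        rec = np.repeat(rec_win, window)
        ratio, p = dispersion_test(mask, chroms, rec)
        assert 0.8 < ratio < 1.25
        assert p > 0.01

    def test_degenerate_inputs_rejected(self, rng):
        mask, chroms, rec = self.windows(np.zeros(30), rng)
        with pytest.raises(ValueError, match="no seasonal"):
            dispersion_test(mask, chroms, rec)
        mask, chroms, rec = self.windows(rng.poisson(3, 10), rng)
        with pytest.raises(ValueError, match="20 windows"):
            dispersion_test(mask, chroms, rec)
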