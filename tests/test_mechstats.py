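"""Mechano-regulation statistics against exhaustive, closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import mechanoct as mc
from mechanoct.mechstats import (
    MechanoregulationModel,
    build_event_table,
    ccr_sweep,
    conditional_probability,
    per_band_summary,
    roc_auc,
)

from conftest import analysis_tables


def make_table(eps, events, **extra):
    df = pd.DataFrame({"eps_norm": np.asarray(eps, dtype=float), "event": list(events)})
    df["region"] = extra.get("region", "peripheral")
    df["band"] = extra.get("band", 1)
    df["band_prev"] = extra.get("band_prev", 1)
    df["band_curr"] = extra.get("band_curr", 1)
    df["mineralized"] = extra.get("mineralized", np.nan)
    return df


def auc_pairwise_oracle(pos, neg):
    """Exhaustive Mann-Whitney pairwise count (ties give half credit)."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


def ccr_brute_force(table, grid):
    """Exhaustive two-threshold sweep via explicit per-row prediction."""
    x = table["eps_norm"].to_numpy(float)
    ev = table["event"].to_numpy()
    classes = [c for c in ("resorption", "quiescence", "formation") if (ev == c).any()]
    best = -1.0
    mat = np.full((len(grid), len(grid)), np.nan)
    for i, tl in enumerate(grid):
        for j, th in enumerate(grid):
            if tl > th:
                continue
            pred = np.where(x >= th, "formation", np.where(x <= tl, "resorption", "quiescence"))
            recalls = [np.mean(pred[ev == c] == c) for c in classes]
            mat[i, j] = np.mean(recalls)
            best = max(best, mat[i, j])
    return mat, best


class TestEventTable:
    def test_constant_strain_normalizes_to_one(self, surrogate_dataset):
        images, masks = surrogate_dataset["images"], surrogate_dataset["masks"]
        banded = mc.bin_to_bands(images[0])
        rm = mc.classify_remodeling(banded, banded)
        strain = mc.StrainField(
            effective_strain=np.full(images[0].shape, 0.004),
            sed=np.zeros(images[0].shape),
            spacing_um=images[0].spacing_um,
        )
        table = build_event_table(strain, rm, masks, banded)
        np.testing.assert_allclose(table["eps_norm"], 1.0)

    def test_normalization_is_99th_percentile_of_simulation_region(self, spec_tiny, masks_tiny):
        """~1% of simulation-region voxels exceed 1 and table strains equal
        the per-voxel strain over the regional 99th percentile."""
        img = mc.make_baseline_phantom(spec_tiny)
        banded = mc.bin_to_bands(img)
        bands = mc.DensityBands()
        mat = mc.build_material_map(banded, bands, masks=masks_tiny)
        strain = mc.solve_axial(mat).to_strain_field()
        rm = mc.classify_remodeling(banded, banded)
        table = build_event_table(strain, rm, masks_tiny, banded)
        eps = strain.effective_strain
        p99 = np.percentile(eps[masks_tiny.region_mask("all")], 99)
        frac_region = (eps / p99 > 1.0).mean()
        assert 0.005 < frac_region <= 0.0105
        row = table.iloc[0]
        assert row.eps_norm == pytest.approx(eps.ravel()[int(row.voxel)] / p99, rel=1e-12)

    def test_rows_biject_with_ground_truth_surface_states(self, surrogate_dataset):
        images, log, masks = (
            surrogate_dataset["images"],
            surrogate_dataset["log"],
            surrogate_dataset["masks"],
        )
        provider = mc.surrogate_strain_provider()
        table = analysis_tables(images[:2], masks, provider)
        rec = log.steps[0]
        expected_idx = np.sort(
            np.concatenate([rec.formation_candidates, rec.resorption_candidates])
        )
        np.testing.assert_array_equal(np.sort(table["voxel"].to_numpy()), expected_idx)
        formed = set(rec.formation_candidates[rec.formed].tolist())
        resorbed = set(rec.resorption_candidates[rec.resorbed].tolist())
        got_formed = set(table.loc[table.event == "formation", "voxel"].tolist())
        got_resorbed = set(table.loc[table.event == "resorption", "voxel"].tolist())
        assert got_formed == formed
        assert got_resorbed == resorbed

    def test_empty_surface_warns(self, surrogate_dataset):
        masks = surrogate_dataset["masks"]
        shape = surrogate_dataset["images"][0].shape
        empty = mc.bin_to_bands(mc.DensityImage(np.zeros(shape)))
        rm = mc.classify_remodeling(empty, empty)
        strain = mc.StrainField(np.ones(shape), np.ones(shape), (10.5,) * 3)
        with pytest.warns(UserWarning):
            table = build_event_table(strain, rm, masks, empty)
        assert table.empty


class TestConditionalProbability:
    def test_probabilities_sum_to_one_exactly(self, surrogate_dataset):
        """Normalization is exact at the count level (each row lands in one
        event class of its bin); the float ratios sum to 1 within 1 ulp."""
        table = surrogate_dataset["table"]
        curve = conditional_probability(table, 50)
        ok = curve.occupied
        # exact rational normalization: per-bin event counts partition rows
        recon = np.round(
            np.stack([curve.p_form, curve.p_quiesc, curve.p_res])[:, ok]
            * curve.counts[ok]
        )
        np.testing.assert_array_equal(recon.sum(axis=0), curve.counts[ok])
        np.testing.assert_allclose(
            curve.p_form[ok] + curve.p_quiesc[ok] + curve.p_res[ok], 1.0,
            rtol=0, atol=3e-16,
        )

    def test_pooling_bins_recovers_marginal_rates(self, surrogate_dataset):
        table = surrogate_dataset["table"]
        curve = conditional_probability(table, 25)
        ok = curve.occupied
        marginal_form = (curve.p_form[ok] * curve.counts[ok]).sum() / curve.counts.sum()
        assert marginal_form == pytest.approx((table.event == "formation").mean())

    def test_random_labels_give_flat_curves(self):
        rng = np.random.default_rng(0)
        n = 60_000
        eps = rng.uniform(0, 1.1, n)
        events = rng.choice(
            ["formation", "quiescence", "resorption"], size=n, p=[0.2, 0.5, 0.3]
        )
        curve = conditional_probability(make_table(eps, events), 20)
        ok = curve.occupied & (curve.counts > 500)
        # every bin within 5 sigma of its binomial expectation
        for p, marginal in ((curve.p_form, 0.2), (curve.p_res, 0.3)):
            se = np.sqrt(marginal * (1 - marginal) / curve.counts[ok])
            assert np.all(np.abs(p[ok] - marginal) < 5 * se)

    def test_monotone_generator_recovered(self, surrogate_dataset):
        """Estimated p_form among formation candidates tracks the true rule."""
        table = surrogate_dataset["table"]
        rule = surrogate_dataset["spec"].mechanostat
        cand = table[table.band_prev == 0]
        curve = conditional_probability(cand, 25)
        ok = curve.occupied & (curve.counts >= 30)
        est = curve.p_form[ok]
        true = rule.p_form(curve.bin_centers[ok])
        rho = spearmanr(est, true).statistic
        assert rho > 0.9

    def test_too_few_bins_rejected(self, surrogate_dataset):
        with pytest.raises(ValueError):
            conditional_probability(surrogate_dataset["table"], 1)


class TestROC:
    def test_perfect_separation(self):
        table = make_table([0.1, 0.2, 0.8, 0.9], ["quiescence", "quiescence", "formation", "formation"])
        assert roc_auc(table, "formation").auc == 1.0

    def test_all_ties_give_half(self):
        table = make_table([0.5] * 10, ["formation"] * 3 + ["quiescence"] * 7)
        assert roc_auc(table, "formation").auc == 0.5

    def test_single_class_returns_none(self):
        table = make_table([0.1, 0.2], ["quiescence", "quiescence"])
        assert roc_auc(table, "formation") is None

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        n = 400
        eps = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
        events = np.where(rng.random(n) < 0.3, "formation", "quiescence")
        table = make_table(eps, events)
        auc = roc_auc(table, "formation").auc
        oracle = auc_pairwise_oracle(eps[events == "formation"], eps[events != "formation"])
        assert auc == pytest.approx(oracle, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.data())
    def test_pairwise_oracle_property(self, data):
        n = data.draw(st.integers(4, 40))
        eps = np.array(data.draw(st.lists(
            st.floats(0, 2, allow_nan=False), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if labels.all() or not labels.any():
            return
        events = np.where(labels, "formation", "quiescence")
        auc = roc_auc(make_table(eps, events), "formation").auc
        assert auc == pytest.approx(auc_pairwise_oracle(eps[labels], eps[~labels]), abs=1e-12)

    def test_mineralization_uses_quiescent_bone_only(self, surrogate_dataset):
        table = surrogate_dataset["table"]
        roc = roc_auc(table, "mineralization")
        defined = table["mineralized"].notna()
        assert roc.n_pos + roc.n_neg == int(defined.sum())
        # defined only at quiescent bone rows
        assert (table.loc[defined, "event"] == "quiescence").all()
        assert (table.loc[defined, "band_prev"] >= 1).all()


class TestCCR:
    def test_perfectly_separated_classes_reach_full_score(self):
        eps = [0.05, 0.1, 0.4, 0.5, 0.8, 0.9]
        ev = ["resorption"] * 2 + ["quiescence"] * 2 + ["formation"] * 2
        res = ccr_sweep(make_table(eps, ev), 50)
        assert res.max_ccr == pytest.approx(1.0)

    def test_degenerate_all_formation_cell_is_one_third(self):
        rng = np.random.default_rng(1)
        eps = rng.uniform(0.01, 1, 90)
        ev = ["resorption"] * 30 + ["quiescence"] * 30 + ["formation"] * 30
        res = ccr_sweep(make_table(eps, ev), 40)
        # grid[0] = 0: everything predicted formation
        assert res.ccr[0, 0] == pytest.approx(1.0 / 3.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        n = 200
        eps = np.round(rng.uniform(0, 1, n), 2)
        ev = rng.choice(["resorption", "quiescence", "formation"], n, p=[0.3, 0.5, 0.2])
        table = make_table(eps, ev)
        res = ccr_sweep(table, 15)
        mat, best = ccr_brute_force(table, res.grid)
        np.testing.assert_allclose(res.ccr, mat, atol=1e-12)
        assert res.max_ccr == pytest.approx(best, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.data())
    def test_brute_force_property(self, data):
        n = data.draw(st.integers(6, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        eps = np.round(rng.uniform(0, 1, n), 1)
        ev = rng.choice(["resorption", "quiescence", "formation"], n)
        table = make_table(eps, ev)
        res = ccr_sweep(table, 8)
        mat, best = ccr_brute_force(table, res.grid)
        np.testing.assert_allclose(res.ccr, mat, atol=1e-12)

    def test_max_ccr_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        eps = rng.uniform(0, 1, 150)
        ev = rng.choice(["resorption", "quiescence", "formation"], 150)
        t1 = make_table(eps, ev)
        # strictly monotone transform of the score
        t2 = make_table(np.expm1(3 * eps), ev)
        # sweep on the empirical values so grids correspond through the map
        assert ccr_sweep(t1, 120).max_ccr == pytest.approx(
            ccr_sweep(t2, 120).max_ccr, abs=0.02
        )

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            ccr_sweep(make_table([0.1], ["formation"]), 1)


class TestNullCalibration:
    def test_shuffled_labels_drive_auc_to_half(self, surrogate_dataset):
        table = surrogate_dataset["table"].copy()
        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(50):
            table["event"] = rng.permutation(table["event"].to_numpy())
            roc = roc_auc(table, "formation")
            if roc is not None:
                aucs.append(roc.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)


class TestSummaries:
    def test_all_region_is_pooled_not_averaged(self, surrogate_dataset):
        table = surrogate_dataset["table"]
        bands = mc.DensityBands()
        summary = per_band_summary(table, bands.n_bands, n_grid=20)
        for band in sorted(table.loc[table.band >= 1, "band"].unique()):
            pooled = table[table.band == band]
            roc = roc_auc(pooled, "formation")
            got = summary[
                (summary.region == "all")
                & (summary.band == band)
                & (summary.metric == "auc_formation")
            ]
            # one row per interval in this stratum
            for (_, row) in got.iterrows():
                sub = pooled[pooled.interval == row.interval]
                expected = roc_auc(sub, "formation")
                if expected is None:
                    assert np.isnan(row.value)
                else:
                    assert row.value == pytest.approx(expected.auc)

    def test_band_key_count_matches_band_edges(self, surrogate_dataset):
        bands = mc.DensityBands()
        summary = per_band_summary(surrogate_dataset["table"], bands.n_bands, n_grid=10)
        assert set(summary["band"].unique()) == set(range(1, bands.n_bands + 1))

    def test_model_results_and_summary_text(self, surrogate_dataset):
        res = MechanoregulationModel(surrogate_dataset["table"], n_grid=40).fit()
        text = res.summary()
        assert "AUC (formation)" in text
        assert "max CCR" in text
        assert res.auc_formation.auc > 0.5
        assert res.ccr.max_ccr > 1.0 / 3.0
        assert np.isfinite(res.auc_formation.auc_se)
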