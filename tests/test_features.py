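"""Feature alignment, isotope/charge reasoning and differential statistics."""

import numpy as np
import pandas as pd
import pytest

from cimccs import features as feat
from cimccs import simulate as sim


def _run(mz, drift, intensity):
    return pd.DataFrame({"mz": mz, "drift_bins": drift, "intensity": intensity})


class TestAlignment:
    def test_duplicated_run_is_idempotent(self):
        run = _run([400.0, 500.0, 600.0], [50.0, 60.0, 70.0], [10.0, 20.0, 30.0])
        table = feat.align_features([run, run.copy()])
        assert len(table) == 3
        assert (table["n_members"] == 2).all()

    def test_features_outside_mz_tolerance_stay_apart(self):
        run = _run([500.00, 500.05], [60.0, 60.0], [10.0, 10.0])
        assert len(feat.align_features([run])) == 2

    def test_features_outside_drift_tolerance_stay_apart(self):
        run = _run([500.00, 500.01], [60.0, 65.0], [10.0, 10.0])
        assert len(feat.align_features([run])) == 2

    def test_membership_conservation(self):
        rng = np.random.default_rng(0)
        runs = [
            _run(rng.uniform(100, 1000, 40), rng.uniform(10, 190, 40), rng.lognormal(5, 1, 40))
            for _ in range(4)
        ]
        table = feat.align_features(runs)
        assert table["n_members"].sum() == 4 * 40

    def test_jittered_runs_recover_true_features(self):
        """3 jittered renderings of 50 well-separated features: never merge,
        split only at the rate the jitter statistics allow."""
        exact = 0
        for s in range(200):
            study = sim.simulate_feature_study(
                n_features=50, n_per_group=2, effect_fraction=0, seed=s
            )
            runs = [study.runs[k] for k in list(study.runs)[:3]]
            n = len(feat.align_features(runs))
            assert n >= 50  # merges would lose planted features
            exact += n == 50
        # analytic floor: per-member split prob 2*(1-Phi(2/(0.4*sqrt(2)))) ~ 4e-4,
        # so >= ~95% of seeds keep all 50 features intact
        assert exact / 200 >= 0.95

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="intensity"):
            feat.align_features([pd.DataFrame({"mz": [1.0], "drift_bins": [1.0]})])


class TestIsotopeFlagging:
    def test_constructed_pair_is_flagged(self):
        run = _run([500.000, 501.0034], [60.0, 60.0], [100.0, 30.0])
        table = feat.flag_isotopes(feat.align_features([run]))
        iso = table[table["role"] == "isotope"]
        assert len(iso) == 1
        assert iso.iloc[0]["mz"] == pytest.approx(501.0034)
        assert iso.iloc[0]["charge"] == 1

    def test_drift_separated_pair_not_flagged(self):
        run = _run([500.000, 501.0034], [60.0, 65.0], [100.0, 30.0])
        table = feat.flag_isotopes(feat.align_features([run]))
        assert (table["role"] == "analyte").all()

    def test_ratio_outside_bounds_not_flagged(self):
        run = _run([500.000, 501.0034], [60.0, 60.0], [100.0, 500.0])
        table = feat.flag_isotopes(feat.align_features([run]))
        assert (table["role"] == "analyte").all()

    def test_chains_capped_at_depth(self):
        # M, M+1, M+2, M+3 at equal spacing; depth limit 2 leaves M+3 unflagged
        run = _run(
            [500.000, 501.0034, 502.0067, 503.0101], [60.0] * 4, [100.0, 40.0, 16.0, 6.0]
        )
        table = feat.flag_isotopes(feat.align_features([run]), max_depth=2)
        assert (table["role"] == "isotope").sum() == 2

    def test_simulated_sensitivity_and_false_flags(self):
        sens, false = [], []
        for s in range(100):
            study = sim.simulate_feature_study(
                n_features=80, isotope_fraction=0.25, effect_fraction=0, seed=s
            )
            table = feat.align_features(
                list(study.runs.values()), run_names=list(study.runs)
            )
            flagged = feat.flag_isotopes(table)
            truth = study.truth.values["features"]
            true_iso = truth.loc[truth["role"] == "isotope", "mz"].to_numpy()
            is_true = np.array(
                [np.abs(true_iso - m).min() < 0.01 for m in flagged["mz"]]
            )
            hit = (flagged["role"] == "isotope").to_numpy()
            sens.append((hit & is_true).sum() / is_true.sum())
            false.append((hit & ~is_true).sum() / (~is_true).sum())
        assert np.mean(sens) >= 0.95
        assert np.mean(false) <= 0.02


class TestChargeLinking:
    def test_doubly_charged_pair_links(self):
        res = feat.link_multiply_charged(529.3989, 265.2030)
        assert res.is_pair
        assert res.ppm_residual == pytest.approx(-1.4, abs=0.1)

    def test_unrelated_mz_does_not_link(self):
        assert not feat.link_multiply_charged(529.3989, 270.0).is_pair

    def test_exact_pair_zero_residual(self):
        mz1 = 600.0
        mz2 = (600.0 + 1.00782503207) / 2
        res = feat.link_multiply_charged(mz1, mz2)
        assert res.is_pair and res.ppm_residual == pytest.approx(0.0, abs=1e-9)

    def test_ordering_precondition(self):
        with pytest.raises(ValueError):
            feat.link_multiply_charged(265.0, 529.0)


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self):
        img, _ = sim.simulate_ion_images(n_images=1, seed=1)
        assert feat.spatial_correlation(img[0], img[0]) == pytest.approx(1.0)

    def test_negated_image_is_minus_one(self):
        img, _ = sim.simulate_ion_images(n_images=1, seed=1)
        assert feat.spatial_correlation(img[0], -img[0]) == pytest.approx(-1.0)

    def test_noisy_renderings_correlate(self):
        imgs, _ = sim.simulate_ion_images(snr=10.0, seed=2)
        assert feat.spatial_correlation(imgs[0], imgs[1]) > 0.9

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            feat.spatial_correlation(np.ones((4, 4)), np.random.default_rng(0).normal(size=(4, 4)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            feat.spatial_correlation(np.zeros((3, 3)), np.zeros((4, 4)))


def _two_group_table(control, tumor):
    table = pd.DataFrame({"mz": np.arange(len(control)) + 100.0})
    control = np.atleast_2d(control)
    tumor = np.atleast_2d(tumor)
    for i in range(control.shape[1]):
        table[f"control{i+1}"] = control[:, i]
    for i in range(tumor.shape[1]):
        table[f"tumor{i+1}"] = tumor[:, i]
    groups = {c: ("control" if c.startswith("control") else "tumor")
              for c in table.columns if c != "mz"}
    return table, groups


class TestDifferentialFilter:
    def test_identical_group_means_excluded(self):
        table, groups = _two_group_table([[5.0, 5.0, 5.0, 5.0]], [[5.0, 5.0, 5.0, 5.0]])
        kept, stats = feat.differential_filter(table, groups)
        assert stats.iloc[0]["fold_change"] == pytest.approx(1.0)
        assert len(kept) == 0

    def test_large_shift_included_with_expected_fc(self):
        rng = np.random.default_rng(0)
        control = 100.0 + rng.normal(0, 1e-6, (1, 4))
        tumor = 10.0 + rng.normal(0, 1e-6, (1, 4))
        table, groups = _two_group_table(control, tumor)
        kept, stats = feat.differential_filter(table, groups)
        assert len(kept) == 1
        assert stats.iloc[0]["fold_change"] == pytest.approx(10.0, rel=1e-4)

    def test_small_groups_raise(self):
        table, groups = _two_group_table([[5.0, 6.0]], [[5.0, 6.0]])
        groups.pop("control2")
        with pytest.raises(ValueError, match="2 samples"):
            feat.differential_filter(table, groups)

    def test_invariant_to_global_rescaling(self):
        study = sim.simulate_feature_study(n_features=60, effect_fraction=0.2, seed=3)
        table = sim.study_intensity_table(study)
        _, s1 = feat.differential_filter(table, study.groups)
        scaled = table.copy()
        for c in study.groups:
            scaled[c] = scaled[c] * 1e3
        _, s2 = feat.differential_filter(scaled, study.groups)
        assert np.allclose(s1["p_value"], s2["p_value"])
        assert np.allclose(s1["fold_change"], s2["fold_change"])

    def test_threshold_relaxation_is_monotone(self):
        study = sim.simulate_feature_study(n_features=200, effect_fraction=0.3, seed=5)
        table = sim.study_intensity_table(study)
        kept_strict, _ = feat.differential_filter(table, study.groups, 2.0, 0.05)
        kept_loose, _ = feat.differential_filter(table, study.groups, 1.5, 0.1)
        assert set(kept_strict.index) <= set(kept_loose.index)

    def test_planted_large_effects_all_recovered(self):
        study = sim.simulate_feature_study(
            n_features=100, effect_fraction=0.2, effect_size=10.0,
            intensity_sigma=0.05, seed=7,
        )
        table = sim.study_intensity_table(study)
        kept, stats = feat.differential_filter(table, study.groups)
        truth = study.truth.values["features"]
        effect_idx = truth.index[truth["is_effect"]]
        assert set(effect_idx) <= set(kept.index)


class TestVolcano:
    def test_classification(self):
        stats = pd.DataFrame(
            {
                "fold_change": [1.0, 8.3, 4.0, 0.04],
                "p_value": [1.0, 0.009, 0.2, 0.001],
            }
        )
        v = feat.volcano_data(stats)
        assert list(v["significance"]) == ["ns", "up", "ns", "down"]
        assert v["log2_fc"].iloc[0] == 0.0

    def test_background_removal_flags(self):
        run = _run([500.0, 556.2771], [60.0, 62.0], [10.0, 500.0])
        table = feat.align_features([run])
        out = feat.remove_background(table, [556.2771], ppm_tol=10)
        assert (out["role"] == "background").sum() == 1
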