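"""Fit statistics, bootstrap comparison, dynamic range, edge flags, structure-function."""

import warnings

import numpy as np
import pandas as pd
import pytest

from maculasum.evaluation import (
    bootstrap_compare,
    dynamic_range,
    error_by_sensitivity_bin,
    flag_edge_locations,
    goodness_of_fit,
    structure_function_eval,
)
from maculasum.evaluation import test_retest_noise as retest_noise
from maculasum.structural_rgc import gcl_to_density
from maculasum.summation_template import DEFAULT_TEMPLATE, template_sensitivity


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        obs = np.array([10.0, 20.0, 30.0, 15.0])
        gof = goodness_of_fit(obs, obs, ["a", "a", "b", "b"],
                              exclude_calibration_cohort=False)
        assert gof.r2_overall == pytest.approx(100.0)
        assert gof.rmse_overall == 0.0
        assert (gof.by_group["rmse"] == 0.0).all()

    def test_alternating_unit_residuals(self):
        obs = np.array([10.0, 20.0, 10.0, 20.0])
        pred = obs + np.array([1.0, -1.0, 1.0, -1.0])
        gof = goodness_of_fit(obs, pred, ["g"] * 4,
                              exclude_calibration_cohort=False)
        assert gof.rmse_overall == pytest.approx(1.0)

    def test_calibration_cohort_exclusion(self):
        rng = np.random.default_rng(1)
        obs = rng.uniform(5, 25, 40)
        pred = obs + rng.normal(0, 1, 40)
        grp = np.array(["young"] * 15 + ["control"] * 25)
        with_flag = goodness_of_fit(obs, pred, grp)
        deleted = goodness_of_fit(obs[15:], pred[15:], grp[15:],
                                  exclude_calibration_cohort=False)
        assert with_flag.r2_overall == pytest.approx(deleted.r2_overall)
        assert with_flag.rmse_overall == pytest.approx(deleted.rmse_overall)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            gof = goodness_of_fit(
                np.full(5, 7.0), np.arange(5.0), ["g"] * 5,
                exclude_calibration_cohort=False,
            )
        assert not gof.r2_defined

    def test_recorded_mode_clamps_predictions(self):
        obs = np.array([0.0, 10.0])
        pred = np.array([-20.0, 10.0])
        gof = goodness_of_fit(obs, pred, ["g", "g"], censored=[1, 0],
                              exclude_calibration_cohort=False)
        assert gof.rmse_overall == 0.0


class TestBootstrapCompare:
    def test_identical_errors_null(self):
        e = np.array([1.0, -2.0, 0.5, 1.5, -1.0, 2.0])
        subj = ["a", "a", "b", "b", "c", "c"]
        res = bootstrap_compare(e, e.copy(), subj, B=100, seed=0)
        assert res["improvement_pct"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_factor_two_dominance(self):
        rng = np.random.default_rng(2)
        e1 = rng.normal(0, 1, 60)
        subj = np.repeat([f"s{i}" for i in range(10)], 6)
        res = bootstrap_compare(e1, 2.0 * e1, subj, B=500, seed=2)
        assert res["improvement_pct"] == pytest.approx(50.0)
        assert res["p_value"] < 2.0 / 500
        lo, hi = res["rmse_h1_ci"]
        assert lo <= res["rmse_h1"] <= hi
        lo, hi = res["rmse_h2_ci"]
        assert lo <= res["rmse_h2"] <= hi

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare([1.0, 2.0], [1.0, 2.0], ["a", "a"], B=10)


class TestDynamicRange:
    def test_constant_vector_zero(self):
        assert dynamic_range(np.full(50, 3.3)) == 0.0

    def test_evenly_spaced_values(self):
        v = np.linspace(0.0, 100.0, 1001)
        assert dynamic_range(v) == pytest.approx(98.0, abs=0.01)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 5, 400)
        assert dynamic_range(v + 17.0) == pytest.approx(dynamic_range(v), rel=1e-12)

    def test_affine_compression_forces_ratio(self):
        """structural = 0.11*(functional - c) + c gives a DR ratio of 0.11."""
        rng = np.random.default_rng(4)
        functional = rng.uniform(-20, 20, 300)
        for c in (0.0, 5.0, -12.0):
            structural = 0.11 * (functional - c) + c
            ratio = dynamic_range(structural) / dynamic_range(functional)
            assert ratio == pytest.approx(0.11, rel=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range([1.0])


class TestEdgeFlags:
    def test_no_flags_when_all_errors_equal(self):
        obs = np.full(100, 12.0)
        pred = np.full(100, 10.0)
        flags = flag_edge_locations(obs, pred)
        assert not flags.flags.any()

    def test_single_outlier_flagged_exactly(self):
        obs = np.zeros(100)
        obs[37] = 10.0
        flags = flag_edge_locations(obs, np.zeros(100))
        assert flags.flags.sum() == 1
        assert flags.flags[37]

    def test_underpowered_warning(self):
        with pytest.warns(UserWarning, match="underpowered"):
            flags = flag_edge_locations(np.arange(10.0), np.zeros(10))
        assert flags.underpowered


class TestEdgeClustering:
    def test_flags_cluster_at_scotoma_borders(self, profiles):
        """With noise-free perimetry, every G-V flag lands within 2 deg of a
        generated sharp scotoma edge: the large stimulus straddles the edge
        and summates intact retina the one-density-per-location model cannot
        see."""
        from maculasum.hierarchical_fit import (
            HierarchicalModelSpec,
            McmcSettings,
            fit_hierarchical,
            posterior_predict,
        )
        from maculasum.synthetic_cohort import (
            NoiseConfig,
            StudyConfig,
            _arc_distance,
            attach_stimulus_columns,
            generate_study,
        )

        cfg = StudyConfig(
            n_young=1, n_controls=1, n_per_glaucoma_stage=2,
            noise=NoiseConfig(0.0, 0.0, 0.0), seed=42,
        )
        truths, obs = generate_study(cfg, profiles)
        fitted = attach_stimulus_columns(obs, cfg.protocol, profiles)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_hierarchical(
                fitted,
                HierarchicalModelSpec("horizontal", DEFAULT_TEMPLATE),
                McmcSettings(chains=2, warmup=300, samples=300),
                seed=11,
            )
            pred = posterior_predict(post, fitted)
        m = ((fitted["stimulus"] == "GV") & (fitted["censored"] == 0)).to_numpy()
        flags = flag_edge_locations(fitted["sensitivity_db"].to_numpy()[m], pred[m])
        gv = fitted.loc[m, ["eye_id", "x_deg", "y_deg"]].copy()
        gv["flag"] = flags.flags
        info = {t.eye_id: t.damage_info for t in truths}

        def edge_dist(row):
            di = info.get(row.eye_id)
            if not di:
                return np.inf
            return min(
                abs(
                    _arc_distance(
                        np.array([row.x_deg]), np.array([row.y_deg]), arc
                    )[0]
                    - arc["width"]
                )
                for arc in di["arcs"]
            )

        gv["edge_d"] = gv.apply(edge_dist, axis=1)
        damaged = gv[np.isfinite(gv["edge_d"])]
        near = damaged["edge_d"] <= 2.0
        rate_near = damaged.loc[near, "flag"].mean()
        rate_far = damaged.loc[~near, "flag"].mean()
        assert damaged["flag"].sum() > 0
        assert rate_near >= 2.0 * max(rate_far, 1e-9)


def make_sf_frame(densities, eyes=("E1",), noise=None):
    stims = {"GI": 0.10, "GII": 0.21, "GIII": 0.43, "GIV": 0.86, "GV": 1.72}
    conv = 6.6
    rows, dens_rows = [], []
    for eye in eyes:
        for li, d in enumerate(densities):
            x, y = 1.0 + 2 * li, 1.0
            dens_rows.append(
                dict(eye_id=eye, x_deg=x, y_deg=y, poff_density_per_deg2=d)
            )
            for name, diam in stims.items():
                area = np.pi * (diam / 2) ** 2
                u = 10 * np.log10(area * 200.0 * d * conv)
                s = template_sensitivity(u, DEFAULT_TEMPLATE)
                rows.append(
                    dict(
                        eye_id=eye, x_deg=x, y_deg=y, stimulus=name,
                        sensitivity_db=max(s, 0.0), censored=int(s <= 0),
                        area_deg2=area, duration_ms=200.0, convergence=conv,
                    )
                )
    return pd.DataFrame(rows), pd.DataFrame(dens_rows)


class TestStructureFunction:
    def test_identity_gives_zero_rmse(self):
        obs, dens = make_sf_frame([60.0, 50.0, 40.0, 55.0])
        functional = dens.copy()
        out = structure_function_eval(
            obs, dens, DEFAULT_TEMPLATE, functional, gi_threshold_db=3.0
        )
        assert out["rmse_all_db"] == pytest.approx(0.0, abs=1e-9)
        assert out["rmse_gi_subset_db"] == pytest.approx(0.0, abs=1e-9)
        assert out["rmse_density_db"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_density_bias_moves_density_rmse_exactly(self):
        obs, dens = make_sf_frame([60.0, 50.0, 40.0])
        functional = dens.copy()
        biased = dens.copy()
        biased["poff_density_per_deg2"] *= 10.0**0.3  # +3 dB
        out = structure_function_eval(obs, biased, DEFAULT_TEMPLATE, functional)
        assert out["rmse_density_db"] == pytest.approx(3.0, abs=1e-9)

    def test_missing_gi_rows_warns_and_skips_subset(self):
        obs, dens = make_sf_frame([50.0])
        obs = obs[obs["stimulus"] != "GI"]
        with pytest.warns(UserWarning, match="G-I"):
            out = structure_function_eval(obs, dens, DEFAULT_TEMPLATE)
        assert np.isnan(out["rmse_gi_subset_db"])

    def test_floor_hurts_unrestricted_rmse_on_advanced_eyes(
        self, small_study, profiles
    ):
        """The residual-tissue floor compresses only the damaged tail, so on
        advanced eyes the all-locations structure-function RMSE exceeds the
        RMSE restricted to locations still seeing G-I at >= 10 dB."""
        from maculasum.synthetic_cohort import _LocationSampler

        cfg = small_study["config"]
        sampler = _LocationSampler(cfg.protocol, profiles)
        adv_ids = [t.eye_id for t in small_study["truths"] if t.cohort == "advanced"]
        obs = small_study["fitted"]
        obs = obs[obs["eye_id"].isin(adv_ids)]
        frames = []
        for t in small_study["truths"]:
            if t.eye_id not in adv_ids:
                continue
            dmap = gcl_to_density(t.gcl_thickness, profiles)
            frames.append(
                pd.DataFrame(
                    {
                        "eye_id": t.eye_id,
                        "x_deg": t.location_table["x_deg"],
                        "y_deg": t.location_table["y_deg"],
                        "poff_density_per_deg2": sampler.location_density(dmap.poff),
                    }
                )
            )
        structural = pd.concat(frames, ignore_index=True)
        from maculasum.synthetic_cohort import gi_floor_threshold

        thr = gi_floor_threshold(
            profiles, DEFAULT_TEMPLATE, cfg.floor.residual_fraction, cfg.protocol
        )
        out = structure_function_eval(
            obs, structural, DEFAULT_TEMPLATE, gi_threshold_db=thr
        )
        assert out["rmse_all_db"] > out["rmse_gi_subset_db"]


class TestNoiseHelpers:
    def test_zero_noise_gives_zero_test_retest(self, profiles):
        from maculasum.synthetic_cohort import (
            NoiseConfig,
            StudyConfig,
            generate_study,
        )

        cfg = StudyConfig(
            n_young=1, n_controls=1, n_per_glaucoma_stage=1,
            noise=NoiseConfig(0.0, 0.0, 0.0), seed=3,
        )
        _, obs = generate_study(cfg, profiles)
        assert retest_noise(obs) == pytest.approx(0.0, abs=1e-12)

    def test_error_bins_partition_rows(self):
        rng = np.random.default_rng(5)
        obs = rng.uniform(0, 39, 200)
        pred = obs + rng.normal(0, 2, 200)
        bins = error_by_sensitivity_bin(obs, pred)
        assert bins["n"].sum() == 200
        assert (bins["rmse"] >= 0).all()
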