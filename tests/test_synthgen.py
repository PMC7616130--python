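"""Synthetic generators: determinism, distributional targets, closure."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from axonkit import arbor, synthgen
from axonkit.synthgen import (ArborParams, CohortConfig, ForceCurveParams,
                              GranuleMovieParams, GrowthConeImageParams,
                              generate_arbor, generate_cohort,
                              generate_force_curve, generate_granule_kymograph,
                              generate_growth_cone_image)


# ---------------------------------------------------------------------------
# Arbors


def test_arbor_determinism():
    p = ArborParams()
    t1 = generate_arbor(p, seed=11)
    t2 = generate_arbor(p, seed=11)
    pd.testing.assert_frame_equal(t1.nodes, t2.nodes)
    t3 = generate_arbor(p, seed=12)
    assert not t1.nodes.equals(t3.nodes)


def test_arbor_no_higher_orders_when_lambda_zero():
    p = dataclasses.replace(ArborParams(), mean_branches_per_order=(1.0, 0.0, 0.0))
    for s in range(10):
        tree = generate_arbor(p, seed=s)
        row = arbor.analyze_tree(tree)
        assert row["N2"] == 0 and row["N3"] == 0
        assert row["ACI"] == 1.0


def test_arbor_rejects_negative_effect():
    with pytest.raises(ValueError):
        generate_arbor(ArborParams(), (-1.0, 1.0), seed=0)


def test_arbor_order2_poisson_mean():
    """Monte-Carlo: order-2 side-branch count has the configured mean."""
    p = dataclasses.replace(ArborParams(), mean_branches_per_order=(1.0, 2.0, 0.0))
    counts = []
    for s in range(500):
        _, truth = generate_arbor(p, seed=s, return_truth=True)
        counts.append(truth["chain_counts"][2])
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - 2.0) <= 3 * se


def test_arbor_effect_multiplier_reduces_branching():
    base, reduced = [], []
    for s in range(200):
        base.append(arbor.analyze_tree(generate_arbor(ArborParams(), seed=s))["ACI"])
        reduced.append(arbor.analyze_tree(
            generate_arbor(ArborParams(), (1.0, 0.4, 0.4), seed=s))["ACI"])
    assert np.mean(reduced) < np.mean(base) - 0.1


def test_looping_arbor_turns():
    p = dataclasses.replace(ArborParams(), loop_probability=1.0)
    turns = [arbor.analyze_tree(generate_arbor(p, seed=s))["turn_deg"]
             for s in range(20)]
    assert np.median(turns) > 270


# ---------------------------------------------------------------------------
# Growth-cone images


def test_image_noiseless_construction():
    p = dataclasses.replace(GrowthConeImageParams(), gaussian_noise_sd=0.0,
                            poisson_noise=False, background_level=10.0,
                            actin_level=100.0)
    ch, masks = generate_growth_cone_image(p, seed=0)
    actin = ch["actin"]
    assert np.all(actin[masks["actin"]] == 110.0)
    assert np.all(actin[~masks["actin"]] == 10.0)
    tub = ch["tubulin"]
    assert np.all(tub[masks["tubulin"]] == 10.0 + p.tubulin_level)
    assert not (masks["tubulin"] & masks["actin"]).any()


def test_image_zero_level_is_background():
    p = dataclasses.replace(GrowthConeImageParams(), gaussian_noise_sd=0.0,
                            poisson_noise=False, actin_level=0.0)
    ch, _ = generate_growth_cone_image(p, seed=0)
    assert np.all(ch["actin"] == p.background_level)


def test_image_poisson_mean_recovery():
    p = dataclasses.replace(GrowthConeImageParams(), gaussian_noise_sd=0.0,
                            poisson_noise=True, actin_level=100.0,
                            background_level=10.0)
    ch, masks = generate_growth_cone_image(p, seed=4)
    vals = ch["actin"][masks["actin"]]
    n = vals.size
    assert n > 1000
    assert abs(vals.mean() - 110.0) <= 3 * np.sqrt(110.0 / n)


def test_image_geometry_guard():
    p = dataclasses.replace(GrowthConeImageParams(), central_radius_um=10.0)
    with pytest.raises(ValueError, match="exceeds"):
        generate_growth_cone_image(p, seed=0)


# ---------------------------------------------------------------------------
# Force curves


def test_force_curve_closed_form_value():
    """Noiseless force at δ = 100 nm equals the Hertz closed form."""
    p = dataclasses.replace(ForceCurveParams(), E_true_pa=1e4, nu=0.5,
                            R_m=70e-9, n_samples=400)
    curve, truth = generate_force_curve(p, seed=0, return_truth=True)
    target = (4 / 3) * (1e4 / 0.75) * np.sqrt(7e-8) * (1e-7) ** 1.5
    i = int(np.argmin(np.abs(truth["delta_m"] - 1e-7)))
    # interpolate the clean force to exactly δ=100 nm
    f_at = np.interp(1e-7, truth["delta_m"], truth["force_clean_n"])
    assert f_at == pytest.approx(target, rel=1e-6)
    assert truth["force_clean_n"][i] == pytest.approx(target, rel=5e-2)


def test_force_curve_zero_modulus_is_baseline():
    p = dataclasses.replace(ForceCurveParams(), E_true_pa=0.0,
                            baseline_slope_n_per_m=1e-6)
    curve = generate_force_curve(p, seed=0)
    drift = 1e-6 * (curve.z_m - curve.z_m[0])
    assert np.allclose(curve.force_N, drift)


def test_force_curve_self_consistency():
    """δ + F/k must equal the piezo travel past contact exactly."""
    p = ForceCurveParams()
    curve, truth = generate_force_curve(p, seed=2, return_truth=True)
    post = curve.z_m > p.z_contact_m
    lhs = truth["delta_m"][post] + truth["force_clean_n"][post] / p.k_n_per_m
    assert np.allclose(lhs, curve.z_m[post] - p.z_contact_m, atol=1e-13)


def test_force_curve_determinism():
    p = dataclasses.replace(ForceCurveParams(), force_noise_sd_n=1e-12)
    c1 = generate_force_curve(p, seed=5)
    c2 = generate_force_curve(p, seed=5)
    assert np.array_equal(c1.force_N, c2.force_N)


# ---------------------------------------------------------------------------
# Granule kymographs


def test_kymograph_frame_count():
    p = GranuleMovieParams()   # 2 fps, 60 s
    kymo, _ = generate_granule_kymograph(p, seed=0)
    assert kymo.n_frames == 120
    assert kymo.dt_s == pytest.approx(0.5)


def test_kymograph_granule_poisson_mean():
    p = GranuleMovieParams()   # 0.2 per µm × 25 µm
    counts = []
    for s in range(400):
        _, truth = generate_granule_kymograph(p, seed=s)
        counts.append(truth["track_id"].nunique() if len(truth) else 0)
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - 5.0) <= 3 * se + 0.1


def test_stationary_tracks_have_zero_net_displacement():
    p = dataclasses.replace(GranuleMovieParams(), frac_stationary=1.0,
                            frac_anterograde=0.0, frac_retrograde=0.0)
    _, truth = generate_granule_kymograph(p, seed=3)
    for _, sub in truth.groupby("track_id"):
        net = sub["position_um"].iloc[-1] - sub["position_um"].iloc[0]
        assert abs(net) < 0.5   # jitter only


def test_granule_fraction_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        dataclasses.replace(GranuleMovieParams(), frac_stationary=0.9).validate()


# ---------------------------------------------------------------------------
# Cohort writer


def test_cohort_layout_and_replay(tmp_path):
    cfg = CohortConfig(conditions=("a", "b"), n_per_condition=3, seed=9,
                       curves_per_cell=2)
    man1 = generate_cohort(cfg, tmp_path / "c1")
    assert len(list((tmp_path / "c1").glob("*/arbors/*.swc"))) == 6
    assert len(list((tmp_path / "c1").glob("*/images/*_actin.tif"))) == 6
    assert len(list((tmp_path / "c1").glob("*/afm/*.tsv"))) == 12
    assert len(list((tmp_path / "c1").glob("*/kymo/*.tif"))) == 6
    man2 = generate_cohort(cfg, tmp_path / "c2")
    import hashlib
    def checksums(root):
        return {p.relative_to(root).as_posix():
                hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(root.glob("**/*")) if p.is_file()}
    assert checksums(tmp_path / "c1") == checksums(tmp_path / "c2")
    assert man1["items"] == man2["items"]


def test_cohort_refuses_overwrite(tmp_path):
    cfg = CohortConfig(conditions=("a",), n_per_condition=1)
    generate_cohort(cfg, tmp_path / "c")
    with pytest.raises(FileExistsError):
        generate_cohort(cfg, tmp_path / "c")
    generate_cohort(cfg, tmp_path / "c", overwrite=True)


def test_cohort_branch_effect_lowers_aci(tmp_path):
    cfg = CohortConfig(conditions=("ctrl", "mut"), n_per_condition=20, seed=3,
                       effects={"mut": {"branch_multipliers": (1.0, 0.4, 0.4)}})
    generate_cohort(cfg, tmp_path / "c", stages=("arbor",))
    df = arbor.analyze_swc_dir(tmp_path / "c")
    df["condition"] = df["axon_id"].str.rsplit("_", n=1).str[0]
    means = df.groupby("condition")["ACI"].mean()
    assert means["mut"] < means["ctrl"]
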