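"""Vertical profiles, the two normalizations, LOESS and zone assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coralpore.core_io import FragmentMeta
from coralpore.porosity_mapping import PorosityMap
from coralpore.profile_analysis import (
    LoessCurve,
    VerticalProfile,
    assign_zones,
    extract_vertical_profile,
    fit_loess,
    locate_extremum,
    normalize_coordinates,
    transform_variable,
)


def _map_with_levels(levels):
    """levels: {k: [MiP values of the XY windows at that level]}"""
    rows = []
    for k, vals in levels.items():
        for j, v in enumerate(vals):
            rows.append({
                "i": 0, "j": j, "k": k, "cx_vox": 0, "cy_vox": j, "cz_vox": k,
                "cx_mm": 0.0, "cy_mm": 0.9 * j, "cz_mm": 0.9 * k,
                "n_solid": 900, "n_micro": 100, "n_air": 0, "n_mask": 0,
                "MiP": float(v), "MaP": 0.0, "TP": float(v), "SVF": 100.0 - v,
                "colony_fraction": 1.0, "valid": True,
            })
    return PorosityMap(windows=pd.DataFrame(rows), window_size_mm=0.9, voxel_size_um=90.0)


def test_profile_level_mean_and_sem():
    pmap = _map_with_levels({0: [4.0, 6.0], 1: [5.0, 5.0]})
    prof = extract_vertical_profile(pmap)
    assert prof.data.loc[0, "MiP_mean"] == 5.0
    assert prof.data.loc[0, "MiP_sem"] == pytest.approx(np.std([4, 6], ddof=1) / np.sqrt(2))  # = 1.0
    assert prof.data.loc[1, "MiP_sem"] == 0.0


def test_profile_needs_two_levels():
    with pytest.raises(ValueError, match=">= 2"):
        extract_vertical_profile(_map_with_levels({0: [5.0, 5.0]}))


def test_profile_flat_for_all_solid(small_phantom):
    from coralpore.porosity_mapping import compute_porosity_map
    from coralpore.segmentation import segment_tomogram
    from coralpore.synthetic_data import SyntheticTruth, generate_phantom

    truth = SyntheticTruth(mip_baseline_pct=0.0, mip_amplitude_pct=0.0,
                           map_baseline_pct=0.0, map_decrement_pct=0.0, noise_sd=0.0)
    tomo, _ = generate_phantom(truth, (60, 60, 140), voxel_size_um=24.3)
    # an all-solid colony has a degenerate histogram: fixed thresholds apply
    phases = segment_tomogram(tomo, air_threshold=50.0, mode="fixed",
                              t_low=50.0, t_high=150.0)
    prof = extract_vertical_profile(compute_porosity_map(phases))
    np.testing.assert_allclose(prof.data["SVF_mean"], 100.0)


def _profile_from_indices(z_indices, values=None):
    n = len(z_indices)
    values = values if values is not None else np.linspace(5, 10, n)
    df = pd.DataFrame({
        "z_index": z_indices,
        "z_center_vox": np.asarray(z_indices, dtype=float),
        "z_mm_phys": 0.9 * np.asarray(z_indices, dtype=float),
        "n_windows": 1,
        "MiP_mean": values, "MiP_sem": 0.0,
        "MaP_mean": 40.0 - np.asarray(values), "MaP_sem": 0.0,
        "TP_mean": 40.0, "TP_sem": 0.0, "SVF_mean": 60.0, "SVF_sem": 0.0,
    })
    return VerticalProfile(data=df, fragment_id="p")


class TestCoordinateNormalization:
    def test_largest_fragment_endpoints(self):
        prof = _profile_from_indices(list(range(10)))
        out = normalize_coordinates(prof, reference=(0, 9))
        assert out.data["z_mm"].iloc[0] == pytest.approx(0.45)
        assert out.data["z_mm"].iloc[-1] == pytest.approx(8.45)

    def test_midpoint(self):
        prof = _profile_from_indices([0, 5, 10])
        out = normalize_coordinates(prof, reference=(0, 10))
        assert out.data["z_norm"].iloc[1] == pytest.approx(0.5)
        assert out.data["z_mm"].iloc[1] == pytest.approx(4.45)

    def test_brute_force_grid(self):
        prof = _profile_from_indices(list(range(10)))
        out = normalize_coordinates(prof, reference=(0, 9))
        for j in range(10):
            assert out.data["z_norm"].iloc[j] == pytest.approx(j / 9)
            assert out.data["z_mm"].iloc[j] == pytest.approx((j / 9) * 8 + 0.45)

    def test_smaller_fragment_uses_reference_denominator(self):
        prof = _profile_from_indices([2, 3, 4, 5, 6])
        out = normalize_coordinates(prof, reference=(0, 9))
        # own minimum maps to 0, span normalized by the reference range
        assert out.data["z_norm"].iloc[0] == 0.0
        assert out.data["z_norm"].iloc[-1] == pytest.approx(4 / 9)

    def test_zero_reference_range_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_coordinates(_profile_from_indices([0, 1]), reference=(3, 3))

    def test_affine_reindexing_commutes(self):
        """Shifting/scaling the raw indices together with the reference
        leaves the normalized coordinate unchanged."""
        prof_a = _profile_from_indices([0, 2, 4, 6])
        prof_b = _profile_from_indices([10, 14, 18, 22])  # z -> 2z + 10
        out_a = normalize_coordinates(prof_a, reference=(0, 6))
        out_b = normalize_coordinates(prof_b, reference=(10, 22))
        np.testing.assert_allclose(out_a.data["z_mm"], out_b.data["z_mm"])


class TestVariableTransform:
    def test_hand_example(self):
        tp = transform_variable(values=np.array([5.0, 7.0, 10.0]))
        np.testing.assert_allclose(tp.delta, [0.0, 2.0, 5.0])
        assert tp.delta_max == 5.0
        np.testing.assert_allclose(tp.normalized, [0.0, 0.4, 1.0])

    def test_constant_profile_zero_range(self):
        with pytest.raises(ValueError, match="zero range"):
            transform_variable(values=np.array([3.0, 3.0, 3.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30).filter(
        lambda v: max(v) > min(v)))
    def test_min_to_zero_max_to_one(self, values):
        tp = transform_variable(values=np.array(values))
        assert tp.normalized.min() == 0.0
        assert tp.normalized.max() == 1.0
        assert (tp.delta >= 0).all()

    def test_idempotent_on_unit_range(self):
        tp = transform_variable(values=np.array([5.0, 7.0, 10.0]))
        tp2 = transform_variable(values=tp.normalized)
        np.testing.assert_allclose(tp2.normalized, tp.normalized)

    def test_reads_profile_column(self):
        prof = _profile_from_indices([0, 1, 2], values=np.array([5.0, 7.0, 10.0]))
        tp = transform_variable(prof, variable="MiP")
        np.testing.assert_allclose(tp.normalized, [0.0, 0.4, 1.0])
        assert tp.variable == "MiP"


class TestLoess:
    def test_reproduces_straight_line(self):
        x = np.linspace(0, 10, 25)
        y = 2.0 * x - 3.0
        curve = fit_loess(x, y, span=0.5)
        np.testing.assert_allclose(curve.fitted, 2.0 * curve.grid - 3.0, atol=1e-8)

    def test_agrees_with_statsmodels_on_line(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        x = np.linspace(0, 10, 30)
        y = 0.5 * x + 1.0
        curve = fit_loess(x, y, span=0.4)
        ref = lowess(y, x, frac=0.4, return_sorted=True)
        ours = np.interp(ref[:, 0], curve.grid, curve.fitted)
        np.testing.assert_allclose(ours, ref[:, 1], atol=1e-6)

    def test_gaussian_bump_argmax(self):
        x = np.linspace(0, 8, 30)
        y = np.exp(-0.5 * ((x - 3.1) / 0.8) ** 2)
        curve = fit_loess(x, y, span=0.3)
        step = curve.grid[1] - curve.grid[0]
        assert abs(curve.grid[np.argmax(curve.fitted)] - 3.1) <= step + 1e-12

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="too few"):
            fit_loess(np.arange(3.0), np.arange(3.0), span=0.3)

    def test_span_out_of_range(self):
        with pytest.raises(ValueError, match="span"):
            fit_loess(np.arange(10.0), np.arange(10.0), span=1.5)

    def test_weights_pull_fit(self):
        x = np.tile(np.linspace(0, 9, 10), 2)
        y = np.concatenate([np.zeros(10), np.ones(10)])
        w_hi = np.concatenate([np.ones(10), 9 * np.ones(10)])
        curve = fit_loess(x, y, span=0.5, weights=w_hi)
        assert curve.fitted.mean() > 0.8  # dominated by the heavy points


class TestExtremum:
    def test_peak_of_three_point_curve(self):
        curve = LoessCurve(grid=np.array([0.45, 4.45, 8.45]),
                           fitted=np.array([1.0, 5.0, 2.0]), span=0.3)
        ext = locate_extremum(curve, kind="peak")
        assert ext.location_mm == 4.45
        assert ext.value == 5.0
        assert not ext.at_boundary

    def test_monotone_curve_flagged_boundary(self):
        curve = LoessCurve(grid=np.linspace(0, 1, 11),
                           fitted=np.linspace(0, 1, 11), span=0.3)
        ext = locate_extremum(curve, kind="peak")
        assert ext.location_mm == 1.0
        assert ext.at_boundary

    def test_valley_and_tie_break_apical(self):
        curve = LoessCurve(grid=np.array([0.0, 1.0, 2.0, 3.0]),
                           fitted=np.array([5.0, 2.0, 2.0, 5.0]), span=0.3)
        ext = locate_extremum(curve, kind="valley")
        assert ext.location_mm == 1.0  # first (apical) of the tied minima


class TestZones:
    def _profile_mm(self, z_mm):
        df = pd.DataFrame({
            "z_index": np.arange(len(z_mm)),
            "z_center_vox": np.arange(len(z_mm), dtype=float),
            "z_mm_phys": np.asarray(z_mm, dtype=float),
            "z_mm": np.asarray(z_mm, dtype=float),
            "n_windows": 1,
            "MiP_mean": 5.0, "MiP_sem": 0.0, "MaP_mean": 30.0, "MaP_sem": 0.0,
            "TP_mean": 35.0, "TP_sem": 0.0, "SVF_mean": 65.0, "SVF_sem": 0.0,
        })
        return VerticalProfile(data=df, fragment_id="z")

    def _meta(self, low, high):
        return FragmentMeta("28G", "P. panamensis", "Pacific", 12.0, (low, high))

    def test_three_way_partition(self):
        prof = self._profile_mm([0.45, 1.45, 2.45, 3.45, 7.45])
        za = assign_zones(prof, self._meta(1.1, 2.9))
        assert list(za.labels) == [
            "coral_tissue", "green_band", "green_band", "skeleton", "skeleton"]
        assert za.counts == {"coral_tissue": 1, "green_band": 2, "skeleton": 2}
        assert sum(za.counts.values()) == len(prof.data)

    def test_band_covering_everything(self):
        prof = self._profile_mm([1.0, 2.0, 3.0])
        za = assign_zones(prof, self._meta(0.5, 3.5))
        assert (za.labels == "green_band").all()

    def test_band_outside_profile_rejected(self):
        prof = self._profile_mm([0.45, 4.45, 8.45])
        with pytest.raises(ValueError, match="does not overlap"):
            assign_zones(prof, self._meta(9.5, 9.9))


def test_banded_phantom_peak_recovery(small_phantom):
    """End-to-end on one phantom: the LOESS microporosity peak lands within
    one window of the generator's band center."""
    from coralpore.porosity_mapping import compute_porosity_map
    from coralpore.profile_analysis import fit_map_loess
    from coralpore.segmentation import segment_tomogram

    truth, tomo, _ = small_phantom
    pmap = compute_porosity_map(segment_tomogram(tomo))
    curve = fit_map_loess(pmap, variable="MiP", span=0.3)
    ext = locate_extremum(curve, kind="peak")
    assert abs(ext.location_mm - truth.band_center_mm) <= 0.9
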