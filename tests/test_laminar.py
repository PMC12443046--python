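import numpy as np
import pytest

import hippovaso as hv
from hippovaso import glm, laminar
from hippovaso import phantom as ph


def _flat_sheets(n_v=25, thickness_mm=4.0):
    """Parallel planar sheets: inner at z=0, outer at z=thickness."""
    rng = np.random.default_rng(0)
    xy = rng.uniform(5.0, 20.0, (n_v, 2))
    inner = np.column_stack([xy, np.zeros(n_v)])
    outer = np.column_stack([xy, np.full(n_v, thickness_mm)])
    mid = (inner + outer) / 2
    sub = np.full(n_v, ph.SUBFIELD_CODES["CA1"], dtype=int)
    return {"inner": inner, "mid": mid, "outer": outer}, sub


class TestComputeDepthBins:
    def test_flat_sheet_spacing(self):
        surfaces, sub = _flat_sheets(thickness_mm=4.0)
        bins = laminar.compute_depth_bins(surfaces, sub)
        np.testing.assert_allclose(bins.spacing_mm, 4.0 / 19, rtol=1e-12)
        # consecutive bins equidistant along the segment
        steps = np.diff(bins.coords, axis=1)
        norms = np.linalg.norm(steps, axis=2)
        np.testing.assert_allclose(norms, 4.0 / 19, rtol=1e-6)

    def test_bin_convention(self):
        surfaces, sub = _flat_sheets()
        bins = laminar.compute_depth_bins(surfaces, sub)
        # bin 11 (index 10) on the inner surface, bin 30 on the outer
        np.testing.assert_allclose(bins.coords[:, 10], surfaces["inner"],
                                   atol=1e-12)
        np.testing.assert_allclose(bins.coords[:, 29], surfaces["outer"],
                                   atol=1e-12)
        # extension continues beyond the inner surface (lower z here)
        assert np.all(bins.coords[:, 0, 2] < surfaces["inner"][:, 2])

    def test_ca3_has_no_extension_bins(self, phantom):
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        ca3 = bins.vertices_of("CA3")
        assert ca3.size > 0
        assert np.isnan(bins.coords[ca3, :10]).all()
        assert np.isfinite(bins.coords[ca3, 10:]).all()

    def test_extended_subfields_have_30_bins(self, phantom):
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        for sf in ("Sub", "CA1", "CA2"):
            v = bins.vertices_of(sf)
            assert np.isfinite(bins.coords[v]).all()

    def test_dg_ca4_vertices_excluded(self, phantom):
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        dg = phantom.subfield_of_vertex == ph.SUBFIELD_CODES["DG_CA4"]
        assert not bins.valid_vertex[dg].any()

    def test_degenerate_vertex_flagged(self):
        surfaces, sub = _flat_sheets()
        surfaces["outer"][3] = surfaces["inner"][3]
        with pytest.warns(UserWarning, match="degenerate"):
            bins = laminar.compute_depth_bins(surfaces, sub)
        assert not bins.valid_vertex[3]
        assert bins.valid_vertex.sum() == len(sub) - 1

    def test_anchor_failure_flagged(self):
        surfaces, sub = _flat_sheets()
        surfaces["mid"][5, 2] += 3.0  # push anchor off the segment
        with pytest.warns(UserWarning, match="anchor"):
            bins = laminar.compute_depth_bins(surfaces, sub)
        assert not bins.valid_vertex[5]

    def test_orientation_auto_detected_from_labels(self, phantom):
        ref = laminar.compute_depth_bins(
            phantom.surfaces, phantom.subfield_of_vertex,
            phantom.label_volume, phantom.affine,
        )
        swapped = {"inner": phantom.surfaces["outer"],
                   "outer": phantom.surfaces["inner"],
                   "mid": phantom.surfaces["mid"]}
        out = laminar.compute_depth_bins(
            swapped, phantom.subfield_of_vertex,
            phantom.label_volume, phantom.affine,
        )
        assert out.flipped and not ref.flipped
        np.testing.assert_allclose(out.coords, ref.coords, equal_nan=True)


class TestSampleProfiles:
    def test_linear_ramp_field(self, phantom):
        # analytic field f = depth fraction along inner->outer
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        geo = phantom.geometry
        shape = phantom.label_volume.shape
        cx, cy = (shape[0] - 1) / 2, (shape[1] - 1) / 2
        ix, iy, _ = np.indices(shape)
        r = np.hypot(ix - cx, iy - cy)
        frac = (r - (geo.mid_radius_vox - geo.thickness_vox / 2)) / geo.thickness_vox
        pset = laminar.sample_profiles(frac, bins, phantom.affine)
        for sf, prof in pset.profiles.items():
            expected = (np.arange(1, 31) - 11) / 19.0
            got = prof[10:]
            np.testing.assert_allclose(got, expected[10:], atol=0.02)

    def test_constant_volume_flat_profile(self, phantom):
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        pset = laminar.sample_profiles(np.full(phantom.label_volume.shape, 3.5),
                                       bins, phantom.affine)
        for prof in pset.profiles.values():
            finite = prof[np.isfinite(prof)]
            np.testing.assert_allclose(finite, 3.5, rtol=1e-12)

    def test_sampling_linearity(self, phantom):
        rng = np.random.default_rng(0)
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        u = rng.normal(size=phantom.label_volume.shape)
        v = rng.normal(size=phantom.label_volume.shape)
        a, b = 2.5, -1.25
        combo = laminar.sample_profiles(a * u + b * v, bins, phantom.affine)
        pu = laminar.sample_profiles(u, bins, phantom.affine)
        pv = laminar.sample_profiles(v, bins, phantom.affine)
        for sf in combo.profiles:
            np.testing.assert_allclose(
                combo.profiles[sf], a * pu.profiles[sf] + b * pv.profiles[sf],
                rtol=1e-9, equal_nan=True,
            )

    def test_depth_impulse_localization(self, phantom):
        # impulse layer at depth fraction d -> profile argmax at nearest bin
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        geo = phantom.geometry
        shape = phantom.label_volume.shape
        cx, cy = (shape[0] - 1) / 2, (shape[1] - 1) / 2
        ix, iy, _ = np.indices(shape)
        r = np.hypot(ix - cx, iy - cy)
        for d in np.linspace(0.1, 0.9, 10):
            r_d = geo.mid_radius_vox - geo.thickness_vox / 2 + d * geo.thickness_vox
            vol = np.exp(-0.5 * ((r - r_d) / 0.8) ** 2)
            pset = laminar.sample_profiles(vol, bins, phantom.affine)
            target_bin = 11 + d * 19  # continuous bin coordinate
            for sf, prof in pset.profiles.items():
                got = np.nanargmax(prof) + 1
                assert abs(got - target_bin) <= 1.0, (sf, d)

    def test_out_of_bounds_error(self, phantom):
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        with pytest.raises(ValueError, match="outside"):
            laminar.sample_profiles(np.zeros((3, 3, 3)), bins, phantom.affine)


def _profile_set(n_t=100, seed=0, contrast=""):
    rng = np.random.default_rng(seed)
    profiles = {"CA1": rng.normal(10.0, 1.0, (30, n_t))}
    return laminar.DepthProfileSet(
        profiles=profiles,
        sem={"CA1": np.full((30, n_t), np.nan)},
        n_vertices={"CA1": 50},
        contrast=contrast,
        timestamp_ms=np.arange(n_t) * 6000.0,
    )


class TestZtransform:
    def test_baseline_mean_zero_sd_one(self, design):
        pset = _profile_set()
        z = laminar.ztransform_profiles(pset, design, 3000.0)
        idx = z.provenance["ztransform"]["baseline_indices"]
        base = z.profiles["CA1"][:, idx]
        np.testing.assert_allclose(base.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(base.std(axis=1, ddof=1), 1.0, rtol=1e-10)

    def test_delay_changes_baseline_set(self, design):
        pset = _profile_set()
        z0 = laminar.ztransform_profiles(pset, design, 3000.0, delay_s=0.0)
        z4 = laminar.ztransform_profiles(pset, design, 3000.0, delay_s=4.0)
        assert (z0.provenance["ztransform"]["baseline_indices"]
                != z4.provenance["ztransform"]["baseline_indices"])

    def test_shift_invariance(self, design):
        pset = _profile_set(seed=3)
        shifted = _profile_set(seed=3)
        shifted.profiles["CA1"] = shifted.profiles["CA1"] + 123.0
        za = laminar.ztransform_profiles(pset, design, 3000.0)
        zb = laminar.ztransform_profiles(shifted, design, 3000.0)
        np.testing.assert_allclose(za.profiles["CA1"], zb.profiles["CA1"],
                                   rtol=1e-9)

    def test_zero_sd_flagged(self, design):
        pset = _profile_set()
        pset.profiles["CA1"][5] = 1.0  # constant depth
        z = laminar.ztransform_profiles(pset, design, 3000.0)
        assert np.isnan(z.profiles["CA1"][5]).all()

    def test_requires_math_volumes(self):
        pset = _profile_set(n_t=4)
        d = ph.TaskDesign(events=[(0.0, 18.0, "memory")], n_trials_per_condition=1)
        with pytest.raises(ValueError, match="math"):
            laminar.ztransform_profiles(pset, d, 3000.0)


class TestLaminarGlm:
    def test_noise_free_recovery(self, phantom, design, quiet_run):
        vaso = quiet_run["vaso"]
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        pset = laminar.sample_profiles(vaso.data, bins, phantom.affine,
                                       contrast="vaso_corrected",
                                       timestamp_ms=vaso.timestamp_ms)
        X = glm.build_design(design, None, vaso.timestamp_ms)
        lc = laminar.laminar_glm(pset, X)
        assert lc.negated_for_vaso
        # the sampled laminar signal is exactly a multiple of the regressor,
        # so the depth contrast equals the sampled amplitude to ~1e-6
        h = X.column("memory")
        for sf, con in lc.contrast.items():
            prof = pset.profiles[sf]
            finite = np.isfinite(con)
            amp = -(prof[finite] @ (h - h.mean())) / ((h - h.mean()) @ h)
            np.testing.assert_allclose(con[finite], amp, rtol=1e-6, atol=1e-10)

    def test_orthogonal_profiles_zero_contrast(self, design):
        ts = np.arange(100) * 6000.0
        X = glm.build_design(design, None, ts)
        pset = laminar.DepthProfileSet(
            profiles={"CA1": np.ones((30, 100)) * 5.0},
            sem={"CA1": np.full((30, 100), np.nan)},
            n_vertices={"CA1": 10},
            timestamp_ms=ts,
        )
        lc = laminar.laminar_glm(pset, X)
        np.testing.assert_allclose(lc.contrast["CA1"], 0.0, atol=1e-10)

    def test_bold_vaso_peak_dissociation(self, phantom, design, quiet_run):
        # BOLD weighted to SRLM/inner in CA1; CBV peaks mid-depth
        bins = laminar.compute_depth_bins(phantom.surfaces,
                                          phantom.subfield_of_vertex)
        X = glm.build_design(design, None, quiet_run["vaso"].timestamp_ms)
        peaks = {}
        for name in ("vaso", "bold"):
            s = quiet_run[name]
            pset = laminar.sample_profiles(s.data, bins, phantom.affine,
                                           contrast=s.contrast,
                                           timestamp_ms=s.timestamp_ms)
            lc = laminar.laminar_glm(pset, X)
            con = lc.contrast["CA1"]
            peaks[name] = np.nanargmax(con) + 1
        assert peaks["bold"] <= 12       # SRLM / inner surface
        assert 17 <= peaks["vaso"] <= 24  # mid-depth
        assert peaks["bold"] != peaks["vaso"]

    def test_multi_run_sem(self, design):
        ts = np.arange(100) * 6000.0
        X = glm.build_design(design, None, ts)
        runs = [_profile_set(seed=s) for s in (1, 2, 3)]
        lc = laminar.laminar_glm(runs, X)
        assert lc.n_runs == 3
        assert np.isfinite(lc.sem["CA1"]).all()

    def test_time_mismatch_rejected(self, design):
        ts = np.arange(100) * 6000.0
        X = glm.build_design(design, None, ts)
        pset = _profile_set(n_t=90)
        with pytest.raises(ValueError, match="match"):
            laminar.laminar_glm(pset, X)
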