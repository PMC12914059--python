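"""Temporal-frequency analysis: spectra, power-law fits, phasors, maps,
compartment aggregation, group tests, visualization helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepuv import dynamics, synth

FR = 8.0
N = 500


def power_law_spectrum(beta, n=N, fr=FR):
    freqs = np.fft.rfftfreq(n, 1 / fr)[1:]
    return dynamics.PixelSpectrum(freqs, freqs ** -float(beta))


class TestPixelSpectrum:
    def test_sinusoid_concentrates_in_its_bin(self):
        t = np.arange(N) / FR
        sp = dynamics.pixel_spectrum(np.sin(2 * np.pi * 1.0 * t), FR)
        assert sp.frequencies[np.argmax(sp.magnitude)] == pytest.approx(1.0, abs=0.02)

    def test_constant_offset_invariance(self, rng):
        tr = rng.normal(0, 1, N)
        a = dynamics.pixel_spectrum(tr, FR)
        b = dynamics.pixel_spectrum(tr + 3.7, FR)
        assert np.allclose(a.magnitude, b.magnitude)

    def test_grid_excludes_dc_and_bounded_by_nyquist(self, rng):
        sp = dynamics.pixel_spectrum(rng.normal(0, 1, N), FR)
        assert sp.frequencies[0] > 0
        assert sp.frequencies[-1] <= FR / 2
        assert np.all(np.diff(sp.frequencies) > 0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            dynamics.pixel_spectrum(np.zeros(5), FR)


class TestFitPowerLaw:
    @pytest.mark.parametrize("beta", [1.0, 2.0])
    def test_exact_power_law_recovered_exactly(self, beta):
        b, r2 = dynamics.fit_power_law(power_law_spectrum(beta))
        assert b == pytest.approx(beta, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_spectrum_gives_zero_exponent(self):
        b, r2 = dynamics.fit_power_law(power_law_spectrum(0.0))
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_zero_bins_dropped_before_fit(self):
        sp = power_law_spectrum(1.0)
        mags = sp.magnitude.copy()
        mags[::7] = 0.0
        b, _ = dynamics.fit_power_law(dynamics.PixelSpectrum(sp.frequencies, mags))
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_flagged_undefined(self):
        sp = dynamics.PixelSpectrum(power_law_spectrum(1.0).frequencies,
                                    np.zeros(N // 2))
        b, r2 = dynamics.fit_power_law(sp)
        assert np.isnan(b) and np.isnan(r2)

    def test_exclusion_rule_no_bin_below_f_min(self):
        # for 500 frames @ 8 Hz the retained grid starts at 0.112 Hz
        freqs = np.fft.rfftfreq(N, 1 / FR)[1:]
        retained = freqs[freqs >= dynamics.DEFAULT_F_MIN]
        assert retained[0] == pytest.approx(0.112, abs=1e-9)
        assert np.all(retained >= 0.1)


class TestPhasor:
    def test_constant_trace_maps_to_origin(self):
        sp = dynamics.pixel_spectrum(np.full(N, 0.5), FR)
        g, s = dynamics.phasor(sp)
        assert (g, s) == (0.0, 0.0)

    def test_delta_at_x_zero_maps_to_unit_g(self):
        # spectral mass entirely at f_min (x = 0): the delta-decay limit
        freqs = np.linspace(dynamics.DEFAULT_F_MIN, FR / 2, 40)
        mags = np.zeros(40)
        mags[0] = 1.0
        g, s = dynamics.phasor(dynamics.PixelSpectrum(freqs, mags))
        assert (g, s) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_distance_from_origin_increases_with_beta(self):
        dists = [np.hypot(*dynamics.phasor(power_law_spectrum(b)))
                 for b in np.linspace(0.0, 3.0, 16)]
        assert np.all(np.diff(dists) > 0)

    def test_advective_beats_brownian_distance(self):
        d2 = np.hypot(*dynamics.phasor(power_law_spectrum(2.0)))
        d1 = np.hypot(*dynamics.phasor(power_law_spectrum(1.0)))
        assert d2 > d1

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(lo=st.floats(0.0, 2.0), delta=st.floats(0.1, 1.0))
    def test_distance_monotone_property(self, lo, delta):
        d_lo = np.hypot(*dynamics.phasor(power_law_spectrum(lo)))
        d_hi = np.hypot(*dynamics.phasor(power_law_spectrum(lo + delta)))
        assert d_hi > d_lo


class TestDynamicMaps:
    def test_defined_pixels_match_mask_area(self, subtype_scene):
        cfg, _, truth, stack = subtype_scene
        maps = dynamics.dynamic_maps(stack, truth.label_mask, cfg.frame_rate)
        assert maps.defined.sum() == (truth.label_mask > 0).sum()
        assert np.all(np.isnan(maps.beta[truth.label_mask == 0]))

    def test_identical_stacks_identical_maps(self, subtype_scene):
        cfg, _, truth, stack = subtype_scene
        m1 = dynamics.dynamic_maps(stack[:64], truth.label_mask, cfg.frame_rate)
        m2 = dynamics.dynamic_maps(stack[:64].copy(), truth.label_mask, cfg.frame_rate)
        assert np.array_equal(m1.beta, m2.beta, equal_nan=True)
        assert np.array_equal(m1.g, m2.g, equal_nan=True)

    def test_global_offset_changes_nothing(self, subtype_scene):
        cfg, _, truth, stack = subtype_scene
        sub = stack[:64].astype(np.float64)
        m1 = dynamics.dynamic_maps(sub, truth.label_mask, cfg.frame_rate)
        m2 = dynamics.dynamic_maps(sub + 0.17, truth.label_mask, cfg.frame_rate)
        assert np.allclose(m1.beta, m2.beta, equal_nan=True, atol=1e-8)
        assert np.allclose(m1.s, m2.s, equal_nan=True, atol=1e-8)

    def test_empty_mask_gives_empty_maps(self, subtype_scene):
        cfg, _, truth, stack = subtype_scene
        maps = dynamics.dynamic_maps(stack[:16], np.zeros_like(truth.label_mask),
                                     cfg.frame_rate)
        assert maps.defined.sum() == 0

    def test_cytoplasm_more_active_than_nucleus(self, subtype_scene):
        cfg, _, truth, stack = subtype_scene
        maps = dynamics.dynamic_maps(stack, truth.label_mask, cfg.frame_rate)
        for row in truth.cells.itertuples():
            agg = dynamics.aggregate_cell_dynamics(
                maps, truth.label_mask == row.cell_id,
                truth.nucleus_mask == row.cell_id)
            assert agg["cyto_mean_beta"] > agg["nucleus_mean_beta"]


class TestAggregate:
    def _uniform_maps(self, value=1.4, shape=(32, 32)):
        plane = np.full(shape, value)
        return dynamics.DynamicMaps(plane.copy(), plane.copy(), plane.copy(),
                                    np.ones(shape), FR)

    def test_uniform_maps_give_uniform_means(self):
        maps = self._uniform_maps(1.4)
        cell = np.zeros((32, 32), bool)
        cell[8:24, 8:24] = True
        nucleus = np.zeros_like(cell)
        nucleus[12:20, 12:20] = True
        agg = dynamics.aggregate_cell_dynamics(maps, cell, nucleus)
        for comp in ("cell", "nucleus", "cyto"):
            assert agg[f"{comp}_mean_beta"] == pytest.approx(1.4)
            assert agg[f"{comp}_mean_gs"] == pytest.approx(1.4 ** 2)

    def test_cell_mean_is_area_weighted_compartment_mean(self, subtype_scene):
        cfg, _, truth, stack = subtype_scene
        maps = dynamics.dynamic_maps(stack[:64], truth.label_mask, cfg.frame_rate)
        cell = truth.label_mask == 1
        nucleus = truth.nucleus_mask == 1
        agg = dynamics.aggregate_cell_dynamics(maps, cell, nucleus)
        n_nuc = nucleus.sum()
        n_cyt = (cell & ~nucleus).sum()
        weighted = (agg["nucleus_mean_beta"] * n_nuc + agg["cyto_mean_beta"] * n_cyt) / (n_nuc + n_cyt)
        assert agg["cell_mean_beta"] == pytest.approx(weighted, rel=1e-9)

    def test_empty_nucleus_flagged(self):
        maps = self._uniform_maps()
        cell = np.zeros((32, 32), bool)
        cell[4:12, 4:12] = True
        agg = dynamics.aggregate_cell_dynamics(maps, cell, np.zeros_like(cell))
        assert agg["nucleus_flag"]
        assert np.isnan(agg["nucleus_mean_beta"])


class TestCompareGroups:
    def test_identical_groups_null(self):
        t, p = dynamics.compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_separated_normals_tiny_p(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        t, p = dynamics.compare_groups(a, b)
        assert p < 1e-10

    def test_swap_negates_t_preserves_p(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 12)
        t1, p1 = dynamics.compare_groups(a, b)
        t2, p2 = dynamics.compare_groups(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_closed_form_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        t, _ = dynamics.compare_groups(a, b)
        assert t == pytest.approx(expected)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            dynamics.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestVisualization:
    def test_pseudocolor_endpoints_and_midpoint(self):
        low = dynamics.pseudocolor(np.full((4, 4), 1.0))
        high = dynamics.pseudocolor(np.full((4, 4), 2.0))
        mid = dynamics.pseudocolor(np.full((4, 4), 1.5))
        assert np.allclose(low[0, 0], [0, 0, 1])
        assert np.allclose(high[0, 0], [1, 0, 0])
        assert np.allclose(mid[0, 0], [0.5, 0, 0.5])

    def test_pseudocolor_clips_and_rejects_degenerate_range(self):
        img = dynamics.pseudocolor(np.array([[0.0, 5.0]]))
        assert np.allclose(img[0, 0], [0, 0, 1]) and np.allclose(img[0, 1], [1, 0, 0])
        with pytest.raises(ValueError):
            dynamics.pseudocolor(np.zeros((2, 2)), value_range=(1.0, 1.0))

    def test_line_profile_flat_for_uniform_map(self):
        cell = np.zeros((40, 40), bool)
        cell[10:30, 5:35] = True
        prof = dynamics.line_profile(np.full((40, 40), 2.2), cell)
        assert not prof.short_flag
        assert prof.profile.shape == (30,)
        assert np.allclose(prof.profile, 2.2)

    def test_line_profile_shows_central_nuclear_dip(self, subtype_scene):
        cfg, _, truth, stack = subtype_scene
        maps = dynamics.dynamic_maps(stack, truth.label_mask, cfg.frame_rate)
        row = truth.cells.iloc[0]
        prof = dynamics.line_profile(maps.beta, truth.label_mask == row.cell_id)
        p = prof.profile[np.isfinite(prof.profile)]
        center = p[len(p) // 2 - 2: len(p) // 2 + 3].mean()
        edges = np.concatenate([p[:3], p[-3:]]).mean()
        assert center < edges

    def test_line_profile_short_cell_flagged(self):
        cell = np.zeros((12, 20), bool)
        cell[3:8, 2:18] = True
        prof = dynamics.line_profile(np.ones((12, 20)), cell)
        assert prof.short_flag


class TestStackOps:
    def test_truncate_keeps_leading_frames(self, subtype_scene):
        *_, stack = subtype_scene
        short = dynamics.truncate_stack(stack, 300)
        assert short.shape[0] == 300
        assert np.array_equal(short, stack[:300])
        assert dynamics.truncate_stack(stack, 500).shape[0] == 500
        with pytest.raises(ValueError):
            dynamics.truncate_stack(stack, 4)

    def test_degrade_halves_frame_size(self, subtype_scene):
        *_, stack = subtype_scene
        deg = dynamics.degrade_resolution(stack[:8], 2)
        assert deg.shape == (8, stack.shape[1] // 2, stack.shape[2] // 2)

    def test_degrade_preserves_constant_frames(self):
        out = dynamics.degrade_resolution(np.full((4, 64, 64), 0.3), 2)
        assert np.allclose(out, 0.3)

    def test_degrade_validation(self):
        with pytest.raises(ValueError):
            dynamics.degrade_resolution(np.zeros((4, 64, 64)), 3.5)
        with pytest.raises(ValueError):
            dynamics.degrade_resolution(np.zeros((4, 24, 24)), 2)

    def test_degradation_reduces_subtype_contrast(self, subtype_scene):
        # halving lateral resolution blurs compartments together and
        # shrinks the CD4-vs-CD8 cytoplasmic beta separation
        cfg, frame, truth, stack = subtype_scene
        maps_full = dynamics.dynamic_maps(stack, truth.label_mask, cfg.frame_rate)
        deg = dynamics.degrade_resolution(stack, 2)
        maps_deg = dynamics.dynamic_maps(deg, truth.label_mask[::2, ::2], cfg.frame_rate)

        def sep(maps, lab_mask, nuc_mask):
            means = {}
            for row in truth.cells.itertuples():
                cyto = (lab_mask == row.cell_id) & ~(nuc_mask == row.cell_id)
                means.setdefault(row.label, []).append(np.nanmean(maps.beta[cyto]))
            return np.mean(means["cd4"]) - np.mean(means["cd8"])

        full = sep(maps_full, truth.label_mask, truth.nucleus_mask)
        degraded = sep(maps_deg, truth.label_mask[::2, ::2], truth.nucleus_mask[::2, ::2])
        assert 0 < degraded < full
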