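import numpy as np
import pandas as pd
import pytest

from lvmotion.fit import (
    FitConfig,
    FitResult,
    GridSpec,
    ParamProfile,
    aggregate_profiles,
    figure_of_merit,
    fit_frame,
    fit_series,
)
from lvmotion.mesh import ModelImage, build_uniform_mesh, deform_mesh, rasterize_mesh
from lvmotion.phantom import (
    PhantomSpec,
    default_geometry,
    default_profiles,
    render_series,
)
from lvmotion.preprocess import estimate_geometry
from lvmotion.transform import ModelParams

EXAMPLE_ALPHA_NORM = 0.31
EXAMPLE_BETA_NORM = -0.14


def make_model(zero_mask):
    pixels = np.ones_like(zero_mask, dtype=np.uint8)
    pixels[zero_mask] = 0
    return ModelImage(pixels=pixels, pixel_spacing=(1.0, 1.0), center_pixel=(0.0, 0.0))


class TestFigureOfMerit:
    def test_perfect_match_is_zero(self):
        mask = np.zeros((8, 8), bool)
        mask[2, 2:6] = True
        model = make_model(mask)
        image = model.pixels.astype(float)
        assert figure_of_merit(model, image) == 0.0

    def test_complete_mismatch_is_one(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 1:5] = True
        model = make_model(mask)
        assert figure_of_merit(model, np.ones((8, 8))) == 1.0

    def test_half_match_hand_built(self):
        # oracle: direct sum over an 8-pixel case — 4 mesh pixels on 0s,
        # 4 on 1s -> mean squared difference 0.5
        mask = np.zeros((4, 4), bool)
        mask[0, :4] = True
        mask[1, :4] = True
        model = make_model(mask)
        image = np.ones((4, 4))
        image[0, :4] = 0.0
        assert figure_of_merit(model, image) == pytest.approx(0.5)

    def test_no_mesh_pixels_raises(self):
        model = make_model(np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            figure_of_merit(model, np.ones((4, 4)))

    def test_shape_mismatch_raises(self):
        model = make_model(np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            figure_of_merit(model, np.ones((5, 5)))


class TestFitFrame:
    def test_self_match_recovers_null(self, estimated_geometry, base_mesh):
        img = rasterize_mesh(base_mesh, (256, 256), (1.0, 1.0),
                             estimated_geometry.center)
        grid = GridSpec(alpha_norm_range=(0.0, 0.05), beta_norm_range=(-0.05, 0.05),
                        refine=False)
        res = fit_frame(img.pixels.astype(float), estimated_geometry, base_mesh, grid)
        assert (res.alpha, res.beta) == (0.0, 0.0)
        assert res.F_best == 0.0

    def test_worked_example_recovery(self, estimated_geometry, base_mesh, example_binary):
        res = fit_frame(example_binary, estimated_geometry, base_mesh, GridSpec(),
                        frame_index=1)
        assert res.alpha_norm == pytest.approx(EXAMPLE_ALPHA_NORM, abs=0.01)
        assert res.beta_norm == pytest.approx(EXAMPLE_BETA_NORM, abs=0.01)
        assert 0.0 <= res.F_best <= res.F_initial <= 1.0
        assert res.merit_reduction_pct > 0.0

    def test_equals_brute_force_oracle(self, estimated_geometry, base_mesh, example_binary):
        # oracle: naive double loop over a 21x21 grid using the public
        # deform -> rasterize -> figure_of_merit route
        grid = GridSpec(alpha_norm_range=(0.21, 0.41), beta_norm_range=(-0.24, -0.04),
                        refine=False)
        res = fit_frame(example_binary, estimated_geometry, base_mesh, grid)

        r_epi = estimated_geometry.r_epi
        best = None
        n_cells = 0
        for an in grid.coarse_alphas():
            for bn in grid.coarse_betas():
                n_cells += 1
                deformed = deform_mesh(base_mesh, ModelParams(an * r_epi, bn * r_epi))
                img = rasterize_mesh(deformed, example_binary.shape, (1.0, 1.0),
                                     estimated_geometry.center)
                f = figure_of_merit(img, example_binary)
                key = (f, abs(an), abs(bn), an, bn)
                if best is None or key < best:
                    best = key
        assert n_cells == 21 * 21
        assert res.F_best == best[0]
        assert res.alpha_norm == pytest.approx(best[3], abs=1e-12)
        assert res.beta_norm == pytest.approx(best[4], abs=1e-12)

    def test_minimizer_optimality_exhaustive(self, estimated_geometry, base_mesh,
                                             example_binary):
        from lvmotion.fit import _GridEvaluator

        grid = GridSpec(alpha_norm_range=(0.28, 0.34), beta_norm_range=(-0.17, -0.11),
                        refine=False)
        res = fit_frame(example_binary, estimated_geometry, base_mesh, grid)
        ev = _GridEvaluator(base_mesh, estimated_geometry, example_binary)
        _, _, F = ev.scan(grid.coarse_alphas(), grid.coarse_betas())
        assert res.F_best <= np.nanmin(F) + 1e-15
        assert np.all((F >= 0) | np.isnan(F)) and np.nanmax(F) <= 1.0

    def test_out_of_domain_cells_skipped(self, estimated_geometry, base_mesh,
                                         example_binary):
        # alpha/r_epi = 0.6 -> alpha = 18 mm > r_endo: cells must be skipped,
        # not crash the scan; the minimizer stays inside the domain
        grid = GridSpec(alpha_norm_range=(0.0, 0.6), beta_norm_range=(0.0, 0.0),
                        refine=False)
        res = fit_frame(example_binary, estimated_geometry, base_mesh, grid)
        r_min = base_mesh.radii.min()
        assert res.alpha < r_min

    def test_all_cells_out_of_domain_raises(self, estimated_geometry, base_mesh,
                                            example_binary):
        grid = GridSpec(alpha_norm_range=(0.55, 0.6), beta_norm_range=(0.0, 0.0),
                        refine=False)
        with pytest.raises(ValueError):
            fit_frame(example_binary, estimated_geometry, base_mesh, grid)

    def test_blank_frame_prefers_null_model(self, estimated_geometry, base_mesh):
        grid = GridSpec(alpha_norm_range=(0.0, 0.05), beta_norm_range=(-0.03, 0.03),
                        refine=False)
        res = fit_frame(np.ones((256, 256)), estimated_geometry, base_mesh, grid)
        assert (res.alpha, res.beta) == (0.0, 0.0)
        assert res.F_best == 1.0


@pytest.fixture(scope="module")
def undeformed_series():
    spec = PhantomSpec(n_frames=3, fading=np.ones(3))
    series, _ = render_series(spec)
    series.geometry = estimate_geometry(series.frames[0], pixel_spacing=(1.0, 1.0))
    return series


class TestFitSeries:
    def test_identical_frames_all_null(self):
        # model-consistent frames: each frame IS the raster of the mesh
        # the fitter will build, so the null model scores F = 0 exactly
        from lvmotion.mesh import build_uniform_mesh, rasterize_mesh
        from lvmotion.preprocess import LVGeometry, TaggedSeries

        geom = LVGeometry(center=(127.5, 127.5), r_epi=30.0, r_endo=15.0)
        cfg = FitConfig(
            grid=GridSpec(alpha_norm_range=(0.0, 0.03),
                          beta_norm_range=(-0.02, 0.02), refine=False)
        )
        mesh = build_uniform_mesh(geom, cfg.tag_spacing_mm, cfg.line_width_mm,
                                  sample_step=cfg.sample_step_factor)
        raster = rasterize_mesh(mesh, (256, 256), (1.0, 1.0), geom.center)
        frame = raster.pixels.astype(float)
        series = TaggedSeries(
            frames=[frame, frame, frame],
            times=np.array([0.0, 1 / 3, 2 / 3]),
            pixel_spacing=(1.0, 1.0),
            T_cardiac=1.0,
            geometry=geom,
        )
        profile = fit_series(series, cfg)
        assert np.all(profile.table["alpha_norm"] == 0.0)
        assert np.all(profile.table["beta_norm"] == 0.0)
        assert np.all(profile.table["F_best"] == 0.0)

    def test_end_to_end_recovery_bounded(self):
        # sub-pixel sampling keeps every phase within two coarse grid
        # steps of the generating profile (small-alpha frames are
        # pixel-quantization limited; see the fitter docstring)
        alpha_prof, beta_prof = default_profiles("apex")
        geometry = default_geometry()
        geometry.slice_level = "apex"
        spec = PhantomSpec(geometry=geometry, alpha_profile=alpha_prof,
                           beta_profile=beta_prof)
        series, truth = render_series(spec)
        series.geometry = estimate_geometry(series.frames[0], pixel_spacing=(1.0, 1.0),
                                            slice_level="apex")
        profile = fit_series(series, FitConfig(bilinear=True))
        err_a = np.abs(profile.table["alpha_norm"].to_numpy() - truth.alpha_norm)
        err_b = np.abs(profile.table["beta_norm"].to_numpy() - truth.beta_norm)
        assert err_a.max() <= 0.02
        assert err_b.max() <= 0.02

    def test_deterministic(self, undeformed_series):
        grid = GridSpec(alpha_norm_range=(0.0, 0.02), beta_norm_range=(0.0, 0.0),
                        refine=False)
        cfg = FitConfig(grid=grid)
        a = fit_series(undeformed_series, cfg)
        b = fit_series(undeformed_series, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_missing_geometry_raises(self):
        spec = PhantomSpec(n_frames=2)
        series, _ = render_series(spec)
        series.geometry = None
        with pytest.raises(ValueError):
            fit_series(series)


class TestFitResult:
    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            FitResult(alpha=0.0, beta=0.0, F_best=0.5, F_initial=0.2,
                      grid_spec=GridSpec(), frame_index=0, r_epi=30.0)

    def test_merit_reduction(self):
        res = FitResult(alpha=3.0, beta=0.0, F_best=0.2, F_initial=0.8,
                        grid_spec=GridSpec(), frame_index=1, r_epi=30.0)
        assert res.merit_reduction_pct == pytest.approx(75.0)
        assert res.alpha_norm == pytest.approx(0.1)


def make_profile(alpha_values, phases=None, level="mid"):
    phases = phases if phases is not None else np.linspace(0, 0.9, len(alpha_values))
    table = pd.DataFrame(
        {
            "phase_fraction": phases,
            "alpha_norm": alpha_values,
            "beta_norm": np.zeros(len(alpha_values)),
            "F_best": np.zeros(len(alpha_values)),
            "merit_reduction_pct": np.zeros(len(alpha_values)),
        }
    )
    return ParamProfile(table=table, slice_level=level, r_epi=30.0)


class TestAggregateProfiles:
    def test_identical_profiles_zero_sd(self):
        p = make_profile([0.1, 0.2, 0.3])
        agg = aggregate_profiles([p, p])
        np.testing.assert_allclose(agg.table["alpha_norm"], [0.1, 0.2, 0.3])
        np.testing.assert_allclose(agg.table["alpha_norm_sd"], 0.0)

    def test_two_values_hand_computed(self):
        # oracle: hand computation with the n-1 denominator
        agg = aggregate_profiles([make_profile([0.3]), make_profile([0.5])])
        assert agg.table["alpha_norm"].iloc[0] == pytest.approx(0.4)
        assert agg.table["alpha_norm_sd"].iloc[0] == pytest.approx(np.sqrt(0.02))
        assert agg.table["alpha_norm_sd"].iloc[0] == pytest.approx(0.1414, abs=2e-4)

    def test_sd_consistent_with_known_jitter(self, rng):
        # oracle: simulation — 5 subjects with N(0, sigma) jitter,
        # 20 replicates; mean sample SD tracks sigma
        sigma = 0.05
        sds = []
        for _ in range(20):
            profiles = [make_profile(np.clip(0.3 + rng.normal(0, sigma, 4), 0, None))
                        for _ in range(5)]
            sds.append(aggregate_profiles(profiles).table["alpha_norm_sd"].mean())
        assert np.mean(sds) == pytest.approx(sigma, rel=0.25)

    def test_mismatched_phase_grid_raises(self):
        a = make_profile([0.1, 0.2])
        b = make_profile([0.1, 0.2], phases=[0.0, 0.6])
        with pytest.raises(ValueError):
            aggregate_profiles([a, b])

    def test_mismatched_level_raises(self):
        with pytest.raises(ValueError):
            aggregate_profiles([make_profile([0.1]), make_profile([0.1], level="apex")])

    def test_needs_two_profiles(self):
        with pytest.raises(ValueError):
            aggregate_profiles([make_profile([0.1])])


class TestParamProfileIO:
    def test_csv_round_trip(self, tmp_path):
        p = make_profile([0.1, 0.25, 0.05], level="apex")
        p.to_csv(tmp_path / "prof.csv", metadata={"note": "test"})
        loaded = ParamProfile.from_csv(tmp_path / "prof.csv")
        pd.testing.assert_frame_equal(loaded.table, p.table)
        assert loaded.slice_level == "apex"
        assert loaded.r_epi == 30.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_profile([0.1, -0.2])
        with pytest.raises(ValueError):
            make_profile([0.1, 0.2], phases=[0.5, 0.1])

    def test_peaks(self):
        p = make_profile([0.0, 0.4, 0.1])
        phase, value = p.peak_alpha()
        assert value == 0.4
        assert phase == pytest.approx(0.45)
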