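import itertools

import numpy as np
import pytest

from petkin.curves import SampledCurve
from petkin.mapping import (VoxelFit, basis_from_source, fit_voxel,
                            map_image, map_voxel_kinetics,
                            true_parameter_maps)
from petkin.phantom import make_study
from petkin.residue import ResidueFunction, kety_residue, summarize_residue
from petkin.schedule import build_frame_schedule
from petkin.segmentation import segment_image
from petkin.subtac import (DEFAULT_DELAY_GRID_MIN, InjectionWindow, SubTAC,
                           SubTACBasis, SubTACModeller, build_basis,
                           fit_subtac, injection_windows, residue_knots,
                           select_segment_model)
from petkin.tac import convolve_residue_aif


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_recovers_proportionality_groups(self):
        """Scaled copies of three distinct shapes yield exactly 3 segments."""
        rng = np.random.default_rng(0)
        t = np.linspace(0, 10, 40)
        shapes = [np.exp(-t / 2), t * np.exp(-t), 1 - np.exp(-t)]
        curves, truth = [], []
        for g, shape in enumerate(shapes):
            for _ in range(20):
                curves.append(rng.uniform(0.5, 3.0) * shape)
                truth.append(g)
        ds = segment_image(np.asarray(curves), s_target=10)
        assert ds.n_segments == 3
        # labels must be a relabelling of the construction groups
        truth = np.asarray(truth)
        for g in range(3):
            assert len(np.unique(ds.labels[truth == g])) == 1

    def test_single_voxel(self):
        curve = np.linspace(1, 0, 10)[None]
        ds = segment_image(curve, s_target=1)
        assert ds.n_segments == 1
        np.testing.assert_allclose(ds.means[0], curve[0])
        assert np.all(ds.sds[0] > 0)  # floor rule applies

    def test_identical_voxels_stay_one_segment(self):
        curves = np.tile(np.linspace(1, 0, 12), (30, 1))
        ds = segment_image(curves, s_target=8)
        assert ds.n_segments == 1

    def test_labels_partition_voxels(self):
        rng = np.random.default_rng(1)
        curves = rng.uniform(size=(40, 15))
        ds = segment_image(curves, s_target=6)
        assert ds.labels.shape == (40,)
        assert set(ds.labels) == set(range(ds.n_segments))
        assert ds.sizes.sum() == 40

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError):
            segment_image(np.ones((3, 5)), s_target=4)


# ---------------------------------------------------------------------------
# sub-TAC fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def single_window():
    sched = build_frame_schedule([(1, 60), (15, 2), (15, 5), (12, 10),
                                  (8, 15), (6, 20)])
    t = np.linspace(0, sched.scan_end_min, 2000)
    rel = t - 1.0
    vals = np.where(rel > 0, (rel / 0.5) ** 3 * np.exp(3 * (1 - rel / 0.5)), 0.0)
    aif = SampledCurve(t, 30.0 * vals, "water input")
    return InjectionWindow("h2o", aif, sched, np.arange(sched.n_frames))


@pytest.fixture(scope="module")
def modeller(single_window):
    return SubTACModeller([single_window])


class TestFitSubTAC:
    def test_noiseless_recovery_with_delay(self, single_window, modeller):
        """A monotone residue with an on-grid delay is recovered exactly."""
        delay = 10.0 / 60.0
        # generate data on the modeller's own quadrature so recovery is exact
        A = modeller._per_window[0]["designs"][delay]["residue"]
        coef = np.concatenate([np.linspace(0.2, 0.0, A.shape[1] - 1), [0.1]])
        z = A @ coef
        sigma = np.full_like(z, 0.01 * z.max())
        st = modeller.fit(z, sigma, "residue")
        assert st.delays_min[0] * 60 == pytest.approx(10.0)
        resid = np.linalg.norm(st.curve - z) / np.linalg.norm(z)
        assert resid < 1e-8

    def test_zero_data_gives_zero_subtac(self, modeller, single_window):
        n = single_window.schedule_local.n_frames
        st = modeller.fit(np.zeros(n), np.ones(n), "residue")
        np.testing.assert_allclose(st.curve, 0.0, atol=1e-12)

    def test_patlak_type_data_gives_constant_residue(self, single_window, modeller):
        """Data equal to c * integral of the input fits a flat residue."""
        sched = single_window.schedule_local
        R = ResidueFunction([0.0, sched.scan_end_min], [0.7, 0.7])
        z = convolve_residue_aif(R, single_window.aif, 0.0, sched).values
        sigma = np.full_like(z, 0.01 * z.max())
        st = modeller.fit(z, sigma, "residue")
        Rhat = st.residues[0]
        # flat everywhere except possibly the weakly identified first knot
        vals = Rhat(np.linspace(0.1, sched.scan_end_min, 20))
        np.testing.assert_allclose(vals, 0.7, rtol=1e-3)
        assert Rhat(0.0) == pytest.approx(0.7, rel=0.05)

    def test_residue_constraints_enforced(self, single_window, modeller):
        rng = np.random.default_rng(3)
        n = single_window.schedule_local.n_frames
        z = np.abs(rng.normal(1.0, 1.0, n))
        st = modeller.fit(z, np.ones(n), "residue")
        R = st.residues[0]
        assert np.all(R.knot_values >= 0)
        assert np.all(np.diff(R.knot_values) <= 1e-12)

    def test_distribution_kind_monotone_increasing(self, single_window, modeller):
        sched = single_window.schedule_local
        # accumulation-type data: steadily growing signal
        z = np.linspace(0, 5, sched.n_frames) ** 1.5
        st = modeller.fit(z, np.ones_like(z), "distribution")
        knots, vals = st.distributions[0]
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all(vals >= -1e-12)

    def test_invalid_inputs(self, single_window, modeller):
        n = single_window.schedule_local.n_frames
        with pytest.raises(ValueError):
            modeller.fit(np.ones(n), np.zeros(n), "residue")
        with pytest.raises(ValueError):
            modeller.fit(np.ones(n), np.ones(n), "bogus")
        with pytest.raises(ValueError):
            SubTACModeller([single_window], delay_grid_min=np.array([]))

    def test_one_shot_wrapper(self, single_window):
        n = single_window.schedule_local.n_frames
        st = fit_subtac(np.zeros(n), np.ones(n), [single_window])
        assert st.kind == "residue"


class TestModelSelection:
    def test_residue_data_selects_residue(self, single_window, modeller):
        sched = single_window.schedule_local
        R = kety_residue(0.5, 0.6, sched.scan_end_min)
        z = convolve_residue_aif(R, single_window.aif, 0.0, sched).values
        st = select_segment_model(z, np.full_like(z, 0.01 * z.max()), modeller)
        assert st.kind == "residue"

    def test_scaled_input_site_data_selects_iv_site(self, single_window, modeller):
        """Pure scaled, shifted input-site signal beats any residue fit."""
        sched = single_window.schedule_local
        from petkin.tac import FineGrid
        grid = FineGrid.for_schedule(sched)
        shifted = np.interp(grid.t_min - 4.0 / 60, single_window.aif.time_min,
                            single_window.aif.values)
        z = 0.8 * grid.average(shifted)
        st = select_segment_model(z, np.full_like(z, 1e-3 * z.max()), modeller)
        assert st.kind == "iv_site"
        assert st.scales[0] == pytest.approx(0.8, rel=5e-3)

    def test_tie_retains_residue(self, single_window, modeller):
        """When no alternative clearly wins, the residue fit is kept."""
        n = single_window.schedule_local.n_frames
        st = select_segment_model(np.zeros(n), np.ones(n), modeller)
        assert st.kind == "residue"


# ---------------------------------------------------------------------------
# basis selection
# ---------------------------------------------------------------------------

class TestBuildBasis:
    def _dataset_from_curves(self, curves, noise, rng):
        from petkin.segmentation import ReducedDataset
        means = curves + rng.normal(0, noise, curves.shape)
        sds = np.full_like(curves, max(noise, 1e-3))
        return ReducedDataset(means, sds, np.ones(len(curves), int),
                              np.arange(len(curves)))

    def test_redundant_duplicates_are_pruned(self, single_window, modeller):
        """Duplicated sub-TACs collapse towards the distinct generators."""
        sched = single_window.schedule_local
        rng = np.random.default_rng(7)
        gen = [kety_residue(0.8, 1.2, sched.scan_end_min),
               kety_residue(0.3, 0.2, sched.scan_end_min),
               ResidueFunction([0.0, sched.scan_end_min], [0.5, 0.5])]
        base_curves = np.stack([
            convolve_residue_aif(R, single_window.aif, 0.0, sched).values
            for R in gen])
        # segments: noisy positive mixtures of the three generators
        mix = rng.uniform(0.2, 1.0, (12, 3))
        seg_curves = mix @ base_curves
        ds = self._dataset_from_curves(seg_curves, 1e-3, rng)
        cands = []
        for i, c in enumerate(base_curves):
            for _ in range(6):  # heavy redundancy
                cands.append(SubTAC("residue", c.copy(), (0.0,), (gen[i],),
                                    source_segment=None))
        basis = build_basis(cands, ds, modeller, add_supplements=False)
        assert basis.K < len(cands)
        # the selected basis must still fit the dataset to the noise floor
        from scipy.optimize import nnls
        X = basis.X
        for y in ds.means:
            _, rnorm = nnls(X, y)
            assert rnorm / np.linalg.norm(y) < 5e-3

    def test_single_candidate_is_retained(self, single_window, modeller):
        sched = single_window.schedule_local
        R = kety_residue(0.5, 0.5, sched.scan_end_min)
        c = convolve_residue_aif(R, single_window.aif, 0.0, sched).values
        rng = np.random.default_rng(0)
        ds = self._dataset_from_curves(c[None], 1e-3, rng)
        basis = build_basis([SubTAC("residue", c, (0.0,), (R,))], ds,
                            modeller, add_supplements=False)
        assert basis.K == 1

    def test_zero_column_dropped_immediately(self, single_window, modeller):
        sched = single_window.schedule_local
        R = kety_residue(0.5, 0.5, sched.scan_end_min)
        c = convolve_residue_aif(R, single_window.aif, 0.0, sched).values
        rng = np.random.default_rng(0)
        ds = self._dataset_from_curves(c[None], 1e-3, rng)
        zero = SubTAC("residue", np.zeros_like(c), (0.0,), (None,))
        basis = build_basis([SubTAC("residue", c, (0.0,), (R,)), zero], ds,
                            modeller, add_supplements=False)
        assert all(np.any(col.curve != 0) for col in basis.columns)

    def test_supplements_added(self, single_window, modeller):
        sched = single_window.schedule_local
        R = kety_residue(0.5, 0.5, sched.scan_end_min)
        c = convolve_residue_aif(R, single_window.aif, 0.0, sched).values
        rng = np.random.default_rng(0)
        ds = self._dataset_from_curves(c[None], 1e-3, rng)
        basis = build_basis([SubTAC("residue", c, (0.0,), (R,))], ds,
                            modeller, rise_tolerance=-1.0)  # no pruning
        kinds = {col.kind for col in basis.columns}
        assert {"aif_spike", "patlak"} <= kinds


# ---------------------------------------------------------------------------
# voxel fitting and kinetic mapping
# ---------------------------------------------------------------------------

def exhaustive_nnls(A, b):
    """Brute-force NNLS oracle: enumerate all support sets."""
    n = A.shape[1]
    best_x, best = np.zeros(n), np.linalg.norm(b)
    for r in range(1, n + 1):
        for sup in itertools.combinations(range(n), r):
            sub = A[:, sup]
            x, *_ = np.linalg.lstsq(sub, b, rcond=None)
            if np.any(x < -1e-12):
                continue
            resid = np.linalg.norm(sub @ x - b)
            if resid < best - 1e-12:
                best = resid
                best_x = np.zeros(n)
                best_x[list(sup)] = x
    return best_x, best


class TestFitVoxel:
    def test_exact_representation(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(20, 2))
        z = X @ np.array([2.0, 3.0])
        fit = fit_voxel(z, X)
        np.testing.assert_allclose(fit.alpha, [2.0, 3.0], atol=1e-10)

    def test_zero_curve(self):
        X = np.random.default_rng(1).uniform(size=(10, 3))
        fit = fit_voxel(np.zeros(10), X)
        np.testing.assert_allclose(fit.alpha, 0.0)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_oracle(self, trial):
        """Active-set NNLS equals the enumerate-all-supports oracle."""
        rng = np.random.default_rng(1000 + trial)
        K = rng.integers(2, 5)
        n = rng.integers(K + 1, 21)
        A = rng.normal(size=(n, K))
        b = rng.normal(size=n)
        fit = fit_voxel(b, A)
        x_oracle, r_oracle = exhaustive_nnls(A, b)
        assert fit.residual_norm == pytest.approx(r_oracle, abs=1e-8)
        np.testing.assert_allclose(fit.alpha, x_oracle, atol=1e-6)

    def test_replicate_columns_never_increase_sse(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(15, 3))
        z = rng.uniform(size=15)
        base = fit_voxel(z, X).residual_norm
        X2 = np.column_stack([X, X[:, 0], X[:, 2]])
        assert fit_voxel(z, X2).residual_norm <= base + 1e-10

    def test_input_validation(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            fit_voxel(np.ones(4), X)
        with pytest.raises(ValueError):
            fit_voxel(np.array([1.0, np.nan, 1, 1, 1]), X)


@pytest.fixture(scope="module")
def study_basis():
    design = make_study("h2o_fdg", dose=1.0, ratio_or_j=25,
                        n_replicates=2, seed=0)
    return design, basis_from_source(design.source)


class TestKineticMapping:
    def test_single_column_delay(self, study_basis):
        design, basis = study_basis
        k = [i for i, c in enumerate(basis.columns) if c.is_residue_kind][1]
        alpha = np.zeros(basis.K)
        alpha[k] = 1.0
        fit = VoxelFit(alpha, basis.X @ alpha, 0.0)
        s = map_voxel_kinetics(fit, basis, injection=0)
        assert s.delay_min == pytest.approx(basis.columns[k].delays_min[0])

    def test_flow_weighted_delay_symmetric(self, single_window):
        """Two equal-flow components with delays 0 and 10 s average to 5 s."""
        sched = single_window.schedule_local
        R = kety_residue(0.5, 0.5, sched.scan_end_min)
        cols = []
        for d in (0.0, 10.0 / 60.0):
            c = convolve_residue_aif(R, single_window.aif, d, sched).values
            cols.append(SubTAC("residue", c, (d,), (R,)))
        basis = SubTACBasis(tuple(cols), (single_window,))
        fit = VoxelFit(np.array([1.0, 1.0]), basis.X @ np.ones(2), 0.0)
        s = map_voxel_kinetics(fit, basis, injection=0)
        assert s.delay_min * 60 == pytest.approx(5.0)

    def test_linearity_against_summed_residue(self, study_basis):
        """Mapping a combination equals summarising the summed residue."""
        design, basis = study_basis
        rng = np.random.default_rng(2)
        alpha = np.zeros(basis.K)
        res_idx = [i for i, c in enumerate(basis.columns) if c.is_residue_kind]
        for i in res_idx[:3]:
            alpha[i] = rng.uniform(0.2, 1.5)
        fit = VoxelFit(alpha, basis.X @ alpha, 0.0)
        s = map_voxel_kinetics(fit, basis, injection=0)
        combined = None
        for i in res_idx[:3]:
            R = basis.columns[i].residues[0].scaled(alpha[i])
            combined = R if combined is None else combined + R
        t_end = basis.windows[0].schedule_local.scan_end_min
        ref = summarize_residue(combined, T_B=0.25, T_E=t_end)
        assert s.V_D == pytest.approx(ref.V_D, rel=1e-10)
        assert s.K_D == pytest.approx(ref.K_D, rel=1e-10)
        assert s.K_i == pytest.approx(ref.K_i, rel=1e-10)

    def test_no_residue_columns_flagged_zero(self, single_window):
        spike = SubTAC("aif_spike", np.ones(single_window.schedule_local.n_frames),
                       (0.0,), (None,), window_index=0, scales=(1.0,))
        basis = SubTACBasis((spike,), (single_window,))
        fit = VoxelFit(np.array([2.0]), basis.X @ np.array([2.0]), 0.0)
        s = map_voxel_kinetics(fit, basis, injection=0)
        assert s.K_D == 0.0 and s.K_i == 0.0
        assert s.V_B == pytest.approx(2.0)  # spike coefficient is blood volume

    def test_true_parameter_maps_match_region_mix(self):
        design = make_study("repeat_h2o", dose=1.0, ratio_or_j=2,
                            n_replicates=2, seed=0)
        maps = true_parameter_maps(design.source, injection=0)
        profs = design.source.region_map.profiles
        # K_D truth is a non-negative mixture of per-region flows
        assert maps["K_D"].shape == (profs.shape[1],)
        assert np.all(maps["K_D"] >= 0)
        assert maps["K_D"].max() > 0.3  # activation region carries high flow


class TestEndToEndRecovery:
    def test_known_basis_recovery_correlates_with_truth(self):
        """Noisy study + known basis: flow map correlates strongly with truth."""
        from petkin.experiments import Study1D, robustness_phantom
        rm = robustness_phantom()
        design = make_study("h2o_fdg", dose=1.0, ratio_or_j=25,
                            n_replicates=2, seed=3, region_map=rm)
        study = Study1D.from_design(design)
        basis = basis_from_source(design.source)
        truth = true_parameter_maps(design.source, injection=0)
        rng = np.random.default_rng(11)
        Z = study.replicate_recon(rng)
        maps, _, _ = map_image(Z, basis, weights=study.frame_weights(),
                               injection=0)
        assert np.corrcoef(maps["K_D"], truth["K_D"])[0, 1] > 0.9
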