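import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myelometry.grids import AXON, LOOP, MYELIN, NUCLEUS, SOMA, GridSpec
from myelometry.phantom import (
    DEFAULT_EM_CONTRAST,
    FibreSpec,
    ModalityTransform,
    NodeSpec,
    PhantomBoundsError,
    PlacementError,
    PSFModel,
    add_fiducials,
    apply_modality_transform,
    build_fibre_phantom,
    build_node_phantom,
    render_em,
    render_lm,
    straight_fibre,
)


class TestFibrePhantom:
    def test_cylinder_volume_within_1pc(self, cylinder):
        # analytic: pi * 0.6^2 * 20 = 22.619 µm^3
        expected = np.pi * 0.6**2 * 20.0
        assert cylinder["truth"].volumes_um3["axon"] == pytest.approx(expected, rel=0.01)

    def test_fibre_volume_within_1pc(self, cylinder):
        fibre = (
            cylinder["truth"].volumes_um3["axon"] + cylinder["truth"].volumes_um3["myelin"]
        )
        assert fibre == pytest.approx(np.pi * 1.0**2 * 20.0, rel=0.01)

    def test_volume_error_shrinks_with_refinement(self):
        # convergence toward pi r^2 L under grid refinement
        errs = []
        for vox in (0.05, 0.03, 0.02):
            n_xy = int(np.ceil(2.6 / vox))
            grid = GridSpec((int(4.4 / vox), n_xy, n_xy), (vox,) * 3)
            spec = straight_fibre(1.2, 2.0, 4.0, grid)
            _, truth = build_fibre_phantom(spec, grid)
            errs.append(abs(truth.volumes_um3["axon"] / (np.pi * 0.36 * 4.0) - 1))
        assert all(e <= 0.01 for e in errs)
        assert errs[-1] < errs[0]

    def test_g_equals_d_over_D_exactly(self, cylinder):
        truth = cylinder["truth"].fibres[0]
        assert truth.g == truth.axon_diameter_um / truth.fibre_diameter_um

    def test_thin_annulus_limit(self):
        vox = 0.05
        grid = GridSpec((44, 50, 50), (vox,) * 3)
        # D = d + 2 voxels of myelin, then shrink toward zero thickness
        thick = build_fibre_phantom(straight_fibre(1.2, 1.2 + 2 * vox, 1.0, grid), grid)
        thin = build_fibre_phantom(straight_fibre(1.2, 1.2 + 1e-6, 1.0, grid), grid)
        assert thick[0].mask(MYELIN).sum() > 0
        assert thin[0].mask(MYELIN).sum() == 0

    def test_bounds_error_names_axis(self):
        grid = GridSpec((40, 30, 30), (0.05,) * 3)
        with pytest.raises(PhantomBoundsError, match="row"):
            spec = FibreSpec(
                np.array([[1.0, 0.75, 0.75], [1.5, 0.75, 0.75]]), 1.2, 2.0
            )
            build_fibre_phantom(spec, grid)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FibreSpec(np.array([[0, 0, 0], [1, 0, 0]]), 2.0, 1.2)
        with pytest.raises(ValueError):
            FibreSpec(np.array([[0, 0, 0], [0, 0, 0]]), 1.0, 2.0)

    def test_default_axon_diameter_in_range(self):
        # small-diameter axons: d in [1, 2] µm
        assert 1.0 <= 1.2 <= 2.0


class TestNodePhantom:
    def test_radial_ray_crosses_n_bands(self, node_phantom):
        labels = node_phantom["labels"]
        grid = node_phantom["grid"]
        truth = node_phantom["truth"]
        off = truth.meta["node"]["full_lamellae_axial_offset_um"]
        zc = grid.center_um()[0]
        k = int((zc + off) / grid.voxel_size[0])
        row = labels.data[k, :, labels.data.shape[2] // 2]
        loop = row == LOOP
        n_bands = int(np.sum(np.diff(loop.astype(int)) == 1) + loop[0])
        # ray spans the full diameter: bands on both sides of the axon
        assert n_bands == 2 * node_phantom["node"].n_lamellae_per_side

    def test_gap_has_no_myelin_or_loops(self, node_phantom):
        labels = node_phantom["labels"]
        grid = node_phantom["grid"]
        lo, hi = node_phantom["truth"].meta["node"]["gap_axial_interval_um"]
        z0 = grid.center_um()[0] - node_phantom["fibre"].length_um / 2.0
        vox = grid.voxel_size[0]
        k_lo = int(np.ceil((z0 + lo) / vox + 0.5))
        k_hi = int((z0 + hi) / vox - 0.5)
        gap = labels.data[k_lo : k_hi + 1]
        assert not np.isin(gap, [MYELIN, LOOP]).any()
        assert (gap == AXON).any()

    def test_single_lamella(self):
        vox = 0.04
        grid = GridSpec((60, 80, 80), (vox,) * 3)
        fibre = straight_fibre(1.2, 2.0, 2.0, grid)
        node = NodeSpec(0.4, n_lamellae_per_side=1, lamellar_period_um=0.2,
                        paranode_length_um=0.4)
        labels, truth = build_node_phantom(fibre, node, grid)
        off = truth.meta["node"]["full_lamellae_axial_offset_um"]
        k = int((grid.center_um()[0] + off) / vox)
        row = labels.data[k, :, 40]
        loop = row == LOOP
        n_bands = int(np.sum(np.diff(loop.astype(int)) == 1) + loop[0])
        assert n_bands == 2  # one band either side of the axon

    def test_lamellae_must_fit_in_myelin(self):
        grid = GridSpec((60, 80, 80), (0.04,) * 3)
        fibre = straight_fibre(1.2, 2.0, 2.0, grid)  # myelin thickness 0.4
        node = NodeSpec(0.4, n_lamellae_per_side=10, lamellar_period_um=0.08)
        with pytest.raises(ValueError, match="lamellae"):
            build_node_phantom(fibre, node, grid)


class TestFiducials:
    def _empty(self, extent=10.0, vox=0.2):
        n = int(extent / vox)
        grid = GridSpec((n, n, n), (vox,) * 3)
        return build_fibre_phantom(straight_fibre(1.0, 1.6, extent * 0.6, grid), grid)[0]

    def test_zero_counts_noop(self):
        labels = self._empty()
        out, fids = add_fiducials(labels, 0, 0, rng_seed=0)
        assert fids == []
        np.testing.assert_array_equal(out.data, labels.data)

    def test_deterministic_for_seed(self):
        labels = self._empty()
        out1, f1 = add_fiducials(labels, 2, 2, rng_seed=7)
        out2, f2 = add_fiducials(labels, 2, 2, rng_seed=7)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert [f.center_um for f in f1] == [f.center_um for f in f2]

    def test_disjoint_blobs_inside_walls(self):
        labels = self._empty()
        out, fids = add_fiducials(labels, 5, 0, rng_seed=3)
        assert len(fids) == 5
        # no overlap with fibre labels by construction
        assert not ((out.data == SOMA) & (labels.data != 0)).any()
        centers = np.array([f.center_um for f in fids])
        semi = np.array([f.semi_axes_um for f in fids])
        extent = np.array(labels.grid.extent_um)
        assert np.all(centers - semi >= -1e-9)
        assert np.all(centers + semi <= extent + 1e-9)
        # pairwise-overlap oracle: the sum of individual ellipsoid voxel
        # counts must equal the total soma voxel count (no voxel claimed twice)
        grid = out.grid
        zc, yc, xc = (grid.axis_centers(a) for a in range(3))
        total = 0
        for f in fids:
            ez = ((zc - f.center_um[0]) / f.semi_axes_um[0]) ** 2
            ey = ((yc - f.center_um[1]) / f.semi_axes_um[1]) ** 2
            ex = ((xc - f.center_um[2]) / f.semi_axes_um[2]) ** 2
            inside = ez[:, None, None] + ey[None, :, None] + ex[None, None, :] <= 1.0
            assert np.all(out.data[inside] == SOMA)
            total += int(inside.sum())
        assert total == int((out.data == SOMA).sum())

    def test_placement_error_when_full(self):
        grid = GridSpec((10, 10, 10), (0.2,) * 3)
        labels = build_fibre_phantom(straight_fibre(1.0, 1.6, 1.2, grid), grid)[0]
        with pytest.raises(PlacementError):
            add_fiducials(labels, 3, 0, rng_seed=0, soma_semi_axes_um=(0.9, 1.0),
                          max_retries=50)


class TestRenderEM:
    def test_noiseless_is_piecewise_constant(self, cylinder, cylinder_em):
        labels = cylinder["labels"]
        img = cylinder_em.data
        for mat in (AXON, MYELIN):
            vals = img[labels.data == mat]
            assert np.all(vals == DEFAULT_EM_CONTRAST[mat])

    def test_contrast_ordering_enforced(self, cylinder):
        with pytest.raises(ValueError, match="myelin < axon < background"):
            render_em(cylinder["labels"], contrast_map={MYELIN: 250.0})

    def test_default_em_grid_geometry(self):
        grid = GridSpec((300, 10, 10), (0.08, 0.0138, 0.0138))
        assert grid.voxel_size == (0.08, 0.0138, 0.0138)

    def test_noise_histogram_modes(self, cylinder):
        em = render_em(cylinder["labels"], noise_sd=10.0, rng_seed=5)
        labels = cylinder["labels"].data
        for mat in (AXON, MYELIN):
            vals = em.data[labels == mat]
            assert abs(vals.mean() - DEFAULT_EM_CONTRAST[mat]) < 1.0
            assert abs(vals.std() - 10.0) < 1.0

    def test_seed_changes_noise_only(self, cylinder):
        a = render_em(cylinder["labels"], noise_sd=5.0, rng_seed=1)
        b = render_em(cylinder["labels"], noise_sd=5.0, rng_seed=2)
        a0 = render_em(cylinder["labels"], noise_sd=0.0, rng_seed=1)
        b0 = render_em(cylinder["labels"], noise_sd=0.0, rng_seed=2)
        assert not np.array_equal(a.data, b.data)
        np.testing.assert_array_equal(a0.data, b0.data)

    def test_resample_to_coarser_grid(self, cylinder):
        src = cylinder["grid"]
        coarse = GridSpec(
            (src.shape[0] // 2, src.shape[1] // 2, src.shape[2] // 2),
            tuple(2 * v for v in src.voxel_size),
        )
        em = render_em(cylinder["labels"], coarse)
        assert em.data.shape == coarse.shape
        assert set(np.unique(em.data)) <= {40.0, 150.0, 200.0}


class TestRenderLM:
    def test_ideal_psf_matched_grid_is_binary_source(self, cylinder):
        lm = render_lm(cylinder["labels"], PSFModel.preset("ideal"))
        myelin = lm.channel("myelin").data
        np.testing.assert_array_equal(myelin, cylinder["labels"].mask(MYELIN).astype(np.float32))

    def test_blur_widens_apparent_outer_diameter(self):
        vox = 0.02
        grid = GridSpec((20, 160, 160), (vox,) * 3)
        labels, _ = build_fibre_phantom(straight_fibre(1.2, 2.0, 0.3, grid), grid)
        lm = render_lm(labels, PSFModel("x", fwhm_lateral_um=0.25, fwhm_axial_um=0.0))
        prof = lm.channel("myelin").data[10, :, 80].astype(float)
        y = grid.axis_centers(1)
        half = prof.max() / 2.0
        above = np.nonzero(prof >= half)[0]
        i0, i1 = above[0], above[-1]
        # sub-sample outer half-max crossings by linear interpolation
        lo = y[i0 - 1] + (y[i0] - y[i0 - 1]) * (half - prof[i0 - 1]) / (prof[i0] - prof[i0 - 1])
        hi = y[i1] + (y[i1 + 1] - y[i1]) * (prof[i1] - half) / (prof[i1] - prof[i1 + 1])
        assert hi - lo > 2.0  # blurred annulus looks wider than D

    def test_nuclear_channel_sources_from_nuclei(self):
        grid = GridSpec((30, 30, 30), (0.2,) * 3)
        labels = build_fibre_phantom(straight_fibre(1.0, 1.6, 3.0, grid), grid)[0]
        labels, _ = add_fiducials(labels, 0, 1, rng_seed=11)
        lm = render_lm(labels, PSFModel.preset("ideal"))
        nuc = lm.channel("nuclei").data
        np.testing.assert_array_equal(nuc > 0, labels.data == NUCLEUS)

    def test_default_lm_voxel_size(self):
        grid = GridSpec((29, 10, 10), (0.3, 0.068, 0.068))
        assert grid.voxel_size == (0.3, 0.068, 0.068)


class TestModalityTransform:
    def test_identity_exact(self):
        pts = np.array([[1.0, 2.0], [-3.0, 0.5]])
        out = apply_modality_transform(pts, ModalityTransform())
        np.testing.assert_array_equal(out, pts)

    def test_translation_345(self):
        pts = np.array([[0.0, 0.0], [5.0, -2.0]])
        out = apply_modality_transform(pts, ModalityTransform(translation=(0.3, 0.4)))
        np.testing.assert_allclose(np.linalg.norm(out - pts, axis=1), 0.5)

    def test_uniaxial_scale_displacement_linear(self):
        xs = np.array([[1.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        out = apply_modality_transform(xs, ModalityTransform(scale=(0.98, 1.0)))
        np.testing.assert_allclose(
            np.abs(out[:, 0] - xs[:, 0]), 0.02 * np.abs(xs[:, 0]), atol=1e-12
        )

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            ModalityTransform(scale=(0.0, 1.0))

    @given(
        tx=st.floats(-5, 5), ty=st.floats(-5, 5),
        sx=st.floats(0.5, 2), sy=st.floats(0.5, 2),
        rot=st.floats(-180, 180),
        x=st.floats(-50, 50), y=st.floats(-50, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_property(self, tx, ty, sx, sy, rot, x, y):
        t = ModalityTransform(translation=(tx, ty), scale=(sx, sy), rotation_deg=rot)
        pts = np.array([[x, y]])
        back = t.apply_inverse(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)
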