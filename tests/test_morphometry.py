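import numpy as np
import pytest
from scipy import stats

from myelometry.grids import GridSpec
from myelometry.morphometry import (
    DiameterPair,
    GRatioResult,
    LineProfile,
    MeasurementError,
    compare_gratio_groups,
    count_lamellae,
    g_ratio_area,
    g_ratio_diameter,
    g_ratio_volume,
    line_scan,
    profile_to_diameters,
)
from myelometry.phantom import build_node_phantom, render_em, straight_fibre


def trapezoid_profile(edges=(0.6, 1.0), lumen=150.0, myelin=40.0, background=200.0,
                      ramp=0.05, span=1.6, step=0.005):
    """Piecewise-linear EM-like fibre profile with exact half-depth edges.

    Each transition is a linear ramp of width ``ramp`` centred exactly on the
    nominal edge, so half-depth crossings sit at the stated positions.
    """
    inner, outer = edges
    x = np.arange(-span, span + step / 2, step)
    y = np.empty_like(x)
    for i, xi in enumerate(x):
        a = abs(xi)
        if a <= inner - ramp / 2:
            y[i] = lumen
        elif a <= inner + ramp / 2:
            y[i] = lumen + (myelin - lumen) * (a - (inner - ramp / 2)) / ramp
        elif a <= outer - ramp / 2:
            y[i] = myelin
        elif a <= outer + ramp / 2:
            y[i] = myelin + (background - myelin) * (a - (outer - ramp / 2)) / ramp
        else:
            y[i] = background
    return LineProfile(x - x[0], y)


class TestLineScan:
    def test_constant_image(self):
        prof = line_scan(np.full((20, 20), 3.0), (1.0, 1.0), (1.0, 18.0), 50)
        np.testing.assert_allclose(prof.intensities, 3.0)

    def test_step_edge_within_one_pixel(self):
        img = np.zeros((10, 40))
        img[:, 20:] = 100.0  # edge at x = 20 px (physical 20 µm at 1 µm px)
        prof = line_scan(img, (5.0, 2.0), (5.0, 38.0), 500)
        crossing = prof.positions_um[np.argmax(prof.intensities >= 50.0)] + 2.0
        assert abs(crossing - 20.0) <= 1.0

    def test_zero_length_scan(self):
        with pytest.raises(ValueError, match="zero-length"):
            line_scan(np.zeros((5, 5)), (2.0, 2.0), (2.0, 2.0), 10)

    def test_out_of_bounds(self):
        with pytest.raises(ValueError, match="outside"):
            line_scan(np.zeros((5, 5)), (2.0, 2.0), (2.0, 99.0), 10)

    def test_physical_calibration(self):
        img = np.tile(np.arange(30.0), (5, 1))
        prof = line_scan(img, (0.1, 0.02), (0.1, 0.58), 29,
                         pixel_size_um=(0.04, 0.02))
        assert prof.spacing_um == pytest.approx(0.02, rel=1e-6)


class TestProfileToDiameters:
    def test_ideal_trapezoid_exact(self):
        pair = profile_to_diameters(trapezoid_profile())
        assert pair.d_um == pytest.approx(1.2, abs=1e-9)
        assert pair.D_um == pytest.approx(2.0, abs=1e-9)

    def test_bright_polarity(self):
        prof = trapezoid_profile(lumen=20.0, myelin=230.0, background=10.0)
        prof = LineProfile(prof.positions_um, prof.intensities, polarity="bright-myelin")
        pair = profile_to_diameters(prof)
        assert pair.d_um == pytest.approx(1.2, abs=1e-9)
        assert pair.D_um == pytest.approx(2.0, abs=1e-9)

    def test_em_render_within_one_pixel(self, cylinder, cylinder_em):
        grid = cylinder["grid"]
        k = cylinder_em.data.shape[0] // 2
        x_um = grid.center_um()[2]
        W = grid.extent_um[1]
        prof = line_scan(
            cylinder_em.plane(k), (0.03, x_um), (W - 0.03, x_um), 800,
            pixel_size_um=(0.05, 0.05),
        )
        pair = profile_to_diameters(prof)
        assert abs(pair.d_um - 1.2) <= 0.05
        assert abs(pair.D_um - 2.0) <= 0.05

    def test_flat_profile_raises(self):
        prof = LineProfile(np.linspace(0, 1, 50), np.full(50, 9.0))
        with pytest.raises(MeasurementError):
            profile_to_diameters(prof)

    def test_single_trough_raises(self):
        x = np.linspace(0, 2, 100)
        y = 200 - 150 * np.exp(-((x - 1) ** 2) / 0.02)
        with pytest.raises(MeasurementError, match="extrema"):
            profile_to_diameters(LineProfile(x, y))


class TestGRatioEstimators:
    def test_diameter_simple(self):
        res = g_ratio_diameter([DiameterPair(1.2, 2.0)])
        assert res.mean == pytest.approx(0.6)

    def test_diameter_limit_to_one(self):
        res = g_ratio_diameter([DiameterPair(2.0 - 1e-9, 2.0)])
        assert res.mean == pytest.approx(1.0, abs=1e-6)

    def test_area_circular_identity(self):
        res = g_ratio_area([np.pi * 0.36], [np.pi])
        assert res.mean == pytest.approx(0.6, abs=1e-12)

    def test_area_equals_diameter_for_circles(self):
        d, D = 1.37, 1.9
        g_d = d / D
        g_a = g_ratio_area([np.pi * (d / 2) ** 2], [np.pi * (D / 2) ** 2]).mean
        assert abs(g_a - g_d) <= 1e-12

    def test_elliptical_axon(self):
        # ellipse 1.2 x 1.0 µm axes in a circular D=2.0 fibre
        ca = np.pi * 0.6 * 0.5
        CA = np.pi * 1.0**2
        res = g_ratio_area([ca], [CA])
        assert res.mean == pytest.approx(np.sqrt(0.3), abs=1e-12)

    def test_volume_cylinder(self):
        res = g_ratio_volume([22.62], [62.83])
        assert res.mean == pytest.approx(0.6, abs=1e-3)

    def test_volume_taper_invariance(self):
        # tapered fibre, constant local d/D: radii r(z) and r(z)/0.6
        z = np.linspace(0, 10, 200)
        r = 0.5 + 0.03 * z
        va = np.trapezoid(np.pi * r**2, z)
        vf = np.trapezoid(np.pi * (r / 0.6) ** 2, z)
        res = g_ratio_volume([va], [vf])
        assert res.mean == pytest.approx(0.6, abs=1e-9)

    def test_summary_stats(self):
        res = GRatioResult.from_values("diameter", [0.5, 0.6, 0.7])
        assert res.n == 3
        assert res.sem == pytest.approx(res.sd / np.sqrt(3))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            g_ratio_area([2.0], [1.0])
        with pytest.raises(ValueError):
            g_ratio_volume([1.0], [1.0])


class TestCountLamellae:
    def test_constructed_periodic_troughs(self):
        x = np.linspace(0, 2, 400)
        y = 150 + 50 * np.cos(2 * np.pi * 10 * x / 2.0)  # 10 full periods
        profile = LineProfile(x, y)
        assert count_lamellae(profile, 0.2) == 10

    def test_flat_profile_zero(self):
        assert count_lamellae(LineProfile(np.linspace(0, 1, 20), np.full(20, 5.0))) == 0

    def test_node_phantom_em_render(self, node_phantom):
        grid = node_phantom["grid"]
        em = render_em(node_phantom["labels"])
        off = node_phantom["truth"].meta["node"]["full_lamellae_axial_offset_um"]
        k = int((grid.center_um()[0] + off) / grid.voxel_size[0])
        c = grid.center_um()[1]
        W = grid.extent_um[1]
        prof = line_scan(
            em.plane(k), (c, c), (W - 0.01, c), 400,
            pixel_size_um=grid.voxel_size[1:],
        )
        assert count_lamellae(prof, 0.2) == 10


class TestAnova:
    def _res(self, values):
        return GRatioResult.from_values("diameter", values)

    def test_identical_groups(self):
        res = compare_gratio_groups(
            {"a": self._res([0.5, 0.6, 0.7]), "b": self._res([0.5, 0.6, 0.7])}
        )
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups(self):
        res = compare_gratio_groups(
            {"a": self._res([1e-6, 1e-6 * 2, 1e-6, 1e-6 * 2]),
             "b": self._res([1.0, 1.0 + 1e-6, 1.0, 1.0 + 1e-6])}
        )
        assert res.p_value < 1e-6

    def test_all_identical_undefined(self):
        res = compare_gratio_groups(
            {"a": self._res([0.6, 0.6]), "b": self._res([0.6, 0.6])}
        )
        assert np.isnan(res.f_statistic)
        assert res.note is not None

    def test_matches_scipy(self, rng):
        groups = {n: self._res(rng.normal(0.6, 0.05, 12)) for n in "abc"}
        res = compare_gratio_groups(groups)
        f, p = stats.f_oneway(*[g.values for g in groups.values()])
        assert res.f_statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_two_groups_t_squared_identity(self, rng):
        a = rng.normal(0.6, 0.05, 15)
        b = rng.normal(0.65, 0.05, 10)
        res = compare_gratio_groups({"a": self._res(a), "b": self._res(b)})
        t, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = {n: self._res(rng.normal(0.6, 0.05, 8)) for n in "abc"}
            if compare_gratio_groups(groups).p_value <= 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) <= 0.02

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            compare_gratio_groups({"a": self._res([0.5, 0.6])})


class TestEstimatorAgreementProperties:
    def test_three_estimators_agree_on_cylinder(self, cylinder, cylinder_em):
        """Circular geometry: all three estimators recover g within tolerance."""
        from myelometry.segmentation import measure_labels

        grid = cylinder["grid"]
        truth = cylinder["truth"]
        g_true = truth.fibres[0].g

        res = measure_labels(cylinder["labels"])
        t = res.totals.set_index("material")
        v_ax = t.loc["axon", "volume_um3"]
        v_fib = v_ax + t.loc["myelin", "volume_um3"]
        g_vol = g_ratio_volume([v_ax], [v_fib]).mean
        assert abs(g_vol - g_true) <= 0.02

        areas = res.slice_areas
        ax = areas[areas.material == "axon"].set_index("plane").area_um2
        my = areas[areas.material == "myelin"].set_index("plane").area_um2
        common = ax[(ax > 0) & (my > 0)].index
        g_area = g_ratio_area(
            ax.loc[common].to_numpy(), (ax + my).loc[common].to_numpy()
        ).mean
        assert abs(g_area - g_true) <= 0.02

        x_um = grid.center_um()[2]
        W = grid.extent_um[1]
        pairs = []
        for k in np.linspace(30, grid.shape[0] - 30, 20).astype(int):
            prof = line_scan(
                cylinder_em.plane(k), (0.03, x_um), (W - 0.03, x_um), 800,
                pixel_size_um=(0.05, 0.05),
            )
            pairs.append(profile_to_diameters(prof))
        g_diam = g_ratio_diameter(pairs).mean
        assert abs(g_diam - g_true) <= 0.02
        assert abs(g_vol - g_diam) <= 0.02
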