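"""Thickness-to-density mapping, displaced footprints, and polygon counts."""

import numpy as np
import pytest
from shapely.geometry import Point

from maculasum.structural_rgc import (
    CoverageError,
    DisplacedFootprint,
    RasterMap,
    RgcDensityMap,
    displace_footprint,
    gcl_to_density,
    load_profiles,
    mean_density,
    poff_fraction,
    rgc_count,
)
from maculasum.synthetic_cohort import StimulusSpec


def uniform_map(value, extent=10.6, pitch=0.2):
    ax = np.arange(-extent, extent + pitch / 2, pitch)
    return RasterMap(ax, ax, np.full((ax.size, ax.size), float(value)))


def density_from(values_fn, extent=10.6, pitch=0.2):
    ax = np.arange(-extent, extent + pitch / 2, pitch)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    v = values_fn(xx, yy)
    return RgcDensityMap(total=RasterMap(ax, ax, v), poff=RasterMap(ax, ax, v))


class TestGclToDensity:
    def test_zero_thickness_zero_density(self, profiles):
        d = gcl_to_density(uniform_map(0.0), profiles)
        assert not d.total.values.any()
        assert not d.poff.values.any()

    def test_linear_in_thickness(self, profiles):
        d1 = gcl_to_density(uniform_map(20.0), profiles)
        d2 = gcl_to_density(uniform_map(40.0), profiles)
        np.testing.assert_allclose(d2.total.values, 2.0 * d1.total.values, rtol=1e-12)
        np.testing.assert_allclose(d2.poff.values, 2.0 * d1.poff.values, rtol=1e-12)

    def test_pointwise_formula_oracle(self, profiles):
        """Density at random pixels equals a scalar recomputation of the map."""
        thick = uniform_map(40.0)
        d = gcl_to_density(thick, profiles)
        rng = np.random.default_rng(5)
        for _ in range(10):
            i = rng.integers(thick.x.size)
            j = rng.integers(thick.y.size)
            ecc = float(np.hypot(thick.x[i], thick.y[j]))
            expected_total = (
                40.0e-3
                * profiles.volumetric_density(ecc)
                * profiles.mm_per_deg(ecc) ** 2
            )
            assert d.total.values[i, j] == pytest.approx(expected_total, rel=1e-12)
            assert d.poff.values[i, j] == pytest.approx(
                expected_total * profiles.poff_fraction(ecc), rel=1e-12
            )

    def test_negative_thickness_rejected(self, profiles):
        m = uniform_map(1.0)
        bad = RasterMap(m.x, m.y, m.values - 2.0)
        with pytest.raises(ValueError):
            gcl_to_density(bad, profiles)

    def test_db_accessor_flags_zero_density(self, profiles):
        d = gcl_to_density(uniform_map(0.0), profiles)
        assert np.isnan(d.db("poff")).all()


class TestPoffFraction:
    def test_bounded_in_unit_interval(self, profiles):
        for ecc in (0.0, 2.0, 8.0, 15.0):
            assert 0.0 < poff_fraction(ecc, profiles) < 1.0

    def test_constant_profile_returns_constant(self, profiles):
        import dataclasses

        from maculasum.structural_rgc import _Profile

        const = dataclasses.replace(
            profiles,
            poff_fraction=_Profile(
                np.array([0.0, 15.0]), np.array([0.1, 0.1]), "poff_fraction"
            ),
        )
        for ecc in (0.0, 3.7, 10.0):
            assert poff_fraction(ecc, const) == pytest.approx(0.1)

    def test_matches_table_interpolation(self, profiles):
        tbl_e = profiles.poff_fraction.ecc
        tbl_v = profiles.poff_fraction.value
        for ecc in (2.0, 8.0):
            assert poff_fraction(ecc, profiles) == pytest.approx(
                np.interp(ecc, tbl_e, tbl_v), rel=1e-12
            )

    def test_out_of_range_rejected(self, profiles):
        with pytest.raises(ValueError):
            poff_fraction(15.5, profiles)


class TestDisplaceFootprint:
    def test_outside_zone_equals_undisplaced_disc(self, profiles):
        stim = StimulusSpec("GIII", 0.43)
        fp = displace_footprint((9.0, 3.0), stim, profiles)
        r = np.hypot(fp.vertices[:, 0] - 9.0, fp.vertices[:, 1] - 3.0)
        np.testing.assert_allclose(r, 0.215, atol=1e-9)

    def test_displacement_is_outward(self, profiles):
        fp = displace_footprint((1.0, 1.0), StimulusSpec("GIII", 0.43), profiles)
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        undisp_ecc = np.hypot(1.0 + 0.215 * np.cos(theta), 1.0 + 0.215 * np.sin(theta))
        ecc = np.hypot(fp.vertices[:, 0], fp.vertices[:, 1])
        assert np.all(ecc >= undisp_ecc - 1e-12)
        assert fp.polygon().is_valid
        assert fp.area > 0

    def test_concentric_discs_stay_nested(self, profiles):
        inner = displace_footprint((1.0, 1.0), StimulusSpec("GIII", 0.43), profiles,
                                   n_vertices=256)
        outer = displace_footprint((1.0, 1.0), StimulusSpec("GV", 1.72), profiles,
                                   n_vertices=256)
        poly = outer.polygon()
        assert all(
            poly.contains(Point(p)) or poly.touches(Point(p))
            for p in inner.vertices
        )

    def test_degenerate_stimulus_rejected(self, profiles):
        from types import SimpleNamespace

        zero = SimpleNamespace(name="degenerate", diameter_deg=0.0, duration_ms=200.0)
        with pytest.raises(ValueError):
            displace_footprint((1.0, 1.0), zero, profiles)

    def test_far_location_rejected(self, profiles):
        with pytest.raises(ValueError):
            displace_footprint((9.0, 9.0), StimulusSpec("GI", 0.10), profiles)


def square_footprint(x0, y0, x1, y1, n_per_side=32):
    verts = (
        [(x, y0) for x in np.linspace(x0, x1, n_per_side, endpoint=False)]
        + [(x1, y) for y in np.linspace(y0, y1, n_per_side, endpoint=False)]
        + [(x, y1) for x in np.linspace(x1, x0, n_per_side, endpoint=False)]
        + [(x0, y) for y in np.linspace(y1, y0, n_per_side, endpoint=False)]
    )
    return DisplacedFootprint(
        vertices=np.array(verts), location=((x0 + x1) / 2, (y0 + y1) / 2),
        stimulus_name="synthetic",
    )


class TestRgcCount:
    def test_uniform_density_gives_density_times_area(self, profiles):
        dens = density_from(lambda x, y: np.full(x.shape, 123.0))
        fp = displace_footprint((3.0, 1.0), StimulusSpec("GI", 0.10), profiles)
        count = rgc_count(dens, fp, "poff")
        assert count == pytest.approx(123.0 * fp.area, rel=1e-3)

    def test_linear_field_analytic_integral(self):
        # density = 50 + 3x over the rectangle [0,2]x[0,1]:
        # integral = 50*2*1 + 3 * (x^2/2 |_0^2) * 1 = 100 + 6 = 106
        dens = density_from(lambda x, y: 50.0 + 3.0 * x)
        fp = square_footprint(0.0, 0.0, 2.0, 1.0)
        assert rgc_count(dens, fp, "total") == pytest.approx(106.0, rel=1e-9)

    def test_additive_over_disjoint_halves(self):
        dens = density_from(lambda x, y: 50.0 + 2.0 * x + y**2)
        whole = square_footprint(-1.0, -1.0, 1.0, 1.0)
        left = square_footprint(-1.0, -1.0, 0.0, 1.0)
        right = square_footprint(0.0, -1.0, 1.0, 1.0)
        total = rgc_count(dens, whole, "total")
        assert rgc_count(dens, left, "total") + rgc_count(
            dens, right, "total"
        ) == pytest.approx(total, rel=1e-3)

    def test_partition_conserves_counts(self):
        """Counts over a 4x4 tiling of a region sum to the whole-region count."""
        dens = density_from(lambda x, y: 80.0 + 5.0 * np.sin(x) * np.cos(y))
        whole = square_footprint(-4.0, -4.0, 4.0, 4.0, n_per_side=64)
        total = rgc_count(dens, whole, "total")
        tiles = 0.0
        edges = np.linspace(-4.0, 4.0, 5)
        for i in range(4):
            for j in range(4):
                tiles += rgc_count(
                    dens,
                    square_footprint(edges[i], edges[j], edges[i + 1], edges[j + 1]),
                    "total",
                )
        assert tiles == pytest.approx(total, rel=1e-3)

    def test_area_scaling_under_uniform_density_no_displacement(self, profiles):
        """count(G-V)/count(G-I) equals the squared diameter ratio."""
        import dataclasses

        from maculasum.structural_rgc import _Profile

        no_disp = dataclasses.replace(
            profiles,
            displacement=_Profile(
                np.array([0.0, 15.0]), np.array([0.0, 0.0]), "displacement"
            ),
        )
        dens = density_from(lambda x, y: np.full(x.shape, 77.0))
        gi = displace_footprint((3.0, 3.0), StimulusSpec("GI", 0.10), no_disp)
        gv = displace_footprint((3.0, 3.0), StimulusSpec("GV", 1.72), no_disp)
        ratio = rgc_count(dens, gv, "poff") / rgc_count(dens, gi, "poff")
        assert ratio == pytest.approx((1.72 / 0.10) ** 2, rel=1e-6)

    def test_footprint_outside_raster_raises(self, profiles):
        dens = density_from(lambda x, y: np.full(x.shape, 1.0), extent=2.0)
        fp = square_footprint(1.5, 1.5, 3.0, 3.0)
        with pytest.raises(CoverageError):
            rgc_count(dens, fp, "total")


class TestRoundTrip:
    def test_structural_recomputation_matches_latent_truth(
        self, small_study, profiles
    ):
        """Noise-free structural pipeline reproduces the generator's latent
        density wherever damage has not hit the residual floor."""
        from maculasum.structural_rgc import gcl_to_density
        from maculasum.synthetic_cohort import _LocationSampler

        cfg = small_study["config"]
        sampler = _LocationSampler(cfg.protocol, profiles)
        for truth in small_study["truths"]:
            dmap = gcl_to_density(truth.gcl_thickness, profiles)
            structural = sampler.location_density(dmap.poff)
            latent = truth.location_table["latent_poff_density_per_deg2"].to_numpy()
            if truth.cohort in ("young", "control"):
                # no damage: identity everywhere
                np.testing.assert_allclose(structural, latent, rtol=1e-6)
            else:
                # the residual floor can only raise the structural estimate
                assert np.all(structural >= latent * (1 - 1e-9))
                # and leaves lightly damaged footprints untouched: pointwise
                # agreement between the latent raster and the structural one
                # forces agreement of the footprint averages
                ratio = dmap.poff.values / truth.latent_density.poff.values
                assert ratio.min() >= 1 - 1e-12
                if truth.cohort in ("early", "moderate"):
                    # lightly damaged regions stay below the floor and are
                    # reproduced exactly; advanced eyes may be fully floored
                    intact = np.isclose(ratio, 1.0, rtol=1e-9)
                    assert intact.mean() > 0.25

    def test_poff_cannot_exceed_total(self, profiles):
        with pytest.raises(ValueError):
            RgcDensityMap(
                total=uniform_map(1.0), poff=uniform_map(2.0)
            )
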