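"""GCL thickness to parasol-OFF RGC density, displaced stimulus footprints, counts.

Converts gridded ganglion-cell-layer (GCL) thickness maps (um, fovea-centred,
visual degrees) into localized total and parasol-OFF (P-OFF) RGC densities
per deg^2, displaces and distorts perimetric stimulus footprints to account
for the centrifugal displacement of RGC somas from their receptive fields,
and integrates density over those footprints to obtain per-stimulus RGC
counts.

All computations are in visual degrees: under a spherical-expansion model of
the eye, densities per squared degree are unaffected by axial length, so no
operation here consumes biometry.  Maps and footprints are expressed in
visual-field coordinates with a right-eye convention and the fovea at the
origin; the field-to-retina sign flip is applied once when real maps are
ingested, so everything downstream shares one coordinate frame.

The eccentricity profiles used in the conversion (volumetric density,
mm-per-degree scaling, cone-to-RGC convergence, P-OFF fraction, displacement)
ship as editable interpolation tables.  The packaged defaults are synthetic
plausible curves shaped to the documented qualitative contracts (volumetric
density peaks parafoveally, convergence non-decreasing within 10 deg,
displacement zero beyond 4 deg); swap in histology-derived tables for real
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Polygon

__all__ = [
    "CoverageError",
    "RasterMap",
    "RgcDensityMap",
    "HistologyProfiles",
    "DisplacedFootprint",
    "load_profiles",
    "gcl_to_density",
    "poff_fraction",
    "displace_footprint",
    "rgc_count",
]

ECC_RANGE = (0.0, 15.0)
DEFAULT_DISPLACEMENT_ZONE = 4.0


class CoverageError(ValueError):
    """A requested footprint or location is not covered by the raster."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RasterMap:
    """A scalar field on a regular (x, y) grid in visual degrees.

    ``values[i, j]`` corresponds to ``(x[i], y[j])``.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.x.size, self.y.size):
            raise ValueError("values shape must be (len(x), len(y))")

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.x, self.y), self.values, method="linear", bounds_error=True
        )

    def ecc(self) -> np.ndarray:
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        return np.hypot(xx, yy)

    def to_frame(self, value_col: str) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        return pd.DataFrame(
            {"x_deg": xx.ravel(), "y_deg": yy.ravel(), value_col: self.values.ravel()}
        )


@dataclass(frozen=True)
class RgcDensityMap:
    """Gridded total and parasol-OFF RGC density (cells/deg^2)."""

    total: RasterMap
    poff: RasterMap

    def __post_init__(self) -> None:
        if (self.total.values < 0).any() or (self.poff.values < 0).any():
            raise ValueError("densities must be >= 0")
        if (self.poff.values > self.total.values + 1e-9).any():
            raise ValueError("poff density cannot exceed total density")

    def db(self, which: str = "poff") -> np.ndarray:
        """Density in dB (10*log10).  Zero-density pixels are flagged as NaN."""
        v = (self.poff if which == "poff" else self.total).values
        out = np.full(v.shape, np.nan)
        pos = v > 0
        out[pos] = 10.0 * np.log10(v[pos])
        return out


# ---------------------------------------------------------------------------
# Histology profiles
# ---------------------------------------------------------------------------

class _Profile:
    """Linear interpolation of a tabulated eccentricity profile."""

    def __init__(self, ecc: np.ndarray, value: np.ndarray, name: str):
        order = np.argsort(ecc)
        self.ecc = np.asarray(ecc, dtype=float)[order]
        self.value = np.asarray(value, dtype=float)[order]
        self.name = name
        if self.ecc[0] > ECC_RANGE[0] or self.ecc[-1] < ECC_RANGE[1]:
            raise ValueError(f"profile {name} must cover {ECC_RANGE} deg")

    def __call__(self, ecc):
        e = np.asarray(ecc, dtype=float)
        if (e < ECC_RANGE[0] - 1e-12).any() or (e > ECC_RANGE[1] + 1e-12).any():
            raise ValueError(
                f"eccentricity outside {ECC_RANGE} deg for profile {self.name}"
            )
        out = np.interp(e, self.ecc, self.value)
        return float(out) if np.isscalar(ecc) else out


@dataclass(frozen=True)
class HistologyProfiles:
    """Eccentricity profiles for the thickness-to-density conversion.

    volumetric_density : cells/mm^3 of GCL tissue versus eccentricity
    mm_per_deg         : retinal mm per visual degree versus eccentricity
    convergence_ratio  : cones per P-OFF RGC versus eccentricity
    poff_fraction      : P-OFF share of total RGC density versus eccentricity
    displacement       : radial RGC displacement (deg) versus eccentricity,
                         zero beyond the displacement zone
    """

    volumetric_density: _Profile
    mm_per_deg: _Profile
    convergence_ratio: _Profile
    poff_fraction: _Profile
    displacement: _Profile
    displacement_zone: float = DEFAULT_DISPLACEMENT_ZONE

    def __post_init__(self) -> None:
        for p in (self.volumetric_density, self.mm_per_deg, self.convergence_ratio):
            if (p.value <= 0).any():
                raise ValueError(f"profile {p.name} must be strictly positive")
        f = self.poff_fraction.value
        if (f <= 0).any() or (f >= 1).any():
            raise ValueError("poff_fraction must lie strictly in (0, 1)")
        if (self.displacement.value < 0).any():
            raise ValueError("displacement must be >= 0")
        # r + d(r) strictly increasing keeps the radial map injective, so
        # displaced footprints stay simple and concentric discs stay nested
        slopes = np.diff(self.displacement.value) / np.diff(self.displacement.ecc)
        if (slopes <= -1).any():
            raise ValueError("displacement profile must satisfy d'(ecc) > -1")


def _read_profile(name: str) -> _Profile:
    ref = resources.files("maculasum.profiles").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return _Profile(df["ecc_deg"].to_numpy(), df["value"].to_numpy(), name)


def load_profiles(displacement_zone: float = DEFAULT_DISPLACEMENT_ZONE) -> HistologyProfiles:
    """Load the packaged default profile tables."""
    return HistologyProfiles(
        volumetric_density=_read_profile("volumetric_density"),
        mm_per_deg=_read_profile("mm_per_deg"),
        convergence_ratio=_read_profile("convergence_ratio"),
        poff_fraction=_read_profile("poff_fraction"),
        displacement=_read_profile("displacement"),
        displacement_zone=displacement_zone,
    )


def healthy_gcl_profile() -> _Profile:
    """Packaged synthetic healthy GCL thickness profile (um vs eccentricity)."""
    return _read_profile("healthy_gcl_um")


def poff_fraction(ecc, profiles: HistologyProfiles) -> float:
    """Parasol-OFF fraction of total RGC density at an eccentricity (deg)."""
    return profiles.poff_fraction(ecc)


# ---------------------------------------------------------------------------
# Thickness -> density
# ---------------------------------------------------------------------------

def gcl_to_density(thickness: RasterMap, profiles: HistologyProfiles) -> RgcDensityMap:
    """Convert a GCL thickness map (um) to RGC densities (cells/deg^2).

    Pointwise and linear in thickness:
    ``total = thickness_mm * volumetric_density(ecc) * mm_per_deg(ecc)^2`` and
    ``poff = total * poff_fraction(ecc)``.
    """
    if (thickness.values < 0).any():
        raise ValueError("thickness must be >= 0")
    ecc = thickness.ecc()
    thick_mm = thickness.values * 1e-3
    areal = profiles.mm_per_deg(ecc) ** 2  # mm^2 of retina per deg^2 of field
    total = thick_mm * profiles.volumetric_density(ecc) * areal
    poff = total * profiles.poff_fraction(ecc)
    return RgcDensityMap(
        total=RasterMap(thickness.x, thickness.y, total),
        poff=RasterMap(thickness.x, thickness.y, poff),
    )


# ---------------------------------------------------------------------------
# Displaced footprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplacedFootprint:
    """Stimulus footprint on the GCL after radial RGC displacement."""

    vertices: np.ndarray          # (n, 2) polygon boundary, deg
    location: tuple[float, float]
    stimulus_name: str

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.polygon().area)


def displace_footprint(
    location: tuple[float, float],
    stimulus,
    profiles: HistologyProfiles,
    n_vertices: int = 128,
) -> DisplacedFootprint:
    """Displace the boundary of a stimulus disc radially from the fovea.

    Each of ``n_vertices`` boundary points of the disc centred at ``location``
    is moved outward along its own foveal ray by ``d(ecc) >= 0``; ``d`` is
    continuous and identically zero beyond the displacement zone, so
    footprints outside the zone coincide with the undisplaced disc.
    """
    x0, y0 = float(location[0]), float(location[1])
    if np.hypot(x0, y0) > 10.0 + 1e-9:
        raise ValueError("location must lie within 10 deg eccentricity")
    radius = stimulus.diameter_deg / 2.0
    if radius <= 0:
        raise ValueError("degenerate zero-area stimulus")
    if n_vertices < 64:
        raise ValueError("footprint needs >= 64 boundary vertices")

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    bx = x0 + radius * np.cos(theta)
    by = y0 + radius * np.sin(theta)
    ecc = np.hypot(bx, by)
    d = profiles.displacement(np.minimum(ecc, ECC_RANGE[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(ecc > 0, (ecc + d) / np.where(ecc > 0, ecc, 1.0), 1.0)
    verts = np.column_stack([bx * scale, by * scale])
    return DisplacedFootprint(
        vertices=verts, location=(x0, y0), stimulus_name=getattr(stimulus, "name", "?")
    )


# ---------------------------------------------------------------------------
# Counts: signed triangle-fan Gauss quadrature over the polygon
# ---------------------------------------------------------------------------

# degree-5 symmetric 7-point rule on the reference triangle
_TRI_W = np.array(
    [0.225]
    + [0.125939180544827] * 3
    + [0.132394152788506] * 3
)
_a1, _b1 = 0.797426985353087, 0.101286507323456
_a2, _b2 = 0.059715871789770, 0.470142064105115
_TRI_BARY = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [_a1, _b1, _b1], [_b1, _a1, _b1], [_b1, _b1, _a1],
        [_a2, _b2, _b2], [_b2, _a2, _b2], [_b2, _b2, _a2],
    ]
)


def footprint_quadrature(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature points and signed weights integrating over a simple polygon.

    Triangulates as a signed fan from the vertex centroid; overlapping fan
    triangles of opposite orientation cancel, so the rule is valid for any
    simple polygon and exact for integrands up to degree 5 per triangle.
    Weights sum to the polygon area.
    """
    v = np.asarray(vertices, dtype=float)
    c = v.mean(axis=0)
    v2 = np.roll(v, -1, axis=0)
    # signed area of each fan triangle (c, v_i, v_{i+1})
    signed = 0.5 * (
        (v[:, 0] - c[0]) * (v2[:, 1] - c[1]) - (v2[:, 0] - c[0]) * (v[:, 1] - c[1])
    )
    # points: bary combination of (c, v_i, v_{i+1}) for each rule node
    pts = (
        _TRI_BARY[:, 0, None, None] * c[None, None, :]
        + _TRI_BARY[:, 1, None, None] * v[None, :, :]
        + _TRI_BARY[:, 2, None, None] * v2[None, :, :]
    )  # (7, n_edges, 2)
    w = _TRI_W[:, None] * signed[None, :]
    return pts.reshape(-1, 2), w.ravel()


def rgc_count(
    density: RgcDensityMap,
    footprint: DisplacedFootprint,
    which: str = "poff",
) -> float:
    """Number of RGCs under a footprint: integral of density over the polygon."""
    if which not in ("total", "poff"):
        raise ValueError("which must be 'total' or 'poff'")
    raster = density.poff if which == "poff" else density.total
    pts, w = footprint_quadrature(footprint.vertices)
    if (
        pts[:, 0].min() < raster.x[0] or pts[:, 0].max() > raster.x[-1]
        or pts[:, 1].min() < raster.y[0] or pts[:, 1].max() > raster.y[-1]
    ):
        raise CoverageError(
            f"footprint at {footprint.location} not covered by the density raster"
        )
    vals = raster.interpolator()(pts)
    return float(np.dot(w, vals))


def mean_density(
    density: RgcDensityMap, footprint: DisplacedFootprint, which: str = "poff"
) -> float:
    """Area-averaged density over a displaced footprint (cells/deg^2)."""
    pts, w = footprint_quadrature(footprint.vertices)
    raster = density.poff if which == "poff" else density.total
    if (
        pts[:, 0].min() < raster.x[0] or pts[:, 0].max() > raster.x[-1]
        or pts[:, 1].min() < raster.y[0] or pts[:, 1].max() > raster.y[-1]
    ):
        raise CoverageError(
            f"footprint at {footprint.location} not covered by the density raster"
        )
    vals = raster.interpolator()(pts)
    return float(np.dot(w, vals) / w.sum())
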