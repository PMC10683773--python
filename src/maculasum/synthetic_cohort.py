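"""Synthetic macular spatial-summation study: ground truth plus observations.

Emulates the design of the clinical study the analysis pipeline targets:
29 young healthy eyes, 20 age-similar controls and 10 glaucoma eyes per
severity stage (early / moderate / advanced, staged by mean-deviation
strata), each tested six times on the 10-2 grid with five Goldmann stimulus
diameters (0.10-1.72 deg, 200 ms).  The young cohort repeats G-I, patients
and controls repeat G-III.

Each eye carries a full ground truth: a fovea-centred GCL thickness raster
and the parasol-OFF RGC density raster it maps to through
:mod:`maculasum.structural_rgc` (so the structural round trip is exact by
construction above the residual-tissue floor), per-location effective
densities under displaced G-III footprints, and a mean-deviation summary.
Glaucoma eyes receive a multiplicative damage field: a smooth diffuse
component times one or more sharp-edged (sigmoidal, sub-degree transition)
arcuate scotomas, with overall severity calibrated per eye so the MD summary
lands inside its stage's stratum.  Functional loss may deepen to a -30 dB
density floor while GCL thickness never thins below the residual fraction --
the structural floor whose dynamic-range compression the evaluation stage
measures.

Observed sensitivities are the template prediction at the local retinal
input plus heteroscedastic Gaussian noise (SD growing as sensitivity falls,
capped), left-censored at 0 dB and capped at a 40 dB ceiling.  Everything is
deterministic given the study seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structural_rgc import (
    HistologyProfiles,
    RasterMap,
    RgcDensityMap,
    displace_footprint,
    footprint_quadrature,
    gcl_to_density,
    healthy_gcl_profile,
    load_profiles,
)
from .summation_template import (
    DEFAULT_TEMPLATE,
    TemplateParameters,
    template_sensitivity,
)

__all__ = [
    "MAX_LUMINANCE_CD_M2",
    "db_to_luminance",
    "luminance_to_db",
    "StimulusSpec",
    "DEFAULT_STIMULI",
    "grid_10_2",
    "TestProtocol",
    "NoiseConfig",
    "StructuralFloorConfig",
    "StudyConfig",
    "EyeTruth",
    "simulate_damage_field",
    "simulate_perimetry",
    "generate_study",
    "gi_floor_threshold",
    "attach_stimulus_columns",
]

#: brightest HFA stimulus; perimetric dB are attenuation relative to it
MAX_LUMINANCE_CD_M2 = 3185.0

#: functional density loss floor (multiplicative): -30 dB of density
FUNCTIONAL_FLOOR_LOSS = 1e-3

# corner eccentricity 10.6*sqrt(2) = 14.99 deg stays inside the profile domain
# while covering every displaced footprint (max vertex eccentricity ~10.4 deg)
RASTER_EXTENT_DEG = 10.6
RASTER_PITCH_DEG = 0.2


def db_to_luminance(db) -> float:
    """Stimulus luminance (cd/m^2) for a perimetric attenuation in dB."""
    return MAX_LUMINANCE_CD_M2 * 10.0 ** (-np.asarray(db, dtype=float) / 10.0)


def luminance_to_db(luminance) -> float:
    """Perimetric dB of attenuation for a stimulus luminance (cd/m^2)."""
    return 10.0 * np.log10(MAX_LUMINANCE_CD_M2 / np.asarray(luminance, dtype=float))


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """A Goldmann circular stimulus."""

    name: str
    diameter_deg: float
    duration_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.diameter_deg <= 0 or self.duration_ms <= 0:
            raise ValueError("stimulus diameter and duration must be > 0")

    @property
    def area_deg2(self) -> float:
        return math.pi * (self.diameter_deg / 2.0) ** 2


DEFAULT_STIMULI = (
    StimulusSpec("GI", 0.10),
    StimulusSpec("GII", 0.21),
    StimulusSpec("GIII", 0.43),
    StimulusSpec("GIV", 0.86),
    StimulusSpec("GV", 1.72),
)


def grid_10_2() -> np.ndarray:
    """The 68 macular test locations (right-eye visual-field degrees).

    Odd-integer coordinates within the central 10 degrees, symmetric under
    reflection in both axes.
    """
    coords = [
        (x, y)
        for x in range(-9, 10, 2)
        for y in range(-9, 10, 2)
        if x * x + y * y <= 82
    ]
    return np.array(coords, dtype=float)


@dataclass(frozen=True)
class TestProtocol:
    """Which stimuli are tested, and which one is repeated per cohort."""

    __test__ = False  # not a pytest class, despite the clinical name

    stimuli: tuple[StimulusSpec, ...] = DEFAULT_STIMULI
    repeats: dict = field(
        default_factory=lambda: {"young": {"GI": 2}, "clinical": {"GIII": 2}}
    )
    grid: np.ndarray = field(default_factory=grid_10_2)

    def repeat_count(self, cohort: str, stimulus_name: str) -> int:
        key = "young" if cohort == "young" else "clinical"
        return self.repeats.get(key, {}).get(stimulus_name, 1)

    def tests_per_eye(self, cohort: str) -> int:
        return sum(self.repeat_count(cohort, s.name) for s in self.stimuli)

    def stimulus(self, name: str) -> StimulusSpec:
        for s in self.stimuli:
            if s.name == name:
                return s
        raise KeyError(f"stimulus {name!r} not in protocol")


@dataclass(frozen=True)
class NoiseConfig:
    """Heteroscedastic perimetric noise: SD grows as sensitivity falls."""

    sd_at_30db: float = 1.5
    sd_slope: float = 0.2
    sd_cap: float = 8.0

    def __post_init__(self) -> None:
        if min(self.sd_at_30db, self.sd_slope, self.sd_cap) < 0:
            raise ValueError("noise parameters must be >= 0")

    def sd(self, sensitivity_db):
        s = np.asarray(sensitivity_db, dtype=float)
        return np.minimum(self.sd_cap, self.sd_at_30db + self.sd_slope * (30.0 - s))


@dataclass(frozen=True)
class StructuralFloorConfig:
    """Residual non-functional tissue that never thins.

    The default leaves the structural estimate floored at about -8 dB of
    density loss, in line with the floor reported at roughly 10 dB of
    macular sensitivity loss; functional loss continues well below it.
    """

    residual_fraction: float = 0.15
    target_dr_ratio: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_fraction < 1.0:
            raise ValueError("residual_fraction must be in [0, 1)")


#: per-stage target MD strata (dB): uniform draw inside these bands keeps each
#: eye inside its clinical stratum (early > -6, moderate -6..-12, advanced < -12)
MD_TARGET_BANDS = {
    "early": (-5.5, -1.0),
    "moderate": (-11.5, -6.5),
    "advanced": (-22.0, -13.0),
}

STAGES = ("early", "moderate", "advanced")


@dataclass(frozen=True)
class StudyConfig:
    n_young: int = 29
    n_controls: int = 20
    n_per_glaucoma_stage: int = 10
    protocol: TestProtocol = field(default_factory=TestProtocol)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    floor: StructuralFloorConfig = field(default_factory=StructuralFloorConfig)
    template: TemplateParameters = DEFAULT_TEMPLATE
    ceiling_db: float = 40.0
    #: which hypothesis generates the data: 'horizontal' (damage moves the
    #: operating point along the template, i.e. Ricco's-area change) or
    #: 'vertical' (sensitivity drops by the dB density loss at fixed shape)
    truth_hypothesis: str = "horizontal"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_young, self.n_controls, self.n_per_glaucoma_stage) < 1:
            raise ValueError("all cohort counts must be >= 1")
        if self.truth_hypothesis not in ("horizontal", "vertical"):
            raise ValueError("truth_hypothesis must be 'horizontal' or 'vertical'")


# ---------------------------------------------------------------------------
# Eye truth
# ---------------------------------------------------------------------------

@dataclass
class EyeTruth:
    eye_id: str
    cohort: str                       # young / control / early / moderate / advanced
    latent_density: RgcDensityMap     # functional truth (may dip below the structural floor)
    gcl_thickness: RasterMap          # um; floored at residual_fraction * healthy
    location_table: pd.DataFrame      # x_deg, y_deg, ecc, convergence, latent & healthy density
    md_summary: float
    truth_hypothesis: str = "horizontal"
    damage_info: dict | None = None   # scotoma/diffuse geometry for damaged eyes


def _raster_axes() -> np.ndarray:
    n = int(round(2 * RASTER_EXTENT_DEG / RASTER_PITCH_DEG)) + 1
    return np.linspace(-RASTER_EXTENT_DEG, RASTER_EXTENT_DEG, n)


class _LocationSampler:
    """Precomputed displaced-footprint quadrature per 10-2 location and stimulus.

    Per-location effective P-OFF density for a stimulus is the area-averaged
    density over that stimulus's displaced footprint, evaluated by bilinear
    interpolation of the density raster at fixed quadrature points.  The
    G-III footprint defines the canonical per-location density (the latent
    quantity the hierarchical model estimates); the per-size averages differ
    from it near sharp scotoma edges, which is what produces the
    edge-of-scotoma misfit for large stimuli.
    """

    def __init__(self, protocol: TestProtocol, profiles: HistologyProfiles):
        self.grid = protocol.grid
        self.points: dict[str, np.ndarray] = {}
        self.weights: dict[str, np.ndarray] = {}
        for stim in protocol.stimuli:
            pts, wts = [], []
            for x, y in self.grid:
                fp = displace_footprint((x, y), stim, profiles, n_vertices=64)
                p, w = footprint_quadrature(fp.vertices)
                pts.append(p)
                wts.append(w / w.sum())
            self.points[stim.name] = np.concatenate(pts)   # (68*K, 2)
            self.weights[stim.name] = np.array(wts)        # (68, K)

    def location_density(
        self, poff_raster: RasterMap, stimulus_name: str = "GIII"
    ) -> np.ndarray:
        w = self.weights[stimulus_name]
        vals = poff_raster.interpolator()(self.points[stimulus_name])
        return np.einsum("ij,ij->i", w, vals.reshape(w.shape))

    def all_densities(self, poff_raster: RasterMap) -> dict[str, np.ndarray]:
        interp = poff_raster.interpolator()
        out = {}
        for name, w in self.weights.items():
            out[name] = np.einsum(
                "ij,ij->i", w, interp(self.points[name]).reshape(w.shape)
            )
        return out


# ---------------------------------------------------------------------------
# Damage field
# ---------------------------------------------------------------------------

def _draw_damage_params(stage: str, rng: np.random.Generator) -> dict:
    """Random shape of one eye's damage field (log10-loss components)."""
    if stage == "early":
        n_bumps, n_arcs, diffuse = 2, 1, 0.10
    elif stage == "moderate":
        n_bumps, n_arcs, diffuse = 3, 1, 0.35
    elif stage == "advanced":
        n_bumps, n_arcs, diffuse = 4, 2, 0.90
    else:
        raise ValueError(f"unknown glaucoma stage {stage!r}")

    bumps = []
    for _ in range(n_bumps):
        ecc = rng.uniform(1.0, 8.0)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        bumps.append(
            dict(
                cx=ecc * np.cos(ang), cy=ecc * np.sin(ang),
                sigma=rng.uniform(2.0, 4.5),
                depth=rng.uniform(0.2, 0.6),   # log10 units at the bump centre
            )
        )
    arcs = []
    for _ in range(n_arcs):
        arcs.append(
            dict(
                radius=rng.uniform(2.0, 7.0),
                angle0=rng.uniform(0.0, 2.0 * np.pi),
                span=rng.uniform(np.deg2rad(50.0), np.deg2rad(160.0)),
                width=rng.uniform(1.0, 2.5),
                edge=0.25,                     # sigmoid transition width, deg (< 1)
                depth=rng.uniform(1.8, 3.0),   # log10 units inside the scotoma
            )
        )
    return {"stage": stage, "diffuse": diffuse, "bumps": bumps, "arcs": arcs}


def _arc_distance(x, y, arc) -> np.ndarray:
    """Distance from points to a circular arc centred on the fovea."""
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    # wrap angular offset from the arc's mid-line into [-pi, pi]
    mid = arc["angle0"] + arc["span"] / 2.0
    dtheta = np.angle(np.exp(1j * (theta - mid)))
    half = arc["span"] / 2.0
    inside = np.abs(dtheta) <= half
    d_radial = np.abs(r - arc["radius"])
    # outside the angular span: distance to the arc endpoint
    end_ang = arc["angle0"] + np.where(dtheta > 0, arc["span"], 0.0)
    ex = arc["radius"] * np.cos(end_ang)
    ey = arc["radius"] * np.sin(end_ang)
    d_end = np.hypot(x - ex, y - ey)
    return np.where(inside, d_radial, d_end)


def _loss_log10(params: dict, severity: float, x, y) -> np.ndarray:
    """log10 of the multiplicative density-loss field, clamped at the floor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    f = np.full(x.shape, -params["diffuse"])
    for b in params["bumps"]:
        f -= b["depth"] * np.exp(
            -((x - b["cx"]) ** 2 + (y - b["cy"]) ** 2) / (2.0 * b["sigma"] ** 2)
        )
    for a in params["arcs"]:
        d = _arc_distance(x, y, a)
        # sharp-edged scotoma: sigmoid of distance to the arc band boundary
        f -= a["depth"] / (1.0 + np.exp((d - a["width"]) / a["edge"]))
    return np.maximum(severity * f, np.log10(FUNCTIONAL_FLOOR_LOSS))


def simulate_damage_field(
    stage: str,
    healthy_density: RgcDensityMap,
    seed: int,
    severity: float = 1.0,
) -> RgcDensityMap:
    """Apply a stage-dependent multiplicative damage field to a density map.

    The loss field is a smooth diffuse component times >= 1 sharp-edged
    arcuate scotoma (sigmoidal boundary, transition width 0.25 deg), clamped
    at the functional floor.  ``stage='none'`` returns the input unchanged.
    """
    if stage == "none":
        return healthy_density
    if (healthy_density.poff.values <= 0).any():
        raise ValueError("healthy density must be positive everywhere")
    params = _draw_damage_params(stage, np.random.default_rng(seed))
    xx, yy = np.meshgrid(
        healthy_density.poff.x, healthy_density.poff.y, indexing="ij"
    )
    loss = 10.0 ** _loss_log10(params, severity, xx, yy)
    return RgcDensityMap(
        total=RasterMap(
            healthy_density.total.x, healthy_density.total.y,
            healthy_density.total.values * loss,
        ),
        poff=RasterMap(
            healthy_density.poff.x, healthy_density.poff.y,
            healthy_density.poff.values * loss,
        ),
    )


# ---------------------------------------------------------------------------
# Perimetry simulation
# ---------------------------------------------------------------------------

def _location_inputs_db(
    densities: np.ndarray, convergence: np.ndarray, stimulus: StimulusSpec
) -> np.ndarray:
    val = stimulus.area_deg2 * stimulus.duration_ms * densities * convergence
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(val)


def _true_sensitivity(
    densities: np.ndarray,
    healthy_densities: np.ndarray,
    convergence: np.ndarray,
    stimulus: StimulusSpec,
    template: TemplateParameters,
    hypothesis: str,
) -> np.ndarray:
    """Noise-free threshold under either generating hypothesis.

    horizontal: the template evaluated at the damaged retinal input (density
    loss moves the operating point along the curve).  vertical: the healthy
    template prediction shifted down by the dB density loss (fixed Ricco's
    area).  The two coincide for undamaged eyes.
    """
    if hypothesis == "horizontal":
        u = _location_inputs_db(densities, convergence, stimulus)
        return template_sensitivity(u, template)
    u0 = _location_inputs_db(healthy_densities, convergence, stimulus)
    with np.errstate(divide="ignore"):
        delta = 10.0 * (np.log10(densities) - np.log10(healthy_densities))
    return template_sensitivity(u0, template) + delta


def simulate_perimetry(
    truth: EyeTruth,
    protocol: TestProtocol,
    template: TemplateParameters,
    noise: NoiseConfig,
    seed: int,
    ceiling_db: float = 40.0,
) -> pd.DataFrame:
    """Simulate one eye's six 10-2 tests.

    True threshold per location/stimulus is the template applied to the
    truth's retinal input; observations add Normal(0, SD(true)) noise, are
    recorded as 0 with the censored flag when <= 0 dB, and cap at the
    ceiling.  Thresholds are drawn directly (no staircase simulation).
    """
    rng = np.random.default_rng(seed)
    loc = truth.location_table
    dens_giii = loc["latent_poff_density_per_deg2"].to_numpy()
    base_giii = loc["healthy_poff_density_per_deg2"].to_numpy()
    conv = loc["convergence"].to_numpy()
    rows = []
    for stim in protocol.stimuli:
        dcol, hcol = f"poff_density_{stim.name}", f"healthy_poff_density_{stim.name}"
        dens = loc[dcol].to_numpy() if dcol in loc.columns else dens_giii
        base = loc[hcol].to_numpy() if hcol in loc.columns else base_giii
        if truth.truth_hypothesis == "horizontal":
            s_true = _true_sensitivity(dens, base, conv, stim, template, "horizontal")
        else:
            # pure vertical shift: the size-independent dB density loss at
            # the canonical (G-III) footprint lowers every stimulus equally
            u0 = _location_inputs_db(base, conv, stim)
            with np.errstate(divide="ignore"):
                delta = 10.0 * (np.log10(dens_giii) - np.log10(base_giii))
            s_true = template_sensitivity(u0, template) + delta
        n_rep = protocol.repeat_count(truth.cohort, stim.name)
        sd = noise.sd(s_true)
        for rep in range(1, n_rep + 1):
            draw = s_true + rng.normal(0.0, 1.0, size=s_true.shape) * sd
            censored = draw <= 0.0
            obs = np.where(censored, 0.0, np.minimum(draw, ceiling_db))
            rows.append(
                pd.DataFrame(
                    {
                        "eye_id": truth.eye_id,
                        "cohort": truth.cohort,
                        "x_deg": loc["x_deg"].to_numpy(),
                        "y_deg": loc["y_deg"].to_numpy(),
                        "stimulus": stim.name,
                        "repeat": rep,
                        "sensitivity_db": obs,
                        "censored": censored.astype(int),
                        "true_sensitivity_db": s_true,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------

def _healthy_truth(
    eye_id: str,
    cohort: str,
    scale: float,
    axes: np.ndarray,
    profiles: HistologyProfiles,
    sampler: _LocationSampler,
    template: TemplateParameters,
    reference_density: np.ndarray,
) -> EyeTruth:
    ecc = np.hypot(*np.meshgrid(axes, axes, indexing="ij"))
    base = healthy_gcl_profile()
    thickness = RasterMap(axes, axes, base(np.minimum(ecc, 15.0)) * scale)
    density = gcl_to_density(thickness, profiles)
    per_stim = sampler.all_densities(density.poff)
    loc_dens = per_stim["GIII"]
    grid = sampler.grid
    conv = profiles.convergence_ratio(np.hypot(grid[:, 0], grid[:, 1]))
    giii = StimulusSpec("GIII", 0.43)
    s_eye = template_sensitivity(_location_inputs_db(loc_dens, conv, giii), template)
    s_ref = template_sensitivity(
        _location_inputs_db(reference_density, conv, giii), template
    )
    table = pd.DataFrame(
        {
            "x_deg": grid[:, 0],
            "y_deg": grid[:, 1],
            "ecc_deg": np.hypot(grid[:, 0], grid[:, 1]),
            "convergence": conv,
            "healthy_poff_density_per_deg2": loc_dens,
            "latent_poff_density_per_deg2": loc_dens,
        }
    )
    for name, d in per_stim.items():
        table[f"poff_density_{name}"] = d
        table[f"healthy_poff_density_{name}"] = d
    return EyeTruth(
        eye_id=eye_id,
        cohort=cohort,
        latent_density=density,
        gcl_thickness=thickness,
        location_table=table,
        md_summary=float(np.mean(s_eye - s_ref)),
    )


def _apply_damage(
    healthy: EyeTruth,
    stage: str,
    md_target: float,
    floor: StructuralFloorConfig,
    profiles: HistologyProfiles,
    sampler: _LocationSampler,
    template: TemplateParameters,
    rng: np.random.Generator,
    hypothesis: str = "horizontal",
) -> EyeTruth:
    """Damage an eye, calibrating overall severity so MD hits its target."""
    params = _draw_damage_params(stage, rng)
    axes_x, axes_y = healthy.latent_density.poff.x, healthy.latent_density.poff.y
    xx, yy = np.meshgrid(axes_x, axes_y, indexing="ij")
    poff0 = healthy.latent_density.poff.values
    total0 = healthy.latent_density.total.values
    conv = healthy.location_table["convergence"].to_numpy()
    base_dens = healthy.location_table["healthy_poff_density_per_deg2"].to_numpy()
    giii = StimulusSpec("GIII", 0.43)
    s_base = _true_sensitivity(base_dens, base_dens, conv, giii, template, hypothesis)

    def md_at(severity: float) -> tuple[float, np.ndarray]:
        loss = 10.0 ** _loss_log10(params, severity, xx, yy)
        poff = RasterMap(axes_x, axes_y, poff0 * loss)
        dens = sampler.location_density(poff)
        s = _true_sensitivity(dens, base_dens, conv, giii, template, hypothesis)
        return float(np.mean(s - s_base)), loss

    lo, hi = 0.0, 1.0
    md_hi, _ = md_at(hi)
    while md_hi > md_target and hi < 64.0:
        lo, hi = hi, hi * 2.0
        md_hi, _ = md_at(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        md_mid, _ = md_at(mid)
        if md_mid > md_target:
            lo = mid
        else:
            hi = mid
    severity = hi  # md(hi) <= target < md(lo); take the side inside the stratum
    _, loss = md_at(severity)

    latent = RgcDensityMap(
        total=RasterMap(axes_x, axes_y, total0 * loss),
        poff=RasterMap(axes_x, axes_y, poff0 * loss),
    )
    structural_loss = np.maximum(loss, floor.residual_fraction)
    thickness = RasterMap(
        axes_x, axes_y, healthy.gcl_thickness.values * structural_loss
    )
    per_stim = sampler.all_densities(latent.poff)
    loc_dens = per_stim["GIII"]
    table = healthy.location_table.copy()
    table["latent_poff_density_per_deg2"] = loc_dens
    for name, d in per_stim.items():
        table[f"poff_density_{name}"] = d
    s = _true_sensitivity(loc_dens, base_dens, conv, giii, template, hypothesis)
    return EyeTruth(
        eye_id=healthy.eye_id,
        cohort=stage,
        latent_density=latent,
        gcl_thickness=thickness,
        location_table=table,
        md_summary=float(np.mean(s - s_base)),
        truth_hypothesis=hypothesis,
        damage_info={"arcs": params["arcs"], "bumps": params["bumps"],
                     "severity": severity, "md_target": md_target},
    )


def generate_study(
    config: StudyConfig,
    profiles: HistologyProfiles | None = None,
) -> tuple[list[EyeTruth], pd.DataFrame]:
    """Generate the full synthetic study: eye truths and the observation table.

    Cohorts: ``young`` (n_young), ``control`` (n_controls) and glaucoma eyes
    labelled by stage (n_per_glaucoma_stage each).  Deterministic given
    ``config.seed``.
    """
    if profiles is None:
        profiles = load_profiles()
    protocol = config.protocol
    axes = _raster_axes()
    sampler = _LocationSampler(protocol, profiles)

    # population reference density per location (unit-scale healthy eye)
    ecc = np.hypot(*np.meshgrid(axes, axes, indexing="ij"))
    ref_density_map = gcl_to_density(
        RasterMap(axes, axes, healthy_gcl_profile()(np.minimum(ecc, 15.0))), profiles
    )
    reference_density = sampler.location_density(ref_density_map.poff)

    ss = np.random.SeedSequence(config.seed)
    plan: list[tuple[str, str]] = []
    plan += [("young", f"Y{i+1:03d}") for i in range(config.n_young)]
    plan += [("control", f"C{i+1:03d}") for i in range(config.n_controls)]
    for stage in STAGES:
        plan += [
            (stage, f"G{stage[0].upper()}{i+1:03d}")
            for i in range(config.n_per_glaucoma_stage)
        ]
    children = ss.spawn(len(plan))

    # older eyes are slightly thinner on average than the young cohort
    age_scale = {"young": 1.0, "control": 0.94}
    truths: list[EyeTruth] = []
    observations: list[pd.DataFrame] = []
    for (cohort, eye_id), child in zip(plan, children):
        rng = np.random.default_rng(child)
        scale = age_scale.get(cohort, 0.94) * float(
            np.clip(rng.normal(1.0, 0.05), 0.8, 1.2)
        )
        truth = _healthy_truth(
            eye_id, cohort if cohort in ("young", "control") else cohort,
            scale, axes, profiles, sampler, config.template, reference_density,
        )
        truth.truth_hypothesis = config.truth_hypothesis
        if cohort in STAGES:
            md_target = float(rng.uniform(*MD_TARGET_BANDS[cohort]))
            truth = _apply_damage(
                truth, cohort, md_target, config.floor, profiles, sampler,
                config.template, rng, config.truth_hypothesis,
            )
        obs = simulate_perimetry(
            truth, protocol, config.template, config.noise,
            seed=int(rng.integers(2**31)), ceiling_db=config.ceiling_db,
        )
        truths.append(truth)
        observations.append(obs)

    table = pd.concat(observations, ignore_index=True)
    table.insert(0, "study_id", f"synthetic-{config.seed}")
    return truths, table


def attach_stimulus_columns(
    observations: pd.DataFrame,
    protocol: TestProtocol,
    profiles: HistologyProfiles | None = None,
) -> pd.DataFrame:
    """Add per-row stimulus area/duration and location convergence columns."""
    if profiles is None:
        profiles = load_profiles()
    df = observations.copy()
    areas = {s.name: s.area_deg2 for s in protocol.stimuli}
    durs = {s.name: s.duration_ms for s in protocol.stimuli}
    unknown = set(df["stimulus"]) - set(areas)
    if unknown:
        raise KeyError(f"stimuli not in protocol: {sorted(unknown)}")
    df["area_deg2"] = df["stimulus"].map(areas)
    df["duration_ms"] = df["stimulus"].map(durs)
    ecc = np.hypot(df["x_deg"].to_numpy(), df["y_deg"].to_numpy())
    df["convergence"] = profiles.convergence_ratio(ecc)
    return df


def gi_floor_threshold(
    profiles: HistologyProfiles | None = None,
    template: TemplateParameters = DEFAULT_TEMPLATE,
    residual_fraction: float = 0.15,
    protocol: TestProtocol | None = None,
) -> float:
    """G-I sensitivity threshold separating floored from intact locations.

    The structure-function subset analysis keeps locations whose G-I
    sensitivity indicates density still above the structural floor.  On the
    clinical scale that threshold is 10 dB; here it is computed for the
    synthetic world as the midpoint between the median healthy G-I
    sensitivity and the median G-I sensitivity at the floored density.
    """
    if profiles is None:
        profiles = load_profiles()
    if protocol is None:
        protocol = TestProtocol()
    axes = _raster_axes()
    ecc = np.hypot(*np.meshgrid(axes, axes, indexing="ij"))
    dmap = gcl_to_density(
        RasterMap(axes, axes, healthy_gcl_profile()(np.minimum(ecc, 15.0))), profiles
    )
    sampler = _LocationSampler(protocol, profiles)
    dens = sampler.location_density(dmap.poff, "GI")
    grid = sampler.grid
    conv = profiles.convergence_ratio(np.hypot(grid[:, 0], grid[:, 1]))
    gi = protocol.stimulus("GI")
    s_healthy = template_sensitivity(_location_inputs_db(dens, conv, gi), template)
    s_floor = template_sensitivity(
        _location_inputs_db(dens * residual_fraction, conv, gi), template
    )
    return float(0.5 * (np.median(s_healthy) + np.median(s_floor)))


def attach_retinal_input(
    observations: pd.DataFrame,
    truths: list[EyeTruth],
    protocol: TestProtocol,
    profiles: HistologyProfiles | None = None,
    *,
    density_source: str = "structural",
) -> pd.DataFrame:
    """Join a per-row ``retinal_input_db`` column from per-location densities.

    ``density_source='structural'`` recomputes densities from each eye's GCL
    thickness map through the structural pipeline (what a real calibration
    would use); ``'latent'`` uses the generator's functional truth.
    """
    if profiles is None:
        profiles = load_profiles()
    sampler = _LocationSampler(protocol, profiles)
    df = attach_stimulus_columns(observations, protocol, profiles)
    dens_frames = []
    for t in truths:
        if density_source == "structural":
            dmap = gcl_to_density(t.gcl_thickness, profiles)
            per_stim = sampler.all_densities(dmap.poff)
        elif density_source == "latent":
            per_stim = {
                s.name: t.location_table[f"poff_density_{s.name}"].to_numpy()
                for s in protocol.stimuli
            }
        else:
            raise ValueError("density_source must be 'structural' or 'latent'")
        for name, dens in per_stim.items():
            dens_frames.append(
                pd.DataFrame(
                    {
                        "eye_id": t.eye_id,
                        "x_deg": t.location_table["x_deg"],
                        "y_deg": t.location_table["y_deg"],
                        "stimulus": name,
                        "poff_density_per_deg2": dens,
                    }
                )
            )
    dens_table = pd.concat(dens_frames, ignore_index=True)
    df = df.merge(dens_table, on=["eye_id", "x_deg", "y_deg", "stimulus"], how="left")
    if df["poff_density_per_deg2"].isna().any():
        raise ValueError("observation rows reference eyes/locations without truth")
    val = (
        df["area_deg2"] * df["duration_ms"]
        * df["poff_density_per_deg2"] * df["convergence"]
    )
    with np.errstate(divide="ignore"):
        df["retinal_input_db"] = 10.0 * np.log10(val)
    return df
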