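"""Synthetic body-scan cohorts with the statistical structure the analysis assumes.

The generator emulates, end to end, the data-generating process the income
analysis is built to untangle:

* a low-dimensional latent body-shape manifold — stature, obesity and
  hip-to-waist factors deforming a fixed-topology template mesh, so the
  "observation" per subject is a non-Euclidean 3D surface;
* nonclassical self-reporting: heights are over-reported everywhere (with
  extra over-reporting by short women), while the weight error flips sign at
  a configurable pivot (defaults 75 kg for men, 50 kg for women) so heavy
  subjects under-report and light subjects over-report;
* endogeneity of stature: a single unobserved ability factor loads on both
  realized stature and log family income, biasing naive OLS;
* instruments (shoe / jacket-or-blouse / pants size) that load on the
  exogenous skeletal component of stature only, hence are correlated with
  stature but independent of ability and of the income disturbance — the
  exclusion restriction a control-function estimator needs.

Everything is reproducible from ``CohortConfig.seed``; identical config and
seed give byte-identical CSV output.  The geometry is a stacked-ring tube
with a hand-authored radius profile, not an anatomical model: what matters
downstream is statistical recovery, not realism.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .meshes import Mesh, mesh_volume_mm3, ring_circumference, write_mesh

__all__ = [
    "LatentProfile",
    "CohortConfig",
    "CohortData",
    "Measurements",
    "make_template_mesh",
    "deform_template",
    "derive_measurements",
    "apply_reporting_error",
    "draw_income_and_instruments",
    "generate_cohort",
    "write_cohort",
    "theoretical_ols_stature_bias",
]

# ---------------------------------------------------------------------------
# Template geometry
# ---------------------------------------------------------------------------

# Relative height stations (t in [0, 1], feet to crown) and radii in mm of the
# tube template before calibration.  Hand-authored to give a body-like
# silhouette: legs, hip bulge, waist pinch, chest/shoulders, neck, head.
_PROFILE_STATIONS = {
    "male": (
        (0.00, 45.0), (0.25, 62.0), (0.45, 95.0), (0.52, 115.0),
        (0.63, 96.0), (0.72, 125.0), (0.80, 138.0), (0.86, 58.0),
        (0.93, 80.0), (1.00, 32.0),
    ),
    "female": (
        (0.00, 42.0), (0.25, 60.0), (0.45, 98.0), (0.52, 122.0),
        (0.63, 88.0), (0.72, 112.0), (0.80, 118.0), (0.86, 52.0),
        (0.93, 75.0), (1.00, 30.0),
    ),
}

# Stations (relative height) at which waist and hip girths are measured and
# where the hip-to-waist deformation is centered.
T_HIP = 0.52
T_WAIST = 0.63
_HW_WIDTH = 0.10  # gaussian half-width of the hip/waist deformation bumps

# Multiplicative deformation gains per one latent standard deviation.
STATURE_GAIN = 0.04    # height: +-4% per z-score  (~7 cm at 175 cm)
OBESITY_GAIN = 0.06    # all radii: +-6% per z-score (~12% of weight)
HIPWAIST_GAIN = 0.08   # hip-up / waist-down per z-score

# Base (latent factors = 0) body scale per gender.
BODY_BASE = {
    "male": {"height_mm": 1750.0, "weight_kg": 78.0},
    "female": {"height_mm": 1620.0, "weight_kg": 62.0},
}


def hip_ring_index(rings: int) -> int:
    return int(round(T_HIP * (rings - 1)))


def waist_ring_index(rings: int) -> int:
    return int(round(T_WAIST * (rings - 1)))


def _tube_faces(rings: int, segments: int) -> np.ndarray:
    """Consistently wound triangle list for a capped tube of rings."""
    faces = []
    for i in range(rings - 1):
        for j in range(segments):
            a = i * segments + j
            b = i * segments + (j + 1) % segments
            c = (i + 1) * segments + (j + 1) % segments
            d = (i + 1) * segments + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    # caps: fan triangulation of the end rings, no extra vertices
    for j in range(1, segments - 1):
        faces.append((0, j + 1, j))                      # bottom
    top = (rings - 1) * segments
    for j in range(1, segments - 1):
        faces.append((top, top + j, top + j + 1))        # top
    return np.asarray(faces, dtype=np.int64)


def make_template_mesh(
    gender: str,
    rings: int,
    segments: int,
    density_kg_per_m3: float = 985.0,
) -> Mesh:
    """Build the gender-specific template: a closed tube of stacked rings.

    Vertex count is exactly ``rings * segments``; ring ``i`` occupies vertex
    indices ``i*segments .. (i+1)*segments-1`` bottom-to-top.  The radius
    profile is interpolated through hand-authored body stations and then
    globally rescaled so the enclosed volume times ``density_kg_per_m3``
    equals the gender's base weight at base height.  Two calls with the same
    arguments return bitwise-identical meshes.
    """
    if gender not in BODY_BASE:
        raise ValueError(f"gender must be 'male' or 'female', got {gender!r}")
    if rings < 8 or segments < 8:
        raise ValueError("rings and segments must both be >= 8")
    stations = np.array(_PROFILE_STATIONS[gender])
    t = np.linspace(0.0, 1.0, rings)
    radii = np.interp(t, stations[:, 0], stations[:, 1])
    height = BODY_BASE[gender]["height_mm"]
    theta = 2.0 * np.pi * np.arange(segments) / segments

    def build(rad: np.ndarray) -> Mesh:
        x = np.outer(rad, np.cos(theta))
        y = np.outer(rad, np.sin(theta))
        z = np.repeat(t * height, segments).reshape(rings, segments)
        verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
        return Mesh(verts, _tube_faces(rings, segments), rings=rings, segments=segments)

    raw = build(radii)
    vol_m3 = abs(mesh_volume_mm3(raw)) * 1e-9
    target_m3 = BODY_BASE[gender]["weight_kg"] / density_kg_per_m3
    # volume scales with the square of a global radius multiplier
    return build(radii * np.sqrt(target_m3 / vol_m3))


def _ring_t(mesh: Mesh) -> np.ndarray:
    """Relative height t of each vertex's ring on the template layout."""
    idx = np.arange(mesh.n_vertices) // mesh.segments
    return idx / (mesh.rings - 1)


# ---------------------------------------------------------------------------
# Latent profile and deformation
# ---------------------------------------------------------------------------

@dataclass
class LatentProfile:
    """Latent factors (z-scores) of one subject; ``ability`` stays unobserved."""

    stature_factor: float
    obesity_factor: float
    hipwaist_factor: float
    gender: str
    ability: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.stature_factor, self.obesity_factor, self.hipwaist_factor, self.ability)
        if not np.all(np.isfinite(vals)):
            raise ValueError("latent factors must be finite")


def deform_template(
    template: Mesh,
    latent: LatentProfile,
    vertex_noise_mm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Mesh:
    """Deform the template along the latent factors, then jitter vertices.

    * stature: all z-coordinates scaled by ``1 + STATURE_GAIN * s``;
    * obesity: all ring radii scaled by ``1 + OBESITY_GAIN * o``;
    * hip-to-waist: radii near the hip station scaled up and near the waist
      station scaled down by ``(1 + HIPWAIST_GAIN * w)^(+-bump(t))``, which
      leaves stature unchanged and makes hip/waist girth ratio strictly
      monotone in the factor;
    * finally i.i.d. Gaussian displacement of scale ``vertex_noise_mm``.

    All factors zero with zero noise returns the template unchanged.
    """
    if template.rings is None or template.segments is None:
        raise ValueError("template must carry ring/segment layout metadata")
    t = _ring_t(template)
    bump_hip = np.exp(-(((t - T_HIP) / _HW_WIDTH) ** 2))
    bump_waist = np.exp(-(((t - T_WAIST) / _HW_WIDTH) ** 2))
    hw_base = 1.0 + HIPWAIST_GAIN * latent.hipwaist_factor
    if hw_base <= 0:
        raise ValueError("hipwaist factor too negative: non-positive radii")
    radial = (1.0 + OBESITY_GAIN * latent.obesity_factor) * hw_base ** (bump_hip - bump_waist)
    if np.any(radial <= 0):
        raise ValueError("obesity factor too negative: non-positive radii")
    verts = template.vertices.copy()
    verts[:, 0] *= radial
    verts[:, 1] *= radial
    verts[:, 2] *= 1.0 + STATURE_GAIN * latent.stature_factor
    if vertex_noise_mm > 0.0:
        if rng is None:
            raise ValueError("rng required when vertex_noise_mm > 0")
        verts += rng.normal(0.0, vertex_noise_mm, size=verts.shape)
    return Mesh(verts, template.faces, rings=template.rings,
                segments=template.segments, topology_id=template.topology_id)


class Measurements(NamedTuple):
    height_cm: float
    weight_kg: float
    waist_cm: float
    hip_cm: float


def derive_measurements(mesh: Mesh, density_kg_per_m3: float = 985.0) -> Measurements:
    """Tape-measure analogues from the mesh itself.

    Height is the vertical extent, waist/hip girths are the ring-polygon
    perimeters at the designated stations, and weight is the enclosed volume
    times a whole-body density (kg/m^3).
    """
    vol = abs(mesh_volume_mm3(mesh))
    if vol <= 0.0:
        raise ValueError("degenerate mesh: zero enclosed volume")
    z = mesh.vertices[:, 2]
    return Measurements(
        height_cm=float(z.max() - z.min()) / 10.0,
        weight_kg=vol * 1e-9 * density_kg_per_m3,
        waist_cm=ring_circumference(mesh, waist_ring_index(mesh.rings)) / 10.0,
        hip_cm=ring_circumference(mesh, hip_ring_index(mesh.rings)) / 10.0,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_noise_scales() -> dict:
    return {
        "vertex_mm": 3.0,
        "income": 0.5,
        "reporting_height_cm": 0.6,
        "reporting_weight_kg": 1.5,
    }


def _default_income_coefficients() -> dict:
    return {
        "intercept": 9.5,
        "education_years": 0.08,
        "experience_years": 0.02,
        "experience_sq": -0.0004,
        "n_children": -0.02,
        "race": {"white": 0.0, "black": -0.08, "asian": 0.04, "other": -0.03},
        "marital_status": {"married": 0.12, "single": 0.0, "other": -0.04},
        "occupation": {"managerial": 0.15, "technical": 0.08, "service": -0.02,
                       "manual": -0.05, "other": 0.0},
        # per-latent-factor effects (log-income units per z-score)
        "beta": {
            "male": {"stature": 0.06, "obesity": 0.005, "hipwaist": 0.0},
            "female": {"stature": 0.01, "obesity": -0.06, "hipwaist": 0.005},
        },
    }


@dataclass
class CohortConfig:
    """Everything that defines a synthetic cohort; JSON-serializable.

    ``endogeneity_strength`` is the loading of the unobserved ability factor
    on both realized stature and log income (a float applies to both genders,
    a mapping sets them separately; the default makes female stature
    endogenous and male stature exogenous).  ``hipwaist_sd`` gives women a
    third active shape factor while male hip-to-waist variance is ~0, so a
    dimension scan should find 2 male / 3 female intrinsic dimensions.
    """

    n_subjects: int = 2383
    seed: int = 0
    rings: int = 16
    segments: int = 12
    male_fraction: float = 1122 / 2383
    gender_mode: str = "quota"  # "quota" (exact counts) or "binomial"
    income_coefficients: dict = field(default_factory=_default_income_coefficients)
    endogeneity_strength: float | dict = field(
        default_factory=lambda: {"male": 0.0, "female": 0.6})
    instrument_strengths: tuple = (0.8, 0.6, 0.7)  # shoe, jacket/blouse, pants
    instrument_noise_sd: float = 0.6
    noise_scales: dict = field(default_factory=_default_noise_scales)
    weight_signswitch_kg: dict = field(
        default_factory=lambda: {"male": 75.0, "female": 50.0})
    weight_error_slope: float = 0.25
    height_over_report_cm: float = 1.0
    female_height_extra_slope: float = 0.15  # cm of extra over-report per cm below base
    hipwaist_sd: dict = field(default_factory=lambda: {"male": 0.0, "female": 1.0})
    factor_sds: dict = field(
        default_factory=lambda: {"stature": 1.0, "obesity": 1.0})
    density_kg_per_m3: float = 985.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.rings < 8 or self.segments < 8:
            raise ValueError("rings and segments must both be >= 8")
        if any(v < 0 for v in self.noise_scales.values()):
            raise ValueError("noise scales must be non-negative")
        if self.gender_mode not in ("quota", "binomial"):
            raise ValueError("gender_mode must be 'quota' or 'binomial'")

    def lam(self, gender: str) -> float:
        if isinstance(self.endogeneity_strength, dict):
            return float(self.endogeneity_strength[gender])
        return float(self.endogeneity_strength)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        if "instrument_strengths" in d:
            d["instrument_strengths"] = tuple(d["instrument_strengths"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Reporting errors, income and instruments
# ---------------------------------------------------------------------------

def apply_reporting_error(
    measured_height_cm: np.ndarray,
    measured_weight_kg: np.ndarray,
    gender: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-reported height/weight with nonclassical error structure.

    Height: a positive over-report offset for everyone, plus — for women
    only — extra over-reporting that grows linearly the further measured
    height falls below the female base height (so the conditional mean error
    has a negative slope at low heights and is flat above), plus noise.

    Weight: error ``-slope * (weight - pivot[gender]) + noise`` whose
    conditional mean crosses zero exactly at the configured sign-switch
    pivot: light subjects over-report, heavy subjects under-report.
    """
    h = np.asarray(measured_height_cm, dtype=float)
    w = np.asarray(measured_weight_kg, dtype=float)
    g = np.asarray(gender)
    if not (h.shape == w.shape == g.shape):
        raise ValueError("height, weight and gender must have equal shapes")
    female = g == "female"

    h_err = np.full_like(h, config.height_over_report_cm)
    base_f = BODY_BASE["female"]["height_mm"] / 10.0
    h_err += np.where(female,
                      config.female_height_extra_slope * np.maximum(0.0, base_f - h),
                      0.0)
    pivot = np.where(female, config.weight_signswitch_kg["female"],
                     config.weight_signswitch_kg["male"])
    w_err = -config.weight_error_slope * (w - pivot)

    s_h = config.noise_scales["reporting_height_cm"]
    s_w = config.noise_scales["reporting_weight_kg"]
    if s_h > 0:
        h_err = h_err + rng.normal(0.0, s_h, size=h.shape)
    if s_w > 0:
        w_err = w_err + rng.normal(0.0, s_w, size=w.shape)
    return h + h_err, w + w_err


def _cat_effect(values: np.ndarray, table: dict) -> np.ndarray:
    return np.array([table[v] for v in values], dtype=float)


def draw_income_and_instruments(
    latents: pd.DataFrame,
    covariates: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Log family income and the three sizing instruments.

    Income is ``alpha'X + beta_g'(stature, obesity, hipwaist) +
    lambda_g * ability + noise``; realized stature itself already carries the
    ``lambda_g * ability`` loading (see :func:`generate_cohort`), which is
    what biases naive OLS.  Instruments load on the exogenous skeletal
    component of stature (``stature_base``) plus independent noise, so they
    correlate with stature but not with ability or the income disturbance.

    Returns ``(log_income, instruments)`` with instruments of shape (n, 3).
    """
    co = config.income_coefficients
    n = len(latents)
    if len(covariates) != n:
        raise ValueError("latents and covariates must have equal length")
    y = np.full(n, co["intercept"], dtype=float)
    y += co["education_years"] * covariates["education_years"].to_numpy(float)
    exper = covariates["experience_years"].to_numpy(float)
    y += co["experience_years"] * exper + co["experience_sq"] * exper ** 2
    y += co["n_children"] * covariates["n_children"].to_numpy(float)
    for col in ("race", "marital_status", "occupation"):
        y += _cat_effect(covariates[col].to_numpy(), co[col])

    gender = latents["gender"].to_numpy()
    lam = np.array([config.lam(g) for g in gender])
    for fac in ("stature", "obesity", "hipwaist"):
        beta = np.array([co["beta"][g][fac] for g in gender])
        y += beta * latents[f"{fac}_factor"].to_numpy(float)
    y += lam * latents["ability"].to_numpy(float)
    s_inc = config.noise_scales["income"]
    if s_inc > 0:
        y = y + rng.normal(0.0, s_inc, size=n)

    kappa = np.asarray(config.instrument_strengths, dtype=float)
    s0 = latents["stature_base"].to_numpy(float)
    z = kappa[None, :] * s0[:, None]
    z = z + rng.normal(0.0, config.instrument_noise_sd, size=z.shape)
    return y, z


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

_RACE_LEVELS = ("white", "black", "asian", "other")
_RACE_P = (0.68, 0.13, 0.08, 0.11)
_MARITAL_LEVELS = ("married", "single", "other")
_MARITAL_P = (0.55, 0.35, 0.10)
_OCC_LEVELS = ("managerial", "technical", "service", "manual", "other")
_OCC_P = (0.25, 0.20, 0.20, 0.20, 0.15)

SUBJECT_COLUMNS = [
    "id", "gender", "measured_height", "measured_weight",
    "reported_height", "reported_weight", "bmi",
    "hip_circumference_cm", "waist_circumference_cm",
    "education_years", "experience_years", "race", "marital_status",
    "n_children", "occupation", "shoe_size", "garment_size", "pants_size",
    "log_family_income",
]


@dataclass
class CohortData:
    """A generated cohort: meshes, observable table, and the latent truth.

    ``table`` holds only observables (the subject CSV schema); ``latents``
    is the simulation truth — factors, ability, stature_base — kept separate
    so oracle checks can use it while the observable record never exposes
    the confounder.
    """

    meshes: list[Mesh] | None
    table: pd.DataFrame
    latents: pd.DataFrame
    config: CohortConfig


def _draw_truncnorm(rng, loc, scale, lo, hi, size):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_cohort(config: CohortConfig, include_meshes: bool = True) -> CohortData:
    """Generate a full cohort: one mesh and one subject record per person.

    Fully reproducible from ``config.seed``.  With ``gender_mode='quota'``
    the male count is exactly ``round(male_fraction * n)`` (so the default
    2,383-subject cohort has 1,122 men and 1,261 women); ``'binomial'``
    draws each gender independently.  Measurements (height, weight, girths)
    are derived from each subject's deformed mesh, never from the latent
    factors directly; ``include_meshes=False`` merely drops the meshes from
    the return value without changing the random stream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    if config.gender_mode == "quota":
        n_male = int(round(config.male_fraction * n))
        gender = np.array(["male"] * n_male + ["female"] * (n - n_male))
    else:
        gender = np.where(rng.random(n) < config.male_fraction, "male", "female")

    stature_base = rng.normal(size=n) * config.factor_sds["stature"]
    ability = rng.normal(size=n)
    obesity = rng.normal(size=n) * config.factor_sds["obesity"]
    hw_sd = np.array([config.hipwaist_sd[g] for g in gender])
    hipwaist = rng.normal(size=n) * hw_sd
    lam = np.array([config.lam(g) for g in gender])
    stature = stature_base + lam * ability

    latents = pd.DataFrame({
        "gender": gender,
        "stature_factor": stature,
        "obesity_factor": obesity,
        "hipwaist_factor": hipwaist,
        "ability": ability,
        "stature_base": stature_base,
    })

    templates = {g: make_template_mesh(g, config.rings, config.segments,
                                       config.density_kg_per_m3)
                 for g in ("male", "female")}
    noise_mm = config.noise_scales["vertex_mm"]
    meshes: list[Mesh] = []
    meas = np.empty((n, 4))
    for i in range(n):
        lp = LatentProfile(stature[i], obesity[i], hipwaist[i], gender[i], ability[i])
        m = deform_template(templates[gender[i]], lp, noise_mm, rng)
        meas[i] = derive_measurements(m, config.density_kg_per_m3)
        meshes.append(m)

    edu = np.round(_draw_truncnorm(rng, 13.5, 2.5, 8, 22, n), 1)
    exper = np.round(_draw_truncnorm(rng, 18.0, 10.0, 0, 45, n), 1)
    race = rng.choice(_RACE_LEVELS, size=n, p=_RACE_P)
    marital = rng.choice(_MARITAL_LEVELS, size=n, p=_MARITAL_P)
    children = np.minimum(rng.poisson(1.1, size=n), 6)
    occupation = rng.choice(_OCC_LEVELS, size=n, p=_OCC_P)
    covariates = pd.DataFrame({
        "education_years": edu, "experience_years": exper, "race": race,
        "marital_status": marital, "n_children": children, "occupation": occupation,
    })

    height, weight, waist, hip = meas[:, 0], meas[:, 1], meas[:, 2], meas[:, 3]
    rep_h, rep_w = apply_reporting_error(height, weight, gender, config, rng)
    log_income, instruments = draw_income_and_instruments(
        latents, covariates, config, rng)

    table = pd.DataFrame({
        "id": np.arange(n),
        "gender": gender,
        "measured_height": height,
        "measured_weight": weight,
        "reported_height": rep_h,
        "reported_weight": rep_w,
        "bmi": weight / (height / 100.0) ** 2,
        "hip_circumference_cm": hip,
        "waist_circumference_cm": waist,
        "education_years": edu,
        "experience_years": exper,
        "race": race,
        "marital_status": marital,
        "n_children": children,
        "occupation": occupation,
        "shoe_size": instruments[:, 0],
        "garment_size": instruments[:, 1],
        "pants_size": instruments[:, 2],
        "log_family_income": log_income,
    })[SUBJECT_COLUMNS]

    return CohortData(meshes if include_meshes else None, table, latents, config)


def write_cohort(
    cohort: CohortData,
    outdir: str | Path,
    mesh_format: str = "obj",
    write_meshes: bool = True,
    write_latents: bool = False,
) -> Path:
    """Persist a cohort: subjects.csv, config.json, metadata.json, meshes/.

    The subject CSV holds only observable fields.  The latent truth table is
    written (as ``latents.csv``) only on request and is clearly simulation
    metadata, not part of the observable record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(outdir / "subjects.csv", index=False, float_format="%.8g")
    (outdir / "config.json").write_text(cohort.config.to_json() + "\n")
    meta = {
        "seed": cohort.config.seed,
        "n_subjects": int(cohort.config.n_subjects),
        "columns": SUBJECT_COLUMNS,
        "mesh_format": mesh_format if write_meshes else None,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    if write_latents:
        cohort.latents.to_csv(outdir / "latents.csv", index=False, float_format="%.8g")
    if write_meshes and cohort.meshes is not None:
        mdir = outdir / "meshes"
        mdir.mkdir(exist_ok=True)
        for i, m in enumerate(cohort.meshes):
            write_mesh(m, mdir / f"subject_{i:05d}.{mesh_format}")
    return outdir


def theoretical_ols_stature_bias(endogeneity_strength: float,
                                 stature_base_var: float = 1.0) -> float:
    """Closed-form plim bias of OLS on stature under the single-factor model.

    With stature = s0 + lam*a (s0, a independent standard normals up to
    ``stature_base_var``) and the income disturbance containing lam*a, the
    omitted-variable bias of the stature coefficient is
    ``lam^2 / (var(s0) + lam^2)``.
    """
    lam2 = float(endogeneity_strength) ** 2
    return lam2 / (stature_base_var + lam2)
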