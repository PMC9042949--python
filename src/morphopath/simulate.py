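"""Synthetic-study generator with a known ground-truth path model.

A synthetic study mirrors the structure of a facial-perception sample: raw
(unaligned) 72-point landmark configurations for both sexes, a specimen
covariate table (age, weight/height, CIELab colour, repeated facial
width/height measurements), and two rater-by-stimulus rating matrices
(perceived sex-typicality and dominance on the 1-7 scale) — all generated
from explicit, recoverable parameters so every downstream stage of the
pipeline can be verified against truth.

The generative chain is the path model itself: standard-normal age drives
BMI, age and BMI drive a correlated mediator block (colour channels or one
latent colour factor, fWHR, SShD, DIST), and the mediators drive bivariate
latent perceived outcomes with a residual correlation. Mediator and outcome
residual sds default to the values making every variable unit-variance, so
within-sample standardisation leaves the generative slopes interpretable.
Landmark shape is the unit-centroid-size template displaced along a unit
dimorphism axis (sex offset +-separation/2 plus the within-sex SShD latent),
with isotropic idiosyncratic noise, tangential semi-landmark jitter, and a
random similarity nuisance transform so superimposition is exercised.
Latent ratings are mapped to the 1-7 scale by affine rescaling to a preset
mean/SD, perturbed per rater, rounded and clamped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateShapeError, NotPositiveDefiniteError
from .landmarks import (
    LandmarkConfiguration,
    LandmarkScheme,
    write_scheme,
    write_specimen_table,
    write_tps,
)
from .measures import RatingMatrix

__all__ = [
    "GroundTruth",
    "SyntheticStudy",
    "default_template",
    "default_scheme",
    "dimorphism_axis_from_template",
    "preset_truth",
    "PRESET_SAMPLE_SIZES",
    "simulate_landmarks",
    "simulate_path_table",
    "simulate_study",
    "write_study",
]

CHANNEL_MEDIATORS = ["L", "a", "b", "fwhr", "sshd", "dist"]
FACTOR_MEDIATORS = ["colour", "fwhr", "sshd", "dist"]

#: stimulus counts of the four calibration samples
PRESET_SAMPLE_SIZES = {"czech_women": 106, "czech_men": 89,
                       "cmr_women": 50, "cmr_men": 49}


# ---------------------------------------------------------------------------
# template geometry

def default_template() -> np.ndarray:
    """Schematic frontal-face template: 72 points, unit centroid size.

    Points 0-35 are fixed anatomical landmarks (eyes, brows, nose, mouth,
    chin, jaw, temples, ears, forehead); points 36-71 are semi-landmarks on
    four curves (jaw outline 16, left/right brow 6+6, upper lip 8). All
    downstream mathematics is scheme-agnostic; this particular layout only
    needs to be non-degenerate and face-like.
    """
    fixed = [
        (-0.30, 0.30), (0.30, 0.30),            # pupils
        (-0.15, 0.30), (0.15, 0.30),            # inner eye corners
        (-0.45, 0.32), (0.45, 0.32),            # outer eye corners
        (-0.12, 0.48), (0.12, 0.48),            # inner brow anchors
        (-0.48, 0.50), (0.48, 0.50),            # outer brow anchors
        (0.00, 0.30), (0.00, -0.05),            # nasion, nose tip
        (-0.14, -0.10), (0.14, -0.10),          # nostrils
        (0.00, -0.15),                          # subnasale
        (-0.25, -0.40), (0.25, -0.40),          # mouth corners
        (0.00, -0.33), (0.00, -0.50),           # cupid's bow, lower lip
        (0.00, -0.95), (-0.20, -0.88), (0.20, -0.88),  # chin
        (-0.62, -0.45), (0.62, -0.45),          # gonia
        (-0.68, 0.05), (0.68, 0.05),            # zygia
        (-0.60, 0.55), (0.60, 0.55),            # temples
        (0.00, 0.80), (0.00, 0.95),             # forehead, trichion
        (-0.72, 0.15), (0.72, 0.15),            # tragia
        (-0.30, 0.37), (0.30, 0.37),            # upper eyelids
        (-0.30, 0.24), (0.30, 0.24),            # lower eyelids
    ]
    pts = list(fixed)
    # jaw outline: lower half of an ellipse, left to right
    t = np.linspace(np.pi * 1.06, np.pi * 1.94, 16)
    for ti in t:
        pts.append((0.70 * np.cos(ti), -0.05 + 0.95 * np.sin(ti)))
    # brows: gentle arches
    for side in (-1, 1):
        xs = np.linspace(0.14, 0.46, 6) * side
        for u, x in zip(np.linspace(0, 1, 6), xs):
            pts.append((x, 0.50 + 0.05 * np.sin(np.pi * u)))
    # upper lip
    xs = np.linspace(-0.22, 0.22, 8)
    for x in xs:
        pts.append((x, -0.36 + 0.045 * np.cos(np.pi * x / 0.5)))
    template = np.asarray(pts, dtype=float)
    template -= template.mean(axis=0)
    template /= np.sqrt(np.sum(template ** 2))
    return template


def default_scheme() -> LandmarkScheme:
    roles = ["fixed"] * 36 + ["semi"] * 36
    curves: list[str | None] = [None] * 36
    curves += ["jaw"] * 16 + ["brow_l"] * 6 + ["brow_r"] * 6 + ["lip"] * 8
    return LandmarkScheme(roles=np.array(roles, dtype=object),
                          curve_ids=np.array(curves, dtype=object))


def dimorphism_axis_from_template(template: np.ndarray) -> np.ndarray:
    """Unit 144-vector pointing from female-like towards male-like shape.

    A masculinising deformation of the template: laterally wider jaw and
    zygia, lower brows, thinner upper lip, longer chin. The difference is
    centred (no net translation) and normalised to unit length.
    """
    masc = template.copy()
    scheme = default_scheme()
    jaw = [i for i in range(72) if scheme.curve_ids[i] == "jaw"]
    brows = [i for i in range(72)
             if scheme.curve_ids[i] in ("brow_l", "brow_r")] + [6, 7, 8, 9]
    lip = [i for i in range(72) if scheme.curve_ids[i] == "lip"]
    wide = jaw + [20, 21, 22, 23, 24, 25, 26]     # jaw curve + gonia/zygia/chin
    masc[wide, 0] *= 1.10
    masc[[19, 20, 21], 1] -= 0.04                 # longer chin
    masc[brows, 1] -= 0.05                        # lower brows
    masc[lip, 1] = -0.36 + 0.55 * (masc[lip, 1] + 0.36)  # thinner lip
    delta = masc - template
    delta -= delta.mean(axis=0)
    flat = delta.reshape(-1)
    return flat / np.linalg.norm(flat)


# ---------------------------------------------------------------------------
# ground truth

def _check_corr(name: str, r: np.ndarray, dim: int) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (dim, dim):
        raise ValueError(f"{name} must be {dim}x{dim}, got {r.shape}")
    if not np.allclose(r, r.T):
        raise NotPositiveDefiniteError(name, f"{name} is not symmetric")
    if not np.allclose(np.diag(r), 1.0):
        raise NotPositiveDefiniteError(name, f"{name} diagonal is not 1")
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(name) from exc
    return r


@dataclass
class GroundTruth:
    """Complete generative parameter set for one synthetic study.

    Shape units are Procrustes units (the template has unit centroid size).
    ``mediator_slopes`` is (2, m) for (age, bmi) rows; ``outcome_slopes`` is
    (2, 2+m) with rows (sex-typicality, dominance) and columns (age, bmi,
    mediators). Residual sds default to the unit-marginal-variance solution.
    """

    # shape geometry
    template_shape: np.ndarray = field(default_factory=default_template)
    dimorphism_axis: np.ndarray | None = None
    sshd_separation: float = 0.04
    sshd_within_sex_sd: float = 0.013
    idiosyncratic_sd: float = 0.005
    curve_jitter_sd: float = 0.003
    # covariates
    age_mean: float = 23.09
    age_sd: float = 4.12
    bmi_mean: float = 21.80
    bmi_sd: float = 2.89
    bmi_on_age_slope: float = 0.25
    height_mean: float = 1.68
    height_sd: float = 0.06
    # facial measures
    fwhr_mean: float = 1.93
    fwhr_sd: float = 0.12
    face_height_px_mean: float = 120.0
    face_height_px_sd: float = 8.0
    measurement_noise_sd: float = 1.5
    lab_means: np.ndarray = field(
        default_factory=lambda: np.array([61.38, 17.39, 13.12]))
    lab_sds: np.ndarray = field(
        default_factory=lambda: np.array([3.46, 2.50, 2.14]))
    # path model
    colour_mode: str = "channels"
    colour_factor_loadings: np.ndarray = field(
        default_factory=lambda: np.array([0.85, 0.95, 0.97]))
    mediator_slopes: np.ndarray | None = None
    mediator_residual_corr: np.ndarray | None = None
    mediator_residual_sds: np.ndarray | None = None
    outcome_slopes: np.ndarray | None = None
    outcome_residual_corr: float = 0.3
    outcome_residual_sds: np.ndarray | None = None
    # ratings
    sextypicality_mean: float = 4.00
    sextypicality_sd: float = 0.84
    dominance_mean: float = 3.81
    dominance_sd: float = 0.66
    rater_noise_sd: float = 1.2
    rater_bias_sd: float = 0.0  # per-rater main effect; residual-only default
    n_raters: int = 102        # the published mean rater count per set
    focal_sex: str = "female"
    seed: int = 0

    def __post_init__(self):
        self.template_shape = np.asarray(self.template_shape, dtype=float)
        if self.dimorphism_axis is None:
            self.dimorphism_axis = dimorphism_axis_from_template(
                self.template_shape)
        self.dimorphism_axis = np.asarray(self.dimorphism_axis, dtype=float)
        k = self.template_shape.shape[0]
        if self.dimorphism_axis.shape != (2 * k,):
            raise ValueError("dimorphism_axis length must be 2 * n_landmarks")
        norm = np.linalg.norm(self.dimorphism_axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError(f"dimorphism_axis must be unit length (|d|={norm:.4g})")
        if self.colour_mode not in ("channels", "factor"):
            raise ValueError(f"unknown colour_mode {self.colour_mode!r}")
        m = len(self.mediators)
        if self.mediator_slopes is None:
            self.mediator_slopes = np.zeros((2, m))
        self.mediator_slopes = np.asarray(self.mediator_slopes, dtype=float)
        if self.mediator_slopes.shape != (2, m):
            raise ValueError(f"mediator_slopes must be (2, {m})")
        if self.mediator_residual_corr is None:
            self.mediator_residual_corr = np.eye(m)
        self.mediator_residual_corr = _check_corr(
            "mediator_residual_corr", self.mediator_residual_corr, m)
        if self.outcome_slopes is None:
            self.outcome_slopes = np.zeros((2, 2 + m))
        self.outcome_slopes = np.asarray(self.outcome_slopes, dtype=float)
        if self.outcome_slopes.shape != (2, 2 + m):
            raise ValueError(f"outcome_slopes must be (2, {2 + m})")
        if not -1.0 < self.outcome_residual_corr < 1.0:
            raise NotPositiveDefiniteError(
                "outcome_residual_corr",
                f"outcome_residual_corr={self.outcome_residual_corr} is "
                "outside (-1, 1)")
        for name in ("sshd_within_sex_sd", "idiosyncratic_sd",
                     "curve_jitter_sd", "age_sd", "bmi_sd", "height_sd",
                     "fwhr_sd", "face_height_px_sd", "measurement_noise_sd",
                     "rater_noise_sd", "rater_bias_sd",
                     "sextypicality_sd", "dominance_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_raters < 2:
            raise ValueError("n_raters must be >= 2")
        self.lab_means = np.asarray(self.lab_means, dtype=float)
        self.lab_sds = np.asarray(self.lab_sds, dtype=float)
        self.colour_factor_loadings = np.asarray(
            self.colour_factor_loadings, dtype=float)
        if np.any(np.abs(self.colour_factor_loadings) > 1):
            raise ValueError("colour factor loadings must lie in [-1, 1]")

    @property
    def mediators(self) -> list[str]:
        return (CHANNEL_MEDIATORS if self.colour_mode == "channels"
                else FACTOR_MEDIATORS)

    def predictor_covariance(self) -> np.ndarray:
        """Implied covariance of (age, bmi, mediators), all unit variance."""
        m = len(self.mediators)
        beta = self.bmi_on_age_slope
        c2 = np.array([[1.0, beta], [beta, 1.0]])
        s = self.mediator_slopes                     # (2, m)
        med_resid = self._mediator_resid_cov()
        g = np.zeros((2 + m, 2 + m))
        g[:2, :2] = c2
        cross = c2 @ s                                # (2, m)
        g[:2, 2:] = cross
        g[2:, :2] = cross.T
        g[2:, 2:] = s.T @ c2 @ s + med_resid
        return g

    def _mediator_resid_sds(self) -> np.ndarray:
        if self.mediator_residual_sds is not None:
            return np.asarray(self.mediator_residual_sds, dtype=float)
        beta = self.bmi_on_age_slope
        c2 = np.array([[1.0, beta], [beta, 1.0]])
        explained = np.einsum("ij,ik,kj->j", self.mediator_slopes, c2,
                              self.mediator_slopes)
        resid_var = 1.0 - explained
        if np.any(resid_var <= 0.02):
            raise ValueError(
                "mediator slopes explain (nearly) all variance; no "
                "positive unit-variance residual sd exists")
        return np.sqrt(resid_var)

    def _mediator_resid_cov(self) -> np.ndarray:
        sds = self._mediator_resid_sds()
        return np.outer(sds, sds) * self.mediator_residual_corr

    def _outcome_resid_sds(self) -> np.ndarray:
        if self.outcome_residual_sds is not None:
            return np.asarray(self.outcome_residual_sds, dtype=float)
        g = self.predictor_covariance()
        explained = np.einsum("ij,jk,ik->i", self.outcome_slopes, g,
                              self.outcome_slopes)
        resid_var = 1.0 - explained
        if np.any(resid_var <= 0.02):
            raise ValueError(
                "outcome slopes explain (nearly) all variance; no positive "
                "unit-variance residual sd exists")
        return np.sqrt(resid_var)

    def to_jsonable(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, np.ndarray):
                out[key] = val.tolist()
            elif isinstance(val, (np.floating, np.integer)):
                out[key] = val.item()
            else:
                out[key] = val
        return out


# ---------------------------------------------------------------------------
# presets (calibrated to the published per-sample descriptive moments)

def _channels_corr() -> np.ndarray:
    m = np.eye(6)
    pairs = {(0, 1): 0.45, (0, 2): 0.35, (1, 2): 0.40,   # L-a-b
             (3, 5): 0.10, (4, 5): 0.10}
    for (i, j), r in pairs.items():
        m[i, j] = m[j, i] = r
    return m


def _factor_corr() -> np.ndarray:
    m = np.eye(4)
    m[2, 3] = m[3, 2] = 0.10                              # sshd-dist
    return m


def _med_slopes(names, **kwargs) -> np.ndarray:
    s = np.zeros((2, len(names)))
    for key, (a, b) in kwargs.items():
        j = names.index(key)
        s[0, j], s[1, j] = a, b
    return s


def _out_slopes(names, sextypicality=None, dominance=None) -> np.ndarray:
    cols = ["age", "bmi"] + list(names)
    s = np.zeros((2, len(cols)))
    for row, spec_map in ((0, sextypicality or {}), (1, dominance or {})):
        for key, val in spec_map.items():
            s[row, cols.index(key)] = val
    return s


def preset_truth(name: str, seed: int = 0) -> GroundTruth:
    """Calibrated ground truths for the four study samples.

    Descriptive moments (age, BMI, fWHR, CIELab, rating means/SDs, SShD
    separation and spread, DIST level) follow the published per-sample
    descriptive table; generative path slopes and residual correlations are
    set to the corresponding published posterior means (unreported slopes
    zero), so pipeline recovery can be checked against them. Czech presets
    use correlated-channel colour; Cameroonian presets use the single
    latent-factor colour regime with loadings matching the published
    factor-score R^2 per channel.
    """
    common = dict(seed=seed)
    if name == "czech_women":
        return GroundTruth(
            age_mean=23.09, age_sd=4.12, bmi_mean=21.80, bmi_sd=2.89,
            fwhr_mean=1.93, fwhr_sd=0.12,
            lab_means=np.array([61.38, 17.39, 13.12]),
            lab_sds=np.array([3.46, 2.50, 2.14]),
            sshd_separation=0.04, sshd_within_sex_sd=0.013,
            idiosyncratic_sd=0.005,
            colour_mode="channels",
            mediator_residual_corr=_channels_corr(),
            mediator_slopes=_med_slopes(CHANNEL_MEDIATORS,
                                        fwhr=(0.0, 0.30), dist=(0.0, 0.10),
                                        L=(-0.10, 0.0), sshd=(0.10, 0.0)),
            outcome_slopes=_out_slopes(
                CHANNEL_MEDIATORS,
                sextypicality={"sshd": -0.24, "dist": -0.26},
                dominance={"age": 0.30}),
            outcome_residual_corr=0.31,
            sextypicality_mean=4.00, sextypicality_sd=0.84,
            dominance_mean=3.81, dominance_sd=0.66,
            focal_sex="female", **common)
    if name == "czech_men":
        return GroundTruth(
            age_mean=23.38, age_sd=4.25, bmi_mean=22.99, bmi_sd=2.36,
            fwhr_mean=1.88, fwhr_sd=0.11,
            lab_means=np.array([58.77, 19.15, 13.72]),
            lab_sds=np.array([2.74, 2.66, 1.57]),
            sshd_separation=0.04, sshd_within_sex_sd=0.010,
            idiosyncratic_sd=0.005,
            colour_mode="channels",
            mediator_residual_corr=_channels_corr(),
            mediator_slopes=_med_slopes(CHANNEL_MEDIATORS,
                                        fwhr=(0.0, 0.30), dist=(0.0, 0.10),
                                        L=(-0.10, 0.0), sshd=(0.10, 0.0)),
            outcome_slopes=_out_slopes(
                CHANNEL_MEDIATORS,
                sextypicality={"age": 0.24, "sshd": 0.15, "b": 0.18},
                dominance={"age": 0.23, "bmi": 0.30, "b": 0.16,
                           "sshd": 0.08}),
            outcome_residual_corr=0.77,
            sextypicality_mean=4.17, sextypicality_sd=0.85,
            dominance_mean=3.94, dominance_sd=0.71,
            focal_sex="male", **common)
    if name == "cmr_women":
        return GroundTruth(
            age_mean=21.24, age_sd=1.89, bmi_mean=24.30, bmi_sd=4.17,
            fwhr_mean=2.16, fwhr_sd=0.17,
            lab_means=np.array([38.36, 21.09, 18.13]),
            lab_sds=np.array([6.45, 3.18, 4.45]),
            sshd_separation=0.02, sshd_within_sex_sd=0.009,
            idiosyncratic_sd=0.0042,
            colour_mode="factor",
            colour_factor_loadings=np.array([0.877, 0.949, 0.9995]),
            mediator_residual_corr=_factor_corr(),
            mediator_slopes=_med_slopes(FACTOR_MEDIATORS,
                                        fwhr=(0.0, 0.30), dist=(0.0, 0.10),
                                        sshd=(0.10, 0.0)),
            outcome_slopes=_out_slopes(
                FACTOR_MEDIATORS,
                sextypicality={"colour": 0.52},
                dominance={"bmi": 0.24, "sshd": 0.24}),
            outcome_residual_corr=-0.24,
            sextypicality_mean=4.88, sextypicality_sd=0.58,
            dominance_mean=3.90, dominance_sd=0.49,
            focal_sex="female", **common)
    if name == "cmr_men":
        return GroundTruth(
            age_mean=22.00, age_sd=2.24, bmi_mean=23.15, bmi_sd=2.33,
            fwhr_mean=2.09, fwhr_sd=0.17,
            lab_means=np.array([32.91, 17.44, 13.33]),
            lab_sds=np.array([6.24, 3.41, 4.33]),
            sshd_separation=0.02, sshd_within_sex_sd=0.008,
            idiosyncratic_sd=0.0042,
            colour_mode="factor",
            colour_factor_loadings=np.array([0.742, 0.9995, 0.985]),
            mediator_residual_corr=_factor_corr(),
            mediator_slopes=_med_slopes(FACTOR_MEDIATORS,
                                        fwhr=(0.0, 0.30), dist=(0.0, 0.10),
                                        sshd=(0.10, 0.0)),
            outcome_slopes=_out_slopes(
                FACTOR_MEDIATORS,
                sextypicality={"age": 0.31, "colour": -0.29, "sshd": 0.29},
                dominance={"sshd": 0.29}),
            outcome_residual_corr=0.42,
            sextypicality_mean=5.62, sextypicality_sd=0.57,
            dominance_mean=4.11, dominance_sd=0.51,
            focal_sex="male", **common)
    if name == "custom":
        return GroundTruth(**common)
    raise ValueError(f"unknown preset {name!r}; expected one of "
                     f"{sorted(PRESET_SAMPLE_SIZES) + ['custom']}")


# ---------------------------------------------------------------------------
# simulation

def _z(rng, n, sd_gate):
    """Standard-normal latents, or zeros when the governing sd is zero."""
    return rng.standard_normal(n) if sd_gate > 0 else np.zeros(n)


def simulate_path_table(truth: GroundTruth, n: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Latent standardised path-model variables for ``n`` specimens.

    Columns: age, bmi, the mediators, and the two outcome latents — each
    unit variance under the default residual-sd solution. This is the exact
    generative counterpart of the fitted path model and is used both inside
    :func:`simulate_study` and directly for parameter-recovery simulations.
    """
    med = truth.mediators
    m = len(med)
    age = _z(rng, n, truth.age_sd)
    beta = truth.bmi_on_age_slope
    bmi_resid_sd = np.sqrt(max(1.0 - beta ** 2, 0.0))
    bmi_v = beta * age + bmi_resid_sd * _z(rng, n, truth.bmi_sd)
    x2 = np.column_stack([age, bmi_v])
    med_mean = x2 @ truth.mediator_slopes
    resid_sds = truth._mediator_resid_sds()
    cov = np.outer(resid_sds, resid_sds) * truth.mediator_residual_corr
    if np.all(resid_sds == 0):
        med_resid = np.zeros((n, m))
    else:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
        med_resid = rng.standard_normal((n, m)) @ chol.T
    mediators = med_mean + med_resid
    xo = np.column_stack([x2, mediators])
    out_mean = xo @ truth.outcome_slopes.T
    o_sds = truth._outcome_resid_sds()
    rho = truth.outcome_residual_corr
    o_cov = np.outer(o_sds, o_sds) * np.array([[1.0, rho], [rho, 1.0]])
    if np.all(o_sds == 0):
        out_resid = np.zeros((n, 2))
    else:
        chol_o = np.linalg.cholesky(o_cov + 1e-12 * np.eye(2))
        out_resid = rng.standard_normal((n, 2)) @ chol_o.T
    outcomes = out_mean + out_resid
    frame = pd.DataFrame({"age": age, "bmi": bmi_v})
    for j, name in enumerate(med):
        frame[name] = mediators[:, j]
    frame["perceived_sextypicality"] = outcomes[:, 0]
    frame["perceived_dominance"] = outcomes[:, 1]
    return frame


def true_parameter_values(truth: GroundTruth) -> dict[str, float]:
    """Generative values keyed by the fitted model's parameter names.

    Slopes, residual sds and residual correlations of the default-variant
    path model; intercepts are zero by construction (standardised scale).
    Used by parameter-recovery simulations to score posterior coverage.
    """
    med = truth.mediators
    values = {"slope[age->bmi]": float(truth.bmi_on_age_slope),
              "sd[bmi]": float(np.sqrt(max(
                  1.0 - truth.bmi_on_age_slope ** 2, 0.0)))}
    for name in ["bmi"] + med + ["perceived_sextypicality",
                                 "perceived_dominance"]:
        values[f"intercept[{name}]"] = 0.0
    for j, name in enumerate(med):
        values[f"slope[age->{name}]"] = float(truth.mediator_slopes[0, j])
        values[f"slope[bmi->{name}]"] = float(truth.mediator_slopes[1, j])
    out_names = ["perceived_sextypicality", "perceived_dominance"]
    cols = ["age", "bmi"] + med
    for k, o in enumerate(out_names):
        for c, col in enumerate(cols):
            values[f"slope[{col}->{o}]"] = float(truth.outcome_slopes[k, c])
    med_sds = truth._mediator_resid_sds()
    for j, name in enumerate(med):
        values[f"sd[{name}]"] = float(med_sds[j])
    for i in range(len(med)):
        for j in range(i + 1, len(med)):
            values[f"corr[{med[i]},{med[j]}]"] = \
                float(truth.mediator_residual_corr[i, j])
    out_sds = truth._outcome_resid_sds()
    for k, o in enumerate(out_names):
        values[f"sd[{o}]"] = float(out_sds[k])
    values[f"corr[{out_names[0]},{out_names[1]}]"] = \
        float(truth.outcome_residual_corr)
    return values


def _template_area(template: np.ndarray) -> float:
    centred = template - template.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return float(s[0] * s[1])


def simulate_landmarks(truth: GroundTruth, sshd_latent,
                       rng: np.random.Generator,
                       noise_scales=None,
                       specimen_ids=None) -> list[LandmarkConfiguration]:
    """Raw digitising-space configurations for given shape-space latents.

    Each configuration is the template displaced by ``latent * axis``, plus
    isotropic idiosyncratic noise and tangential semi-landmark jitter, then
    rotated (uniform angle), scaled (log-uniform on [0.5, 2]) and translated
    — the nuisance transforms a digitiser would introduce.
    """
    template = truth.template_shape
    k = template.shape[0]
    if _template_area(template) <= 1e-12:
        raise DegenerateShapeError("template has zero area")
    latents = np.asarray(sshd_latent, dtype=float)
    n = latents.shape[0]
    scheme = default_scheme() if k == 72 else None
    axis = truth.dimorphism_axis.reshape(k, 2)
    if noise_scales is None:
        noise_scales = np.full(n, truth.idiosyncratic_sd)
    tangents = np.zeros((k, 2))
    if scheme is not None:
        for j in scheme.semi_indices:
            prev, nxt = scheme.curve_neighbours(j)
            a = template[prev] if prev is not None else template[j]
            b = template[nxt] if nxt is not None else template[j]
            chord = b - a
            nrm = np.linalg.norm(chord)
            if nrm > 0:
                tangents[j] = chord / nrm
    ids = specimen_ids or [f"S{i:03d}" for i in range(n)]
    configs = []
    for i in range(n):
        shape = template + latents[i] * axis
        shape = shape + noise_scales[i] * rng.standard_normal((k, 2))
        if scheme is not None and truth.curve_jitter_sd > 0:
            lam = truth.curve_jitter_sd * rng.standard_normal(k)
            shape = shape + lam[:, None] * tangents
        theta = rng.uniform(0.0, 2.0 * np.pi)
        scale = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
        shift = rng.uniform(-1.0, 1.0, size=2)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        configs.append(LandmarkConfiguration(
            specimen_id=ids[i], points=shape @ rot.T * scale + shift))
    return configs


@dataclass
class SyntheticStudy:
    """One complete simulated study plus its generating truth and latents."""

    truth: GroundTruth
    configs: list[LandmarkConfiguration]
    scheme: LandmarkScheme
    specimens: pd.DataFrame
    ratings_sextypicality: RatingMatrix
    ratings_dominance: RatingMatrix
    latents: pd.DataFrame


def simulate_study(truth: GroundTruth, n_per_sex: int,
                   seed: int | None = None) -> SyntheticStudy:
    """Generate a full study: landmarks, covariate table, rating matrices.

    ``n_per_sex`` specimens per sex share one covariate calibration and
    differ in shape by the +-separation/2 offset along the dimorphism axis
    (females negative). Deterministic given the seed (``truth.seed`` unless
    overridden).
    """
    if n_per_sex < 3:
        raise ValueError("n_per_sex must be >= 3")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = 2 * n_per_sex
    sex = np.array(["female"] * n_per_sex + ["male"] * n_per_sex)
    ids = [f"{'F' if s == 'female' else 'M'}{i % n_per_sex:03d}"
           for i, s in enumerate(sex)]

    latents = simulate_path_table(truth, n, rng)
    latents.insert(0, "id", ids)
    latents.insert(1, "sex", sex)

    # shape latents: sex offset plus within-sex variation from the sshd z
    offset = np.where(sex == "male", 0.5, -0.5) * truth.sshd_separation
    shape_latent = offset + truth.sshd_within_sex_sd * latents["sshd"].to_numpy()
    latents["shape_latent"] = shape_latent
    # per-specimen idiosyncratic scale modulated by the dist latent
    dist_z = latents["dist"].to_numpy()
    noise_scales = truth.idiosyncratic_sd * np.clip(1.0 + 0.25 * dist_z,
                                                    0.2, None)
    configs = simulate_landmarks(truth, shape_latent, rng,
                                 noise_scales=noise_scales, specimen_ids=ids)

    # covariate table in measurement units
    age = truth.age_mean + truth.age_sd * latents["age"].to_numpy()
    bmi_v = truth.bmi_mean + truth.bmi_sd * latents["bmi"].to_numpy()
    height = truth.height_mean + truth.height_sd * _z(rng, n, truth.height_sd)
    weight = bmi_v * height ** 2
    if truth.colour_mode == "channels":
        chan_z = latents[["L", "a", "b"]].to_numpy()
    else:
        load = truth.colour_factor_loadings
        unique_sd = np.sqrt(np.clip(1.0 - load ** 2, 0.0, None))
        colour_z = latents["colour"].to_numpy()
        noise = rng.standard_normal((n, 3)) if np.any(unique_sd > 0) \
            else np.zeros((n, 3))
        chan_z = colour_z[:, None] * load[None, :] + noise * unique_sd[None, :]
    lab = truth.lab_means[None, :] + truth.lab_sds[None, :] * chan_z

    fwhr_value = truth.fwhr_mean + truth.fwhr_sd * latents["fwhr"].to_numpy()
    face_h = truth.face_height_px_mean + truth.face_height_px_sd \
        * _z(rng, n, truth.face_height_px_sd)
    face_w = fwhr_value * face_h
    mnoise = truth.measurement_noise_sd
    meas = {name: base + mnoise * _z(rng, n, mnoise)
            for name, base in (("width1", face_w), ("width2", face_w),
                               ("height1", face_h), ("height2", face_h))}

    specimens = pd.DataFrame({
        "id": ids, "sex": sex,
        "age": np.round(age, 2),
        "weight": np.round(weight, 2),
        "height": np.round(height, 3),
        "L": np.round(lab[:, 0], 2),
        "a": np.round(lab[:, 1], 2),
        "b": np.round(lab[:, 2], 2),
        "width1": np.round(meas["width1"], 2),
        "width2": np.round(meas["width2"], 2),
        "height1": np.round(meas["height1"], 2),
        "height2": np.round(meas["height2"], 2),
    })

    def _ratings(latent_col, target_mean, target_sd, prefix):
        lat7 = target_mean + target_sd * latents[latent_col].to_numpy()
        noise = (truth.rater_noise_sd
                 * rng.standard_normal((truth.n_raters, n))
                 if truth.rater_noise_sd > 0
                 else np.zeros((truth.n_raters, n)))
        if truth.rater_bias_sd > 0:   # per-rater main effect (lenient/harsh)
            noise = noise + truth.rater_bias_sd \
                * rng.standard_normal(truth.n_raters)[:, None]
        values = np.clip(np.round(lat7[None, :] + noise), 1, 7)
        return RatingMatrix(values=values,
                            rater_ids=[f"{prefix}R{r:03d}"
                                       for r in range(truth.n_raters)],
                            stimulus_ids=ids)

    ratings_st = _ratings("perceived_sextypicality", truth.sextypicality_mean,
                          truth.sextypicality_sd, "ST_")
    ratings_do = _ratings("perceived_dominance", truth.dominance_mean,
                          truth.dominance_sd, "DO_")

    return SyntheticStudy(
        truth=truth, configs=configs, scheme=default_scheme(),
        specimens=specimens, ratings_sextypicality=ratings_st,
        ratings_dominance=ratings_do, latents=latents,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Persist a study as plain-text files (TPS, CSV, JSON truth record)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": out_dir / "faces.tps",
        "scheme": out_dir / "scheme.txt",
        "specimens": out_dir / "specimens.csv",
        "ratings_sextypicality": out_dir / "ratings_sextypicality.csv",
        "ratings_dominance": out_dir / "ratings_dominance.csv",
        "truth": out_dir / "truth.json",
        "latents": out_dir / "latents.csv",
    }
    write_tps(study.configs, paths["tps"])
    write_scheme(study.scheme, paths["scheme"])
    write_specimen_table(study.specimens, paths["specimens"])
    study.ratings_sextypicality.save(paths["ratings_sextypicality"])
    study.ratings_dominance.save(paths["ratings_dominance"])
    paths["truth"].write_text(json.dumps(study.truth.to_jsonable(), indent=1,
                                         sort_keys=True) + "\n")
    study.latents.to_csv(paths["latents"], index=False)
    return paths
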