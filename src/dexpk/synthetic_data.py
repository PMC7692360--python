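"""Virtual populations and trials with the statistical structure of the pooled analysis.

Emulates five study designs — a target-controlled-infusion adult study
(represented by its published loading + maintenance surrogate), a paediatric
post-cardiac-surgery bolus study, an obese/non-obese adult infusion study, an
adult laparoscopic-surgery infusion study, and a short low-dose adult
infusion study — over the pooled demographic envelope (weight 3.1–152 kg,
postmenstrual age 40.6 weeks to 70.8 years). Between-subject variability is
lognormal per parameter; residual error combines proportional and additive
components with a lognormal subject-level scale effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model_core import (
    CovariateRecord,
    DoseEvent,
    PKParameters,
    ThetaSet,
    individual_parameters,
    predict_ffm,
    concentrations,
)

__all__ = [
    "StudyDesign",
    "OmegaSpec",
    "ResidualSpec",
    "Subject",
    "PopulationDataset",
    "DEFAULT_OMEGA",
    "DEFAULT_RESIDUAL",
    "FIVE_DESIGNS",
    "design_library",
    "sample_population",
    "residual_sd",
    "simulate_trial",
]

#: Pooled demographic envelope, kg.
WEIGHT_ENVELOPE = (3.1, 152.0)

#: Default lower limit of quantification, µg/L.
DEFAULT_LLOQ = 0.005

PK_PARAM_NAMES = ("cl", "v1", "v2", "v3", "q2", "q3")

# Median height (cm) and weight (kg) by age (years) used as the paediatric
# growth reference; linearly interpolated. Values approximate published
# growth-chart medians for boys; girls are offset by 2%.
_GROWTH_AGE = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 12.0, 14.0, 16.0, 18.0])
_GROWTH_HT = np.array([50.0, 61.0, 67.0, 75.0, 87.0, 96.0, 109.0, 122.0, 138.0, 149.0, 163.0, 173.0, 176.0])
_GROWTH_WT = np.array([3.5, 6.0, 7.9, 9.6, 12.2, 14.3, 18.3, 23.0, 32.0, 40.0, 51.0, 61.0, 68.0])


@dataclass(frozen=True)
class StudyDesign:
    """Dosing template, sampling schedule and covariate ranges for one study arm."""

    name: str
    age_range: tuple[float, float]  # years
    sampling_times: tuple[float, ...]  # min after first dose
    age_dist: str = "uniform"  # "uniform" | "loguniform"
    bmi_range: tuple[float, float] | None = None  # adults: weight from BMI x height^2
    weight_range: tuple[float, float] | None = None  # absolute kg bounds
    loading_ug_kg: tuple[float, float] = (0.0, 0.0)  # drawn log-uniform in range
    loading_duration_min: float = 10.0
    maintenance_ug_kg_h: tuple[float, ...] = ()  # randomised arms
    maintenance_duration_min: float = 0.0
    has_ffm_measured: bool = False
    sex_prob_male: float = 0.5

    def __post_init__(self) -> None:
        horizon = self.loading_duration_min + self.maintenance_duration_min
        # samples may extend past the infusion (washout) but not before time 0
        if min(self.sampling_times) <= 0:
            raise ValueError("sampling times must be positive")
        if self.age_range[0] < 0 or self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid age range")

    def build_regimen(self, rng: np.random.Generator, weight_kg: float) -> list[DoseEvent]:
        events: list[DoseEvent] = []
        lo, hi = self.loading_ug_kg
        if hi > 0:
            per_kg = lo if lo == hi else float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            events.append(
                DoseEvent.infusion(0.0, self.loading_duration_min, per_kg * weight_kg)
            )
        if self.maintenance_ug_kg_h:
            arm = self.maintenance_ug_kg_h[rng.integers(len(self.maintenance_ug_kg_h))]
            events.append(
                DoseEvent(
                    start=self.loading_duration_min,
                    duration=self.maintenance_duration_min,
                    rate=arm * weight_kg / 60.0,
                )
            )
        return events


def _sampling(*groups: Sequence[float]) -> tuple[float, ...]:
    out: list[float] = []
    for g in groups:
        out.extend(g)
    return tuple(sorted(set(out)))


#: The five emulated study designs.
FIVE_DESIGNS: dict[str, StudyDesign] = {
    # TCI step study emulated via its published surrogate regimen:
    # 2 µg/kg loading over 10 min, then 1 µg/kg/h for 2 h.
    "hannivoort": StudyDesign(
        name="hannivoort",
        age_range=(18.0, 72.0),
        bmi_range=(18.0, 30.0),
        loading_ug_kg=(2.0, 2.0),
        loading_duration_min=10.0,
        maintenance_ug_kg_h=(1.0,),
        maintenance_duration_min=120.0,
        sampling_times=_sampling([2, 5, 10, 20, 30, 60, 90, 120, 130], [132, 135, 140, 150, 190, 250]),
    ),
    # Paediatric bolus-type study: 1-4 µg/kg over 10 min, sparse-ish sampling.
    "potts": StudyDesign(
        name="potts",
        age_range=(0.02, 16.0),
        age_dist="loguniform",
        loading_ug_kg=(1.0, 4.0),
        loading_duration_min=10.0,
        sampling_times=_sampling([12, 16, 22, 30], [90, 210, 480]),
    ),
    # Obese and non-obese adults: 0.5 µg/kg over 10 min, then 0.25 or 0.5
    # µg/kg/h for 110 min, dense sampling during and after infusion.
    "cortinez": StudyDesign(
        name="cortinez",
        age_range=(18.0, 60.0),
        bmi_range=(18.5, 49.0),
        loading_ug_kg=(0.5, 0.5),
        loading_duration_min=10.0,
        maintenance_ug_kg_h=(0.25, 0.5),
        maintenance_duration_min=110.0,
        has_ffm_measured=True,
        sampling_times=_sampling(
            [2, 5, 10, 15, 20, 30, 45, 60, 90, 120], [122, 125, 130, 140, 150, 180, 240, 360, 480]
        ),
    ),
    # Adults 47-126 kg: 0.5 µg/kg over 10 min then 0.5 µg/kg/h, long washout.
    "rolle": StudyDesign(
        name="rolle",
        age_range=(18.0, 60.0),
        weight_range=(47.0, 126.0),
        loading_ug_kg=(0.5, 0.5),
        loading_duration_min=10.0,
        maintenance_ug_kg_h=(0.5,),
        maintenance_duration_min=170.0,
        has_ffm_measured=True,
        sampling_times=_sampling(
            [5, 10, 20, 30, 45, 60, 90, 120, 150, 180],
            [185, 190, 200, 210, 240, 300, 420, 540, 900],
        ),
    ),
    # Healthy young adults, brief low-dose infusion targeting ~0.3 µg/L.
    "talke": StudyDesign(
        name="talke",
        age_range=(21.0, 36.0),
        weight_range=(52.0, 89.0),
        loading_ug_kg=(0.25, 0.25),
        loading_duration_min=15.0,
        sampling_times=_sampling([1, 2, 3, 4, 5, 7.5, 10, 15], [30, 45, 75]),
    ),
}


def design_library(names: Sequence[str] | None = None) -> list[StudyDesign]:
    """Designs by name; all five when names is None."""
    if names is None:
        return list(FIVE_DESIGNS.values())
    try:
        return [FIVE_DESIGNS[n] for n in names]
    except KeyError as exc:
        raise KeyError(f"unknown design {exc.args[0]!r}; known: {sorted(FIVE_DESIGNS)}") from None


@dataclass(frozen=True)
class OmegaSpec:
    """Diagonal between-subject variance matrix on the log scale.

    ``omega2`` maps parameter name (cl, v1, ...) to variance ω²;
    ``omega2_ruv`` is the variance of the subject-level residual-scale
    effect. Reported magnitude is PPV% = 100·√ω².
    """

    omega2: Mapping[str, float]
    omega2_ruv: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.omega2.items():
            if name not in PK_PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if v < 0:
                raise ValueError("variances must be non-negative")
        if self.omega2_ruv < 0:
            raise ValueError("omega2_ruv must be non-negative")

    def ppv_percent(self) -> dict[str, float]:
        return {k: 100.0 * float(np.sqrt(v)) for k, v in self.omega2.items()}


@dataclass(frozen=True)
class ResidualSpec:
    """Combined proportional + additive residual error.

    SD(pred) = sqrt(pred²·cv² + sd²) · exp(η_ruv); cv is a fraction,
    sd is µg/L.
    """

    theta_ruv_cv: float = 0.19
    theta_ruv_sd: float = 0.004

    def __post_init__(self) -> None:
        if self.theta_ruv_cv < 0 or self.theta_ruv_sd < 0:
            raise ValueError("residual components must be non-negative")

    @property
    def is_noise_free(self) -> bool:
        # permitted for degenerate simulations; estimation requires noise
        return self.theta_ruv_cv == 0 and self.theta_ruv_sd == 0


#: Final-model between-subject variability (PPV%: CL 35.8, V1 103.9, V2 41.8,
#: V3 61.6, Q2 63.2, Q3 89.7; residual-scale effect 32%).
DEFAULT_OMEGA = OmegaSpec(
    omega2={
        "cl": 0.358**2,
        "v1": 1.039**2,
        "v2": 0.418**2,
        "v3": 0.616**2,
        "q2": 0.632**2,
        "q3": 0.897**2,
    },
    omega2_ruv=0.32**2,
)

#: Final-model residual error: 19% proportional, 0.004 µg/L additive.
DEFAULT_RESIDUAL = ResidualSpec(theta_ruv_cv=0.19, theta_ruv_sd=0.004)


@dataclass
class Subject:
    """One simulated (or loaded) subject."""

    id: int
    covariates: CovariateRecord
    events: list[DoseEvent]
    obs_times: np.ndarray  # min
    dv: np.ndarray  # observed concentration, µg/L
    study: str
    true_params: PKParameters | None = None
    true_eta: dict[str, float] | None = None
    true_eta_ruv: float | None = None


@dataclass
class PopulationDataset:
    """Subjects with dose events, observations and covariates."""

    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return int(sum(len(s.dv) for s in self.subjects))

    def by_study(self) -> dict[str, list[Subject]]:
        out: dict[str, list[Subject]] = {}
        for s in self.subjects:
            out.setdefault(s.study, []).append(s)
        return out


# ---------------------------------------------------------------------------
# Covariate sampling
# ---------------------------------------------------------------------------

def _reference_height(age: float, sex: str) -> float:
    h = float(np.interp(age, _GROWTH_AGE, _GROWTH_HT))
    if age >= 18.0:
        h = 176.0 if sex == "male" else 163.0
    elif sex == "female":
        h *= 0.98
    return h


def _draw_covariates(design: StudyDesign, rng: np.random.Generator) -> CovariateRecord:
    lo, hi = design.age_range
    if design.age_dist == "loguniform":
        age = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        age = float(rng.uniform(lo, hi))
    sex = "male" if rng.random() < design.sex_prob_male else "female"
    height = _reference_height(age, sex) * float(rng.uniform(0.95, 1.05))

    if design.bmi_range is not None:
        bmi = float(np.exp(rng.uniform(*np.log(design.bmi_range))))
        weight = bmi * (height / 100.0) ** 2
    elif design.weight_range is not None:
        weight = float(np.exp(rng.uniform(*np.log(design.weight_range))))
    else:
        ref = float(np.interp(age, _GROWTH_AGE, _GROWTH_WT))
        weight = ref * float(np.exp(rng.uniform(np.log(0.75), np.log(1.35))))
    weight = float(np.clip(weight, *WEIGHT_ENVELOPE))

    pma = age * 52.18 + 40.0
    ffm_measured = None
    if design.has_ffm_measured:
        # DXA measurement emulated as the predictive equation plus 5% noise
        ffm = predict_ffm(sex, age, weight, height) * float(np.exp(rng.normal(0.0, 0.05)))
        ffm_measured = min(ffm, 0.99 * weight)
    return CovariateRecord(
        age=age, weight_tbw=weight, height=height, sex=sex, pma=pma, ffm_measured=ffm_measured
    )


def sample_population(
    n: int,
    designs: Sequence[StudyDesign],
    seed: int | np.random.Generator,
) -> list[tuple[CovariateRecord, StudyDesign]]:
    """Draw n subjects' covariates, cycling through the given designs.

    Weight is drawn log-uniform within the design's range (or derived from a
    log-uniform BMI for adult BMI-defined designs, or from a growth reference
    for children), height from an age–height reference curve ±5%, and sex
    Bernoulli(0.5). Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not designs:
        raise ValueError("at least one design is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n):
        design = designs[i % len(designs)]
        out.append((_draw_covariates(design, rng), design))
    return out


# ---------------------------------------------------------------------------
# Residual error and trial simulation
# ---------------------------------------------------------------------------

def residual_sd(
    pred_conc: float | np.ndarray, spec: ResidualSpec, eta_ruv: float = 0.0
) -> float | np.ndarray:
    """Residual SD at a predicted concentration: sqrt(pred²cv² + sd²)·e^η."""
    pred = np.asarray(pred_conc, dtype=float)
    if np.any(pred < 0):
        raise ValueError("pred_conc must be non-negative")
    out = np.sqrt(pred**2 * spec.theta_ruv_cv**2 + spec.theta_ruv_sd**2) * np.exp(eta_ruv)
    return float(out) if np.isscalar(pred_conc) else out


def simulate_trial(
    theta: ThetaSet,
    omega_spec: OmegaSpec,
    residual_spec: ResidualSpec,
    designs: Sequence[StudyDesign],
    n: int,
    seed: int | np.random.Generator,
    lloq: float = DEFAULT_LLOQ,
) -> PopulationDataset:
    """Simulate a full trial: covariates, lognormal BSV, kinetics, residual noise.

    Per subject, η ~ Normal(0, ω²) multiplies each typical parameter through
    exp(η); the individual profile is sampled at the design's schedule and
    observation noise Y = pred + SD·ε is added with ε ~ Normal(0, 1).
    Draws below the quantification floor are redrawn (rejection) so the
    returned dataset contains no censored records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    population = sample_population(n, designs, rng)
    subjects: list[Subject] = []
    re_names = [k for k in PK_PARAM_NAMES if omega_spec.omega2.get(k, 0.0) > 0]
    for sid, (cov, design) in enumerate(population, start=1):
        typ = individual_parameters(theta, cov)
        eta = {k: float(rng.normal(0.0, np.sqrt(omega_spec.omega2[k]))) for k in re_names}
        params = typ.with_eta(eta)
        eta_ruv = (
            float(rng.normal(0.0, np.sqrt(omega_spec.omega2_ruv)))
            if omega_spec.omega2_ruv > 0
            else 0.0
        )
        events = design.build_regimen(rng, cov.weight_tbw)
        times = np.asarray(design.sampling_times, dtype=float)
        pred = concentrations(params, events, times)
        if residual_spec.is_noise_free:
            dv = pred.copy()
        else:
            sd = residual_sd(pred, residual_spec, eta_ruv)
            dv = pred + sd * rng.standard_normal(len(times))
            # rejection sampling keeps every record above the quantification floor
            for _ in range(100):
                low = dv < lloq
                if not low.any():
                    break
                dv[low] = pred[low] + sd[low] * rng.standard_normal(int(low.sum()))
            dv = np.maximum(dv, lloq)
        subjects.append(
            Subject(
                id=sid,
                covariates=cov,
                events=events,
                obs_times=times,
                dv=dv,
                study=design.name,
                true_params=params,
                true_eta=eta,
                true_eta_ruv=eta_ruv,
            )
        )
    return PopulationDataset(subjects=subjects)
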