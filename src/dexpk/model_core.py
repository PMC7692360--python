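"""Deterministic kinetics and covariate model for dexmedetomidine.

Maps demographics and population typical values to individual pharmacokinetic
parameters (allometric size scaling on normal fat mass, sigmoid clearance
maturation in postmenstrual age) and simulates three-compartment
concentration-time profiles under arbitrary piecewise-constant infusion
regimens via eigendecomposition of the linear rate matrix.

Internal units are fixed: time min, volume L, clearance L/min, amount µg,
concentration µg/L (equivalent to ng/mL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ThetaSet",
    "CovariateRecord",
    "DerivedSize",
    "PKParameters",
    "DoseEvent",
    "SimulatedProfile",
    "DEFAULT_THETA",
    "STD_WEIGHT_KG",
    "STD_FFM_KG",
    "fsize",
    "maturation_fraction",
    "predict_ffm",
    "normal_fat_mass",
    "derive_size",
    "individual_parameters",
    "impute_pma",
    "simulate_profile",
    "concentrations",
    "concentrations_batch",
    "compile_regimen",
]

# Standardisation constants: the reference subject is a 70 kg, 1.76 m adult
# male with a predicted fat-free mass of 56.1 kg.
STD_WEIGHT_KG = 70.0
STD_FFM_KG = 56.1
ALLOMETRIC_EXP_CL = 0.75
ALLOMETRIC_EXP_V = 1.0
WEEKS_PER_YEAR = 52.18
TERM_PMA_WEEKS = 40.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThetaSet:
    """Population typical values standardised to the 70 kg reference subject.

    Clearances are L/min per standard subject, volumes L per standard
    subject. ``tm50`` (weeks) and ``hill`` parameterise the sigmoid
    maturation of elimination clearance; ``ffat_v``/``ffat_cl`` are the
    fractions of fat mass contributing to the size descriptor of volumes
    and clearances respectively.
    """

    cl_std: float
    v1_std: float
    v2_std: float
    v3_std: float
    q2_std: float
    q3_std: float
    tm50: float
    hill: float = 1.0
    ffat_v: float = 0.0
    ffat_cl: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl_std", "v1_std", "v2_std", "v3_std", "q2_std", "q3_std"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tm50 <= 0 or self.hill <= 0:
            raise ValueError("tm50 and hill must be positive")
        for name in ("ffat_v", "ffat_cl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.5:
                raise ValueError(f"{name} must lie in [0, 1.5]")

    def replace(self, **kwargs) -> "ThetaSet":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


#: Final universal-model estimates (clearances L/min/70 kg, volumes L/70 kg,
#: TM50 weeks; Hill and FfatCL fixed).
DEFAULT_THETA = ThetaSet(
    cl_std=0.897,
    v1_std=25.2,
    v2_std=34.4,
    v3_std=65.4,
    q2_std=1.68,
    q3_std=0.62,
    tm50=52.4,
    hill=1.0,
    ffat_v=0.293,
    ffat_cl=0.0,
)


@dataclass(frozen=True)
class CovariateRecord:
    """Raw demographics for one subject."""

    age: float  # years
    weight_tbw: float  # kg
    height: float  # cm
    sex: str  # "male" | "female"
    pma: float | None = None  # postmenstrual age, weeks
    ffm_measured: float | None = None  # kg, e.g. from DXA

    def __post_init__(self) -> None:
        if self.weight_tbw <= 0:
            raise ValueError("weight_tbw must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.pma is not None and self.pma < 22:
            raise ValueError("pma must be >= 22 weeks when present")


@dataclass(frozen=True)
class DerivedSize:
    """Computed body-composition and maturation quantities for one subject."""

    bmi: float  # kg/m^2
    ffm: float  # kg
    fat: float  # kg
    nfm_cl: float  # kg
    nfm_v: float  # kg
    fsize_cl: float
    fsize_v: float
    mf: float  # maturation fraction in [0, 1)


@dataclass(frozen=True)
class PKParameters:
    """Individual three-compartment parameters (L, L/min)."""

    cl: float
    v1: float
    v2: float
    v3: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "v2", "v3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("q2", "q3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_eta(self, eta: Mapping[str, float]) -> "PKParameters":
        """Apply exponential (lognormal) random effects, P_i = P_tv * exp(eta)."""
        vals = {k: getattr(self, k) for k in ("cl", "v1", "v2", "v3", "q2", "q3")}
        for key, e in eta.items():
            if key not in vals:
                raise KeyError(f"unknown parameter {key!r}")
            vals[key] = vals[key] * float(np.exp(e))
        return PKParameters(**vals)


@dataclass(frozen=True)
class DoseEvent:
    """One dosing event: a zero-duration bolus or a constant-rate infusion.

    For infusions ``rate`` is µg/min; for boluses (duration 0) ``rate``
    carries the bolus amount in µg.
    """

    start: float  # min
    duration: float  # min; 0 = bolus
    rate: float  # µg/min, or amount µg when duration == 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration < 0 or self.rate < 0:
            raise ValueError("start, duration and rate must be non-negative")

    @classmethod
    def bolus(cls, start: float, amount_ug: float) -> "DoseEvent":
        return cls(start=start, duration=0.0, rate=amount_ug)

    @classmethod
    def infusion(cls, start: float, duration: float, amount_ug: float) -> "DoseEvent":
        if duration <= 0:
            raise ValueError("infusion duration must be positive")
        return cls(start=start, duration=duration, rate=amount_ug / duration)

    @property
    def amount(self) -> float:
        """Total drug delivered by this event, µg."""
        return self.rate if self.duration == 0 else self.rate * self.duration


@dataclass(frozen=True)
class SimulatedProfile:
    """Concentration-time course with per-compartment amounts and mass audit."""

    times: np.ndarray  # min
    central_conc: np.ndarray  # µg/L
    amounts: np.ndarray  # (n, 3) µg
    eliminated: np.ndarray  # cumulative µg cleared from central
    dosed: np.ndarray  # cumulative µg administered

    def mass_balance_error(self) -> float:
        """Max relative violation of dosed - eliminated = sum(amounts)."""
        lhs = self.dosed - self.eliminated
        rhs = self.amounts.sum(axis=1)
        scale = np.maximum(self.dosed, 1e-300)
        return float(np.max(np.abs(lhs - rhs) / scale, initial=0.0))


# ---------------------------------------------------------------------------
# Covariate operations
# ---------------------------------------------------------------------------

def fsize(size_kg: float, std_kg: float, exponent: float) -> float:
    """Allometric fractional size, (size/std)^exponent.

    Exponent 3/4 for functional processes (clearances), 1 for volumes.
    """
    if size_kg <= 0 or std_kg <= 0:
        raise ValueError("size and standard size must be positive")
    return (size_kg / std_kg) ** exponent


def maturation_fraction(pma_weeks: float, tm50: float, hill: float) -> float:
    """Sigmoid maturation of clearance with postmenstrual age.

    MF = PMA^Hill / (TM50^Hill + PMA^Hill); equals 1/2 at PMA = TM50 and
    approaches 1 asymptotically.
    """
    if np.any(np.asarray(pma_weeks) <= 0):
        raise ValueError("pma_weeks must be positive")
    if tm50 <= 0 or hill <= 0:
        raise ValueError("tm50 and hill must be positive")
    # log-domain ratio keeps large PMA^Hill from overflowing
    r = np.exp(hill * (np.log(tm50) - np.log(pma_weeks)))
    out = 1.0 / (1.0 + r)
    return float(out) if np.isscalar(pma_weeks) else out


def _janmahasatian_ffm(sex: str, weight_kg: float, bmi: float) -> float:
    if sex == "male":
        return 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)
    return 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)


def predict_ffm(sex: str, age_years: float, weight_kg: float, height_cm: float) -> float:
    """Predict fat-free mass (kg) from sex, age, weight and height.

    Children (< 18 y) use the Al-Sallami equations: an age- and sex-dependent
    prefactor multiplying the Janmahasatian adult form. The male prefactor is
    0.88 + 0.12/(1 + (age/13.4)^-12.7); the female prefactor is
    1.11 - 0.11/(1 + (age/7.1)^-1.1). Adults use the Janmahasatian form
    directly (the prefactors tend to 1 with age).
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    if age_years < 0:
        raise ValueError("age must be non-negative")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    adult = _janmahasatian_ffm(sex, weight_kg, bmi)
    if age_years >= 18.0:
        ffm = adult
    elif sex == "male":
        # age -> 0 limit: (age/13.4)^-12.7 -> inf, prefactor -> 0.88
        pre = 0.88 + (1.0 - 0.88) / (1.0 + (age_years / 13.4) ** -12.7) if age_years > 0 else 0.88
        ffm = pre * adult
    else:
        pre = 1.11 + (1.0 - 1.11) / (1.0 + (age_years / 7.1) ** -1.1) if age_years > 0 else 1.11
        ffm = pre * adult
    if ffm > weight_kg * 1.05:
        warnings.warn(
            f"predicted FFM {ffm:.1f} kg exceeds body weight {weight_kg:.1f} kg by >5%",
            stacklevel=2,
        )
    return ffm


def normal_fat_mass(ffm_kg: float, tbw_kg: float, ffat: float) -> float:
    """NFM = FFM + Ffat * (TBW - FFM): fat-free mass plus a fraction of fat."""
    if ffat < 0:
        raise ValueError("ffat must be non-negative")
    if ffm_kg <= 0:
        raise ValueError("ffm must be positive")
    fat = tbw_kg - ffm_kg
    return ffm_kg + ffat * fat


def impute_pma(age_years: float) -> float:
    """Postmenstrual age assuming birth at term: age*52.18 + 40 weeks."""
    return age_years * WEEKS_PER_YEAR + TERM_PMA_WEEKS


def _subject_ffm(cov: CovariateRecord) -> float:
    if cov.ffm_measured is not None:
        if cov.ffm_measured <= 0:
            raise ValueError("measured FFM must be positive")
        return cov.ffm_measured
    return predict_ffm(cov.sex, cov.age, cov.weight_tbw, cov.height)


def derive_size(theta: ThetaSet, cov: CovariateRecord) -> DerivedSize:
    """Compute BMI, FFM/FAT/NFM, allometric size fractions and maturation.

    The standard NFM is recomputed per parameter class from the reference
    subject (FFM 56.1 kg, TBW 70 kg) with that class's Ffat, so that the
    reference subject maps exactly to the population typical values.
    """
    bmi = cov.weight_tbw / (cov.height / 100.0) ** 2
    ffm = _subject_ffm(cov)
    fat = cov.weight_tbw - ffm
    if fat < 0:
        warnings.warn(
            f"FFM {ffm:.1f} kg exceeds TBW {cov.weight_tbw:.1f} kg; fat mass clamped to 0",
            stacklevel=2,
        )
        fat = 0.0
    nfm_cl = ffm + theta.ffat_cl * fat
    nfm_v = ffm + theta.ffat_v * fat
    std_fat = STD_WEIGHT_KG - STD_FFM_KG
    nfm_std_cl = STD_FFM_KG + theta.ffat_cl * std_fat
    nfm_std_v = STD_FFM_KG + theta.ffat_v * std_fat
    pma = cov.pma if cov.pma is not None else impute_pma(cov.age)
    return DerivedSize(
        bmi=bmi,
        ffm=ffm,
        fat=fat,
        nfm_cl=nfm_cl,
        nfm_v=nfm_v,
        fsize_cl=fsize(nfm_cl, nfm_std_cl, ALLOMETRIC_EXP_CL),
        fsize_v=fsize(nfm_v, nfm_std_v, ALLOMETRIC_EXP_V),
        mf=maturation_fraction(pma, theta.tm50, theta.hill),
    )


def individual_parameters(theta: ThetaSet, cov: CovariateRecord) -> PKParameters:
    """Typical individual parameters for given demographics.

    Elimination clearance scales allometrically (exponent 3/4) on its NFM and
    is multiplied by the maturation fraction; intercompartmental clearances
    scale allometrically but are not subject to maturation; volumes scale
    linearly on the volume-class NFM.
    """
    ds = derive_size(theta, cov)
    return PKParameters(
        cl=theta.cl_std * ds.fsize_cl * ds.mf,
        q2=theta.q2_std * ds.fsize_cl,
        q3=theta.q3_std * ds.fsize_cl,
        v1=theta.v1_std * ds.fsize_v,
        v2=theta.v2_std * ds.fsize_v,
        v3=theta.v3_std * ds.fsize_v,
    )


# ---------------------------------------------------------------------------
# Three-compartment kinetics
# ---------------------------------------------------------------------------

class CompiledRegimen(NamedTuple):
    """Piecewise-constant input compiled from dose events.

    ``knots`` are segment boundaries (min, starting at 0); ``rates`` the
    central-compartment input rate (µg/min) in each of the len(knots) segments
    (the last extends to infinity); ``bolus_times``/``bolus_amounts`` are
    instantaneous central additions applied at the start of the matching knot.
    """

    knots: np.ndarray
    rates: np.ndarray
    bolus_times: np.ndarray
    bolus_amounts: np.ndarray


def compile_regimen(events: Iterable[DoseEvent]) -> CompiledRegimen:
    """Merge overlapping dose events into a piecewise-constant rate function."""
    events = list(events)
    cuts = {0.0}
    boluses: dict[float, float] = {}
    for ev in events:
        cuts.add(ev.start)
        if ev.duration > 0:
            cuts.add(ev.start + ev.duration)
        else:
            boluses[ev.start] = boluses.get(ev.start, 0.0) + ev.rate
    knots = np.array(sorted(cuts))
    rates = np.zeros(len(knots))
    for ev in events:
        if ev.duration > 0:
            on = (knots >= ev.start) & (knots < ev.start + ev.duration)
            rates[on] += ev.rate
    bt = np.array(sorted(boluses))
    ba = np.array([boluses[t] for t in bt])
    return CompiledRegimen(knots=knots, rates=rates, bolus_times=bt, bolus_amounts=ba)


def _rate_matrix(p: PKParameters) -> tuple[np.ndarray, float]:
    k10 = p.cl / p.v1
    k12 = p.q2 / p.v1
    k21 = p.q2 / p.v2
    k13 = p.q3 / p.v1
    k31 = p.q3 / p.v3
    a = np.array(
        [
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ]
    )
    return a, k10


def _phi(lam: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """(exp(lam*tau)-1)/lam with the lam->0 limit tau."""
    x = np.multiply.outer(tau, lam)
    lam_safe = np.where(lam == 0.0, 1.0, lam)
    tau_b = np.broadcast_to(np.expand_dims(np.asarray(tau, dtype=float), -1), x.shape)
    return np.where(lam == 0.0, tau_b, np.expm1(x) / lam_safe)


def _psi(lam: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """(exp(lam*tau)-1-lam*tau)/lam^2 with the lam->0 limit tau^2/2."""
    x = np.multiply.outer(tau, lam)
    small = np.abs(x) < 1e-8
    lam_safe = np.where(lam == 0.0, 1.0, lam)
    exact = (np.expm1(np.where(small, 0.0, x)) - x) / lam_safe**2
    tau2 = np.expand_dims(np.asarray(tau) ** 2, -1) / 2.0
    series = tau2 * (1.0 + x / 3.0)  # leading terms of the expansion
    return np.where(small | (lam == 0.0), series, exact)


class _Kinetics:
    """Eigensystem of the rate matrix, reused across segment propagations."""

    def __init__(self, p: PKParameters):
        a, self.k10 = _rate_matrix(p)
        lam, vec = np.linalg.eig(a)
        if np.max(np.abs(lam.imag)) > 1e-9 * max(np.max(np.abs(lam.real)), 1e-30):
            raise ValueError("rate matrix has complex eigenvalues; invalid parameters")
        self.lam = lam.real
        self.vec = vec.real
        self.vinv = np.linalg.inv(self.vec)
        self.v1 = p.v1

    def propagate(
        self, a0: np.ndarray, rate: float, taus: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Amounts (m,3) and central-amount integrals (m,) at local times taus."""
        z0 = self.vinv @ a0
        beta = self.vinv[:, 0] * rate
        ph = _phi(self.lam, taus)
        ps = _psi(self.lam, taus)
        z = z0 * np.exp(np.multiply.outer(taus, self.lam)) + beta * ph
        iz = z0 * ph + beta * ps
        amounts = z @ self.vec.T
        int_central = iz @ self.vec.T[:, 0]
        return amounts, int_central


def _simulate(
    kin: _Kinetics, creg: CompiledRegimen, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Amounts, cumulative eliminated and cumulative dosed at sorted times."""
    n = len(times)
    amounts = np.zeros((n, 3))
    eliminated = np.zeros(n)
    dosed = np.zeros(n)

    a = np.zeros(3)
    elim = 0.0
    dose_in = 0.0
    t0 = 0.0
    knots = creg.knots
    bolus_idx = {t: amt for t, amt in zip(creg.bolus_times, creg.bolus_amounts)}
    horizon = max(times[-1] if n else 0.0, knots[-1]) + 1.0
    bounds = np.append(knots, horizon)

    for seg in range(len(knots)):
        t_start, t_end = bounds[seg], bounds[seg + 1]
        if t_start in bolus_idx:
            a[0] += bolus_idx[t_start]
            dose_in += bolus_idx[t_start]
        rate = creg.rates[seg]
        mask = (times >= t_start) & (times < t_end) if seg < len(knots) - 1 else times >= t_start
        if mask.any():
            taus = times[mask] - t_start
            amts, ic = kin.propagate(a, rate, taus)
            amounts[mask] = amts
            eliminated[mask] = elim + kin.k10 * ic
            dosed[mask] = dose_in + rate * taus
        if t_end <= horizon and seg < len(knots) - 1:
            dt = np.array([t_end - t_start])
            amts, ic = kin.propagate(a, rate, dt)
            a = amts[0]
            elim += kin.k10 * ic[0]
            dose_in += rate * (t_end - t_start)
        t0 = t_end
    return amounts, eliminated, dosed


def simulate_profile(
    params: PKParameters,
    regimen: Sequence[DoseEvent] | CompiledRegimen,
    times: Sequence[float] | np.ndarray,
) -> SimulatedProfile:
    """Simulate the three-compartment model under a piecewise-constant regimen.

    Solves the linear mammillary system (central elimination CL/V1, exchange
    clearances Q2, Q3) exactly on each constant-rate segment using the
    eigendecomposition of the rate matrix. Central concentration is the
    central amount divided by V1. Cumulative elimination is integrated
    analytically so mass balance is an independent audit, not an identity.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if len(times) and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("times must be sorted and non-negative")
    creg = regimen if isinstance(regimen, CompiledRegimen) else compile_regimen(regimen)
    kin = _Kinetics(params)
    amounts, eliminated, dosed = _simulate(kin, creg, times)
    conc = np.maximum(amounts[:, 0], 0.0) / params.v1
    return SimulatedProfile(
        times=times, central_conc=conc, amounts=amounts, eliminated=eliminated, dosed=dosed
    )


def concentrations(
    params: PKParameters,
    regimen: Sequence[DoseEvent] | CompiledRegimen,
    times: np.ndarray,
) -> np.ndarray:
    """Central concentrations only — fast path used by estimation."""
    creg = regimen if isinstance(regimen, CompiledRegimen) else compile_regimen(regimen)
    kin = _Kinetics(params)
    amounts, _, _ = _simulate(kin, creg, np.asarray(times, dtype=float))
    return np.maximum(amounts[:, 0], 0.0) / params.v1


def concentrations_batch(param_mat: np.ndarray, creg: CompiledRegimen, times: np.ndarray) -> np.ndarray:
    """Central concentrations for many parameter sets sharing one regimen.

    ``param_mat`` has shape (k, 6) with columns (cl, v1, v2, v3, q2, q3);
    returns shape (k, len(times)). The eigendecomposition and segment
    propagation are vectorised over the k parameter sets, which is what makes
    finite-difference Jacobians in the mixed-effects estimator affordable.
    """
    pm = np.asarray(param_mat, dtype=float)
    if pm.ndim != 2 or pm.shape[1] != 6:
        raise ValueError("param_mat must have shape (k, 6)")
    if np.any(pm[:, :4] <= 0) or np.any(pm[:, 4:] < 0):
        raise ValueError("cl, v1..v3 must be positive; q2, q3 non-negative")
    cl, v1, v2, v3, q2, q3 = pm.T
    k = pm.shape[0]
    k10 = cl / v1
    a = np.zeros((k, 3, 3))
    a[:, 0, 0] = -(k10 + q2 / v1 + q3 / v1)
    a[:, 0, 1] = q2 / v2
    a[:, 0, 2] = q3 / v3
    a[:, 1, 0] = q2 / v1
    a[:, 1, 1] = -q2 / v2
    a[:, 2, 0] = q3 / v1
    a[:, 2, 2] = -q3 / v3
    lam, vec = np.linalg.eig(a)
    lam = lam.real
    vec = vec.real
    vinv = np.linalg.inv(vec)

    times = np.asarray(times, dtype=float)
    n = len(times)
    central = np.zeros((k, n))
    state = np.zeros((k, 3))
    knots = creg.knots
    bolus_idx = {t: amt for t, amt in zip(creg.bolus_times, creg.bolus_amounts)}
    horizon = max(times[-1] if n else 0.0, knots[-1]) + 1.0
    bounds = np.append(knots, horizon)

    def _prop(a0: np.ndarray, rate: float, taus: np.ndarray) -> np.ndarray:
        # z(tau) = z0*exp(lam*tau) + beta*phi; amounts = V z
        z0 = np.einsum("kij,kj->ki", vinv, a0)
        beta = vinv[:, :, 0] * rate
        x = taus[None, :, None] * lam[:, None, :]
        lam_safe = np.where(lam == 0.0, 1.0, lam)[:, None, :]
        ph = np.where(lam[:, None, :] == 0.0, taus[None, :, None], np.expm1(x) / lam_safe)
        z = z0[:, None, :] * np.exp(x) + beta[:, None, :] * ph
        return np.einsum("kmc,kic->kmi", z, vec)

    for seg in range(len(knots)):
        t_start, t_end = bounds[seg], bounds[seg + 1]
        if t_start in bolus_idx:
            state[:, 0] += bolus_idx[t_start]
        rate = creg.rates[seg]
        mask = (times >= t_start) & (times < t_end) if seg < len(knots) - 1 else times >= t_start
        if mask.any():
            amts = _prop(state, rate, times[mask] - t_start)
            central[:, mask] = amts[:, :, 0]
        if seg < len(knots) - 1:
            state = _prop(state, rate, np.array([t_end - t_start]))[:, 0, :]
    return np.maximum(central, 0.0) / v1[:, None]
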