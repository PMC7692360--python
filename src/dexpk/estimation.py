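"""Nonlinear mixed-effects estimation for the population model.

The marginal likelihood of each subject's data is approximated by a Laplace
expansion at the conditional mode of the subject's random effects, with the
residual standard deviation evaluated at the conditional prediction (the
first-order-conditional-with-interaction analogue). The conditional mode is
found by a penalised Gauss-Newton search whose Jacobians come from
finite differences of the batched kinetics kernel, and the curvature term
uses the Gauss-Newton Hessian J'WJ + Omega^-1.

Population parameters (typical values, log-scale variances, residual
components) are optimised on the log scale. Model comparison uses the
likelihood-ratio chi-square criterion; uncertainty comes from the numerical
Hessian and/or a stratified nonparametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace


import numpy as np
from scipy import optimize, stats

from ._kernels import population_m2ll
from .model_core import (
    CompiledRegimen,
    ThetaSet,
    compile_regimen,
    impute_pma,
)
from .synthetic_data import (
    OmegaSpec,
    PopulationDataset,
    ResidualSpec,
    Subject,
    PK_PARAM_NAMES,
)
from .model_core import predict_ffm, STD_FFM_KG, STD_WEIGHT_KG

__all__ = [
    "FitConfig",
    "FitResult",
    "BootstrapResult",
    "LrtDecision",
    "VarianceDecomposition",
    "objective",
    "fit",
    "lrt",
    "shrinkage",
    "bootstrap",
    "variance_decomposition",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: ThetaSet fields that may be estimated.
ESTIMABLE_THETA = ("cl_std", "v1_std", "v2_std", "v3_std", "q2_std", "q3_std", "tm50", "ffat_v")


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    ``theta_names`` lists the ThetaSet fields to estimate (all on the log
    scale); random effects are taken from the keys of the initial OmegaSpec.
    Convergence to "3 significant digits" is operationalised as a relative
    parameter change below ``xtol_rel`` together with an objective change
    below ``ftol_abs`` over the final iteration.
    """

    theta_names: tuple[str, ...] = ("cl_std", "v1_std", "v2_std", "v3_std", "q2_std", "q3_std", "tm50")
    estimate_omega: bool = True
    estimate_residual_cv: bool = True
    compute_ci: bool = True
    xtol_rel: float = 1e-3
    ftol_abs: float = 0.01
    maxiter: int = 200
    inner_tol: float = 1e-7
    inner_maxiter: int = 40
    fd_step: float = 1e-5  # outer finite-difference step on the log scale
    gtol: float = 1e-5  # projected-gradient stop for the outer optimiser

    def __post_init__(self) -> None:
        for name in self.theta_names:
            if name not in ESTIMABLE_THETA:
                raise ValueError(f"cannot estimate {name!r}")


@dataclass
class FitResult:
    """Optimum of the approximate marginal likelihood."""

    obj: float  # -2 log likelihood
    theta: ThetaSet
    omega: OmegaSpec
    residual: ResidualSpec
    theta_se: dict[str, float] = field(default_factory=dict)
    theta_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    omega_ppv: dict[str, float] = field(default_factory=dict)
    ebes: dict[str, np.ndarray] = field(default_factory=dict)
    shrinkage_pct: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    precision: float = float("nan")  # max |projected gradient| at the optimum
    n_evaluations: int = 0
    message: str = ""


@dataclass
class LrtDecision:
    """Likelihood-ratio comparison of nested models."""

    delta_obj: float
    df: int
    threshold: float
    significant: bool


@dataclass
class VarianceDecomposition:
    """Split of total parameter variance into covariate-predicted and random parts.

    ``ppvt2`` is the total log-scale variance without covariates, ``bsvr2``
    the random variance remaining once covariates are modelled; their
    difference is the covariate-predictable part and ``ratio`` its share of
    the total.
    """

    ppvt2: float
    bsvr2: float
    bsvp2: float
    ratio: float


@dataclass
class BootstrapResult:
    """Stratified nonparametric bootstrap summary."""

    medians: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_requested: int
    n_converged: int
    estimates: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return self.n_requested - self.n_converged


# ---------------------------------------------------------------------------
# Subject preprocessing and the Laplace (FOCE-I analogue) objective
# ---------------------------------------------------------------------------

class _ObjectiveEngine:
    """Objective over a fixed dataset, evaluated by the compiled kernel.

    Dose regimens, observations and the theta-independent covariate pieces
    (FFM, fat mass, PMA) are flattened once into offset-indexed arrays; each
    evaluation rebuilds the subjects' typical parameter matrix and makes a
    single compiled call.
    """

    def __init__(
        self,
        dataset: PopulationDataset,
        config: FitConfig,
        re_names: tuple[str, ...],
    ):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.config = config
        self.re_names = re_names
        self.re_idx = np.array([PK_PARAM_NAMES.index(n) for n in re_names], dtype=np.int64)
        n = len(dataset)

        ffm, fat, pma = np.empty(n), np.empty(n), np.empty(n)
        y_parts, t_parts, knot_parts, rate_parts, bt_parts, ba_parts = [], [], [], [], [], []
        obs_off = [0]
        seg_off = [0]
        bolus_off = [0]
        for i, s in enumerate(dataset.subjects):
            cov = s.covariates
            f = cov.ffm_measured
            if f is None:
                f = predict_ffm(cov.sex, cov.age, cov.weight_tbw, cov.height)
            ffm[i] = f
            fat[i] = max(cov.weight_tbw - f, 0.0)
            pma[i] = cov.pma if cov.pma is not None else impute_pma(cov.age)
            creg: CompiledRegimen = compile_regimen(s.events)
            y_parts.append(np.asarray(s.dv, dtype=float))
            t_parts.append(np.asarray(s.obs_times, dtype=float))
            knot_parts.append(creg.knots)
            rate_parts.append(creg.rates)
            bt_parts.append(creg.bolus_times)
            ba_parts.append(creg.bolus_amounts)
            obs_off.append(obs_off[-1] + len(s.dv))
            seg_off.append(seg_off[-1] + len(creg.knots))
            bolus_off.append(bolus_off[-1] + len(creg.bolus_times))
        self.ffm, self.fat, self.pma = ffm, fat, pma
        self.y_flat = np.concatenate(y_parts)
        self.times_flat = np.concatenate(t_parts)
        self.obs_off = np.asarray(obs_off, dtype=np.int64)
        self.knots_flat = np.concatenate(knot_parts)
        self.rates_flat = np.concatenate(rate_parts)
        self.seg_off = np.asarray(seg_off, dtype=np.int64)
        self.bolus_t_flat = (
            np.concatenate(bt_parts) if any(len(b) for b in bt_parts) else np.empty(0)
        )
        self.bolus_a_flat = (
            np.concatenate(ba_parts) if any(len(b) for b in ba_parts) else np.empty(0)
        )
        self.bolus_off = np.asarray(bolus_off, dtype=np.int64)
        self.etas = np.zeros((n, max(len(re_names), 1)))
        self.n_subjects = n

    def typical_matrix(self, theta: ThetaSet) -> np.ndarray:
        """Per-subject typical (cl, v1, v2, v3, q2, q3) under theta."""
        std_fat = STD_WEIGHT_KG - STD_FFM_KG
        nfm_cl = self.ffm + theta.ffat_cl * self.fat
        nfm_v = self.ffm + theta.ffat_v * self.fat
        fs_cl = (nfm_cl / (STD_FFM_KG + theta.ffat_cl * std_fat)) ** 0.75
        fs_v = nfm_v / (STD_FFM_KG + theta.ffat_v * std_fat)
        mf = 1.0 / (1.0 + (theta.tm50 / self.pma) ** theta.hill)
        return np.column_stack(
            [
                theta.cl_std * fs_cl * mf,
                theta.v1_std * fs_v,
                theta.v2_std * fs_v,
                theta.v3_std * fs_v,
                theta.q2_std * fs_cl,
                theta.q3_std * fs_cl,
            ]
        )

    def value(self, theta: ThetaSet, omega: OmegaSpec, residual: ResidualSpec) -> float:
        if residual.is_noise_free:
            raise ValueError("objective requires a non-degenerate residual model")
        om2 = np.array([omega.omega2[n] for n in self.re_names])
        if len(om2) and np.any(om2 <= 0):
            raise ValueError("omega variances must be positive for active random effects")
        typ_all = self.typical_matrix(theta)
        if not np.all(np.isfinite(typ_all)) or np.any(typ_all[:, :4] <= 0):
            return np.inf
        return float(
            population_m2ll(
                typ_all,
                self.re_idx,
                om2,
                residual.theta_ruv_cv,
                residual.theta_ruv_sd,
                self.y_flat,
                self.times_flat,
                self.obs_off,
                self.knots_flat,
                self.rates_flat,
                self.seg_off,
                self.bolus_t_flat,
                self.bolus_a_flat,
                self.bolus_off,
                self.config.inner_tol,
                self.config.inner_maxiter,
                self.etas,
            )
        )

    def ebes(self) -> dict[str, np.ndarray]:
        return {name: self.etas[:, i].copy() for i, name in enumerate(self.re_names)}


def empirical_bayes(
    dataset: PopulationDataset,
    theta: ThetaSet,
    omega: OmegaSpec,
    residual: ResidualSpec,
    config: FitConfig | None = None,
) -> dict[str, np.ndarray]:
    """Conditional modes (EBEs) of every subject's random effects.

    Returns one array of per-subject modes for each random effect named in
    the OmegaSpec (positive variance).
    """
    config = config or FitConfig()
    re_names = tuple(k for k in PK_PARAM_NAMES if omega.omega2.get(k, 0.0) > 0)
    engine = _ObjectiveEngine(dataset, config, re_names)
    value = engine.value(theta, omega, residual)
    if not np.isfinite(value):
        raise ValueError("objective is not finite at the supplied parameters")
    return engine.ebes()


def objective(
    dataset: PopulationDataset,
    theta: ThetaSet,
    omega: OmegaSpec,
    residual: ResidualSpec,
    config: FitConfig | None = None,
) -> float:
    """-2 log marginal likelihood of the dataset under the population model.

    Random effects are the OmegaSpec entries with positive variance; each
    subject contributes a Laplace approximation evaluated at the conditional
    mode of its random effects, with the residual SD computed from the
    conditional prediction (interaction). Subjects with non-finite
    predictions make the objective +inf (optimiser-safe).
    """
    config = config or FitConfig()
    re_names = tuple(k for k in PK_PARAM_NAMES if omega.omega2.get(k, 0.0) > 0)
    engine = _ObjectiveEngine(dataset, config, re_names)
    return engine.value(theta, omega, residual)


# ---------------------------------------------------------------------------
# Population fit
# ---------------------------------------------------------------------------

def _pack(
    theta: ThetaSet, omega: OmegaSpec, residual: ResidualSpec,
    config: FitConfig, re_names: tuple[str, ...],
) -> tuple[np.ndarray, list[str]]:
    x, names = [], []
    for n in config.theta_names:
        x.append(np.log(getattr(theta, n)))
        names.append(n)
    if config.estimate_omega:
        for n in re_names:
            x.append(0.5 * np.log(omega.omega2[n]))
            names.append(f"omega_{n}")
    if config.estimate_residual_cv:
        x.append(np.log(residual.theta_ruv_cv))
        names.append("ruv_cv")
    return np.array(x), names


def _unpack(
    x: np.ndarray, names: list[str],
    theta0: ThetaSet, omega0: OmegaSpec, residual0: ResidualSpec,
) -> tuple[ThetaSet, OmegaSpec, ResidualSpec]:
    tkw: dict[str, float] = {}
    om2 = dict(omega0.omega2)
    cv = residual0.theta_ruv_cv
    for xi, n in zip(x, names):
        if n.startswith("omega_"):
            om2[n[6:]] = float(np.exp(2.0 * xi))
        elif n == "ruv_cv":
            cv = float(np.exp(xi))
        else:
            tkw[n] = float(np.exp(xi))
    theta = theta0.replace(**tkw)
    omega = OmegaSpec(omega2=om2, omega2_ruv=omega0.omega2_ruv)
    residual = ResidualSpec(theta_ruv_cv=cv, theta_ruv_sd=residual0.theta_ruv_sd)
    return theta, omega, residual


def fit(
    dataset: PopulationDataset,
    initial_values: tuple[ThetaSet, OmegaSpec, ResidualSpec],
    config: FitConfig | None = None,
) -> FitResult:
    """Maximise the approximate marginal likelihood over population parameters.

    All parameters are optimised on the log scale (typical values, omega
    standard deviations, residual CV). Asymptotic 95% CIs come from the
    central-finite-difference Hessian of the objective at the optimum when
    ``config.compute_ci`` is set. Non-convergence is reported through the
    ``converged`` flag with partial estimates retained.
    """
    config = config or FitConfig()
    theta0, omega0, residual0 = initial_values
    re_names = tuple(k for k in PK_PARAM_NAMES if omega0.omega2.get(k, 0.0) > 0)
    engine = _ObjectiveEngine(dataset, config, re_names)
    x0, names = _pack(theta0, omega0, residual0, config, re_names)
    n_eval = 0

    def func(x: np.ndarray) -> float:
        # a large finite penalty instead of +inf: the L-BFGS-B line search
        # backtracks cleanly from finite values but aborts on inf/nan
        nonlocal n_eval
        n_eval += 1
        try:
            theta, omega, residual = _unpack(x, names, theta0, omega0, residual0)
            v = engine.value(theta, omega, residual)
        except (ValueError, FloatingPointError):
            return 1e10
        return v if np.isfinite(v) else 1e10

    # generous log-scale box keeps the line search out of degenerate regions
    bounds = [(xi - 4.0, xi + 4.0) for xi in x0]
    res = optimize.minimize(
        func,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": config.maxiter,
            "eps": config.fd_step,
            "ftol": 1e-11,
            "gtol": config.gtol,
        },
    )
    xhat = res.x
    theta, omega, residual = _unpack(xhat, names, theta0, omega0, residual0)
    obj = engine.value(theta, omega, residual)
    ebes = engine.ebes()
    shr = {
        n: shrinkage(ebes[n], omega.omega2[n])
        for n in re_names
        if omega.omega2[n] > 0
    }

    theta_se: dict[str, float] = {}
    theta_ci: dict[str, tuple[float, float]] = {}
    if config.compute_ci:
        se_log = _log_scale_se(func, xhat)
        for n, xh, se in zip(names, xhat, se_log):
            est = float(np.exp(xh))
            if n.startswith("omega_") or n == "ruv_cv":
                continue
            theta_se[n] = est * se  # delta method back to the natural scale
            theta_ci[n] = (est * float(np.exp(-1.96 * se)), est * float(np.exp(1.96 * se)))

    return FitResult(
        obj=float(obj),
        theta=theta,
        omega=omega,
        residual=residual,
        theta_se=theta_se,
        theta_ci=theta_ci,
        omega_ppv=omega.ppv_percent(),
        ebes=ebes,
        shrinkage_pct=shr,
        converged=bool(res.success),
        precision=float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan"),
        n_evaluations=n_eval,
        message=str(res.message),
    )


def _log_scale_se(func, xhat: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """SEs on the log scale from a central-difference Hessian of -2LL."""
    p = len(xhat)
    hess = np.zeros((p, p))
    f0 = func(xhat)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = step
            ej = np.zeros(p); ej[j] = step
            if i == j:
                hess[i, i] = (func(xhat + ei) - 2 * f0 + func(xhat - ei)) / step**2
            else:
                hess[i, j] = hess[j, i] = (
                    func(xhat + ei + ej) - func(xhat + ei - ej)
                    - func(xhat - ei + ej) + func(xhat - ei - ej)
                ) / (4 * step**2)
    try:
        # -2LL Hessian: covariance = 2 * H^-1
        cov = 2.0 * np.linalg.inv(hess)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian not positive definite; SEs unavailable", stacklevel=2)
        return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# Model comparison, shrinkage, variance decomposition
# ---------------------------------------------------------------------------

def lrt(obj_reduced: float, obj_full: float, added_params: int) -> LrtDecision:
    """Likelihood-ratio test for nested models.

    A drop in -2LL strictly greater than the 95% chi-square quantile with
    ``added_params`` degrees of freedom is significant at the 0.05 level
    (3.84 for one added parameter; the boundary value itself is not
    significant).
    """
    if not (np.isfinite(obj_reduced) and np.isfinite(obj_full)):
        raise ValueError("objective values must be finite")
    if added_params < 1:
        raise ValueError("added_params must be >= 1")
    delta = obj_reduced - obj_full
    if delta < 0:
        warnings.warn(
            "full model has higher -2LL than reduced model: possible optimisation failure",
            stacklevel=2,
        )
    threshold = float(stats.chi2.ppf(0.95, added_params))
    return LrtDecision(
        delta_obj=float(delta),
        df=added_params,
        threshold=threshold,
        significant=bool(delta > threshold),
    )


def shrinkage(ebe_values: np.ndarray, omega2: float) -> float:
    """Eta-shrinkage percentage, 100·(1 - SD(EBE)/omega).

    Approaches 0 when individual data are rich and 100 when they carry no
    information about the random effect. Undefined for omega2 = 0 (NaN).
    """
    ebe_values = np.asarray(ebe_values, dtype=float)
    if len(ebe_values) < 2:
        raise ValueError("need at least two subjects")
    if omega2 <= 0:
        warnings.warn("shrinkage undefined for zero omega", stacklevel=2)
        return float("nan")
    val = 100.0 * (1.0 - ebe_values.std(ddof=1) / np.sqrt(omega2))
    return float(np.clip(val, 0.0, 100.0))


def variance_decomposition(ppvt2: float, bsvr2: float) -> VarianceDecomposition:
    """Covariate-explained share of between-subject variance.

    ``bsvp2 = ppvt2 - bsvr2`` is the part of the no-covariate variance
    removed by the covariate model, and ``ratio`` its fraction of the total.
    """
    if ppvt2 <= 0:
        raise ValueError("ppvt2 must be positive")
    if bsvr2 < 0:
        raise ValueError("bsvr2 must be non-negative")
    bsvp2 = ppvt2 - bsvr2
    if bsvp2 < 0:
        warnings.warn("bsvr2 exceeds ppvt2; ratio clamped to 0", stacklevel=2)
        bsvp2 = 0.0
    return VarianceDecomposition(
        ppvt2=ppvt2, bsvr2=bsvr2, bsvp2=bsvp2, ratio=bsvp2 / ppvt2
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def stratified_resample(
    dataset: PopulationDataset, rng: np.random.Generator
) -> PopulationDataset:
    """Resample subjects with replacement within each study stratum."""
    subjects: list[Subject] = []
    for label, members in dataset.by_study().items():
        idx = rng.integers(0, len(members), size=len(members))
        subjects.extend(members[i] for i in idx)
    return PopulationDataset(subjects=subjects)


def bootstrap(
    dataset: PopulationDataset,
    n_reps: int,
    seed: int | np.random.Generator,
    initial_values: tuple[ThetaSet, OmegaSpec, ResidualSpec],
    config: FitConfig | None = None,
) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the population fit.

    Subjects are resampled with replacement within each study label so every
    replicate preserves the per-study subject counts; each replicate is
    refitted and parameter medians with 2.5/97.5 percentile CIs are reported.
    Replicates that fail to converge are excluded and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config = config or FitConfig()
    collected: dict[str, list[float]] = {}
    n_converged = 0
    for _ in range(n_reps):
        rep = stratified_resample(dataset, rng)
        try:
            result = fit(rep, initial_values, replace(config, compute_ci=False))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not result.converged or not np.isfinite(result.obj):
            continue
        n_converged += 1
        for n in config.theta_names:
            collected.setdefault(n, []).append(getattr(result.theta, n))
        for n, v in result.omega.omega2.items():
            if v > 0 and config.estimate_omega:
                collected.setdefault(f"omega_{n}", []).append(float(np.sqrt(v)))
        if config.estimate_residual_cv:
            collected.setdefault("ruv_cv", []).append(result.residual.theta_ruv_cv)
    if n_converged < max(1, int(0.8 * n_reps)):
        warnings.warn(
            f"only {n_converged}/{n_reps} bootstrap replicates converged", stacklevel=2
        )
    estimates = {k: np.asarray(v) for k, v in collected.items()}
    medians = {k: float(np.median(v)) for k, v in estimates.items()}
    ci95 = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in estimates.items()
    }
    return BootstrapResult(
        medians=medians, ci95=ci95, n_requested=n_reps,
        n_converged=n_converged, estimates=estimates,
    )
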