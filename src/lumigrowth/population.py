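"""Nonlinear mixed-effects estimation for the growth model (SAEM).

Statistical model
-----------------
Each animal i has individual structural parameters drawn lognormally around
population typical values::

    theta_i = theta_mu * exp(eta_i),    eta_i ~ N(0, diag(omega^2))

and observations with proportional residual error::

    y_ij = f(t_ij, theta_i) * (1 + eps_ij),    eps_ij ~ N(0, sigma^2)

The fixed effects theta_mu, the random-effect variances omega^2 (diagonal;
no parameter correlations are estimated) and sigma are estimated by maximum
likelihood with the SAEM algorithm: a Metropolis-Hastings E-step sampling
eta_i per subject, a stochastic-approximation update of the complete-data
sufficient statistics (step size 1 during exploration, 1/(k - K1) during
smoothing), and closed-form M-step updates.

The inter-animal coefficient of variation of a lognormal parameter is
``CV% = 100 * sqrt(exp(omega^2) - 1)``.  Relative standard errors come from
a Louis-type Monte-Carlo estimate of the observed Fisher information at the
optimum.

The module is written around a small subject-model protocol so the same
engine fits the stage-1 bioluminescence model (parameters a, K; P0 fixed at
injected cells x photons/cell) and the stage-2 caliper scaling model
(parameter lambda over frozen individual trajectories).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import logsumexp

from .growth_model import (
    ConversionConstants,
    ModelParameters,
    signal_to_volume_cm3,
    total_signal,
)

__all__ = [
    "LongitudinalDataset",
    "PopulationParameters",
    "FitResult",
    "SaemSettings",
    "individual_parameters",
    "individual_log_likelihood",
    "cv_percent_from_omega2",
    "omega2_from_cv_percent",
    "two_stage_fit",
    "saem_fit",
    "fit_lambda",
    "joint_fit",
    "compute_rse",
    "marginal_log_likelihood",
    "GrowthSubjectModel",
    "ScaleSubjectModel",
]

BIOLUMINESCENCE = "bioluminescence"
CALIPER = "caliper"


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

class LongitudinalDataset:
    """Per-subject time series of observations tagged by observable type.

    Thin wrapper over a DataFrame with columns ``subject, time, observable,
    value`` (times in days post-graft; values photons/sec for
    bioluminescence, cm^3 for caliper).
    """

    COLUMNS = ("subject", "time", "observable", "value")

    def __init__(self, frame: pd.DataFrame, min_bioluminescence_records: int = 2):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["time"] = frame["time"].astype(float)
        frame["value"] = frame["value"].astype(float)
        if (frame["time"] < 0).any():
            raise ValueError("times must be >= 0 (days post-graft)")
        if (frame["value"] <= 0).any():
            raise ValueError("values must be > 0 (multiplicative modeling)")
        bad = set(frame["observable"]) - {BIOLUMINESCENCE, CALIPER}
        if bad:
            raise ValueError(f"unknown observable tags: {sorted(bad)}")
        if min_bioluminescence_records > 0:
            counts = (
                frame[frame["observable"] == BIOLUMINESCENCE].groupby("subject").size()
            )
            subjects = frame["subject"].unique()
            if len(counts) < len(subjects) or (counts < min_bioluminescence_records).any():
                raise ValueError(
                    f"every subject needs >= {min_bioluminescence_records} "
                    "bioluminescence records"
                )
        self.frame = frame.sort_values(["subject", "observable", "time"]).reset_index(
            drop=True
        )

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.frame["subject"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def observable(self, tag: str) -> pd.DataFrame:
        return self.frame[self.frame["observable"] == tag]

    def subject_series(self, tag: str) -> dict:
        """Map subject -> (times, values) arrays for one observable."""
        out = {}
        for sid, grp in self.observable(tag).groupby("subject", sort=False):
            out[sid] = (grp["time"].to_numpy(), grp["value"].to_numpy())
        return out

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LongitudinalDataset":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, random-effect variances, and residual error.

    ``theta_mu`` maps parameter name -> typical value (natural units);
    ``omega2`` maps parameter name -> variance of the log-scale random
    effect; ``sigma`` is the proportional residual SD (dimensionless).
    """

    theta_mu: dict
    omega2: dict
    sigma: float

    def __post_init__(self) -> None:
        if set(self.theta_mu) != set(self.omega2):
            raise ValueError("theta_mu and omega2 must share parameter names")
        for k, v in self.theta_mu.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"theta_mu[{k}] must be > 0")
        for k, v in self.omega2.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"omega2[{k}] must be >= 0")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def names(self) -> list:
        return list(self.theta_mu)

    @property
    def cv_percent(self) -> dict:
        return {k: cv_percent_from_omega2(w) for k, w in self.omega2.items()}


@dataclass
class FitResult:
    """Estimation output: the machine twin of a population-fit results table."""

    estimates: PopulationParameters
    cv_percent: dict
    rse_percent: dict
    individual_eta: pd.DataFrame        # conditional modes, subjects x parameters
    loglik_trace: np.ndarray            # complete-data log-likelihood per iteration
    converged: bool
    n_subjects: int
    n_observations: int
    settings: "SaemSettings" = None
    message: str = ""

    @property
    def individual_parameters(self) -> pd.DataFrame:
        """Individual parameter values theta_i = theta_mu * exp(eta_i)."""
        mu = self.estimates.theta_mu
        out = self.individual_eta.copy()
        for k in out.columns:
            out[k] = mu[k] * np.exp(out[k])
        return out

    def table(self) -> pd.DataFrame:
        """Results-table view: estimate, inter-animal CV%, RSE% per parameter."""
        rows = []
        for k in self.estimates.names:
            rows.append(
                {
                    "parameter": k,
                    "estimate": self.estimates.theta_mu[k],
                    "cv_percent": self.cv_percent.get(k, np.nan),
                    "rse_percent": self.rse_percent.get(k, np.nan),
                }
            )
        rows.append(
            {
                "parameter": "sigma",
                "estimate": self.estimates.sigma,
                "cv_percent": np.nan,
                "rse_percent": self.rse_percent.get("sigma", np.nan),
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SaemSettings:
    """SAEM schedule and MCMC tuning.

    Defaults (300 exploration + 200 smoothing iterations, 3 MH transitions
    per subject per iteration, proposal adapted toward ~30% acceptance) are
    standard for low-dimensional structural models.
    """

    n_explore: int = 300
    n_smooth: int = 200
    n_transitions: int = 3
    target_accept: float = 0.30
    adapt_rate: float = 0.4
    seed: int = 0
    omega2_floor: float = 1e-8
    sigma_floor: float = 1e-6
    rse_samples: int = 400
    rse_warmup: int = 100


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def cv_percent_from_omega2(omega2: float) -> float:
    """Inter-animal CV%% of a lognormal parameter: 100*sqrt(exp(w2)-1)."""
    if omega2 < 0:
        raise ValueError("omega2 must be >= 0")
    return 100.0 * np.sqrt(np.expm1(omega2))


def omega2_from_cv_percent(cv: float) -> float:
    """Inverse of :func:`cv_percent_from_omega2`: w2 = log(1 + (cv/100)^2)."""
    if cv < 0:
        raise ValueError("CV must be >= 0")
    return float(np.log1p((cv / 100.0) ** 2))


def individual_parameters(theta_mu: dict, eta: dict) -> dict:
    """Individual parameters theta_i = theta_mu * exp(eta), componentwise."""
    if set(eta) - set(theta_mu):
        raise ValueError("eta has components absent from theta_mu")
    return {k: theta_mu[k] * np.exp(eta.get(k, 0.0)) for k in theta_mu}


def individual_log_likelihood(values, predictions, sigma: float) -> float:
    """Gaussian log-density under the proportional error model.

    ``y = f * (1 + eps)`` with ``eps ~ N(0, sigma^2)`` means
    ``y ~ N(f, (sigma * f)^2)``; a zero prediction at an observation time is
    degenerate and raises.
    """
    y = np.asarray(values, dtype=float)
    f = np.asarray(predictions, dtype=float)
    if np.any(f <= 0):
        raise ValueError("proportional error model needs strictly positive predictions")
    sd = sigma * f
    z = (y - f) / sd
    return float(np.sum(-0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * z * z))


def _loglik_prop(y: np.ndarray, f: np.ndarray, sigma: float) -> float:
    """Fast non-validating proportional-error log-density (internal)."""
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        return -np.inf
    sd = sigma * f
    z = (y - f) / sd
    return float(np.sum(-0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * z * z))


# ---------------------------------------------------------------------------
# subject models
# ---------------------------------------------------------------------------

class GrowthSubjectModel:
    """Stage-1 structural model: logistic proliferative signal, theta = (a, K).

    P0 is fixed (injected cell count converted via the cells-to-light ratio),
    not estimated.
    """

    param_names = ("a", "K")

    def __init__(self, p0_signal: float):
        if p0_signal <= 0:
            raise ValueError("p0_signal must be > 0")
        self.p0 = p0_signal

    def predict(self, times: np.ndarray, theta: np.ndarray) -> np.ndarray:
        a, K = theta
        if K <= self.p0:
            # carrying capacity proposals below the inoculum are unphysical
            return np.full(len(times), np.nan)
        ratio = K / self.p0 - 1.0
        return K / (1.0 + ratio * np.exp(-a * times))


class ScaleSubjectModel:
    """Stage-2 model: caliper volume = lambda_i * (frozen cell-mass volume).

    ``base`` maps subject -> callable t -> cell-mass volume in cm^3 from the
    stage-1 individual trajectory.
    """

    param_names = ("lam",)

    def __init__(self, base: dict):
        self.base = base
        self._subject = None

    def for_subject(self, sid):
        m = ScaleSubjectModel(self.base)
        m._subject = sid
        return m

    def predict(self, times: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return theta[0] * self.base[self._subject](times)


class JointSubjectModel:
    """Joint model: theta = (a, K, lam), both observables per subject.

    Each subject's series concatenates bioluminescence then caliper
    records; ``n_biolum`` says where the split falls.  A single residual
    parameter is shared across the two instruments in this mode.
    """

    param_names = ("a", "K", "lam")

    def __init__(self, p0_signal: float, conv: ConversionConstants, n_biolum: dict):
        if p0_signal <= 0:
            raise ValueError("p0_signal must be > 0")
        self.p0 = p0_signal
        self.conv = conv
        self.n_biolum = n_biolum
        self._subject = None

    def for_subject(self, sid):
        m = JointSubjectModel(self.p0, self.conv, self.n_biolum)
        m._subject = sid
        return m

    def predict(self, times: np.ndarray, theta: np.ndarray) -> np.ndarray:
        a, K, lam = theta
        if K <= self.p0:
            return np.full(len(times), np.nan)
        nb = self.n_biolum[self._subject]
        ratio = K / self.p0 - 1.0
        P = K / (1.0 + ratio * np.exp(-a * times[:nb]))
        t_cal = times[nb:]
        pars = ModelParameters(a=a, K=K, P0=self.p0)
        vol = lam * signal_to_volume_cm3(total_signal(t_cal, pars), self.conv)
        return np.concatenate([P, np.atleast_1d(vol)])


def _subject_predictors(model, subjects):
    """Bind a subject model to each subject id (identity for shared models)."""
    if hasattr(model, "for_subject"):
        return {sid: model.for_subject(sid) for sid in subjects}
    return {sid: model for sid in subjects}


# ---------------------------------------------------------------------------
# two-stage baseline (initialization + sanity oracle)
# ---------------------------------------------------------------------------

def _init_growth_guess(t: np.ndarray, y: np.ndarray, p0: float, model):
    """Coarse grid start for (a, K).

    Subjects observed already at plateau leave ``a`` unidentified; a grid
    over plausible rates and capacities picks the least-bad corner instead
    of trusting an early-slope estimate that can be degenerate.
    """
    best = (0.3, max(float(np.max(y)) * 1.5, p0 * 10.0))
    best_sse = np.inf
    for a0 in (0.1, 0.2, 0.3, 0.45, 0.7, 1.0, 1.5):
        for kf in (1.05, 1.5, 3.0):
            k0 = max(float(np.max(y)) * kf, p0 * 2.0)
            f = model.predict(t, np.array([a0, k0]))
            if np.any(~np.isfinite(f)) or np.any(f <= 0):
                continue
            sse = float(np.sum((np.log(f) - np.log(y)) ** 2))
            if sse < best_sse:
                best_sse, best = sse, (a0, k0)
    return best


def two_stage_fit(
    data: LongitudinalDataset,
    p0_signal: float,
    min_a: float = 2e-3,
) -> tuple:
    """Naive two-stage estimates: per-subject least squares, then pooling.

    Each subject's (a, K) is fit by nonlinear least squares on
    log-observations; the population fixed effects are geometric means of
    the individual estimates, omega^2 the variance of their logs, and sigma
    the RMS proportional residual.  Subjects whose fit fails (or whose
    signal is flat, leaving a unidentified) are excluded with a warning.

    Returns ``(PopulationParameters, individual_estimates: DataFrame)``.
    """
    series = data.subject_series(BIOLUMINESCENCE)
    model = GrowthSubjectModel(p0_signal)
    rows = {}
    resid_sq, n_res = [], 0
    for sid, (t, y) in series.items():
        if len(t) < 3:
            warnings.warn(f"subject {sid}: fewer than 3 observations, excluded")
            continue
        a0, k0 = _init_growth_guess(t, y, p0_signal, model)

        def resfun(logtheta, t=t, y=y):
            f = model.predict(t, np.exp(logtheta))
            if np.any(~np.isfinite(f)) or np.any(f <= 0):
                return np.full(len(t), 1e6)
            return np.log(f) - np.log(y)

        # bounded fit: rates and capacities outside these ranges are not
        # identifiable from a day-6..43 design and would poison the pooling
        lo = np.log([1e-3, p0_signal * 1.2])
        hi = np.log([5.0, float(np.max(y)) * 50.0])
        x0 = np.clip(np.log([a0, max(k0, p0_signal * 1.3)]), lo + 1e-6, hi - 1e-6)
        try:
            sol = least_squares(
                resfun, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14
            )
            a_hat, k_hat = np.exp(sol.x)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"subject {sid}: fit failed ({exc}), excluded")
            continue
        if not sol.success or not np.isfinite(a_hat) or a_hat < min_a or k_hat <= p0_signal:
            warnings.warn(f"subject {sid}: degenerate individual fit, excluded")
            continue
        rows[sid] = {"a": a_hat, "K": k_hat}
        f = model.predict(t, np.array([a_hat, k_hat]))
        resid_sq.append(np.sum(((y - f) / f) ** 2))
        n_res += len(t)
    if len(rows) < 2:
        raise RuntimeError("two-stage fit: fewer than 2 subjects could be fit")
    indiv = pd.DataFrame.from_dict(rows, orient="index")
    logs = np.log(indiv[["a", "K"]].to_numpy())
    mu = logs.mean(axis=0)
    w2 = logs.var(axis=0)
    sigma = float(np.sqrt(max(np.sum(resid_sq) / n_res, 1e-8)))
    pop = PopulationParameters(
        theta_mu={"a": float(np.exp(mu[0])), "K": float(np.exp(mu[1]))},
        omega2={"a": float(w2[0]), "K": float(w2[1])},
        sigma=sigma,
    )
    return pop, indiv


# ---------------------------------------------------------------------------
# SAEM core
# ---------------------------------------------------------------------------

def _saem_engine(series, model, init: PopulationParameters, settings: SaemSettings,
                 phi_init: dict | None = None):
    """Generic SAEM over one observable.

    ``series`` maps subject -> (times, values); ``model`` follows the
    subject-model protocol.  Works on phi_i = log(theta_i) ~ N(mu, diag w2).
    Deterministic given ``settings.seed``.
    """
    names = list(model.param_names)
    p = len(names)
    subjects = list(series)
    n = len(subjects)
    if n < 3:
        raise ValueError("SAEM needs at least 3 subjects")
    rng = np.random.default_rng(settings.seed)
    predictors = _subject_predictors(model, subjects)
    times = {sid: series[sid][0] for sid in subjects}
    values = {sid: series[sid][1] for sid in subjects}
    n_obs = int(sum(len(v) for v in values.values()))

    mu = np.log([init.theta_mu[k] for k in names])
    w2 = np.maximum([init.omega2[k] for k in names], settings.omega2_floor)
    sig2 = max(init.sigma**2, settings.sigma_floor**2)

    # per-subject phi chains start at individual estimates when available
    phi = np.tile(mu, (n, 1))
    if phi_init is not None:
        for i, sid in enumerate(subjects):
            if sid in phi_init:
                phi[i] = np.log(np.asarray(phi_init[sid], dtype=float))

    def data_loglik(i, phi_i):
        f = predictors[subjects[i]].predict(times[subjects[i]], np.exp(phi_i))
        return _loglik_prop(values[subjects[i]], f, np.sqrt(sig2)), f

    cur_ll = np.empty(n)
    cur_ss = np.empty(n)  # sum of squared proportional residuals at current phi
    for i in range(n):
        ll, f = data_loglik(i, phi[i])
        cur_ll[i] = ll
        cur_ss[i] = np.sum(((values[subjects[i]] - f) / f) ** 2) if np.all(f > 0) else np.inf

    prop_scale = 0.4
    n_iter = settings.n_explore + settings.n_smooth
    # sufficient statistics: S1 = sum phi, S2 = sum phi^2, S3 = sum SS_i
    s1 = phi.sum(axis=0)
    s2 = (phi**2).sum(axis=0)
    s3 = float(np.sum(cur_ss[np.isfinite(cur_ss)]))
    trace = np.empty((n_iter, 2 * p + 1))
    ll_trace = np.empty(n_iter)
    diverged = False

    for k in range(n_iter):
        sigma = np.sqrt(sig2)
        # --- E-step: MH transitions per subject (random walk on phi)
        accepted = 0
        proposed = 0
        prior_sd = np.sqrt(np.maximum(w2, settings.omega2_floor))
        for _ in range(settings.n_transitions):
            steps = rng.standard_normal((n, p)) * (prop_scale * prior_sd)
            log_u = np.log(rng.random(n))
            for i in range(n):
                cand = phi[i] + steps[i]
                f = predictors[subjects[i]].predict(times[subjects[i]], np.exp(cand))
                ll_cand = _loglik_prop(values[subjects[i]], f, sigma)
                lp_cand = -0.5 * np.sum((cand - mu) ** 2 / w2)
                lp_cur = -0.5 * np.sum((phi[i] - mu) ** 2 / w2)
                proposed += 1
                if log_u[i] < (ll_cand + lp_cand) - (cur_ll[i] + lp_cur):
                    phi[i] = cand
                    cur_ll[i] = ll_cand
                    cur_ss[i] = float(np.sum(((values[subjects[i]] - f) / f) ** 2))
                    accepted += 1
        if k < settings.n_explore:
            rate = accepted / max(proposed, 1)
            prop_scale *= np.exp(settings.adapt_rate * (rate - settings.target_accept))
            prop_scale = float(np.clip(prop_scale, 1e-3, 10.0))

        # --- SA-step
        gamma = 1.0 if k < settings.n_explore else 1.0 / (k - settings.n_explore + 1)
        s1 = s1 + gamma * (phi.sum(axis=0) - s1)
        s2 = s2 + gamma * ((phi**2).sum(axis=0) - s2)
        s3 = s3 + gamma * (float(np.sum(cur_ss)) - s3)

        # --- M-step (closed form for the lognormal/proportional model)
        mu = s1 / n
        w2 = np.maximum(s2 / n - mu**2, settings.omega2_floor)
        sig2 = max(s3 / n_obs, settings.sigma_floor**2)

        prior_ll = float(
            np.sum(-0.5 * np.log(2 * np.pi * w2) - 0.5 * (phi - mu) ** 2 / w2)
        )
        ll_trace[k] = float(np.sum(cur_ll)) + prior_ll
        trace[k] = np.concatenate([mu, w2, [np.sqrt(sig2)]])
        if not np.all(np.isfinite(trace[k])):
            diverged = True
            break

    est = PopulationParameters(
        theta_mu={k_: float(np.exp(m)) for k_, m in zip(names, mu)},
        omega2={k_: float(w) for k_, w in zip(names, w2)},
        sigma=float(np.sqrt(sig2)),
    )

    # conditional modes of eta given the final population parameters
    eta_rows = {}
    sigma = np.sqrt(sig2)
    for i, sid in enumerate(subjects):
        def neg_joint(eta, i=i):
            phi_i = mu + eta
            f = predictors[subjects[i]].predict(times[subjects[i]], np.exp(phi_i))
            ll = _loglik_prop(values[subjects[i]], f, sigma)
            return -(ll - 0.5 * np.sum(eta**2 / w2))

        res = minimize(neg_joint, phi[i] - mu, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        eta_rows[sid] = dict(zip(names, res.x))
    eta_df = pd.DataFrame.from_dict(eta_rows, orient="index")[names]

    converged = not diverged and np.all(np.isfinite(ll_trace[: k + 1]))
    result = FitResult(
        estimates=est,
        cv_percent=est.cv_percent,
        rse_percent={},
        individual_eta=eta_df,
        loglik_trace=ll_trace[: k + 1],
        converged=bool(converged),
        n_subjects=n,
        n_observations=n_obs,
        settings=settings,
        message="" if converged else "SAEM trace diverged (NaN encountered)",
    )
    # stash internals for RSE / likelihood computations
    result._internals = {
        "series": series,
        "model": model,
        "predictors": predictors,
        "names": names,
        "phi_final": phi.copy(),
        "subjects": subjects,
    }
    return result


def saem_fit(
    data: LongitudinalDataset,
    p0_signal: float,
    init: PopulationParameters | None = None,
    settings: SaemSettings = SaemSettings(),
    compute_se: bool = True,
) -> FitResult:
    """Fit the population growth model to bioluminescence data by SAEM.

    Initialization defaults to the two-stage estimates (per-subject least
    squares pooled into population values); individual chains start at the
    per-subject estimates.  Returns a :class:`FitResult` with estimates,
    inter-animal CV%%, and (optionally) Louis-type RSE%%.
    """
    if data.n_subjects < 3:
        raise ValueError("population fit needs at least 3 subjects")
    phi_init = None
    if init is None:
        init, indiv = two_stage_fit(data, p0_signal)
        phi_init = {
            sid: (row["a"], row["K"]) for sid, row in indiv.iterrows()
        }
    series = data.subject_series(BIOLUMINESCENCE)
    model = GrowthSubjectModel(p0_signal)
    fit = _saem_engine(series, model, init, settings, phi_init=phi_init)
    if compute_se and fit.converged:
        fit.rse_percent = compute_rse(fit)
    return fit


def fit_lambda(
    stage1: FitResult,
    data: LongitudinalDataset,
    conv: ConversionConstants = ConversionConstants(),
    p0_signal: float | None = None,
    settings: SaemSettings | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Stage-2 sequential fit of the caliper proportionality constant lambda.

    Individual (a_i, K_i) are frozen at their stage-1 conditional modes; each
    animal's cell-mass volume trajectory v_i(t) = (P+N)/conversion is treated
    as known, and lambda is estimated as a lognormal population parameter
    with proportional error on the caliper observations::

        V_ij = lambda_i * v_i(t_ij) * (1 + eps_ij)
    """
    if not stage1.converged:
        raise ValueError("stage-1 fit did not converge; cannot proceed to lambda")
    series = data.subject_series(CALIPER)
    if not series:
        raise ValueError("no caliper records in dataset")
    indiv = stage1.individual_parameters
    internals = getattr(stage1, "_internals", None)
    p0 = p0_signal
    if p0 is None and internals is not None:
        p0 = internals["model"].p0
    if p0 is None:
        raise ValueError("p0_signal required when stage-1 internals are unavailable")

    base = {}
    for sid in series:
        if sid not in indiv.index:
            raise ValueError(f"caliper subject {sid} missing from stage-1 fit")
        pars = ModelParameters(
            a=float(indiv.loc[sid, "a"]), K=float(indiv.loc[sid, "K"]), P0=p0
        )
        base[sid] = (
            lambda t, pars=pars: signal_to_volume_cm3(total_signal(t, pars), conv)
        )
    model = ScaleSubjectModel(base)

    # moment-based initialization from per-subject ratios
    lam_hat = {}
    resid = []
    for sid, (t, y) in series.items():
        v = base[sid](t)
        ratio = y / v
        lam_i = float(np.exp(np.mean(np.log(ratio))))
        lam_hat[sid] = (lam_i,)
        resid.append(np.mean((ratio / lam_i - 1.0) ** 2))
    logs = np.log([v[0] for v in lam_hat.values()])
    init = PopulationParameters(
        theta_mu={"lam": float(np.exp(np.mean(logs)))},
        omega2={"lam": float(max(np.var(logs), 1e-6))},
        sigma=float(np.sqrt(max(np.mean(resid), 1e-6))),
    )
    if settings is None:
        settings = stage1.settings if stage1.settings is not None else SaemSettings()
        settings = replace(settings, seed=settings.seed + 1)
    fit = _saem_engine(series, model, init, settings, phi_init=lam_hat)
    if compute_se and fit.converged:
        fit.rse_percent = compute_rse(fit)
    return fit


def joint_fit(
    data: LongitudinalDataset,
    p0_signal: float,
    conv: ConversionConstants = ConversionConstants(),
    settings: SaemSettings = SaemSettings(),
    compute_se: bool = True,
) -> FitResult:
    """One-shot SAEM fit of (a, K, lambda) on both observables jointly.

    Alternative to the default sequential workflow (:func:`saem_fit` then
    :func:`fit_lambda`).  A single proportional residual parameter is
    shared by the bioluminescence and caliper records in this mode, so the
    sequential route remains the default.
    """
    bli = data.subject_series(BIOLUMINESCENCE)
    cal = data.subject_series(CALIPER)
    if not cal:
        raise ValueError("no caliper records in dataset")
    init_pop, indiv = two_stage_fit(data, p0_signal)
    series, phi_init, lam_logs = {}, {}, []
    for sid, (t_b, y_b) in bli.items():
        if sid not in cal or sid not in indiv.index:
            continue
        t_c, y_c = cal[sid]
        series[sid] = (np.concatenate([t_b, t_c]), np.concatenate([y_b, y_c]))
        pars = ModelParameters(
            a=float(indiv.loc[sid, "a"]), K=float(indiv.loc[sid, "K"]), P0=p0_signal
        )
        v = signal_to_volume_cm3(total_signal(t_c, pars), conv)
        lam_i = float(np.exp(np.mean(np.log(y_c / v))))
        phi_init[sid] = (pars.a, pars.K, lam_i)
        lam_logs.append(np.log(lam_i))
    model = JointSubjectModel(
        p0_signal, conv, {sid: len(bli[sid][0]) for sid in series}
    )
    init = PopulationParameters(
        theta_mu={**init_pop.theta_mu, "lam": float(np.exp(np.mean(lam_logs)))},
        omega2={**init_pop.omega2, "lam": float(max(np.var(lam_logs), 1e-6))},
        sigma=init_pop.sigma,
    )
    fit = _saem_engine(series, model, init, settings, phi_init=phi_init)
    if compute_se and fit.converged:
        fit.rse_percent = compute_rse(fit)
    return fit


# ---------------------------------------------------------------------------
# standard errors (Louis / observed Fisher information) and likelihood
# ---------------------------------------------------------------------------

def _mcmc_samples(fit: FitResult, n_samples: int, warmup: int, seed: int):
    """Post-hoc MH chains of phi_i at the frozen final estimates."""
    ints = fit._internals
    series, predictors = ints["series"], ints["predictors"]
    subjects, names = ints["subjects"], ints["names"]
    p = len(names)
    est = fit.estimates
    mu = np.log([est.theta_mu[k] for k in names])
    w2 = np.maximum([est.omega2[k] for k in names], 1e-10)
    sigma = est.sigma
    rng = np.random.default_rng(seed)
    out = {}
    for i, sid in enumerate(subjects):
        t, y = series[sid]
        phi = ints["phi_final"][i].copy()
        f = predictors[sid].predict(t, np.exp(phi))
        cur = _loglik_prop(y, f, sigma) - 0.5 * np.sum((phi - mu) ** 2 / w2)
        cur_ss = float(np.sum(((y - f) / f) ** 2))
        scale = 0.4 * np.sqrt(w2)
        keep_phi = np.empty((n_samples, p))
        keep_ss = np.empty(n_samples)
        for m in range(warmup + n_samples):
            cand = phi + rng.standard_normal(p) * scale
            f = predictors[sid].predict(t, np.exp(cand))
            ll = _loglik_prop(y, f, sigma) - 0.5 * np.sum((cand - mu) ** 2 / w2)
            if np.log(rng.random()) < ll - cur:
                phi, cur = cand, ll
                cur_ss = float(np.sum(((y - f) / f) ** 2))
            if m >= warmup:
                keep_phi[m - warmup] = phi
                keep_ss[m - warmup] = cur_ss
        out[sid] = (keep_phi, keep_ss, len(y))
    return out, mu, w2, sigma


def compute_rse(fit: FitResult, seed: int | None = None) -> dict:
    """Relative standard errors from the observed Fisher information.

    Louis decomposition with Monte-Carlo conditional expectations: per
    subject, I_i = -E[H_i | y] - Cov[g_i | y] where g_i, H_i are the
    complete-data score and Hessian in (mu, omega^2, sigma^2).  The RSE of a
    fixed effect theta = exp(mu) equals 100*SE(mu) by the delta method.

    A singular information matrix yields per-parameter NaN with a warning.
    """
    if not hasattr(fit, "_internals"):
        raise ValueError("fit carries no internals; rerun the SAEM fit")
    settings = fit.settings or SaemSettings()
    if seed is None:
        seed = settings.seed + 9001
    samples, mu, w2, sigma = _mcmc_samples(
        fit, settings.rse_samples, settings.rse_warmup, seed
    )
    names = fit._internals["names"]
    p = len(names)
    dim = 2 * p + 1  # (mu_k, w2_k, sigma2)
    sig2 = sigma**2
    info = np.zeros((dim, dim))
    for sid, (phis, sss, n_i) in samples.items():
        d = phis - mu  # (M, p)
        M = len(phis)
        g = np.empty((M, dim))
        g[:, :p] = d / w2
        g[:, p : 2 * p] = -0.5 / w2 + 0.5 * d**2 / w2**2
        g[:, -1] = -0.5 * n_i / sig2 + 0.5 * sss / sig2**2
        Hbar = np.zeros((dim, dim))
        # E[H]: blocks are diagonal in k apart from (mu_k, w2_k) coupling
        for k in range(p):
            dk2 = np.mean(d[:, k] ** 2)
            dk = np.mean(d[:, k])
            Hbar[k, k] = -1.0 / w2[k]
            Hbar[k, p + k] = Hbar[p + k, k] = -dk / w2[k] ** 2
            Hbar[p + k, p + k] = 0.5 / w2[k] ** 2 - dk2 / w2[k] ** 3
        Hbar[-1, -1] = 0.5 * n_i / sig2**2 - np.mean(sss) / sig2**3
        gbar = g.mean(axis=0)
        cov_g = (g.T @ g) / M - np.outer(gbar, gbar)
        info += -Hbar - cov_g
    out = {}
    try:
        cov = np.linalg.inv(info)
        var = np.diag(cov)
        if np.any(var[: p] <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        warnings.warn("observed information matrix is singular; RSEs set to NaN")
        return {k: float("nan") for k in names} | {"sigma": float("nan")}
    for k, name in enumerate(names):
        out[name] = float(100.0 * np.sqrt(var[k]))  # SE(mu) == SE(theta)/theta
    # sigma RSE via sigma2: SE(sigma)/sigma = SE(sigma2)/(2 sigma2)
    if var[-1] > 0:
        out["sigma"] = float(100.0 * np.sqrt(var[-1]) / (2.0 * sig2))
    else:
        out["sigma"] = float("nan")
    return out


def marginal_log_likelihood(
    fit_or_pop,
    data_series: dict | None = None,
    model=None,
    n_samples: int = 2000,
    seed: int = 0,
) -> float:
    """Observed-data log-likelihood by Laplace importance sampling.

    For each subject the conditional mode of phi_i is found, a Gaussian
    proposal is built from a numerical Hessian (inflated 2x for tail cover),
    and the marginal density is estimated by importance sampling.  Accepts
    either a FitResult (using its internals) or an explicit
    (PopulationParameters, series, model) triple.
    """
    if isinstance(fit_or_pop, FitResult):
        ints = fit_or_pop._internals
        series = ints["series"]
        predictors = ints["predictors"]
        names = ints["names"]
        pop = fit_or_pop.estimates
    else:
        pop = fit_or_pop
        if data_series is None or model is None:
            raise ValueError("series and model required with explicit parameters")
        series = data_series
        predictors = _subject_predictors(model, list(series))
        names = list(model.param_names)
    p = len(names)
    mu = np.log([pop.theta_mu[k] for k in names])
    w2 = np.maximum([pop.omega2[k] for k in names], 1e-10)
    sigma = pop.sigma
    rng = np.random.default_rng(seed)
    total = 0.0
    for sid, (t, y) in series.items():
        def log_joint(phi):
            f = predictors[sid].predict(t, np.exp(phi))
            return (
                _loglik_prop(y, f, sigma)
                - 0.5 * np.sum((phi - mu) ** 2 / w2)
                - 0.5 * np.sum(np.log(2 * np.pi * w2))
            )

        res = minimize(lambda x: -log_joint(x), mu.copy(), method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000})
        mode = res.x
        # numerical Hessian at the mode
        h = 1e-4
        H = np.zeros((p, p))
        f0 = log_joint(mode)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h
                ej = np.zeros(p); ej[j] = h
                H[i, j] = H[j, i] = (
                    log_joint(mode + ei + ej)
                    - log_joint(mode + ei)
                    - log_joint(mode + ej)
                    + f0
                ) / h**2
        cov = -np.linalg.inv(H)
        # symmetrize and inflate; fall back to prior covariance if sick
        cov = 0.5 * (cov + cov.T) * 2.0
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(w2))
        draws = mode + rng.standard_normal((n_samples, p)) @ L.T
        lq = -0.5 * np.sum(
            np.linalg.solve(L, (draws - mode).T) ** 2, axis=0
        ) - np.sum(np.log(np.diag(L))) - 0.5 * p * np.log(2 * np.pi)
        lj = np.array([log_joint(d) for d in draws])
        total += float(logsumexp(lj - lq) - np.log(n_samples))
    return total
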