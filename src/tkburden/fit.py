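"""Per-individual estimation of toxicokinetic parameters.

Estimates (k_a, k_e, V/F) for oral series — or (k_e, V) for intravenous
series — by weighted nonlinear least squares with a Levenberg–Marquardt
iteration, the weighting being the reciprocal of each observed concentration
(appropriate when measurement error is proportional to the signal).
Asymptotic 95 % confidence intervals come from the inverse weighted
Gauss–Newton Hessian with a Student-t quantile at n − p degrees of freedom.

A two-compartment comparator model (biexponential disposition) is provided so
that AIC can rank the one-compartment model against a richer alternative, and
relative oral bioavailability is computed as the dose-normalised AUC ratio

    F = (AUC_po / dose_po) / (AUC_iv / dose_iv).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import DoseSpec, TKParameters, half_life, model_auc, oral_concentration

__all__ = [
    "ConcentrationSeries",
    "FitResult",
    "BioavailabilityResult",
    "fit_one_compartment",
    "fit_two_compartment_comparator",
    "compute_aic",
    "compute_relative_bioavailability",
    "summarize_group",
    "trapezoid_auc",
]

Weighting = Literal["inverse_observed", "uniform"]


@dataclass(frozen=True)
class ConcentrationSeries:
    """One subject's dose, route and (time, concentration) observations.

    Times are hours, strictly increasing and non-negative; concentrations are
    µg ml⁻¹ and non-negative (zero marks a value below the quantification
    limit). ``label`` is kinetically inert metadata such as the radiolabel
    position.
    """

    subject_id: str
    sex: str
    label: str
    dose: DoseSpec
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size:
            raise ValueError("times and concentrations differ in length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError(f"times must be strictly increasing and >= 0 ({self.subject_id})")
        if np.any(c < 0):
            raise ValueError(f"concentrations must be >= 0 ({self.subject_id})")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def route(self) -> str:
        return self.dose.route

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitResult:
    """Converged (or diagnosed) weighted least-squares fit for one subject."""

    model: str  # "one_compartment" or "two_compartment"
    series: ConcentrationSeries
    param_names: tuple[str, ...]
    estimates: tuple[float, ...]
    se: tuple[float, ...]
    ci95: tuple[tuple[float, float], ...]
    significant: tuple[bool, ...]
    wrss: float
    n_obs: int  # observations entering the objective
    n_excluded: int  # zero-concentration points dropped under 1/C weighting
    converged: bool
    n_iter: int
    weighting: Weighting
    flipped: bool = False  # oral solution re-expressed so that k_a > k_e

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def aic(self) -> float:
        return compute_aic(self)

    def __getitem__(self, name: str) -> float:
        return self.estimates[self.param_names.index(name)]

    @property
    def tk_parameters(self) -> TKParameters:
        """The estimates as a TKParameters record (one-compartment only)."""
        if self.model != "one_compartment":
            raise ValueError("TKParameters only defined for the one-compartment model")
        if self.series.route == "oral":
            return TKParameters(
                k_a=self["k_a"], k_e=self["k_e"], v_over_f=self["v_over_f"], route="oral"
            )
        return TKParameters(k_e=self["k_e"], v_over_f=self["v"], route="iv")

    @property
    def auc(self) -> float:
        return model_auc(self.tk_parameters, self.series.dose)


@dataclass(frozen=True)
class BioavailabilityResult:
    """Dose-normalised oral/i.v. AUC ratio."""

    f: float
    auc_po: float
    auc_iv_reference: float
    dose_po: float
    dose_iv: float
    exceeds_one: bool = field(default=False)


def trapezoid_auc(series: ConcentrationSeries) -> float:
    """Linear trapezoidal AUC over the observed window (h·µg ml⁻¹)."""
    return float(np.trapezoid(series.concentrations, series.times))


def _prepare(series: ConcentrationSeries, weighting: Weighting):
    t = np.asarray(series.times, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    if weighting == "inverse_observed":
        keep = c > 0  # 1/C weight undefined at zero: excluded, counted
        t, c = t[keep], c[keep]
        w = 1.0 / c
        n_excluded = int((~keep).sum())
    elif weighting == "uniform":
        w = np.ones_like(c)
        n_excluded = 0
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return t, c, np.sqrt(w), n_excluded


def _default_init_oral(t, c, dose_ug) -> np.ndarray:
    """Deterministic starting values: terminal log-linear slope for k_e,
    method of residuals for k_a, dose/(AUC·k_e) for V/F."""
    pos = c > 0
    tp, cp = t[pos], c[pos]
    # k_e from the last 3 positive observations
    tt, cc = tp[-3:], np.log(cp[-3:])
    ke = max(-np.polyfit(tt, cc, 1)[0], 1e-3)
    # curve stripping: extrapolate the terminal line back, fit the residual
    b = np.polyfit(tt, cc, 1)[1]
    early = tp < tp[-3]
    ka = 3.0 * ke
    if early.sum() >= 2:
        resid = np.exp(b - ke * tp[early]) - cp[early]
        ok = resid > 0
        if ok.sum() >= 2:
            slope = -np.polyfit(tp[early][ok], np.log(resid[ok]), 1)[0]
            if slope > ke:
                ka = slope
    auc = max(np.trapezoid(cp, tp), 1e-12)
    v = dose_ug / (auc * ke)
    return np.array([ka, ke, v])


def _default_init_iv(t, c, dose_ug) -> np.ndarray:
    pos = c > 0
    tp, cp = t[pos], c[pos]
    slope, intercept = np.polyfit(tp, np.log(cp), 1)
    ke = max(-slope, 1e-3)
    v = dose_ug / max(np.exp(intercept), 1e-12)
    return np.array([ke, v])


def _asymptotic_ci(jac: np.ndarray, wrss: float, n: int, p: int, theta: np.ndarray):
    """SEs and 95 % CIs from the Gauss–Newton Hessian J'J of the weighted
    residuals, with residual variance WRSS/(n−p)."""
    dof = max(n - p, 1)
    s2 = wrss / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    tq = stats.t.ppf(0.975, dof)
    ci = tuple((float(th - tq * s), float(th + tq * s)) for th, s in zip(theta, se))
    sig = tuple(bool(lo > 0 or hi < 0) for lo, hi in ci)
    return tuple(float(s) for s in se), ci, sig


def _run_lm(residual_fn, x0, n_obs):
    """Damped least-squares iteration; objective never increases from x0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.least_squares(
            residual_fn, x0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=2000
        )
    return res


def fit_one_compartment(
    series: ConcentrationSeries,
    init: TKParameters | None = None,
    weighting: Weighting = "inverse_observed",
) -> FitResult:
    """Fit the one-compartment model to a single subject's series.

    Oral series estimate (k_a, k_e, V/F); i.v. series estimate (k_e, V).
    The oral solution is reported with k_a > k_e (the two orderings trace
    identical curves); when the optimiser lands on the k_a < k_e branch the
    equivalent canonical representation is returned and flagged.
    """
    t, c, sqrt_w, n_excluded = _prepare(series, weighting)
    dose_ug = series.dose.amount_ug_per_kg
    oral = series.route == "oral"
    p = 3 if oral else 2
    if len(t) <= p:
        raise ValueError(
            f"{series.subject_id}: {len(t)} usable observations cannot support "
            f"a {p}-parameter fit"
        )

    if oral:
        names = ("k_a", "k_e", "v_over_f")

        def predict(theta):
            ka, ke, v = theta
            if abs(ka - ke) < 1e-12 * max(abs(ke), 1e-12):
                return dose_ug / v * ka * t * np.exp(-ka * t)
            return dose_ug / v * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))

        x0 = (
            np.array([init.k_a, init.k_e, init.v_over_f])
            if init is not None
            else _default_init_oral(t, c, dose_ug)
        )
    else:
        names = ("k_e", "v")

        def predict(theta):
            ke, v = theta
            return dose_ug / v * np.exp(-ke * t)

        x0 = (
            np.array([init.k_e, init.v_over_f])
            if init is not None
            else _default_init_iv(t, c, dose_ug)
        )

    def residual(theta):
        return sqrt_w * (c - predict(theta))

    res = _run_lm(residual, x0, len(t))
    theta = res.x
    wrss = float(np.sum(res.fun**2))
    converged = bool(res.success and np.all(np.isfinite(theta)))

    flipped = False
    if oral and converged and 0 < theta[0] < theta[1]:
        # flip-flop: (k_a, k_e, V/F) and (k_e, k_a, V/F·k_e/k_a) trace the
        # same curve; canonicalise to k_a > k_e
        ka, ke, v = theta
        theta = np.array([ke, ka, v * ke / ka])
        flipped = True
        res = _run_lm(residual, theta, len(t))  # re-polish at the canonical branch
        theta = res.x
        wrss = float(np.sum(res.fun**2))

    se, ci, sig = _asymptotic_ci(res.jac, wrss, len(t), p, theta)
    return FitResult(
        model="one_compartment",
        series=series,
        param_names=names,
        estimates=tuple(float(x) for x in theta),
        se=se,
        ci95=ci,
        significant=sig,
        wrss=wrss,
        n_obs=len(t),
        n_excluded=n_excluded,
        converged=converged,
        n_iter=int(res.nfev),
        weighting=weighting,
        flipped=flipped,
    )


def fit_two_compartment_comparator(
    series: ConcentrationSeries, weighting: Weighting = "inverse_observed"
) -> FitResult:
    """Fit a two-compartment disposition model under the same weighting.

    i.v.: C(t) = C₁e^(−λ₁t) + C₂e^(−λ₂t) (4 parameters).
    oral: C(t) = C₁e^(−λ₁t) + C₂e^(−λ₂t) − (C₁+C₂)e^(−k_a t) (5 parameters,
    constrained so that C(0) = 0).

    Exists so :func:`compute_aic` can rank it against the one-compartment
    model; its parameters have no TKParameters representation.
    """
    t, c, sqrt_w, n_excluded = _prepare(series, weighting)
    oral = series.route == "oral"
    p = 5 if oral else 4
    if len(t) <= p:
        raise ValueError(
            f"{series.subject_id}: {len(t)} usable observations cannot support "
            f"a {p}-parameter fit"
        )

    one = fit_one_compartment(series, weighting=weighting)
    if oral:
        names = ("k_a", "c1", "lambda1", "c2", "lambda2")
        ka0, ke0 = one["k_a"], one["k_e"]
        dose_amp = series.dose.amount_ug_per_kg / one["v_over_f"]
        amp0 = dose_amp * ka0 / (ka0 - ke0) if abs(ka0 - ke0) > 1e-9 else dose_amp
        x0 = np.array([ka0, 0.8 * amp0, ke0, 0.2 * amp0, 3.0 * ke0])

        def predict(theta):
            ka, c1, l1, c2, l2 = theta
            return (
                c1 * np.exp(-l1 * t)
                + c2 * np.exp(-l2 * t)
                - (c1 + c2) * np.exp(-ka * t)
            )

    else:
        names = ("c1", "lambda1", "c2", "lambda2")
        ke0 = one["k_e"]
        c0 = series.dose.amount_ug_per_kg / one["v"]
        x0 = np.array([0.7 * c0, ke0, 0.3 * c0, 4.0 * ke0])

        def predict(theta):
            c1, l1, c2, l2 = theta
            return c1 * np.exp(-l1 * t) + c2 * np.exp(-l2 * t)

    def residual(theta):
        return sqrt_w * (c - predict(theta))

    res = _run_lm(residual, x0, len(t))
    theta = res.x
    wrss = float(np.sum(res.fun**2))
    converged = bool(res.success and np.all(np.isfinite(theta)))
    se, ci, sig = _asymptotic_ci(res.jac, wrss, len(t), p, theta)
    return FitResult(
        model="two_compartment",
        series=series,
        param_names=names,
        estimates=tuple(float(x) for x in theta),
        se=se,
        ci95=ci,
        significant=sig,
        wrss=wrss,
        n_obs=len(t),
        n_excluded=n_excluded,
        converged=converged,
        n_iter=int(res.nfev),
        weighting=weighting,
    )


def compute_aic(fit: FitResult) -> float:
    """AIC = n·ln(WRSS) + 2p — the convention of classical pharmacokinetic
    fitting software; lower is better, only differences are meaningful."""
    if fit.wrss <= 0:
        warnings.warn("WRSS is zero (perfect fit); AIC reported as -inf")
        return -math.inf
    return fit.n_obs * math.log(fit.wrss) + 2 * fit.n_params


def compute_relative_bioavailability(
    po: FitResult | float,
    iv_reference_auc: float,
    doses: tuple[float, float],
) -> BioavailabilityResult:
    """F = (AUC_po/dose_po) / (AUC_iv/dose_iv).

    ``po`` is either an oral FitResult (its compartmental AUC is used) or an
    AUC value directly; ``iv_reference_auc`` is typically the group-mean i.v.
    AUC; ``doses`` is (oral, i.v.) in mg kg⁻¹ bw. Values of F above 1 can
    only arise from estimation noise and are flagged.
    """
    auc_po = po.auc if isinstance(po, FitResult) else float(po)
    dose_po, dose_iv = doses
    if iv_reference_auc <= 0:
        raise ValueError("reference i.v. AUC must be positive")
    if auc_po <= 0 or dose_po <= 0 or dose_iv <= 0:
        raise ValueError("AUCs and doses must be positive")
    f = (auc_po / dose_po) / (iv_reference_auc / dose_iv)
    return BioavailabilityResult(
        f=f,
        auc_po=auc_po,
        auc_iv_reference=iv_reference_auc,
        dose_po=dose_po,
        dose_iv=dose_iv,
        exceeds_one=f > 1.0,
    )


def _fit_row(fit: FitResult) -> dict:
    s = fit.series
    row = {
        "subject_id": s.subject_id,
        "sex": s.sex,
        "label": s.label,
        "route": s.route,
        "dose_mg_per_kg": s.dose.amount,
        "model": fit.model,
        "converged": fit.converged,
        "wrss": fit.wrss,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
    }
    for name, est, se in zip(fit.param_names, fit.estimates, fit.se):
        row[name] = est
        row[f"se_{name}"] = se
    if fit.model == "one_compartment" and fit.converged:
        row["auc"] = fit.auc
        row["elimination_half_life_min"] = half_life(fit["k_e"])
        if s.route == "oral":
            row["absorption_half_life_min"] = half_life(fit["k_a"])
    return row


def summarize_group(
    fits: Sequence[FitResult],
    by: Sequence[str] = ("route", "dose_mg_per_kg", "label", "sex"),
) -> pd.DataFrame:
    """Group summaries: mean, SD (n−1), min, max per kinetic quantity.

    Non-converged fits are kept in the table (flagged) but excluded from the
    summary statistics; empty groups after that exclusion are skipped with a
    warning.
    """
    rows = [_fit_row(f) for f in fits]
    df = pd.DataFrame(rows)
    conv = df[df["converged"]]
    if conv.empty:
        warnings.warn("no converged fits to summarise")
        return pd.DataFrame()
    dropped = len(df) - len(conv)
    if dropped:
        warnings.warn(f"{dropped} non-converged fit(s) excluded from group summary")
    value_cols = [
        col
        for col in (
            "k_a",
            "k_e",
            "v_over_f",
            "v",
            "auc",
            "absorption_half_life_min",
            "elimination_half_life_min",
        )
        if col in conv.columns
    ]
    agg = conv.groupby(list(by), dropna=False)[value_cols].agg(
        ["mean", "std", "min", "max", "count"]
    )
    return agg
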