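"""Closed-form one-compartment concentration curves and derived quantities.

The model treats the body as a single well-mixed compartment. After an
intravenous bolus the blood concentration decays monoexponentially; after an
oral dose it follows the Bateman curve of first-order absorption (rate
constant ``k_a``) and first-order elimination (rate constant ``k_e``).
Rate constants are stored in h⁻¹ throughout; half-lives are reported in
minutes, matching the convention of toxicokinetic study reports.

These functions serve double duty: as model functions for the nonlinear
fitting in :mod:`tkburden.fit`, and as the continuous-time oracle for the
discrete body-burden simulator in :mod:`tkburden.burden`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Route",
    "TKParameters",
    "DoseSpec",
    "iv_concentration",
    "oral_concentration",
    "half_life",
    "time_of_cmax",
    "cmax",
    "model_auc",
]

Route = Literal["iv", "oral"]

#: Relative |k_a - k_e| / k_e below which the Bateman curve switches to its
#: analytic k_a -> k_e limit (removable singularity).
_EQUAL_RATE_RTOL = 1e-8


@dataclass(frozen=True)
class TKParameters:
    """A subject's kinetic constants.

    Parameters
    ----------
    k_e
        First-order elimination rate constant, h⁻¹. Must be positive.
    k_a
        First-order absorption rate constant, h⁻¹. Required (and positive)
        for the oral route; ``None`` for intravenous dosing.
    v_over_f
        Apparent volume of distribution divided by bioavailability, in
        ml per kg body weight. After an i.v. dose bioavailability is 1 by
        definition, so the value stored is the volume of distribution itself.
    route
        ``"iv"`` or ``"oral"``.
    """

    k_e: float
    v_over_f: float
    route: Route
    k_a: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ("iv", "oral"):
            raise ValueError(f"unknown route {self.route!r}")
        if not self.k_e > 0:
            raise ValueError(f"k_e must be positive, got {self.k_e}")
        if not self.v_over_f > 0:
            raise ValueError(f"v_over_f must be positive, got {self.v_over_f}")
        if self.route == "oral":
            if self.k_a is None or not self.k_a > 0:
                raise ValueError("oral route requires k_a > 0")


@dataclass(frozen=True)
class DoseSpec:
    """An administered dose: amount in mg active ingredient per kg bw."""

    amount: float
    route: Route

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose must be positive, got {self.amount}")
        if self.route not in ("iv", "oral"):
            raise ValueError(f"unknown route {self.route!r}")

    @property
    def amount_ug_per_kg(self) -> float:
        return self.amount * 1000.0


def _check_times(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("time must be non-negative")


def iv_concentration(
    params: TKParameters, dose: DoseSpec, t: float | np.ndarray
) -> float | np.ndarray:
    """Blood concentration (µg ml⁻¹) after an i.v. bolus: (dose/V)·e^(−k_e·t).

    ``t`` is in hours; scalar or array. Raises on negative times or a route
    mismatch.
    """
    if params.route != "iv" or dose.route != "iv":
        raise ValueError("iv_concentration requires i.v. parameters and dose")
    t_arr = np.asarray(t, dtype=float)
    _check_times(t_arr)
    c0 = dose.amount_ug_per_kg / params.v_over_f
    out = c0 * np.exp(-params.k_e * t_arr)
    return float(out) if np.isscalar(t) else out


def oral_concentration(
    params: TKParameters, dose: DoseSpec, t: float | np.ndarray
) -> float | np.ndarray:
    """Blood concentration (µg ml⁻¹) after an oral dose (Bateman curve).

    C(t) = (dose/(V/F)) · k_a/(k_a−k_e) · (e^(−k_e·t) − e^(−k_a·t))

    At the removable singularity k_a = k_e the analytic limit
    (dose/(V/F)) · k·t·e^(−k·t) is used instead.
    """
    if params.route != "oral" or dose.route != "oral":
        raise ValueError("oral_concentration requires oral parameters and dose")
    t_arr = np.asarray(t, dtype=float)
    _check_times(t_arr)
    ka, ke = params.k_a, params.k_e
    scale = dose.amount_ug_per_kg / params.v_over_f
    if abs(ka - ke) / ke < _EQUAL_RATE_RTOL:
        out = scale * ka * t_arr * np.exp(-ka * t_arr)
    else:
        out = scale * ka / (ka - ke) * (np.exp(-ke * t_arr) - np.exp(-ka * t_arr))
    return float(out) if np.isscalar(t) else out


def half_life(k: float) -> float:
    """Half-life in minutes for a first-order rate constant ``k`` in h⁻¹.

    60·ln(2)/k; report to one decimal when formatting.
    """
    if not k > 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return 60.0 * math.log(2.0) / k


def time_of_cmax(params: TKParameters) -> float:
    """Time (h) of the peak of the oral curve: ln(k_a/k_e)/(k_a − k_e).

    Symmetric under exchanging k_a and k_e; at k_a = k_e the analytic limit
    1/k applies. For i.v. parameters the maximum is at t = 0.
    """
    if params.route == "iv":
        return 0.0
    ka, ke = params.k_a, params.k_e
    if abs(ka - ke) / ke < _EQUAL_RATE_RTOL:
        return 1.0 / ka
    return math.log(ka / ke) / (ka - ke)


def cmax(params: TKParameters, dose: DoseSpec) -> tuple[float, float]:
    """(C_max µg ml⁻¹, t_max h). For i.v. this is the boundary (C(0), 0)."""
    if params.route == "iv":
        return iv_concentration(params, dose, 0.0), 0.0
    tmax = time_of_cmax(params)
    return oral_concentration(params, dose, tmax), tmax


def model_auc(params: TKParameters, dose: DoseSpec) -> float:
    """Compartmental area under the curve from 0 to ∞, in h·µg ml⁻¹.

    i.v.: dose/(V·k_e); oral: dose/((V/F)·k_e). Equal to the closed-form
    integral of the corresponding concentration curve.
    """
    if params.route != dose.route:
        raise ValueError("route mismatch between parameters and dose")
    return dose.amount_ug_per_kg / (params.v_over_f * params.k_e)
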