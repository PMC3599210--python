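"""Synthetic ADME-study generator.

The rat ADME study behind this package is unpublished, so analyses are
exercised on synthetic datasets that emulate its design: groups of three
males and three females dosed intravenously at 0.5 mg kg⁻¹ bw or orally at
0.5 / 100 mg kg⁻¹ bw (two radiolabel positions, kinetically inert), blood
sampled at 0.25, 0.5, 1, 2, 4, 8, 12, 24 and 48 h. Individual rate constants
are drawn from moment-matched lognormal distributions whose natural-scale
means and SDs default to the study's published group summaries
(:data:`STUDY_GROUP_SUMMARY`); measurement noise is proportional
(lognormal, default CV 10 %), and values below the quantification limit are
censored to zero.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fit import ConcentrationSeries
from .model import DoseSpec, TKParameters, iv_concentration, oral_concentration

__all__ = [
    "STUDY_GROUP_SUMMARY",
    "GroupSpec",
    "StudyDesign",
    "GroupDistributions",
    "PopulationSpec",
    "Individual",
    "default_design",
    "default_population",
    "sample_individuals",
    "generate_series",
    "generate_tissue_panel",
    "generate_study",
    "STUDY_SAMPLING_TIMES_H",
]

#: Blood sampling schedule of the ADME study, hours post-dose.
STUDY_SAMPLING_TIMES_H = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)

#: Published per-group summary statistics (mean, SD on the natural scale)
#: from the rat thiamethoxam ADME study: absorption and elimination rate
#: constants (h⁻¹), AUC (h·µg ml⁻¹) and, for oral groups, relative
#: bioavailability. Keys: (route, dose mg/kg, radiolabel tag, sex).
STUDY_GROUP_SUMMARY: dict[tuple, dict[str, tuple[float, float]]] = {
    ("iv", 0.5, "thiazol", "male"): {"k_e": (0.26, 0.02), "auc": (2.30, 0.19)},
    ("iv", 0.5, "thiazol", "female"): {"k_e": (0.50, 0.11), "auc": (1.63, 0.38)},
    ("oral", 0.5, "thiazol", "male"): {
        "k_a": (2.1, 1.62), "k_e": (0.23, 0.09), "auc": (1.49, 0.15), "f": (0.62, 0.11)},
    ("oral", 0.5, "thiazol", "female"): {
        "k_a": (2.3, 1.93), "k_e": (0.23, 0.13), "auc": (1.56, 0.53), "f": (0.94, 0.27)},
    ("oral", 0.5, "oxadiazin", "male"): {
        "k_a": (1.20, 0.93), "k_e": (0.34, 0.034), "auc": (1.30, 0.015), "f": (0.67, 0.01)},
    ("oral", 0.5, "oxadiazin", "female"): {
        "k_a": (3.2, 0.29), "k_e": (0.25, 0.06), "auc": (1.03, 0.13), "f": (0.75, 0.12)},
    ("oral", 100.0, "thiazol", "male"): {
        "k_a": (0.78, 0.32), "k_e": (0.28, 0.12), "auc": (342.0, 80.0), "f": (0.84, 0.21)},
    ("oral", 100.0, "thiazol", "female"): {
        "k_a": (1.6, 0.71), "k_e": (0.18, 0.06), "auc": (278.0, 59.0), "f": (0.94, 0.22)},
    ("oral", 100.0, "oxadiazin", "male"): {
        "k_a": (0.71, 0.73), "k_e": (0.25, 0.11), "auc": (359.0, 50.0), "f": (0.80, 0.11)},
    ("oral", 100.0, "oxadiazin", "female"): {
        "k_a": (2.00, 1.37), "k_e": (0.19, 0.06), "auc": (294.0, 24.0), "f": (0.96, 0.11)},
}


@dataclass(frozen=True)
class GroupSpec:
    route: str
    dose: float  # mg a.i. kg⁻¹ bw
    label: str  # radiolabel tag, kinetically inert
    n_males: int = 3
    n_females: int = 3

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one animal per sex")


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple[GroupSpec, ...]
    sampling_times_h: tuple[float, ...] = STUDY_SAMPLING_TIMES_H
    loq: float = 0.005  # µg ml⁻¹, below which values are censored to zero
    noise_cv: float = 0.10  # proportional measurement noise

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times_h)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class GroupDistributions:
    """Natural-scale (mean, SD) for each kinetic parameter of one group."""

    k_e: tuple[float, float]
    v_over_f: tuple[float, float]
    k_a: tuple[float, float] | None = None


@dataclass(frozen=True)
class PopulationSpec:
    """Per-group parameter distributions (lognormal via moment matching)."""

    groups: Mapping[tuple, GroupDistributions]

    def for_group(self, g: GroupSpec, sex: str) -> GroupDistributions:
        return self.groups[(g.route, g.dose, g.label, sex)]


@dataclass(frozen=True)
class Individual:
    subject_id: str
    sex: str
    label: str
    dose: DoseSpec
    params: TKParameters


def default_design() -> StudyDesign:
    """The study layout: one i.v. group and four oral groups of 3M + 3F."""
    return StudyDesign(
        groups=(
            GroupSpec("iv", 0.5, "thiazol"),
            GroupSpec("oral", 0.5, "thiazol"),
            GroupSpec("oral", 0.5, "oxadiazin"),
            GroupSpec("oral", 100.0, "thiazol"),
            GroupSpec("oral", 100.0, "oxadiazin"),
        )
    )


def default_population() -> PopulationSpec:
    """Distribution defaults from the published group summaries.

    V/F is never printed in study summaries, so its mean is derived from the
    compartmental identity V/F = dose / (AUC · k_e) applied to the group-mean
    AUC and k_e, and its coefficient of variation is taken from the AUC (the
    AUC spread at a common dose is, to first order, the V/F spread).
    """
    groups = {}
    for key, s in STUDY_GROUP_SUMMARY.items():
        route, dose, _, _ = key
        ke_m, ke_s = s["k_e"]
        auc_m, auc_s = s["auc"]
        v_mean = dose * 1000.0 / (auc_m * ke_m)  # ml per kg bw
        v_sd = v_mean * (auc_s / auc_m)
        groups[key] = GroupDistributions(
            k_e=(ke_m, ke_s),
            v_over_f=(v_mean, v_sd),
            k_a=s.get("k_a"),
        )
    return PopulationSpec(groups=groups)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draw with the requested natural-scale mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("lognormal moments require mean > 0 and sd >= 0")
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def sample_individuals(
    spec: PopulationSpec, design: StudyDesign, seed: int
) -> list[Individual]:
    """Draw one parameter set per animal, deterministically for a seed."""
    rng = np.random.default_rng(seed)
    out: list[Individual] = []
    counter = 0
    for g in design.groups:
        for sex, n in (("male", g.n_males), ("female", g.n_females)):
            dist = spec.for_group(g, sex)
            for _ in range(n):
                counter += 1
                ke = float(_lognormal(rng, *dist.k_e))
                v = float(_lognormal(rng, *dist.v_over_f))
                if g.route == "oral":
                    if dist.k_a is None:
                        raise ValueError(f"group {g} lacks a k_a distribution")
                    ka = float(_lognormal(rng, *dist.k_a))
                    params = TKParameters(k_a=ka, k_e=ke, v_over_f=v, route="oral")
                else:
                    params = TKParameters(k_e=ke, v_over_f=v, route="iv")
                out.append(
                    Individual(
                        subject_id=f"R{counter:03d}",
                        sex=sex,
                        label=g.label,
                        dose=DoseSpec(g.dose, g.route),
                        params=params,
                    )
                )
    return out


def _true_curve(params: TKParameters, dose: DoseSpec, t: np.ndarray) -> np.ndarray:
    if params.route == "iv":
        return iv_concentration(params, dose, t)
    return oral_concentration(params, dose, t)


def generate_series(
    individual: Individual, design: StudyDesign, seed_or_rng: int | np.random.Generator
) -> ConcentrationSeries:
    """Sample one subject's concentration–time series.

    True curve × lognormal noise (CV = design.noise_cv); values below the
    LOQ are censored to zero, mirroring real late-time blood samples that
    fall under the quantification limit within 24 h at the low dose.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    t = np.asarray(design.sampling_times_h, dtype=float)
    c = _true_curve(individual.params, individual.dose, t)
    if design.noise_cv > 0:
        c = c * _lognormal(rng, 1.0, design.noise_cv, size=t.size)
    c = np.where(c < design.loq, 0.0, c)
    return ConcentrationSeries(
        subject_id=individual.subject_id,
        sex=individual.sex,
        label=individual.label,
        dose=individual.dose,
        times=tuple(t),
        concentrations=tuple(float(x) for x in c),
    )


def generate_tissue_panel(
    individual: Individual,
    partition_coeffs: Mapping[str, float],
    times_h: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tissue concentrations under the rapid-equilibrium assumption.

    Each tissue tracks blood scaled by a constant partition coefficient, so a
    noiseless tissue correlates perfectly with blood — the structural feature
    that justifies collapsing the body into a single blood compartment.
    """
    if any(v <= 0 for v in partition_coeffs.values()):
        raise ValueError("partition coefficients must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, dtype=float)
    blood = _true_curve(individual.params, individual.dose, t)
    data = {"time_h": t, "blood": blood}
    for tissue, coeff in partition_coeffs.items():
        c = coeff * blood
        if noise_cv > 0:
            c = c * _lognormal(rng, 1.0, noise_cv, size=t.size)
        data[tissue] = c
    return pd.DataFrame(data)


def generate_study(
    spec: PopulationSpec | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> list[ConcentrationSeries]:
    """Generate the full default study: 5 groups × 6 animals × 9 samples."""
    spec = spec or default_population()
    design = design or default_design()
    rng = np.random.default_rng(seed)
    individuals = sample_individuals(spec, design, seed=int(rng.integers(2**31 - 1)))
    return [generate_series(ind, design, rng) for ind in individuals]
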