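"""Synthetic cohorts of toe-extension trials with known ground truth.

No participant-level recordings are distributed with the reference
cohort, so testing the pipeline end to end requires a generator whose
statistical structure matches the published group summaries. The model
is deliberately minimal: a saturating-exponential rise

    force(t) = plateau * (1 - exp(-t / tau)) * (1 + eps_t),

with ``eps_t`` i.i.d. Normal(0, noise_cv) multiplicative fluctuation,
clipped at zero. This is the simplest shape exhibiting the features the
curve parameters are built to measure — a fast rise to a noisy plateau.
For a noiseless curve the 80%-of-peak crossing happens at

    t* = -tau * ln(1 - 0.8 * (1 - exp(-duration / tau)))

which tends to ``tau * ln 5`` (~1.609 * tau) as duration/tau grows, a
convenient analytic oracle for rise-time tests. A logistic rise is
available as an alternative shape.

Default group profiles are calibrated by back-solving plateau and tau
from the reference cohort's per-cell peak-force and rise-time summaries
(tau = rise_time / ln 5). This is a calibration of the generator, not a
claim about the real data-generating process. Between-subject
variability comes from the published SDs; the generator has no
within-subject trial repetition (the reference protocol recorded a
single trial per subject).

All randomness flows from explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from . import reference
from .io import ForceTrial, SubjectRecord

__all__ = [
    "GroupProfile",
    "Cohort",
    "default_profiles",
    "simulate_trial",
    "simulate_cohort",
    "induce_correlation",
    "noiseless_rise_time",
]

LN5 = math.log(5.0)

#: Default between-sample multiplicative fluctuation of the force signal.
DEFAULT_NOISE_CV = 0.05

#: Per-cell sample sizes consistent with the reference cohort margins
#: (17 older / 14 younger; 9 male / 22 female).
DEFAULT_CELL_N = {("older", "male"): 4, ("older", "female"): 13,
                  ("younger", "male"): 5, ("younger", "female"): 9}


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one (age group, sex) cell."""

    age_group: str
    sex: str
    n: int
    plateau_mean: float  # N
    plateau_sd: float  # N
    tau_mean: float  # s
    tau_sd: float  # s
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self) -> None:
        if self.plateau_mean <= 0 or self.tau_mean <= 0:
            raise ValueError("plateau_mean and tau_mean must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n < 0:
            raise ValueError("n must be non-negative")


class Cohort(NamedTuple):
    """A generated cohort with its ground-truth manifest."""

    trials: list[ForceTrial]
    subjects: list[SubjectRecord]
    manifest: pd.DataFrame  # subject_id, age_group, sex, true_plateau, true_tau, seed


def default_profiles(noise_cv: float = DEFAULT_NOISE_CV,
                     n_scale: int = 1) -> list[GroupProfile]:
    """Profiles calibrated to the reference cohort's per-cell summaries."""
    profiles = []
    for (age_group, sex), n in DEFAULT_CELL_N.items():
        peak_mean, peak_sd = reference.GROUP_SUMMARY["peak_N"][age_group][sex]
        rise_mean, rise_sd = reference.GROUP_SUMMARY["rise_time_s"][age_group][sex]
        profiles.append(
            GroupProfile(
                age_group=age_group,
                sex=sex,
                n=n * n_scale,
                plateau_mean=peak_mean,
                plateau_sd=peak_sd,
                tau_mean=rise_mean / LN5,
                tau_sd=rise_sd / LN5,
                noise_cv=noise_cv,
            )
        )
    return profiles


def noiseless_rise_time(tau: float, duration: float = 10.0) -> float:
    """Exact 80%-of-peak crossing time of the noiseless exponential curve.

    Approaches ``tau * ln 5`` when ``duration >> tau``.
    """
    return -tau * math.log1p(-0.8 * (1.0 - math.exp(-duration / tau)))


def _shape(t: np.ndarray, tau: float, kind: str) -> np.ndarray:
    if kind == "exponential":
        return 1.0 - np.exp(-t / tau)
    if kind == "logistic":
        # midpoint placed so the early rise roughly matches the exponential
        return 1.0 / (1.0 + np.exp(-(t - 2.0 * tau) / (tau / 2.0)))
    raise ValueError(f"unknown curve shape {kind!r}")


def simulate_trial(
    plateau: float,
    tau: float,
    noise_cv: float,
    seed: int,
    *,
    duration: float = 10.0,
    hz: float = 50.0,
    subject_id: str = "sim",
    shape: str = "exponential",
) -> ForceTrial:
    """One synthetic trial in newtons, deterministic given ``seed``.

    Samples are stamped at the end of each sampling interval
    (t = 1/hz, 2/hz, ..., duration), matching the device convention.
    """
    if plateau <= 0 or tau <= 0 or duration <= 0:
        raise ValueError("plateau, tau and duration must be positive")
    n = int(round(duration * hz))
    t = np.arange(1, n + 1) / hz
    base = plateau * _shape(t, tau, shape)
    rng = np.random.default_rng(seed)
    force = base * (1.0 + rng.normal(0.0, noise_cv, n)) if noise_cv > 0 else base
    force = np.clip(force, 0.0, None)
    return ForceTrial(
        subject_id=subject_id,
        time=t,
        force=force,
        unit="N",
        sampling_hz=hz,
        expected_samples=n,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0) -> float:
    """Resample until strictly above ``low`` (rejection sampling)."""
    if sd <= 0:
        if mean <= low:
            raise ValueError("degenerate truncated normal at or below bound")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    raise RuntimeError("truncated-normal sampling failed to converge")


def simulate_cohort(
    profiles: Iterable[GroupProfile],
    seed: int,
    *,
    duration: float = 10.0,
    hz: float = 50.0,
    shape: str = "exponential",
) -> Cohort:
    """Generate trials, subject records and a ground-truth manifest.

    Per profile, ``n`` subjects receive plateau and tau drawn from
    truncated normals; demographics come from the reference cohort's
    sex-stratified weight/height summaries (BMI computed as
    weight/height^2) and grip strength from the (age, sex) cell
    summary. Pure function of ``(profiles, seed)``.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    trials: list[ForceTrial] = []
    subjects: list[SubjectRecord] = []
    records: list[dict] = []
    counter = 0
    for profile in profiles:
        for _ in range(profile.n):
            counter += 1
            sid = f"S{counter:04d}"
            plateau = _truncated_normal(rng, profile.plateau_mean, profile.plateau_sd)
            tau = _truncated_normal(rng, profile.tau_mean, profile.tau_sd, low=1e-3)
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trial = simulate_trial(
                plateau, tau, profile.noise_cv, trial_seed,
                duration=duration, hz=hz, subject_id=sid, shape=shape,
            )
            w_mean, w_sd = reference.DEMOGRAPHICS_BY_SEX["weight_kg"][profile.sex]
            h_mean, h_sd = reference.DEMOGRAPHICS_BY_SEX["height_m"][profile.sex]
            g_mean, g_sd = reference.GROUP_SUMMARY["grip_strength_N"][profile.age_group][profile.sex]
            weight = _truncated_normal(rng, w_mean, w_sd)
            height = _truncated_normal(rng, h_mean, h_sd, low=0.5)
            grip = _truncated_normal(rng, g_mean, g_sd)
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    age_group=profile.age_group,
                    sex=profile.sex,
                    weight_kg=weight,
                    height_m=height,
                    bmi=weight / height**2,
                    grip_strength_N=grip,
                )
            )
            trials.append(trial)
            records.append(
                {"subject_id": sid, "age_group": profile.age_group,
                 "sex": profile.sex, "true_plateau": plateau, "true_tau": tau,
                 "seed": trial_seed}
            )
    return Cohort(trials, subjects, pd.DataFrame(records))


def induce_correlation(
    cohort: Cohort,
    rho: float,
    seed: int,
    covariate: str = "grip_strength_N",
) -> Cohort:
    """Regenerate a subject covariate as a rho-correlated Gaussian copy
    of the per-subject true plateau, preserving the covariate's marginal
    mean and SD. Lets tests target a known feature-covariate correlation.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    plateau = cohort.manifest["true_plateau"].to_numpy()
    if len(plateau) < 2 or plateau.std(ddof=1) == 0:
        raise ValueError("need at least two subjects with plateau variation")
    z1 = (plateau - plateau.mean()) / plateau.std(ddof=1)
    z2 = rng.standard_normal(len(plateau))
    current = np.array([getattr(s, covariate) for s in cohort.subjects], dtype=float)
    mean_c, sd_c = current.mean(), current.std(ddof=1)
    new = mean_c + sd_c * (rho * z1 + math.sqrt(1.0 - rho**2) * z2)
    new = np.clip(new, 0.0, None)  # strengths cannot be negative
    subjects = [replace(s, **{covariate: float(v)})
                for s, v in zip(cohort.subjects, new)]
    return Cohort(cohort.trials, subjects, cohort.manifest)
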