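"""Five-parameter characterization of a force-development curve.

The curve of an isometric toe-extension effort rises quickly and then
fluctuates around a plateau. Five parameters summarize it:

* **peak force** — the maximum sample (N);
* **rise time** — elapsed time from trial start to the first sample at
  or above 80% of the peak (s). The 80% cut-off reflects near-complete
  motor-unit recruitment at ~80% of maximum voluntary contraction and
  standardizes the rise-time definition across subjects;
* **average force after threshold** — mean force from that first 80%
  crossing (inclusive) to the end of the trial (N);
* **percent above average** — percentage of *all* samples in the trial
  at or above that average (%);
* **RFD** — rate of force development: 0.8·peak divided by the rise
  time (N/s).

Rise time treats each sample as the end of its sampling interval, so a
trial whose very first sample already exceeds the threshold gets a rise
time of one sampling interval (0.02 s at 50 Hz), never zero; this keeps
RFD finite and makes the result independent of whether the device
stamps its first sample at 0.00 s or 0.02 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ForceTrial, SubjectRecord

__all__ = [
    "STANDARD_GRAVITY",
    "CurveFeatures",
    "DegenerateTrialError",
    "to_newtons",
    "extract_features",
    "features_table",
]

#: Standard gravity, m/s^2, used to convert device kilograms to newtons.
STANDARD_GRAVITY = 9.80665

FEATURE_COLUMNS = (
    "subject_id",
    "peak_N",
    "rise_time_s",
    "avg_after80_N",
    "pct_above_avg",
    "rfd_N_per_s",
    "flags",
)


class DegenerateTrialError(ValueError):
    """The trial carries no positive force, so no features exist."""


@dataclass(frozen=True)
class CurveFeatures:
    """The five curve parameters extracted from one trial (forces in N)."""

    subject_id: str
    peak_N: float
    rise_time_s: float
    avg_after80_N: float
    pct_above_avg: float
    rfd_N_per_s: float
    flags: tuple[str, ...] = ()


def to_newtons(trial: ForceTrial, g: float = STANDARD_GRAVITY) -> ForceTrial:
    """Convert a kilogram-recorded trial to newtons; identity on N-trials."""
    if trial.unit == "N":
        return trial
    return replace(trial, force=trial.force * g, unit="N")


def extract_features(
    trial: ForceTrial, *, pct_reference: str = "post_threshold"
) -> CurveFeatures:
    """Extract the five curve parameters from a newton-unit trial.

    Parameters
    ----------
    trial
        A complete trial with ``unit == "N"``.
    pct_reference
        Which average anchors the percent-above-average parameter:
        ``"post_threshold"`` (the mean from the 80% crossing to the end;
        default) or ``"whole_trial"`` (the mean of all samples).

    Raises
    ------
    DegenerateTrialError
        If no sample is strictly positive.
    """
    if trial.unit != "N":
        raise ValueError("extract_features expects forces in newtons; "
                         "convert with to_newtons first")
    if pct_reference not in ("post_threshold", "whole_trial"):
        raise ValueError(f"unknown pct_reference {pct_reference!r}")

    force = trial.force
    peak = float(force.max())
    if peak <= 0:
        raise DegenerateTrialError(
            f"trial {trial.subject_id!r} has no positive force"
        )

    threshold = 0.8 * peak
    idx = int(np.argmax(force >= threshold))  # first crossing
    dt = trial.dt
    rise_time = float(trial.time[idx] - trial.time[0]) + dt

    flags: list[str] = []
    if idx == 0:
        flags.append("rise_floor")

    # compensated summation: the mean is correctly rounded, so the
    # >=-count below is reproducible even when samples sit at the mean
    avg_after = math.fsum(force[idx:]) / (force.size - idx)
    reference = (avg_after if pct_reference == "post_threshold"
                 else math.fsum(force) / force.size)
    if pct_reference == "whole_trial":
        flags.append("pct_vs_whole_trial_mean")
    pct_above = 100.0 * int(np.count_nonzero(force >= reference)) / force.size
    rfd = threshold / rise_time

    return CurveFeatures(
        subject_id=trial.subject_id,
        peak_N=peak,
        rise_time_s=rise_time,
        avg_after80_N=avg_after,
        pct_above_avg=pct_above,
        rfd_N_per_s=rfd,
        flags=tuple(flags),
    )


def features_table(
    trials: list[ForceTrial],
    subjects: list[SubjectRecord],
    *,
    g: float = STANDARD_GRAVITY,
    pct_reference: str = "post_threshold",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-trial curve parameters joined to subject demographics.

    Kilogram trials are converted to newtons with ``g`` first. Returns
    the joined table (one row per feature-bearing trial) and a list of
    ``(subject_id, reason)`` for degenerate trials, which are reported
    rather than silently dropped.

    Raises
    ------
    KeyError
        If a trial's subject_id has no subject record.
    """
    by_id = {s.subject_id: s for s in subjects}
    rows: list[dict] = []
    degenerate: list[tuple[str, str]] = []
    for trial in trials:
        if trial.subject_id not in by_id:
            raise KeyError(
                f"trial subject_id {trial.subject_id!r} not found in the subject table"
            )
        try:
            feats = extract_features(to_newtons(trial, g), pct_reference=pct_reference)
        except DegenerateTrialError as err:
            degenerate.append((trial.subject_id, str(err)))
            continue
        subj = by_id[trial.subject_id]
        rows.append(
            {
                "subject_id": feats.subject_id,
                "peak_N": feats.peak_N,
                "rise_time_s": feats.rise_time_s,
                "avg_after80_N": feats.avg_after80_N,
                "pct_above_avg": feats.pct_above_avg,
                "rfd_N_per_s": feats.rfd_N_per_s,
                "flags": ";".join(feats.flags),
                "age_group": subj.age_group,
                "sex": subj.sex,
                "weight_kg": subj.weight_kg,
                "height_m": subj.height_m,
                "bmi": subj.bmi,
                "grip_strength_N": subj.grip_strength_N,
            }
        )
    columns = list(FEATURE_COLUMNS) + [
        "age_group", "sex", "weight_kg", "height_m", "bmi", "grip_strength_N",
    ]
    return pd.DataFrame(rows, columns=columns), degenerate
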