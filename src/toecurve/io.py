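"""Reading and writing dynamometer trial files and subject tables.

A trial file is the raw output of a portable toe-extension dynamometer:
plain text, two numeric columns (time in seconds, force), sampled at
50 Hz for 10 s, so a complete trial has 500 rows. Force is recorded in
kilograms by the device; analysis converts to newtons downstream.

The only missingness these devices produce is a short gap at the *end*
of a trial (the recording stops a few samples early). Ingestion repairs
such gaps by last-value imputation, provided the gap is shorter than a
configured limit (default: strictly fewer than 10 samples). Interior
gaps or non-finite values are structural faults and are rejected.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IngestConfig",
    "ForceTrial",
    "SubjectRecord",
    "TrialParseError",
    "TrialStructureError",
    "EndGapError",
    "read_trial",
    "write_trial",
    "impute_tail",
    "read_subjects",
    "write_subjects",
    "trials_equal",
]

AGE_GROUPS = ("older", "younger")
SEXES = ("male", "female")

SUBJECT_COLUMNS = (
    "subject_id",
    "age_group",
    "sex",
    "weight_kg",
    "height_m",
    "bmi",
    "grip_strength_N",
)


class TrialParseError(ValueError):
    """A trial file contains a row that cannot be parsed."""


class TrialStructureError(ValueError):
    """A trial file parses but violates the expected structure."""


class EndGapError(ValueError):
    """The missing tail of a trial exceeds the configured end-gap limit."""


@dataclass(frozen=True)
class IngestConfig:
    """Settings for trial-file ingestion.

    Parameters
    ----------
    sampling_hz
        Nominal sampling rate of the device.
    expected_samples
        Number of samples in a complete trial.
    max_end_gap
        Strict upper bound on the number of trailing missing samples
        that may be imputed; a gap of ``max_end_gap`` or more is an error.
    hz_tolerance
        Relative deviation of the inferred sampling rate from
        ``sampling_hz`` above which a warning is emitted.
    default_unit
        Unit assumed for the force column when the file does not say.
    """

    sampling_hz: float = 50.0
    expected_samples: int = 500
    max_end_gap: int = 10
    hz_tolerance: float = 0.01
    default_unit: str = "kg"


@dataclass(frozen=True)
class ForceTrial:
    """One subject's force-time recording.

    ``time`` is strictly increasing and the same length as ``force``;
    after ingestion that length equals ``expected_samples``. ``unit`` is
    ``"kg"`` (device native) or ``"N"``.
    """

    subject_id: str
    time: np.ndarray
    force: np.ndarray
    unit: str = "kg"
    sampling_hz: float = 50.0
    expected_samples: int = 500
    imputed_count: int = 0
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "force", force)
        if self.unit not in ("kg", "N"):
            raise ValueError(f"unknown force unit {self.unit!r}")
        if time.ndim != 1 or force.ndim != 1:
            raise ValueError("time and force must be 1-D")
        if len(time) != len(force):
            raise ValueError(
                f"time ({len(time)}) and force ({len(force)}) lengths differ"
            )
        if len(time) == 0:
            raise ValueError("empty trial")
        if not np.all(np.diff(time) > 0):
            raise TrialStructureError("time is not strictly increasing")
        if not np.all(np.isfinite(force)):
            raise TrialStructureError("non-finite force values")
        if self.imputed_count < 0:
            raise ValueError("imputed_count must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.force)

    @property
    def dt(self) -> float:
        """Median sampling interval, in seconds."""
        if len(self.time) < 2:
            return 1.0 / self.sampling_hz
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        """Trial duration in seconds, counting each sample as an interval end."""
        return float(self.time[-1] - self.time[0]) + self.dt


def trials_equal(a: ForceTrial, b: ForceTrial, *, atol: float = 1e-6) -> bool:
    """True when two trials agree in metadata and numerically in data."""
    return (
        a.subject_id == b.subject_id
        and a.unit == b.unit
        and a.expected_samples == b.expected_samples
        and a.imputed_count == b.imputed_count
        and len(a.time) == len(b.time)
        and np.allclose(a.time, b.time, atol=atol, rtol=0)
        and np.allclose(a.force, b.force, atol=atol, rtol=0)
    )


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and grip strength for one participant."""

    subject_id: str
    age_group: str
    sex: str
    weight_kg: float
    height_m: float
    bmi: float
    grip_strength_N: float

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.bmi > 0:
            raise ValueError("bmi must be positive")
        if self.grip_strength_N < 0:
            raise ValueError("grip_strength_N must be non-negative")


def impute_tail(
    force: Sequence[float], expected_samples: int, max_end_gap: int
) -> tuple[np.ndarray, int]:
    """Fill a short end-of-trial gap with the last observed value.

    Returns the completed force array and the number of imputed samples.
    Raises :class:`EndGapError` when the gap is ``max_end_gap`` or longer,
    and :class:`ValueError` for empty input or over-long input.
    """
    arr = np.asarray(force, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot impute an empty trial")
    gap = expected_samples - arr.size
    if gap < 0:
        raise ValueError(
            f"trial has {arr.size} samples, more than expected {expected_samples}"
        )
    if gap == 0:
        return arr, 0
    if gap >= max_end_gap:
        raise EndGapError(
            f"end gap of {gap} samples reaches the limit of {max_end_gap}"
        )
    return np.concatenate([arr, np.full(gap, arr[-1])]), gap


_META_RE = re.compile(r"#\s*(\w+)\s*=\s*(\S+)")


def _parse_lines(path: Path) -> tuple[list[tuple[int, float, float]], dict[str, str]]:
    rows: list[tuple[int, float, float]] = []
    meta: dict[str, str] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _META_RE.match(line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            fields = line.split(",") if "," in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) < 2:
                raise TrialParseError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}"
                )
            try:
                t, f = float(fields[0]), float(fields[1])
            except ValueError:
                if not rows and not header_seen:
                    header_seen = True  # single optional header line
                    continue
                raise TrialParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            rows.append((lineno, t, f))
    return rows, meta


def read_trial(path: str | Path, config: IngestConfig | None = None) -> ForceTrial:
    """Parse a two-column trial text file and repair a short end gap.

    The delimiter (comma or whitespace) is auto-detected; one optional
    header line and ``#`` comment lines are skipped. ``# key=value``
    comments may carry ``subject_id`` and ``unit`` metadata. Trailing
    non-finite forces count as end-of-trial missingness; interior ones
    are structural errors.
    """
    config = config or IngestConfig()
    path = Path(path)
    rows, meta = _parse_lines(path)
    if not rows:
        raise TrialParseError(f"{path}: no data rows")

    time = np.array([r[1] for r in rows])
    force = np.array([r[2] for r in rows])

    # Trailing NaN/inf forces are device drop-outs at the end of the trial.
    finite = np.isfinite(force)
    n_trailing_bad = len(force) - (int(np.max(np.nonzero(finite)[0])) + 1 if finite.any() else 0)
    if n_trailing_bad:
        time, force, finite = time[:-n_trailing_bad], force[:-n_trailing_bad], finite[:-n_trailing_bad]
    if not finite.all():
        bad = int(np.nonzero(~finite)[0][0])
        raise TrialStructureError(
            f"{path}:{rows[bad][0]}: non-finite force in the interior of the trial"
        )
    if force.size == 0:
        raise TrialParseError(f"{path}: no finite force samples")
    if np.any(np.diff(time) <= 0):
        bad = int(np.nonzero(np.diff(time) <= 0)[0][0]) + 1
        raise TrialStructureError(
            f"{path}:{rows[bad][0]}: time not strictly increasing"
        )
    if len(force) > config.expected_samples:
        raise TrialStructureError(
            f"{path}: {len(force)} samples exceed expected {config.expected_samples}"
        )

    dt = float(np.median(np.diff(time))) if len(time) > 1 else 1.0 / config.sampling_hz
    inferred_hz = 1.0 / dt
    flags: list[str] = []
    if abs(inferred_hz - config.sampling_hz) / config.sampling_hz > config.hz_tolerance:
        warnings.warn(
            f"{path}: inferred sampling rate {inferred_hz:.2f} Hz deviates from "
            f"nominal {config.sampling_hz:g} Hz by more than "
            f"{config.hz_tolerance:.0%}",
            stacklevel=2,
        )
        flags.append("sampling_rate_mismatch")
    if time[0] <= dt / 2:
        flags.append("time_origin_zero")

    force, imputed = impute_tail(force, config.expected_samples, config.max_end_gap)
    if imputed:
        time = np.concatenate([time, time[-1] + dt * np.arange(1, imputed + 1)])
    elif "imputed_count" in meta:
        # a previously repaired trial records its provenance in the header
        imputed = int(meta["imputed_count"])

    unit = meta.get("unit", config.default_unit)
    subject_id = meta.get("subject_id", path.stem)
    return ForceTrial(
        subject_id=subject_id,
        time=time,
        force=force,
        unit=unit,
        sampling_hz=inferred_hz,
        expected_samples=config.expected_samples,
        imputed_count=imputed,
        flags=tuple(flags),
    )


def write_trial(trial: ForceTrial, path: str | Path) -> Path:
    """Write a trial as a two-column text file that round-trips through
    :func:`read_trial` (metadata carried in ``# key=value`` comments)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={trial.subject_id}\n")
        fh.write(f"# unit={trial.unit}\n")
        fh.write(f"# imputed_count={trial.imputed_count}\n")
        fh.write("time_s\tforce\n")
        for t, f in zip(trial.time, trial.force):
            fh.write(f"{t:.6f}\t{f:.6f}\n")
    return path


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read the subject metadata CSV into validated records."""
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate subject_id {sorted(set(dupes))}")
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            age_group=str(row.age_group),
            sex=str(row.sex),
            weight_kg=float(row.weight_kg),
            height_m=float(row.height_m),
            bmi=float(row.bmi),
            grip_strength_N=float(row.grip_strength_N),
        )
        for row in df.itertuples(index=False)
    ]


def write_subjects(subjects: Sequence[SubjectRecord], path: str | Path,
                   header_comment: str | None = None) -> Path:
    """Write subject records as CSV (inverse of :func:`read_subjects`)."""
    path = Path(path)
    df = pd.DataFrame([s.__dict__ for s in subjects], columns=list(SUBJECT_COLUMNS))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
    return path
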