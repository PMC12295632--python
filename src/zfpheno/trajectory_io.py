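"""Trajectory data model and I/O for the larval swim assay.

A trajectory is a per-well time series of (x, y) positions in millimetres
sampled at a fixed rate; a light schedule is the ordered list of
illumination epochs that structured the assay (the standard design is
three 30 s light / 30 s dark cycles, 180 s total, after dark acclimation;
t = 0 is the start of the recording, not of acclimation).

Coordinates are in mm with the well centre as origin; pixel calibration
and tracking are upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: Default sampling rate (samples/s). Always passed explicitly, never inferred.
DEFAULT_RATE_HZ = 25.0

#: Tolerance on inter-sample spacing, in seconds. A dropped frame is an
#: error rather than something to interpolate over, so that distance and
#: duration metrics keep exact semantics.
SAMPLING_TOL_S = 1e-6

GROUPS = ("control", "treated")
CONDITIONS = ("light", "dark")

TRACK_COLUMNS = ("well", "group", "t_s", "x_mm", "y_mm")


@dataclass(frozen=True)
class Trajectory:
    """One larva's tracked path: uniformly sampled positions in mm.

    Invariants (enforced at construction): strictly increasing times with
    uniform spacing 1/rate_hz within ``SAMPLING_TOL_S``; finite
    coordinates; at least two samples.
    """

    well_id: str
    group: str
    rate_hz: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.group not in GROUPS:
            raise ValidationError(
                f"well {self.well_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if not self.rate_hz > 0:
            raise ValidationError(f"well {self.well_id!r}: rate_hz must be positive")
        n = len(self.t)
        if n < 2:
            raise ValidationError(f"well {self.well_id!r}: need at least 2 samples, got {n}")
        if not (len(self.x) == len(self.y) == n):
            raise ValidationError(f"well {self.well_id!r}: t, x, y lengths differ")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"well {self.well_id!r}: non-finite values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValidationError(
                f"well {self.well_id!r}: time not strictly increasing at index {i + 1}"
            )
        expected = 1.0 / self.rate_hz
        dev = np.abs(dt - expected)
        if np.any(dev > SAMPLING_TOL_S):
            i = int(np.argmax(dev > SAMPLING_TOL_S))
            raise ValidationError(
                f"well {self.well_id!r}: non-uniform sampling at interval {i}: "
                f"dt={dt[i]:.9f} s, expected {expected:.9f} s (tol {SAMPLING_TOL_S} s)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        """Span covered by the sampling intervals."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, contiguous, alternating light/dark epochs starting at t = 0."""

    epochs: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        epochs = tuple((float(s), float(e), str(c)) for s, e, c in self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValidationError("schedule must contain at least one epoch")
        if abs(epochs[0][0]) > 1e-12:
            raise ValidationError("first epoch must start at t=0")
        prev_end = 0.0
        prev_cond: str | None = None
        for start, end, cond in epochs:
            if cond not in CONDITIONS:
                raise ValidationError(f"unknown condition {cond!r}")
            if abs(start - prev_end) > 1e-9:
                raise ValidationError("epochs must be contiguous and non-overlapping")
            if end <= start:
                raise ValidationError("epoch end must exceed its start")
            if cond == prev_cond:
                raise ValidationError("conditions must alternate between consecutive epochs")
            prev_end, prev_cond = end, cond

    @property
    def span_s(self) -> float:
        return self.epochs[-1][1]

    def condition_at(self, t: float | np.ndarray) -> np.ndarray:
        """Condition label for each time point (last epoch is right-closed)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([s for s, _, _ in self.epochs])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(self.epochs) - 1)
        labels = np.array([c for _, _, c in self.epochs])
        return labels[idx]

    def __iter__(self) -> Iterator[tuple[float, float, str]]:
        return iter(self.epochs)


@dataclass
class CohortDataset:
    """A plate's worth of trajectories under one light schedule."""

    larvae: list[Trajectory]
    schedule: LightSchedule
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [tr.well_id for tr in self.larvae]
        if len(set(ids)) != len(ids):
            dupes = sorted({w for w in ids if ids.count(w) > 1})
            raise ValidationError(f"duplicate well ids: {dupes}")
        span = self.schedule.span_s
        for tr in self.larvae:
            if tr.t[0] > 1e-6 or tr.t[-1] < span - 1e-6:
                raise ValidationError(
                    f"well {tr.well_id!r} does not span the schedule "
                    f"([{tr.t[0]:.3f}, {tr.t[-1]:.3f}] s vs {span:.3f} s)"
                )
        self.metadata.setdefault(
            "group_sizes",
            {g: sum(tr.group == g for tr in self.larvae) for g in GROUPS},
        )

    def by_group(self, group: str) -> list[Trajectory]:
        return [tr for tr in self.larvae if tr.group == group]


def standard_schedule(n_cycles: int = 3, light_s: float = 30.0, dark_s: float = 30.0) -> LightSchedule:
    """Alternating light-first schedule: ``n_cycles`` cycles of light then dark.

    The default (3, 30, 30) is the standard 180 s light/dark assay.
    """
    if n_cycles < 1 or light_s <= 0 or dark_s <= 0:
        raise ValidationError("n_cycles, light_s and dark_s must all be positive")
    epochs = []
    t = 0.0
    for _ in range(int(n_cycles)):
        epochs.append((t, t + light_s, "light"))
        t += light_s
        epochs.append((t, t + dark_s, "dark"))
        t += dark_s
    return LightSchedule(tuple(epochs))


def read_schedule(path: str | Path) -> LightSchedule:
    """Load a schedule from YAML: either n_cycles/light_s/dark_s or an epoch list."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise FormatError(f"{path}: schedule config must be a mapping")
    if "epochs" in cfg:
        return LightSchedule(tuple((e["start_s"], e["end_s"], e["condition"]) for e in cfg["epochs"]))
    try:
        return standard_schedule(cfg["n_cycles"], cfg["light_s"], cfg["dark_s"])
    except KeyError as exc:
        raise FormatError(f"{path}: schedule config missing key {exc}") from exc


def write_schedule(schedule: LightSchedule, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "epochs": [
            {"start_s": s, "end_s": e, "condition": c} for s, e, c in schedule.epochs
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def read_tracks(path: str | Path, rate_hz: float, schedule: LightSchedule | None = None,
                metadata: dict | None = None) -> CohortDataset:
    """Read a trajectory CSV (columns well, group, t_s, x_mm, y_mm) into a cohort.

    Rows are grouped by well (file order preserved) and time-sorted within
    each well; all Trajectory invariants are enforced. When ``schedule`` is
    omitted, a standard schedule spanning the common trajectory duration is
    not guessed — a 180 s standard schedule is used only if every well spans
    it; otherwise a ValidationError asks for an explicit schedule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["well", "t_s"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicated (well, t_s) row: well={row['well']!r}, t_s={row['t_s']}"
        )
    larvae = []
    for well, sub in df.groupby("well", sort=False):
        sub = sub.sort_values("t_s")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValidationError(f"{path}: well {well!r} has conflicting group labels {list(groups)}")
        larvae.append(
            Trajectory(
                well_id=str(well),
                group=str(groups[0]),
                rate_hz=float(rate_hz),
                t=sub["t_s"].to_numpy(),
                x=sub["x_mm"].to_numpy(),
                y=sub["y_mm"].to_numpy(),
            )
        )
    if schedule is None:
        schedule = standard_schedule()
    return CohortDataset(larvae=larvae, schedule=schedule, metadata=metadata or {})


def write_tracks(dataset: CohortDataset, path: str | Path) -> Path:
    """Write a cohort to the trajectory CSV schema, wells in input order.

    Times are written to 6 decimals (sub-microsecond, ample at any realistic
    frame rate); coordinates at full precision so read∘write round-trips to
    well below 1e-9 mm.
    """
    path = Path(path)
    frames = []
    for tr in dataset.larvae:
        frames.append(
            pd.DataFrame(
                {
                    "well": tr.well_id,
                    "group": tr.group,
                    "t_s": [format(v, ".6f") for v in tr.t],
                    "x_mm": [repr(float(v)) for v in tr.x],
                    "y_mm": [repr(float(v)) for v in tr.y],
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(TRACK_COLUMNS))
    out.to_csv(path, index=False)
    return path
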