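"""Regional TAC extraction and reference-tissue quantification.

Dynamic PET data are represented as frame-average, decay-corrected
regional concentrations (kBq/ml) on a contiguous frame schedule.
Binding is quantified two ways:

* reference-region Logan graphical analysis: ordinary least squares of
  ``Y_i = int_0^{t_i} C_T / C_T(t_i)`` against
  ``X_i = [int_0^{t_i} C_R (+ C_R(t_i)/k2_ref)] / C_T(t_i)`` over
  frames with mid-time >= t*, slope = DVR, BP_ND = DVR - 1. The
  ``C_R/k2_ref`` term is omitted by default and available as an option;
  with a late t* its influence is small, and the choice is recorded in
  the fit result rather than guessed silently.
* late-window ratio: duration-weighted mean of the target over the
  final window (default 30 min) divided by the same for the reference.

Integrals use frame-duration-weighted piecewise-constant integration,
which is exact for frame-average data. Inputs are assumed
decay-corrected to a common time origin; no decay correction is
performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .phantom_sim import Image4D

__all__ = [
    "FrameSchedule",
    "TAC",
    "LoganFit",
    "RatioResult",
    "dtbz_raclopride_schedule",
    "fdg_schedule",
    "total_duration",
    "extract_tacs",
    "cumulative_integral",
    "logan_bpnd",
    "ratio_last_window",
    "tacs_to_frame",
    "read_tacs_csv",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames (seconds)."""

    starts: tuple[float, ...]
    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        if starts.shape != durs.shape:
            raise InvalidSpecError("starts and durations must have equal length")
        if starts.size and np.any(durs <= 0):
            raise InvalidSpecError("frame durations must be > 0")
        if starts.size and not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise InvalidSpecError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations(cls, durations: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        durs = tuple(float(d) for d in durations)
        starts = tuple(t0 + float(s) for s in np.concatenate([[0.0], np.cumsum(durs)[:-1]])) if durs else ()
        return cls(starts, durs)

    @property
    def mid_times(self) -> np.ndarray:
        return np.asarray(self.starts) + np.asarray(self.durations) / 2.0

    @property
    def total_duration_s(self) -> float:
        if not self.durations:
            return 0.0
        return float(self.starts[-1] + self.durations[-1])

    def __len__(self) -> int:
        return len(self.durations)


def dtbz_raclopride_schedule() -> FrameSchedule:
    """16-frame, 60-min schedule: 4x60 s, 3x120 s, 8x300 s, 1x600 s."""
    return FrameSchedule.from_durations([60.0] * 4 + [120.0] * 3 + [300.0] * 8 + [600.0])


def fdg_schedule() -> FrameSchedule:
    """17-frame, 60-min schedule: 4x60 s, 3x120 s, 10x300 s."""
    return FrameSchedule.from_durations([60.0] * 4 + [120.0] * 3 + [300.0] * 10)


def total_duration(schedule: FrameSchedule) -> float:
    """Total acquisition duration in minutes."""
    return schedule.total_duration_s / 60.0


@dataclass
class TAC:
    """Frame-average regional time-activity curve (kBq/ml).

    ``fine`` optionally carries the fine-grid samples (t in s, values)
    from which a simulated curve was frame-averaged, so that forward
    models can convolve without re-interpolation.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region: str = ""
    fine: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schedule),):
            raise InvalidSpecError(
                f"TAC length {self.values.shape} does not match schedule with "
                f"{len(self.schedule)} frames"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpecError("TAC contains non-finite values")


@dataclass(frozen=True)
class LoganFit:
    """Reference-region Logan fit result; ``bp_nd = dvr - 1`` exactly."""

    dvr: float
    bp_nd: float
    intercept: float
    t_star: float
    n_points_used: int
    r_squared: float
    max_rel_residual: float
    k2_ref: float | None = None


@dataclass(frozen=True)
class RatioResult:
    """Late-window target/reference concentration ratio."""

    target_region: str
    reference_region: str
    window_start_min: float
    window_end_min: float
    ratio: float


# ---------------------------------------------------------------------------
# TAC extraction
# ---------------------------------------------------------------------------


def extract_tacs(img4d: Image4D, label_masks: Mapping[str, object]) -> dict[str, TAC]:
    """Per-frame region means from a dynamic image.

    ``label_masks`` maps region name to a Mask (or boolean array).
    Raises if a region selects no voxels, naming the region.
    """
    schedule = img4d.schedule
    out: dict[str, TAC] = {}
    for name, mask in label_masks.items():
        data = np.asarray(getattr(mask, "data", mask), dtype=bool)
        if data.shape != img4d.grid.shape:
            raise InvalidSpecError(f"mask shape mismatch for region {name!r}")
        if not data.any():
            raise InvalidSpecError(f"region {name!r} is empty")
        out[name] = TAC(
            schedule=schedule,
            values=img4d.values[data, :].mean(axis=0),
            region=name,
        )
    return out


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def cumulative_integral(tac: TAC, t: float | np.ndarray) -> float | np.ndarray:
    """Integral of the TAC from 0 to ``t`` (seconds), in kBq*s/ml.

    Piecewise-constant frame integration: full frames contribute
    value * duration, a partial frame contributes proportionally. Exact
    at frame boundaries for frame-average data.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise InvalidSpecError("integration time must be >= 0")
    total = tac.schedule.total_duration_s
    if np.any(t_arr > total + 1e-9):
        raise InvalidSpecError(
            f"integration time exceeds acquisition ({total} s)"
        )
    starts = np.asarray(tac.schedule.starts)
    durs = np.asarray(tac.schedule.durations)
    cum = np.concatenate([[0.0], np.cumsum(tac.values * durs)])
    idx = np.clip(np.searchsorted(starts, t_arr, side="right") - 1, 0, len(durs) - 1)
    partial = np.clip(t_arr - starts[idx], 0.0, durs[idx])
    out = cum[idx] + tac.values[idx] * partial
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Logan graphical analysis
# ---------------------------------------------------------------------------


def logan_bpnd(
    target: TAC,
    reference: TAC,
    t_star: float = 20.0,
    k2_ref: float | None = None,
) -> LoganFit:
    """Reference-region Logan fit over frames with mid-time >= t* (min).

    Slope of the ordinary-least-squares line is the distribution volume
    ratio (DVR); BP_ND = DVR - 1. Requires at least three frames past
    t* with strictly positive target values. ``max_rel_residual`` (the
    largest |residual| / |Y|) diagnoses whether t* is late enough for
    the plot to have linearized.
    """
    if len(target.schedule) != len(reference.schedule):
        raise InvalidSpecError("target and reference schedules differ")
    mids = target.schedule.mid_times
    sel = mids / 60.0 >= t_star - 1e-9
    n = int(sel.sum())
    if n < 3:
        raise InvalidSpecError(
            f"only {n} frames with mid-time >= t*={t_star} min; need >= 3"
        )
    ct = target.values[sel]
    if np.any(ct <= 0):
        raise InvalidSpecError("non-positive target values in the fit window")
    t_sel = mids[sel]
    int_t = np.asarray(cumulative_integral(target, t_sel)) / 60.0  # kBq*min/ml
    int_r = np.asarray(cumulative_integral(reference, t_sel)) / 60.0
    y = int_t / ct
    x = int_r / ct
    if k2_ref is not None:
        if k2_ref <= 0:
            raise InvalidSpecError("k2_ref must be > 0")
        x = x + reference.values[sel] / (k2_ref * ct)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    max_rel = float(np.max(np.abs(resid) / np.maximum(np.abs(y), 1e-30)))
    return LoganFit(
        dvr=float(slope),
        bp_nd=float(slope) - 1.0,
        intercept=float(intercept),
        t_star=float(t_star),
        n_points_used=n,
        r_squared=r2,
        max_rel_residual=max_rel,
        k2_ref=k2_ref,
    )


# ---------------------------------------------------------------------------
# Late-window ratio
# ---------------------------------------------------------------------------


def ratio_last_window(
    target: TAC, reference: TAC, window_minutes: float = 30.0
) -> RatioResult:
    """Duration-weighted target/reference ratio over the final window.

    Frames are selected by mid-time falling inside the last
    ``window_minutes`` of the acquisition.
    """
    total_s = target.schedule.total_duration_s
    window_s = window_minutes * 60.0
    if window_s > total_s + 1e-9:
        raise InvalidSpecError("window exceeds acquisition duration")
    mids = target.schedule.mid_times
    sel = mids >= total_s - window_s - 1e-9
    if not sel.any():
        raise InvalidSpecError("no frames with mid-time inside the window")
    durs = np.asarray(target.schedule.durations)[sel]
    t_mean = float(np.sum(target.values[sel] * durs) / durs.sum())
    r_mean = float(np.sum(reference.values[sel] * durs) / durs.sum())
    if r_mean <= 0:
        raise InvalidSpecError("reference mean over the window must be > 0")
    return RatioResult(
        target_region=target.region,
        reference_region=reference.region,
        window_start_min=(total_s - window_s) / 60.0,
        window_end_min=total_s / 60.0,
        ratio=t_mean / r_mean,
    )


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


def tacs_to_frame(tacs: Mapping[str, TAC]) -> pd.DataFrame:
    """Tidy table: region, frame_start_s, frame_duration_s, value_kbq_ml."""
    rows = []
    for name, tac in tacs.items():
        for t0, d, v in zip(tac.schedule.starts, tac.schedule.durations, tac.values):
            rows.append(
                {
                    "region": name,
                    "frame_start_s": t0,
                    "frame_duration_s": d,
                    "value_kbq_ml": v,
                }
            )
    return pd.DataFrame(rows)


def read_tacs_csv(path: str | Path) -> dict[str, TAC]:
    """Read TACs written by :func:`tacs_to_frame` (CSV)."""
    df = pd.read_csv(path)
    required = {"region", "frame_start_s", "frame_duration_s", "value_kbq_ml"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidSpecError(f"TAC CSV missing columns: {sorted(missing)}")
    out: dict[str, TAC] = {}
    for name, g in df.groupby("region", sort=False):
        g = g.sort_values("frame_start_s")
        schedule = FrameSchedule(
            tuple(g["frame_start_s"].astype(float)),
            tuple(g["frame_duration_s"].astype(float)),
        )
        out[str(name)] = TAC(schedule, g["value_kbq_ml"].to_numpy(float), str(name))
    return out
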