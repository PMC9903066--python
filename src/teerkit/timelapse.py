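"""Timelapse analytics: baseline-relative TEER trajectories, condition
summaries, and transient-response metrics.

Each chip is normalized against its own pre-exposure baseline fit (the T₋₁
measurement), which removes chip-to-chip baseline variation and is what makes
trajectories from different chips comparable.  Group summaries report mean,
SD and n of relative TEER per condition and timepoint, excluding chips whose
fit did not converge at that timepoint.  Transient metrics (time of nadir,
nadir value, endpoint recovery) distinguish a TNFα-like transient dip from a
sustained, combination-like barrier loss.

No significance testing lives here; the outputs are tidy tables suitable for
external statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TeerTrajectory",
    "GroupSummary",
    "TransientMetrics",
    "DoseOrderingReport",
    "normalize_to_baseline",
    "trajectories_from_fits",
    "summarize_groups",
    "summaries_to_frame",
    "transient_metrics",
    "dose_ordering_check",
]

logger = logging.getLogger(__name__)


@dataclass
class TeerTrajectory:
    """Per-chip TEER time course (hours relative to exposure).

    ``valid`` marks timepoints with a trustworthy (converged) fit.
    """

    chip_id: str
    times_h: np.ndarray
    teer: np.ndarray
    baseline_teer: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.teer = np.asarray(self.teer, dtype=float)
        if self.times_h.shape != self.teer.shape:
            raise ValueError("times and teer must have the same shape")
        if self.times_h.size and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.teer.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.teer.shape:
                raise ValueError("valid mask must match teer shape")


def normalize_to_baseline(traj: TeerTrajectory) -> TeerTrajectory:
    """Divide a trajectory by its own baseline TEER.

    The returned trajectory has ``baseline_teer == 1.0``, so normalization is
    idempotent.  A non-positive baseline is a degenerate chip and raises;
    callers building groups should exclude and log such chips (see
    :func:`summarize_groups`).
    """
    if not traj.baseline_teer > 0:
        raise ValueError(
            f"chip {traj.chip_id}: non-positive baseline TEER "
            f"({traj.baseline_teer}); cannot normalize"
        )
    return TeerTrajectory(
        chip_id=traj.chip_id,
        times_h=traj.times_h.copy(),
        teer=traj.teer / traj.baseline_teer,
        baseline_teer=1.0,
        valid=traj.valid.copy(),
    )


def trajectories_from_fits(fits: pd.DataFrame) -> list[TeerTrajectory]:
    """Build per-chip trajectories from a fit-results table.

    Expects columns ``chip_id, time_min, teer_ohm_cm2, converged``.  The
    baseline TEER is the fit at the latest pre-exposure time (time < 0); the
    trajectory itself contains the post-exposure timepoints in hours.
    """
    required = {"chip_id", "time_min", "teer_ohm_cm2", "converged"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fit table missing columns: {sorted(missing)}")
    out: list[TeerTrajectory] = []
    for chip_id, g in fits.groupby("chip_id", sort=True):
        g = g.sort_values("time_min")
        pre = g[g["time_min"] < 0]
        if pre.empty:
            logger.warning("chip %s has no pre-exposure baseline; skipped", chip_id)
            continue
        baseline = float(pre.iloc[-1]["teer_ohm_cm2"])
        post = g[g["time_min"] >= 0]
        out.append(
            TeerTrajectory(
                chip_id=str(chip_id),
                times_h=post["time_min"].to_numpy() / 60.0,
                teer=post["teer_ohm_cm2"].to_numpy(),
                baseline_teer=baseline,
                valid=post["converged"].to_numpy(dtype=bool),
            )
        )
    return out


@dataclass
class GroupSummary:
    """Per-condition summary of relative TEER over time."""

    kind: str
    dose: float
    table: pd.DataFrame  # columns: time_h, mean, sd, n

    @property
    def condition(self) -> tuple[str, float]:
        return (self.kind, self.dose)


def summarize_groups(
    trajectories: list[TeerTrajectory],
    condition_map: dict[str, tuple[str, float]],
) -> list[GroupSummary]:
    """Group chips by condition and summarize relative TEER per timepoint.

    Chips with a non-positive baseline are excluded (and logged); timepoints
    with a non-converged fit are excluded from that timepoint's n.
    """
    unmapped = [t.chip_id for t in trajectories if t.chip_id not in condition_map]
    if unmapped:
        raise ValueError(f"chips not present in condition_map: {unmapped}")

    rows = []
    for traj in trajectories:
        try:
            rel = normalize_to_baseline(traj)
        except ValueError as exc:
            logger.warning("excluding chip: %s", exc)
            continue
        kind, dose = condition_map[traj.chip_id]
        for t, v, ok in zip(rel.times_h, rel.teer, rel.valid):
            rows.append((kind, dose, float(t), float(v), bool(ok)))
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["kind", "dose", "time_h", "rel_teer", "ok"])
    df = df[df["ok"]]

    summaries = []
    for (kind, dose), g in df.groupby(["kind", "dose"], sort=True):
        agg = (
            g.groupby("time_h")["rel_teer"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )
        agg["sd"] = agg["sd"].fillna(0.0)  # n == 1 groups
        summaries.append(GroupSummary(kind=str(kind), dose=float(dose), table=agg))
    return summaries


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Concatenate group summaries into one tidy table."""
    frames = []
    for s in summaries:
        t = s.table.copy()
        t.insert(0, "dose_ng_ml", s.dose)
        t.insert(0, "kind", s.kind)
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["kind", "dose_ng_ml", "time_h", "mean", "sd", "n"])
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TransientMetrics:
    """Nadir and recovery of a relative trajectory.

    ``endpoint_recovery`` is the mean relative TEER in the final window
    divided by the nadir value; a ratio well above 1 indicates recovery,
    a ratio near 1 a sustained loss.
    """

    time_of_nadir_h: float
    nadir: float
    endpoint_recovery: float


def transient_metrics(
    rel_traj: TeerTrajectory, endpoint_window_h: float = 4.0
) -> TransientMetrics:
    """Nadir time/value and endpoint recovery of a relative trajectory.

    The endpoint is the mean of values within the final ``endpoint_window_h``
    hours of the trajectory.
    """
    ok = rel_traj.valid
    t = rel_traj.times_h[ok]
    v = rel_traj.teer[ok]
    if t.size < 3:
        raise ValueError("need at least 3 valid timepoints for transient metrics")
    i = int(np.argmin(v))
    nadir = float(v[i])
    in_window = t >= t[-1] - endpoint_window_h
    endpoint = float(np.mean(v[in_window]))
    return TransientMetrics(
        time_of_nadir_h=float(t[i]),
        nadir=nadir,
        endpoint_recovery=endpoint / nadir,
    )


@dataclass(frozen=True)
class DoseOrderingReport:
    """Whether group mean relative TEER decreases with dose at one timepoint."""

    kind: str
    time_h: float
    doses: tuple[float, ...]
    means: tuple[float, ...]
    non_increasing: bool
    tolerance: float


def dose_ordering_check(
    summaries: list[GroupSummary],
    time_h: float,
    kind: str | None = None,
    tolerance: float = 0.0,
) -> DoseOrderingReport:
    """Check that mean relative TEER is non-increasing in dose at ``time_h``.

    The summary timepoint closest to ``time_h`` is used for each group.
    ``tolerance`` allows small violations (e.g. noise or dose saturation).
    """
    if kind is None:
        kinds = {s.kind for s in summaries}
        if len(kinds) != 1:
            raise ValueError(
                f"summaries contain multiple scenario kinds {sorted(kinds)}; "
                "pass kind= explicitly"
            )
        kind = kinds.pop()
    groups = sorted(
        (s for s in summaries if s.kind == kind), key=lambda s: s.dose
    )
    doses, means = [], []
    for s in groups:
        idx = int(np.argmin(np.abs(s.table["time_h"].to_numpy() - time_h)))
        doses.append(s.dose)
        means.append(float(s.table["mean"].iloc[idx]))
    ok = all(means[i + 1] <= means[i] + tolerance for i in range(len(means) - 1))
    return DoseOrderingReport(
        kind=kind,
        time_h=time_h,
        doses=tuple(doses),
        means=tuple(means),
        non_increasing=ok,
        tolerance=tolerance,
    )
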