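"""Behavioral measures for the helping behavior test (HBT).

A free rat can release a trapped conspecific by opening a restrainer door;
openings count only if they precede the experimenter's half-way opening at
40 min (2400 s) of the 60 min session.  This module turns per-session records
and tracking tables into the study's behavioral measures: opener
classification, acquisition curves, velocity-filtered tracks, and
zone-around-the-restrainer occupancy metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Half-way door opening by the experimenter, s into the 3600 s session.
HALFWAY_S = 2400.0
SESSION_LENGTH_S = 3600.0

#: Velocity ceiling above which tracking samples are physically implausible.
MAX_PLAUSIBLE_VELOCITY_CM_S = 30.0


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangle around the restrainer; containment half-open
    ([x0, x1) x [y0, y1)) so adjacent zones partition the arena."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("degenerate zone (zero area)")

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


@dataclass
class MovementTrack:
    """Positions (t_s, x_cm, y_cm) sampled at a fixed rate for one session."""

    samples: pd.DataFrame  # columns t_s, x_cm, y_cm [, door_open]
    rat_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        t = self.samples["t_s"].to_numpy()
        if len(t) >= 2 and not (np.diff(t) > 0).all():
            raise ValueError("track times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        t = self.samples["t_s"].to_numpy()
        return float(t[-1] - t[0]) if len(t) >= 2 else 0.0

    def velocity(self) -> np.ndarray:
        """Speed (cm/s) by central differences; one-sided at the ends.

        Gaps from removed samples are handled by differencing across actual
        time stamps, never by interpolation.
        """
        t = self.samples["t_s"].to_numpy()
        x = self.samples["x_cm"].to_numpy()
        y = self.samples["y_cm"].to_numpy()
        if len(t) < 2:
            return np.zeros(len(t))
        vx = np.gradient(x, t)
        vy = np.gradient(y, t)
        return np.hypot(vx, vy)


def filter_velocity(
    track: MovementTrack, max_v: float = MAX_PLAUSIBLE_VELOCITY_CM_S
) -> MovementTrack:
    """Drop samples whose speed from the last retained sample exceeds
    *max_v* cm/s.

    The filter walks the track sequentially: a sample is dropped when its
    displacement from the previous retained sample implies a speed above the
    ceiling; the next sample is then judged against the retained sample across
    the gap (never against the dropped artifact, and never interpolated), so a
    single teleporting sample removes exactly itself.
    """
    t = track.samples["t_s"].to_numpy()
    x = track.samples["x_cm"].to_numpy()
    y = track.samples["y_cm"].to_numpy()
    keep = np.ones(len(t), dtype=bool)
    last = 0
    for i in range(1, len(t)):
        v = np.hypot(x[i] - x[last], y[i] - y[last]) / (t[i] - t[last])
        if v > max_v:
            keep[i] = False
        else:
            last = i
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "velocity filter: dropped %d/%d samples (> %.1f cm/s)",
            n_dropped, len(keep), max_v,
        )
    return MovementTrack(
        track.samples.loc[keep].reset_index(drop=True), track.rat_id, track.day
    )


def classify_openers(records: pd.DataFrame, final_k: int = 3) -> pd.Series:
    """Opener = opened the restrainer on ALL of the last *final_k* testing days.

    *records* has columns rat_id, day, opened_by_rat and optionally
    ``latched`` marking a final c-Fos day with a latched restrainer, which is
    excluded from the window.  Raises if any rat lacks a record for one of the
    final days.
    """
    rec = records.copy()
    if "latched" in rec.columns:
        rec = rec[~rec["latched"].astype(bool)]
    days = np.sort(rec["day"].unique())
    final_days = days[-final_k:]
    if len(final_days) < final_k:
        raise ValueError(f"fewer than {final_k} testing days present")
    out = {}
    for rat, grp in rec.groupby("rat_id"):
        sub = grp.set_index("day")
        missing = [d for d in final_days if d not in sub.index]
        if missing:
            raise ValueError(f"rat {rat!r} missing records for final days {missing}")
        out[rat] = bool(sub.loc[final_days, "opened_by_rat"].astype(bool).all())
    return pd.Series(out, name="opener")


def opening_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Per-day % door-openings and mean +/- SEM latency (cap convention).

    Latency on non-opening sessions is the 2400 s cap.
    """
    rec = records.copy()
    rec["opened_by_rat"] = rec["opened_by_rat"].astype(bool)
    if "latency_s" not in rec.columns:
        rec["latency_s"] = np.where(rec["opened_by_rat"], np.nan, HALFWAY_S)
    rec.loc[~rec["opened_by_rat"], "latency_s"] = HALFWAY_S
    rows = []
    for day, grp in rec.groupby("day"):
        lat = grp["latency_s"].astype(float)
        rows.append(
            {
                "day": day,
                "pct_openings": 100.0 * grp["opened_by_rat"].mean(),
                "n_tested": len(grp),
                "latency_mean": lat.mean(),
                "latency_sem": lat.sem() if len(lat) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("day").reset_index(drop=True)


def _entry_exit_counts(inside: np.ndarray) -> tuple[int, int]:
    if len(inside) == 0:
        return 0, 0
    d = np.diff(inside.astype(int))
    return int((d == 1).sum()), int((d == -1).sum())


def zone_metrics(
    track: MovementTrack, zone: Zone, bin: str = "per_session"
) -> pd.DataFrame:
    """Time-in-zone, entry count and mean velocity, per session or per minute.

    An entry is an out->in transition; a track that starts inside the zone has
    0 entries until it exits and re-enters.  Time-in-zone sums the sample
    intervals whose starting sample lies inside, so time in + time out equals
    the session duration exactly.
    """
    t = track.samples["t_s"].to_numpy()
    inside = zone.contains(track.samples["x_cm"], track.samples["y_cm"])
    v = track.velocity()
    if bin == "per_session":
        bins = np.zeros(len(t), dtype=int)
        starts = [t[0] if len(t) else 0.0]
    elif bin == "per_minute":
        bins = ((t - t[0]) // 60.0).astype(int) if len(t) else np.array([], int)
        starts = sorted(set(bins))
    else:
        raise ValueError("bin must be per_session or per_minute")
    dt = np.diff(t) if len(t) >= 2 else np.array([])
    rows = []
    for b in sorted(set(bins)) if len(t) else []:
        m = bins == b
        idx = np.where(m)[0]
        seg_inside = inside[idx]
        entries, _ = _entry_exit_counts(seg_inside)
        # interval i spans t[i]..t[i+1]; attribute it to the bin of its start
        iv = idx[idx < len(dt)]
        time_in = float(dt[iv][inside[iv]].sum()) if len(iv) else 0.0
        time_total = float(dt[iv].sum()) if len(iv) else 0.0
        rows.append(
            {
                "bin": b,
                "time_in_zone_s": time_in,
                "time_out_zone_s": time_total - time_in,
                "entries": entries,
                "mean_velocity_cm_s": float(v[m].mean()) if m.any() else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin", "time_in_zone_s", "time_out_zone_s", "entries",
            "mean_velocity_cm_s",
        ],
    )


def zone_entry_times(track: MovementTrack, zone: Zone, min_gap_s: float = 0.0):
    """Times of out->in transitions into *zone* (used to align photometry)."""
    t = track.samples["t_s"].to_numpy()
    inside = zone.contains(track.samples["x_cm"], track.samples["y_cm"])
    if len(t) == 0 or not inside.any():
        return np.array([])
    d = np.diff(inside.astype(int))
    times = t[1:][d == 1]
    if min_gap_s > 0 and len(times) > 1:
        kept = [times[0]]
        for ti in times[1:]:
            if ti - kept[-1] >= min_gap_s:
                kept.append(ti)
        times = np.asarray(kept)
    return times


def export_day_minute_tables(
    tracks: dict[tuple[str, int], MovementTrack],
    records: pd.DataFrame,
    zone: Zone,
) -> pd.DataFrame:
    """Tidy long table (rat, day, minute, velocity, time_in_zone[, door_state])
    for external mixed-model tooling."""
    rec = records.set_index(["rat_id", "day"]) if len(records) else None
    rows = []
    for (rat, day), track in sorted(tracks.items()):
        per_min = zone_metrics(track, zone, bin="per_minute")
        has_door = "door_open" in track.samples.columns
        for _, r in per_min.iterrows():
            row = {
                "rat_id": rat,
                "day": day,
                "minute": int(r["bin"]),
                "velocity_cm_s": r["mean_velocity_cm_s"],
                "time_in_zone_s": r["time_in_zone_s"],
            }
            if has_door:
                m = (track.samples["t_s"] - track.samples["t_s"].iloc[0]) // 60 == r["bin"]
                row["door_state"] = float(track.samples.loc[m, "door_open"].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def load_track(path, rat_id: str = "", day: int = 0) -> MovementTrack:
    """Read a tracking CSV with columns t_s, x_cm, y_cm [, door_open]."""
    df = pd.read_csv(path)
    for col in ("t_s", "x_cm", "y_cm"):
        if col not in df.columns:
            raise ValueError(f"track file lacks column {col!r}")
    return MovementTrack(df, rat_id=rat_id, day=day)


def load_sessions(path) -> pd.DataFrame:
    """Read a session CSV: rat_id, condition, day, opened_by_rat, latency_s."""
    df = pd.read_csv(path)
    for col in ("rat_id", "day", "opened_by_rat"):
        if col not in df.columns:
            raise ValueError(f"session file lacks column {col!r}")
    df["opened_by_rat"] = df["opened_by_rat"].astype(bool)
    bad = df["opened_by_rat"] & (df.get("latency_s", pd.Series(dtype=float)) > HALFWAY_S)
    if isinstance(bad, pd.Series) and bad.any():
        raise ValueError("opened sessions must have latency <= 2400 s")
    return df
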