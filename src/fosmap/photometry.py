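"""Two-channel fiber-photometry processing.

The calcium-dependent 470 nm channel and the calcium-independent 405 nm
(isosbestic) control share motion artifacts and slow drift.  The control is
fit to the signal by ordinary least squares over the whole session; the
residual, normalized by the session median of the raw signal, is the motion-
corrected dF/F.  Event-triggered averages (PSTHs) and the pre/post zone-entry
statistics operate on that trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TestResult, ttest_two_sample, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

SESSION_KINDS = ("ingroup", "outgroup", "empty_restrainer", "empty_arena")
EVENT_TYPES = ("zone_entry", "door_opening", "eating")


@dataclass
class PhotometrySession:
    """Synchronized two-channel trace with typed event times."""

    t: np.ndarray
    s470: np.ndarray
    s405: np.ndarray
    events: dict[str, np.ndarray] = field(default_factory=dict)
    in_zone: np.ndarray | None = None
    session_kind: str = "ingroup"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.s470 = np.asarray(self.s470, float)
        self.s405 = np.asarray(self.s405, float)
        if not (len(self.t) == len(self.s470) == len(self.s405)):
            raise ValueError("t, s470, s405 must have equal length")
        if self.in_zone is not None and len(self.in_zone) != len(self.t):
            raise ValueError("in_zone length mismatch")
        for kind, times in self.events.items():
            times = np.asarray(times, float)
            if len(times) and (times.min() < self.t[0] or times.max() > self.t[-1]):
                raise ValueError(f"{kind} events outside the session")
            self.events[kind] = np.sort(times)

    @property
    def sampling_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class PSTHResult:
    """Event-triggered average of dF/F around lag 0 = event time."""

    lags: np.ndarray
    mean: np.ndarray
    sem: np.ndarray       # NaN when n_events == 1
    n_events: int
    n_dropped: int = 0


def compute_dff(session: PhotometrySession) -> np.ndarray:
    """Motion-corrected dF/F.

    The 405 nm control is regressed onto the 470 nm signal by OLS over the
    whole session; dF/F = (s470 - fit) / median(s470).  A constant control
    cannot carry artifact information: the fit degenerates to the signal mean
    and a warning is logged.
    """
    s405, s470 = session.s405, session.s470
    if np.ptp(s405) == 0:
        logger.warning("constant 405 nm control; correction is mean-subtraction only")
        fitted = np.full_like(s470, s470.mean())
    else:
        slope, intercept = np.polyfit(s405, s470, 1)
        fitted = slope * s405 + intercept
    corrected = s470 - fitted
    denom = float(np.median(s470))
    if denom == 0:
        raise ValueError("median of s470 is zero; cannot normalize")
    return corrected / denom


def detect_zone_entries(
    in_zone: np.ndarray, t: np.ndarray, min_gap_s: float = 0.0
) -> np.ndarray:
    """Times where ``in_zone`` flips 0 -> 1 (first in-zone sample of each entry)."""
    in_zone = np.asarray(in_zone, bool)
    t = np.asarray(t, float)
    if len(in_zone) == 0 or not in_zone.any():
        return np.array([])
    d = np.diff(in_zone.astype(int))
    times = t[1:][d == 1]
    if min_gap_s > 0 and len(times) > 1:
        kept = [times[0]]
        for ti in times[1:]:
            if ti - kept[-1] >= min_gap_s:
                kept.append(ti)
        times = np.asarray(kept)
    return times


def event_psth(
    dff: np.ndarray,
    t: np.ndarray,
    events: np.ndarray,
    window: tuple[float, float] = (-10.0, 10.0),
) -> PSTHResult:
    """Average dF/F segments aligned at each event (lag 0 = event time).

    Events whose full window falls outside the session are dropped (logged).
    Dispersion is the SEM across events; undefined (NaN) for a single event.
    """
    t = np.asarray(t, float)
    dff = np.asarray(dff, float)
    events = np.asarray(events, float)
    dt = float(np.median(np.diff(t)))
    pre = int(round(-window[0] / dt))
    post = int(round(window[1] / dt))
    lags = np.arange(-pre, post + 1) * dt
    segments = []
    n_dropped = 0
    for ev in events:
        i = int(round((ev - t[0]) / dt))
        if i - pre < 0 or i + post >= len(t):
            n_dropped += 1
            continue
        segments.append(dff[i - pre: i + post + 1])
    if not segments:
        raise ValueError("no events with a full window inside the session")
    if n_dropped:
        logger.info("PSTH: dropped %d events with partial windows", n_dropped)
    seg = np.vstack(segments)
    mean = seg.mean(axis=0)
    if len(seg) > 1:
        sem = seg.std(axis=0, ddof=1) / np.sqrt(len(seg))
    else:
        sem = np.full_like(mean, np.nan)
    return PSTHResult(lags, mean, sem, len(seg), n_dropped)


def pre_post_entry_test(
    dff: np.ndarray, t: np.ndarray, events: np.ndarray
) -> TestResult:
    """Wilcoxon signed-rank of mean dF/F in the second before vs after entry.

    Per event, dF/F is averaged over [-1, 0) and (0, +1]; the paired test
    runs across events.  Needs >= 5 usable events (pool sessions otherwise).
    """
    t = np.asarray(t, float)
    dff = np.asarray(dff, float)
    dt = float(np.median(np.diff(t)))
    k = int(round(1.0 / dt))
    pre_means, post_means = [], []
    for ev in np.asarray(events, float):
        i = int(round((ev - t[0]) / dt))
        if i - k < 0 or i + k >= len(t):
            continue
        pre_means.append(dff[i - k: i].mean())
        post_means.append(dff[i + 1: i + k + 1].mean())
    if len(pre_means) < 5:
        raise ValueError(
            f"only {len(pre_means)} usable events (< 5); pool sessions and retry"
        )
    return wilcoxon_signed_rank(np.asarray(pre_means), np.asarray(post_means))


def zone_occupancy_comparison(
    sessions: list[tuple[np.ndarray, np.ndarray]]
) -> TestResult:
    """Paired comparison of mean dF/F inside vs outside the zone across
    sessions.

    *sessions* is a list of (dff, in_zone) pairs; sessions with an empty zone
    side are dropped (logged).  The two-level repeated-measures comparison is
    the paired t (F = t^2 reported in extras).
    """
    inside, outside = [], []
    n_dropped = 0
    for dff, in_zone in sessions:
        in_zone = np.asarray(in_zone, bool)
        if not in_zone.any() or in_zone.all():
            n_dropped += 1
            continue
        inside.append(float(np.asarray(dff)[in_zone].mean()))
        outside.append(float(np.asarray(dff)[~in_zone].mean()))
    if n_dropped:
        logger.info("zone comparison: dropped %d one-sided sessions", n_dropped)
    if len(inside) < 2:
        raise ValueError("need >= 2 usable sessions")
    res = ttest_two_sample(np.asarray(inside), np.asarray(outside), paired=True)
    res.extras["F"] = res.statistic**2
    res.extras["df_F"] = (1, res.n - 1)
    res.extras["mean_inside"] = float(np.mean(inside))
    res.extras["mean_outside"] = float(np.mean(outside))
    return res


# ---------------------------------------------------------------------------
# I/O


def load_session(path, session_kind: str = "ingroup") -> PhotometrySession:
    """Read a session from HDF5 (datasets t, s470, s405 [, in_zone]) or CSV."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            in_zone = f["in_zone"][:] if "in_zone" in f else None
            return PhotometrySession(
                f["t"][:], f["s470"][:], f["s405"][:],
                in_zone=in_zone, session_kind=session_kind,
            )
    df = pd.read_csv(path)
    in_zone = df["in_zone"].to_numpy(bool) if "in_zone" in df.columns else None
    return PhotometrySession(
        df["t"].to_numpy(), df["s470"].to_numpy(), df["s405"].to_numpy(),
        in_zone=in_zone, session_kind=session_kind,
    )


def save_session(session: PhotometrySession, path) -> None:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=session.t)
            f.create_dataset("s470", data=session.s470)
            f.create_dataset("s405", data=session.s405)
            if session.in_zone is not None:
                f.create_dataset("in_zone", data=session.in_zone.astype(np.uint8))
        return
    cols = {"t": session.t, "s470": session.s470, "s405": session.s405}
    if session.in_zone is not None:
        cols["in_zone"] = session.in_zone.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def load_events(path) -> dict[str, np.ndarray]:
    """Read an event CSV with columns type, t_s."""
    df = pd.read_csv(path)
    return {
        kind: np.sort(grp["t_s"].to_numpy(float))
        for kind, grp in df.groupby("type")
    }
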