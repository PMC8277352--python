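"""Synthetic-data generators with the statistical structure the pipeline
assumes.

Every generator is a pure function of its spec (the seed included) and writes
the same file dialects the loaders read.  The activity generator produces
overdispersed counts with planted block-correlation modules and
condition-specific multiplicative effects; the behavior generator produces
acquisition curves (openers acquire door-opening and their latency decays)
and zone-biased random-walk tracks; the photometry generator produces a
two-channel trace with shared drift and motion artifact plus event-locked
calcium transients; the tracing generator plants a co-label/door-opening
correlation in one designated region.  Ground truth is returned alongside
(and written as sidecar JSON by the CLI) so that downstream recovery tests
can assert against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import HALFWAY_S, SESSION_LENGTH_S, MovementTrack, Zone
from .data import CONDITION_LABELS, ActivityDataset, REGION_CATEGORIES
from .photometry import PhotometrySession
from .tracing import TracingDataset

# ---------------------------------------------------------------------------
# Study-scale defaults

#: Per-condition group sizes.  The six social conditions sum to 46 subjects
#: (one-way ANOVA df = (5, 40)); the broad reference pool (brief + two-free +
#: trapped + baseline) sums to 48.
PAPER_N_PER_CONDITION = {
    "HBT_ingroup": 8,
    "HBT_outgroup": 8,
    "brief_ingroup": 8,
    "brief_outgroup": 7,
    "two_free_ingroup": 8,
    "two_free_outgroup": 7,
    "chocolate": 8,
    "trapped": 9,
    "baseline": 9,
}

#: Named regions of interest with anatomical categories; the remainder of the
#: 84 sampled regions are filled with systematic placeholders.
_NAMED_REGIONS = [
    ("NacSh", "nucleus accumbens shell", "striatal"),
    ("NacC", "nucleus accumbens core", "striatal"),
    ("ACC", "anterior cingulate cortex", "frontal"),
    ("PrL", "prelimbic cortex", "frontal"),
    ("MO", "medial orbitofrontal cortex", "frontal"),
    ("LO", "lateral orbitofrontal cortex", "frontal"),
    ("AI", "anterior insula", "insular"),
    ("PI", "posterior insula", "insular"),
    ("LS", "lateral septum", "striatal"),
    ("CPu", "caudate putamen", "striatal"),
    ("BLA", "basolateral amygdala", "other"),
    ("CeA", "central amygdala", "other"),
    ("PVN", "paraventricular hypothalamus", "hypothalamic"),
    ("LH", "lateral hypothalamus", "hypothalamic"),
    ("CA1", "hippocampal CA1", "hippocampal"),
    ("CA3", "hippocampal CA3", "hippocampal"),
    ("DG", "dentate gyrus", "hippocampal"),
    ("S1", "primary somatosensory cortex", "sensory"),
    ("V1", "primary visual cortex", "sensory"),
    ("A1", "primary auditory cortex", "sensory"),
]


def make_region_table(n_regions: int = 84) -> pd.DataFrame:
    """Region metadata table with *n_regions* rows (named ROIs first)."""
    rows = list(_NAMED_REGIONS[:n_regions])
    cats = list(REGION_CATEGORIES)
    i = 0
    while len(rows) < n_regions:
        cat = cats[i % len(cats)]
        rows.append((f"{cat[:3].upper()}{i:02d}", f"synthetic region {i}", cat))
        i += 1
    meta = pd.DataFrame(rows, columns=["region_id", "full_name", "category"])
    meta["ap_mm"] = np.round(np.linspace(5.2, -8.0, len(meta)), 2)
    return meta.set_index("region_id")


# ---------------------------------------------------------------------------
# Activity counts


@dataclass
class SyntheticSpec:
    """Parameters of the count generator.

    Counts follow a log-normal-Poisson mixture averaged over two replicate
    ROIs: log-mean = log(baseline) + dispersion * (sqrt(loading) z_module +
    sqrt(1 - loading) noise) + log(effect).  ``module_loading`` is the latent
    log-scale correlation between regions sharing a module.
    """

    seed: int
    n_per_condition: dict = field(
        default_factory=lambda: dict(PAPER_N_PER_CONDITION)
    )
    n_regions: int = 84
    n_modules: int = 4
    module_assignments: dict | None = None  # region -> module id
    module_loading: float = 0.5
    effect_table: list = field(default_factory=list)  # (region, condition, effect)
    baseline_mean: float = 40.0
    dispersion: float = 0.4
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.module_loading < 1):
            raise ValueError("module_loading must lie in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        for _, _, eff in self.effect_table:
            if eff <= 0:
                raise ValueError("effects must be > 0")
        bad = set(self.n_per_condition) - set(CONDITION_LABELS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")


def default_activity_spec(seed: int) -> SyntheticSpec:
    """Study-shaped activity spec: global HBT elevation plus ingroup-specific
    accumbens effects."""
    effects = []
    # overall elevation in both HBT conditions, stronger for ingroup (drives
    # the PLS LV1 contrast and the total-activity comparisons)
    meta = make_region_table(84)
    for region in meta.index:
        effects.append((region, "HBT_ingroup", 1.5))
        effects.append((region, "HBT_outgroup", 1.25))
    # ingroup-specific accumbens recruitment
    effects.append(("NacSh", "HBT_ingroup", 1.8))
    effects.append(("NacC", "HBT_ingroup", 1.6))
    return SyntheticSpec(seed=seed, effect_table=effects)


def make_activity(spec: SyntheticSpec) -> tuple[ActivityDataset, dict]:
    """Draw an activity dataset; returns (dataset, ground_truth)."""
    rng = np.random.default_rng(spec.seed)
    meta = make_region_table(spec.n_regions)
    regions = list(meta.index)
    if spec.module_assignments is None:
        modules = {
            r: i % spec.n_modules for i, r in enumerate(regions)
        }
    else:
        modules = dict(spec.module_assignments)
        if set(modules) != set(regions):
            raise ValueError("module_assignments must cover every region")
    effect = {}
    for region, condition, eff in spec.effect_table:
        if region not in regions:
            raise ValueError(f"effect references unknown region {region!r}")
        if condition not in CONDITION_LABELS:
            raise ValueError(f"effect references unknown condition {condition!r}")
        effect[(region, condition)] = effect.get((region, condition), 1.0) * eff

    subjects, conditions = [], []
    for cond in CONDITION_LABELS:
        n = spec.n_per_condition.get(cond, 0)
        for i in range(n):
            subjects.append(f"{cond}_{i+1:02d}")
            conditions.append(cond)

    lam = np.sqrt(spec.module_loading)
    rows = np.empty((len(subjects), len(regions)))
    for si, (subj, cond) in enumerate(zip(subjects, conditions)):
        z_mod = rng.standard_normal(spec.n_modules)
        for ri, region in enumerate(regions):
            z = lam * z_mod[modules[region]] + np.sqrt(
                1 - spec.module_loading
            ) * rng.standard_normal()
            mu = (
                spec.baseline_mean
                * np.exp(spec.dispersion * z - spec.dispersion**2 / 2)
                * effect.get((region, cond), 1.0)
            )
            # two replicate ROIs averaged -> continuous half-integer counts
            rows[si, ri] = rng.poisson(mu, size=2).mean()
    counts = pd.DataFrame(rows, index=subjects, columns=regions)
    if spec.missing_rate > 0:
        mask = rng.random(counts.shape) < spec.missing_rate
        counts = counts.mask(mask)
    ds = ActivityDataset(counts, pd.Series(conditions, index=subjects), meta)
    truth = {
        "module_assignments": modules,
        "effect_table": [
            {"region": r, "condition": c, "effect": e}
            for (r, c), e in effect.items()
        ],
        "module_loading": spec.module_loading,
    }
    return ds, truth


# ---------------------------------------------------------------------------
# Behavior


@dataclass
class BehaviorSpec:
    seed: int
    n_rats: int = 8
    n_days: int = 12
    opener_fraction: float = 0.75
    acquisition_day_low: int = 2
    acquisition_day_high: int = 6
    latency_floor_s: float = 120.0
    latency_initial_s: float = 1800.0
    latency_decay_days: float = 2.5
    latency_noise_s: float = 120.0
    session_length_s: float = SESSION_LENGTH_S
    halfway_s: float = HALFWAY_S
    condition: str = "HBT_ingroup"
    # track parameters
    track_hz: float = 10.0
    track_duration_s: float = 600.0
    arena_cm: float = 50.0
    zone: Zone = field(default_factory=lambda: Zone(30.0, 30.0, 50.0, 50.0))
    mean_speed_cm_s: float = 5.4
    zone_preference: float = 0.0   # 0 = unbiased walk
    artifact_rate: float = 0.0     # fraction of teleporting samples

    def __post_init__(self) -> None:
        if self.halfway_s >= self.session_length_s:
            raise ValueError("halfway_s must be < session_length_s")
        if not (0 <= self.opener_fraction <= 1):
            raise ValueError("opener_fraction in [0, 1]")


def _make_track(spec: BehaviorSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = int(spec.track_duration_s * spec.track_hz)
    dt = 1.0 / spec.track_hz
    t = np.arange(n) * dt
    pos = np.empty((n, 2))
    pos[0] = rng.uniform(0, spec.arena_cm, 2)
    heading = rng.uniform(0, 2 * np.pi)
    zc = np.array([
        (spec.zone.x0 + spec.zone.x1) / 2, (spec.zone.y0 + spec.zone.y1) / 2
    ])
    for i in range(1, n):
        heading += rng.normal(0, 0.6)
        step_dir = np.array([np.cos(heading), np.sin(heading)])
        if spec.zone_preference > 0:
            to_zone = zc - pos[i - 1]
            norm = np.linalg.norm(to_zone)
            if norm > 1:
                step_dir = (
                    (1 - spec.zone_preference) * step_dir
                    + spec.zone_preference * to_zone / norm
                )
                step_dir /= np.linalg.norm(step_dir)
        speed = max(0.0, rng.normal(spec.mean_speed_cm_s, 1.5))
        cand = pos[i - 1] + speed * dt * step_dir
        # reflect at walls
        for d in range(2):
            if cand[d] < 0:
                cand[d] = -cand[d]
                heading += np.pi / 2
            elif cand[d] > spec.arena_cm:
                cand[d] = 2 * spec.arena_cm - cand[d]
                heading += np.pi / 2
        pos[i] = cand
    if spec.artifact_rate > 0:
        hit = rng.random(n) < spec.artifact_rate
        hit[0] = hit[-1] = False
        pos[hit] = rng.uniform(0, spec.arena_cm, (int(hit.sum()), 2)) + np.array(
            [200.0, 200.0]
        )
    return pd.DataFrame({"t_s": t, "x_cm": pos[:, 0], "y_cm": pos[:, 1]})


def make_behavior(
    spec: BehaviorSpec, make_tracks: bool = True
) -> tuple[pd.DataFrame, dict, dict]:
    """Door-opening records, movement tracks, and ground truth.

    Openers acquire door-opening on a per-rat acquisition day and then open
    on every later day with exponentially decaying latency toward a floor;
    non-openers never open before the half-way point.
    """
    rng = np.random.default_rng(spec.seed)
    n_open = int(round(spec.opener_fraction * spec.n_rats))
    order = rng.permutation(spec.n_rats)
    opener_idx = set(order[:n_open])
    records = []
    acquisition = {}
    for rat in range(spec.n_rats):
        rat_id = f"rat{rat+1:02d}"
        if rat in opener_idx:
            acq = int(
                rng.integers(spec.acquisition_day_low, spec.acquisition_day_high + 1)
            )
        else:
            acq = None
        acquisition[rat_id] = acq
        for day in range(1, spec.n_days + 1):
            opened = acq is not None and day >= acq
            if opened:
                lat = (
                    spec.latency_floor_s
                    + (spec.latency_initial_s - spec.latency_floor_s)
                    * np.exp(-(day - acq) / spec.latency_decay_days)
                    + rng.normal(0, spec.latency_noise_s)
                )
                lat = float(np.clip(lat, 5.0, spec.halfway_s))
            else:
                lat = spec.halfway_s
            records.append(
                {
                    "rat_id": rat_id,
                    "condition": spec.condition,
                    "day": day,
                    "opened_by_rat": opened,
                    "latency_s": lat,
                }
            )
    sessions = pd.DataFrame(records)
    tracks = {}
    if make_tracks:
        for rat in range(spec.n_rats):
            rat_id = f"rat{rat+1:02d}"
            for day in range(1, spec.n_days + 1):
                df = _make_track(spec, rng)
                tracks[(rat_id, day)] = MovementTrack(df, rat_id=rat_id, day=day)
    truth = {
        "openers": sorted(f"rat{r+1:02d}" for r in opener_idx),
        "acquisition_days": acquisition,
    }
    return sessions, tracks, truth


# ---------------------------------------------------------------------------
# Photometry


@dataclass
class PhotometrySpec:
    seed: int
    duration_s: float = 1200.0
    sampling_hz: float = 20.0
    baseline_470: float = 100.0
    baseline_405: float = 60.0
    gain: float = 1.5               # s470 scale on the shared drift+artifact
    drift_amplitude: float = 8.0    # slow photobleaching amplitude
    drift_tau_s: float = 600.0
    artifact_amplitude: float = 3.0
    artifact_smooth_s: float = 0.5
    transient_amplitude: float = 4.0
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.5
    noise_sd: float = 0.3
    event_times: dict = field(default_factory=dict)  # type -> list of s
    session_kind: str = "ingroup"

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be > 0")
        if not (self.transient_decay_s > self.transient_rise_s > 0):
            raise ValueError("need decay > rise > 0")
        for kind, times in self.event_times.items():
            arr = np.asarray(times, float)
            if len(arr) and (arr.min() < 0 or arr.max() > self.duration_s):
                raise ValueError(f"{kind} events outside [0, duration]")


def transient_kernel(spec: PhotometrySpec) -> np.ndarray:
    """Unit-peak double-exponential calcium kernel at the spec sampling rate."""
    dt = 1.0 / spec.sampling_hz
    length = int((spec.transient_rise_s + 8 * spec.transient_decay_s) / dt)
    tt = np.arange(length) * dt
    k = (1 - np.exp(-tt / spec.transient_rise_s)) * np.exp(-tt / spec.transient_decay_s)
    return k / k.max()


def make_photometry(spec: PhotometrySpec) -> tuple[PhotometrySession, dict]:
    """Two-channel trace with shared artifact and event-locked transients."""
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s * spec.sampling_hz)
    dt = 1.0 / spec.sampling_hz
    t = np.arange(n) * dt
    drift = spec.drift_amplitude * np.exp(-t / spec.drift_tau_s)
    # motion artifact: white noise smoothed to ~artifact_smooth_s timescale
    smooth = max(1, int(spec.artifact_smooth_s * spec.sampling_hz))
    white = rng.standard_normal(n + 2 * smooth)
    kernel = np.ones(smooth) / smooth
    artifact = np.convolve(white, kernel, mode="same")[smooth:-smooth]
    artifact *= spec.artifact_amplitude / max(artifact.std(), 1e-12)

    transients = np.zeros(n)
    k = transient_kernel(spec)
    all_events = {}
    for kind, times in spec.event_times.items():
        times = np.sort(np.asarray(times, float))
        all_events[kind] = times
        for ev in times:
            i = int(round(ev / dt))
            j = min(n, i + len(k))
            if i < n:
                transients[i:j] += spec.transient_amplitude * k[: j - i]

    shared = drift + artifact
    s405 = spec.baseline_405 + shared + rng.normal(0, spec.noise_sd, n)
    s470 = (
        spec.baseline_470
        + spec.gain * shared
        + transients
        + rng.normal(0, spec.noise_sd, n)
    )
    session = PhotometrySession(
        t, s470, s405, events=all_events, session_kind=spec.session_kind
    )
    truth = {
        "transient_amplitude": spec.transient_amplitude,
        "event_times": {k_: list(map(float, v)) for k_, v in all_events.items()},
        "noise_sd": spec.noise_sd,
        "expected_dff_peak": spec.transient_amplitude / spec.baseline_470,
    }
    return session, truth


# ---------------------------------------------------------------------------
# Tracing


def make_tracing(
    n_rats: int,
    target_region: str = "ACC",
    slope: float = 0.4,
    seed: int = 0,
    regions: tuple[str, ...] = ("ACC", "PrL", "MO", "AI", "BLA", "CeA", "LS", "PI"),
    noise_sd: float = 6.0,
    opener_fraction: float = 0.6,
) -> tuple[TracingDataset, dict]:
    """Co-label counts with a planted door-opening correlation in one region."""
    if n_rats < 4:
        raise ValueError("need >= 4 rats")
    if target_region not in regions:
        raise ValueError("target_region must be among regions")
    rng = np.random.default_rng(seed)
    rats = [f"rat{i+1:02d}" for i in range(n_rats)]
    openers = rng.random(n_rats) < opener_fraction
    pct_open = np.where(
        openers, rng.uniform(50, 100, n_rats), rng.uniform(0, 20, n_rats)
    )
    rows = []
    for ri, rat in enumerate(rats):
        for region in regions:
            fg = int(rng.poisson(60)) + 5
            if region == target_region:
                pct = 10.0 + slope * pct_open[ri] + rng.normal(0, noise_sd)
            else:
                pct = rng.uniform(5, 45)
            pct = float(np.clip(pct, 0, 100))
            colabel = int(round(fg * pct / 100.0))
            cfos = colabel + int(rng.poisson(40))
            rows.append(
                {
                    "rat_id": rat,
                    "region_id": region,
                    "fg_count": fg,
                    "cfos_count": cfos,
                    "colabel_count": colabel,
                }
            )
    behavior = pd.DataFrame(
        {"pct_door_openings": pct_open, "opener": openers}, index=pd.Index(rats, name="rat_id")
    )
    ds = TracingDataset(pd.DataFrame(rows), behavior)
    truth = {"target_region": target_region, "slope": slope}
    return ds, truth
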