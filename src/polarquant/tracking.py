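"""Time-lapse cell tracking, reversal detection and the dynamic asymmetry index.

Cells are linked across frames by greedy nearest-centroid matching with a
displacement gate, keeping the two pole identities (a/b) persistent along
each track. Reversals are detected as sign changes of the displacement
projected onto the cell's long axis, gated by a minimum cumulative run
displacement to suppress single-frame jitter. Pole roles (leading/lagging)
follow the motion direction and swap exactly at reversals, defining the
signed dynamic asymmetry index

    omega_dyn = (F_leading - F_lagging) / (F_leading + F_lagging)

so -1 is unipolar at the lagging pole, +1 unipolar at the leading pole and 0
bipolar symmetric. Frames enter the pooled omega_dyn statistics only when the
cell moved for three or more successive frames without reversing, excluding
the first frame after and the last frame before a reversal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .image_quant import detect_polar_clusters, extract_cells

__all__ = [
    "Observation",
    "Track",
    "ReversalEvent",
    "MotilityStats",
    "DynamicOmegaSeries",
    "build_observations",
    "link_tracks",
    "compute_speeds",
    "detect_reversals",
    "reversal_frequency",
    "fraction_moving",
    "assign_leading_lagging",
    "dynamic_omega",
    "welch_t_test",
    "track_motility_stats",
]

#: Median per-interval speed above which a track counts as moving (px).
DEFAULT_MOVING_THRESHOLD = 0.5


@dataclass(frozen=True)
class Observation:
    """One cell in one frame: centroid, persistent pole anchors, per-pole
    cluster fluorescence (0 when no cluster was detected at that pole)."""

    frame: int
    centroid: tuple[float, float]       # (row, col)
    pole_a: tuple[float, float]
    pole_b: tuple[float, float]
    f_pole_a: float = 0.0
    f_pole_b: float = 0.0


@dataclass
class Track:
    """One cell followed over consecutive frames.

    Pole identities a/b are geometric and persistent: they are *not*
    relabeled at reversals, which is what makes leading/lagging role
    assignment and the signed omega_dyn well defined.
    """

    track_id: int
    frames: np.ndarray                   # strictly increasing frame indices
    centroids: np.ndarray                # (n, 2)
    pole_a: np.ndarray                   # (n, 2)
    pole_b: np.ndarray                   # (n, 2)
    f_pole_a: np.ndarray                 # (n,)
    f_pole_b: np.ndarray                 # (n,)
    frame_interval_s: float = 30.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        for name in ("centroids", "pole_a", "pole_b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("f_pole_a", "f_pole_b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval_s)

    @property
    def mean_axis_length(self) -> float:
        return float(np.mean(np.linalg.norm(self.pole_b - self.pole_a, axis=1)))


@dataclass(frozen=True)
class ReversalEvent:
    """Frame index of the first frame moving in the new direction."""

    frame_index: int


@dataclass(frozen=True)
class MotilityStats:
    track_id: int
    speeds: np.ndarray                   # per-interval (px/interval by default)
    reversal_count: int | None           # events in the reporting window
    window_s: float
    moving: bool


@dataclass(frozen=True)
class DynamicOmegaSeries:
    frames: np.ndarray
    omega: np.ndarray                    # NaN where undefined
    included: np.ndarray                 # bool


def build_observations(label_stack: np.ndarray, fluor_stack: np.ndarray,
                       mode: str = "timelapse", pole_fraction: float = 0.2
                       ) -> list[list[Observation]]:
    """Per-frame observations from label/fluorescence stacks.

    Per-pole fluorescence is the total intensity of the accepted polar
    cluster at that pole (time-lapse cluster rule), 0 when none is accepted.
    """
    if label_stack.shape != fluor_stack.shape:
        raise ValueError("label and fluorescence stacks must have the same shape")
    frames = []
    for i in range(label_stack.shape[0]):
        obs = []
        for cell in extract_cells(label_stack[i], fluor_stack[i], frame_id=i):
            f = {"a": 0.0, "b": 0.0}
            for cl in detect_polar_clusters(cell, fluor_stack[i], mode=mode,
                                            pole_fraction=pole_fraction):
                f[cl.pole_label] = cl.total_intensity
            obs.append(Observation(frame=i, centroid=cell.centroid,
                                   pole_a=cell.pole_a, pole_b=cell.pole_b,
                                   f_pole_a=f["a"], f_pole_b=f["b"]))
        frames.append(obs)
    return frames


def _pole_order(prev: Track | dict, obs: Observation) -> tuple:
    """Keep pole identities persistent by nearest-pole matching."""
    pa_prev, pb_prev = np.asarray(prev["pole_a"]), np.asarray(prev["pole_b"])
    pa, pb = np.asarray(obs.pole_a, dtype=float), np.asarray(obs.pole_b, dtype=float)
    keep = np.linalg.norm(pa - pa_prev) + np.linalg.norm(pb - pb_prev)
    swap = np.linalg.norm(pb - pa_prev) + np.linalg.norm(pa - pb_prev)
    if swap < keep:
        return tuple(pb), tuple(pa), obs.f_pole_b, obs.f_pole_a
    return tuple(pa), tuple(pb), obs.f_pole_a, obs.f_pole_b


def link_tracks(frames: list[list[Observation]], max_displacement: float | None = None,
                frame_interval_s: float = 30.0) -> list[Track]:
    """Greedy nearest-centroid linking with a displacement gate.

    The default gate is half the mean cell (axis) length per frame. An
    ambiguous match — two active cells within the gate of one observation, or
    one cell with two observations within the gate — terminates the involved
    tracks at that frame; unmatched observations start new tracks. Tracks are
    never merged across gaps.
    """
    if len(frames) < 2:
        raise ValueError("tracking requires at least 2 frames")
    if max_displacement is None:
        lengths = [np.linalg.norm(np.subtract(o.pole_b, o.pole_a))
                   for fr in frames for o in fr]
        max_displacement = 0.5 * float(np.mean(lengths)) if lengths else 10.0

    active: list[dict] = []
    done: list[dict] = []
    next_id = 0

    def start(obs: Observation) -> dict:
        nonlocal next_id
        t = {"id": next_id, "frames": [obs.frame], "centroids": [obs.centroid],
             "pole_a": [tuple(map(float, obs.pole_a))],
             "pole_b": [tuple(map(float, obs.pole_b))],
             "f_a": [obs.f_pole_a], "f_b": [obs.f_pole_b]}
        next_id += 1
        return t

    for obs in frames[0]:
        active.append(start(obs))

    for fi in range(1, len(frames)):
        obs_list = frames[fi]
        pairs = []  # (distance, track index, obs index)
        for ti, tr in enumerate(active):
            last = np.asarray(tr["centroids"][-1])
            for oi, obs in enumerate(obs_list):
                d = float(np.linalg.norm(last - np.asarray(obs.centroid)))
                if d <= max_displacement:
                    pairs.append((d, ti, tr["id"], oi))
        # ambiguity: any track or observation with >1 candidate terminates
        from collections import Counter
        t_counts = Counter(p[1] for p in pairs)
        o_counts = Counter(p[3] for p in pairs)
        ambiguous_t = {ti for ti, c in t_counts.items() if c > 1}
        ambiguous_t |= {p[1] for p in pairs if o_counts[p[3]] > 1}
        matched_t, matched_o = set(), set()
        for d, ti, _, oi in sorted(pairs):
            if ti in ambiguous_t or ti in matched_t or oi in matched_o:
                continue
            tr, obs = active[ti], obs_list[oi]
            last = {"pole_a": tr["pole_a"][-1], "pole_b": tr["pole_b"][-1]}
            pa, pb, fa, fb = _pole_order(last, obs)
            tr["frames"].append(obs.frame)
            tr["centroids"].append(obs.centroid)
            tr["pole_a"].append(pa)
            tr["pole_b"].append(pb)
            tr["f_a"].append(fa)
            tr["f_b"].append(fb)
            matched_t.add(ti)
            matched_o.add(oi)
        survivors = []
        for ti, tr in enumerate(active):
            if ti in matched_t:
                survivors.append(tr)
            else:
                done.append(tr)
        active = survivors
        for oi, obs in enumerate(obs_list):
            if oi not in matched_o:
                active.append(start(obs))
    done.extend(active)
    done.sort(key=lambda t: t["id"])
    return [Track(track_id=t["id"], frames=t["frames"], centroids=t["centroids"],
                  pole_a=t["pole_a"], pole_b=t["pole_b"], f_pole_a=t["f_a"],
                  f_pole_b=t["f_b"], frame_interval_s=frame_interval_s)
            for t in done]


def compute_speeds(track: Track, px_size_um: float | None = None) -> np.ndarray:
    """Euclidean centroid displacement per consecutive frame pair.

    Units: pixels per interval, or µm per interval when ``px_size_um`` given.
    """
    if len(track) < 2:
        raise ValueError("speed computation requires >= 2 frames")
    d = np.linalg.norm(np.diff(track.centroids, axis=0), axis=1)
    return d * px_size_um if px_size_um else d


def _axis_projections(track: Track) -> np.ndarray:
    """Per-interval centroid displacement projected on the long axis (a->b)."""
    axes = track.pole_b - track.pole_a
    norms = np.linalg.norm(axes, axis=1)
    norms[norms == 0] = 1.0
    u = axes / norms[:, None]
    disp = np.diff(track.centroids, axis=0)
    return np.sum(disp * u[:-1], axis=1)


def _significant_runs(track: Track, min_displacement: float) -> list[tuple[int, int, int]]:
    """Maximal same-sign runs of axis-projected motion with cumulative
    displacement >= min_displacement. Returns (start interval, end interval
    inclusive, sign) triples; zero projections extend the current run."""
    proj = _axis_projections(track)
    runs = []
    sign = 0
    start = 0
    cum = 0.0
    for i, p in enumerate(proj):
        s = int(np.sign(p))
        if s == 0 or s == sign:
            cum += abs(p)
            continue
        if sign != 0:
            runs.append((start, i - 1, sign, cum))
        sign, start, cum = s, i, abs(p)
    if sign != 0:
        runs.append((start, len(proj) - 1, sign, cum))
    return [(a, b, s) for a, b, s, c in runs if c >= min_displacement]


def detect_reversals(track: Track, min_displacement: float | None = None) -> list[ReversalEvent]:
    """Sign changes of the axis-projected displacement, gated so that both
    the preceding and the following run exceed ``min_displacement``
    cumulatively (default: ~one cell width, taken as a quarter of the cell's
    axis length). The event frame is the first frame moving in the new
    direction."""
    if len(track) < 3:
        raise ValueError("reversal detection requires >= 3 frames")
    if min_displacement is None:
        min_displacement = 0.25 * track.mean_axis_length
    runs = _significant_runs(track, min_displacement)
    events = []
    for prev, cur in zip(runs, runs[1:]):
        if cur[2] != prev[2]:
            events.append(ReversalEvent(frame_index=int(track.frames[cur[0]])))
    return events


def reversal_frequency(track: Track, window_s: float,
                       min_displacement: float | None = None) -> int:
    """Reversal count in the first full reporting window (e.g. 600 s for
    T4P-dependent motility, 900 s for gliding). Tracks shorter than the
    window are rejected."""
    if track.duration_s < window_s:
        raise ValueError("track shorter than the reporting window")
    events = detect_reversals(track, min_displacement)
    t0 = track.frames[0] * track.frame_interval_s
    return sum(1 for e in events
               if e.frame_index * track.frame_interval_s <= t0 + window_s)


def fraction_moving(tracks: list[Track],
                    speed_threshold: float = DEFAULT_MOVING_THRESHOLD) -> float:
    """Fraction of tracks whose median per-interval speed exceeds the threshold."""
    if not tracks:
        raise ValueError("no tracks")
    return float(np.mean([np.median(compute_speeds(t)) > speed_threshold for t in tracks]))


def assign_leading_lagging(track: Track, events: list[ReversalEvent] | None = None,
                           min_displacement: float | None = None) -> list[str | None]:
    """Per-frame role of pole b: 'leading' or 'lagging' (pole a is the
    opposite); None for every frame of a track with no significant motion.

    Roles are derived from the gated run structure, so they swap exactly at
    the detected reversal events.
    """
    if min_displacement is None:
        min_displacement = 0.25 * track.mean_axis_length
    runs = _significant_runs(track, min_displacement)
    if not runs:
        return [None] * len(track)
    if events is None:
        events = detect_reversals(track, min_displacement)
    sign = runs[0][2]
    event_frames = {e.frame_index for e in events}
    roles = []
    for f in track.frames:
        if int(f) in event_frames:
            sign = -sign
        roles.append("leading" if sign > 0 else "lagging")
    return roles


def dynamic_omega(track: Track, events: list[ReversalEvent] | None = None,
                  min_displacement: float | None = None,
                  min_run_frames: int = 3) -> DynamicOmegaSeries:
    """Signed per-frame asymmetry index with the standard inclusion rule.

    omega_dyn = (F_leading - F_lagging)/(F_leading + F_lagging). A frame is
    included only when the cell moved for >= ``min_run_frames`` successive
    frames without reversing, excluding the first frame after a reversal and
    the last frame before one; frames with zero total polar fluorescence or
    undefined roles are excluded.
    """
    if events is None:
        events = detect_reversals(track, min_displacement)
    roles_b = assign_leading_lagging(track, events, min_displacement)
    n = len(track)
    omega = np.full(n, np.nan)
    included = np.zeros(n, dtype=bool)

    # segment positions into runs bounded by reversal event frames
    event_pos = sorted(int(np.nonzero(track.frames == e.frame_index)[0][0])
                       for e in events)
    bounds = [0] + event_pos + [n]
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]   # frames [lo, hi)
        run = list(range(lo, hi))
        ok = len(run) >= min_run_frames
        for j, i in enumerate(run):
            if roles_b[i] is None:
                continue
            f_lead = track.f_pole_b[i] if roles_b[i] == "leading" else track.f_pole_a[i]
            f_lag = track.f_pole_a[i] if roles_b[i] == "leading" else track.f_pole_b[i]
            tot = f_lead + f_lag
            if tot <= 0:
                continue
            omega[i] = (f_lead - f_lag) / tot
            first_after_reversal = (k > 0 and j == 0)
            last_before_reversal = (k < len(bounds) - 2 and j == len(run) - 1)
            included[i] = ok and not first_after_reversal and not last_before_reversal
    return DynamicOmegaSeries(frames=track.frames.copy(), omega=omega, included=included)


def welch_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Student's t-test for samples with unequal variances.

    Welch's statistic with Welch-Satterthwaite degrees of freedom; only the
    p-value's tail probability comes from scipy's t distribution. Two
    zero-variance samples with equal means give (0, 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    diff = a.mean() - b.mean()
    if denom == 0:
        return (0.0, 1.0) if diff == 0 else (np.copysign(np.inf, diff), 0.0)
    t = diff / denom
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * _scipy_stats.t.sf(abs(t), df)
    return float(t), float(p)


def track_motility_stats(track: Track, window_s: float,
                         speed_threshold: float = DEFAULT_MOVING_THRESHOLD,
                         min_displacement: float | None = None) -> MotilityStats:
    """Per-track speeds, windowed reversal count and moving flag."""
    speeds = compute_speeds(track)
    try:
        count = reversal_frequency(track, window_s, min_displacement)
    except ValueError:
        count = None
    return MotilityStats(track_id=track.track_id, speeds=speeds, reversal_count=count,
                         window_s=window_s,
                         moving=bool(np.median(speeds) > speed_threshold))
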