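"""Behavioral metrics computed from midline tracks.

Covers the track-level vocabulary of larval chemotaxis screens: track
quality filtering, the spine-based turn angle, turn/head-sweep detection,
the navigation index, orientation-conditioned turn rates, and
stimulation-window statistics with the Welch Z test used for comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import HeadSweepEvent, Track, TrackSet, TurnEvent

POSTERIOR_SLICE = slice(4, 11)  # posterior 2/3 of the 11 spine points (7 points)
ANTERIOR_SLICE = slice(0, 2)  # anterior 1/5 (2 points); index 0 is the head

__all__ = [
    "filter_tracks",
    "turn_angle",
    "spine_bend",
    "turn_angle_series",
    "heading_series",
    "speed_series",
    "detect_turns",
    "navigation_index",
    "turn_rate_by_orientation",
    "OrientationBinTable",
    "stimulus_window_stats",
    "WindowStats",
    "welch_z_test",
]


def filter_tracks(tracks: TrackSet, min_duration: float = 5.0, min_travel: float = 1.0,
                  travel_metric: str = "path") -> TrackSet:
    """Reject tracks shorter than 5 s or that moved less than one body length.

    ``travel_metric`` selects how "moved" is measured: "path" (total path
    length; default, keeps curled-but-active larvae out of the rejected set
    only if they actually crawl) or "net" (net displacement).
    """
    if travel_metric not in ("path", "net"):
        raise ValueError("travel_metric must be 'path' or 'net'")
    kept = []
    for tr in tracks:
        if tr.body_length is None or not tr.body_length > 0:
            raise ValueError(f"track {tr.larva_id!r} lacks a positive body_length")
        travel = tr.path_length() if travel_metric == "path" else tr.net_displacement()
        if tr.duration >= min_duration and travel >= min_travel * tr.body_length:
            kept.append(tr)
    return TrackSet(kept)


def spine_bend(spine: np.ndarray) -> tuple[float, float, float]:
    """Geometry of the anterior bend of one 11-point spine.

    Fits a total-least-squares line to the posterior 7 spine points, finds
    the anterior-1/5 point (of 2) most distant from that line, and returns
    ``(distance, signed_distance, arc_length)`` where ``arc_length`` runs
    along the spine from the fitted segment's anterior end (point index 4) to
    the chosen point. The sign is positive for a bend to the larva's left.
    """
    spine = np.asarray(spine, dtype=float)
    if spine.shape != (11, 2) or not np.all(np.isfinite(spine)):
        raise ValueError("spine must be 11 finite 2-D points")
    post = spine[POSTERIOR_SLICE]
    center = post.mean(axis=0)
    centered = post - center
    if np.allclose(centered, 0):
        raise ValueError("degenerate spine: posterior points are identical")
    # total least squares: principal direction of the posterior points
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if np.dot(v, spine[4] - spine[10]) < 0:
        v = -v  # orient tail -> head
    normal = np.array([-v[1], v[0]])
    offsets = (spine[ANTERIOR_SLICE] - center) @ normal
    k = int(np.argmax(np.abs(offsets)))
    signed = float(offsets[k])
    d = abs(signed)
    seg = np.diff(spine[k:5], axis=0)
    arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return d, signed, arc


def turn_angle(spine: np.ndarray, return_distance: bool = False):
    """Turn angle (degrees) of one spine posture.

    The defining quantity is the perpendicular distance d from the
    total-least-squares line through the posterior 2/3 of the spine to the
    most distant anterior-1/5 point; the angle form arctan(d / L) uses the
    arc length L from the fitted segment to that point, making the metric
    scale-invariant. ``return_distance=True`` also returns the raw distance.
    """
    d, _, arc = spine_bend(spine)
    ang = float(np.degrees(np.arctan2(d, arc))) if arc > 0 else 90.0
    return (ang, d) if return_distance else ang


def turn_angle_series(track: Track, signed: bool = False) -> np.ndarray:
    """Per-frame turn angle (degrees); signed gives bend side (left > 0)."""
    out = np.empty(len(track.t))
    for i in range(len(track.t)):
        d, s, arc = spine_bend(track.spine[i])
        val = np.degrees(np.arctan2(d, arc)) if arc > 0 else 90.0
        out[i] = np.sign(s) * val if signed else val
    return out


def speed_series(track: Track) -> np.ndarray:
    """Per-frame crawl speed from centroid displacement (length/s)."""
    v = np.gradient(track.centroid, track.t, axis=0)
    return np.hypot(v[:, 0], v[:, 1])


def heading_series(track: Track, smooth: float = 0.5) -> np.ndarray:
    """Per-frame heading (radians) from centroid velocity, smoothed over 0.5 s."""
    v = np.gradient(track.centroid, track.t, axis=0)
    w = max(int(np.round(smooth / track.frame_dt)), 1)
    kern = np.ones(w) / w
    vx = np.convolve(v[:, 0], kern, mode="same")
    vy = np.convolve(v[:, 1], kern, mode="same")
    return np.arctan2(vy, vx)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs where mask is True (inclusive)."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    return (a + np.pi) % (2 * np.pi) - np.pi


def detect_turns(track: Track, angle_threshold: float = 20.0,
                 min_duration: float = 0.2) -> list[TurnEvent]:
    """Detect turns as sustained supra-threshold bends of the anterior spine.

    A turn is a maximal interval where |turn angle| >= ``angle_threshold``
    (degrees) lasting at least ``min_duration`` seconds. Within a turn, head
    sweeps are the maximal constant-sign excursions of the signed bend; the
    accepted sweep is the one whose side the post-turn heading change
    follows.
    """
    if not angle_threshold > 0:
        raise ValueError("angle_threshold must be positive")
    signed = turn_angle_series(track, signed=True)
    dt = track.frame_dt
    heading = heading_series(track)
    events: list[TurnEvent] = []
    for i0, i1 in _runs_of(np.abs(signed) >= angle_threshold):
        if (i1 - i0 + 1) * dt < min_duration:
            continue
        pre = heading[max(i0 - 1, 0)]
        post = heading[min(i1 + 1, len(heading) - 1)]
        turn_dir = np.sign(_wrap_angle(post - pre))
        sweeps: list[HeadSweepEvent] = []
        signs = np.sign(signed[i0 : i1 + 1])
        for j0, j1 in _runs_of(signs != 0):
            # split the excursion at sign changes
            seg = signs[j0 : j1 + 1]
            change = np.nonzero(np.diff(seg) != 0)[0]
            bounds = [j0] + [j0 + c + 1 for c in change] + [j1 + 1]
            for a, b in zip(bounds[:-1], bounds[1:]):
                s0, s1 = i0 + a, i0 + b - 1
                sweeps.append(
                    HeadSweepEvent(
                        t_start=float(track.t[s0]),
                        t_end=float(track.t[s1] + dt),
                        accepted=bool(signs[a] == turn_dir),
                        is_first=False,
                        larva_id=track.larva_id,
                    )
                )
        if sweeps:
            sweeps[0].is_first = True
            if turn_dir == 0:  # no measurable reorientation: commit to the last sweep
                for hs in sweeps:
                    hs.accepted = False
                sweeps[-1].accepted = True
        events.append(
            TurnEvent(
                larva_id=track.larva_id,
                t_start=float(track.t[i0]),
                t_end=float(track.t[i1] + dt),
                head_sweeps=sweeps,
            )
        )
    return events


def navigation_index(tracks: TrackSet, gradient_axis=(1.0, 0.0)) -> float:
    """Mean velocity along the gradient divided by mean crawling speed.

    Pooled over all frames of all tracks; +1/-1 for uniform straight
    up/down-gradient crawling, 0 for unbiased movement.
    """
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    g = np.asarray(gradient_axis, dtype=float)
    g = g / np.hypot(*g)
    num = 0.0
    den = 0.0
    for tr in tracks:
        v = np.diff(tr.centroid, axis=0) / np.diff(tr.t)[:, None]
        num += float(np.sum(v @ g))
        den += float(np.sum(np.hypot(v[:, 0], v[:, 1])))
    if den == 0:
        raise ValueError("zero total crawling speed")
    return num / den


@dataclass
class OrientationBinTable:
    """Turn rate binned by orientation relative to the up-gradient direction."""

    table: pd.DataFrame
    toward_rate: float
    away_rate: float
    toward_se: float
    away_se: float
    z: float
    p: float


def turn_rate_by_orientation(
    tracks: TrackSet,
    turns: list[TurnEvent],
    gradient_axis=(1.0, 0.0),
    bin_width: float = 30.0,
    toward_halfwidth: float = 15.0,
) -> OrientationBinTable:
    """Turn rate per orientation bin and the toward-vs-away contrast.

    Orientation is heading relative to up-gradient; run frames (outside
    detected turns) populate the denominators, turn starts the numerators.
    Rates are turns/min with Poisson counting SEs; the toward (|theta| <=
    15 deg) vs away (|theta - 180| <= 15 deg) comparison uses a Welch Z test.
    Empty bins yield NaN rates (flagged, not errored).
    """
    g = np.asarray(gradient_axis, dtype=float)
    theta_g = np.arctan2(g[1], g[0])
    centers = np.arange(0.0, 360.0, bin_width)
    n_bins = len(centers)
    n_frames = np.zeros(n_bins, dtype=int)
    n_turn = np.zeros(n_bins, dtype=int)
    dt = tracks[0].frame_dt if len(tracks) else np.nan
    turns_by_larva: dict[str, list[TurnEvent]] = {}
    for ev in turns:
        turns_by_larva.setdefault(ev.larva_id, []).append(ev)

    def bin_of(theta_deg):
        return (np.round(np.asarray(theta_deg) / bin_width).astype(int)) % n_bins

    for tr in tracks:
        heading = heading_series(tr)
        rel = np.degrees(_wrap_angle(heading - theta_g))
        in_turn = np.zeros(len(tr.t), dtype=bool)
        for ev in turns_by_larva.get(tr.larva_id, []):
            in_turn |= (tr.t >= ev.t_start) & (tr.t < ev.t_end)
        idx = bin_of(rel[~in_turn])
        np.add.at(n_frames, idx, 1)
        for ev in turns_by_larva.get(tr.larva_id, []):
            i = int(np.searchsorted(tr.t, ev.t_start))
            i = min(i, len(tr.t) - 1)
            n_turn[bin_of(rel[i])] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n_frames * dt / 60.0  # minutes of run time per bin
        rate = np.where(n_frames > 0, n_turn / np.maximum(denom, 1e-300), np.nan)
        se = np.where(n_frames > 0, np.sqrt(n_turn) / np.maximum(denom, 1e-300), np.nan)
    centers_signed = np.where(centers > 180, centers - 360.0, centers)
    table = pd.DataFrame(
        {
            "center_deg": centers_signed,
            "N_turn": n_turn,
            "N_frames": n_frames,
            "rate_per_min": rate,
            "se_per_min": se,
        }
    )
    toward = table.loc[table["center_deg"] == 0].iloc[0]
    away = table.loc[table["center_deg"] == 180].iloc[0]
    if toward["N_frames"] > 0 and away["N_frames"] > 0 and (toward["se_per_min"] + away["se_per_min"]) > 0:
        z, p = welch_z_test(
            away["rate_per_min"], max(away["se_per_min"], 1e-300), int(away["N_turn"]),
            toward["rate_per_min"], max(toward["se_per_min"], 1e-300), int(toward["N_turn"]),
        )
    else:
        z, p = np.nan, np.nan
    return OrientationBinTable(
        table=table,
        toward_rate=float(toward["rate_per_min"]),
        away_rate=float(away["rate_per_min"]),
        toward_se=float(toward["se_per_min"]),
        away_se=float(away["se_per_min"]),
        z=float(z),
        p=float(p),
    )


@dataclass
class WindowStats:
    """Onset/offset-window behavioral statistics pooled over stimulations.

    Turn-angle entries are baseline-subtracted degrees; speed entries are
    fractions of the baseline speed.
    """

    turn_angle_onset: float
    turn_angle_onset_se: float
    turn_angle_offset: float
    turn_angle_offset_se: float
    speed_onset: float
    speed_onset_se: float
    speed_offset: float
    speed_offset_se: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["turn_angle_onset", "turn_angle_offset", "speed_onset", "speed_offset"],
                "mean": [self.turn_angle_onset, self.turn_angle_offset, self.speed_onset, self.speed_offset],
                "se": [self.turn_angle_onset_se, self.turn_angle_offset_se, self.speed_onset_se, self.speed_offset_se],
                "n": [self.n] * 4,
            }
        )


def _window_mean(t: np.ndarray, y: np.ndarray, start: float, end: float, label: str) -> float:
    if end > t[-1] + 1e-9:
        warnings.warn(f"{label} window [{start:.1f}, {end:.1f}] extends past track end; truncated")
    mask = (t >= start) & (t < end)
    return float(np.mean(y[mask])) if mask.any() else np.nan


def stimulus_window_stats(
    tracks: TrackSet,
    light_onsets=(30.0, 75.0),
    light_offsets=(45.0, 90.0),
    onset_window: tuple[float, float] = (0.0, 5.0),
    offset_window: tuple[float, float] = (2.0, 7.0),
    baseline: float = 5.0,
) -> WindowStats:
    """Onset/offset response statistics for turn angle and crawl speed.

    The onset metric averages the response over ``onset_window`` after light
    on, normalized to the 5 s pre-light baseline (turn angle: difference in
    degrees; speed: fraction of baseline). The offset metric averages over
    ``offset_window`` after light off, normalized to the last 5 s of light.
    Statistics are pooled over all stimulation pulses, then summarized as
    mean +/- SE over tracks (experiments).
    """
    per_track = {"ta_on": [], "ta_off": [], "sp_on": [], "sp_off": []}
    for tr in tracks:
        ta = turn_angle_series(tr)
        sp = speed_series(tr)
        vals = {"ta_on": [], "ta_off": [], "sp_on": [], "sp_off": []}
        for onset in np.atleast_1d(light_onsets):
            base_ta = _window_mean(tr.t, ta, onset - baseline, onset, "baseline")
            base_sp = _window_mean(tr.t, sp, onset - baseline, onset, "baseline")
            win_ta = _window_mean(tr.t, ta, onset + onset_window[0], onset + onset_window[1], "onset")
            win_sp = _window_mean(tr.t, sp, onset + onset_window[0], onset + onset_window[1], "onset")
            vals["ta_on"].append(win_ta - base_ta)
            vals["sp_on"].append(win_sp / base_sp if base_sp else np.nan)
        for offset in np.atleast_1d(light_offsets):
            base_ta = _window_mean(tr.t, ta, offset - baseline, offset, "during-light baseline")
            base_sp = _window_mean(tr.t, sp, offset - baseline, offset, "during-light baseline")
            win_ta = _window_mean(tr.t, ta, offset + offset_window[0], offset + offset_window[1], "offset")
            win_sp = _window_mean(tr.t, sp, offset + offset_window[0], offset + offset_window[1], "offset")
            vals["ta_off"].append(win_ta - base_ta)
            vals["sp_off"].append(win_sp / base_sp if base_sp else np.nan)
        for key in per_track:
            per_track[key].append(float(np.nanmean(vals[key])))

    def mean_se(xs):
        xs = np.asarray(xs, dtype=float)
        xs = xs[np.isfinite(xs)]
        if len(xs) == 0:
            return np.nan, np.nan
        se = float(np.std(xs, ddof=1) / np.sqrt(len(xs))) if len(xs) > 1 else 0.0
        return float(np.mean(xs)), se

    ta_on, ta_on_se = mean_se(per_track["ta_on"])
    ta_off, ta_off_se = mean_se(per_track["ta_off"])
    sp_on, sp_on_se = mean_se(per_track["sp_on"])
    sp_off, sp_off_se = mean_se(per_track["sp_off"])
    return WindowStats(
        turn_angle_onset=ta_on,
        turn_angle_onset_se=ta_on_se,
        turn_angle_offset=ta_off,
        turn_angle_offset_se=ta_off_se,
        speed_onset=sp_on,
        speed_onset_se=sp_on_se,
        speed_offset=sp_off,
        speed_offset_se=sp_off_se,
        n=len(tracks),
    )


def welch_z_test(mean_a: float, se_a: float, n_a: int, mean_b: float, se_b: float, n_b: int):
    """Welch Z test on two group means with known standard errors.

    z = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2), two-sided p from the
    standard normal. Group sizes are carried for reporting only.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be >= 0")
    if se_a == 0 and se_b == 0:
        if mean_a == mean_b:
            return 0.0, 1.0
        raise ValueError("zero standard errors with unequal means: z undefined")
    z = (mean_a - mean_b) / np.sqrt(se_a**2 + se_b**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
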