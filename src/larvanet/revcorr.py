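"""Reverse-correlation analysis of turn initiation under white-ish light flicker.

Implements the linear–nonlinear–Poisson (LNP) treatment of larval turning:
turn-triggered averages (TTA) of the stimulus, smoothing of the TTA by a
third-order linear-system impulse response, causal filtering of the stimulus
by the resulting kernel (scaled so the filtered signal has unit variance over
the whole stimulus history), a histogram estimator of the turn rate as a
function of filtered-signal value, and a ratio-of-Gaussians (ROG) closed form
for that rate. The pipeline is exposed both as free functions and as the
``TurnLNP`` model / ``TurnLNPResults`` pair.

Notation: the filtered signal is x_f; the rate estimator is
``r(x_f) = N_turn(x_f) / N_all(x_f) * (1/dt)`` over histogram bins of width
0.25, with dt the behavior sampling period (1/14 s). The ROG form is

    r_ROG(x) = rbar * [exp(-(x - mu)^2 / (2 sigma^2)) / sigma] / exp(-x^2 / 2)

with rbar = N_turn / T, mu and sigma^2 the mean and (population) variance of
x_f over the turn-triggered ensemble, and T the total time in runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import GroundTruth, HeadSweepEvent, StimulusTrace

DEFAULT_FRAME_RATE = 14.0
DEFAULT_TTA_BIN = 0.1
DEFAULT_RATE_BIN = 0.25
DEFAULT_TTA_WINDOW = (-10.0, 5.0)
KERNEL_SUPPORT_TOL = 1e-3

__all__ = [
    "TTA",
    "Kernel",
    "FilteredSignal",
    "ROGParams",
    "KernelFitError",
    "third_order_impulse_response",
    "frame_grid",
    "turn_triggered_average",
    "headsweep_triggered_average",
    "fit_kernel",
    "filter_stimulus",
    "empirical_rate",
    "ratio_of_gaussians",
    "TurnLNP",
    "TurnLNPResults",
]


class KernelFitError(RuntimeError):
    """Raised when the impulse-response fit to the TTA does not converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def third_order_impulse_response(t, gain: float, tau: float):
    """Impulse response of three identical cascaded first-order stages.

    h(t) = gain * (t/tau)^2 * exp(-t/tau) for t >= 0, zero before. The peak
    sits at t = 2*tau with height gain * 4 e^-2.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    x = t[pos] / tau
    out[pos] = gain * x**2 * np.exp(-x)
    return out


def frame_grid(stimulus: StimulusTrace, frame_rate: float = DEFAULT_FRAME_RATE) -> np.ndarray:
    """Behavior-camera frame times spanning the stimulus."""
    duration = stimulus.t[-1] - stimulus.t[0]
    n = int(np.floor(duration * frame_rate)) + 1
    return stimulus.t[0] + np.arange(n) / frame_rate


@dataclass
class TTA:
    """An event-triggered average of the stimulus on a uniform lag grid."""

    lags: np.ndarray
    values: np.ndarray
    n_events: int
    bin: float = DEFAULT_TTA_BIN

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "mean": self.values, "n": self.n_events})


@dataclass
class Kernel:
    """A fitted convolution kernel, sampled on the behavior frame grid.

    ``values`` are the scaled samples h[k] at lags k/frame_rate; ``scale`` is
    the factor applied so that the filtered signal has unit variance over the
    stimulus used for fitting. ``degenerate`` flags a zero-gain (flat-TTA)
    kernel, for which no variance scaling is possible.
    """

    gain: float
    tau: float
    frame_rate: float
    values: np.ndarray
    scale: float = 1.0
    degenerate: bool = False

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def sample(self, lags) -> np.ndarray:
        """Scaled kernel evaluated at arbitrary lags (s >= 0)."""
        return third_order_impulse_response(lags, self.gain, self.tau) * self.scale


@dataclass
class FilteredSignal:
    """Kernel-filtered stimulus resampled to the behavior frame grid.

    ``valid`` is False for the initial transient (one kernel length) where
    the causal convolution has incomplete history.
    """

    t: np.ndarray
    xf: np.ndarray
    valid: np.ndarray
    frame_rate: float

    def variance(self) -> float:
        return float(np.var(self.xf))


@dataclass
class ROGParams:
    """Ratio-of-Gaussians rate parameters (rbar in turns/s)."""

    rbar: float
    mu: float
    sigma2: float
    n_turn: int = 0
    T: float = 0.0

    def __post_init__(self) -> None:
        if self.rbar < 0:
            raise ValueError("rbar must be >= 0")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    def rate(self, x):
        """r_ROG(x) in turns/s."""
        x = np.asarray(x, dtype=float)
        num = np.exp(-((x - self.mu) ** 2) / (2.0 * self.sigma2)) / self.sigma
        den = np.exp(-(x**2) / 2.0)
        return self.rbar * num / den

    def standard_errors(self) -> dict[str, float]:
        """Monte-Carlo standard errors of the three parameters.

        rbar is a count over time (Poisson), mu a sample mean, sigma a sample
        SD of the turn-triggered ensemble.
        """
        n = max(self.n_turn, 1)
        return {
            "rbar": np.sqrt(n) / self.T if self.T > 0 else np.nan,
            "mu": self.sigma / np.sqrt(n),
            "sigma": self.sigma / np.sqrt(2.0 * n),
        }


def _event_triggered_average(
    stimulus: StimulusTrace,
    event_times: np.ndarray,
    window: tuple[float, float],
    bin: float,
) -> TTA:
    t, red = stimulus.t, stimulus.red
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("window must satisfy w1 > w0")
    rate = stimulus.rate
    # sample offsets relative to the event, shared by all events (uniform grid)
    k0 = int(np.ceil(w0 * rate))
    k1 = int(np.floor(w1 * rate))
    offsets = np.arange(k0, k1 + 1)
    n_bins = int(np.round((w1 - w0) / bin))
    # small epsilon keeps samples sitting exactly on a bin edge in the
    # half-open bin to their right
    bin_idx = np.minimum(
        np.floor((offsets / rate - w0) / bin + 1e-9).astype(int), n_bins - 1
    )
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    n_used = 0
    for t0 in np.atleast_1d(np.asarray(event_times, dtype=float)):
        i0 = int(np.round((t0 - t[0]) * rate))
        lo, hi = i0 + offsets[0], i0 + offsets[-1]
        if lo < 0 or hi >= len(t):
            continue  # truncated window: exclude the event
        seg = red[i0 + offsets]
        sums += np.bincount(bin_idx, weights=seg, minlength=n_bins)
        counts += np.bincount(bin_idx, minlength=n_bins)
        n_used += 1
    if n_used == 0:
        raise ValueError("no events with full window coverage")
    lags = w0 + (np.arange(n_bins) + 0.5) * bin
    return TTA(lags=lags, values=sums / counts, n_events=n_used, bin=bin)


def turn_triggered_average(
    stimulus: StimulusTrace,
    turn_starts,
    window: tuple[float, float] = DEFAULT_TTA_WINDOW,
    bin: float = DEFAULT_TTA_BIN,
) -> TTA:
    """Mean stimulus waveform aligned to turn onsets (lag 0 = turn start).

    Turns whose window extends beyond the recorded stimulus are excluded.
    """
    return _event_triggered_average(stimulus, turn_starts, window, bin)


def headsweep_triggered_average(
    stimulus: StimulusTrace,
    head_sweeps: list[HeadSweepEvent],
    accepted: bool,
    window: tuple[float, float] = (-5.0, 5.0),
    bin: float = DEFAULT_TTA_BIN,
) -> TTA:
    """Stimulus average aligned to first-head-sweep onsets of one class.

    Only the first head sweep of each turn enters; the accept/reject decision
    happens after sweep onset, so positive lags are informative.
    """
    times = np.array(
        [hs.t_start for hs in head_sweeps if hs.is_first and hs.accepted == accepted]
    )
    if len(times) == 0:
        label = "accepted" if accepted else "rejected"
        raise ValueError(f"no first head sweeps of class {label!r}")
    return _event_triggered_average(stimulus, times, window, bin)


def _resample_to_frames(stimulus: StimulusTrace, frame_rate: float) -> np.ndarray:
    """Block-average the stimulus onto the behavior frame grid."""
    frames = frame_grid(stimulus, frame_rate)
    edges = np.append(frames, frames[-1] + 1.0 / frame_rate)
    idx = np.clip(np.searchsorted(edges, stimulus.t, side="right") - 1, 0, len(frames) - 1)
    sums = np.bincount(idx, weights=stimulus.red, minlength=len(frames))
    counts = np.bincount(idx, minlength=len(frames))
    counts[counts == 0] = 1
    return sums / counts


def filter_stimulus(
    stimulus: StimulusTrace,
    kernel: Kernel,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> FilteredSignal:
    """Causal convolution of the mean-subtracted stimulus with the kernel.

    The result lives on the behavior frame grid; the first kernel-length of
    samples is flagged invalid (incomplete history).
    """
    frames = frame_grid(stimulus, frame_rate)
    if len(frames) < len(kernel.values):
        raise ValueError("stimulus shorter than the kernel support")
    s = _resample_to_frames(stimulus, frame_rate)
    s = s - s.mean()
    xf = np.convolve(s, kernel.values)[: len(s)] / frame_rate
    valid = np.arange(len(s)) >= len(kernel.values)
    return FilteredSignal(t=frames, xf=xf, valid=valid, frame_rate=frame_rate)


def fit_kernel(
    tta: TTA,
    stimulus: StimulusTrace,
    frame_rate: float = DEFAULT_FRAME_RATE,
    support_tol: float = KERNEL_SUPPORT_TOL,
) -> Kernel:
    """Smooth the TTA with a third-order impulse response and scale it.

    The mean-subtracted, time-reversed pre-turn part of the TTA is fitted by
    h(s) = gain * (s/tau)^2 * exp(-s/tau); the kernel is then rescaled so the
    variance of the filtered signal over the entire stimulus history is 1.
    A flat TTA yields a zero-gain kernel flagged ``degenerate``.
    """
    pre = tta.lags < 0
    if pre.sum() < 4:
        raise ValueError("TTA has too few pre-turn lags to fit a kernel")
    s_lags = -tta.lags[pre][::-1]  # time before the turn, increasing from ~0
    h_raw = tta.values[pre][::-1] - float(np.mean(stimulus.red))
    scale0 = max(np.max(np.abs(h_raw)), 1e-300)
    if np.max(np.abs(h_raw)) < 1e-9 * max(1.0, abs(float(np.mean(stimulus.red)))):
        values = np.zeros(2)
        return Kernel(gain=0.0, tau=1.0, frame_rate=frame_rate, values=values, degenerate=True)
    i_peak = int(np.argmax(np.abs(h_raw)))
    tau0 = max(s_lags[i_peak] / 2.0, tta.bin)
    gain0 = h_raw[i_peak] / (4.0 * np.exp(-2.0))
    try:
        popt, _ = curve_fit(
            third_order_impulse_response,
            s_lags,
            h_raw,
            p0=[gain0, tau0],
            bounds=([-np.inf, 1e-3], [np.inf, s_lags[-1]]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise KernelFitError(
            "kernel fit did not converge",
            diagnostics={"p0": [gain0, tau0], "n_lags": int(pre.sum()), "tta_peak": scale0},
        ) from exc
    gain, tau = float(popt[0]), float(popt[1])
    # truncate support where the response has decayed below tolerance
    dt = 1.0 / frame_rate
    s_max = 20.0 * tau
    grid = np.arange(0.0, s_max, dt)
    h = third_order_impulse_response(grid, gain, tau)
    peak = np.max(np.abs(h))
    keep = np.nonzero(np.abs(h) >= support_tol * peak)[0]
    values = h[: keep[-1] + 1] if len(keep) else h[:2]
    kern = Kernel(gain=gain, tau=tau, frame_rate=frame_rate, values=values)
    sd = np.sqrt(filter_stimulus(stimulus, kern, frame_rate).variance())
    if sd == 0:
        kern.degenerate = True
        return kern
    kern.scale = 1.0 / sd
    kern.values = kern.values / sd
    return kern


def empirical_rate(
    xf: np.ndarray,
    turn_frames,
    run_mask,
    bin: float = DEFAULT_RATE_BIN,
    dt: float = 1.0 / DEFAULT_FRAME_RATE,
) -> pd.DataFrame:
    """Histogram estimator of the turn rate versus filtered-signal value.

    ``run_mask`` marks frames where larvae were in runs (able to start a
    turn): a boolean vector for one larva, a (n_larvae, n_frames) boolean
    matrix, or an integer vector of larvae-in-run counts per frame.
    ``turn_frames`` are frame indices of turn starts (repeats allowed).
    Returns per-bin N_turn, N_all, r = N_turn/N_all/dt (turns/s) and the
    Poisson counting SE sqrt(N_turn)/N_all/dt; bins with N_all = 0 get NaN.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    xf = np.asarray(xf, dtype=float)
    run_mask = np.asarray(run_mask)
    if run_mask.ndim == 2:
        run_counts = run_mask.sum(axis=0).astype(int)
    elif run_mask.dtype == bool:
        run_counts = run_mask.astype(int)
    else:
        run_counts = run_mask.astype(int)
    if len(run_counts) != len(xf):
        raise ValueError("run_mask length must match xf")
    turn_frames = np.asarray(turn_frames, dtype=int)
    xs = np.concatenate([xf[run_counts > 0], xf[turn_frames]]) if len(turn_frames) else xf[run_counts > 0]
    lo = np.floor(xs.min() / bin) * bin
    hi = np.ceil(xs.max() / bin) * bin
    edges = np.arange(lo, hi + bin / 2, bin)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin])
    n_all, _ = np.histogram(xf, bins=edges, weights=run_counts)
    n_turn, _ = np.histogram(xf[turn_frames], bins=edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n_all > 0, n_turn / np.maximum(n_all, 1) / dt, np.nan)
        se = np.where(n_all > 0, np.sqrt(n_turn) / np.maximum(n_all, 1) / dt, np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_center": edges[:-1] + bin / 2,
            "N_turn": n_turn.astype(int),
            "N_all": n_all.astype(int),
            "r": r,
            "se": se,
        }
    )


def ratio_of_gaussians(xf_at_turns, T: float, n_turn: int | None = None) -> ROGParams:
    """Fit the ROG rate from the turn-triggered ensemble of x_f.

    rbar = N_turn/T; mu and sigma^2 are the ensemble mean and population
    variance. T is the total time larvae spent in runs (seconds).
    """
    xf_at_turns = np.asarray(xf_at_turns, dtype=float)
    if not T > 0:
        raise ValueError("T must be positive")
    if len(xf_at_turns) < 2:
        raise ValueError("need at least two turns to estimate the ROG parameters")
    n = int(n_turn) if n_turn is not None else len(xf_at_turns)
    mu = float(np.mean(xf_at_turns))
    sigma2 = float(np.var(xf_at_turns))  # population (divide-by-N) estimator
    if sigma2 == 0:
        raise ValueError("turn-triggered ensemble has zero variance")
    return ROGParams(rbar=n / T, mu=mu, sigma2=sigma2, n_turn=n, T=float(T))


class TurnLNP:
    """LNP model of turn initiation, built from a stimulus and turn events.

    Parameters
    ----------
    stimulus : StimulusTrace
        The shared light stimulus (all larvae see the same trace).
    turn_times : array-like
        Turn-start times pooled over larvae (seconds).
    run_mask : ndarray
        Per-frame run occupancy on the frame grid of ``frame_grid(stimulus)``:
        boolean (n_larvae, n_frames) or integer counts per frame.
    head_sweeps : list of HeadSweepEvent, optional
        Enables head-sweep-triggered averages on the fitted model.
    """

    def __init__(
        self,
        stimulus: StimulusTrace,
        turn_times,
        run_mask,
        frame_rate: float = DEFAULT_FRAME_RATE,
        head_sweeps: list[HeadSweepEvent] | None = None,
        tta_window: tuple[float, float] = DEFAULT_TTA_WINDOW,
        tta_bin: float = DEFAULT_TTA_BIN,
        rate_bin: float = DEFAULT_RATE_BIN,
    ):
        self.stimulus = stimulus
        self.turn_times = np.sort(np.asarray(turn_times, dtype=float))
        self.run_mask = np.asarray(run_mask)
        self.frame_rate = frame_rate
        self.head_sweeps = head_sweeps or []
        self.tta_window = tta_window
        self.tta_bin = tta_bin
        self.rate_bin = rate_bin

    @classmethod
    def from_simulation(cls, stimulus: StimulusTrace, truth: GroundTruth, **kwargs) -> "TurnLNP":
        """Build the model from generator ground-truth events."""
        return cls(
            stimulus,
            turn_times=truth.all_turn_times(),
            run_mask=truth.run_mask,
            head_sweeps=truth.head_sweeps,
            **kwargs,
        )

    def fit(self) -> "TurnLNPResults":
        tta = turn_triggered_average(self.stimulus, self.turn_times, self.tta_window, self.tta_bin)
        kernel = fit_kernel(tta, self.stimulus, self.frame_rate)
        if kernel.degenerate:
            raise KernelFitError("flat TTA: zero-gain kernel, no LNP fit possible")
        fs = filter_stimulus(self.stimulus, kernel, self.frame_rate)
        dt = 1.0 / self.frame_rate
        turn_frames = np.round((self.turn_times - fs.t[0]) * self.frame_rate).astype(int)
        inside = (turn_frames >= 0) & (turn_frames < len(fs.xf))
        turn_frames = turn_frames[inside]
        run_counts = (
            self.run_mask.sum(axis=0).astype(int)
            if self.run_mask.ndim == 2
            else self.run_mask.astype(int)
        )
        rate_table = empirical_rate(fs.xf, turn_frames, run_counts, self.rate_bin, dt)
        T = float(run_counts.sum()) * dt
        rog = ratio_of_gaussians(fs.xf[turn_frames], T, n_turn=len(turn_frames))
        return TurnLNPResults(
            model=self, tta=tta, kernel=kernel, filtered=fs, rate_table=rate_table, rog=rog
        )


@dataclass
class TurnLNPResults:
    """Results of a fitted LNP turn model."""

    model: TurnLNP
    tta: TTA
    kernel: Kernel
    filtered: FilteredSignal
    rate_table: pd.DataFrame
    rog: ROGParams

    @property
    def params(self) -> dict[str, float]:
        return {
            "gain": self.kernel.gain,
            "tau": self.kernel.tau,
            "rbar": self.rog.rbar,
            "mu": self.rog.mu,
            "sigma2": self.rog.sigma2,
        }

    def predicted_rate(self, x):
        return self.rog.rate(x)

    def conservation_error(self) -> float:
        """| sum_bins r * N_all * dt - N_turn | (should be ~0)."""
        tab = self.rate_table
        dt = 1.0 / self.model.frame_rate
        lhs = np.nansum(tab["r"] * tab["N_all"] * dt)
        return float(abs(lhs - tab["N_turn"].sum()))

    def block_standard_errors(self, n_blocks: int = 10) -> dict[str, float]:
        """Monte-Carlo SEs of (rbar, mu, sigma) from contiguous time blocks.

        The naive per-turn SEs (``rog.standard_errors``) assume independent
        turn-triggered samples, but every larva sees the same stimulus, so
        turns cluster on the same x_f excursions. Splitting the recording
        into ``n_blocks`` time blocks and treating per-block estimates as
        replicates captures that shared-stimulus dependence.
        """
        fs = self.filtered
        turn_frames = np.round(
            (self.model.turn_times - fs.t[0]) * self.model.frame_rate
        ).astype(int)
        turn_frames = turn_frames[(turn_frames >= 0) & (turn_frames < len(fs.xf))]
        run_counts = (
            self.model.run_mask.sum(axis=0)
            if self.model.run_mask.ndim == 2
            else self.model.run_mask
        ).astype(int)
        edges = np.linspace(0, len(fs.xf), n_blocks + 1).astype(int)
        dt = 1.0 / self.model.frame_rate
        reps = {"rbar": [], "mu": [], "sigma": []}
        for b0, b1 in zip(edges[:-1], edges[1:]):
            sel = (turn_frames >= b0) & (turn_frames < b1)
            xs = fs.xf[turn_frames[sel]]
            T_b = run_counts[b0:b1].sum() * dt
            if len(xs) < 2 or T_b <= 0:
                continue
            reps["rbar"].append(len(xs) / T_b)
            reps["mu"].append(xs.mean())
            reps["sigma"].append(xs.std())
        out = {}
        for key, vals in reps.items():
            vals = np.asarray(vals)
            out[key] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) >= 2 else np.nan
            )
        return out

    def headsweep_tta(self, accepted: bool, window=(-5.0, 5.0)) -> TTA:
        return headsweep_triggered_average(
            self.model.stimulus, self.model.head_sweeps, accepted, window, self.tta.bin
        )

    def summary(self) -> str:
        se = self.rog.standard_errors()
        lines = [
            "LNP turn-initiation model",
            "=" * 44,
            f"n turns used (TTA)      {self.tta.n_events:>12d}",
            f"n turns used (ROG)      {self.rog.n_turn:>12d}",
            f"total run time T (s)    {self.rog.T:>12.1f}",
            f"kernel gain             {self.kernel.gain:>12.4g}",
            f"kernel tau (s)          {self.kernel.tau:>12.4f}",
            f"kernel scale            {self.kernel.scale:>12.4g}",
            f"Var(x_f)                {self.filtered.variance():>12.6f}",
            f"rbar (turns/s)          {self.rog.rbar:>12.4f}  (se {se['rbar']:.4f})",
            f"mu                      {self.rog.mu:>12.4f}  (se {se['mu']:.4f})",
            f"sigma                   {self.rog.sigma:>12.4f}  (se {se['sigma']:.4f})",
            f"conservation |err|      {self.conservation_error():>12.3e}",
        ]
        return "\n".join(lines)

    def plot(self, axes=None):
        """Two-panel figure: TTA with fitted kernel, and rate vs x_f with ROG."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        ax0, ax1 = axes
        ax0.plot(self.tta.lags, self.tta.values, ".", ms=3, label="TTA")
        pre = self.tta.lags < 0
        fitted = (
            self.kernel.sample(-self.tta.lags[pre]) / self.kernel.scale
            + np.mean(self.model.stimulus.red)
        )
        ax0.plot(self.tta.lags[pre], fitted, "-", label="fit")
        ax0.set_xlabel("lag (s)")
        ax0.set_ylabel("stimulus")
        ax0.legend()
        tab = self.rate_table
        ax1.errorbar(tab["bin_center"], tab["r"], yerr=tab["se"], fmt="o", ms=3, label="r(x_f)")
        xs = np.linspace(tab["bin_center"].min(), tab["bin_center"].max(), 200)
        ax1.plot(xs, self.rog.rate(xs), "-", label="ROG")
        ax1.set_xlabel("x_f")
        ax1.set_ylabel("turn rate (1/s)")
        ax1.legend()
        return axes
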