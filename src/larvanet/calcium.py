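"""Calcium-response scoring and variance decomposition.

Consumes extracted two-channel fluorescence traces (GCaMP activity channel,
optional tdTomato structural channel), normalizes, computes dF/F0 against a
5 s pre-stimulus baseline, scores ON (first 3 s of stimulation) and OFF
(8 s after stimulation) responses, and decomposes response variance into
inter- vs intra-individual components with a one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CalciumRecording, CalciumRecordingSet

DEFAULT_BASELINE = 5.0
DEFAULT_ON_WINDOW = 3.0
DEFAULT_OFF_WINDOW = 8.0

__all__ = [
    "normalize_ratio",
    "dff",
    "response_scores",
    "score_recording",
    "score_recordings",
    "paired_wilcoxon",
    "variance_decomposition",
    "VarianceComponents",
]


def normalize_ratio(F_gcamp, F_tdtom, literal: bool = False) -> np.ndarray:
    """Normalize the activity channel against the structural channel.

    F(t) = F_gcamp(t)/median(F_gcamp) - F_tdtom(t)/median(F_tdtom). With
    ``literal=True`` the tdTomato term is divided by median(F_gcamp) instead
    (the form some reports print; the default corrects the denominator so
    that identical traces normalize to exactly zero).
    """
    F_gcamp = np.asarray(F_gcamp, dtype=float)
    F_tdtom = np.asarray(F_tdtom, dtype=float)
    if F_gcamp.shape != F_tdtom.shape:
        raise ValueError("channels must have equal length")
    if np.any(F_gcamp <= 0) or np.any(F_tdtom <= 0):
        raise ValueError("fluorescence channels must be strictly positive")
    med_g = np.median(F_gcamp)
    med_t = np.median(F_tdtom)
    if med_g == 0 or med_t == 0:
        raise ValueError("zero median fluorescence")
    denom_t = med_g if literal else med_t
    return F_gcamp / med_g - F_tdtom / denom_t


def dff(trace, t, stim_start: float, baseline: float = DEFAULT_BASELINE) -> np.ndarray:
    """dF/F0 with F0 the mean over the ``baseline`` seconds before the stimulation.

    Each stimulation gets its own F0 (call once per stimulus epoch).
    """
    trace = np.asarray(trace, dtype=float)
    t = np.asarray(t, dtype=float)
    mask = (t >= stim_start - baseline) & (t < stim_start)
    if not mask.any():
        raise ValueError("no pre-stimulus samples in the baseline window")
    f0 = float(np.mean(trace[mask]))
    if f0 == 0:
        raise ValueError("F0 = 0: dF/F0 undefined")
    return (trace - f0) / f0


@dataclass
class ResponseScore:
    """Per-trial response scores (averaged over repeated stimulations)."""

    individual_id: str
    trial_id: str
    on_score: float
    off_score: float
    off_peak: float
    amplitude: float
    abs_response: float


def response_scores(
    trace,
    t,
    epochs,
    on_window: float = DEFAULT_ON_WINDOW,
    off_window: float = DEFAULT_OFF_WINDOW,
    baseline: float = DEFAULT_BASELINE,
) -> dict[str, float]:
    """Score a normalized trace against its stimulus epochs.

    Per epoch: ON = mean dF/F0 over the first ``on_window`` seconds of
    stimulation; OFF = mean (and peak) dF/F0 over the ``off_window`` seconds
    after it; amplitude = |max - min| dF/F0 over the baseline-through-
    stimulation span (so a pure excursion from a flat baseline measures its
    full size); abs_response = |mean dF/F0 during| - |mean dF/F0 over the
    baseline|.
    Repeated stimulations are averaged. Epochs shorter than ``on_window``
    are truncated with a warning.
    """
    t = np.asarray(t, dtype=float)
    per_epoch = {"on": [], "off": [], "off_peak": [], "amp": [], "absresp": []}
    for label, start, end in epochs:
        if end - start < on_window:
            warnings.warn(
                f"epoch {label!r} shorter than the ON window ({end - start:.1f} < {on_window:.1f} s); truncated"
            )
        d = dff(trace, t, start, baseline)
        on_mask = (t >= start) & (t < start + min(on_window, end - start))
        during = (t >= start) & (t < end)
        off_mask = (t >= end) & (t < end + off_window)
        base_mask = (t >= start - baseline) & (t < start)
        amp_mask = base_mask | during
        on = float(np.mean(d[on_mask])) if on_mask.any() else np.nan
        off = float(np.mean(d[off_mask])) if off_mask.any() else np.nan
        off_peak = float(np.max(d[off_mask])) if off_mask.any() else np.nan
        amp = float(np.max(d[amp_mask]) - np.min(d[amp_mask])) if amp_mask.any() else np.nan
        absresp = (
            abs(float(np.mean(d[during]))) - abs(float(np.mean(d[base_mask])))
            if during.any() and base_mask.any()
            else np.nan
        )
        per_epoch["on"].append(on)
        per_epoch["off"].append(off)
        per_epoch["off_peak"].append(off_peak)
        per_epoch["amp"].append(abs(amp))
        per_epoch["absresp"].append(absresp)
    return {
        "on_score": float(np.nanmean(per_epoch["on"])),
        "off_score": float(np.nanmean(per_epoch["off"])),
        "off_peak": float(np.nanmean(per_epoch["off_peak"])),
        "amplitude": float(np.nanmean(per_epoch["amp"])),
        "abs_response": float(np.nanmean(per_epoch["absresp"])),
    }


def score_recording(
    rec: CalciumRecording,
    use_ratio: bool = False,
    **kwargs,
) -> ResponseScore:
    """Score one recording; ``use_ratio=True`` normalizes against tdTomato first."""
    if use_ratio:
        if rec.F_tdtom is None:
            raise ValueError("recording has no tdTomato channel")
        # shift to a positive baseline so dF/F0 stays defined
        trace = normalize_ratio(rec.F_gcamp, rec.F_tdtom) + 1.0
    else:
        trace = rec.F_gcamp
    scores = response_scores(trace, rec.t, rec.epochs, **kwargs)
    return ResponseScore(
        individual_id=rec.individual_id, trial_id=rec.trial_id, **scores
    )


def score_recordings(recs: CalciumRecordingSet, **kwargs) -> pd.DataFrame:
    """Per-trial score table for a recording set."""
    rows = [vars(score_recording(r, **kwargs)) for r in recs]
    return pd.DataFrame(rows)


def paired_wilcoxon(scores_pre, scores_post):
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are handled by Pratt's method; the exact distribution
    is used for n <= 25, the normal approximation above. All-zero
    differences return (0, 1) with a warning.
    """
    pre = np.asarray(scores_pre, dtype=float)
    post = np.asarray(scores_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if len(pre) < 2:
        raise ValueError("need at least two pairs")
    diff = post - pre
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    method = "exact" if len(pre) <= 25 and not np.any(diff == 0) else "approx"
    if np.any(diff == 0) and len(pre) <= 25:
        method = "approx"  # Pratt zeros rule out the exact null distribution
    res = stats.wilcoxon(post, pre, zero_method="pratt", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class VarianceComponents:
    """One-way ANOVA results with individual identity as the factor."""

    F_statistic: float
    p: float
    r2: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    n_individuals: int
    n_total: int

    def summary(self) -> str:
        lines = [
            "Response variance decomposition (one-way ANOVA, factor = individual)",
            "=" * 68,
            f"individuals                 {self.n_individuals:>10d}",
            f"observations                {self.n_total:>10d}",
            f"SS between / within     {self.ss_between:>10.4g} / {self.ss_within:<10.4g}",
            f"df between / within     {self.df_between:>10d} / {self.df_within:<10d}",
            f"Fisher's F                  {self.F_statistic:>10.4g}",
            f"p value                     {self.p:>10.4g}",
            f"r^2 (inter-individual)      {self.r2:>10.4f}",
        ]
        return "\n".join(lines)


def variance_decomposition(scores: pd.DataFrame | dict, value: str = "on_score",
                           group: str = "individual_id") -> VarianceComponents:
    """Partition response variance into inter- vs intra-individual parts.

    Accepts a per-trial score table (``group``/``value`` columns) or a dict
    mapping individual id to a sequence of scores. F = MS_between/MS_within,
    r^2 = SS_between/SS_total. With all scores identical, F is NaN-flagged
    and r^2 is 0 by convention.
    """
    if isinstance(scores, dict):
        groups = [np.asarray(v, dtype=float) for v in scores.values()]
    else:
        groups = [g[value].to_numpy(dtype=float) for _, g in scores.groupby(group)]
    if len(groups) < 2:
        raise ValueError("need at least two individuals")
    if not any(len(g) >= 2 for g in groups):
        raise ValueError("need repeated trials for at least one individual (no within-variance)")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    n_total = len(all_vals)
    k = len(groups)
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ss_total = ss_between + ss_within
    df_between = k - 1
    df_within = n_total - k
    if ss_total == 0:
        return VarianceComponents(
            F_statistic=float("nan"), p=float("nan"), r2=0.0,
            df_between=df_between, df_within=df_within,
            ss_between=0.0, ss_within=0.0, n_individuals=k, n_total=n_total,
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        F = float("inf")
        p = 0.0
    else:
        F = ms_between / ms_within
        p = float(stats.f.sf(F, df_between, df_within))
    return VarianceComponents(
        F_statistic=float(F),
        p=p,
        r2=ss_between / ss_total,
        df_between=df_between,
        df_within=df_within,
        ss_between=ss_between,
        ss_within=ss_within,
        n_individuals=k,
        n_total=n_total,
    )
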