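"""Synthetic-data generators for every input the analysis pipeline consumes.

Four experiment families are emulated:

* a Brownian-random-walk light stimulus (reflected at the 0/255 intensity
  bounds, 112 Hz update) driving LNP-governed turn initiation with
  ratio-of-Gaussians rate and head-sweep acceptance tied to the change of the
  filtered signal during the sweep;
* gradient klinotaxis: run-and-turn trajectories whose per-frame turn rate is
  modulated by heading relative to the up-gradient direction;
* paired left/right connectomes with symmetric true synapse counts per
  homolog pair and independent spurious contacts at the per-contact false
  positive rate of the reconstruction method (default 0.0167);
* two-channel calcium recordings with separate inter-individual and
  intra-individual response-amplitude variance components.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    CalciumRecording,
    CalciumRecordingSet,
    GroundTruth,
    HeadSweepEvent,
    PairedAdjacency,
    StimulusTrace,
    Track,
    TrackSet,
)
from .revcorr import (
    Kernel,
    ROGParams,
    filter_stimulus,
    frame_grid,
    third_order_impulse_response,
)

DEFAULT_UPDATE_RATE = 112.0
DEFAULT_FRAME_RATE = 14.0
DEFAULT_FP_RATE = 0.0167
DEFAULT_BODY_LENGTH = 4.0  # mm (third instar)
DEFAULT_SPEED = 0.8  # mm/s crawl speed

__all__ = [
    "simulate_stimulus",
    "default_true_kernel",
    "simulate_larvae_lnp",
    "simulate_larvae_gradient",
    "simulate_connectome",
    "simulate_calcium",
]


def simulate_stimulus(
    duration: float,
    update_rate: float = DEFAULT_UPDATE_RATE,
    step_sd: float = 25.0,
    start: float = 127.5,
    blue: float = 20.0,
    seed: int | None = None,
) -> StimulusTrace:
    """Red-light intensity following a reflected Gaussian random walk on [0, 255].

    Reflection (rather than clipping) at the bounds preserves the variance of
    the increments; the blue channel is constant. ``step_sd`` is the SD of one
    increment (intensity units per update).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not update_rate > 0:
        raise ValueError("update_rate must be positive")
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(np.round(duration * update_rate))
    steps = rng.normal(0.0, step_sd, size=n - 1) if step_sd > 0 else np.zeros(n - 1)
    walk = start + np.concatenate([[0.0], np.cumsum(steps)])
    folded = np.mod(walk, 2 * 255.0)
    red = np.where(folded > 255.0, 2 * 255.0 - folded, folded)
    t = np.arange(n) / update_rate
    return StimulusTrace(t=t, red=red, blue=blue)


def default_true_kernel(
    gain: float = 1.0, tau: float = 0.5, frame_rate: float = DEFAULT_FRAME_RATE
) -> Kernel:
    """A third-order impulse-response kernel to use as simulation truth."""
    dt = 1.0 / frame_rate
    grid = np.arange(0.0, 20.0 * tau, dt)
    h = third_order_impulse_response(grid, gain, tau)
    keep = np.nonzero(np.abs(h) >= 1e-3 * np.max(np.abs(h)))[0]
    return Kernel(gain=gain, tau=tau, frame_rate=frame_rate, values=h[: keep[-1] + 1])


def _render_spines(
    centroid: np.ndarray, heading: np.ndarray, bend: np.ndarray, body_length: float
) -> np.ndarray:
    """Render 11-point midlines: straight posterior, progressively bent anterior.

    ``bend`` is the signed anterior bend in radians (0 during runs). Point 0
    is the head; points 4..10 lie straight along the heading; points 0..3
    rotate about point 4 by a fraction of the bend that grows toward the head.
    """
    n = len(heading)
    L = body_length
    u = np.stack([np.cos(heading), np.sin(heading)], axis=-1)
    spine = np.empty((n, 11, 2))
    ks = np.arange(11)
    for k in ks[4:]:
        spine[:, k, :] = centroid + u * (0.5 - k / 10.0) * L
    p4 = spine[:, 4, :]
    for k in ks[:4]:
        frac = (4 - k) / 4.0
        ang = heading + bend * frac
        dirk = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        spine[:, k, :] = p4 + dirk * (4 - k) / 10.0 * L
    return spine


def _as_rog(nonlinearity) -> ROGParams:
    if isinstance(nonlinearity, ROGParams):
        return nonlinearity
    if isinstance(nonlinearity, dict):
        return ROGParams(
            rbar=nonlinearity["rbar"],
            mu=nonlinearity.get("mu", 0.0),
            sigma2=nonlinearity.get("sigma2", 1.0),
        )
    rbar, mu, sigma2 = nonlinearity
    return ROGParams(rbar=rbar, mu=mu, sigma2=sigma2)


def simulate_larvae_lnp(
    stimulus: StimulusTrace,
    kernel: Kernel | None = None,
    nonlinearity: ROGParams | dict | tuple = (0.067, -0.5, 0.64),
    n_larvae: int = 20,
    duration: float | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    seed: int | None = None,
    sweep_duration: float = 0.5,
    max_sweeps: int = 3,
    accept_slope: float = 2.0,
    accept_bias: float = 0.0,
    turn_angle_range: tuple[float, float] = (30.0, 120.0),
    bend_peak: float = 70.0,
    speed: float = DEFAULT_SPEED,
    body_length: float = DEFAULT_BODY_LENGTH,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate larvae whose turn initiation follows an LNP model.

    Per frame, a larva in a run starts a turn with probability
    ``r_ROG(x_f(t)) * dt`` where x_f is the (unit-variance) kernel-filtered
    stimulus shared by all larvae. A turn is a sequence of head sweeps of
    ``sweep_duration`` each, on alternating sides; a sweep is accepted with
    probability ``sigmoid(accept_bias + accept_slope * dx_f)`` where dx_f is
    the change of x_f over the sweep (forced accept at ``max_sweeps``). On
    acceptance the heading changes by a uniform draw from
    ``turn_angle_range`` degrees toward the accepted side and the run resumes.
    """
    rog = _as_rog(nonlinearity)
    kernel = kernel if kernel is not None else default_true_kernel(frame_rate=frame_rate)
    if not np.all(np.isfinite(kernel.values)):
        raise ValueError("kernel values must be finite")
    rng = np.random.default_rng(seed)
    frames = frame_grid(stimulus, frame_rate)
    if duration is not None:
        frames = frames[frames <= stimulus.t[0] + duration]
    n_frames = len(frames)
    dt = 1.0 / frame_rate

    fs = filter_stimulus(stimulus, kernel, frame_rate)
    xf = fs.xf[:n_frames].copy()
    sd = xf.std()
    std_factor = sd if sd > 0 else 1.0
    xf /= std_factor  # unit variance, as the ROG nonlinearity assumes

    p_turn = rog.rate(xf) * dt
    if np.any(p_turn >= 1.0):
        raise ValueError(
            "turn rate * dt >= 1 somewhere: the per-frame Bernoulli "
            "approximation of the point process is violated"
        )

    sweep_frames = max(int(np.round(sweep_duration * frame_rate)), 1)
    RUN, TURN = 0, 1
    state = np.full(n_larvae, RUN)
    side = np.zeros(n_larvae)
    sweep_start = np.zeros(n_larvae, dtype=int)
    sweep_end = np.zeros(n_larvae, dtype=int)
    sweeps_done = np.zeros(n_larvae, dtype=int)
    heading = rng.uniform(0, 2 * np.pi, n_larvae)
    pos = np.zeros((n_larvae, 2))
    pos[:] = rng.uniform(-50, 50, (n_larvae, 2))

    heading_hist = np.empty((n_larvae, n_frames))
    pos_hist = np.empty((n_larvae, n_frames, 2))
    bend_hist = np.zeros((n_larvae, n_frames))
    run_mask = np.zeros((n_larvae, n_frames), dtype=bool)
    turn_times: dict[str, list[float]] = {f"larva-{j:03d}": [] for j in range(n_larvae)}
    head_sweeps: list[HeadSweepEvent] = []
    bend_peak_rad = np.deg2rad(bend_peak)
    amin, amax = np.deg2rad(turn_angle_range[0]), np.deg2rad(turn_angle_range[1])

    for i in range(n_frames):
        # resolve sweeps ending at this frame
        ending = (state == TURN) & (sweep_end == i)
        if ending.any():
            idx = np.nonzero(ending)[0]
            dxf = xf[i] - xf[sweep_start[idx]]
            p_acc = 1.0 / (1.0 + np.exp(-(accept_bias + accept_slope * dxf)))
            forced = sweeps_done[idx] >= max_sweeps
            acc = (rng.random(len(idx)) < p_acc) | forced
            for j, a in zip(idx, acc):
                head_sweeps.append(
                    HeadSweepEvent(
                        t_start=float(frames[sweep_start[j]]),
                        t_end=float(frames[i]),
                        accepted=bool(a),
                        is_first=sweeps_done[j] == 1,
                        larva_id=f"larva-{j:03d}",
                    )
                )
            acc_idx = idx[acc]
            heading[acc_idx] += side[acc_idx] * rng.uniform(amin, amax, len(acc_idx))
            state[acc_idx] = RUN
            rej_idx = idx[~acc]
            side[rej_idx] *= -1
            sweeps_done[rej_idx] += 1
            sweep_start[rej_idx] = i
            sweep_end[rej_idx] = i + sweep_frames

        in_run = state == RUN
        run_mask[:, i] = in_run
        # turn initiation from runs
        if p_turn[i] > 0:
            starting = in_run & (rng.random(n_larvae) < p_turn[i])
            if starting.any():
                idx = np.nonzero(starting)[0]
                for j in idx:
                    turn_times[f"larva-{j:03d}"].append(float(frames[i]))
                state[idx] = TURN
                side[idx] = rng.choice([-1.0, 1.0], len(idx))
                sweeps_done[idx] = 1
                sweep_start[idx] = i
                sweep_end[idx] = i + sweep_frames

        turning = state == TURN
        frac = np.where(turning, (i - sweep_start) / sweep_frames, 0.0)
        bend_hist[:, i] = np.where(turning, side * bend_peak_rad * np.sin(np.pi * frac), 0.0)
        heading_hist[:, i] = heading
        pos_hist[:, i] = pos
        moving = state == RUN
        pos[moving] += speed * dt * np.stack(
            [np.cos(heading[moving]), np.sin(heading[moving])], axis=-1
        )

    tracks = []
    for j in range(n_larvae):
        spine = _render_spines(pos_hist[j], heading_hist[j], bend_hist[j], body_length)
        tracks.append(
            Track(
                larva_id=f"larva-{j:03d}",
                t=frames,
                spine=spine,
                centroid=pos_hist[j],
                body_length=body_length,
            )
        )
    truth = GroundTruth(
        kernel_lags=kernel.lags,
        kernel_values=kernel.values / std_factor,
        rbar=rog.rbar,
        mu=rog.mu,
        sigma2=rog.sigma2,
        turn_times={k: np.array(v) for k, v in turn_times.items()},
        head_sweeps=head_sweeps,
        run_mask=run_mask,
        frame_t=frames,
        xf=xf,
        params={
            "accept_slope": accept_slope,
            "accept_bias": accept_bias,
            "sweep_duration": sweep_duration,
            "max_sweeps": max_sweeps,
            "frame_rate": frame_rate,
            "seed": seed,
        },
    )
    return TrackSet(tracks), truth


def simulate_larvae_gradient(
    gradient_axis=(1.0, 0.0),
    base_turn_rate: float = 0.1,
    modulation: float = 0.3,
    n_larvae: int = 50,
    duration: float = 300.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    seed: int | None = None,
    turn_duration: float = 1.0,
    sweep_range: tuple[float, float] = (30.0, 120.0),
    bend_peak: float = 70.0,
    speed: float = DEFAULT_SPEED,
    body_length: float = DEFAULT_BODY_LENGTH,
    initial_heading: float | None = None,
    return_truth: bool = False,
):
    """Gradient-biased run-and-turn trajectories (klinotaxis caricature).

    The per-frame turn rate is ``base * (1 - modulation * cos(theta))`` with
    theta the heading relative to the up-gradient direction: positive
    modulation suppresses turning while heading up-gradient, producing
    up-gradient drift. After a turn of ``turn_duration`` seconds (stationary,
    anterior spine bent), the heading changes by a uniform draw from
    ``sweep_range`` degrees to a random side.
    """
    if abs(modulation) > 1:
        raise ValueError("|modulation| must be <= 1 (negative rates otherwise)")
    dt = 1.0 / frame_rate
    if base_turn_rate * (1 + abs(modulation)) * dt >= 1:
        raise ValueError("base_turn_rate too high for the frame rate")
    rng = np.random.default_rng(seed)
    g = np.asarray(gradient_axis, dtype=float)
    theta_g = np.arctan2(g[1], g[0])
    n_frames = int(np.round(duration * frame_rate))
    frames = np.arange(n_frames) / frame_rate

    turn_frames = max(int(np.round(turn_duration * frame_rate)), 1)
    heading = (
        np.full(n_larvae, float(initial_heading))
        if initial_heading is not None
        else rng.uniform(0, 2 * np.pi, n_larvae)
    )
    pos = rng.uniform(-50, 50, (n_larvae, 2))
    in_turn = np.zeros(n_larvae, dtype=bool)
    turn_start = np.zeros(n_larvae, dtype=int)
    turn_side = np.zeros(n_larvae)

    heading_hist = np.empty((n_larvae, n_frames))
    pos_hist = np.empty((n_larvae, n_frames, 2))
    bend_hist = np.zeros((n_larvae, n_frames))
    turn_times: dict[str, list[float]] = {f"larva-{j:03d}": [] for j in range(n_larvae)}
    amin, amax = np.deg2rad(sweep_range[0]), np.deg2rad(sweep_range[1])
    bend_peak_rad = np.deg2rad(bend_peak)

    for i in range(n_frames):
        ending = in_turn & (i - turn_start >= turn_frames)
        if ending.any():
            idx = np.nonzero(ending)[0]
            heading[idx] += turn_side[idx] * rng.uniform(amin, amax, len(idx))
            in_turn[idx] = False
        rate = base_turn_rate * (1.0 - modulation * np.cos(heading - theta_g))
        starting = ~in_turn & (rng.random(n_larvae) < rate * dt)
        if starting.any():
            idx = np.nonzero(starting)[0]
            for j in idx:
                turn_times[f"larva-{j:03d}"].append(float(frames[i]))
            in_turn[idx] = True
            turn_start[idx] = i
            turn_side[idx] = rng.choice([-1.0, 1.0], len(idx))
        frac = np.where(in_turn, (i - turn_start) / turn_frames, 0.0)
        bend_hist[:, i] = np.where(in_turn, turn_side * bend_peak_rad * np.sin(np.pi * frac), 0.0)
        heading_hist[:, i] = heading
        pos_hist[:, i] = pos
        moving = ~in_turn
        pos[moving] += speed * dt * np.stack(
            [np.cos(heading[moving]), np.sin(heading[moving])], axis=-1
        )

    tracks = []
    for j in range(n_larvae):
        spine = _render_spines(pos_hist[j], heading_hist[j], bend_hist[j], body_length)
        tracks.append(
            Track(
                larva_id=f"larva-{j:03d}",
                t=frames,
                spine=spine,
                centroid=pos_hist[j],
                body_length=body_length,
            )
        )
    trackset = TrackSet(tracks)
    if not return_truth:
        return trackset
    truth = {
        "turn_times": {k: np.array(v) for k, v in turn_times.items()},
        "base_turn_rate": base_turn_rate,
        "modulation": modulation,
        "gradient_axis": tuple(g),
    }
    return trackset, truth


DEFAULT_CLASS_MAP = {"MBON": 8, "LHN": 6, "KC": 12, "PN": 4, "DAN": 4, "other": 16}


def _default_count_distribution(rng: np.random.Generator, size: int) -> np.ndarray:
    """Shifted geometric synapse counts over {1, 2, ...} (heavy-tailed)."""
    return rng.geometric(0.25, size)


def simulate_connectome(
    n_per_class: dict[str, int] | None = None,
    p_connect: float = 0.08,
    count_distribution=None,
    fp_rate: float = DEFAULT_FP_RATE,
    ipsi_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[PairedAdjacency, pd.DataFrame]:
    """Generate a paired left/right connectome with false-positive contacts.

    True connections exist at pair level with probability ``p_connect``; each
    side's synapse count (presynaptic left/right neuron onto both postsynaptic
    homologs) is an independent draw from ``count_distribution`` and is split
    between ipsi- and contralateral targets. Spurious contacts are added per
    (pre, post) neuron cell with count S distributed P(S = n) = (1-p) p^n, so
    an entirely spurious n-contact connection occurs at rate p^n.

    Returns the observed :class:`PairedAdjacency` and a truth table with the
    per-side true counts and whether each true connection passes the 3/3/10
    strong-connection rule.
    """
    n_per_class = dict(DEFAULT_CLASS_MAP if n_per_class is None else n_per_class)
    if not n_per_class or sum(n_per_class.values()) == 0:
        raise ValueError("n_per_class must name at least one class with pairs")
    if not (0 <= fp_rate < 1):
        raise ValueError("fp_rate must lie in [0, 1)")
    count_distribution = count_distribution or _default_count_distribution
    rng = np.random.default_rng(seed)

    transmitters = {
        "MBON": ("ACh", "GABA", "Glu"),
        "LHN": ("ACh", "GABA"),
        "KC": ("ACh",),
        "PN": ("ACh",),
        "DAN": ("unknown",),
        "other": ("ACh", "GABA", "Glu", "unknown"),
    }
    ann_rows = []
    pair_ids = []
    for cls, n_pairs in n_per_class.items():
        for i in range(n_pairs):
            pid = f"{cls}-{i:02d}"
            pair_ids.append(pid)
            tx = rng.choice(transmitters.get(cls, ("unknown",)))
            valence = rng.choice(["positive", "negative"]) if cls == "MBON" else "none"
            for hemi in ("L", "R"):
                mate = f"{pid} {'R' if hemi == 'L' else 'L'}"
                ann_rows.append(
                    {
                        "id": f"{pid} {hemi}",
                        "hemisphere": hemi,
                        "homolog_id": mate,
                        "class": cls,
                        "transmitter": tx,
                        "valence": valence,
                    }
                )
    annotations = pd.DataFrame(ann_rows)
    neuron_ids = annotations["id"].tolist()
    n_neurons = len(neuron_ids)
    pos_of = {nid: k for k, nid in enumerate(neuron_ids)}
    counts = np.zeros((n_neurons, n_neurons), dtype=int)

    truth_rows = []
    n_pairs_total = len(pair_ids)
    connected = rng.random((n_pairs_total, n_pairs_total)) < p_connect
    np.fill_diagonal(connected, False)
    for a, pre in enumerate(pair_ids):
        for b, post in enumerate(pair_ids):
            if not connected[a, b]:
                continue
            syn_left = int(count_distribution(rng, 1)[0])
            syn_right = int(count_distribution(rng, 1)[0])
            for syn, hemi in ((syn_left, "L"), (syn_right, "R")):
                ipsi = int(rng.binomial(syn, ipsi_fraction))
                contra = syn - ipsi
                pre_i = pos_of[f"{pre} {hemi}"]
                counts[pre_i, pos_of[f"{post} {hemi}"]] += ipsi
                counts[pre_i, pos_of[f"{post} {'R' if hemi == 'L' else 'L'}"]] += contra
            total = syn_left + syn_right
            truth_rows.append(
                {
                    "pre_pair": pre,
                    "post_pair": post,
                    "syn_left_true": syn_left,
                    "syn_right_true": syn_right,
                    "total_true": total,
                    "true_strong": syn_left >= 3 and syn_right >= 3 and total >= 10,
                }
            )

    if fp_rate > 0:
        # geometric spurious contact counts: P(S = n) = (1 - p) p^n per cell
        spurious = rng.geometric(1.0 - fp_rate, size=(n_neurons, n_neurons)) - 1
        np.fill_diagonal(spurious, 0)
        counts += spurious

    adjacency = pd.DataFrame(counts, index=neuron_ids, columns=neuron_ids)
    truth = pd.DataFrame(
        truth_rows,
        columns=["pre_pair", "post_pair", "syn_left_true", "syn_right_true", "total_true", "true_strong"],
    )
    return PairedAdjacency(adjacency, annotations), truth


def _transient(t: np.ndarray, start: float, end: float, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Saturating-rise / exponential-decay response shape, peak ~1."""
    g = np.zeros_like(t)
    during = (t >= start) & (t < end)
    g[during] = 1.0 - np.exp(-(t[during] - start) / rise_tau)
    after = t >= end
    g_end = 1.0 - np.exp(-(end - start) / rise_tau)
    g[after] = g_end * np.exp(-(t[after] - end) / decay_tau)
    return g


def simulate_calcium(
    n_individuals: int = 8,
    n_trials: int = 3,
    response_mean: float = 0.6,
    sd_between: float = 0.3,
    sd_within: float = 0.1,
    baseline_level: float = 100.0,
    epochs: list[tuple[str, float, float]] | None = None,
    frame_rate: float = 5.0,
    duration: float | None = None,
    noise_sd: float = 0.01,
    tdtom_level: float = 50.0,
    tdtom_noise_sd: float = 0.005,
    rise_tau: float = 0.2,
    decay_tau: float = 1.5,
    seed: int | None = None,
) -> CalciumRecordingSet:
    """Two-channel calcium traces with nested variance components.

    Individual i has a latent response amplitude a_i ~ N(response_mean,
    sd_between^2); trial j of individual i responds with a_ij ~ N(a_i,
    sd_within^2). The GCaMP trace is baseline * (1 + a_ij * g(t)) with g a
    rise/decay transient during each stimulus epoch, times multiplicative
    shot-like noise. The tdTomato channel is constant up to noise and serves
    only to exercise ratiometric normalization.
    """
    if sd_between < 0 or sd_within < 0:
        raise ValueError("variance components must be >= 0")
    if not baseline_level > 0:
        raise ValueError("baseline_level must be positive")
    rng = np.random.default_rng(seed)
    if epochs is None:
        epochs = [("stim", 10.0 + 18.0 * k, 13.0 + 18.0 * k) for k in range(4)]
    t_end = duration if duration is not None else max(e[2] for e in epochs) + 12.0
    t = np.arange(0.0, t_end, 1.0 / frame_rate)
    g = np.zeros_like(t)
    for _, start, end in epochs:
        g += _transient(t, start, end, rise_tau, decay_tau)

    recordings = []
    a_i_map: dict[str, float] = {}
    a_ij_map: dict[tuple[str, str], float] = {}
    for i in range(n_individuals):
        ind = f"ind-{i:02d}"
        a_i = rng.normal(response_mean, sd_between)
        a_i_map[ind] = float(a_i)
        for j in range(n_trials):
            trial = f"trial-{j:02d}"
            a_ij = rng.normal(a_i, sd_within)
            a_ij_map[(ind, trial)] = float(a_ij)
            noise = rng.normal(0.0, noise_sd, len(t)) if noise_sd > 0 else np.zeros(len(t))
            F_g = baseline_level * (1.0 + a_ij * g) * (1.0 + noise)
            F_g = np.maximum(F_g, 1e-6)
            tnoise = (
                rng.normal(0.0, tdtom_noise_sd, len(t))
                if tdtom_noise_sd > 0
                else np.zeros(len(t))
            )
            F_t = tdtom_level * (1.0 + tnoise)
            recordings.append(
                CalciumRecording(
                    individual_id=ind,
                    trial_id=trial,
                    t=t,
                    F_gcamp=F_g,
                    F_tdtom=F_t,
                    epochs=list(epochs),
                )
            )
    truth = {
        "a_i": a_i_map,
        "a_ij": a_ij_map,
        "response_mean": response_mean,
        "sd_between": sd_between,
        "sd_within": sd_within,
        "expected_r2": (
            sd_between**2 / (sd_between**2 + sd_within**2)
            if sd_between + sd_within > 0
            else 0.0
        ),
    }
    return CalciumRecordingSet(recordings, truth=truth)
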