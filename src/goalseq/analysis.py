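"""Sequence-event classification and population-dynamics analyses.

Two criteria separate smooth from jump-like sequence events:

* max-jump: the Euclidean displacement between positions decoded from
  consecutive frames exceeds a threshold (default 40 cm) at least once;
* cluster count: mean-shift mode seeking on the spatial distribution of
  spiking activity detects more than one activity cluster in any frame.

The transition distance d* is the start-to-end distance that best
separates the two classes: a proportion 1 - alpha of jump-like events
travel farther than d* and an equal proportion of smooth events travel
less. Additional analyses: ripple-band spectrogram of the CA3 population
rate, early/middle/late rate summary, bump speed vs distance, and
rotation/scaling of trajectories onto a common start->goal template.
"""
from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d

from .network import Network, NetworkParams, Simulator, SpikeRecord, build_network
from .sequence import SequenceEvent, run_sequence
from .decoding import TuningCurveSet, spike_count_frames, subset_decode

__all__ = [
    "TransitionAnalysis",
    "classify_max_jump",
    "mean_shift_clusters",
    "frame_spike_positions",
    "classify_cluster_count",
    "transition_distance",
    "rate_spectrogram",
    "peak_frequency",
    "thirds_rate_summary",
    "speed_vs_distance",
    "normalize_trajectories",
    "run_parameter_sweep",
    "sweep_sigma_grid",
]

JUMP_THRESHOLD = 40.0   # cm
MS_BANDWIDTH = 52.5     # cm, mean-shift kernel bandwidth


def classify_max_jump(track: np.ndarray, threshold: float = JUMP_THRESHOLD) -> str:
    """"jump" iff any consecutive-frame displacement strictly exceeds the
    threshold; NaN frames (undecodable) are dropped first."""
    track = np.asarray(track, dtype=float)
    track = track[~np.isnan(track).any(axis=1)]
    if len(track) < 2:
        raise ValueError("need at least two decoded frames")
    steps = np.linalg.norm(np.diff(track, axis=0), axis=1)
    return "jump" if np.any(steps > threshold) else "non_jump"


def mean_shift_clusters(
    points: np.ndarray,
    weights: Optional[np.ndarray] = None,
    bandwidth: float = MS_BANDWIDTH,
    tol: float = 0.1,
    max_iter: int = 500,
    merge_radius: Optional[float] = None,
) -> np.ndarray:
    """Modes of the Gaussian kernel density over 2-D points by mean shift.

    Every point seeds an iterate; converged iterates closer than
    ``merge_radius`` (default bandwidth/2) are merged. Returns the cluster
    centers ordered by descending attracted mass.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("mean shift needs at least one point")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)
    merge_radius = bandwidth / 2.0 if merge_radius is None else merge_radius

    # seed one iterate per occupied (bandwidth/2)-cell: every point lies
    # well within one bandwidth of a seed, so no mode can be missed, and
    # the iteration count drops for dense frames
    cell = bandwidth / 2.0
    bins = np.floor(pts / cell).astype(np.int64)
    _, first, inv = np.unique(bins, axis=0, return_index=True,
                              return_inverse=True)
    seeds = np.zeros((len(first), 2))
    wsum = np.zeros(len(first))
    np.add.at(seeds, inv, pts * w[:, None])
    np.add.at(wsum, inv, w)
    seeds /= wsum[:, None]

    # all seeds iterate together in float32; distances via the matmul
    # expansion |m - x|^2 = |m|^2 + |x|^2 - 2 m.x
    P = pts.astype(np.float32)
    wf = w.astype(np.float32)
    modes32 = seeds.astype(np.float32)
    done = np.zeros(len(modes32), dtype=bool)
    p2 = (P * P).sum(1)
    inv_two_bw2 = np.float32(-1.0 / (2.0 * bandwidth ** 2))
    tol2 = np.float32(tol * tol)
    for _ in range(max_iter):
        act = ~done
        if not act.any():
            break
        m = modes32[act]
        d2 = (m * m).sum(1)[:, None] + p2[None, :] - 2.0 * (m @ P.T)
        k = np.exp(inv_two_bw2 * d2) * wf[None, :]
        new = (k @ P) / k.sum(axis=1)[:, None]
        shift2 = ((new - m) ** 2).sum(1)
        modes32[act] = new
        idx = np.flatnonzero(act)
        done[idx[shift2 <= tol2]] = True
    modes = modes32.astype(float)
    seed_w = wsum

    # merge modes within merge_radius, heaviest first
    order = np.argsort(-seed_w)
    centers: list[np.ndarray] = []
    mass: list[float] = []
    for i in order:
        m = modes[i]
        for j, c in enumerate(centers):
            if np.linalg.norm(m - c) < merge_radius:
                mass[j] += seed_w[i]
                break
        else:
            centers.append(m)
            mass.append(seed_w[i])
    out = np.asarray(centers)
    return out[np.argsort(-np.asarray(mass))]


def frame_spike_positions(
    spikes: SpikeRecord,
    centers: np.ndarray,
    t0: float,
    t1: float,
    window: float = 5.0,
    step: float = 2.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per decoding frame: field centers of spiking cells and spike counts."""
    starts, counts = spike_count_frames(spikes, len(centers), t0, t1,
                                        window, step)
    frames = []
    for k in range(len(starts)):
        idx = np.flatnonzero(counts[k])
        frames.append((centers[idx], counts[k, idx]))
    return frames


def classify_cluster_count(
    frames: Sequence[tuple[np.ndarray, np.ndarray]],
    bandwidth: float = MS_BANDWIDTH,
) -> tuple[str, np.ndarray]:
    """"jump" iff any frame shows two or more activity clusters."""
    n_clusters = np.zeros(len(frames), dtype=int)
    for k, (pts, w) in enumerate(frames):
        if len(pts) == 0:
            continue
        n_clusters[k] = len(mean_shift_clusters(pts, w, bandwidth))
    label = "jump" if np.any(n_clusters >= 2) else "non_jump"
    return label, n_clusters


@dataclass
class TransitionAnalysis:
    """Separation of jump vs smooth start-to-end distance distributions."""

    d_star: float
    alpha: float
    criterion: str = "cluster_count"
    n_jump: int = 0
    n_nonjump: int = 0


def transition_distance(
    nonjump_d: np.ndarray, jump_d: np.ndarray, criterion: str = "cluster_count"
) -> TransitionAnalysis:
    """Distance d* with equal miss proportions alpha on both sides.

    alpha(d) = max(P[jump <= d], P[non-jump >= d]); the scan over midpoints
    of the pooled sorted distances minimizes alpha, ties resolved toward
    the smallest d.
    """
    nj = np.sort(np.asarray(nonjump_d, dtype=float))
    jd = np.sort(np.asarray(jump_d, dtype=float))
    if len(nj) == 0 or len(jd) == 0:
        raise ValueError("transition distance undefined with an empty class")
    pooled = np.sort(np.concatenate([nj, jd]))
    cands = np.concatenate([[pooled[0] - 1.0],
                            (pooled[:-1] + pooled[1:]) / 2.0,
                            [pooled[-1] + 1.0]])
    a_j = np.searchsorted(jd, cands, side="right") / len(jd)
    a_n = 1.0 - np.searchsorted(nj, cands, side="left") / len(nj)
    alpha = np.maximum(a_j, a_n)
    best = int(np.argmin(alpha))  # argmin takes the first (smallest d) tie
    return TransitionAnalysis(
        d_star=float(max(cands[best], 0.0)), alpha=float(alpha[best]),
        criterion=criterion, n_jump=len(jd), n_nonjump=len(nj))


def rate_spectrogram(
    pop_rate: np.ndarray,
    dt: float = 0.2,
    nperseg: int = 1024,
    step_ms: float = 2.0,
    smooth_ms: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hanning-tapered spectrogram of the smoothed population rate.

    ``pop_rate`` is the per-step CA3-exc spike count; it is converted to a
    rate, smoothed with a Gaussian kernel of ``smooth_ms`` width, and
    analysed with windows of ``nperseg`` samples advanced by ``step_ms``.
    Returns (frequencies Hz, window times ms, power).
    """
    x = np.asarray(pop_rate, dtype=float)
    if len(x) < nperseg:
        raise ValueError("record shorter than one spectrogram window")
    fs = 1000.0 / dt
    if smooth_ms > 0:
        x = gaussian_filter1d(x, smooth_ms / dt)
    hop = max(int(round(step_ms / dt)), 1)
    f, t, S = signal.spectrogram(
        x - x.mean(), fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg - hop, mode="psd")
    return f, t * 1000.0, S


def peak_frequency(
    pop_rate: np.ndarray, dt: float = 0.2, fmin: float = 20.0, **kw
) -> float:
    """Frequency of maximum time-averaged spectral power above ``fmin``."""
    nperseg = min(kw.pop("nperseg", 1024), len(pop_rate))
    f, _, S = rate_spectrogram(pop_rate, dt=dt, nperseg=nperseg, **kw)
    mean_p = S.mean(axis=1)
    mean_p[f < fmin] = 0.0
    return float(f[np.argmax(mean_p)])


def thirds_rate_summary(
    pop_rates: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- s.e.m. of the population rate in the early, middle and late
    third of the biased period, across events.

    ``pop_rates`` holds one per-step rate array per event, restricted to
    the bias window. Returns (means, sems), each of length 3.
    """
    per_event = np.array([
        [np.mean(np.array_split(np.asarray(r, float), 3)[k]) for k in range(3)]
        for r in pop_rates
    ])
    means = per_event.mean(axis=0)
    sems = per_event.std(axis=0, ddof=1) / np.sqrt(len(per_event)) \
        if len(per_event) > 1 else np.zeros(3)
    return means, sems


def speed_vs_distance(
    tracks: Sequence[np.ndarray],
) -> pd.DataFrame:
    """Per-event start-to-end distance and mean per-frame displacement.

    Intended for non-jump events. Returns a DataFrame with columns
    ``distance`` and ``speed`` plus a linear fit and Spearman correlation
    in ``DataFrame.attrs``.
    """
    rows = []
    for tr in tracks:
        tr = np.asarray(tr, dtype=float)
        tr = tr[~np.isnan(tr).any(axis=1)]
        if len(tr) < 2:
            continue
        steps = np.linalg.norm(np.diff(tr, axis=0), axis=1)
        rows.append((float(np.linalg.norm(tr[-1] - tr[0])),
                     float(steps.mean())))
    if len(rows) < 2:
        raise ValueError("need at least two events")
    df = pd.DataFrame(rows, columns=["distance", "speed"])
    fit = stats.linregress(df["distance"], df["speed"])
    rho = stats.spearmanr(df["distance"], df["speed"])
    df.attrs["slope"] = float(fit.slope)
    df.attrs["intercept"] = float(fit.intercept)
    df.attrs["spearman_rho"] = float(rho.statistic)
    df.attrs["spearman_p"] = float(rho.pvalue)
    return df


def normalize_trajectories(
    tracks: Sequence[np.ndarray],
    starts: Sequence[np.ndarray],
    goals: Sequence[np.ndarray],
    template_axis: np.ndarray = np.array([0.0, 1.0]),
) -> list[np.ndarray]:
    """Rotate and scale each trajectory onto a common start->goal template.

    The rigid rotation maps each event's start->goal vector onto
    ``template_axis``; coordinates are expressed relative to the start and
    scaled by the start->goal distance, so the goal maps to the template
    axis tip. Events with start == goal are skipped.
    """
    out = []
    for tr, s, g in zip(tracks, starts, goals):
        s = np.asarray(s, float)
        v = np.asarray(g, float) - s
        L = np.linalg.norm(v)
        if L == 0:
            continue
        u = v / L
        # rotation taking u onto the template axis
        t = template_axis / np.linalg.norm(template_axis)
        cos = u @ t
        sin = u[0] * t[1] - u[1] * t[0]
        R = np.array([[cos, -sin], [sin, cos]])
        tr = np.asarray(tr, dtype=float)
        out.append(((tr - s) @ R.T) / L)
    return out


# ----------------------------------------------------------------------
# parameter sweep over Gaussian profile widths


def sweep_sigma_grid(
    base: float = 50.0, factors: Sequence[float] = (0.5, 0.75, 1.0)
) -> list[tuple[float, float]]:
    """The 3x3 (sigma_DG-CA3, sigma_CA3) grid of the profile-width sweep."""
    vals = [base * f for f in factors]
    return [(sd, sc) for sc in vals for sd in vals]


def _scaled_params(
    params: NetworkParams, sigma_dg: float, sigma_ca3: float,
    weight_scaling: str = "area",
) -> NetworkParams:
    """Rescale profile widths, keeping the 2-D weight integral ("area",
    w ~ (sigma0/sigma)^2) or the linear sum ("linear", w ~ sigma0/sigma)
    constant."""
    pw = 2.0 if weight_scaling == "area" else 1.0
    s_dg0 = params.dg_ca3.sigma
    s_c0 = params.ca3_rec.sigma
    return dc_replace(
        params,
        dg_ca3=dc_replace(params.dg_ca3, sigma=sigma_dg, cutoff=sigma_dg,
                          weight_max=params.dg_ca3.weight_max
                          * (s_dg0 / sigma_dg) ** pw),
        ca3_rec=dc_replace(params.ca3_rec, sigma=sigma_ca3,
                           weight_max=params.ca3_rec.weight_max
                           * (s_c0 / sigma_ca3) ** pw),
    )


def run_parameter_sweep(
    params: NetworkParams,
    snapshots: Sequence[tuple[np.ndarray, np.ndarray]],
    tuning: TuningCurveSet,
    rng: np.random.Generator,
    n_events: int = 50,
    sigma_grid: Optional[Sequence[tuple[float, float]]] = None,
    weight_scaling: str = "area",
    n_subsets: int = 4,
    subset_size: int = 160,
    decode_bin: float = 5.25,
    jump_track: str = "bayesian",
) -> pd.DataFrame:
    """Sequence statistics across the (sigma_DG-CA3, sigma_CA3) grid.

    ``snapshots`` supplies (context->DG weight vector, start position)
    pairs stored from behavioral simulations; each configuration replays
    ``n_events`` sequences drawn from them (cycled). Events are classified
    by both criteria and the transition-distance separation is computed
    per criterion where both classes occur.
    """
    grid = list(sigma_grid) if sigma_grid is not None else sweep_sigma_grid()
    snaps = list(snapshots)
    rows = []
    for sigma_dg, sigma_ca3 in grid:
        p = _scaled_params(params, sigma_dg, sigma_ca3, weight_scaling)
        net = build_network(p)
        tun = dc_replace(tuning, bin_size=decode_bin)
        cache: dict = {}
        labels_c, labels_m, dists, com_tracks = [], [], [], []
        for e in range(n_events):
            W, start = snaps[e % len(snaps)]
            sim = Simulator(net, rng)
            ev = run_sequence(sim, W, start, "sweep")
            if ev.spikes.n_spikes == 0:
                continue
            t0, t1 = ev.init_ms, ev.duration
            frames = frame_spike_positions(ev.spikes, net.positions, t0, t1)
            lab_c, _ = classify_cluster_count(frames)
            if jump_track == "bayesian":
                dec = subset_decode(ev.spikes, tun, t0, t1, rng,
                                    n_subsets=n_subsets,
                                    subset_size=subset_size,
                                    log_f_cache=cache)
                track = dec.pooled_com
            else:
                track = ev.com_after_init()
            try:
                lab_m = classify_max_jump(track)
            except ValueError:
                lab_m = "non_jump"
            labels_c.append(lab_c)
            labels_m.append(lab_m)
            dists.append(ev.start_to_end_distance)
            com_tracks.append(ev.com_after_init())
        labels_c = np.array(labels_c)
        labels_m = np.array(labels_m)
        dists = np.array(dists)
        row = {
            "sigma_dg_ca3": sigma_dg, "sigma_ca3": sigma_ca3,
            "n_events": len(dists),
            "jump_pct_cluster": 100.0 * np.mean(labels_c == "jump"),
            "jump_pct_maxjump": 100.0 * np.mean(labels_m == "jump"),
            "criteria_agreement": float(np.mean(labels_c == labels_m)),
        }
        for name, labels in (("cluster", labels_c), ("maxjump", labels_m)):
            jd, nd = dists[labels == "jump"], dists[labels == "non_jump"]
            if len(jd) and len(nd):
                ta = transition_distance(nd, jd, criterion=name)
                row[f"d_star_{name}"] = ta.d_star
                row[f"alpha_{name}"] = ta.alpha
            else:
                row[f"d_star_{name}"] = np.nan
                row[f"alpha_{name}"] = np.nan
        nj = [t for t, l in zip(com_tracks, labels_c) if l == "non_jump"]
        if len(nj) >= 2:
            sd = speed_vs_distance(nj)
            row["speed_slope"] = sd.attrs["slope"]
            row["speed_spearman"] = sd.attrs["spearman_rho"]
        else:
            row["speed_slope"] = np.nan
            row["speed_spearman"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
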