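"""Memoryless Bayesian position decoding from spike-count frames.

Under independent-Poisson firing and a uniform occupancy prior, the
posterior probability that the population represents position x given the
spike-count vector r observed in a window of length tau is

    P[x | r]  proportional to  ( prod_i f_i(x)^{r_i} ) * exp(-tau * sum_i f_i(x))

where f_i is unit i's spatial tuning curve. The computation is carried out
in log space. Because the product over many units underflows for large
populations, the network is subdivided into random subsets decoded
independently; the pooled estimate is the center of mass of the
across-subset mean posterior. A spike-count-weighted population-vector
readout is provided as an independent cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .network import Network, Simulator, SpikeRecord
from .sequence import SequenceEvent

__all__ = [
    "TuningCurveSet",
    "DecodedTrajectory",
    "build_tuning_curves",
    "bayesian_posterior",
    "subset_decode",
    "population_vector_decode",
    "spike_count_frames",
]

DEFAULT_BIN_SIZE = 2.625  # cm, = one tenth of a full-scale place-field sigma


@dataclass
class TuningCurveSet:
    """Per-unit expected firing rate over a square grid of position bins.

    In ``analytic`` mode the curves are isotropic Gaussians
    ``f_i(x) = peak_i * exp(-||x - c_i||^2 / sigma_tc^2)`` with the peak and
    width calibrated from a short movement-state simulation; ``simulated``
    mode stores binned rate maps from a random-walk traversal directly.
    """

    centers: np.ndarray            # (N, 2) place-field centers, cm
    bin_size: float
    env_side: float
    mode: str = "analytic"
    peak: Optional[np.ndarray] = None     # (N,) Hz, analytic mode
    sigma_tc: float = 25.0                # cm, analytic mode
    rate_maps: Optional[np.ndarray] = None  # (N, M) Hz, simulated mode
    floor: float = 1e-4                   # Hz, keeps log-rates finite

    @property
    def n_units(self) -> int:
        return len(self.centers)

    @property
    def bins_per_side(self) -> int:
        return int(round(self.env_side / self.bin_size))

    @property
    def bin_centers(self) -> np.ndarray:
        """(M, 2) coordinates of the spatial bins, row-major."""
        c = (np.arange(self.bins_per_side) + 0.5) * self.bin_size
        xx, yy = np.meshgrid(c, c, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def rates(self, units: np.ndarray) -> np.ndarray:
        """(len(units), M) expected rates in Hz, floored away from zero."""
        units = np.asarray(units)
        if self.mode == "simulated":
            f = self.rate_maps[units]
        else:
            bc = self.bin_centers.astype(np.float32)
            c = self.centers[units].astype(np.float32)
            d2 = ((c[:, None, :] - bc[None, :, :]) ** 2).sum(-1)
            f = self.peak[units, None].astype(np.float32) * np.exp(
                -d2 / np.float32(self.sigma_tc ** 2))
        return np.maximum(f, self.floor)


def build_tuning_curves(
    net: Network,
    mode: str = "analytic",
    rng: Optional[np.random.Generator] = None,
    bin_size: float = DEFAULT_BIN_SIZE,
    dwell_ms: float = 250.0,
    walk_ms: float = 60_000.0,
) -> TuningCurveSet:
    """Estimate CA3 tuning curves from movement-state activity.

    ``analytic``: park the rat at a series of distances from a probe cell's
    field center, measure that cell's firing rate (recurrents gated off, as
    during movement), and fit ``peak * exp(-d^2/sigma^2)``; all units share
    the fitted peak and width, centered on their lattice position.
    ``simulated``: a random-walk traversal of the arena binned into rate
    maps per unit (intended for small lattices; memory scales as N x M).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    env = net.p.lattice.env_side

    if mode == "analytic":
        # probe the central cell to stay clear of lattice edges
        probe = net.n // 2 + net.p.lattice.grid_side // 2
        center = net.positions[probe]
        dists = np.linspace(0.0, 60.0, 13)
        rates = np.empty_like(dists)
        for k, d in enumerate(dists):
            sim = Simulator(net, rng)
            pos = center + np.array([d, 0.0])
            out = sim.run(dwell_ms, place_pos=pos, recurrents_on=False,
                          record=("ca3e",))
            rates[k] = np.sum(out["ca3e"].ids == probe) / (dwell_ms / 1000.0)
        def g(d, peak, sig):
            return peak * np.exp(-d ** 2 / sig ** 2)
        p0 = (max(rates.max(), 1.0), 25.0)
        try:
            (peak, sig), _ = optimize.curve_fit(g, dists, rates, p0=p0)
        except RuntimeError:
            peak, sig = p0
        return TuningCurveSet(
            centers=net.positions, bin_size=bin_size, env_side=env,
            mode="analytic", peak=np.full(net.n, float(abs(peak))),
            sigma_tc=float(abs(sig)))

    if mode == "simulated":
        m = int(round(env / bin_size))
        step_ms = 100.0
        n_steps = int(walk_ms / step_ms)
        lo = net.p.lattice.arena_offset
        hi = lo + net.p.lattice.arena_side
        # bounded random walk over the arena
        pos = np.empty((n_steps, 2))
        pos[0] = rng.uniform(lo, hi, 2)
        steps = rng.normal(0.0, 12.0, (n_steps - 1, 2))
        for k in range(1, n_steps):
            pos[k] = np.clip(pos[k - 1] + steps[k - 1], lo, hi)
        sim = Simulator(net, rng)
        counts = np.zeros((net.n, m * m))
        occ = np.zeros(m * m)
        for k in range(n_steps):
            out = sim.run(step_ms, place_pos=pos[k], recurrents_on=False,
                          record=("ca3e",))
            b = _bin_index(pos[k], bin_size, m)
            occ[b] += step_ms / 1000.0
            np.add.at(counts[:, b], out["ca3e"].ids, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            maps = counts / occ[None, :]
        maps[:, occ == 0] = 0.0
        return TuningCurveSet(
            centers=net.positions, bin_size=bin_size, env_side=env,
            mode="simulated", rate_maps=maps)

    raise ValueError(f"unknown mode {mode!r}")


def _bin_index(pos: np.ndarray, bin_size: float, m: int) -> int:
    i = min(int(pos[0] / bin_size), m - 1)
    j = min(int(pos[1] / bin_size), m - 1)
    return j * m + i


def bayesian_posterior(
    counts: np.ndarray,
    log_f: np.ndarray,
    f_sum: np.ndarray,
    tau_s: float,
) -> np.ndarray:
    """Normalized posterior over position bins for one frame (log-space).

    ``log_f`` is (n_units, M) log tuning curves, ``f_sum`` their per-bin sum
    (Hz), ``tau_s`` the window length in seconds.
    """
    ll = counts @ log_f - tau_s * f_sum
    ll -= ll.max()
    post = np.exp(ll)
    z = post.sum()
    if not np.isfinite(z) or z <= 0.0:
        raise FloatingPointError(
            f"posterior underflow for subset of {len(counts)} units")
    return post / z


def spike_count_frames(
    spikes: SpikeRecord,
    n_units: int,
    t0: float,
    t1: float,
    window: float = 5.0,
    step: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame spike-count matrix: windows of ``window`` ms every ``step``.

    Returns (frame start times, counts of shape (n_frames, n_units)).
    """
    starts = np.arange(t0, t1 - window + 1e-9, step)
    order = np.argsort(spikes.times, kind="stable")
    ts, ids = spikes.times[order], spikes.ids[order]
    lo = np.searchsorted(ts, starts, side="left")
    hi = np.searchsorted(ts, starts + window, side="left")
    counts = np.zeros((len(starts), n_units), dtype=np.int64)
    for k, (a, b) in enumerate(zip(lo, hi)):
        if b > a:
            counts[k] = np.bincount(ids[a:b], minlength=n_units)
    return starts, counts


@dataclass
class DecodedTrajectory:
    """Per-frame position estimates for one sequence event."""

    times: np.ndarray                 # frame start times, ms
    pooled_com: np.ndarray            # (n_frames, 2); NaN where undecodable
    subset_com: np.ndarray            # (n_subsets, n_frames, 2), NaN = skipped
    subsets: np.ndarray               # (n_subsets, subset_size) unit ids
    window: float = 5.0
    step: float = 2.0
    posteriors: Optional[np.ndarray] = None   # (n_frames, M) mean posterior

    def valid_pooled(self) -> np.ndarray:
        return self.pooled_com[~np.isnan(self.pooled_com[:, 0])]


def subset_decode(
    spikes: SpikeRecord,
    tuning: TuningCurveSet,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    n_subsets: int = 40,
    subset_size: int = 160,
    window: float = 5.0,
    step: float = 2.0,
    keep_posteriors: bool = False,
    log_f_cache: Optional[dict] = None,
) -> DecodedTrajectory:
    """Decode a spike record with random disjoint cell subsets.

    Each subset yields a per-frame posterior center of mass; frames in
    which a subset fired no spikes are skipped for that subset. The pooled
    track is the center of mass of the across-subset mean of the
    (individually normalized) posteriors. ``log_f_cache`` allows reusing
    the per-subset log tuning curves across events when the partition is
    held fixed (pass a dict keyed by subset index; the partition is then
    taken from the cache as well).
    """
    N = tuning.n_units
    if n_subsets * subset_size > N:
        raise ValueError("partition larger than the population")
    if log_f_cache is not None and "subsets" in log_f_cache:
        subsets = log_f_cache["subsets"]
    else:
        perm = rng.permutation(N)[: n_subsets * subset_size]
        subsets = perm.reshape(n_subsets, subset_size)
        if log_f_cache is not None:
            log_f_cache["subsets"] = subsets

    times, counts = spike_count_frames(spikes, N, t0, t1, window, step)
    tau_s = window / 1000.0
    bc = tuning.bin_centers
    n_frames = len(times)
    subset_com = np.full((n_subsets, n_frames, 2), np.nan)
    post_sum = np.zeros((n_frames, bc.shape[0]))
    post_n = np.zeros(n_frames, dtype=int)

    for s in range(n_subsets):
        units = subsets[s]
        key = ("f", s)
        if log_f_cache is not None and key in log_f_cache:
            log_f, f_sum = log_f_cache[key]
        else:
            f = tuning.rates(units)
            log_f, f_sum = np.log(f), f.sum(axis=0)
            if log_f_cache is not None:
                log_f_cache[key] = (log_f, f_sum)
        c_sub = counts[:, units]
        active = c_sub.sum(axis=1) > 0
        if not active.any():
            continue
        # all frames of this subset in one log-space batch
        ll = c_sub[active].astype(log_f.dtype) @ log_f - tau_s * f_sum
        ll -= ll.max(axis=1, keepdims=True)
        post = np.exp(ll)
        z = post.sum(axis=1)
        if not np.all(np.isfinite(z) & (z > 0)):
            raise FloatingPointError(
                f"posterior underflow for subset of {subset_size} units")
        post /= z[:, None]
        subset_com[s, active] = post @ bc
        post_sum[active] += post
        post_n[active] += 1

    pooled = np.full((n_frames, 2), np.nan)
    ok = post_n > 0
    mean_post = np.full((n_frames, bc.shape[0]), np.nan)
    mean_post[ok] = post_sum[ok] / post_n[ok, None]
    pooled[ok] = mean_post[ok] @ bc
    return DecodedTrajectory(
        times=times, pooled_com=pooled, subset_com=subset_com,
        subsets=subsets, window=window, step=step,
        posteriors=mean_post if keep_posteriors else None)


def population_vector_decode(counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Spike-count-weighted mean of field centers for one frame."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("population vector undefined for zero counts")
    return (counts @ centers) / total
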