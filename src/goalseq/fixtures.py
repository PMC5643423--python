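"""Small deterministic synthetic datasets for exercising the analysis stack.

These generators produce decoder- and classifier-ready inputs without
running the spiking network: Poisson spike trains matched to Gaussian
tuning curves (stationary or translating bumps), two-cluster spatial
frames, and toy learned-weight vectors.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .network import SpikeRecord
from .params import LatticeSpec, build_lattice_positions

__all__ = ["make_fixture", "poisson_bump_spikes"]


def poisson_bump_spikes(
    centers: np.ndarray,
    rng: np.random.Generator,
    bump_center,
    duration: float = 200.0,
    peak_rate: float = 100.0,
    sigma: float = 30.0,
    velocity: Optional[np.ndarray] = None,
) -> SpikeRecord:
    """Poisson spikes from units with Gaussian rate profiles around a
    (possibly moving) bump center.

    ``bump_center`` is the position at t=0 (cm); ``velocity`` in cm/ms
    moves it linearly. Rates are ``peak * exp(-d^2/sigma^2)``, matching
    the analytic tuning-curve model.
    """
    bump_center = np.asarray(bump_center, dtype=float)
    dt = 1.0
    n_steps = int(round(duration / dt))
    times, ids = [], []
    for k in range(n_steps):
        c = bump_center if velocity is None else bump_center + velocity * k * dt
        d2 = ((centers - c) ** 2).sum(axis=1)
        lam = peak_rate * np.exp(-d2 / sigma ** 2) * dt / 1000.0
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(len(centers)), counts)
        if len(idx):
            ids.append(idx)
            times.append(k * dt + rng.uniform(0, dt, len(idx)))
    if not times:
        return SpikeRecord(np.empty(0), np.empty(0, dtype=int))
    t = np.concatenate(times)
    i = np.concatenate(ids)
    order = np.argsort(t, kind="stable")
    return SpikeRecord(t[order], i[order])


def make_fixture(kind: str, seed: int, grid_side: int = 40):
    """Deterministic synthetic inputs for decoding/analysis.

    Kinds: ``stationary_bump_spikes``, ``translating_bump_spikes``
    (return (SpikeRecord, centers, metadata)), ``two_blob_frame``
    (positions + weights of a bimodal activity frame),
    ``toy_weight_snapshot`` (a learned-looking context->DG weight vector).
    """
    rng = np.random.default_rng(seed)
    lat = LatticeSpec(grid_side=grid_side)
    centers = build_lattice_positions(lat)

    if kind == "stationary_bump_spikes":
        c = np.array([180.0, 240.0])
        rec = poisson_bump_spikes(centers, rng, c)
        return rec, centers, {"center": c, "sigma": 30.0, "peak": 100.0,
                              "duration": 200.0}
    if kind == "translating_bump_spikes":
        c = np.array([140.0, 140.0])
        v = np.array([0.4, 0.2])  # cm/ms
        rec = poisson_bump_spikes(centers, rng, c, duration=300.0, velocity=v)
        return rec, centers, {"center": c, "velocity": v, "sigma": 30.0,
                              "peak": 100.0, "duration": 300.0}
    if kind == "two_blob_frame":
        a = rng.normal([130.0, 130.0], 12.0, (25, 2))
        b = rng.normal([280.0, 280.0], 12.0, (18, 2))
        pts = np.vstack([a, b])
        w = np.ones(len(pts))
        return pts, w, {"centers": np.array([[130.0, 130.0],
                                             [280.0, 280.0]])}
    if kind == "toy_weight_snapshot":
        goal = np.array([260.0, 160.0])
        d = np.linalg.norm(centers - goal, axis=1)
        W = np.exp(-d ** 2 / 35.0 ** 2) * rng.uniform(0.4, 1.0, len(centers))
        return W, centers, {"goal": goal}
    raise ValueError(f"unknown fixture kind {kind!r}")
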