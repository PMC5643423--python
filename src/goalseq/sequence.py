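"""One sequence-generation episode: bump initialization, bias, endpoint.

A sequence event lasts ``init_ms + bias_ms`` (default 50 + 350 ms). During
initialization the CA3 recurrents are gated on, a place-specific current is
injected into CA3 pyramidal cells at the rat's position, and the active
context population fires at a low rate; an activity bump representing the
current location forms. The place current is then switched off and the
active context rate is stepped up, so that the learned context->DG->CA3
drive biases the bump, which may travel toward the encoded goal. The bump
center of mass at the end of the episode is the next navigational goal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .network import Simulator, SpikeRecord

__all__ = ["SequenceEvent", "run_sequence", "bump_center_of_mass"]


@dataclass
class SequenceEvent:
    """Spiking record and bump track of one sequence-generation episode."""

    start_pos: np.ndarray
    context: str
    spikes: SpikeRecord          # CA3-exc spikes, times relative to onset
    com_times: np.ndarray        # window start times, ms from onset
    com_track: np.ndarray        # (n_windows, 2) bump center of mass, cm
    endpoint: np.ndarray         # final center of mass, cm
    pop_rate: np.ndarray         # per-step CA3-exc spike counts
    init_ms: float = 50.0
    bias_ms: float = 350.0
    degenerate: bool = False
    dg_spikes: Optional[SpikeRecord] = None
    u_samples: Optional[np.ndarray] = None   # sampled CA3-exc potentials
    u_sample_ids: Optional[np.ndarray] = None

    @property
    def duration(self) -> float:
        return self.init_ms + self.bias_ms

    def com_after_init(self) -> np.ndarray:
        """Bump track with the initialization period excluded."""
        return self.com_track[self.com_times >= self.init_ms]

    @property
    def start_to_end_distance(self) -> float:
        track = self.com_after_init()
        return float(np.linalg.norm(track[-1] - track[0]))


def bump_center_of_mass(
    spikes: SpikeRecord,
    centers: np.ndarray,
    t0: float,
    t1: float,
    window: float = 4.0,
    step: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window spatial mean of spiking cells' field centers.

    Windows of ``window`` ms advanced by ``step`` ms over [t0, t1]; each
    window's estimate is the spike-count-weighted mean of the field centers
    of the cells spiking in it. Empty windows carry the previous estimate
    forward. Raises if the record is empty over [t0, t1].
    """
    starts = np.arange(t0, t1 - window + 1e-9, step)
    if len(starts) == 0:
        raise ValueError("analysis interval shorter than one window")
    m = (spikes.times >= t0) & (spikes.times < t1)
    if not np.any(m):
        raise ValueError("no spikes in the analysis interval")
    ts, ids = spikes.times[m], spikes.ids[m]
    order = np.argsort(ts, kind="stable")
    ts, ids = ts[order], ids[order]
    track = np.empty((len(starts), 2))
    prev = None
    lo = np.searchsorted(ts, starts, side="left")
    hi = np.searchsorted(ts, starts + window, side="left")
    for k, (a, b) in enumerate(zip(lo, hi)):
        if b > a:
            prev = centers[ids[a:b]].mean(axis=0)
        if prev is None:
            # leading empty windows: backfill from first estimate later
            track[k] = np.nan
        else:
            track[k] = prev
    if np.isnan(track[:, 0]).any():
        first = track[~np.isnan(track[:, 0])][0]
        track[np.isnan(track[:, 0])] = first
    return starts, track


def run_sequence(
    sim: Simulator,
    ctx_weights: np.ndarray,
    start_pos: np.ndarray,
    context: str,
    *,
    init_ms: float = 50.0,
    bias_ms: float = 350.0,
    on_step: Optional[Callable] = None,
    record_u_ids: Optional[np.ndarray] = None,
    record_dg: bool = False,
    com_window: float = 4.0,
    com_step: float = 2.0,
) -> SequenceEvent:
    """Run one sequence-generation episode on the simulator.

    The CA3 state is reset at onset (membranes at rest, currents cleared):
    place-cell dynamics during the preceding movement do not carry over, so
    the episode is fully determined by the initial bump location, the
    context->DG weights and the noise stream.
    """
    net = sim.net
    p = net.p
    t_onset = sim.t
    sim.reset_membranes()
    sim.reset_currents()

    rate: list = []
    record = ["ca3e"] + (["dg"] if record_dg else [])
    record_u = {"ca3e": record_u_ids} if record_u_ids is not None else None

    out1 = sim.run(
        init_ms,
        ctx_weights=ctx_weights,
        ctx_rate=p.ctx_rate_move,
        place_pos=np.asarray(start_pos, dtype=float),
        place_targets=("ca3e",),
        recurrents_on=True,
        record=record,
        record_u=record_u,
        on_step=on_step,
        rate_out=rate,
    )
    out2 = sim.run(
        bias_ms,
        ctx_weights=ctx_weights,
        ctx_rate=p.ctx_rate_bias,
        place_pos=None,
        recurrents_on=True,
        record=record,
        record_u=record_u,
        on_step=on_step,
        rate_out=rate,
    )

    def _cat(name) -> SpikeRecord:
        return SpikeRecord(
            np.concatenate([out1[name].times, out2[name].times]) - t_onset,
            np.concatenate([out1[name].ids, out2[name].ids]).astype(int),
        )

    spikes = _cat("ca3e")
    dg_rec = _cat("dg") if record_dg else None

    duration = init_ms + bias_ms
    degenerate = False
    if spikes.n_spikes == 0:
        degenerate = True
    else:
        # bump failure: some 20 ms window after initialization without spikes
        post = spikes.times[spikes.times >= init_ms]
        edges = np.arange(init_ms, duration + 1e-9, 20.0)
        counts, _ = np.histogram(post, bins=edges)
        degenerate = bool((counts == 0).any())

    if spikes.n_spikes:
        com_times, com_track = bump_center_of_mass(
            spikes, net.positions, 0.0, duration,
            window=com_window, step=com_step)
        endpoint = com_track[-1].copy()
    else:
        com_times = np.empty(0)
        com_track = np.empty((0, 2))
        endpoint = np.asarray(start_pos, dtype=float).copy()

    u = None
    if record_u_ids is not None:
        u = np.vstack([out1["u_ca3e"], out2["u_ca3e"]])

    return SequenceEvent(
        start_pos=np.asarray(start_pos, dtype=float),
        context=context,
        spikes=spikes,
        com_times=com_times,
        com_track=com_track,
        endpoint=endpoint,
        pop_rate=np.asarray(rate, dtype=float),
        init_ms=init_ms,
        bias_ms=bias_ms,
        degenerate=degenerate,
        dg_spikes=dg_rec,
        u_samples=u,
        u_sample_ids=record_u_ids,
    )
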