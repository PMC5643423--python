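"""Serialization of simulation outputs.

Spike trains, sequence events and weight snapshots go into one HDF5
archive per run; summary tables (trial statistics, sweep results) are
plain CSV.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .behavior import TrialLog, WeightSnapshot
from .network import SpikeRecord
from .sequence import SequenceEvent

__all__ = ["trial_table", "save_block", "load_snapshots", "load_events"]


def trial_table(logs: Sequence[TrialLog], network_id: int = 0) -> pd.DataFrame:
    """One row per trial phase: latency, endpoint error, sequence span."""
    rows = []
    for lg in logs:
        rows.append({
            "network": network_id,
            "trial": lg.trial,
            "phase": lg.phase,
            "latency_s": lg.latency_s,
            "endpoint_error_cm": lg.endpoint_error,
            "seq_distance_cm": lg.sequence.start_to_end_distance
            if lg.sequence.spikes.n_spikes else 0.0,
            "degenerate": lg.sequence.degenerate,
            "n_events": len(lg.events),
        })
    return pd.DataFrame(rows)


def save_block(path, logs: Sequence[TrialLog],
               snapshots: Sequence[WeightSnapshot] = (),
               network_id: int = 0, mode: str = "a") -> None:
    """Append one network's trial phases and weight snapshots to an archive."""
    with h5py.File(path, mode) as h5:
        g = h5.create_group(f"network{network_id}")
        for k, lg in enumerate(logs):
            ge = g.create_group(f"phase{k:03d}")
            ge.attrs.update({"trial": lg.trial, "phase": lg.phase,
                             "latency_s": lg.latency_s,
                             "endpoint_error_cm": lg.endpoint_error})
            ge.create_dataset("start_pos", data=lg.start_pos)
            ge.create_dataset("reward_pos", data=lg.reward_pos)
            ge.create_dataset("path", data=lg.path, compression="gzip")
            ev = lg.sequence
            ge.create_dataset("spike_times", data=ev.spikes.times,
                              compression="gzip")
            ge.create_dataset("spike_ids", data=ev.spikes.ids,
                              compression="gzip")
            ge.create_dataset("com_times", data=ev.com_times)
            ge.create_dataset("com_track", data=ev.com_track)
            ge.create_dataset("endpoint", data=ev.endpoint)
            ge.create_dataset("pop_rate", data=ev.pop_rate,
                              compression="gzip")
        gs = g.create_group("snapshots")
        for k, sn in enumerate(snapshots):
            gg = gs.create_group(f"snap{k:03d}")
            gg.attrs.update({"trial": sn.trial, "phase": sn.phase})
            gg.create_dataset("start_pos", data=sn.start_pos)
            gg.create_dataset("W_home", data=sn.W_home, compression="gzip")
            gg.create_dataset("W_away", data=sn.W_away, compression="gzip")


def load_snapshots(path, min_trial: int = 2) -> list[tuple[np.ndarray, np.ndarray]]:
    """(active-context weights, start position) pairs from an archive.

    Only phases from ``min_trial`` on are returned (post-learning by
    default), with the weight vector of the context that was active.
    """
    pairs = []
    with h5py.File(path, "r") as h5:
        for gname in sorted(h5):
            g = h5[gname]
            if "snapshots" not in g:
                continue
            for sname in sorted(g["snapshots"]):
                sn = g["snapshots"][sname]
                if sn.attrs["trial"] < min_trial:
                    continue
                key = "W_home" if sn.attrs["phase"] == "home" else "W_away"
                pairs.append((sn[key][...], sn["start_pos"][...]))
    return pairs


def load_events(path) -> list[dict]:
    """Sequence events (spikes, COM tracks, metadata) from an archive."""
    out = []
    with h5py.File(path, "r") as h5:
        for gname in sorted(h5):
            g = h5[gname]
            for pname in sorted(k for k in g if k.startswith("phase")):
                ge = g[pname]
                out.append({
                    "network": gname, "trial": int(ge.attrs["trial"]),
                    "phase": str(ge.attrs["phase"]),
                    "spikes": SpikeRecord(ge["spike_times"][...],
                                          ge["spike_ids"][...]),
                    "com_times": ge["com_times"][...],
                    "com_track": ge["com_track"][...],
                    "endpoint": ge["endpoint"][...],
                    "pop_rate": ge["pop_rate"][...],
                    "start_pos": ge["start_pos"][...],
                    "reward_pos": ge["reward_pos"][...],
                })
    return out
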