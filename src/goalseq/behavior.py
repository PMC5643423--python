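"""Home/Away foraging task with sequence-guided navigation.

A square 2 m x 2 m arena centered in the virtual environment carries a
6 x 6 grid of 36 feeder wells (~33 cm pitch). Home trial phases (reward at
a fixed, per-network Home well) alternate with Away phases (reward at a
random well). At each phase onset the matching context population is
activated, one place-cell sequence is generated, and the rat navigates to
the sequence endpoint; it then probes the nearest well, performs a focal
search over the four wells nearest the endpoint, and finally an exhaustive
search over the remaining wells. Finding reward triggers a +1 phasic
signal; probing the endpoint well and finding it unbaited triggers a
single -1 signal.

Neural simulation during movement is restricted to windows around the
reward events: eligibility traces decay with tau_trace = 100 ms, so spikes
older than 6 tau before an event contribute < 0.3% to the weight update
and movement outside these windows is advanced kinematically, with traces
decayed in closed form.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import Network, Simulator
from .plasticity import PlasticityState, REWARD_DURATION
from .sequence import SequenceEvent, run_sequence

__all__ = ["Arena", "TrialLog", "navigate_to", "focal_search",
           "random_search", "run_block", "WeightSnapshot"]

TRACE_HORIZON = 600.0  # ms of pre-event movement simulated for traces


@dataclass(frozen=True)
class Arena:
    """Feeder layout and movement kinematics of the foraging task."""

    arena_side: float = 200.0
    arena_offset: float = 110.0   # arena origin in environment coordinates
    n_side: int = 6
    reward_radius: float = 5.0    # cm
    speed: float = 15.0           # cm/s
    step_ms: float = 100.0
    motion_noise_var: float = 0.5  # cm^2, per movement-vector component

    @property
    def wells(self) -> np.ndarray:
        """(36, 2) feeder coordinates in environment cm, row-major grid."""
        pitch = self.arena_side / self.n_side
        c = self.arena_offset + (np.arange(self.n_side) + 0.5) * pitch
        xx, yy = np.meshgrid(c, c, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def step_length(self) -> float:
        return self.speed * self.step_ms / 1000.0

    @property
    def corners(self) -> np.ndarray:
        o, s = self.arena_offset, self.arena_side
        return np.array([[o, o], [o + s, o], [o, o + s], [o + s, o + s]])

    def clip(self, pos: np.ndarray) -> np.ndarray:
        o, s = self.arena_offset, self.arena_side
        return np.clip(pos, o, o + s)


@dataclass
class TrialLog:
    """Behavioral record of one trial phase."""

    trial: int
    phase: str                     # "home" | "away"
    start_pos: np.ndarray
    reward_pos: np.ndarray
    sequence: SequenceEvent
    path: np.ndarray               # (n_steps+1, 2), one row per motion step
    latency_s: float               # phase onset -> reward discovery
    endpoint_error: float          # ||sequence endpoint - baited well||
    events: list = field(default_factory=list)  # (time_ms from onset, kind)


@dataclass
class WeightSnapshot:
    """Context->DG weights at a phase boundary (before the phase's updates)."""

    trial: int
    phase: str
    start_pos: np.ndarray
    W_home: np.ndarray
    W_away: np.ndarray


def navigate_to(
    pos: np.ndarray,
    target: np.ndarray,
    arena: Arena,
    rng: np.random.Generator,
    max_steps: int = 10_000,
) -> np.ndarray:
    """Noisy straight-line walk from ``pos`` until within reward radius.

    Each 100 ms step displaces the rat by ``speed * step`` along the unit
    vector toward the target plus independent Gaussian noise per component.
    Returns the path including the start position.
    """
    pos = np.asarray(pos, dtype=float).copy()
    target = np.asarray(target, dtype=float)
    sd = np.sqrt(arena.motion_noise_var)
    path = [pos.copy()]
    for _ in range(max_steps):
        if np.linalg.norm(pos - target) <= arena.reward_radius:
            break
        vec = target - pos
        dist = np.linalg.norm(vec)
        step = arena.step_length * vec / dist + rng.normal(0.0, sd, 2)
        pos = arena.clip(pos + step)
        path.append(pos.copy())
    else:
        raise RuntimeError("navigation step cap exceeded")
    return np.asarray(path)


def focal_search(endpoint: np.ndarray, arena: Arena) -> np.ndarray:
    """Indices of the four wells nearest the endpoint, nearest first.

    Ties are broken by well index.
    """
    d = np.linalg.norm(arena.wells - np.asarray(endpoint, dtype=float), axis=1)
    order = np.lexsort((np.arange(len(d)), d))
    return order[:4]


def random_search(
    visited: set,
    current_pos: np.ndarray,
    arena: Arena,
    rng: Optional[np.random.Generator] = None,
    mode: str = "nearest",
) -> list:
    """Order in which the remaining wells are probed (each exactly once).

    ``nearest``: greedy nearest-unvisited-first from the current position
    (deterministic); ``uniform``: a uniformly random permutation.
    """
    remaining = [i for i in range(len(arena.wells)) if i not in visited]
    if mode == "uniform":
        if rng is None:
            raise ValueError("uniform mode needs an rng")
        return list(rng.permutation(remaining))
    order = []
    pos = np.asarray(current_pos, dtype=float)
    rem = set(remaining)
    while rem:
        ds = {i: np.linalg.norm(arena.wells[i] - pos) for i in rem}
        nxt = min(sorted(rem), key=lambda i: ds[i])
        order.append(nxt)
        pos = arena.wells[nxt]
        rem.discard(nxt)
    return order


def _walk_phase(
    start: np.ndarray,
    endpoint: np.ndarray,
    baited: np.ndarray,
    arena: Arena,
    rng: np.random.Generator,
    search_mode: str = "uniform",
) -> tuple[np.ndarray, float, Optional[float], list]:
    """Kinematic walk of one phase: endpoint, probe, focal, random search.

    Returns (path, t_reward_ms, t_omission_ms or None, events).
    Times are ms from walk onset; position at step k is path[k].
    """
    wells = arena.wells
    endpoint = arena.clip(np.asarray(endpoint, dtype=float))
    focal = focal_search(endpoint, arena)
    probe_well = int(focal[0])

    pos = np.asarray(start, dtype=float).copy()
    path = [pos.copy()]
    sd = np.sqrt(arena.motion_noise_var)
    visited: set = set()
    events: list = []
    t_omission: Optional[float] = None

    # waypoints are generated lazily: endpoint, then wells in search order
    def waypoint_stream():
        yield ("endpoint", endpoint)
        for w in focal:
            yield ("well", int(w))
        for w in random_search(visited, path[-1], arena, rng, search_mode):
            yield ("well", int(w))

    stream = waypoint_stream()
    kind, wp = next(stream)
    t = 0.0
    for _ in range(200_000):
        target = wells[wp] if kind == "well" else wp
        if np.linalg.norm(pos - baited) <= arena.reward_radius:
            events.append((t, "reward"))
            return np.asarray(path), t, t_omission, events
        # mark any well we pass through as visited
        near = np.linalg.norm(wells - pos, axis=1) <= arena.reward_radius
        for i in np.flatnonzero(near):
            if i not in visited:
                visited.add(int(i))
                if int(i) == probe_well and t_omission is None:
                    t_omission = t
                    events.append((t, "reward_omission"))
        if np.linalg.norm(pos - target) <= arena.reward_radius:
            try:
                while True:
                    kind, wp = next(stream)
                    if kind == "endpoint" or wp not in visited:
                        break
            except StopIteration:
                raise RuntimeError("search exhausted without finding reward")
            continue
        vec = target - pos
        step = arena.step_length * vec / np.linalg.norm(vec) + rng.normal(0, sd, 2)
        pos = arena.clip(pos + step)
        path.append(pos.copy())
        t += arena.step_ms
    raise RuntimeError("phase step cap exceeded")


def _interp_path(path: np.ndarray, step_ms: float):
    """Piecewise-linear position lookup, ms from walk onset."""
    n = len(path)

    def f(t_ms: float) -> np.ndarray:
        x = min(max(t_ms / step_ms, 0.0), n - 1.0)
        k = int(x)
        if k >= n - 1:
            return path[-1]
        frac = x - k
        return path[k] * (1 - frac) + path[k + 1] * frac

    return f


def run_block(
    net: Network,
    arena: Arena,
    n_pairs: int,
    rng: np.random.Generator,
    *,
    home_well: int = 0,
    plasticity: Optional[PlasticityState] = None,
    search_mode: str = "uniform",
    snapshots: Optional[list] = None,
) -> tuple[list[TrialLog], PlasticityState]:
    """Run ``n_pairs`` alternating Home/Away trial phases.

    The rat starts in a random arena corner; afterwards each phase starts
    at the previous reward site. Returns the per-phase trial logs and the
    final plasticity state; ``snapshots``, when given, collects the
    context->DG weight vectors at every phase onset.
    """
    sim = Simulator(net, rng)
    ps = plasticity or PlasticityState.init(
        net.n, rng, w_init_max=net.p.w_ctx_init_max)
    ps._dt_hint = net.p.dt
    wells = arena.wells
    pos = arena.corners[rng.integers(4)].astype(float)
    logs: list[TrialLog] = []

    for trial in range(1, n_pairs + 1):
        for phase in ("home", "away"):
            if phase == "home":
                baited_idx = home_well
            else:
                choices = [i for i in range(len(wells)) if i != home_well]
                baited_idx = int(rng.choice(choices))
            baited = wells[baited_idx]
            if snapshots is not None:
                snapshots.append(WeightSnapshot(
                    trial, phase, pos.copy(),
                    ps.W_home.copy(), ps.W_away.copy()))

            t_onset = sim.t
            W_ctx = ps.weights(phase)
            hook = ps.make_hook(phase)
            ev = run_sequence(sim, W_ctx, pos, phase, on_step=hook)

            path, t_rew, t_omit, events = _walk_phase(
                pos, ev.endpoint, baited, arena, rng, search_mode)
            pos_at = _interp_path(path, arena.step_ms)
            t_walk0 = sim.t  # absolute time the walk starts

            # reward-event windows that require spiking simulation
            ev_times = []
            if t_omit is not None:
                ev_times.append((t_omit, -1))
            ev_times.append((t_rew, +1))
            windows = []
            for t_evt, r in ev_times:
                w0 = max(0.0, t_evt - TRACE_HORIZON)
                if windows and w0 <= windows[-1][1]:
                    windows[-1][1] = t_evt + REWARD_DURATION
                    windows[-1][2].append((t_evt, r))
                else:
                    windows.append([w0, t_evt + REWARD_DURATION, [(t_evt, r)]])

            for w0, w1, evs in windows:
                gap = (t_walk0 + w0) - sim.t
                if gap > 0:
                    ps.decay_traces(gap)
                    sim.t += gap
                cursor = w0
                for t_evt, r in evs:
                    if t_evt > cursor:
                        sim.run(t_evt - cursor, ctx_weights=W_ctx,
                                ctx_rate=net.p.ctx_rate_move,
                                place_pos=lambda tm: pos_at(tm - t_walk0),
                                simulate_ca3=False, on_step=hook)
                        cursor = t_evt
                    ps.set_reward(r, sim.t)
                # reward (or omission) window: during +1 the rat sits at the
                # reward site consuming; during -1 it keeps searching
                last_r = evs[-1][1]
                place = (np.asarray(path[-1], dtype=float) if last_r > 0
                         else (lambda tm: pos_at(tm - t_walk0)))
                sim.run(w1 - cursor, ctx_weights=W_ctx,
                        ctx_rate=net.p.ctx_rate_move,
                        place_pos=place, simulate_ca3=False, on_step=hook)
            ps.R = 0

            latency_s = (ev.duration + t_rew) / 1000.0
            logs.append(TrialLog(
                trial=trial, phase=phase, start_pos=pos.copy(),
                reward_pos=baited.copy(), sequence=ev, path=path,
                latency_s=latency_s,
                endpoint_error=float(np.linalg.norm(
                    arena.clip(ev.endpoint) - baited)),
                events=[(ev.duration + t, k) for t, k in events],
            ))
            pos = path[-1].copy()
    return logs, ps
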