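"""Reward-gated Hebbian plasticity with eligibility traces at context->DG.

Each context cell projects to exactly one DG granule cell, so the learnable
weights of either context population form a vector over DG cells. Pre- and
postsynaptic eligibility traces decay exponentially (tau_trace) and are set
to 1 whenever the corresponding neuron spikes. A phasic reward signal R
gates the weight change:

    dw/dt = alpha_L * [x * y - w]+   if R = +1   (saturating potentiation)
    dw/dt = -alpha_L * x * y         if R = -1   (depression, floored at 0)
    dw/dt = 0                        if R =  0

The saturating (x*y - w) form makes learning one-shot rather than
accumulative: repeated visits to a rewarded place converge to the same
weight as a single visit, avoiding occupancy bias.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["PlasticityState"]

REWARD_DURATION = 100.0  # ms the phasic reward signal stays non-zero


@dataclass
class PlasticityState:
    """Traces, reward signal and the learnable context->DG weight vectors."""

    n: int
    tau_trace: float = 100.0  # ms
    alpha_L: float = 50.0     # learning rate, nA/s
    x_home: np.ndarray = field(default=None)  # presynaptic traces
    x_away: np.ndarray = field(default=None)
    y: np.ndarray = field(default=None)       # postsynaptic (DG) traces
    W_home: np.ndarray = field(default=None)  # nA
    W_away: np.ndarray = field(default=None)
    R: int = 0
    R_until: float = -np.inf  # simulation time the reward signal expires

    @classmethod
    def init(cls, n: int, rng: np.random.Generator,
             w_init_max: float = 0.3, **kw) -> "PlasticityState":
        st = cls(n=n, **kw)
        st.x_home = np.zeros(n)
        st.x_away = np.zeros(n)
        st.y = np.zeros(n)
        st.W_home = rng.uniform(0.0, w_init_max, size=n)
        st.W_away = rng.uniform(0.0, w_init_max, size=n)
        return st

    # ------------------------------------------------------------------
    def weights(self, context: str) -> np.ndarray:
        return self.W_home if context == "home" else self.W_away

    def x_trace(self, context: str) -> np.ndarray:
        return self.x_home if context == "home" else self.x_away

    def decay_traces(self, dt: float) -> None:
        f = np.exp(-dt / self.tau_trace)
        self.x_home *= f
        self.x_away *= f
        self.y *= f

    def update_traces(self, dt: float, ctx_spikes: Optional[np.ndarray],
                      dg_spikes: Optional[np.ndarray], context: str) -> None:
        """Decay all traces by one step, then register this step's spikes."""
        self.decay_traces(dt)
        if ctx_spikes is not None:
            self.x_trace(context)[ctx_spikes > 0] = 1.0
        if dg_spikes is not None:
            self.y[dg_spikes] = 1.0

    # ------------------------------------------------------------------
    def set_reward(self, value: int, t_now: float,
                   duration: float = REWARD_DURATION) -> None:
        self.R = int(value)
        self.R_until = t_now + duration

    def reward_active(self, t_now: float) -> bool:
        return self.R != 0 and t_now <= self.R_until

    def apply_reward_update(self, dt: float, context: str) -> None:
        """One Euler step of the gated rule on the active context's weights.

        Only the projection of the currently active context population is
        plastic in a given trial phase (contextual selectivity).
        """
        if self.R == 0:
            return
        a = self.alpha_L * dt / 1000.0
        W = self.weights(context)
        xy = self.x_trace(context) * self.y
        if self.R > 0:
            W += a * np.maximum(xy - W, 0.0)
        else:
            np.clip(W - a * xy, 0.0, None, out=W)

    # ------------------------------------------------------------------
    def make_hook(self, context: str):
        """Per-step callback for :meth:`goalseq.network.Simulator.run`."""
        def on_step(t_ms, ctx_counts, dg_spikes, _dt=None):
            dt = _dt if _dt is not None else self._dt_hint
            self.update_traces(dt, ctx_counts, dg_spikes, context)
            if self.reward_active(t_ms):
                self.apply_reward_update(dt, context)
            elif self.R != 0 and t_ms > self.R_until:
                self.R = 0
        return on_step

    _dt_hint: float = 0.2
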