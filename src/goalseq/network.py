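"""Spiking circuit: context -> DG -> CA3 (exc + inh) with attractor dynamics.

The circuit contains five populations. Two cortical context populations
("Home" and "Away") fire as Poisson processes and project one-to-one onto
dentate-gyrus (DG) granule cells through learnable weights. DG cells project
to CA3 pyramidal cells with a local Gaussian footprint; CA3 pyramidal cells
are recurrently connected with a broader Gaussian profile and interact with
a single pool of interneurons providing global, delayed inhibition. DG and
CA3 cells are leaky integrate-and-fire neurons with current-based synapses
(instantaneous rise, exponential decay); all linear equations are advanced
by exact integration at a fixed step.

Weight-density rescaling: when the lattice is coarser than the reference
80 x 80 grid (same environment size, fewer cells), per-synapse weights of
the spatially convergent projections are multiplied by the cell-density
ratio so that the summed synaptic current each neuron receives is preserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import sparse

from .params import (
    REFERENCE_SPACING,
    LatticeSpec,
    NeuronParams,
    PlaceFieldSpec,
    SynapseSpec,
    build_lattice_positions,
    gaussian_weight,
)

__all__ = [
    "NetworkParams",
    "Network",
    "Simulator",
    "SpikeRecord",
    "build_network",
    "poisson_context_spikes",
]

#: reference population sizes of the full-scale model
REF_N_EXC = 6400
REF_N_INH = 259


@dataclass(frozen=True)
class NetworkParams:
    """Complete static description of the circuit."""

    lattice: LatticeSpec = LatticeSpec()
    n_inh: int = REF_N_INH
    dt: float = 0.2  # integration step, ms

    dg: NeuronParams = NeuronParams(t_refr=3.0, noise_sd=0.0)
    ca3e: NeuronParams = NeuronParams(t_refr=3.0, noise_sd=2.0)
    ca3i: NeuronParams = NeuronParams(t_refr=4.0, noise_sd=2.0)

    # Peak per-spike current increments (nA). The spatial profiles, time
    # constants, delays and topologies follow the source architecture; the
    # three CA3-internal gains (DG->CA3 peak, recurrent peak, inh->inh) are
    # calibrated by mean-field balance so that the attractor operates in a
    # sparse, inhibition-stabilized regime (persistent ~50 cm bump at
    # 10-20 Hz with ripple-band population oscillations) instead of
    # refractory-limited saturation; see docs/methods.md.
    ctx_dg: SynapseSpec = SynapseSpec(tau=6.0, delay=0.0, weight_max=0.3,
                                      topology="one-to-one")
    dg_ca3: SynapseSpec = SynapseSpec(tau=6.0, delay=0.0, weight_max=0.2,
                                      sigma=50.0, cutoff=50.0,
                                      topology="gaussian-local")
    ca3_rec: SynapseSpec = SynapseSpec(tau=6.0, delay=2.5, weight_max=0.02,
                                       sigma=50.0, autapses=False,
                                       topology="gaussian-all-to-all")
    exc_inh: SynapseSpec = SynapseSpec(tau=6.0, delay=2.5, weight_max=0.00975)
    inh_exc: SynapseSpec = SynapseSpec(tau=2.0, delay=2.5, weight_max=0.01845)
    inh_inh: SynapseSpec = SynapseSpec(tau=2.0, delay=2.5, weight_max=0.05)

    placefield: PlaceFieldSpec = PlaceFieldSpec()

    #: interpretation of the membrane-noise amplitude (mV/ms):
    #: "sqrt_dt" = white-noise (Wiener) scaling, per-step sd noise_sd*sqrt(dt);
    #: "dt" = per-ms increment scaling, per-step sd noise_sd*dt.
    #: Default "dt": with the white-noise reading the pre-learning bump
    #: diffuses measurably within one episode; "dt" keeps it stationary.
    noise_scaling: str = "dt"

    #: context Poisson rates (Hz) during movement and sequence bias
    ctx_rate_move: float = 10.0
    ctx_rate_bias: float = 200.0

    #: initial range of the learnable context->DG weights, nA
    w_ctx_init_max: float = 0.3

    @property
    def density_factor(self) -> float:
        """Per-weight scale factor preserving summed input at coarser grids."""
        return (self.lattice.spacing / REFERENCE_SPACING) ** 2

    @property
    def fluctuation_factor(self) -> float:
        """Per-weight factor preserving input *fluctuations* at coarser grids.

        The DG->CA3 goal bias recruits CA3 cells through threshold
        crossings driven by shot-noise fluctuations of the mossy-fiber
        input, whose amplitude scales as weight * sqrt(density); keeping
        the bias effective therefore requires weight proportional to the
        lattice spacing rather than to its square.
        """
        return self.lattice.spacing / REFERENCE_SPACING


class Network:
    """Built weight structures plus integration coefficients."""

    def __init__(self, params: NetworkParams):
        self.p = params
        lat = params.lattice
        self.n = lat.n_cells
        self.n_inh = params.n_inh
        self.positions = build_lattice_positions(lat)

        dens = params.density_factor
        self.W_dgca3 = self._build_gaussian_matrix(
            replace(params.dg_ca3,
                    weight_max=params.dg_ca3.weight_max * params.fluctuation_factor)
        )
        rec = replace(params.ca3_rec, weight_max=params.ca3_rec.weight_max * dens)
        self.W_rec = self._build_dense_gaussian(rec)

        # uniform projections: scale by sender-count ratio so total drive on
        # each target matches the full-scale model
        self.w_ei = params.exc_inh.weight_max * (REF_N_EXC / self.n)
        self.w_ie = params.inh_exc.weight_max * (REF_N_INH / self.n_inh)
        self.w_ii = params.inh_inh.weight_max * (REF_N_INH / self.n_inh)

        dt = params.dt
        self.delay_steps = {
            name: int(np.ceil(getattr(params, name).delay / dt - 1e-12))
            for name in ("ctx_dg", "dg_ca3", "ca3_rec", "exc_inh",
                         "inh_exc", "inh_inh")
        }
        self._coeffs = {
            "dg": _integration_coeffs(params.dg, dt),
            "ca3e": _integration_coeffs(params.ca3e, dt),
            "ca3i": _integration_coeffs(params.ca3i, dt),
        }
        self.decay_exc = np.exp(-dt / params.dg_ca3.tau)   # tau_exc = 6 ms
        self.decay_inh = np.exp(-dt / params.inh_exc.tau)  # tau_inh = 2 ms

    def _build_gaussian_matrix(self, spec: SynapseSpec) -> sparse.csr_matrix:
        """Sparse (pre x post) matrix for a local Gaussian projection."""
        pos = self.positions
        side = self.p.lattice.grid_side
        spacing = self.p.lattice.spacing
        cutoff = spec.cutoff if spec.cutoff is not None else np.inf
        reach = int(np.ceil(cutoff / spacing))
        rows, cols, vals = [], [], []
        offs = np.arange(-reach, reach + 1)
        di, dj = np.meshgrid(offs, offs, indexing="ij")
        d = spacing * np.hypot(di, dj)
        keep = d <= cutoff
        di, dj, d = di[keep], dj[keep], d[keep]
        w = gaussian_weight(d, spec)
        ii = np.arange(side)
        for k in range(len(di)):
            r = ii[(ii + di[k] >= 0) & (ii + di[k] < side)]
            c = ii[(ii + dj[k] >= 0) & (ii + dj[k] < side)]
            if len(r) == 0 or len(c) == 0:
                continue
            rr, cc = np.meshgrid(r, c, indexing="ij")
            pre = rr * side + cc
            post = (rr + di[k]) * side + (cc + dj[k])
            rows.append(pre.ravel())
            cols.append(post.ravel())
            vals.append(np.full(pre.size, w[k]))
        mat = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )
        if not spec.autapses:
            mat.setdiag(0.0)
        return mat.tocsr()

    def _build_dense_gaussian(self, spec: SynapseSpec) -> np.ndarray:
        pos = self.positions.astype(np.float32)
        d2 = np.zeros((self.n, self.n), dtype=np.float32)
        for ax in (0, 1):
            dx = pos[:, ax, None] - pos[None, :, ax]
            np.square(dx, out=dx)
            d2 += dx
        W = np.float32(spec.weight_max) * np.exp(-d2 / np.float32(spec.sigma ** 2))
        if spec.cutoff is not None:
            W[d2 > spec.cutoff ** 2] = 0.0
        if not spec.autapses:
            np.fill_diagonal(W, 0.0)
        return W.astype(np.float32)


def _integration_coeffs(np_: NeuronParams, dt: float) -> dict:
    """Closed-form update coefficients for the linear membrane equation.

    For ``C du/dt = -g_L (u - E_L) + I_syn(t) + I_ext`` with
    ``I_syn(t) = I0 exp(-t/tau_s)`` the solution over one step is
    ``u(dt) = E_L + (u0 - E_L) a_m + I0 b_s + I_ext c`` with the
    coefficients below.
    """
    tau_m = np_.tau_m
    a_m = np.exp(-dt / tau_m)

    def b(tau_s: float) -> float:
        return (1.0 / np_.C) * (np.exp(-dt / tau_s) - a_m) / (1.0 / tau_m - 1.0 / tau_s)

    return {
        "a_m": a_m,
        "b_exc": b(6.0),
        "b_inh": b(2.0),
        "c_ext": (1.0 / np_.g_L) * (1.0 - a_m),
        "refr_steps": int(round(np_.t_refr / dt)),
    }


@dataclass
class SpikeRecord:
    """Spikes of one population: parallel arrays of times (ms) and cell ids."""

    times: np.ndarray
    ids: np.ndarray

    def in_window(self, t0: float, t1: float) -> "SpikeRecord":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRecord(self.times[m], self.ids[m])

    @property
    def n_spikes(self) -> int:
        return len(self.times)


def poisson_context_spikes(
    rate: float, n: int, window: float, rng: np.random.Generator
) -> SpikeRecord:
    """Independent homogeneous Poisson trains for ``n`` context cells.

    ``rate`` in Hz, ``window`` in ms. Returns spikes sorted by time.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    counts = rng.poisson(rate * window / 1000.0, size=n)
    ids = np.repeat(np.arange(n), counts)
    times = rng.uniform(0.0, window, size=counts.sum())
    order = np.argsort(times, kind="stable")
    return SpikeRecord(times[order], ids[order])


class Simulator:
    """Time-evolving state of the circuit, advanced by exact integration.

    The simulator owns the membrane potentials, synaptic currents,
    refractory clocks and the delayed-spike ring buffers. A single
    :meth:`run` call advances the state over a window with fixed drive
    conditions; callers chain runs to schedule phases (bump initialization,
    contextual bias, movement).
    """

    def __init__(self, net: Network, rng: np.random.Generator):
        self.net = net
        self.rng = rng
        self.t = 0.0  # simulation clock, ms
        p = net.p
        n, n_i = net.n, net.n_inh
        EL = p.dg.E_L
        self.u_dg = np.full(n, EL)
        self.u_e = np.full(n, p.ca3e.E_L)
        self.u_i = np.full(n_i, p.ca3i.E_L)
        self.Ie_dg = np.zeros(n)
        self.Ie_e = np.zeros(n)
        self.Ii_e = np.zeros(n)
        self.Ie_i = np.zeros(n_i)
        self.Ii_i = np.zeros(n_i)
        self.refr_dg = np.zeros(n, dtype=np.int64)   # steps remaining
        self.refr_e = np.zeros(n, dtype=np.int64)
        self.refr_i = np.zeros(n_i, dtype=np.int64)
        # ring buffers for delayed projections (slot 0 = next step)
        L = max(net.delay_steps.values()) + 2
        self._ring_len = L
        self._ring_ee = np.zeros((L, n))        # exc->exc current increments
        self._ring_ei = np.zeros(L)             # exc spike counts -> inh
        self._ring_ie = np.zeros(L)             # inh spike counts -> exc
        self._ring_ii = np.zeros(L)             # inh spike counts -> inh
        self._slot = 0

    # ------------------------------------------------------------------
    def reset_currents(self) -> None:
        for a in (self.Ie_dg, self.Ie_e, self.Ii_e, self.Ie_i, self.Ii_i):
            a[:] = 0.0
        self._ring_ee[:] = 0.0
        for r in (self._ring_ei, self._ring_ie, self._ring_ii):
            r[:] = 0.0

    def reset_membranes(self) -> None:
        self.u_dg[:] = self.net.p.dg.E_L
        self.u_e[:] = self.net.p.ca3e.E_L
        self.u_i[:] = self.net.p.ca3i.E_L
        self.refr_dg[:] = 0
        self.refr_e[:] = 0
        self.refr_i[:] = 0

    # ------------------------------------------------------------------
    def run(
        self,
        duration: float,
        *,
        ctx_weights: Optional[np.ndarray] = None,
        ctx_rate: float = 0.0,
        place_pos: Optional[Callable[[float], np.ndarray] | np.ndarray] = None,
        place_targets: Sequence[str] = ("dg", "ca3e"),
        recurrents_on: bool = False,
        simulate_ca3: bool = True,
        record: Sequence[str] = (),
        record_u: Optional[dict] = None,
        on_step: Optional[Callable] = None,
        rate_out: Optional[list] = None,
    ) -> dict:
        """Advance the circuit by ``duration`` ms under fixed drive.

        Parameters
        ----------
        ctx_weights
            One-to-one weights (nA) of the currently active context
            population onto DG; ``None`` silences all context input.
        ctx_rate
            Poisson rate (Hz) of the active context population.
        place_pos
            Rat position for the place-field drive: a static ``(2,)`` array
            or a callable ``t_ms -> position``; ``None`` switches the
            place current off.
        recurrents_on
            Gate for CA3 recurrent and exc->inh transmission (ON during
            sequence generation, OFF during movement).
        simulate_ca3
            When False only context and DG are advanced (movement phases,
            where CA3 activity has no effect on learning or behavior).
        record
            Population names among {"dg", "ca3e", "ca3i", "ctx"} whose
            spikes are returned as :class:`SpikeRecord`.
        record_u
            Mapping ``{"ca3e": indices}``; sampled membrane potentials are
            returned as arrays of shape (n_steps, len(indices)).
        on_step
            Callback ``(t_ms, ctx_spike_counts, dg_spike_mask)`` invoked
            after every step (used for plasticity traces).
        rate_out
            If a list is supplied, per-step CA3-exc spike counts are
            appended to it.
        """
        net = self.net
        p = net.p
        dt = p.dt
        n_steps = int(round(duration / dt))
        n = net.n
        c_dg = net._coeffs["dg"]
        c_e = net._coeffs["ca3e"]
        c_i = net._coeffs["ca3i"]
        EL_dg, EL_e, EL_i = p.dg.E_L, p.ca3e.E_L, p.ca3i.E_L
        Vt_dg, Vt_e, Vt_i = p.dg.V_theta, p.ca3e.V_theta, p.ca3i.V_theta

        if p.noise_scaling == "sqrt_dt":
            sd_e = p.ca3e.noise_sd * np.sqrt(dt)
            sd_i = p.ca3i.noise_sd * np.sqrt(dt)
        elif p.noise_scaling == "dt":
            sd_e = p.ca3e.noise_sd * dt
            sd_i = p.ca3i.noise_sd * dt
        else:
            raise ValueError(f"unknown noise_scaling {p.noise_scaling!r}")

        lam_ctx = ctx_rate * dt / 1000.0
        static_pos = None
        if place_pos is not None and not callable(place_pos):
            static_pos = np.asarray(place_pos, dtype=float)

        from .params import place_current as _pc

        Iext_dg = np.zeros(n)
        Iext_e = np.zeros(n)
        if static_pos is not None:
            cur = _pc(static_pos, net.positions, p.placefield)
            if "dg" in place_targets:
                Iext_dg = cur
            if "ca3e" in place_targets:
                Iext_e = cur

        rec_sets = {name: ([], []) for name in record}
        u_traces = {}
        if record_u:
            u_traces = {k: np.empty((n_steps, len(v))) for k, v in record_u.items()}

        d_ee = net.delay_steps["ca3_rec"]
        d_ei = net.delay_steps["exc_inh"]
        d_ie = net.delay_steps["inh_exc"]
        d_ii = net.delay_steps["inh_inh"]
        L = self._ring_len
        rng = self.rng

        for k in range(n_steps):
            t_now = self.t
            slot = self._slot

            # --- context Poisson spikes -> DG excitatory current (no delay)
            if ctx_weights is not None and lam_ctx > 0.0:
                ctx_counts = rng.poisson(lam_ctx, size=n)
                self.Ie_dg += ctx_counts * ctx_weights
            else:
                ctx_counts = None

            if callable(place_pos):
                cur = _pc(np.asarray(place_pos(t_now), dtype=float),
                          net.positions, p.placefield)
                if "dg" in place_targets:
                    Iext_dg = cur
                if "ca3e" in place_targets:
                    Iext_e = cur

            # --- deliver delayed spikes scheduled for this step
            if simulate_ca3:
                self.Ie_e += self._ring_ee[slot]
                self._ring_ee[slot] = 0.0
                self.Ie_i += self._ring_ei[slot] * net.w_ei
                self._ring_ei[slot] = 0.0
                self.Ii_e += self._ring_ie[slot] * net.w_ie
                self._ring_ie[slot] = 0.0
                self.Ii_i += self._ring_ii[slot] * net.w_ii
                self._ring_ii[slot] = 0.0

            # --- DG membrane update (no noise, no inhibition)
            self.u_dg = (EL_dg + (self.u_dg - EL_dg) * c_dg["a_m"]
                         + self.Ie_dg * c_dg["b_exc"] + Iext_dg * c_dg["c_ext"])
            self.Ie_dg *= net.decay_exc
            in_refr = self.refr_dg > 0
            self.u_dg[in_refr] = EL_dg
            self.refr_dg[in_refr] -= 1
            sp_dg = self.u_dg >= Vt_dg
            if sp_dg.any():
                self.u_dg[sp_dg] = EL_dg
                self.refr_dg[sp_dg] = c_dg["refr_steps"]
                if simulate_ca3:
                    # DG->CA3 has zero delay: delivered next step
                    row = self._ring_ee[(slot + 1) % L]
                    indptr = net.W_dgca3.indptr
                    indices = net.W_dgca3.indices
                    data = net.W_dgca3.data
                    for i in np.flatnonzero(sp_dg):
                        a, b = indptr[i], indptr[i + 1]
                        # column indices are unique within a row
                        row[indices[a:b]] += data[a:b]

            if simulate_ca3:
                # --- CA3 excitatory
                self.u_e = (EL_e + (self.u_e - EL_e) * c_e["a_m"]
                            + self.Ie_e * c_e["b_exc"] - self.Ii_e * c_e["b_inh"]
                            + Iext_e * c_e["c_ext"])
                if sd_e > 0:
                    self.u_e += rng.normal(0.0, sd_e, size=n)
                self.Ie_e *= net.decay_exc
                self.Ii_e *= net.decay_inh
                in_refr = self.refr_e > 0
                self.u_e[in_refr] = EL_e
                self.refr_e[in_refr] -= 1
                sp_e = self.u_e >= Vt_e
                n_sp_e = int(np.count_nonzero(sp_e))
                if n_sp_e:
                    self.u_e[sp_e] = EL_e
                    self.refr_e[sp_e] = c_e["refr_steps"]
                    if recurrents_on:
                        idx = np.flatnonzero(sp_e)
                        self._ring_ee[(slot + 1 + d_ee) % L] += (
                            net.W_rec[idx].sum(axis=0).astype(np.float64))
                        self._ring_ei[(slot + 1 + d_ei) % L] += n_sp_e

                # --- CA3 inhibitory
                self.u_i = (EL_i + (self.u_i - EL_i) * c_i["a_m"]
                            + self.Ie_i * c_i["b_exc"] - self.Ii_i * c_i["b_inh"])
                if sd_i > 0:
                    self.u_i += rng.normal(0.0, sd_i, size=net.n_inh)
                self.Ie_i *= net.decay_exc
                self.Ii_i *= net.decay_inh
                in_refr = self.refr_i > 0
                self.u_i[in_refr] = EL_i
                self.refr_i[in_refr] -= 1
                sp_i = self.u_i >= Vt_i
                n_sp_i = int(np.count_nonzero(sp_i))
                if n_sp_i:
                    self.u_i[sp_i] = EL_i
                    self.refr_i[sp_i] = c_i["refr_steps"]
                    self._ring_ie[(slot + 1 + d_ie) % L] += n_sp_i
                    self._ring_ii[(slot + 1 + d_ii) % L] += n_sp_i

                if rate_out is not None:
                    rate_out.append(n_sp_e)
            else:
                sp_e = sp_i = None

            # --- bookkeeping
            t_next = t_now + dt
            if rec_sets:
                for name, mask in (("dg", sp_dg), ("ca3e", sp_e), ("ca3i", sp_i)):
                    if name in rec_sets and mask is not None and mask.any():
                        ids = np.flatnonzero(mask)
                        rec_sets[name][0].append(np.full(len(ids), t_next))
                        rec_sets[name][1].append(ids)
                if "ctx" in rec_sets and ctx_counts is not None:
                    ids = np.flatnonzero(ctx_counts)
                    if len(ids):
                        rec_sets["ctx"][0].append(np.full(len(ids), t_next))
                        rec_sets["ctx"][1].append(ids)
            for name, arr in u_traces.items():
                src = {"dg": self.u_dg, "ca3e": self.u_e, "ca3i": self.u_i}[name]
                arr[k] = src[record_u[name]]
            if on_step is not None:
                on_step(t_next, ctx_counts, sp_dg)

            if not np.isfinite(self.u_e if simulate_ca3 else self.u_dg).all():
                raise FloatingPointError(
                    f"non-finite membrane potential at t = {t_next:.1f} ms")

            self._slot = (slot + 1) % L
            self.t = t_next

        out = {"t_end": self.t}
        for name, (ts, ids) in rec_sets.items():
            if ts:
                out[name] = SpikeRecord(np.concatenate(ts), np.concatenate(ids))
            else:
                out[name] = SpikeRecord(np.empty(0), np.empty(0, dtype=int))
        for name, arr in u_traces.items():
            out[f"u_{name}"] = arr
        return out


def build_network(params: Optional[NetworkParams] = None) -> Network:
    """Construct the weight structures for the given (default) parameters."""
    return Network(params or NetworkParams())
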