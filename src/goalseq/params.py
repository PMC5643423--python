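"""Static parameter specifications for the network, synapses and place fields.

All positions and distances are in cm, times in ms, currents in nA,
potentials in mV, capacitance in nF and conductance in uS, so that
``I / g_L`` is in mV and ``tau_m = C / g_L`` is in ms.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "LatticeSpec",
    "NeuronParams",
    "SynapseSpec",
    "PlaceFieldSpec",
    "build_lattice_positions",
    "gaussian_weight",
    "place_current",
    "REFERENCE_SPACING",
]

#: lattice spacing of the reference (full-scale) 80 x 80 network, cm
REFERENCE_SPACING = 420.0 / 80.0


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the place-cell sheet and the virtual environment.

    The cell lattice spans a virtual environment larger than the arena the
    simulated rat can visit, so that attractor-bump dynamics are free of
    edge effects within the arena.
    """

    grid_side: int = 80
    env_side: float = 420.0
    arena_side: float = 200.0

    def __post_init__(self) -> None:
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")
        if self.arena_side > self.env_side:
            raise ValueError("arena must fit inside the environment")

    @property
    def spacing(self) -> float:
        return self.env_side / self.grid_side

    @property
    def arena_offset(self) -> float:
        """Margin from environment edge to arena edge (arena is centered)."""
        return (self.env_side - self.arena_side) / 2.0

    @property
    def n_cells(self) -> int:
        return self.grid_side * self.grid_side


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire constants (standard excitatory cell)."""

    C: float = 0.3          # membrane capacitance, nF
    g_L: float = 0.03       # leak conductance, uS
    E_L: float = -70.6      # leak / reset potential, mV
    V_theta: float = -50.4  # spike threshold, mV
    t_refr: float = 3.0     # absolute refractory period, ms
    noise_sd: float = 0.0   # background-noise amplitude xi, mV / ms

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0:
            raise ValueError("C and g_L must be positive")
        if self.t_refr < 0:
            raise ValueError("t_refr must be non-negative")
        if self.V_theta <= self.E_L:
            raise ValueError("threshold must exceed the leak potential")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms (10 ms at defaults)."""
        return self.C / self.g_L


@dataclass(frozen=True)
class SynapseSpec:
    """One projection: kinetics, delay and spatial weight profile.

    ``weight_max`` is the current increment (nA) a single presynaptic spike
    adds to the target's synaptic current at distance 0; for profiles with a
    Gaussian footprint the increment falls off as ``exp(-d^2 / sigma^2)``.
    """

    tau: float                      # synaptic decay constant, ms
    delay: float = 0.0              # transmission delay, ms
    weight_max: float = 0.0         # peak weight, nA per spike
    sigma: Optional[float] = None   # Gaussian profile width, cm (None = uniform)
    cutoff: Optional[float] = None  # zero weight beyond this distance, cm
    topology: str = "uniform-all-to-all"
    autapses: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if self.weight_max < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class PlaceFieldSpec:
    """Location-dependent external drive of DG and CA3 place cells."""

    I_max: float = 10.0     # peak injected current, nA
    sigma_PF: float = 25.0  # place-field width, cm


def build_lattice_positions(spec: LatticeSpec) -> np.ndarray:
    """Place-field centers of the regular grid, cell-centered convention.

    Returns an ``(n_cells, 2)`` array in cm, ordered row-major so that cell
    ``(row, col)`` maps to index ``row * grid_side + col``. The origin is the
    environment's lower-left corner; cell (0, 0) is centered at half a
    spacing from the corner.
    """
    s = spec.spacing
    coords = (np.arange(spec.grid_side) + 0.5) * s
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])


def gaussian_weight(d: np.ndarray | float, spec: SynapseSpec) -> np.ndarray | float:
    """Synaptic weight at distance ``d`` under the projection's profile.

    Uses the same exponent convention as the place-field drive,
    ``w(d) = weight_max * exp(-d^2 / sigma^2)``, zero beyond ``cutoff``.
    Autapse exclusion (d == 0 between a cell and itself) is handled by the
    weight-matrix builders, not here.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if spec.sigma is None:
        w = np.full_like(d, spec.weight_max)
    else:
        w = spec.weight_max * np.exp(-(d ** 2) / spec.sigma ** 2)
    if spec.cutoff is not None:
        w = np.where(d > spec.cutoff, 0.0, w)
    if w.ndim == 0:
        return float(w)
    return w


def place_current(
    x: np.ndarray, centers: np.ndarray, spec: PlaceFieldSpec
) -> np.ndarray:
    """Place-specific external current for every cell, rat at position ``x``.

    ``I(x) = I_max * exp(-||x - x_j||^2 / sigma_PF^2)`` in nA.
    """
    x = np.asarray(x, dtype=float)
    d2 = np.sum((centers - x) ** 2, axis=1)
    return spec.I_max * np.exp(-d2 / spec.sigma_PF ** 2)
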