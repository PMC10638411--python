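"""Graded-response cell dynamics: one discrete time-step of the whole network.

Each excitatory cell is a leaky integrator with temporal summation of its
synaptic, afferent and stimulus input, subtractive local (5x5-pooled) and slow
area-global inhibition, constant uniform white noise, a clamped-linear
("ramp") or logistic output transfer, and spike-rate adaptation.  Inhibitory
cells are leaky integrators of the pooled excitatory output of their patch;
each one subtracts from its matched excitatory cell.

With the default ramp transfer, outputs are exactly zero below threshold, so
the network's activity vector is sparse at all times; the step exploits this
by propagating only the out-links of currently active cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netarch import NetworkState, multi_range
from . import plasticity as _plasticity

__all__ = ["DynamicsParams", "NumericalFault", "step", "sample_noise",
           "stimulus_vector", "transfer"]


class NumericalFault(FloatingPointError):
    """Non-finite state detected during integration."""


@dataclass(frozen=True)
class DynamicsParams:
    """Cellular and circuit constants (time constants in simulation steps)."""
    tau_membrane: float = 2.5        # e-cell leak
    tau_adapt: float = 25.0          # adaptation low-pass
    tau_global: float = 8.0          # slow area-global inhibition
    tau_inhib: float = 2.0           # i-cell leak
    adapt_strength: float = 2.8      # subtractive weight of fast adaptation
    tau_homeo: float = 400.0         # slow activity-average (homeostatic) low-pass
    homeo_strength: float = 3.0      # subtractive weight of the slow activity average
    global_strength: float = 0.15    # per-cell weight of the area-global variable
    local_strength: float = 0.60     # per-cell weight of the matched i-cell
    input_gain: float = 1.0          # gain on (recurrent + afferent + stimulus)
    sigmoid_slope: float = 1.0
    sigmoid_threshold: float = 0.18  # output threshold phi (potential units)
    noise_amplitude: float = 0.30    # baseline uniform noise, on in all phases
    transfer: str = "ramp"           # "ramp" | "logistic" | "identity"

    def __post_init__(self):
        for name in ("tau_membrane", "tau_adapt", "tau_global", "tau_inhib", "tau_homeo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


def transfer(drive: np.ndarray, params: DynamicsParams) -> np.ndarray:
    """Output nonlinearity applied to (V - adapt_strength*a - threshold)."""
    x = params.sigmoid_slope * drive
    if params.transfer == "ramp":
        return np.clip(x, 0.0, 1.0)
    if params.transfer == "logistic":
        # centred so that transfer(0) ~ 0; shifted/rescaled logistic in [0, 1)
        return np.clip(2.0 / (1.0 + np.exp(-2.0 * np.clip(x, -30, 30))) - 1.0, 0.0, 1.0)
    if params.transfer == "identity":
        return x
    raise ValueError(f"unknown transfer {params.transfer!r}")


def sample_noise(n_cells: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform white noise on [-amplitude, +amplitude], fresh each call."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return np.zeros(n_cells)
    return rng.uniform(-amplitude, amplitude, n_cells)


def stimulus_vector(net: NetworkState, patterns: dict[str, np.ndarray],
                    amplitude: float) -> np.ndarray:
    """Dense input-current vector clamping the given per-primary-area cell sets."""
    stim = np.zeros(net.n_cells)
    for area, cells in patterns.items():
        if not net.areas[net.area_index(area)].is_primary:
            raise ValueError(f"external input addresses non-primary area {area!r}")
        sl = net.area_slice(area)
        stim[sl.start + np.asarray(cells, dtype=np.int64)] = amplitude
    return stim


def _area_sums(net: NetworkState, values: np.ndarray) -> np.ndarray:
    return values.reshape(net.n_areas, net.cells_per_area).sum(axis=1)


def step(net: NetworkState, params: DynamicsParams, rng: np.random.Generator,
         stimulus: np.ndarray | None = None,
         rule: "_plasticity.PlasticityRule | None" = None,
         extra_noise: np.ndarray | None = None) -> NetworkState:
    """Advance the network state by one time-step (in place; returns ``net``).

    ``stimulus`` is a dense input-current vector (see :func:`stimulus_vector`);
    ``extra_noise`` an optional additional current (e.g. environmental noise in
    primary areas during inter-trial intervals).  If ``rule`` is given and
    enabled, Hebbian plasticity is applied after the state update using the
    new outputs (pre side) and new potentials (post side).
    """
    N = net.n_cells
    active = np.flatnonzero(net.O)

    # recurrent + afferent drive from currently active cells only
    syn = np.zeros(N)
    if active.size:
        pos = multi_range(net.out_indptr, active)
        if pos.size:
            counts = net.out_indptr[active + 1] - net.out_indptr[active]
            o_rep = np.repeat(net.O[active], counts)
            np.add.at(syn, net.out_tgt[pos], net.w[pos] * o_rep)

    # 5x5 pooled input to i-cells
    poolin = np.zeros(N)
    if active.size:
        ppos = multi_range(net.pool_indptr, active)
        pc = net.pool_indptr[active + 1] - net.pool_indptr[active]
        np.add.at(poolin, net.pool_tgt[ppos], np.repeat(net.O[active], pc))

    net.I_pot += (1.0 / params.tau_inhib) * (-net.I_pot + poolin)
    net.G += (1.0 / params.tau_global) * (-net.G + _area_sums(net, net.O))

    noise = sample_noise(N, params.noise_amplitude, rng)
    if extra_noise is not None:
        noise = noise + extra_noise
    total = params.input_gain * (syn + (0.0 if stimulus is None else stimulus))
    total -= params.local_strength * np.maximum(net.I_pot, 0.0)
    total -= params.global_strength * net.G[net.area_of]
    total += noise

    net.V += (1.0 / params.tau_membrane) * (-net.V + total)

    new_O = transfer(net.V - params.adapt_strength * net.adapt
                     - params.homeo_strength * net.homeo
                     - params.sigmoid_threshold, params)
    # lesioned cells emit 0 and do not update
    dead = ~net.lesion_mask
    if dead.any():
        new_O[dead] = 0.0
        net.V[dead] = 0.0
        net.adapt[dead] = 0.0
    net.adapt += (1.0 / params.tau_adapt) * (-net.adapt + new_O)
    net.homeo += (1.0 / params.tau_homeo) * (-net.homeo + new_O)
    net.O = new_O

    if not np.isfinite(net.V).all():
        raise NumericalFault("non-finite membrane potential encountered")

    if rule is not None and rule.enabled:
        _plasticity.apply_hebbian_sparse(net, rule)
    return net
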