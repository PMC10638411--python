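"""Word-circuit responsiveness assay.

Cell-assembly (CA) membership is identified in the intact trained network by
presenting a word's full multi-area pattern briefly and recording every
excitatory cell's output over the cue plus the following 15 steps.  A cell's
response omega is its time-averaged output over that window; within each
area A and word w the responsiveness threshold is

    theta(w, A) = gamma * max_{e in A} omega(e)_w          (gamma = 0.50)

and a cell is responsive iff omega strictly exceeds theta.  The same
criterion, after an auditory-only (A1) cue, measures how much of each word's
circuit a possibly lesioned network can still reactivate: the per-area count
of responsive CA cells is the unit of word-processing integrity.  Plasticity
is off throughout; baseline noise stays on, as in every phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DynamicsParams, sample_noise, step, stimulus_vector
from .netarch import NetworkState
from .protocol import WordPattern

__all__ = ["AssayConfig", "CAMembership", "ResponseRecord",
           "time_averaged_output", "compute_threshold",
           "identify_ca_cells", "cue_auditory", "record_response"]


@dataclass(frozen=True)
class AssayConfig:
    gamma: float = 0.50          # threshold fraction of the maximal response
    cue_steps: int = 2           # stimulus presentation length
    record_steps: int = 15       # recording continues this long after the cue
    include_cue_in_average: bool = True
    settle_steps: int = 10       # baseline-noise settling after state reset
    max_settle_steps: int = 60   # cap when waiting for global inhibition to decay
    settle_threshold: float = 1.5  # G gate on PFi and PB, as in training ISIs
    min_response: float = 0.05     # absolute floor on omega: below it a cell is
                                   # never responsive (keeps the relative gamma
                                   # threshold meaningful in silenced areas)
    cue_repetitions: int = 1       # responsive counts averaged over this many cues

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")


@dataclass
class CAMembership:
    word_id: str
    cells: dict[str, np.ndarray]      # area -> global-in-area cell indices

    def size(self, area: str) -> int:
        return int(self.cells.get(area, np.empty(0)).size)

    @property
    def total_size(self) -> int:
        return int(sum(v.size for v in self.cells.values()))


@dataclass
class ResponseRecord:
    word_id: str
    omega: np.ndarray                       # (n_cells,) time-averaged outputs
    theta: dict[str, float]                 # per-area thresholds
    responsive: dict[str, np.ndarray]       # per-area responsive cell indices (in-area)
    responsive_count: dict[str, int]
    responsive_ca_count: dict[str, int] = field(default_factory=dict)


def time_averaged_output(trace: np.ndarray, window: int | None = None) -> np.ndarray:
    """Arithmetic mean of the per-cell output trace over the recording window.

    ``trace`` has shape (T, n_cells); ``window`` (default: all T steps) takes
    the last ``window`` steps.  Linear in the trace, values stay in [0, 1].
    """
    trace = np.asarray(trace)
    T = trace.shape[0]
    if window is None:
        window = T
    if window > T or window < 1:
        raise ValueError("averaging window longer than recorded trace")
    return trace[T - window:].mean(axis=0)


def compute_threshold(omega_area: np.ndarray, gamma: float) -> float:
    """theta = gamma * max(omega); responsiveness uses strict inequality."""
    if omega_area.size == 0:
        raise ValueError("empty area")
    return float(gamma * omega_area.max())


def _settle(net: NetworkState, params: DynamicsParams, cfg: AssayConfig,
            rng: np.random.Generator) -> None:
    """Reset to zero state, then settle under baseline noise until the slow
    inhibition of PFi and PB is sub-threshold (mirrors the training ISI gate)."""
    net.reset_state()
    i_pfi, i_pb = net.area_index("PFi"), net.area_index("PB")
    for t in range(cfg.max_settle_steps):
        step(net, params, rng)
        if (t + 1 >= cfg.settle_steps
                and net.G[i_pfi] < cfg.settle_threshold
                and net.G[i_pb] < cfg.settle_threshold):
            break


def record_response(net: NetworkState, stim_patterns: dict[str, np.ndarray],
                    params: DynamicsParams, cfg: AssayConfig,
                    rng: np.random.Generator,
                    stimulus_amplitude: float = 4.0) -> np.ndarray:
    """Cue with the given primary-area patterns and return the omega vector."""
    _settle(net, params, cfg, rng)
    stim = stimulus_vector(net, stim_patterns, stimulus_amplitude)
    frames = []
    for _ in range(cfg.cue_steps):
        step(net, params, rng, stimulus=stim)
        frames.append(net.O.copy())
    for _ in range(cfg.record_steps):
        step(net, params, rng)
        frames.append(net.O.copy())
    trace = np.asarray(frames)
    window = None if cfg.include_cue_in_average else cfg.record_steps
    omega = time_averaged_output(trace, window)
    omega[~net.lesion_mask] = 0.0   # inactivated cells are excluded from the assay
    return omega


def _thresholded(net: NetworkState, omega: np.ndarray, gamma: float,
                 min_response: float = 0.0
                 ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    theta: dict[str, float] = {}
    responsive: dict[str, np.ndarray] = {}
    for a in net.areas:
        sl = net.area_slice(a.name)
        om = omega[sl]
        th = compute_threshold(om, gamma)
        theta[a.name] = th
        responsive[a.name] = np.flatnonzero((om > th) & (om > min_response))
    return theta, responsive


def identify_ca_cells(net: NetworkState, word: WordPattern, params: DynamicsParams,
                      cfg: AssayConfig, rng: np.random.Generator,
                      stimulus_amplitude: float = 4.0) -> CAMembership:
    """CA membership in the intact network: cells responsive to the word's
    full multi-area pattern, per area."""
    omega = record_response(net, dict(word.patterns), params, cfg, rng,
                            stimulus_amplitude)
    _, responsive = _thresholded(net, omega, cfg.gamma, cfg.min_response)
    return CAMembership(word.word_id, responsive)


def cue_auditory(net: NetworkState, word: WordPattern, params: DynamicsParams,
                 cfg: AssayConfig, rng: np.random.Generator,
                 ca: CAMembership | None = None,
                 stimulus_amplitude: float = 4.0) -> ResponseRecord:
    """Present only the word's A1 pattern and count responsive (CA) cells."""
    if "A1" not in word.patterns:
        raise ValueError(f"word {word.word_id!r} lacks an A1 pattern")
    reps = max(1, int(cfg.cue_repetitions))
    count_acc: dict[str, float] = {}
    ca_acc: dict[str, float] = {}
    for _ in range(reps):
        omega = record_response(net, {"A1": word.patterns["A1"]}, params, cfg, rng,
                                stimulus_amplitude)
        theta, responsive = _thresholded(net, omega, cfg.gamma, cfg.min_response)
        for a, v in responsive.items():
            count_acc[a] = count_acc.get(a, 0.0) + v.size
            if ca is not None:
                ca_acc[a] = ca_acc.get(a, 0.0) + np.intersect1d(
                    v, ca.cells.get(a, np.empty(0))).size
    rec = ResponseRecord(
        word_id=word.word_id, omega=omega, theta=theta, responsive=responsive,
        responsive_count={a: int(round(n / reps)) for a, n in count_acc.items()},
    )
    if ca is not None:
        rec.responsive_ca_count = {a: int(round(n / reps))
                                   for a, n in ca_acc.items()}
    return rec
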