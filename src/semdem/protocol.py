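"""Word stimuli and the word-acquisition training protocol.

A "word" is a set of concurrent binary activation patterns delivered to the
network's primary areas: every word has an auditory (A1) and an articulatory
(M1i) pattern; object words additionally have a visual (V1) pattern, action
words a hand-motor (M1L) pattern.  Each pattern activates exactly 19 randomly
chosen cells of the 25 x 25 sheet (~3% of the cells).

Training repeats, for each word, trials consisting of a 16-step pattern
presentation (with a fresh random 19-cell noise pattern delivered to the
non-involved primary area) followed by an inter-stimulus interval during
which only noise drives the network; the next trial starts once the slow
global inhibition of areas PFi and PB has decayed below a fixed threshold,
so that one trial's reverberation does not leak into the next.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DynamicsParams, sample_noise, step, stimulus_vector
from .netarch import ConfigurationError, NetworkState, PRIMARY_AREAS
from .plasticity import PlasticityRule

logger = logging.getLogger(__name__)

__all__ = ["WordPattern", "TrainingSchedule", "TrialLog",
           "generate_word_patterns", "make_noise_pattern", "run_trial", "train"]

OBJECT_AREAS = ("A1", "M1i", "V1")
ACTION_AREAS = ("A1", "M1i", "M1L")


@dataclass(frozen=True)
class WordPattern:
    word_id: str
    category: str                       # "object" | "action"
    patterns: dict[str, np.ndarray]     # area -> sorted cell indices (k_active each)

    def __post_init__(self):
        expected = OBJECT_AREAS if self.category == "object" else ACTION_AREAS
        if self.category not in ("object", "action"):
            raise ConfigurationError(f"unknown word category {self.category!r}")
        if set(self.patterns) != set(expected):
            raise ConfigurationError(
                f"{self.category} word must define patterns exactly for {expected}")

    @property
    def uninvolved_primary(self) -> str:
        return "M1L" if self.category == "object" else "V1"


@dataclass(frozen=True)
class TrainingSchedule:
    trials_per_word: int = 3000
    presentation_steps: int = 16
    stimulus_amplitude: float = 8.0        # clamp current on pattern cells
    isi_inhibition_threshold: float = 1.5  # gate on G of PFi and PB
    max_isi_steps: int = 50
    min_isi_steps: int = 4
    environmental_noise_amplitude: float = 0.15  # extra ISI noise in primary areas
    isi_plasticity: bool = False           # learning is driven by the presentations

    def __post_init__(self):
        if self.presentation_steps < 1 or self.max_isi_steps < 1:
            raise ConfigurationError("presentation_steps and max_isi_steps must be >= 1")


@dataclass
class TrialLog:
    word_id: str
    presentation_steps: int
    isi_steps: int
    settled: bool

    @property
    def steps_run(self) -> int:
        return self.presentation_steps + self.isi_steps


def make_noise_pattern(grid_cells: int, k_active: int,
                       rng: np.random.Generator) -> np.ndarray:
    """A fresh uniform random k_active-subset of the grid's cells."""
    if k_active > grid_cells:
        raise ConfigurationError("k_active exceeds number of grid cells")
    return np.sort(rng.choice(grid_cells, size=k_active, replace=False))


def generate_word_patterns(n_object: int, n_action: int, grid_cells: int = 625,
                           k_active: int = 19,
                           rng: np.random.Generator | None = None
                           ) -> list[WordPattern]:
    """Independent uniform random patterns for n_object + n_action words."""
    rng = np.random.default_rng() if rng is None else rng
    words: list[WordPattern] = []
    for i in range(n_object):
        pats = {a: make_noise_pattern(grid_cells, k_active, rng) for a in OBJECT_AREAS}
        words.append(WordPattern(f"obj{i}", "object", pats))
    for i in range(n_action):
        pats = {a: make_noise_pattern(grid_cells, k_active, rng) for a in ACTION_AREAS}
        words.append(WordPattern(f"act{i}", "action", pats))
    return words


def run_trial(net: NetworkState, word: WordPattern, schedule: TrainingSchedule,
              params: DynamicsParams, rule: PlasticityRule,
              rng: np.random.Generator) -> TrialLog:
    """One training trial: presentation with plasticity on, then a gated ISI."""
    n_grid = net.cells_per_area
    noise_pat = make_noise_pattern(n_grid, word.patterns["A1"].size, rng)
    stim_patterns = dict(word.patterns)
    stim_patterns[word.uninvolved_primary] = noise_pat
    stim = stimulus_vector(net, stim_patterns, schedule.stimulus_amplitude)

    for _ in range(schedule.presentation_steps):
        step(net, params, rng, stimulus=stim, rule=rule)

    # environmental noise to the four primary areas during the ISI
    primary_cells = np.zeros(net.n_cells, dtype=bool)
    for a in PRIMARY_AREAS:
        primary_cells[net.area_slice(a)] = True
    i_pfi, i_pb = net.area_index("PFi"), net.area_index("PB")

    isi = 0
    settled = False
    while isi < schedule.max_isi_steps:
        if (isi >= schedule.min_isi_steps
                and net.G[i_pfi] < schedule.isi_inhibition_threshold
                and net.G[i_pb] < schedule.isi_inhibition_threshold):
            settled = True
            break
        env = np.zeros(net.n_cells)
        env[primary_cells] = sample_noise(int(primary_cells.sum()),
                                          schedule.environmental_noise_amplitude, rng)
        step(net, params, rng, rule=rule if schedule.isi_plasticity else None,
             extra_noise=env)
        isi += 1
    else:
        logger.warning("trial for %s hit max_isi_steps without settling", word.word_id)
    return TrialLog(word.word_id, schedule.presentation_steps, isi, settled)


def train(net: NetworkState, words: list[WordPattern], schedule: TrainingSchedule,
          params: DynamicsParams, rule: PlasticityRule, rng: np.random.Generator,
          progress: bool = False) -> list[TrialLog]:
    """Interleaved training: ``trials_per_word`` block-randomised passes.

    Each block presents every word once, in a fresh random order, so no word
    is systematically trained before another.  Deterministic given the rng.
    """
    if not words:
        raise ConfigurationError("word list must be non-empty")
    logs: list[TrialLog] = []
    order = np.arange(len(words))
    for block in range(schedule.trials_per_word):
        rng.shuffle(order)
        for k in order:
            logs.append(run_trial(net, words[k], schedule, params, rule, rng))
    return logs
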