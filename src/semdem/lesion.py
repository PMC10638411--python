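"""Graded grey-matter and white-matter lesions of the anterior-temporal hub.

Grey-matter damage (GM) inactivates a uniformly sampled fraction of the
target area's excitatory cells: inactivated cells emit zero output, are
frozen by the dynamics and excluded from plasticity and from the assay;
their synapses are left structurally in place.  White-matter damage (WM)
instead removes a uniformly sampled fraction of the plastic e->e links
incident to the target area's cells (within-area and between-area, counted
once each), leaving the cells themselves active.  Severity is the damaged
fraction of the respective population; counts use floor rounding so the
stated severity is never exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netarch import NetworkState

__all__ = ["LesionSpec", "LesionReport", "apply_gm_lesion", "apply_wm_lesion",
           "duplicate_for_lesion_arms", "wm_link_population"]

SEVERITY_LEVELS = (0.0, 0.30, 0.60, 0.90)


@dataclass(frozen=True)
class LesionSpec:
    lesion_type: str            # "GM" | "WM"
    fraction: float
    target_area: str = "AT"
    seed: int | None = None
    nested: bool = False        # severity sets nest: the 30% set is a prefix of
                                # the 60% set, etc. (needs an explicit seed)

    def __post_init__(self):
        if self.lesion_type not in ("GM", "WM"):
            raise ValueError(f"unknown lesion type {self.lesion_type!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("lesion fraction must lie in [0, 1]")


@dataclass
class LesionReport:
    lesion_type: str
    target_area: str
    fraction: float
    n_cells_inactivated: int = 0
    n_links_removed: int = 0
    links_by_projection: dict[str, int] = field(default_factory=dict)


def _rng_for(spec: LesionSpec, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(spec.seed)


def _sample(population: np.ndarray, n_hit: int, spec: LesionSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Uniform subset; with nested=True the subset is the length-n_hit prefix
    of a seed-determined permutation, so higher severities contain lower ones."""
    if spec.nested:
        perm = np.random.default_rng(spec.seed).permutation(population)
        return perm[:n_hit]
    return rng.choice(population, size=n_hit, replace=False)


def apply_gm_lesion(net: NetworkState, spec: LesionSpec,
                    rng: np.random.Generator | None = None) -> LesionReport:
    """Inactivate floor(fraction x n_cells) uniformly sampled target e-cells."""
    assert spec.lesion_type == "GM"
    rng = _rng_for(spec, rng)
    sl = net.area_slice(spec.target_area)
    cells = np.arange(sl.start, sl.stop)
    n_hit = int(np.floor(spec.fraction * cells.size))
    report = LesionReport("GM", spec.target_area, spec.fraction)
    if n_hit == 0:
        return report
    hit = _sample(cells, n_hit, spec, rng)
    net.lesion_mask[hit] = False
    net.V[hit] = 0.0
    net.O[hit] = 0.0
    net.adapt[hit] = 0.0
    report.n_cells_inactivated = n_hit
    return report


def wm_link_population(net: NetworkState, target_area: str = "AT") -> np.ndarray:
    """Positions (into net.w) of all live plastic links with an endpoint in the
    target area's e-cells; within-area links are counted once."""
    sl = net.area_slice(target_area)
    area_idx = net.area_index(target_area)
    src_of = np.repeat(np.arange(net.n_cells), np.diff(net.out_indptr))
    in_area = ((net.area_of[src_of] == area_idx)
               | (net.area_of[net.out_tgt] == area_idx))
    return np.flatnonzero(in_area & net.plastic)


def apply_wm_lesion(net: NetworkState, spec: LesionSpec,
                    rng: np.random.Generator | None = None) -> LesionReport:
    """Remove floor(fraction x |L|) of the links incident to the target area,
    sampled uniformly without replacement; cells stay active."""
    assert spec.lesion_type == "WM"
    rng = _rng_for(spec, rng)
    pop = wm_link_population(net, spec.target_area)
    n_hit = int(np.floor(spec.fraction * pop.size))
    report = LesionReport("WM", spec.target_area, spec.fraction)
    if n_hit == 0:
        return report
    hit = _sample(pop, n_hit, spec, rng)
    net.w[hit] = 0.0
    net.plastic[hit] = False
    report.n_links_removed = n_hit
    counts = np.bincount(net.proj_id[hit], minlength=len(net.projections))
    report.links_by_projection = {
        f"{s}->{t}": int(c) for (s, t, _k), c in zip(net.projections, counts) if c
    }
    return report


def duplicate_for_lesion_arms(net: NetworkState) -> tuple[NetworkState, NetworkState]:
    """Two deep, independent copies of a trained network (GM arm, WM arm)."""
    return net.copy(), net.copy()
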