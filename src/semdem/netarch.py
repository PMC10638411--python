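"""Construction of the 12-area cortical network.

The architecture mirrors left-hemisphere fronto-temporo-occipital cortex as
four "zones" of three areas each (primary -> secondary -> higher association):

* auditory      A1  - AB  - PB      (perisylvian, word-form)
* articulatory  M1i - PMi - PFi     (perisylvian, word-form)
* visual        V1  - TO  - AT      (extrasylvian, object semantics)
* hand motor    M1L - PML - PFL     (extrasylvian, action semantics)

Adjacent areas within a zone are reciprocally connected; four long-distance
links (AT-PFi, PB-PFi, AT-PFL, PB-PFL) stand for the arcuate/uncinate
fascicles and the extreme capsule.  Every area holds a 25 x 25 sheet of
excitatory graded-response cells, each paired with one inhibitory cell that
pools a local 5 x 5 excitatory neighbourhood.  Excitatory links, within and
between areas, are sparse, patchy and topographic: a link is drawn with a
probability that decays with topographic distance (Gaussian kernel, clipped
at grid borders, never wrapped) and is initialised to a weak random efficacy.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AREA_NAMES", "PERISYLVIAN", "EXTRASYLVIAN", "PRIMARY_AREAS", "ZONES",
    "WITHIN_ZONE_PAIRS", "LONG_DISTANCE_PAIRS", "EXTRA_LONG_DISTANCE_PAIRS",
    "AreaSpec", "KernelParams", "ProjectionSpec", "ArchitectureConfig",
    "NetworkState", "ConfigurationError",
    "area_adjacency", "sample_projection", "build_network",
    "kernel_offsets", "expected_out_degree", "multi_range",
]

ZONES: dict[str, tuple[str, str, str]] = {
    "auditory": ("A1", "AB", "PB"),
    "articulatory": ("M1i", "PMi", "PFi"),
    "visual": ("V1", "TO", "AT"),
    "motor": ("M1L", "PML", "PFL"),
}

AREA_NAMES: tuple[str, ...] = (
    "A1", "AB", "PB", "M1i", "PMi", "PFi",
    "V1", "TO", "AT", "M1L", "PML", "PFL",
)

PERISYLVIAN = frozenset({"A1", "AB", "PB", "M1i", "PMi", "PFi"})
EXTRASYLVIAN = frozenset({"V1", "TO", "AT", "M1L", "PML", "PFL"})
PRIMARY_AREAS = ("A1", "M1i", "V1", "M1L")

#: reciprocal links between adjacent areas of each zone (primary-secondary-association chains)
WITHIN_ZONE_PAIRS: tuple[tuple[str, str], ...] = (
    ("A1", "AB"), ("AB", "PB"),
    ("M1i", "PMi"), ("PMi", "PFi"),
    ("V1", "TO"), ("TO", "AT"),
    ("M1L", "PML"), ("PML", "PFL"),
)

#: long-distance cortico-cortical fibre bundles between temporal and frontal hubs
LONG_DISTANCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("AT", "PFi"), ("PB", "PFi"), ("AT", "PFL"), ("PB", "PFL"),
)

#: optional additional hub-hub links (off by default; see ArchitectureConfig)
EXTRA_LONG_DISTANCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("AT", "PB"), ("PFi", "PFL"),
)


class ConfigurationError(ValueError):
    """Raised for invalid architecture / protocol configuration."""


@dataclass(frozen=True)
class AreaSpec:
    name: str
    zone: str
    system: str            # "perisylvian" | "extrasylvian"
    grid_rows: int = 25
    grid_cols: int = 25
    is_primary: bool = False

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass(frozen=True)
class KernelParams:
    """Gaussian distance kernel for probabilistic, patchy, topographic links."""
    halfwidth: int = 9          # kernel spans (2h+1) x (2h+1); 9 -> 19 x 19
    base_probability: float = 0.28   # p at distance 0
    sigma: float = 4.5          # length scale of the probability falloff (cells)


@dataclass(frozen=True)
class ProjectionSpec:
    source: str
    target: str
    kind: str                   # "within_area" | "between_area"
    kernel: KernelParams
    w_init_max: float           # initial efficacies drawn uniform on (0, w_init_max]


@dataclass(frozen=True)
class ArchitectureConfig:
    grid_rows: int = 25
    grid_cols: int = 25
    areas: tuple[str, ...] = AREA_NAMES
    include_extra_long_distance: bool = False
    within_kernel: KernelParams = field(default_factory=lambda: KernelParams(9, 0.28, 4.5))
    between_kernel: KernelParams = field(default_factory=lambda: KernelParams(9, 0.28, 4.5))
    w_max: float = 1.0          # efficacy ceiling of plastic links
    w_init_frac: float = 0.2    # initial weights uniform on (0, w_init_frac * w_max]

    def area_specs(self) -> list[AreaSpec]:
        specs = []
        for name in self.areas:
            zone = _zone_of(name)
            specs.append(AreaSpec(
                name=name, zone=zone,
                system="perisylvian" if name in PERISYLVIAN else "extrasylvian",
                grid_rows=self.grid_rows, grid_cols=self.grid_cols,
                is_primary=name in PRIMARY_AREAS,
            ))
        return specs


def _zone_of(name: str) -> str:
    for zone, members in ZONES.items():
        if name in members:
            return zone
    raise ConfigurationError(f"unknown area name: {name!r}")


def area_adjacency(config: ArchitectureConfig) -> list[frozenset[str]]:
    """Unordered between-area pairs of the architecture.

    Default: the 8 within-zone chain pairs plus 4 long-distance fibre pairs.
    Reciprocity is by construction: each unordered pair yields projections in
    both directions when the network is built.
    """
    known = set(config.areas)
    for name in known:
        _zone_of(name)  # validates
    pairs: list[frozenset[str]] = []
    candidates = list(WITHIN_ZONE_PAIRS) + list(LONG_DISTANCE_PAIRS)
    if config.include_extra_long_distance:
        candidates += list(EXTRA_LONG_DISTANCE_PAIRS)
    for a, b in candidates:
        if a in known and b in known:
            pairs.append(frozenset((a, b)))
    return pairs


def kernel_offsets(kernel: KernelParams, within: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(drow, dcol, p) arrays over the kernel window; excludes (0,0) for within-area."""
    h = kernel.halfwidth
    dr, dc = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    dr, dc = dr.ravel(), dc.ravel()
    if within:
        keep = ~((dr == 0) & (dc == 0))  # no self-connections
        dr, dc = dr[keep], dc[keep]
    d2 = dr.astype(float) ** 2 + dc.astype(float) ** 2
    if np.isinf(kernel.sigma):
        p = np.full(d2.shape, kernel.base_probability)
    else:
        p = kernel.base_probability * np.exp(-d2 / (2.0 * kernel.sigma ** 2))
    return dr, dc, p


def expected_out_degree(kernel: KernelParams, within: bool) -> float:
    """Analytic expected out-degree of an interior source cell (binomial mean)."""
    _, _, p = kernel_offsets(kernel, within)
    return float(p.sum())


def sample_projection(spec: ProjectionSpec, rng: np.random.Generator,
                      grid_rows: int = 25, grid_cols: int = 25
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one sparse patchy topographic projection.

    Returns (source_cell, target_cell, weight) arrays with 0-based row-major
    cell indices local to the source/target grids.  Each candidate pair inside
    the kernel window is linked independently with probability p(d); kernels
    are clipped at grid borders.
    """
    k = spec.kernel
    if k.halfwidth >= max(grid_rows, grid_cols):
        raise ConfigurationError("kernel halfwidth exceeds grid size")
    if not (0.0 <= k.base_probability <= 1.0):
        raise ConfigurationError("base_probability must lie in [0, 1]")
    if k.sigma <= 0:
        raise ConfigurationError("kernel sigma must be positive")
    within = spec.kind == "within_area"
    dr, dc, p = kernel_offsets(k, within)

    rows = np.arange(grid_rows)[:, None]   # (R,1)
    cols = np.arange(grid_cols)[None, :]   # (1,C)
    src_idx = (rows * grid_cols + cols).ravel()

    srcs, tgts = [], []
    n_cells = grid_rows * grid_cols
    for i in range(dr.size):
        tr = rows + dr[i]
        tc = cols + dc[i]
        valid = ((tr >= 0) & (tr < grid_rows) & (tc >= 0) & (tc < grid_cols)).ravel()
        hit = rng.random(n_cells) < p[i]
        keep = valid & hit
        if not keep.any():
            continue
        srcs.append(src_idx[keep])
        tgts.append((tr * grid_cols + tc).ravel()[keep])
    if srcs:
        src = np.concatenate(srcs)
        tgt = np.concatenate(tgts)
    else:
        src = np.empty(0, dtype=np.int64)
        tgt = np.empty(0, dtype=np.int64)
    # weak random initial efficacies on (0, w_init_max]
    w = spec.w_init_max * (1.0 - rng.random(src.size))
    return src.astype(np.int32), tgt.astype(np.int32), w


def multi_range(indptr: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Flat positions of the CSR ranges indptr[s]:indptr[s+1] for each s in sel."""
    sel = np.asarray(sel, dtype=np.int64)
    if sel.size == 0:
        return np.empty(0, dtype=np.int64)
    starts = indptr[sel]
    counts = indptr[sel + 1] - starts
    nz = counts > 0
    if not nz.all():
        starts, counts = starts[nz], counts[nz]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    pos = np.cumsum(counts)[:-1]
    out[0] = starts[0]
    if pos.size:
        out[pos] = starts[1:] - (starts[:-1] + counts[:-1]) + 1
    return np.cumsum(out)


@dataclass
class NetworkState:
    """The single mutable object of the simulator.

    All excitatory cells of all areas share one global 0-based index
    (``area_index * 625 + row * 25 + col``).  Plastic e->e links are stored
    once, source-major (out-link CSR); ``in_indptr``/``in_pos``/``in_src``
    give the matching target-major view into the same ``w`` array.
    """
    config: ArchitectureConfig
    areas: list[AreaSpec]
    seed: int

    # plastic e->e links, source-major
    out_indptr: np.ndarray      # (N+1,) int64
    out_tgt: np.ndarray         # (nnz,) int32, global target cell
    w: np.ndarray               # (nnz,) float64 efficacies in [0, w_max]
    plastic: np.ndarray         # (nnz,) bool; False once removed by a WM lesion
    proj_id: np.ndarray         # (nnz,) int16 index into .projections

    # target-major view
    in_indptr: np.ndarray       # (N+1,) int64
    in_pos: np.ndarray          # (nnz,) int64 positions into w/out_tgt order
    in_src: np.ndarray          # (nnz,) int32 global source cell

    # fixed (non-plastic) inhibitory microcircuit: e-cell -> 5x5 pooling i-cells
    pool_indptr: np.ndarray
    pool_tgt: np.ndarray

    projections: list[tuple[str, str, str]]   # (source, target, kind) per proj_id

    # dynamic state
    V: np.ndarray               # e-cell membrane potentials
    O: np.ndarray               # e-cell outputs in [0, 1]
    adapt: np.ndarray           # e-cell fast adaptation variables
    homeo: np.ndarray           # e-cell slow activity-average (homeostatic) variables
    I_pot: np.ndarray           # i-cell potentials (one i-cell per e-cell)
    G: np.ndarray               # per-area slow global-inhibition variables
    lesion_mask: np.ndarray     # (N,) bool, True = cell active

    area_of: np.ndarray         # (N,) int16 area index per cell

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_cells(self) -> int:
        return self.area_of.size

    @property
    def cells_per_area(self) -> int:
        return self.areas[0].n_cells

    def area_index(self, name: str) -> int:
        for i, a in enumerate(self.areas):
            if a.name == name:
                return i
        raise ConfigurationError(f"area {name!r} not in network")

    def area_slice(self, name: str) -> slice:
        i = self.area_index(name)
        n = self.areas[i].n_cells
        return slice(i * n, (i + 1) * n)

    def reset_state(self) -> None:
        """Zero all dynamic variables (weights and masks untouched)."""
        self.V[:] = 0.0
        self.O[:] = 0.0
        self.adapt[:] = 0.0
        self.homeo[:] = 0.0
        self.I_pot[:] = 0.0
        self.G[:] = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            config=self.config, areas=list(self.areas), seed=self.seed,
            out_indptr=self.out_indptr.copy(), out_tgt=self.out_tgt.copy(),
            w=self.w.copy(), plastic=self.plastic.copy(), proj_id=self.proj_id.copy(),
            in_indptr=self.in_indptr.copy(), in_pos=self.in_pos.copy(),
            in_src=self.in_src.copy(),
            pool_indptr=self.pool_indptr.copy(), pool_tgt=self.pool_tgt.copy(),
            projections=list(self.projections),
            V=self.V.copy(), O=self.O.copy(), adapt=self.adapt.copy(),
            homeo=self.homeo.copy(),
            I_pot=self.I_pot.copy(), G=self.G.copy(),
            lesion_mask=self.lesion_mask.copy(), area_of=self.area_of.copy(),
        )

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.w).tobytes())
        h.update(np.ascontiguousarray(self.plastic).tobytes())
        h.update(np.ascontiguousarray(self.lesion_mask).tobytes())
        return h.hexdigest()

    def out_links_of(self, cells: np.ndarray) -> np.ndarray:
        """Positions (into w) of all out-links of the given global cells."""
        return multi_range(self.out_indptr, np.asarray(cells, dtype=np.int64))

    def in_link_positions_of(self, cells: np.ndarray) -> np.ndarray:
        """Positions (into w) of all in-links of the given global cells."""
        raw = multi_range(self.in_indptr, np.asarray(cells, dtype=np.int64))
        return self.in_pos[raw]


def _pool_links(grid_rows: int, grid_cols: int, halfwidth: int = 2
                ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed e -> i pooling: each e-cell feeds the i-cells of its 5x5 patch."""
    h = halfwidth
    dr, dc = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    dr, dc = dr.ravel(), dc.ravel()
    rows = np.arange(grid_rows)[:, None]
    cols = np.arange(grid_cols)[None, :]
    src_list, tgt_list = [], []
    for i in range(dr.size):
        tr, tc = rows + dr[i], cols + dc[i]
        valid = ((tr >= 0) & (tr < grid_rows) & (tc >= 0) & (tc < grid_cols)).ravel()
        src_list.append((rows * grid_cols + cols).ravel()[valid])
        tgt_list.append((tr * grid_cols + tc).ravel()[valid])
    src = np.concatenate(src_list)
    tgt = np.concatenate(tgt_list)
    order = np.argsort(src, kind="stable")
    src, tgt = src[order], tgt[order]
    n = grid_rows * grid_cols
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=n), out=indptr[1:])
    return indptr, tgt.astype(np.int32)


def build_network(config: ArchitectureConfig, seed: int) -> NetworkState:
    """Build the full architecture: a pure, deterministic function of (config, seed)."""
    areas = config.area_specs()
    n_per = areas[0].n_cells
    name_to_idx = {a.name: i for i, a in enumerate(areas)}
    n_cells = n_per * len(areas)

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xA3,))
    w_init_max = config.w_init_frac * config.w_max

    projections: list[tuple[str, str, str]] = []
    specs: list[ProjectionSpec] = []
    for a in areas:
        projections.append((a.name, a.name, "within_area"))
        specs.append(ProjectionSpec(a.name, a.name, "within_area",
                                    config.within_kernel, w_init_max))
    for pair in area_adjacency(config):
        x, y = sorted(pair)
        for s, t in ((x, y), (y, x)):
            projections.append((s, t, "between_area"))
            specs.append(ProjectionSpec(s, t, "between_area",
                                        config.between_kernel, w_init_max))

    child_seeds = ss.spawn(len(specs))
    src_all, tgt_all, w_all, pid_all = [], [], [], []
    for pid, (spec, child) in enumerate(zip(specs, child_seeds)):
        rng = np.random.default_rng(child)
        s, t, w = sample_projection(spec, rng, config.grid_rows, config.grid_cols)
        src_all.append(s.astype(np.int64) + n_per * name_to_idx[spec.source])
        tgt_all.append(t.astype(np.int64) + n_per * name_to_idx[spec.target])
        w_all.append(w)
        pid_all.append(np.full(s.size, pid, dtype=np.int16))

    src = np.concatenate(src_all)
    tgt = np.concatenate(tgt_all)
    w = np.concatenate(w_all)
    pid = np.concatenate(pid_all)

    order = np.lexsort((tgt, src))
    src, tgt, w, pid = src[order], tgt[order], w[order], pid[order]
    out_indptr = np.zeros(n_cells + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=n_cells), out=out_indptr[1:])

    in_pos = np.argsort(tgt, kind="stable")
    in_indptr = np.zeros(n_cells + 1, dtype=np.int64)
    np.cumsum(np.bincount(tgt, minlength=n_cells), out=in_indptr[1:])
    in_src = src[in_pos].astype(np.int32)

    pool_indptr1, pool_tgt1 = _pool_links(config.grid_rows, config.grid_cols)
    pool_indptr = np.zeros(n_cells + 1, dtype=np.int64)
    deg = np.diff(pool_indptr1)
    pool_tgts = []
    for i in range(len(areas)):
        pool_tgts.append(pool_tgt1.astype(np.int64) + i * n_per)
        pool_indptr[i * n_per + 1:(i + 1) * n_per + 1] = pool_indptr[i * n_per] + np.cumsum(deg)
    pool_tgt = np.concatenate(pool_tgts).astype(np.int32)

    area_of = np.repeat(np.arange(len(areas), dtype=np.int16), n_per)

    return NetworkState(
        config=config, areas=areas, seed=seed,
        out_indptr=out_indptr, out_tgt=tgt.astype(np.int32), w=w,
        plastic=np.ones(w.size, dtype=bool), proj_id=pid,
        in_indptr=in_indptr, in_pos=in_pos, in_src=in_src,
        pool_indptr=pool_indptr, pool_tgt=pool_tgt,
        projections=projections,
        V=np.zeros(n_cells), O=np.zeros(n_cells), adapt=np.zeros(n_cells),
        homeo=np.zeros(n_cells),
        I_pot=np.zeros(n_cells), G=np.zeros(len(areas)),
        lesion_mask=np.ones(n_cells, dtype=bool), area_of=area_of,
    )
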