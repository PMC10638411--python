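"""End-to-end experiment: train instances, lesion, assay, aggregate.

For each network instance: build and train the 12-area network on six
object- and six action-related words; identify each word's cell-assembly
(CA) membership in the intact network; record the intact auditory-cue
response; duplicate the trained network into a grey-matter (GM) and a
white-matter (WM) lesion arm; lesion each arm independently at each severity
level; and re-run the auditory-only assay.  Results accumulate into a long
table (one row per instance x lesion type x severity x word x area) that
feeds the statistics battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayConfig, CAMembership, cue_auditory, identify_ca_cells
from .config import RunConfig
from .dynamics import DynamicsParams
from .lesion import LesionSpec, apply_gm_lesion, apply_wm_lesion, duplicate_for_lesion_arms
from .netarch import NetworkState, build_network
from .protocol import WordPattern, generate_word_patterns, train
from . import stats as _stats

__all__ = ["InstanceResult", "ExperimentResult", "run_instance", "run_experiment",
           "instance_seed"]


def instance_seed(master_seed: int, instance: int, label: str) -> int:
    """Stable sub-seed for one stochastic component of one instance (< 2**31)."""
    import zlib
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(instance, zlib.crc32(label.encode())))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class InstanceResult:
    instance: int
    words: list[WordPattern]
    cas: dict[str, CAMembership]
    counts: pd.DataFrame            # long per-area responsive-CA counts
    network: NetworkState | None = None


@dataclass
class ExperimentResult:
    table: pd.DataFrame             # normalised long table (see stats.normalize_to_intact)
    raw_counts: pd.DataFrame
    instances: list[InstanceResult] = field(default_factory=list)

    def declines(self, severity: int = 90) -> pd.DataFrame:
        return _stats.decline_percent(self.table, severity=severity)


def _assay_counts(net: NetworkState, words: list[WordPattern],
                  cas: dict[str, CAMembership], params: DynamicsParams,
                  acfg: AssayConfig, rng: np.random.Generator,
                  stimulus_amplitude: float) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for w in words:
        rec = cue_auditory(net, w, params, acfg, rng, ca=cas[w.word_id],
                           stimulus_amplitude=stimulus_amplitude)
        out[w.word_id] = rec.responsive_ca_count
    return out


def run_instance(cfg: RunConfig, instance: int, master_seed: int,
                 keep_network: bool = False, progress: bool = False
                 ) -> InstanceResult:
    """Train, lesion and assay one network instance."""
    net = build_network(cfg.architecture, instance_seed(master_seed, instance, "build"))
    words = generate_word_patterns(
        cfg.n_object_words, cfg.n_action_words, net.cells_per_area, cfg.k_active,
        np.random.default_rng(instance_seed(master_seed, instance, "patterns")))
    train_rng = np.random.default_rng(instance_seed(master_seed, instance, "train"))
    train(net, words, cfg.schedule, cfg.dynamics, cfg.plasticity, train_rng,
          progress=progress)

    assay_rng = np.random.default_rng(instance_seed(master_seed, instance, "assay"))
    amp = cfg.schedule.stimulus_amplitude
    cas = {w.word_id: identify_ca_cells(net, w, cfg.dynamics, cfg.assay,
                                        assay_rng, amp) for w in words}

    rows = []
    cat = {w.word_id: w.category for w in words}

    def add_rows(counts: dict[str, dict[str, int]], lesion_type: str, severity: int):
        for wid, per_area in counts.items():
            for area, n in per_area.items():
                rows.append((instance, lesion_type, severity, wid, cat[wid], area, n))

    intact = _assay_counts(net, words, cas, cfg.dynamics, cfg.assay, assay_rng, amp)
    for lt in cfg.lesion_types:
        add_rows(intact, lt, 0)

    gm_base, wm_base = duplicate_for_lesion_arms(net)
    arms = {"GM": gm_base, "WM": wm_base}
    for lt in cfg.lesion_types:
        for sev in cfg.severities:
            if sev == 0:
                continue
            arm = arms[lt].copy()   # independent lesion per severity level
            spec = LesionSpec(lt, sev / 100.0, cfg.lesion_target)
            lrng = np.random.default_rng(
                instance_seed(master_seed, instance, f"lesion-{lt}-{sev}"))
            if lt == "GM":
                apply_gm_lesion(arm, spec, lrng)
            else:
                apply_wm_lesion(arm, spec, lrng)
            counts = _assay_counts(arm, words, cas, cfg.dynamics, cfg.assay,
                                   assay_rng, amp)
            add_rows(counts, lt, sev)

    counts_df = pd.DataFrame(rows, columns=[
        "instance", "lesion_type", "severity", "word_id", "category", "area",
        "responsive_ca_count"])
    return InstanceResult(instance, words, cas, counts_df,
                          network=net if keep_network else None)


def run_experiment(cfg: RunConfig, seed: int, keep_networks: bool = False,
                   progress: bool = False) -> ExperimentResult:
    """Run all instances and return the normalised experiment table."""
    instances = [run_instance(cfg, i, seed, keep_network=keep_networks,
                              progress=progress)
                 for i in range(cfg.n_instances)]
    raw = pd.concat([r.counts for r in instances], ignore_index=True)
    table = _stats.normalize_to_intact(raw)
    return ExperimentResult(table=table, raw_counts=raw, instances=instances)


def make_figures(table: pd.DataFrame, outdir) -> list:
    """Decline-curve figures: intact-normalised responsiveness per system as a
    function of lesion severity, one panel per lesion type x word category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sr = _stats.system_ratios(table)
    paths = []
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for i, cat in enumerate(sorted(sr["category"].unique())):
        for j, lt in enumerate(sorted(sr["lesion_type"].unique())):
            ax = axes[i][j]
            sub = sr[(sr.category == cat) & (sr.lesion_type == lt)]
            for system, style in (("extrasylvian", "o-"), ("perisylvian", "s--")):
                g = (sub[sub.system == system]
                     .groupby("severity")["ratio"])
                mean, sem = g.mean(), g.std() / np.sqrt(g.count())
                ax.errorbar(mean.index, 100 * mean, yerr=100 * sem, fmt=style,
                            capsize=3, label=system)
            ax.set_title(f"{lt} lesion, {cat} words")
            ax.set_xlabel("severity (% AT damage)")
            ax.set_ylabel("responsive CA cells (% of intact)")
            ax.set_ylim(0, 110)
    axes[0][0].legend(frameon=False)
    fig.tight_layout()
    path = outdir / "decline_curves.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths


def standard_battery(table: pd.DataFrame) -> dict:
    """The contrasts reported for this design: ExtraPeri x Severity rmANOVAs
    per lesion type, WordType / LesionType ANOVAs on extrasylvian counts, and
    the Bonferroni-corrected 90%-severity follow-up t-tests."""
    out: dict = {"anova": {}, "ttests": {}}
    sr = _stats.system_ratios(table)
    for lt in sorted(table["lesion_type"].unique()):
        sub = sr[sr["lesion_type"] == lt]
        out["anova"][f"{lt}_ExtraPeri_x_Severity"] = _stats.rm_anova(
            sub, dv="ratio", within=["system", "severity"])
    extra = sr[sr["system"] == "extrasylvian"]
    for lt in sorted(table["lesion_type"].unique()):
        sub = extra[extra["lesion_type"] == lt]
        out["anova"][f"{lt}_WordType_x_Severity"] = _stats.rm_anova(
            sub, dv="ratio", within=["category", "severity"])

    d = _stats.decline_percent(table)
    piv = d.pivot_table(index="instance", values="decline_pct",
                        columns=["lesion_type", "category", "system"])
    pairs = {}
    for lt in piv.columns.get_level_values(0).unique():
        for cat in piv[lt].columns.get_level_values(0).unique():
            pairs[f"{lt}_{cat}_extra_vs_peri"] = (
                piv[(lt, cat, "extrasylvian")].to_numpy(),
                piv[(lt, cat, "perisylvian")].to_numpy())
    out["ttests"]["extra_vs_peri"] = _stats.paired_t_bonferroni(pairs)
    return out
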