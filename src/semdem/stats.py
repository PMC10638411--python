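"""Statistical aggregation and the cell-vs-link lesion expectation oracle.

Assay counts are aggregated into intact-normalised decline curves (the
fraction of each word circuit still responsive at each lesion severity,
relative to the intact network), analysed with repeated-measures ANOVAs
(network instances as subjects) and Bonferroni-corrected dependent-samples
t-tests.  The module also provides an exact combinatorial oracle for the
expected number of cell assemblies hit when removing a given number of cells
versus links from a toy configuration — the argument for why white-matter
damage outpaces equal-fraction grey-matter damage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netarch import AREA_NAMES, EXTRASYLVIAN, PERISYLVIAN

__all__ = ["AnovaResult", "ContrastResult", "normalize_to_intact",
           "system_ratios", "decline_percent", "rm_anova",
           "paired_t_bonferroni", "sign_test", "lesion_expectation_oracle",
           "run_experiment"]


def run_experiment(config, seed: int, **kwargs):
    """End-to-end experiment runner (train, lesion, assay, aggregate);
    see :func:`semdem.experiment.run_experiment`."""
    from .experiment import run_experiment as _run
    return _run(config, seed, **kwargs)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    p_gg: float | None = None       # Greenhouse-Geisser-corrected p, if computed
    note: str = ""


@dataclass
class ContrastResult:
    name: str
    t: float
    df: int
    p_raw: float
    p_corrected: float


def normalize_to_intact(counts: pd.DataFrame) -> pd.DataFrame:
    """Add intact-normalised ratios to a long table of assay counts.

    Expects columns (instance, lesion_type, severity, word_id, category,
    area, responsive_ca_count); the severity-0 rows define the intact counts.
    Rows whose intact count is zero have an undefined ratio and are dropped.
    """
    key = ["instance", "lesion_type", "word_id", "area"]
    intact = (counts.loc[counts["severity"] == 0, key + ["responsive_ca_count"]]
              .rename(columns={"responsive_ca_count": "intact_count"}))
    missing = counts[key].merge(intact[key].drop_duplicates(), on=key,
                                how="left", indicator=True)
    if (missing["_merge"] == "left_only").any():
        raise ValueError("every (instance, lesion_type, word, area) needs a severity-0 record")
    out = counts.merge(intact, on=key, how="left")
    out["system"] = np.where(out["area"].isin(list(PERISYLVIAN)),
                             "perisylvian", "extrasylvian")
    out = out[out["intact_count"] > 0].copy()
    out["ratio"] = out["responsive_ca_count"] / out["intact_count"]
    return out


def system_ratios(table: pd.DataFrame,
                  by: tuple[str, ...] = ("instance", "lesion_type", "severity",
                                         "category", "system")) -> pd.DataFrame:
    """System-level ratios: counts summed over the six areas of each system
    (and words) before dividing — sum(lesioned) / sum(intact)."""
    g = table.groupby(list(by), as_index=False)[["responsive_ca_count", "intact_count"]].sum()
    g["ratio"] = g["responsive_ca_count"] / g["intact_count"]
    return g


def decline_percent(table: pd.DataFrame, severity: int = 90,
                    by: tuple[str, ...] = ("instance", "lesion_type",
                                           "category", "system")) -> pd.DataFrame:
    """Decline = 100 * (1 - ratio at the given severity), per grouping cell."""
    sr = system_ratios(table, by=tuple(by) + ("severity",))
    sel = sr[sr["severity"] == severity].copy()
    sel["decline_pct"] = 100.0 * (1.0 - sel["ratio"])
    return sel.drop(columns=["severity"])


def rm_anova(table: pd.DataFrame, dv: str, within: list[str],
             subject: str = "instance") -> list[AnovaResult]:
    """Repeated-measures ANOVA (1 or 2 within factors, instances as subjects).

    Requires a balanced complete design; raises naming the missing cells
    otherwise.  Backed by pingouin; Greenhouse-Geisser-corrected p-values are
    reported alongside the uncorrected ones when pingouin provides them.
    """
    import pingouin as pg

    cells = table.groupby([subject] + within, observed=True).size()
    expected = table[subject].nunique() * int(np.prod([table[f].nunique() for f in within]))
    if len(cells) != expected:
        full = pd.MultiIndex.from_product(
            [table[subject].unique()] + [table[f].unique() for f in within],
            names=[subject] + within)
        missing = full.difference(cells.index)
        raise ValueError(f"unbalanced design; missing cells: {list(missing)[:10]}")
    if (cells > 1).any():
        data = table.groupby([subject] + within, as_index=False, observed=True)[dv].mean()
    else:
        data = table
    try:
        aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                          detailed=True, correction=True)
    except Exception as exc:   # zero error variance and similar degeneracies
        return [AnovaResult(effect=" x ".join(within), F=float("nan"),
                            df_num=float("nan"), df_den=float("nan"),
                            p=float("nan"), note=f"degenerate design: {exc}")]
    if "F" not in aov.columns:
        return [AnovaResult(effect=" x ".join(within), F=float("nan"),
                            df_num=float("nan"), df_den=float("nan"),
                            p=float("nan"), note="degenerate design: no F computed")]
    # pingouin's one-way layout carries an Error row with the denominator DF;
    # the multi-factor layout lists ddof1/ddof2 per effect directly
    error_df = None
    if "DF" in aov.columns:
        err = aov[aov["Source"].str.lower().isin(("error", "residual"))]
        if len(err):
            error_df = float(err["DF"].iloc[0])
    results = []
    for _, row in aov.iterrows():
        if str(row["Source"]).lower() in ("error", "residual"):
            continue
        p_gg = row.get("p_GG_corr", row.get("p-GG-corr"))
        df_num = float(row["ddof1"]) if "ddof1" in aov.columns else float(row["DF"])
        df_den = float(row["ddof2"]) if "ddof2" in aov.columns else error_df
        p_unc = row.get("p_unc", row.get("p-unc"))
        results.append(AnovaResult(
            effect=str(row["Source"]), F=float(row["F"]),
            df_num=df_num, df_den=df_den,
            p=float(p_unc),
            p_gg=None if p_gg is None or (isinstance(p_gg, float) and math.isnan(p_gg))
                 else float(p_gg),
            note="Greenhouse-Geisser p reported alongside uncorrected F",
        ))
    return results


def paired_t_bonferroni(pairs: dict[str, tuple[np.ndarray, np.ndarray]]
                        ) -> list[ContrastResult]:
    """Dependent-samples t-tests over a family of contrasts, Bonferroni-corrected.

    ``pairs`` maps contrast name -> (x, y) paired observation vectors; the
    family size for the correction is the number of contrasts supplied.
    """
    from scipy import stats as sps

    m = len(pairs)
    out = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 2:
            raise ValueError(f"contrast {name!r}: need >= 2 paired observations")
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x, y)
        out.append(ContrastResult(name, float(t), x.size - 1, float(p),
                                  min(1.0, float(p) * m)))
    return out


def sign_test(differences: np.ndarray, alternative: str = "greater") -> float:
    """Exact binomial sign test p-value on the signs of paired differences."""
    from scipy import stats as sps

    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    k = int((d > 0).sum())
    return float(sps.binomtest(k, d.size, 0.5, alternative=alternative).pvalue)


def lesion_expectation_oracle(ca_definitions: list[set],
                              removal_kind: str, n_removed: int,
                              exhaustive_limit: int = 200_000) -> float:
    """Expected number of CAs affected by removing ``n_removed`` elements
    uniformly at random without replacement.

    ``ca_definitions`` lists, per CA, its set of elements of the removable
    kind (cell ids for ``removal_kind='cells'``, link ids for ``'links'``);
    the removal population is the union of all listed elements.  A CA counts
    as affected as soon as one of its elements is removed.  The expectation
    is computed by exhaustive enumeration of all removal subsets when
    feasible, otherwise by the exact hypergeometric form
    E = sum_i [1 - C(P - |S_i|, n) / C(P, n)].
    """
    if removal_kind not in ("cells", "links"):
        raise ValueError(f"unknown removal kind {removal_kind!r}")
    population = sorted(set().union(*ca_definitions)) if ca_definitions else []
    P = len(population)
    if n_removed > P:
        raise ValueError("n_removed exceeds the population size")
    if n_removed < 0:
        raise ValueError("n_removed must be >= 0")
    if math.comb(P, n_removed) <= exhaustive_limit:
        total = 0
        count = 0
        for subset in itertools.combinations(population, n_removed):
            s = set(subset)
            total += sum(1 for ca in ca_definitions if ca & s)
            count += 1
        return total / count
    denom = math.comb(P, n_removed)
    total = 0.0
    for ca in ca_definitions:
        spared = P - len(ca)
        miss = math.comb(spared, n_removed) / denom if spared >= n_removed else 0.0
        total += 1.0 - miss
    return float(total)
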