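"""Hebbian long-term potentiation and depression on plastic e->e links.

A discrete threshold rule (no gradients, no error signal): per link, with
pre-synaptic output O_pre and post-synaptic membrane potential V_post,

* O_pre >= theta_pre and V_post >= theta_post  ->  w += delta_ltp   (LTP)
* O_pre >= theta_pre and V_post <  theta_post  ->  w -= delta_ltd          (homosynaptic LTD)
* O_pre <  theta_pre and O_post >= theta_pre   ->  w -= delta_ltd_hetero   (heterosynaptic LTD)
* otherwise                                    ->  unchanged

after which weights are clipped to [0, w_max].  Gating LTP and homosynaptic
LTD on post-synaptic depolarisation (not output) lets weakly driven, still-
silent cells recruit their inputs, which is what bootstraps cell-assembly
growth beyond the stimulated primary areas; gating heterosynaptic LTD on the
post cell actually firing makes the erosion of a cell's silent inputs scale
with its overall activity, which drives cells that fire for many words to
shed all but their best-supported word circuit.  Links to or from lesion-inactivated cells, and
links removed by a white-matter lesion, are never updated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netarch import NetworkState, multi_range

__all__ = ["PlasticityRule", "hebbian_update", "apply_hebbian_sparse"]


@dataclass(frozen=True)
class PlasticityRule:
    theta_pre: float = 0.25      # pre-synaptic output threshold, in (0, 1)
    theta_post: float = 0.20     # post-synaptic potential threshold
    delta_ltp: float = 0.004     # efficacy increment per LTP event
    delta_ltd: float = 0.001     # decrement per homosynaptic LTD event
    delta_ltd_hetero: float = 0.002   # decrement per heterosynaptic LTD event
    w_max: float = 1.0           # efficacy ceiling
    enabled: bool = True

    def __post_init__(self):
        if not (0.0 < self.theta_pre < 1.0):
            raise ValueError("theta_pre must lie in (0, 1)")
        if self.delta_ltp <= 0 or self.delta_ltd <= 0 or self.delta_ltd_hetero <= 0:
            raise ValueError("plasticity increments must be positive")


def hebbian_update(weights: np.ndarray, pre_outputs: np.ndarray,
                   post_potentials: np.ndarray, rule: PlasticityRule,
                   updatable: np.ndarray | None = None,
                   post_outputs: np.ndarray | None = None) -> np.ndarray:
    """Reference (dense) rule application over an arbitrary link set.

    ``weights``, ``pre_outputs``, ``post_potentials`` are conformable per-link
    arrays; ``post_outputs`` (defaults to clipped potentials) gates the
    heterosynaptic branch; ``updatable`` optionally masks out links that must
    not change (lesioned endpoints, removed links).  Returns the new weights.
    """
    if not rule.enabled:
        return weights.copy()
    pre = np.asarray(pre_outputs) >= rule.theta_pre
    post = np.asarray(post_potentials) >= rule.theta_post
    if post_outputs is None:
        post_outputs = np.clip(post_potentials, 0.0, 1.0)
    post_firing = np.asarray(post_outputs) >= rule.theta_pre
    dw = np.zeros_like(weights, dtype=float)
    dw[pre & post] = rule.delta_ltp
    dw[pre & ~post] = -rule.delta_ltd
    dw[~pre & post_firing] = -rule.delta_ltd_hetero
    if updatable is not None:
        dw[~np.asarray(updatable, dtype=bool)] = 0.0
    return np.clip(weights + dw, 0.0, rule.w_max)


def apply_hebbian_sparse(net: NetworkState, rule: PlasticityRule) -> None:
    """In-place, activity-sparse application of :func:`hebbian_update` to the
    whole network (identical result, but only links with an above-threshold
    endpoint are visited)."""
    if not rule.enabled:
        return
    pre_ok = net.O >= rule.theta_pre              # lesioned cells emit 0 < theta_pre
    post_ok = (net.V >= rule.theta_post) & net.lesion_mask
    post_firing = net.O >= rule.theta_pre         # gates heterosynaptic LTD

    # links with active pre: LTP if post depolarised, homosynaptic LTD otherwise
    ap = np.flatnonzero(pre_ok & net.lesion_mask)
    if ap.size:
        pos = multi_range(net.out_indptr, ap)
        if pos.size:
            tgt = net.out_tgt[pos]
            upd = net.plastic[pos] & net.lesion_mask[tgt]
            dw = np.where(post_ok[tgt], rule.delta_ltp, -rule.delta_ltd)
            dw[~upd] = 0.0
            net.w[pos] = np.clip(net.w[pos] + dw, 0.0, rule.w_max)

    # links with silent pre into firing posts: heterosynaptic LTD
    apo = np.flatnonzero(post_firing)
    if apo.size:
        raw = multi_range(net.in_indptr, apo)
        if raw.size:
            pos = net.in_pos[raw]
            src = net.in_src[raw]
            sel = net.plastic[pos] & net.lesion_mask[src] & ~pre_ok[src]
            pos = pos[sel]
            if pos.size:
                net.w[pos] = np.clip(net.w[pos] - rule.delta_ltd_hetero, 0.0,
                                     rule.w_max)
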