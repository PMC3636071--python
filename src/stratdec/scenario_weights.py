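"""Model-averaging of biogeographic scenarios over posterior tree samples.

Each split scenario (or ancestral-range marginal) at a node is treated as a
competing model with a fitted log-likelihood.  Because every scenario shares
the same two free rate parameters (d, e), Akaike weights reduce to
likelihoods normalized over the scenario set; both routes are computed and
cross-checked.  Averaging the per-tree weights across a posterior sample of
dated trees gives the *composite* Akaike weight, which folds topological and
temporal uncertainty into a single support value; the evidence ratio (best
weight over runner-up weight) expresses relative rather than absolute
support.  A separate helper tests whether a divergence-time interval
overlaps a geological window such as a continental break-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import dec_core
from .dec_core import DECParams, SplitScenario, StateSpace
from .geography import CodingTable, EpochModel, RangeState
from .tree_io import DatedTree, TreeSample

__all__ = [
    "ScenarioWeightTable",
    "CompositeReport",
    "GeoWindow",
    "akaike_weights",
    "composite_weights",
    "evidence_ratio",
    "filter_two_loglik",
    "temporal_overlap",
    "overlap_report",
]

#: Free parameters of the DEC model shared by every scenario: d and e.
N_FREE_PARAMS = 2


@dataclass
class ScenarioWeightTable:
    """Per-scenario AIC bookkeeping: logL, AIC, delta-AIC and Akaike weight."""

    labels: list[Hashable]
    log_likelihoods: np.ndarray
    aic: np.ndarray
    delta: np.ndarray
    weights: np.ndarray
    k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": [str(l) for l in self.labels],
                "logL": self.log_likelihoods,
                "AIC": self.aic,
                "delta_AIC": self.delta,
                "weight": self.weights,
            }
        )

    def weight_of(self, label: Hashable) -> float:
        return float(self.weights[self.labels.index(label)])


def akaike_weights(
    log_likelihoods: Mapping[Hashable, float] | Sequence[float],
    k: int = N_FREE_PARAMS,
) -> ScenarioWeightTable:
    """Akaike weights for a set of competing scenarios.

    ``AIC_i = -2 logL_i + 2k``; ``w_i = exp(-delta_i / 2)`` normalized.  With
    k identical across scenarios this must equal the directly normalized
    likelihoods; both are computed and asserted to agree, guarding the
    formula against drift.  ``-inf`` log-likelihoods get weight 0.
    """
    if isinstance(log_likelihoods, Mapping):
        labels = list(log_likelihoods.keys())
        ll = np.array([log_likelihoods[l] for l in labels], dtype=float)
    else:
        ll = np.asarray(list(log_likelihoods), dtype=float)
        labels = list(range(len(ll)))
    if ll.size == 0:
        raise ValueError("no scenarios given")
    if np.isnan(ll).any() or (ll == np.inf).any():
        raise ValueError("log-likelihoods must be finite or -inf")
    best = ll.max()
    if not math.isfinite(best):
        raise ValueError("all scenarios have zero likelihood")
    aic = -2.0 * ll + 2.0 * k
    delta = aic - aic.min()
    with np.errstate(over="ignore"):
        raw = np.exp(-delta / 2.0)
    weights = raw / raw.sum()
    # route 2: likelihoods normalized directly (equal k) — must agree
    rel = np.exp(ll - best)
    alt = rel / rel.sum()
    assert np.max(np.abs(weights - alt)) < 1e-12
    return ScenarioWeightTable(
        labels=labels,
        log_likelihoods=ll,
        aic=aic,
        delta=delta,
        weights=weights,
        k=k,
    )


def evidence_ratio(weights: Sequence[float] | ScenarioWeightTable) -> float:
    """Support for the best scenario relative to the runner-up: w1 / w2."""
    w = (
        weights.weights
        if isinstance(weights, ScenarioWeightTable)
        else np.asarray(list(weights), dtype=float)
    )
    if len(w) < 2:
        raise ValueError("evidence ratio needs at least two scenarios")
    top = np.sort(w)[::-1]
    if top[1] <= 0:
        raise ValueError("runner-up scenario has zero weight")
    return float(top[0] / top[1])


def filter_two_loglik(
    scenarios: Iterable[SplitScenario], window: float = 2.0
) -> list[SplitScenario]:
    """Scenarios within ``window`` log-likelihood units of the best.

    A reporting convenience only: weights are always normalized over the
    complete scenario set before any filtering.
    """
    scen = list(scenarios)
    if not scen:
        return []
    best = max(s.log_likelihood for s in scen)
    return [s for s in scen if best - s.log_likelihood < window]


@dataclass
class CompositeReport:
    """Composite (posterior-averaged) Akaike weights at one clade."""

    clade: frozenset[str]
    composite_weights: dict[RangeState, float]
    n_trees_used: int
    n_trees_total: int
    per_tree_weights: list[dict[RangeState, float]] = field(repr=False, default_factory=list)
    split_composite_weights: dict[tuple[RangeState, RangeState, RangeState], float] = field(
        repr=False, default_factory=dict
    )
    fitted_params: list[DECParams] = field(repr=False, default_factory=list)

    @property
    def clade_frequency(self) -> float:
        return self.n_trees_used / self.n_trees_total

    def ranked(self) -> list[tuple[RangeState, float]]:
        return sorted(
            self.composite_weights.items(), key=lambda kv: (-kv[1], kv[0].bits)
        )

    @property
    def evidence_ratio(self) -> float:
        return evidence_ratio([w for _, w in self.ranked()])

    def as_frame(self, area_names: Sequence[str] | None = None) -> pd.DataFrame:
        rows = [
            {"ancestral_range": r.label(area_names), "composite_weight": w}
            for r, w in self.ranked()
        ]
        return pd.DataFrame(rows)


def composite_weights(
    sample: TreeSample,
    coding: CodingTable,
    epochs: EpochModel,
    clade: Iterable[str],
    fit_mode: str = "per-tree",
    params: DECParams | None = None,
    count_absent_trees: bool = False,
) -> CompositeReport:
    """Composite Akaike weights for the ancestral range of one clade.

    For every tree in the sample that contains the clade: fit (or reuse,
    depending on ``fit_mode``) the DEC rates, compute all split-scenario
    likelihoods at the clade's node, marginalize to ancestral ranges, and
    convert to Akaike weights.  The composite weight of each range is the
    arithmetic mean of its per-tree weights.

    fit_mode
        ``"per-tree"``  — re-estimate (d, e) on every tree (matches per-tree
        inference; slower).
        ``"fixed"``     — use ``params`` on every tree.
    count_absent_trees
        If True, trees lacking the clade contribute zero weight to every
        scenario (the mean is taken over the whole sample); by default the
        mean runs over contributing trees only and the clade frequency
        reports how many there were.
    """
    if fit_mode not in ("per-tree", "fixed"):
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    if fit_mode == "fixed" and params is None:
        raise ValueError("fit_mode='fixed' requires params")
    key = frozenset(clade)
    space = StateSpace(coding.n_areas)
    epochs_by_tree: list[EpochModel] = []
    per_tree: list[dict[RangeState, float]] = []
    per_tree_split: list[dict[tuple, float]] = []
    fitted: list[DECParams] = []
    for tree in sample:
        node = tree.find_clade(key)
        if node is None or node.is_tip:
            continue
        ep = validated = _validate_for(epochs, tree)
        epochs_by_tree.append(validated)
        if fit_mode == "per-tree":
            p = dec_core.fit_parameters(tree, coding, ep, space=space).params
        else:
            p = params  # type: ignore[assignment]
        fitted.append(p)
        scen = dec_core.node_split_likelihoods(tree, coding, p, ep, node, space)
        marg = dec_core.range_marginals(scen)
        tab = akaike_weights(marg)
        per_tree.append(dict(zip(tab.labels, tab.weights)))
        stab = akaike_weights(
            {(s.ancestral, s.left, s.right): s.log_likelihood for s in scen}
        )
        per_tree_split.append(dict(zip(stab.labels, stab.weights)))
    if not per_tree:
        raise ValueError("clade not present (as an internal node) in any tree")
    denom = len(sample) if count_absent_trees else len(per_tree)
    composite: dict[RangeState, float] = {}
    for w in per_tree:
        for r, v in w.items():
            composite[r] = composite.get(r, 0.0) + v / denom
    split_composite: dict[tuple, float] = {}
    for w in per_tree_split:
        for s, v in w.items():
            split_composite[s] = split_composite.get(s, 0.0) + v / denom
    return CompositeReport(
        clade=key,
        composite_weights=composite,
        n_trees_used=len(per_tree),
        n_trees_total=len(sample),
        per_tree_weights=per_tree,
        split_composite_weights=split_composite,
        fitted_params=fitted,
    )


def _validate_for(epochs: EpochModel, tree: DatedTree) -> EpochModel:
    from .geography import validate_epochs

    return validate_epochs(epochs, tree.root_age)


@dataclass(frozen=True)
class GeoWindow:
    """A geological event window in Ma (e.g. a continental separation)."""

    label: str
    older_bound: float
    younger_bound: float

    def __post_init__(self) -> None:
        if not (self.older_bound > self.younger_bound >= 0):
            raise ValueError(
                f"window {self.label!r}: need older > younger >= 0, got "
                f"{self.older_bound}-{self.younger_bound}"
            )


def temporal_overlap(
    age_interval: tuple[float, float], window: GeoWindow
) -> tuple[bool, float]:
    """Does a divergence-age interval intersect a geological window?

    ``age_interval`` is (younger, older) in Ma, typically a 95% HPD.  Returns
    the verdict and the length of the intersection in Myr (0 if disjoint).
    Boundary-touching intervals count as overlapping with span 0.
    """
    lo, hi = age_interval
    if lo >= hi:
        raise ValueError(f"inverted age interval ({lo}, {hi})")
    span = min(hi, window.older_bound) - max(lo, window.younger_bound)
    return span >= 0, max(span, 0.0)


def overlap_report(
    intervals: Mapping[str, tuple[float, float]],
    windows: Mapping[str, GeoWindow],
    pairs: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Tabulate overlap verdicts for (divergence, window) pairs."""
    rows = []
    for clade_name, window_name in pairs:
        iv = intervals[clade_name]
        win = windows[window_name]
        ok, span = temporal_overlap(iv, win)
        rows.append(
            {
                "divergence": clade_name,
                "hpd_young": iv[0],
                "hpd_old": iv[1],
                "window": win.label,
                "window_young": win.younger_bound,
                "window_old": win.older_bound,
                "overlaps": ok,
                "overlap_span_myr": span,
            }
        )
    return pd.DataFrame(rows)
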