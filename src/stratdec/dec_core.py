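"""Dispersal-extinction-cladogenesis (DEC) likelihood machinery.

Ranges (subsets of K areas) evolve along branches as a continuous-time Markov
chain: an occupied range R gains area a at rate d * sum_{b in R} m[b][a]
(dispersal out of every occupied source area, scaled by the epoch's
multiplier) and loses any occupied area at rate e (local extinction); a range
reduced to a single area decays to the absorbing null range.  At speciation
the ancestral range is partitioned between the daughters: a single-area range
is inherited identically by both; a widespread range either splits into two
disjoint pieces with one daughter getting a single area, or one daughter
keeps the full range while the other is founded within a single constituent
area (subset sympatry).  All allowed splits of a range share a flat 1/n
prior.

The tree likelihood uses Felsenstein pruning over the range state space with
per-node rescaling; per-node split-scenario likelihoods combine the pruning
("inside") pass with a preorder "outside" pass, so that the likelihoods of
all scenarios at a node sum exactly to the total likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .geography import (
    CodingTable,
    ConfigError,
    DispersalMultiplierMatrix,
    EpochModel,
    RangeState,
    enumerate_ranges,
)
from .tree_io import DatedTree, Node, slice_branch

__all__ = [
    "DECParams",
    "StateSpace",
    "SplitScenario",
    "FitResult",
    "build_generator",
    "branch_transition",
    "enumerate_splits",
    "split_count",
    "tree_log_likelihood",
    "fit_parameters",
    "node_split_likelihoods",
    "range_marginals",
]


@dataclass(frozen=True)
class DECParams:
    """Anagenetic rate parameters: d = dispersal, e = extinction, per Myr."""

    d: float
    e: float

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")


class StateSpace:
    """Indexed DEC range state space for K areas (null state last)."""

    def __init__(self, n_areas: int, max_size: int | None = None):
        self.n_areas = n_areas
        self.states: list[RangeState] = enumerate_ranges(n_areas, max_size)
        self.index: dict[int, int] = {s.bits: i for i, s in enumerate(self.states)}
        self.null_index = len(self.states) - 1
        self.n_states = len(self.states)
        self.n_nonnull = self.n_states - 1
        # split tables, built lazily per ancestral state index
        self._splits: dict[int, list[tuple[int, int]]] = {}

    def splits_of(self, state_idx: int) -> list[tuple[int, int]]:
        """Allowed (left, right) state-index pairs for an ancestral state."""
        if state_idx not in self._splits:
            anc = self.states[state_idx]
            pairs = enumerate_splits(anc)
            self._splits[state_idx] = [
                (self.index[l.bits], self.index[r.bits]) for l, r in pairs
            ]
        return self._splits[state_idx]

    def labels(self, names: Sequence[str] | None = None) -> list[str]:
        return [s.label(names) for s in self.states]


def enumerate_splits(ancestral: RangeState) -> list[tuple[RangeState, RangeState]]:
    """All allowed daughter-range pairs for an ancestral range.

    A single-area range yields the identity split.  For a widespread range R,
    each constituent area a contributes four ordered forms — vicariance
    ({a}, R\\{a}) both ways and subset sympatry ({a}, R) both ways — with
    duplicates removed (for |R| = 2 the two families coincide pairwise).
    """
    if ancestral.is_null:
        raise ConfigError("the null range cannot speciate")
    k = ancestral.n_areas
    if ancestral.size == 1:
        return [(ancestral, ancestral)]
    seen: set[tuple[int, int]] = set()
    out: list[tuple[RangeState, RangeState]] = []
    for a in ancestral.areas():
        single = 1 << a
        rest = ancestral.bits & ~single
        for lb, rb in (
            (single, rest),
            (rest, single),
            (single, ancestral.bits),
            (ancestral.bits, single),
        ):
            if (lb, rb) not in seen:
                seen.add((lb, rb))
                out.append((RangeState(lb, k), RangeState(rb, k)))
    return out


def split_count(ancestral: RangeState) -> int:
    return len(enumerate_splits(ancestral))


def build_generator(
    params: DECParams,
    mult: DispersalMultiplierMatrix,
    space: StateSpace,
) -> np.ndarray:
    """Anagenetic rate matrix over the range state space for one epoch.

    Gain of area a from range R at rate d * sum_{b in R} m[b][a]; loss of any
    occupied area at rate e; the null state is absorbing.  Rows sum to zero.
    """
    if mult.n_areas != space.n_areas:
        raise ConfigError(
            f"multiplier matrix is {mult.n_areas}x{mult.n_areas} but the "
            f"state space has {space.n_areas} areas"
        )
    n = space.n_states
    q = np.zeros((n, n))
    m = mult.m
    for i, state in enumerate(space.states):
        if state.is_null:
            continue
        occupied = state.areas()
        for a in range(space.n_areas):
            abit = 1 << a
            if state.bits & abit:
                # local extinction: lose area a (possibly down to null)
                j = space.index[state.bits & ~abit]
                q[i, j] += params.e
            else:
                rate = params.d * sum(m[b, a] for b in occupied)
                if rate > 0:
                    j = space.index[state.bits | abit]
                    q[i, j] += rate
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


class _EpochGenerators:
    """Per-slice generators (and their expm cache) for one parameter value."""

    def __init__(self, params: DECParams, epochs: EpochModel, space: StateSpace):
        self.generators = [
            build_generator(params, s.multipliers, space) for s in epochs.slices
        ]
        self.epochs = epochs
        self._cache: dict[tuple[int, float], np.ndarray] = {}

    def segment_matrix(self, slice_idx: int, duration: float) -> np.ndarray:
        key = (slice_idx, duration)
        p = self._cache.get(key)
        if p is None:
            p = expm(self.generators[slice_idx] * duration)
            self._cache[key] = p
        return p


def branch_transition(
    params: DECParams,
    epochs: EpochModel,
    parent_age: float,
    child_age: float,
    space: StateSpace,
    _gens: _EpochGenerators | None = None,
) -> np.ndarray:
    """Transition probability matrix along one branch, old -> young.

    The product of per-epoch-segment matrix exponentials, taken in
    chronological order.  A zero-duration branch returns the identity.
    """
    if abs(parent_age - child_age) < 1e-15:
        return np.eye(space.n_states)
    gens = _gens or _EpochGenerators(params, epochs, space)
    epochs = epochs if epochs is not None else gens.epochs
    p: np.ndarray | None = None
    for duration, idx in slice_branch(parent_age, child_age, epochs):
        seg = gens.segment_matrix(idx, duration)
        p = seg if p is None else p @ seg
    assert p is not None
    return p


# ---------------------------------------------------------------------------
# pruning machinery
# ---------------------------------------------------------------------------


def _tip_vector(label: str, coding: CodingTable, space: StateSpace) -> np.ndarray:
    v = np.zeros(space.n_states)
    rng = coding.assignments[label]
    if rng.bits not in space.index:
        raise ConfigError(
            f"tip {label!r} coded with a range outside the state space"
        )
    v[space.index[rng.bits]] = 1.0
    return v


@dataclass
class _PruningResult:
    """Inside pass bookkeeping.

    ``cond[v]`` is the rescaled conditional likelihood vector at node v
    (probability of the tip data below v given v's range, at the node);
    ``down[v]`` is the same vector propagated up v's subtending branch to
    just below v's parent's split; ``log_scale[v]`` is the accumulated log
    rescaling factor shared by both.
    """

    cond: dict[Node, np.ndarray]
    down: dict[Node, np.ndarray]
    log_scale: dict[Node, float]
    log_likelihood: float
    gens: "_EpochGenerators"
    space: StateSpace


def _prune(
    tree: DatedTree,
    coding: CodingTable,
    params: DECParams,
    epochs: EpochModel,
    space: StateSpace,
    root_prior: np.ndarray | None = None,
) -> _PruningResult:
    coding.require(t.label for t in tree.tips())
    if tree.root_age > epochs.oldest_bound + 1e-9:
        raise ConfigError(
            f"root age {tree.root_age} Ma exceeds the epoch span; "
            "run validate_epochs first"
        )
    gens = _EpochGenerators(params, epochs, space)
    cond: dict[Node, np.ndarray] = {}
    down: dict[Node, np.ndarray] = {}
    log_scale: dict[Node, float] = {}
    for nd in tree.postorder():
        if nd.is_tip:
            c = _tip_vector(nd.label, coding, space)
            log_scale[nd] = 0.0
        else:
            left, right = nd.children
            c = np.zeros(space.n_states)
            dl, dr = down[left], down[right]
            for i in range(space.n_nonnull):
                pairs = space.splits_of(i)
                acc = 0.0
                for li, ri in pairs:
                    acc += dl[li] * dr[ri]
                c[i] = acc / len(pairs)
            # a null ancestor cannot produce observed (non-null) tips
            c[space.null_index] = 0.0
            log_scale[nd] = log_scale[left] + log_scale[right]
        # rescale to guard against underflow on deep trees
        mx = c.max()
        if mx > 0 and (mx < 1e-50 or mx > 1e50):
            c = c / mx
            log_scale[nd] += math.log(mx)
        cond[nd] = c
        if nd.parent is not None:
            p = branch_transition(
                params, epochs, nd.parent.age, nd.age, space, _gens=gens
            )
            down[nd] = p @ c

    root_c = cond[tree.root]
    if root_prior is None:
        prior = np.full(space.n_states, 1.0 / space.n_nonnull)
        prior[space.null_index] = 0.0
    else:
        prior = root_prior
    total = float(prior @ root_c)
    if total <= 0.0:
        log_l = -math.inf
    else:
        log_l = math.log(total) + log_scale[tree.root]
    return _PruningResult(cond, down, log_scale, log_l, gens, space)


def tree_log_likelihood(
    tree: DatedTree,
    coding: CodingTable,
    params: DECParams,
    epochs: EpochModel,
    space: StateSpace | None = None,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of the tip ranges under stratified DEC.

    The root range gets a flat prior over non-null states unless an explicit
    ``root_prior`` (over the full state space, null included) is supplied.
    """
    space = space or StateSpace(coding.n_areas)
    return _prune(tree, coding, params, epochs, space, root_prior).log_likelihood


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: DECParams
    log_likelihood: float
    converged: bool
    n_evaluations: int
    starts: list[tuple[DECParams, float]] = field(default_factory=list)


def fit_parameters(
    tree: DatedTree,
    coding: CodingTable,
    epochs: EpochModel,
    bounds: tuple[float, float] = (1e-9, 10.0),
    n_grid: int = 4,
    space: StateSpace | None = None,
) -> FitResult:
    """Maximum-likelihood (d, e) by deterministic multi-start optimization.

    The likelihood is scored on an ``n_grid`` x ``n_grid`` log-spaced grid
    over ``bounds``; Nelder-Mead in log-rate space polishes the two best
    distinct grid points (function tolerance 1e-8 in log-likelihood).  Fully
    deterministic: same inputs give the same output.
    """
    space = space or StateSpace(coding.n_areas)
    lo, hi = bounds
    n_eval = 0

    def nll(logdr: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        d, e = np.exp(logdr)
        d = min(max(d, lo), hi)
        e = min(max(e, lo), hi)
        ll = tree_log_likelihood(tree, coding, DECParams(d, e), epochs, space)
        return -ll if math.isfinite(ll) else 1e300

    grid = np.log(np.geomspace(max(lo, 1e-6), min(hi, 1.0), n_grid))
    starts_scored: list[tuple[float, np.ndarray]] = []
    for gd in grid:
        for ge in grid:
            x = np.array([gd, ge])
            starts_scored.append((nll(x), x))
    starts_scored.sort(key=lambda t: t[0])
    if not math.isfinite(starts_scored[0][0]) or starts_scored[0][0] >= 1e300:
        raise ConfigError("likelihood not finite at any start point")

    endpoints: list[tuple[DECParams, float]] = []
    best_x, best_f = starts_scored[0][1], starts_scored[0][0]
    for f0, x0 in starts_scored[:2]:
        res = minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 400},
        )
        d, e = np.exp(res.x)
        d = min(max(float(d), lo), hi)
        e = min(max(float(e), lo), hi)
        endpoints.append((DECParams(d, e), -float(res.fun)))
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    d, e = np.exp(best_x)
    d = min(max(float(d), lo), hi)
    e = min(max(float(e), lo), hi)
    return FitResult(
        params=DECParams(d, e),
        log_likelihood=-best_f,
        converged=True,
        n_evaluations=n_eval,
        starts=endpoints,
    )


# ---------------------------------------------------------------------------
# per-node split scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitScenario:
    """One biogeographic scenario at a node: ancestral range plus the two
    daughter ranges, with the global log-likelihood of the whole dataset
    when the node is constrained to that scenario."""

    ancestral: RangeState
    left: RangeState
    right: RangeState
    log_likelihood: float


def _outside_vectors(
    tree: DatedTree, pr: _PruningResult
) -> tuple[dict[Node, np.ndarray], dict[Node, float]]:
    """Preorder 'outside' pass.

    ``out[v][j]`` (times exp(out_scale[v])) is the probability of all tip
    data *outside* v's subtree jointly with v being in range j at node v,
    including the root prior.  At the root it is the prior itself, so
    sum_j out[v][j] * cond[v][j] recovers the total likelihood at any node.
    """
    space = pr.space
    prior = np.full(space.n_states, 1.0 / space.n_nonnull)
    prior[space.null_index] = 0.0
    out: dict[Node, np.ndarray] = {tree.root: prior}
    out_scale: dict[Node, float] = {tree.root: 0.0}
    for nd in tree.preorder():
        if nd.is_tip:
            continue
        left, right = nd.children
        o = out[nd]
        for child, sib in ((left, right), (right, left)):
            # outside of `child` at the top of its branch: route the parent's
            # outside mass through every split whose child-slot matches
            top = np.zeros(space.n_states)
            ds = pr.down[sib]
            child_is_left = child is left
            for i in range(space.n_nonnull):
                oi = o[i]
                if oi == 0.0:
                    continue
                pairs = space.splits_of(i)
                w = oi / len(pairs)
                for li, ri in pairs:
                    if child_is_left:
                        top[li] += w * ds[ri]
                    else:
                        top[ri] += w * ds[li]
            p = branch_transition(
                None, None, nd.age, child.age, space, _gens=pr.gens  # type: ignore[arg-type]
            )
            vec = top @ p
            sc = out_scale[nd] + pr.log_scale[sib]
            mx = vec.max()
            if mx > 0 and (mx < 1e-50 or mx > 1e50):
                vec = vec / mx
                sc += math.log(mx)
            out[child] = vec
            out_scale[child] = sc
    return out, out_scale


def node_split_likelihoods(
    tree: DatedTree,
    coding: CodingTable,
    params: DECParams,
    epochs: EpochModel,
    node: Node,
    space: StateSpace | None = None,
    _pruning: _PruningResult | None = None,
    _outside: tuple[dict[Node, np.ndarray], dict[Node, float]] | None = None,
) -> list[SplitScenario]:
    """Global likelihood of every split scenario at one internal node.

    Every (ancestral, left, right) combination allowed by the cladogenesis
    rules is reported, unfiltered; their likelihoods sum to the full tree
    likelihood.  Scenarios with zero likelihood carry ``-inf``.
    """
    if node.is_tip:
        raise ConfigError("split scenarios are defined only at internal nodes")
    space = space or StateSpace(coding.n_areas)
    pr = _pruning or _prune(tree, coding, params, epochs, space)
    out, out_scale = _outside if _outside is not None else _outside_vectors(tree, pr)
    left, right = node.children
    o = out[node]
    dl, dr = pr.down[left], pr.down[right]
    base = out_scale[node] + pr.log_scale[left] + pr.log_scale[right]
    scenarios: list[SplitScenario] = []
    for i in range(space.n_nonnull):
        pairs = space.splits_of(i)
        w = o[i] / len(pairs)
        for li, ri in pairs:
            val = w * dl[li] * dr[ri]
            ll = math.log(val) + base if val > 0 else -math.inf
            scenarios.append(
                SplitScenario(space.states[i], space.states[li], space.states[ri], ll)
            )
    return scenarios


def all_node_split_likelihoods(
    tree: DatedTree,
    coding: CodingTable,
    params: DECParams,
    epochs: EpochModel,
    space: StateSpace | None = None,
) -> dict[Node, list[SplitScenario]]:
    """Split scenarios for every internal node, sharing one inside/outside pass."""
    space = space or StateSpace(coding.n_areas)
    pr = _prune(tree, coding, params, epochs, space)
    outside = _outside_vectors(tree, pr)
    return {
        nd: node_split_likelihoods(
            tree, coding, params, epochs, nd, space, _pruning=pr, _outside=outside
        )
        for nd in tree.internal_nodes()
    }


def range_marginals(scenarios: Iterable[SplitScenario]) -> dict[RangeState, float]:
    """Sum scenario likelihoods by ancestral range (log scale in, log out).

    The summation is done in likelihood space with a shared log offset, so
    the total over ranges equals the total over scenarios exactly.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("no scenarios to marginalize")
    finite = [s.log_likelihood for s in scenarios if math.isfinite(s.log_likelihood)]
    if not finite:
        return {s.ancestral: -math.inf for s in scenarios}
    offset = max(finite)
    acc: dict[RangeState, float] = {}
    for s in scenarios:
        if math.isfinite(s.log_likelihood):
            acc[s.ancestral] = acc.get(s.ancestral, 0.0) + math.exp(
                s.log_likelihood - offset
            )
        else:
            acc.setdefault(s.ancestral, 0.0)
    return {
        r: (math.log(v) + offset if v > 0 else -math.inf) for r, v in acc.items()
    }
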