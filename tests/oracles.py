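"""Independent reference computations used to validate the implementation.

Everything here deliberately avoids the code paths it checks: likelihoods by
exhaustive joint-history enumeration, matrix exponentials by uniformization,
HPD intervals by quadratic search, interval overlap by rasterization.
"""

import itertools
import math

import numpy as np

from stratdec import dec_core
from stratdec.dec_core import DECParams, StateSpace
from stratdec.geography import CodingTable, EpochModel
from stratdec.tree_io import DatedTree


def brute_force_log_likelihood(
    tree: DatedTree,
    coding: CodingTable,
    params: DECParams,
    epochs: EpochModel,
    space: StateSpace,
    restrict_node=None,
    restrict_scenario=None,
) -> float:
    """Sum over every joint assignment of (ancestral range, split) to every
    internal node.  Transition matrices are taken as given — the enumeration
    is the independent part.  Optionally restricts one node to a single
    (ancestral, left, right) scenario."""
    nodes = tree.internal_nodes()
    pmat = {
        nd: dec_core.branch_transition(params, epochs, nd.parent.age, nd.age, space)
        for nd in tree.postorder()
        if nd.parent is not None
    }
    choices = []
    for nd in nodes:
        opts = []
        for i in range(space.n_nonnull):
            pairs = space.splits_of(i)
            for li, ri in pairs:
                opts.append((i, li, ri, 1.0 / len(pairs)))
        if restrict_node is not None and nd is restrict_node:
            a, l, r = restrict_scenario
            opts = [o for o in opts if (o[0], o[1], o[2]) == (a, l, r)]
        choices.append(opts)
    prior = 1.0 / space.n_nonnull
    tip_idx = {
        t: space.index[coding.assignments[t.label].bits] for t in tree.tips()
    }
    total = 0.0
    for combo in itertools.product(*choices):
        assignment = dict(zip(nodes, combo))
        pr = prior
        for nd, (i, li, ri, w) in assignment.items():
            pr *= w
            for child, top_state in zip(nd.children, (li, ri)):
                bottom = (
                    tip_idx[child] if child.is_tip else assignment[child][0]
                )
                pr *= pmat[child][top_state, bottom]
        total += pr
    return math.log(total) if total > 0 else -math.inf


def uniformization_expm(q: np.ndarray, t: float, n_terms: int = 200) -> np.ndarray:
    """exp(q t) via uniformization: e^{-rt} sum_k (rt)^k/k! B^k, B = I + q/r."""
    rate = max(-q.diagonal().min(), 1e-12)
    b = np.eye(q.shape[0]) + q / rate
    term = np.eye(q.shape[0])
    acc = np.zeros_like(q)
    log_weight = -rate * t
    for k in range(n_terms):
        acc += math.exp(log_weight) * term
        term = term @ b
        log_weight += math.log(rate * t) - math.log(k + 1) if rate * t > 0 else -math.inf
    return acc


def brute_force_hpd(samples, mass=0.95):
    """Shortest window by explicit O(n^2) scan over all sample pairs."""
    x = sorted(samples)
    n = len(x)
    need = math.ceil(mass * n)
    best = (x[0], x[-1])
    for i in range(n):
        j = i + need - 1
        if j >= n:
            break
        if x[j] - x[i] < best[1] - best[0]:
            best = (x[i], x[j])
    return best


def rasterized_overlap(a_lo, a_hi, b_lo, b_hi, step=0.01):
    """Overlap verdict + span by scanning a 0.01-Myr grid."""
    lo = min(a_lo, b_lo)
    hi = max(a_hi, b_hi)
    grid = np.arange(lo, hi, step)
    inside = (grid >= a_lo) & (grid <= a_hi) & (grid >= b_lo) & (grid <= b_hi)
    return bool(inside.any()), float(inside.sum() * step)
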