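"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately re-derives quantities the package computes by a
different, slower route: per-sample counting loops, exhaustive partition
enumeration, and factorial-ordering Shapley averages.
"""

from __future__ import annotations

from itertools import permutations, product
from math import factorial

import numpy as np

from treestrat import encode_sample


def counting_tensors(dataset, topology):
    """O(S) per-sample label counting, independent of the sparse builder."""
    t0: dict = {}
    t1: dict = {}
    for row, label in zip(dataset.X, dataset.y):
        profile = encode_sample(row, topology)
        target = t1 if label == 1 else t0
        target[profile] = target.get(profile, 0) + 1
    return t0, t1


def brute_force_maxcut(W) -> float:
    """Max cut value by direct evaluation of every vertex partition."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    best = 0.0
    for bits in product((0, 1), repeat=n):
        value = 0.0
        for u in range(n):
            for v in range(u + 1, n):
                value += W[u, v] * (bits[u] + bits[v] - 2 * bits[u] * bits[v])
        best = max(best, value)
    return best


def permutation_shapley(model, x, background=None):
    """Shapley values via the average marginal contribution over all M!
    player orderings (tractable for M <= 5)."""
    from treestrat.interpret import _background_profiles

    M = model.topology.n_modules
    bg_profiles, bg_weights = _background_profiles(model, background)
    total = float(bg_weights.sum())
    risk_eff = np.where(
        model.output.unseen, model.output.default_risk, model.output.risk
    )
    out_weights = 1 << np.arange(M - 1, -1, -1)
    f_s = model.module_outputs(np.atleast_2d(x))[0]

    def value(coalition: frozenset) -> float:
        mask = np.array([1 if m in coalition else 0 for m in range(M)])
        mixed = np.where(mask[None, :] == 1, f_s[None, :], bg_profiles)
        idx = mixed.astype(np.int64) @ out_weights
        return float(bg_weights @ risk_eff[idx] / total)

    phi = np.zeros(M)
    for order in permutations(range(M)):
        seen: frozenset = frozenset()
        for m in order:
            phi[m] += value(seen | {m}) - value(seen)
            seen = seen | {m}
    return phi / factorial(M)
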