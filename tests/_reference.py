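"""Independent reference implementations used as test oracles.

Deliberately naive: plain-Python, re-derived from the procedure definitions
with no shared code or vectorisation, so they cannot inherit a bug from the
implementations they check.
"""

from __future__ import annotations

import itertools
import math


def brute_force_expand(pair, ids, a, M, k, excluded=frozenset(), max_iter=10000):
    """Greedy seed-pair expansion, re-scanning every candidate each iteration.

    ``a`` is a full square matrix indexable as a[i][j]; ``ids`` the gene
    names in matrix order.  Returns the final member set.
    """
    idx = {g: i for i, g in enumerate(ids)}
    members = set(pair)
    for _ in range(max_iter):
        scored = []
        for g in ids:
            if g in members or g in excluded:
                continue
            pmin = min(a[idx[g]][idx[m]] for m in members)
            if pmin > M:
                scored.append((pmin, g))
        if not scored:
            return members
        scored.sort(key=lambda t: (-t[0], t[1]))
        if len(scored) > k:
            kth = scored[k - 1][0]
            chosen = [g for p, g in scored if p >= kth]
        else:
            chosen = [g for _, g in scored]
        members.update(chosen)
    raise RuntimeError("reference expansion did not terminate")


def hypergeom_upper_tail(x, universe, term, draws):
    """P(X >= x) by exhaustive summation of point probabilities."""
    total = 0.0
    for i in range(x, min(term, draws) + 1):
        total += (
            math.comb(term, i)
            * math.comb(universe - term, draws - i)
            / math.comb(universe, draws)
        )
    return total


def bh_step_up(pvals):
    """Benjamini-Hochberg by direct evaluation of q_(i) = min_{j>=i} p_(j) m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def mean_offdiag(a, idx):
    """Mean of a[i][j] over unordered pairs of idx."""
    vals = [a[i][j] for i, j in itertools.combinations(idx, 2)]
    return sum(vals) / len(vals)
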