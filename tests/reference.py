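"""Independent reference implementations used as oracles by the test suite.

Everything here is deliberately written in the most naive way possible --
straight loops, no shared machinery with the package under test -- so that
agreement between the two is informative.
"""

from __future__ import annotations

import numpy as np

from pfbp.core import LogisticBlockTest
from pfbp.meta import fisher_combine


# ---------------------------------------------------------------------------
# brute-force forward-backward selection over combined block p-values
# ---------------------------------------------------------------------------

def _combined_logp(X, y, subset_rows, cond_cols, cand_col, test):
    lps = []
    for rows in subset_rows:
        yb = y[rows]
        cond = X[np.ix_(rows, cond_cols)] if cond_cols else None
        res = test.process_block(
            yb, cond, X[rows, cand_col][:, None], tuple(cond_cols), (cand_col,)
        )
        if res is None:
            continue
        lps.append(res[0][0])
    if not lps:
        return 0.0
    return fisher_combine(np.array(lps)).log_pvalue


def forward_backward_reference(X, y, subset_rows, alpha, max_vars, test=None):
    """Plain forward-backward selection using Fisher-combined local p-values.

    Every candidate is evaluated on every Sample Subset at every Iteration
    (no dropping, stopping or early return).  Returns the ordered selection
    sequence (as produced by the forward phase) and the final set after the
    backward phase.
    """
    test = test if test is not None else LogisticBlockTest()
    m = X.shape[1]
    log_alpha = np.log(alpha)
    selected: list[int] = []
    sequence: list[int] = []
    while len(selected) < max_vars:
        candidates = [j for j in range(m) if j not in selected]
        if not candidates:
            break
        logps = [
            _combined_logp(X, y, subset_rows, selected, j, test) for j in candidates
        ]
        k = int(np.argmin(logps))  # first minimum = lowest column index on ties
        if logps[k] > log_alpha:
            break
        selected.append(candidates[k])
        sequence.append(candidates[k])
    # backward
    while selected:
        order = sorted(selected)
        logps = [
            _combined_logp(X, y, subset_rows, [s for s in selected if s != j], j, test)
            for j in order
        ]
        k = int(np.argmax(logps))
        if logps[k] <= log_alpha:
            break
        selected.remove(order[k])
        sequence.append(-order[k] - 1)  # negative marks a removal
    return sequence, set(selected)


# ---------------------------------------------------------------------------
# brute-force d-separation by path enumeration
# ---------------------------------------------------------------------------

def _all_paths(adj, x, y):
    """All simple undirected paths between x and y."""
    paths = []

    def walk(node, path, seen):
        if node == y:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in seen:
                walk(nxt, path + [nxt], seen | {nxt})

    walk(x, [x], {x})
    return paths


def dsep_bruteforce(digraph, x, y, z):
    """d-separation by enumerating every simple path and applying the
    collider criterion directly."""
    z = set(z)
    nodes = list(digraph.nodes)
    adj = {v: set(digraph.successors(v)) | set(digraph.predecessors(v)) for v in nodes}
    desc = {v: _descendants(digraph, v) for v in nodes}
    for path in _all_paths(adj, x, y):
        blocked = False
        for i in range(1, len(path) - 1):
            a, b, c = path[i - 1], path[i], path[i + 1]
            is_collider = digraph.has_edge(a, b) and digraph.has_edge(c, b)
            if is_collider:
                if b not in z and not (desc[b] & z):
                    blocked = True
                    break
            else:
                if b in z:
                    blocked = True
                    break
        if not blocked:
            return False  # open path found
    return True


def _descendants(digraph, v):
    out = set()
    stack = [v]
    while stack:
        u = stack.pop()
        for w in digraph.successors(u):
            if w not in out:
                out.add(w)
                stack.append(w)
    return out


def markov_blanket_by_definition(cg):
    """Graph-free Markov-blanket characterization: X belongs to MB(T) exactly
    when T and X stay d-connected given all remaining variables (conditioning
    on everything opens every spouse's collider and blocks every other
    route), checked with the brute-force path criterion."""
    t = cg.target
    nodes = [v for v in cg.graph.nodes if v != t]
    mb = set()
    for x in nodes:
        rest = set(v for v in nodes if v != x)
        if not dsep_bruteforce(cg.graph, t, x, rest):
            mb.add(x)
    return mb


# ---------------------------------------------------------------------------
# exhaustive bootstrap enumeration for two-row stores
# ---------------------------------------------------------------------------

def enumerate_two_row_probability(indicator):
    """Exact bootstrap probability for K=2: average the indicator over the
    four equiprobable resamples (0,0), (0,1), (1,0), (1,1)."""
    vals = [indicator((a, b)) for a in (0, 1) for b in (0, 1)]
    return float(np.mean(vals))
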