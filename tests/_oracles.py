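"""Independent brute-force oracles used by the test suite only."""

import itertools

import numpy as np

from rotshift import mk_models as mk


def enumeration_log_likelihood(tree, states, Q, pi) -> float:
    """Tree likelihood by exhaustive summation over internal-node states.

    Exponential in the number of internal nodes; only for tiny trees.
    Independent of the pruning implementation (shares only exp(Qt)).
    """
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    n = Q.shape[0]
    cache = {}

    def P(t):
        if t not in cache:
            cache[t] = mk.transition_prob(Q, t)
        return cache[t]

    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        like = pi[amap[tree.seed_node]]
        for nd in nodes:
            if nd.parent_node is None:
                continue
            row = amap[nd.parent_node]
            t = nd.edge.length or 0.0
            col = states[nd.taxon.label] - 1 if nd.is_leaf() else amap[nd]
            like *= P(t)[row, col]
            if like == 0.0:
                break
        total += like
    return np.log(total) if total > 0 else -np.inf


def sankoff_parsimony_score(tree, states, n_states: int) -> int:
    """Minimum state changes by Sankoff dynamic programming, unit costs."""
    INF = 10**9
    cost = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            c = np.full(n_states, INF)
            c[states[nd.taxon.label] - 1] = 0
        else:
            c = np.zeros(n_states)
            for ch in nd.child_nodes():
                child = cost[ch]
                # min over child state t of (child cost + 1{s != t})
                c = c + np.minimum(child, child.min() + 1)
        cost[nd] = c
    return int(cost[tree.seed_node].min())
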