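"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's pruning/Fitch code paths: they
enumerate internal-node labelings (and missing-tip states) directly, so
agreement with the package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np

from mitoscolia.ancestral import _tree_index, mk_transition_matrix


def _layout(tree):
    ti = _tree_index(tree, require_lengths=False)
    parent = {}
    for i in range(len(ti.nodes)):
        for c in ti.children[i]:
            parent[c] = i
    return ti, parent


def brute_force_likelihood(tree, states, family, rates, prior, alphabet):
    """(total likelihood, {node signature: posterior vector}) by enumeration.

    Sums products of transition probabilities over every assignment of
    states to internal nodes and to missing tips.
    """
    ti, parent = _layout(tree)
    k = len(alphabet)
    internal = [i for i in range(len(ti.nodes)) if not ti.is_leaf[i]]
    leaves = [i for i in range(len(ti.nodes)) if ti.is_leaf[i]]
    tip_choices = []
    for i in leaves:
        s = states.get(ti.labels[i])
        tip_choices.append(list(range(k)) if s in (None, "?") else [alphabet.index(s)])

    Pcache = {i: mk_transition_matrix(family, rates, ti.blen[i], k)
              for i in range(len(ti.nodes)) if i != ti.root}

    total = 0.0
    post = {i: np.zeros(k) for i in internal}
    for lab in itertools.product(range(k), repeat=len(internal)):
        assign = dict(zip(internal, lab))
        subtotal = 0.0
        for combo in itertools.product(*tip_choices):
            full = dict(assign)
            full.update(dict(zip(leaves, combo)))
            p = prior[full[ti.root]]
            for i in range(len(ti.nodes)):
                if i == ti.root:
                    continue
                p *= Pcache[i][full[parent[i]], full[i]]
            subtotal += p
        total += subtotal
        for i in internal:
            post[i][assign[i]] += subtotal
    marginals = {ti.signatures[i]: post[i] / total for i in internal}
    return total, marginals


def exhaustive_parsimony_minimum(tree, states, alphabet):
    """Minimal change count over all internal labelings (missing tips free)."""
    ti, parent = _layout(tree)
    k = len(alphabet)
    internal = [i for i in range(len(ti.nodes)) if not ti.is_leaf[i]]
    leaves = [i for i in range(len(ti.nodes)) if ti.is_leaf[i]]
    tip_choices = []
    for i in leaves:
        s = states.get(ti.labels[i])
        tip_choices.append(list(range(k)) if s in (None, "?") else [alphabet.index(s)])
    best = None
    for lab in itertools.product(range(k), repeat=len(internal)):
        assign = dict(zip(internal, lab))
        for combo in itertools.product(*tip_choices):
            full = dict(assign)
            full.update(dict(zip(leaves, combo)))
            changes = sum(full[parent[i]] != full[i]
                          for i in range(len(ti.nodes)) if i != ti.root)
            if best is None or changes < best:
                best = changes
    return best


def adjacency_breakpoints(a, b):
    """Circular signed breakpoint count by direct adjacency enumeration."""
    def adj(order):
        elems = order.elements
        n = len(elems)
        s = set()
        for i in range(n):
            x, y = elems[i], elems[(i + 1) % n]
            s.add(((x.key, x.sign), (y.key, y.sign)))
            s.add(((y.key, -y.sign), (x.key, -x.sign)))
        return s
    count = 0
    n = len(a.elements)
    bset = adj(b)
    for i in range(n):
        x, y = a.elements[i], a.elements[(i + 1) % n]
        if ((x.key, x.sign), (y.key, y.sign)) not in bset:
            count += 1
    return count
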