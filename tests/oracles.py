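"""Independent brute-force oracles used to check the fast implementations.

Everything here is written as plainly as possible (explicit Python loops,
no shared code with the package internals) so that agreement between an
oracle and the vectorized implementation is meaningful evidence.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-12


def rank_percentiles_naive(column) -> list[float]:
    """Sort-then-assign rank percentiles with explicit tie averaging."""
    values = list(column)
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return [100.0 * (r - 1.0) / (n - 1.0) for r in ranks]


def gini_impurity(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    p = sum(labels) / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def best_split_bruteforce(X, y, gene_names, min_leaf):
    """Exhaustive search over every (gene, midpoint) split.

    Iterates genes in lexicographic ID order and thresholds ascending,
    keeping the first strict minimum of weighted child Gini — the same
    tie-break the induction documents.  Returns (gene, threshold, weighted
    gini) or None.
    """
    n = len(y)
    best = None
    for j in sorted(range(len(gene_names)), key=lambda j: gene_names[j]):
        distinct = sorted(set(X[i][j] for i in range(n)))
        for a, b in zip(distinct, distinct[1:]):
            thr = (a + b) / 2.0
            high = [i for i in range(n) if X[i][j] >= thr]
            low = [i for i in range(n) if X[i][j] < thr]
            if len(high) < min_leaf or len(low) < min_leaf:
                continue
            w = (
                len(low) * gini_impurity([y[i] for i in low])
                + len(high) * gini_impurity([y[i] for i in high])
            ) / n
            if best is None or w < best[2] - TOL:
                best = (gene_names[j], thr, w)
    return best


def grow_tree_bruteforce(X, y, gene_names, min_samples_split, min_leaf, max_depth,
                         complexity_threshold, n_total=None, root_gini=None, depth=0):
    """Reference CART grower: nested dicts, same stopping rules."""
    n = len(y)
    if n_total is None:
        n_total = n
        root_gini = gini_impurity(y)
    prob = sum(y) / n
    node_gini = gini_impurity(y)
    leaf = {"leaf": True, "probability": prob, "n": n}
    if node_gini == 0.0 or n < min_samples_split or depth >= max_depth:
        return leaf
    found = best_split_bruteforce(X, y, gene_names, min_leaf)
    if found is None:
        return leaf
    gene, thr, w = found
    improvement = (n / n_total) * (node_gini - w)
    if root_gini > 0 and improvement < complexity_threshold * root_gini:
        return leaf
    j = gene_names.index(gene)
    hi = [i for i in range(n) if X[i][j] >= thr]
    lo = [i for i in range(n) if X[i][j] < thr]
    args = (gene_names, min_samples_split, min_leaf, max_depth,
            complexity_threshold, n_total, root_gini, depth + 1)
    return {
        "leaf": False,
        "gene": gene,
        "threshold": thr,
        "probability": prob,
        "n": n,
        "low": grow_tree_bruteforce([X[i] for i in lo], [y[i] for i in lo], *args),
        "high": grow_tree_bruteforce([X[i] for i in hi], [y[i] for i in hi], *args),
    }


def same_tree(node, ref) -> bool:
    """Compare a package DecisionTree node against an oracle dict tree."""
    from hyporank.cart import Leaf, Split

    if ref["leaf"]:
        return isinstance(node, Leaf) and abs(node.probability - ref["probability"]) < 1e-9
    return (
        isinstance(node, Split)
        and node.gene == ref["gene"]
        and abs(node.threshold - ref["threshold"]) < 1e-9
        and same_tree(node.low, ref["low"])
        and same_tree(node.high, ref["high"])
    )


def auc_pair_counting(y_true, scores) -> float:
    """Mann-Whitney AUC: concordant pairs count 1, tied scores count 1/2."""
    pos = [s for s, t in zip(scores, y_true) if t]
    neg = [s for s, t in zip(scores, y_true) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
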