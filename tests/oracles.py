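"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: distances are computed
by enumerating root-to-tip edge paths, maximum-likelihood fits by exhaustive
grid search of the binomial log-likelihood, and ECDF statistics by direct
supremum over observed values.
"""

import itertools

import numpy as np


def pathsum_distances(ptree):
    """Patristic distances by explicit edge-path enumeration.

    For each tip, collect the edges on its path to the root; the distance
    between two tips is the summed length of the symmetric difference of
    their edge sets.
    """
    paths = {}
    for leaf in ptree.tree.leaf_node_iter():
        edges = {}
        node = leaf
        while node.parent_node is not None:
            edges[id(node)] = node.edge.length
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    labels = list(paths)
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = paths[labels[i]], paths[labels[j]]
        shared = pa.keys() & pb.keys()
        d = sum(v for k, v in pa.items() if k not in shared)
        d += sum(v for k, v in pb.items() if k not in shared)
        out[i, j] = out[j, i] = d
    return labels, out


def mrca_depths(ptree):
    """Depth (distance from root, stem included) of the MRCA of every tip pair.

    The MRCA depth is the summed length of the edges shared by the two
    root-to-tip paths.
    """
    stem = ptree.tree.seed_node.edge.length or 0.0
    paths = {}
    for leaf in ptree.tree.leaf_node_iter():
        edges = {}
        node = leaf
        while node.parent_node is not None:
            edges[id(node)] = node.edge.length
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    labels = list(paths)
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = paths[labels[i]], paths[labels[j]]
        depth = stem + sum(pa[k] for k in pa.keys() & pb.keys())
        out[i, j] = out[j, i] = depth
    return labels, out


def binom_loglik(y, X, beta):
    eta = X @ np.asarray(beta, dtype=float)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def grid_max_loglik(y, X, center, half_width=0.5, n_points=41):
    """Max binomial log-likelihood over an axis-aligned grid around center."""
    axes = [
        np.linspace(c - half_width, c + half_width, n_points) for c in center
    ]
    best = -np.inf
    for beta in itertools.product(*axes):
        best = max(best, binom_loglik(y, X, beta))
    return best


def ks_statistic(a, b):
    """Brute-force two-sample KS statistic: sup |ECDF_a - ECDF_b|."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    best = 0.0
    for v in np.concatenate([a, b]):
        fa = np.mean(a <= v)
        fb = np.mean(b <= v)
        best = max(best, abs(fa - fb))
    return best
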