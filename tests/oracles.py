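"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: likelihoods are
computed by exhaustive enumeration over internal-node states rather
than pruning, alignments by a plain Needleman-Wunsch identity count,
and Dollo origins by enumeration over origin assignments.
"""

from __future__ import annotations

import itertools

import numpy as np

from ortholoss.codons import N_STATES


def enumeration_loglike(tree_spec, states, pi, P_of_branch):
    """Log-likelihood by summing over all internal-node state assignments.

    tree_spec: dict with 'root', 'children' (node -> list of nodes),
    'leaf_row' (node -> alignment row or None).  ``P_of_branch`` maps a
    child node to its transition matrix.  ``states`` is
    (n_rows, n_sites) with -1 for fully ambiguous.
    """
    children = tree_spec["children"]
    leaf_row = tree_spec["leaf_row"]
    root = tree_spec["root"]
    internal = [n for n in children if children[n]]
    n_int = len(internal)
    axis_of = {n: i for i, n in enumerate(internal)}
    n_sites = states.shape[1]

    def axis_index(node):
        shape = [1] * n_int
        shape[axis_of[node]] = N_STATES
        return np.arange(N_STATES).reshape(shape)

    total = 0.0
    for s in range(n_sites):
        grid = np.ones((1,) * n_int, dtype=float)
        # root prior
        grid = grid * pi[axis_index(root)]
        for parent in internal:
            for child in children[parent]:
                P = P_of_branch[child]
                if child in axis_of:  # internal child
                    grid = grid * P[axis_index(parent), axis_index(child)]
                else:  # leaf
                    x = states[leaf_row[child], s]
                    if x < 0:
                        continue  # sum_j P[s_par, j] = 1
                    grid = grid * P[:, x][axis_index(parent)]
        total += np.log(grid.sum())
    return float(total)


def nw_identity(a: str, b: str, match=1, mismatch=-1, gap=-1):
    """Plain quadratic Needleman-Wunsch; returns (identity_frac, score)."""
    n, m = len(a), len(b)
    S = np.zeros((n + 1, m + 1))
    S[:, 0] = np.arange(n + 1) * gap
    S[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i, j] = max(
                S[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch),
                S[i - 1, j] + gap,
                S[i, j - 1] + gap,
            )
    # traceback for identity
    i, j, same, cols = n, m, 0, 0
    while i > 0 and j > 0:
        diag = S[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if S[i, j] == diag:
            cols += 1
            same += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif S[i, j] == S[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return same / cols if cols else 0.0, S[n, m]


def dollo_min_events(tree, lesions):
    """Minimum event count over all Dollo-consistent origin assignments.

    ``tree`` is a dendropy tree; ``lesions`` a list of dicts with
    'carriers' and 'unknowns' (sets of leaf labels).  For each lesion,
    valid origin sets are minimal collections of branches (clades) such
    that every carrier is below exactly one origin and no known
    non-carrier is below any origin.  Event count for a combination is
    the number of distinct most-basal lesion-bearing branches over
    eroded leaves (any carrier of any lesion).  Returns the minimum.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    clades = []
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        clades.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))

    def valid_origin_sets(carriers, unknowns):
        known_nc = leaves - carriers - unknowns
        admissible = [c for c in clades if not (c & known_nc) and (c & carriers)]
        best_sets, best_k = [], None
        for k in range(1, len(carriers) + 1):
            for combo in itertools.combinations(admissible, k):
                covered = set()
                ok = True
                for c in combo:
                    got = c & carriers
                    if got & covered:
                        ok = False
                        break
                    covered |= got
                if ok and covered == carriers:
                    best_sets.append(combo)
            if best_sets:
                best_k = k
                break
        return best_sets

    eroded = set()
    for les in lesions:
        eroded |= les["carriers"]
    per_lesion_options = [valid_origin_sets(les["carriers"], les["unknowns"]) for les in lesions]
    if any(not opts for opts in per_lesion_options):
        return None
    best = None
    for combo in itertools.product(*per_lesion_options):
        origin_clades = set()
        for origins in combo:
            origin_clades.update(origins)
        assignment = set()
        for leaf in eroded:
            on_path = [c for c in origin_clades if leaf in c]
            if not on_path:
                continue
            assignment.add(max(on_path, key=len))
        count = len(assignment)
        if best is None or count < best:
            best = count
    return best
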