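"""Independent oracles used by the tests.

These deliberately use different algorithms from the package: a dense
run-length dynamic program instead of seeded diagonal search for inverted
repeats, and a closed-form transition-matrix tree walk instead of simulation
for SNP-column probabilities.
"""

from __future__ import annotations

import dendropy
import numpy as np

from plastcomp.model import revcomp


def brute_force_longest_ir(seq: str, min_len: int, circular: bool = False):
    """All-pairs longest reverse-complement match via a dense DP table.

    Returns (length, set of arm pairs) where each arm pair is a sorted tuple
    of (start mod n, length); empty set if nothing >= min_len.  O(n^2) — toy
    sequences only.
    """
    n = len(seq)
    s = seq + seq if circular else seq
    rc = revcomp(s)
    m = len(s)
    a = np.frombuffer(s.encode(), dtype="S1")
    b = np.frombuffer(rc.encode(), dtype="S1")
    match = a[:, None] == b[None, :]
    run = np.zeros((m + 1, m + 1), dtype=np.int32)
    for i in range(1, m + 1):
        run[i, 1:] = (run[i - 1, :-1] + 1) * match[i - 1, :]
    best_len = 0
    best_pairs: set[tuple] = set()
    ii, pp = np.nonzero(run >= max(min_len, 1))
    for i, p in zip(ii, pp):
        L = min(int(run[i, p]), n)
        a0 = i - L  # arm 1 start in s
        j0 = m - p  # arm 2 start in s
        arm1, arm2 = (a0 % n, L), (j0 % n, L)
        rel = (arm2[0] - arm1[0]) % n
        if rel < L or rel + L > n:
            continue  # overlapping arcs / self-match
        key = tuple(sorted((arm1, arm2)))
        if L > best_len:
            best_len, best_pairs = L, {key}
        elif L == best_len:
            best_pairs.add(key)
    # keep only pairs achieving the maximum that are not extendable subruns
    return best_len, best_pairs


def polymorphic_column_probability(
    newick: str, mult: float, pi=(0.315, 0.185, 0.185, 0.315)
) -> float:
    """P(a column is polymorphic) under the per-branch mutate-once model.

    Per branch of length t a site changes with probability t*mult, the new
    base uniform among the other three.  Computed exactly by propagating
    4x4 matrices M[x, y] = P(all leaves below have base y | node state x)
    from the leaves to the root.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    eye = np.eye(4)

    def matrices(node) -> np.ndarray:
        if node.is_leaf():
            return eye
        out = np.ones((4, 4))
        for child in node.child_nodes():
            p = (child.edge.length or 0.0) * mult
            T = (1.0 - p) * eye + (p / 3.0) * (1.0 - eye)
            out *= T @ matrices(child)
        return out

    mono = float(np.asarray(pi) @ matrices(tree.seed_node).sum(axis=1))
    return 1.0 - mono
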