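"""Independent brute-force oracles used by the test suite.

These are written against the *rules*, not against the package code paths
they check: the evidence oracle re-states the two reliability criteria
directly, and the best-subset LAD oracle enumerates supports exhaustively,
solving each with a variable-split LP formulation (β = β⁺ − β⁻) that differs
from the package's envelope formulation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog

FLAG_NAMES = [
    "metacore_direct_activation",
    "metacore_direct_inhibition",
    "metacore_indirect_activation",
    "metacore_indirect_inhibition",
    "chea",
    "encode",
]


def oracle_edge_strength(flags: dict, tba_z) -> float:
    """Brute-force restatement of the reliability + counting rules."""
    direct = flags.get("metacore_direct_activation") or flags.get(
        "metacore_direct_inhibition"
    )
    indirect = flags.get("metacore_indirect_activation") or flags.get(
        "metacore_indirect_inhibition"
    )
    tba_hit = tba_z is not None and tba_z >= 1
    reliable = bool(direct) or (
        int(bool(indirect)) + int(bool(flags.get("chea")))
        + int(bool(flags.get("encode"))) + int(tba_hit)
        >= 2
    )
    if not reliable:
        return 0.0
    counted = [
        "chea",
        "metacore_direct_activation",
        "metacore_direct_inhibition",
        "metacore_indirect_activation",
        "metacore_indirect_inhibition",
    ]
    es = float(sum(bool(flags.get(f)) for f in counted))
    if tba_hit:
        es += tba_z
    return es


def lad_objective_fixed_support(A: np.ndarray, y: np.ndarray, support) -> float:
    """LAD objective for a fixed support via a split-variable LP.

    Variables: β0⁺, β0⁻, βs⁺, βs⁻ (s in support), e_j.  Constraints
    e_j ≥ ±(y_j − Xβ) expressed as two inequality blocks.
    """
    l = len(y)
    Xs = np.column_stack([np.ones(l)] + [A[s] for s in support])
    p = Xs.shape[1]
    # variables: bplus(p), bminus(p), e(l)
    c = np.concatenate([np.zeros(2 * p), np.ones(l)])
    A_ub = np.block(
        [
            [Xs, -Xs, -np.eye(l)],
            [-Xs, Xs, -np.eye(l)],
        ]
    )
    b_ub = np.concatenate([y, -y])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(0, None)] * (2 * p + l),
        method="highs",
    )
    assert res.status == 0, res.message
    return float(res.fun)


def best_subset_lad_objective(A: np.ndarray, y: np.ndarray, k: int) -> float:
    """Exhaustive enumeration over all supports of size k (a support of size
    k dominates all of its subsets for LAD, so exactly-k suffices)."""
    T = A.shape[0]
    best = np.inf
    for support in combinations(range(T), k):
        best = min(best, lad_objective_fixed_support(A, y, support))
    return best
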