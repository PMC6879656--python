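"""Independent brute-force oracles used to cross-check the package.

Deliberately naive: dict-based counting, pure-Python loops, no shared code
with the implementation under test.
"""

import math
from collections import Counter


def naive_mi(x, y, base=2.0):
    """Plug-in mutual information by direct summation over the joint table."""
    n = len(x)
    assert n == len(y)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log(pab / ((px[a] / n) * (py[b] / n)), base)
    return total


def naive_mrmr(states_by_gene, y, top_n, criterion="MID", base=2.0):
    """Greedy mRMR re-evaluated from scratch at every step.

    states_by_gene: dict gene_id -> list of discrete states.
    Tie-break: lexicographically earlier gene id wins.
    """
    relevance = {g: naive_mi(s, y, base) for g, s in states_by_gene.items()}
    selected = []
    remaining = sorted(states_by_gene)
    tol = 1e-9  # mathematical ties evaluated in different summation orders
    while len(selected) < top_n:
        best_gene, best_obj = None, None
        for g in remaining:
            if not selected:
                obj = relevance[g]
            else:
                red = sum(
                    naive_mi(states_by_gene[g], states_by_gene[s], base) for s in selected
                ) / len(selected)
                if criterion == "MID":
                    obj = relevance[g] - red
                else:
                    obj = relevance[g] / red if red > 0 else math.inf
            if best_obj is None or obj > best_obj + tol:
                best_gene, best_obj = g, obj
        selected.append(best_gene)
        remaining.remove(best_gene)
    return selected
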