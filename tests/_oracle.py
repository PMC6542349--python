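"""Brute-force reference implementation of the replicate-block detector.

Written independently of the package internals, following the procedure's
prose literally with a different mechanization (Counter bookkeeping, one
value taken at a time in step 4).  Shares the package's two documented
conventions, without which no two implementations could agree:
ties sort by original sample index, and all-zero / constant profiles are
skipped as contrast-free.
"""

from collections import Counter
from fractions import Fraction


def oracle_call(values, labels, cutoff=1.0):
    """Return (target_type, cut1, cut2, score) or None for one gene."""
    s = len(values)
    assert len(labels) == s
    counts = Counter(labels)
    if max(values) <= 0 or len(set(values)) == 1:
        return None
    # step 2: decreasing sort, ties by original index
    order = sorted(range(s), key=lambda i: (-values[i], i))
    # step 3: top block must be one full replicate set, all >= cutoff
    target = labels[order[0]]
    r = counts[target]
    for pos in range(r):
        if labels[order[pos]] != target or values[order[pos]] < cutoff:
            return None
    # step 4: take one value at a time until every type touched is covered
    taken = r + 1
    while True:
        touched = {labels[order[p]] for p in range(r, taken)}
        want = sum(counts[u] for u in touched)
        if taken - r == want or taken == s:
            break
        taken += 1
    cut2 = taken
    # step 5: ratio of block means (exact rational arithmetic)
    top = Fraction(sum(Fraction(values[order[p]]) for p in range(r)), r)
    second = Fraction(
        sum(Fraction(values[order[p]]) for p in range(r, cut2)), cut2 - r
    )
    return target, r, cut2, float(second / top)


def oracle_detect(rows, labels, cutoff=1.0):
    """Gene id -> call tuple (or absent) for a dict of gene -> value list."""
    out = {}
    for gene, values in rows.items():
        call = oracle_call(list(values), list(labels), cutoff)
        if call is not None:
            out[gene] = call
    return out
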