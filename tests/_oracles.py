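"""Independent brute-force oracles used by the tests.

These deliberately re-derive each quantity from first principles
(exhaustive enumeration, the textbook correlation formula, direct
counting) without touching the implementation paths they check.
"""

from itertools import combinations, product

import math


def pearson_brute(x, y, min_overlap):
    """Textbook Pearson r over pairwise-complete observations, or None."""
    pairs = [(a, b) for a, b in zip(x, y) if a == a and b == b]  # drop NaN
    n = len(pairs)
    if n < min_overlap or n < 2:
        return None
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    if sxx == 0 or syy == 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def triangles_brute(net, anchors):
    """All (node triple, edge-combination) motifs containing >=1 anchor."""
    ids = net.gene_ids()
    anchors = set(anchors)
    out = set()
    for tri in combinations(ids, 3):
        if not anchors & set(tri):
            continue
        pairs = [(tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])]
        per_pair = [net.edges_between(a, b) for a, b in pairs]
        if any(not es for es in per_pair):
            continue
        for combo in product(*per_pair):
            out.add((tri, tuple((e.pair, e.data_type) for e in combo)))
    return out


def expand_events_brute(events, fam):
    """Gene-pair -> contributing events, by direct Cartesian expansion."""
    merged = {}
    for ev in events:
        for ga in fam.members(ev.subject):
            for gb in fam.members(ev.object):
                if ga == gb:
                    continue
                merged.setdefault(tuple(sorted((ga, gb))), []).append(ev)
    return merged
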