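"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately work per base on explicit position sets, never through the
interval-based implementation they check.
"""

from itertools import combinations


def exon_bases(ivs):
    return {x for s, e in ivs for x in range(s, e)}


def bases_to_intervals(base_set):
    """Maximal intervals covering a set of integer positions."""
    if not base_set:
        return []
    xs = sorted(base_set)
    out, start, prev = [], xs[0], xs[0]
    for x in xs[1:]:
        if x != prev + 1:
            out.append((start, prev + 1))
            start = x
        prev = x
    out.append((start, prev + 1))
    return out


def brute_force_events(a_exons, b_exons, strand):
    """Per-base event classification of a transcript pair.

    Returns a list of (positional_class, divergent-interval tuple) entries:
    divergent bases genomically left of the first shared base form one event,
    right of the last shared base another, and runs of divergent bases
    between the anchors - split only where a shared exonic base intervenes -
    one event each. Positional classes are mapped to transcript orientation
    via the strand.
    """
    A, B = exon_bases(a_exons), exon_bases(b_exons)
    shared, div = A & B, A ^ B
    if not div:
        return []
    if not shared:
        return [("contained", tuple(bases_to_intervals(div)))]
    first, last = min(shared), max(shared)
    upstream_g = [x for x in div if x < first]
    downstream_g = [x for x in div if x > last]
    runs, cur = [], []
    for x in range(first, last + 1):
        if x in div:
            cur.append(x)
        elif x in shared and cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    left_cls = "upstream" if strand == "+" else "downstream"
    right_cls = "downstream" if strand == "+" else "upstream"
    out = []
    if upstream_g:
        out.append((left_cls, tuple(bases_to_intervals(upstream_g))))
    for run in runs:
        out.append(("contained", tuple(bases_to_intervals(run))))
    if downstream_g:
        out.append((right_cls, tuple(bases_to_intervals(downstream_g))))
    return out


def all_exon_chains(n_points, max_exons=4):
    """Every exon chain with <= max_exons exons on a grid of n_points bounds."""
    out = []
    for k in range(1, max_exons + 1):
        for combo in combinations(range(n_points), 2 * k):
            out.append(tuple((combo[2 * i], combo[2 * i + 1]) for i in range(k)))
    return out


def bh_stepup_bruteforce(pvals):
    """Literal Benjamini-Hochberg step-up definition, O(n^2)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def fisher_twosided_enumeration(table):
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def hypergeom_tail_enumeration(k, K, n, N):
    """P(X >= k) for hypergeometric(N, K, n) by summation."""
    from math import comb

    hi = min(K, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, hi + 1)) / comb(N, n)
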