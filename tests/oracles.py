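"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive (enumeration, per-base scans,
closed forms applied by hand) and shares no code with the package.
"""

import math


def binom_upper_tail(m, n, p):
    """Sum the binomial pmf for k = m..n directly."""
    return sum(
        math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(m, n + 1)
    )


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums P(k) over all tables with the observed margins whose
    probability does not exceed the observed table's (with a small
    relative tolerance, the usual convention).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))
    return min(total, 1.0)


def interval_overlaps(dmr_intervals, promoter_intervals):
    """Per-base membership scan: which (dmr, promoter) index pairs overlap.

    Intervals are (chrom, start, end), half-open.
    """
    pairs = set()
    for i, (dc, ds, de) in enumerate(dmr_intervals):
        bases = {(dc, x) for x in range(ds, de)}
        for j, (pc, ps, pe) in enumerate(promoter_intervals):
            if any((pc, x) in bases for x in range(ps, pe)):
                pairs.add((i, j))
    return pairs


def naive_site_count(utr, site):
    """Count occurrences of site in utr by checking every offset."""
    return sum(
        1 for i in range(len(utr) - len(site) + 1) if utr[i:i + len(site)] == site
    )


def revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def bh_stepup(pvals):
    """Hand implementation of the BH step-up adjusted p-values."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q


def welch_t_p(x, y):
    """Closed-form Welch t-test (two-sided) on two sequences."""
    from scipy.stats import t as tdist  # distribution function only

    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df, 2 * tdist.sf(abs(t), df)


def pearson_r(x, y):
    """Closed-form Pearson correlation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
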