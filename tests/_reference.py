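"""Naive, loop-based reference implementations used as independent oracles.

Everything here is written per-site / per-pair in plain Python, independent
of the vectorised package code paths, so agreement is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def ref_allele_counts(dosage_rows):
    """(n, a) for a list of per-sample dosages at one site."""
    n = 0
    a = 0
    for d in dosage_rows:
        if d != MISSING:
            n += 2
            a += d
    return n, a


def ref_hudson_site(n1, a1, n2, a2):
    """Per-site Hudson numerator and denominator (None when <2 alleles)."""
    if n1 < 2 or n2 < 2:
        return None
    p1 = a1 / n1
    p2 = a2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def ref_fst_window(counts1, counts2, start, end):
    """Ratio-of-averages Hudson FST over sites [start, end)."""
    num = den = 0.0
    for i in range(start, end):
        nd = ref_hudson_site(counts1[0][i], counts1[1][i], counts2[0][i], counts2[1][i])
        if nd is not None:
            num += nd[0]
            den += nd[1]
    return num / den if den != 0 else float("nan")


def ref_pbs_window(cf, c1, c2, start, end, eps=1e-6):
    def t(f):
        return -math.log(1.0 - min(f, 1.0 - eps))

    f1 = ref_fst_window(cf, c1, start, end)
    f2 = ref_fst_window(cf, c2, start, end)
    f12 = ref_fst_window(c1, c2, start, end)
    if any(math.isnan(f) for f in (f1, f2, f12)):
        return float("nan")
    return (t(f1) + t(f2) - t(f12)) / 2.0


def ref_het_window(dosage, start, end):
    """Observed heterozygosity: het calls / called calls over the window."""
    het = called = 0
    for i in range(dosage.shape[0]):
        for j in range(start, end):
            d = dosage[i, j]
            if d != MISSING:
                called += 1
                if d == 1:
                    het += 1
    return het / called if called else float("nan")


def ref_pi(dosage):
    """pixy-style pi by brute force over all allele pairs at every site."""
    diffs = comps = 0
    for j in range(dosage.shape[1]):
        alleles = []
        for i in range(dosage.shape[0]):
            d = dosage[i, j]
            if d == MISSING:
                continue
            alleles += [1] * int(d) + [0] * (2 - int(d))
        for x, y in itertools.combinations(alleles, 2):
            comps += 1
            if x != y:
                diffs += 1
    return diffs / comps if comps else float("nan")


def ref_cmh(tables):
    """Direct, scalar evaluation of the CMH 1-df statistic."""
    num = 0.0
    den = 0.0
    any_ok = False
    for t in tables:
        a, b = t[0]
        c, d = t[1]
        n1, n2 = a + b, c + d
        m1, m2 = a + c, b + d
        tt = n1 + n2
        if tt <= 1 or 0 in (n1, n2, m1, m2):
            continue
        any_ok = True
        num += a - n1 * m1 / tt
        den += n1 * n2 * m1 * m2 / (tt**2 * (tt - 1))
    if not any_ok or den == 0:
        return float("nan")
    return num**2 / den


def ref_fisher_two_sided(table):
    """Two-sided Fisher p by exhaustive enumeration of the hypergeometric
    support, with exact rational arithmetic."""
    from fractions import Fraction

    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


def ref_mwu_exact(values_a, values_b):
    """Exact two-sided Mann-Whitney p by enumerating every allocation of the
    pooled values into groups of the observed sizes (midranks for ties)."""
    from scipy.stats import rankdata

    pooled = list(values_a) + list(values_b)
    n_a = len(values_a)
    ranks = rankdata(pooled)
    mu = n_a * len(values_b) / 2.0

    def u_of(idx):
        return sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2.0

    u_obs = u_of(range(n_a))
    obs_dev = abs(u_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(combo) - mu) >= obs_dev - 1e-9:
            hits += 1
    return u_obs, hits / total
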