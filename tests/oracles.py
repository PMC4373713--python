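"""Independent reference implementations used to validate the package.

Everything here is deliberately written as plain-Python, loop-based,
step-by-step evaluation (or literal enumeration), sharing no code with
the vectorized/pandas implementations under test.
"""

from __future__ import annotations

import itertools
import math
from statistics import median


def fst_oracle(p, n):
    """Weir-Cockerham theta evaluated term by term on (p_hat_i, n_i alleles)."""
    s = len(p)
    n_tot = sum(n)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / n_tot
    msp = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / (s - 1)
    msg = sum(ni * pi * (1 - pi) for ni, pi in zip(n, p)) / sum(ni - 1 for ni in n)
    n_c = (n_tot - sum(ni**2 for ni in n) / n_tot) / (s - 1)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return math.nan
    return (msp - msg) / denom


def chisq_oracle(table):
    """Hand-summed Pearson X^2 with row/column-margin expecteds.

    ``table`` is a list of rows; zero-sum columns are skipped (they
    contribute nothing and carry no degrees of freedom).
    """
    rows = len(table)
    cols = len(table[0])
    row_tot = [sum(table[i]) for i in range(rows)]
    col_tot = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    grand = sum(row_tot)
    x2 = 0.0
    ncols = 0
    for j in range(cols):
        if col_tot[j] == 0:
            continue
        ncols += 1
        for i in range(rows):
            e = row_tot[i] * col_tot[j] / grand
            x2 += (table[i][j] - e) ** 2 / e
    df = (rows - 1) * (ncols - 1)
    return x2, df


def anova_oracle(groups):
    """Textbook one-way ANOVA sums of squares on lists of observations."""
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_tot
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    msb = ssb / (k - 1)
    msw = ssw / (n_tot - k)
    return msb / msw if msw > 0 else math.inf, ssb, ssw


def dosages(genotype_counts):
    """Explicit dosage list for genotype counts (n_AA, n_Aa, n_aa)."""
    n_hom, n_het, n_alt = genotype_counts
    return [2] * n_hom + [1] * n_het + [0] * n_alt


def nscm_oracle(panel_counts, n_ind):
    """Step-by-step SS_d for a panel given per-SNP genotype counts.

    ``panel_counts``: list (over SNPs) of lists (over populations) of
    genotype-count triples; ``n_ind``: per-population individual counts.
    """
    s = len(n_ind)
    n_tot = sum(n_ind)
    m = [math.sqrt(1 / ni + 1 / n_tot) for ni in n_ind]
    per_snp = []
    for snp in panel_counts:
        values = [[x / 2 for x in dosages(gc)] for gc in snp]  # frequency scale
        a_ik = [sum(v) / len(v) for v in values]
        a_k = sum(sum(v) for v in values) / n_tot
        pooled = sum(sum((x - ai) ** 2 for x in v) for v, ai in zip(values, a_ik))
        s_k = math.sqrt(pooled / (n_tot - s))
        per_snp.append((a_ik, a_k, s_k))
    s0 = median(sk for _, _, sk in per_snp)
    out = []
    for a_ik, a_k, s_k in per_snp:
        d = [(ai - a_k) / (mi * (s0 + s_k)) if (s0 + s_k) > 0 else (0.0 if ai == a_k else math.inf)
             for ai, mi in zip(a_ik, m)]
        out.append(sum(x**2 for x in d))
    return out, s0


def hypergeom_tail_enumeration(k, N, K, n):
    """P(X >= k) by literal enumeration of all C(N, n) draws (N small)."""
    population = [1] * K + [0] * (N - K)
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


def bh_oracle(p_values):
    """Classic step-up: q_(i) = min_{j >= i} m p_(j) / j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q[i] = running
    return q


def bh_rejections(p_values, alpha):
    """Step-up rejection set: largest r with p_(r) <= r alpha / m."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    r = 0
    for rank, i in enumerate(order, start=1):
        if p_values[i] <= rank * alpha / m:
            r = rank
    return {order[i] for i in range(r)}
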