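"""Vectorized kernels for the simulation benchmark.

These evaluate the four PD measures on whole batches of simulated SNPs at
once, working directly on genotype-count arrays of shape ``(B, s, 3)``
(batch, population, genotype class in ``(AA, Aa, aa)`` order).  All dosage
sums are exact functions of the counts, so the batch results agree with
the scalar implementations in :mod:`popdiff.pd_measures` to floating-point
round-off; the test suite asserts that equivalence.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "draw_counts_batch",
    "fst_theta_batch",
    "chisq_p_batch",
    "anova_p_batch",
    "nscm_ssd_batch",
]


def draw_counts_batch(
    rng: np.random.Generator, n_ind: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Multinomial HWE genotype counts for a batch of SNPs.

    ``p`` has shape ``(B, s)``; ``n_ind`` shape ``(s,)`` in individuals.
    Returns counts of shape ``(B, s, 3)``.
    """
    probs = np.stack([p**2, 2 * p * (1 - p), (1 - p) ** 2], axis=-1)
    # guard accumulated round-off; multinomial requires probabilities summing to <= 1
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=-1, keepdims=True)
    return rng.multinomial(np.broadcast_to(n_ind, p.shape), probs)


def _phat(counts: np.ndarray, n_ind: np.ndarray) -> np.ndarray:
    return (2 * counts[..., 0] + counts[..., 1]) / (2 * n_ind)


def fst_theta_batch(counts: np.ndarray, n_ind: np.ndarray) -> np.ndarray:
    """Weir-Cockerham theta per batch element (allele units internally)."""
    n_ind = np.asarray(n_ind, dtype=float)
    s = counts.shape[1]
    na = 2 * n_ind
    n_tot = na.sum()
    p = _phat(counts, n_ind)
    p_bar = (na * p).sum(axis=-1) / n_tot
    msp = (na * (p - p_bar[:, None]) ** 2).sum(axis=-1) / (s - 1)
    msg = (na * p * (1 - p)).sum(axis=-1) / (na - 1).sum()
    n_c = (n_tot - (na**2).sum() / n_tot) / (s - 1)
    denom = msp + (n_c - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, (msp - msg) / np.where(denom != 0, denom, 1.0), np.nan)


def chisq_p_batch(
    counts: np.ndarray, n_ind: np.ndarray, table: str = "allele"
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson homogeneity chi-square (statistic, p) per batch element."""
    n_ind = np.asarray(n_ind, dtype=float)
    if table == "allele":
        a = 2 * counts[..., 0] + counts[..., 1]
        tot = np.broadcast_to(2 * n_ind, a.shape)
        obs = np.stack([a, tot - a], axis=-1)  # (B, s, 2)
    elif table == "genotype":
        obs = np.asarray(counts, dtype=float)
    else:
        raise ValueError(f"unknown table kind {table!r}")
    col = obs.sum(axis=1)  # (B, c)
    row = obs.sum(axis=2)  # (B, s)
    grand = col.sum(axis=1)  # (B,)
    expected = row[:, :, None] * col[:, None, :] / grand[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        cell = np.where(expected > 0, (obs - expected) ** 2 / np.where(expected > 0, expected, 1.0), 0.0)
    x2 = cell.sum(axis=(1, 2))
    # df = (s - 1) * (nonempty columns - 1), per element
    ncol = (col > 0).sum(axis=1)
    df = (obs.shape[1] - 1) * np.maximum(ncol - 1, 0)
    p = np.where(df > 0, stats.chi2.sf(x2, np.maximum(df, 1)), 1.0)
    x2 = np.where(df > 0, x2, 0.0)
    return x2, p


def anova_p_batch(
    counts: np.ndarray, n_ind: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-way dosage ANOVA (F, p) per batch element."""
    n = np.asarray(n_ind, dtype=float)
    s = counts.shape[1]
    n_tot = n.sum()
    dsum = 2 * counts[..., 0] + counts[..., 1]
    dss = 4 * counts[..., 0] + counts[..., 1]
    gmean = dsum / n
    grand = dsum.sum(axis=-1) / n_tot
    ssb = (n * (gmean - grand[:, None]) ** 2).sum(axis=-1)
    ssw = (dss - n * gmean**2).sum(axis=-1)
    dfb, dfw = s - 1, n_tot - s
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.where(
        ssw > 0,
        stats.f.sf(np.where(ssw > 0, f, 0.0), dfb, dfw),
        np.where(ssb > 0, 0.0, 1.0),
    )
    f = np.where(ssw > 0, f, np.where(ssb > 0, np.inf, np.nan))
    return f, p


def nscm_ssd_batch(
    counts: np.ndarray, n_ind: np.ndarray, m_mode: str = "sqrt"
) -> np.ndarray:
    """SS_d per batch element, the batch itself serving as the SNP panel.

    ``s_0`` is the median pooled SD over the batch, mirroring the
    per-panel convention of :func:`popdiff.pd_measures.nscm_ssd`.
    """
    n = np.asarray(n_ind, dtype=float)
    s = counts.shape[1]
    n_tot = n.sum()
    m = 1.0 / n + 1.0 / n_tot
    if m_mode == "sqrt":
        m = np.sqrt(m)
    elif m_mode != "literal":
        raise ValueError(f"unknown m_mode {m_mode!r}")
    dsum = 2 * counts[..., 0] + counts[..., 1]
    dss = 4 * counts[..., 0] + counts[..., 1]
    a_ik = dsum / (2 * n)
    a_k = dsum.sum(axis=-1) / (2 * n_tot)
    ssw = (dss / 4 - n * a_ik**2).sum(axis=-1)
    sk = np.sqrt(np.maximum(ssw, 0.0) / (n_tot - s))
    s0 = np.median(sk)
    scale = m[None, :] * (s0 + sk)[:, None]
    num = a_ik - a_k[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(scale > 0, num / np.where(scale > 0, scale, 1.0),
                     np.where(num == 0, 0.0, np.inf))
    return (d**2).sum(axis=-1)
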