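"""Gene-set over-representation analysis with swappable backgrounds.

An explicit re-implementation of the DAVID-style workflow: for every term,
count the input genes annotated to it, test over-representation with the
hypergeometric upper tail, report fold enrichment ``(k/n) / (K/N)``, and
correct across terms with the Benjamini-Hochberg step-up.  Terms with
``q <= 0.05`` are flagged significant.  Only genes annotated to at least
one term count toward the input size ``n`` and background size ``N``,
matching the usual over-representation contract.

Backgrounds are explicit arguments, so the same input list can be tested
against the whole annotated genome and against a restricted family such as
the drug-related genes (:func:`compare_backgrounds`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_enrich",
    "bh_adjust",
    "enrich",
    "compare_backgrounds",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

Category = Literal["BP", "MF", "CC", "PATHWAY"]


@dataclass(frozen=True)
class GeneSet:
    """One annotation term and its member genes."""

    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise InvalidInputError(f"term {self.term_id!r} has no genes")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term contingency counts, fold enrichment, and (adjusted) p-value.

    ``k`` of ``n`` annotated input genes fall in the term; ``K`` of ``N``
    annotated background genes do.
    """

    term_id: str
    term_name: str
    category: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    q_value: float | None = None
    significant: bool | None = None


def hypergeom_enrich(
    input_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    *,
    ease: bool = False,
    min_background_count: int = 2,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the input list.

    ``p = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``; with
    ``ease=True`` the tail is evaluated at ``k - 1`` (DAVID's conservative
    EASE variant).  Terms with fewer than ``min_background_count``
    background genes are untestable and dropped (count logged).  Input
    genes outside the background are logged and intersected away.
    """
    input_set = set(input_genes)
    background = set(background_genes)
    if not input_set <= background:
        stray = input_set - background
        logger.warning("%d input genes outside the background; intersecting", len(stray))
        input_set &= background

    annotated = set()
    for gs in gene_sets:
        annotated |= gs.genes
    bg_ann = background & annotated
    in_ann = input_set & annotated
    n, N = len(in_ann), len(bg_ann)
    if N == 0 or n == 0:
        raise InvalidInputError(
            "no annotated genes left in the "
            + ("background" if N == 0 else "input")
            + " after filtering"
        )

    results: list[EnrichmentResult] = []
    dropped = 0
    for gs in gene_sets:
        K = len(gs.genes & bg_ann)
        if K < min_background_count:
            dropped += 1
            continue
        k = len(gs.genes & in_ann)
        fold = (k / n) / (K / N)
        if k == 0:
            p = 1.0
        else:
            tail_at = k - 1 if ease else k
            p = float(stats.hypergeom.sf(tail_at - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=gs.term_id,
                term_name=gs.term_name,
                category=gs.category,
                k=k, n=n, K=K, N=N,
                fold_enrichment=fold,
                p_value=min(p, 1.0),
            )
        )
    if dropped:
        logger.info("dropped %d terms with K < %d in the background", dropped, min_background_count)
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} m p_(j) / j`` over the sorted p-values, capped
    at 1 (delegated to statsmodels' ``fdr_bh``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    input_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    *,
    alpha: float = 0.05,
    per_category: bool = False,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Full over-representation run: hypergeometric p, BH q, significance flag.

    By default BH is applied jointly over all tested terms; with
    ``per_category=True`` the correction is applied within each annotation
    category separately.
    """
    results = hypergeom_enrich(input_genes, background_genes, gene_sets, ease=ease)
    if not results:
        return results
    if per_category:
        out = list(results)
        for cat in {r.category for r in results}:
            idx = [i for i, r in enumerate(results) if r.category == cat]
            q = bh_adjust([results[i].p_value for i in idx])
            for i, qi in zip(idx, q):
                out[i] = replace(results[i], q_value=float(qi), significant=bool(qi <= alpha))
        return out
    q = bh_adjust([r.p_value for r in results])
    return [
        replace(r, q_value=float(qi), significant=bool(qi <= alpha))
        for r, qi in zip(results, q)
    ]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tidy table of enrichment results (one row per term)."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "category": r.category,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def compare_backgrounds(
    input_genes: Iterable[str],
    bg_all: Iterable[str],
    bg_dr: Iterable[str],
    gene_sets: Sequence[GeneSet],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three enrichment runs joined per term.

    Columns carry fold and q for ``input vs bg_all``, ``bg_dr vs bg_all``,
    and ``input vs bg_dr`` — the layout used to ask whether the input is
    enriched beyond what its parent family (e.g. drug-related genes)
    already shows.  Requires ``input <= bg_dr <= bg_all``.
    """
    input_set, dr, full = set(input_genes), set(bg_dr), set(bg_all)
    if not input_set <= dr:
        raise InvalidInputError("input genes must be a subset of the restricted background")
    if not dr <= full:
        raise InvalidInputError("restricted background must be a subset of the full background")

    runs = {
        "input_vs_all": enrich(input_set, full, gene_sets, alpha=alpha),
        "dr_vs_all": enrich(dr, full, gene_sets, alpha=alpha),
        "input_vs_dr": enrich(input_set, dr, gene_sets, alpha=alpha),
    }
    frames = []
    for name, res in runs.items():
        df = results_to_frame(res)[
            ["term_id", "term_name", "category", "fold_enrichment", "q_value"]
        ].rename(columns={"fold_enrichment": f"fold_{name}", "q_value": f"q_{name}"})
        frames.append(df)
    out = frames[0]
    for df in frames[1:]:
        out = out.merge(df, on=["term_id", "term_name", "category"], how="outer")
    return out.sort_values("term_id", ignore_index=True)
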