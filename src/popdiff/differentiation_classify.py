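"""F_st-based classification of SNPs and genes into differentiation groups.

Implements Wright's divergence categories on per-SNP Weir-Cockerham theta
computed from allele-frequency tables: SNPs above 0.25 show very high
divergence (HD), SNPs below 0.05 low divergence (LD).  A gene is HD when
at least one of its mapped SNPs is HD; it is LD only when every mapped SNP
is below the LD bound, so no gene can satisfy both definitions.  SNPs with
theta above 0.5 are individually reportable highlights.  All thresholds
are strict inequalities; NaN theta (monomorphic loci) is excluded
everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .pd_measures import FstComponents, fst_weir_frequencies

__all__ = [
    "FrequencyRecord",
    "SnpGeneMap",
    "GeneGroupAssignment",
    "GroupSummary",
    "fst_from_frequencies",
    "group_snps",
    "group_genes",
    "highlight_snps",
    "summarize_groups",
    "merge_populations",
]

logger = logging.getLogger(__name__)

HD_THRESHOLD = 0.25
LD_THRESHOLD = 0.05
HIGHLIGHT_THRESHOLD = 0.5


@dataclass(frozen=True)
class FrequencyRecord:
    """Observed allele frequency of one SNP in one population."""

    snp_id: str
    population_id: str
    allele_freq: float
    n_alleles: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_freq <= 1.0:
            raise InvalidInputError(
                f"SNP {self.snp_id}/{self.population_id}: allele_freq "
                f"{self.allele_freq} outside [0, 1]"
            )
        if self.n_alleles < 1:
            raise InvalidInputError(
                f"SNP {self.snp_id}/{self.population_id}: n_alleles must be >= 1"
            )
        count = self.allele_freq * self.n_alleles
        # frequencies printed to >= 2 decimals keep freq * n within 5e-3 * n
        # of the true integer allele count
        if abs(count - round(count)) > 5e-3 * self.n_alleles + 1e-9:
            raise InvalidInputError(
                f"SNP {self.snp_id}/{self.population_id}: allele_freq * n_alleles "
                f"= {count:.3f} is not near an integer allele count"
            )


class SnpGeneMap:
    """Mapping from SNP ids to the (nonempty) set of genes they annotate."""

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, frozenset[str]] = {}
        for snp, genes in entries.items():
            gs = frozenset(genes)
            if not gs:
                raise InvalidInputError(f"SNP {snp} maps to an empty gene set")
            self.entries[snp] = gs

    def __contains__(self, snp: str) -> bool:
        return snp in self.entries

    def __getitem__(self, snp: str) -> frozenset[str]:
        return self.entries[snp]

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.entries.values():
            out |= gs
        return frozenset(out)


@dataclass(frozen=True)
class GeneGroupAssignment:
    """Differentiation group of one gene with its supporting evidence."""

    gene_id: str
    group: Literal["HD", "LD", "intermediate"]
    max_fst: float
    n_snps: int
    supporting_snps: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class GroupSummary:
    """Count / mean / median of theta within one SNP group."""

    group: str
    snp_count: int
    mean_fst: float
    median_fst: float


def fst_from_frequencies(
    records: Iterable[FrequencyRecord] | pd.DataFrame,
    min_populations: int = 2,
) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components from an allele-frequency table.

    Accepts an iterable of :class:`FrequencyRecord` or an equivalent
    DataFrame (columns ``snp_id, population, allele_freq, n_alleles``).
    SNPs observed in fewer than ``min_populations`` populations are
    dropped with a logged count.  Returns a DataFrame indexed by
    ``snp_id`` with columns ``theta, msp, msg, n_c, p_bar, n_populations``.
    """
    if isinstance(records, pd.DataFrame):
        df = records.rename(columns={"population": "population_id"})
    else:
        df = pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id,
                    "population_id": r.population_id,
                    "allele_freq": r.allele_freq,
                    "n_alleles": r.n_alleles,
                }
                for r in records
            ]
        )
    if df.empty:
        raise InvalidInputError("empty frequency table")
    if df.duplicated(["snp_id", "population_id"]).any():
        dup = df[df.duplicated(["snp_id", "population_id"])].iloc[0]
        raise InvalidInputError(
            f"duplicate record for SNP {dup['snp_id']} / population {dup['population_id']}"
        )

    rows = []
    dropped = 0
    for snp_id, grp in df.groupby("snp_id", sort=True):
        if len(grp) < min_populations:
            dropped += 1
            continue
        comp = fst_weir_frequencies(
            grp["allele_freq"].to_numpy(), grp["n_alleles"].to_numpy()
        )
        rows.append(
            {
                "snp_id": snp_id,
                "theta": comp.theta_hat,
                "msp": comp.msp,
                "msg": comp.msg,
                "n_c": comp.n_c,
                "p_bar": comp.p_bar,
                "n_populations": len(grp),
            }
        )
    if dropped:
        logger.info("dropped %d SNPs observed in fewer than %d populations", dropped, min_populations)
    if not rows:
        raise InvalidInputError("no SNP had enough populations to score")
    return pd.DataFrame(rows).set_index("snp_id")


def _theta_series(fst_table: pd.DataFrame | pd.Series | Mapping[str, float]) -> pd.Series:
    if isinstance(fst_table, pd.DataFrame):
        return fst_table["theta"]
    if isinstance(fst_table, pd.Series):
        return fst_table
    return pd.Series(dict(fst_table), name="theta")


def group_snps(
    fst_table: pd.DataFrame | pd.Series | Mapping[str, float],
    hd_threshold: float = HD_THRESHOLD,
    ld_threshold: float = LD_THRESHOLD,
) -> tuple[set[str], set[str], set[str]]:
    """Partition scored SNPs into (HD, LD, remainder) by strict thresholds.

    Boundary-equal values fall in the remainder; NaN theta is excluded
    from all three sets.
    """
    if not 0 < ld_threshold < hd_threshold:
        raise InvalidInputError(
            f"thresholds must satisfy 0 < ld ({ld_threshold}) < hd ({hd_threshold})"
        )
    theta = _theta_series(fst_table)
    scored = theta.dropna()
    hd = set(scored.index[scored > hd_threshold])
    ld = set(scored.index[scored < ld_threshold])
    rest = set(scored.index) - hd - ld
    return hd, ld, rest


def group_genes(
    snp_groups: tuple[set[str], set[str], set[str]],
    snp_gene_map: SnpGeneMap,
    fst_table: pd.DataFrame | pd.Series | Mapping[str, float],
    hd_threshold: float = HD_THRESHOLD,
    ld_threshold: float = LD_THRESHOLD,
    ld_rule: Literal["all", "any"] = "all",
) -> list[GeneGroupAssignment]:
    """Assign genes to HD / LD / intermediate from their mapped SNPs' theta.

    HD: at least one mapped SNP with theta above ``hd_threshold``.  LD
    (default rule): every mapped SNP below ``ld_threshold``.  The ``any``
    LD rule instead requires only one SNP below the bound (and none HD),
    probing the looser published phrasing.  Unmapped scored SNPs are
    logged and dropped; NaN theta SNPs do not count as evidence.
    """
    theta = _theta_series(fst_table).dropna()
    unmapped = [s for s in theta.index if s not in snp_gene_map]
    if unmapped:
        logger.info("dropping %d scored SNPs absent from the SNP-gene map", len(unmapped))
    by_gene: dict[str, list[tuple[str, float]]] = {}
    for snp, th in theta.items():
        if snp not in snp_gene_map:
            continue
        for gene in snp_gene_map[snp]:
            by_gene.setdefault(gene, []).append((snp, float(th)))

    out = []
    for gene in sorted(by_gene):
        snps = sorted(by_gene[gene], key=lambda t: (-t[1], t[0]))
        values = np.array([v for _, v in snps])
        max_fst = float(values.max())
        if max_fst > hd_threshold:
            group = "HD"
        elif ld_rule == "all" and bool((values < ld_threshold).all()):
            group = "LD"
        elif ld_rule == "any" and bool((values < ld_threshold).any()):
            group = "LD"
        else:
            group = "intermediate"
        out.append(
            GeneGroupAssignment(
                gene_id=gene,
                group=group,
                max_fst=max_fst,
                n_snps=len(snps),
                supporting_snps=tuple(snps),
            )
        )
    return out


def highlight_snps(
    fst_table: pd.DataFrame | pd.Series | Mapping[str, float],
    threshold: float = HIGHLIGHT_THRESHOLD,
) -> list[tuple[str, float]]:
    """SNPs with theta strictly above ``threshold``, sorted descending.

    Ties break lexicographically by SNP id.
    """
    theta = _theta_series(fst_table).dropna()
    hits = [(str(s), float(v)) for s, v in theta.items() if v > threshold]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def summarize_groups(
    hd: set[str],
    ld: set[str],
    fst_table: pd.DataFrame | pd.Series | Mapping[str, float],
) -> list[GroupSummary]:
    """Count / mean / median theta for the HD group, LD group, and all scored SNPs."""
    theta = _theta_series(fst_table).dropna()
    out = []
    for name, members in (("HD", theta[theta.index.isin(hd)]),
                          ("LD", theta[theta.index.isin(ld)]),
                          ("Total", theta)):
        if len(members) == 0:
            out.append(GroupSummary(name, 0, math.nan, math.nan))
        else:
            out.append(
                GroupSummary(
                    name,
                    int(len(members)),
                    float(members.mean()),
                    float(members.median()),
                )
            )
    return out


def merge_populations(
    records: Sequence[FrequencyRecord],
    merge: Mapping[str, Sequence[str]],
) -> list[FrequencyRecord]:
    """Pool populations before scoring (e.g. CHB + JPT into one East-Asian group).

    The merged frequency is the allele-count-weighted average of the
    member populations; the merged size is the summed allele count.  SNPs
    missing one of a group's members contribute only the members present.
    Populations not named in ``merge`` pass through unchanged.
    """
    member_of = {}
    for new_id, members in merge.items():
        for m in members:
            if m in member_of:
                raise InvalidInputError(f"population {m} appears in two merge groups")
            member_of[m] = new_id

    pooled: dict[tuple[str, str], list[FrequencyRecord]] = {}
    out: list[FrequencyRecord] = []
    for r in records:
        if r.population_id in member_of:
            pooled.setdefault((r.snp_id, member_of[r.population_id]), []).append(r)
        else:
            out.append(r)
    for (snp_id, new_id), rs in pooled.items():
        n = sum(r.n_alleles for r in rs)
        count = sum(r.allele_freq * r.n_alleles for r in rs)
        out.append(
            FrequencyRecord(
                snp_id=snp_id,
                population_id=new_id,
                allele_freq=round(count) / n,
                n_alleles=n,
            )
        )
    return out
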