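"""Per-SNP population-differentiation (PD) statistics.

Four measures of allele-frequency divergence between subpopulations of a
diallelic SNP:

* Weir & Cockerham's moment estimator of Wright's fixation index,
  ``theta_hat = (MSP - MSG) / (MSP + (n_c - 1) MSG)``, computed on allele
  counts (:func:`fst_weir`);
* the Pearson chi-square test of allele-frequency homogeneity across
  populations (:func:`chisq_homogeneity`);
* a one-way fixed-effects ANOVA F-test on per-individual allele dosages
  (:func:`anova_f`);
* the nearest-shrunken-centroid standardized distance, summarized per SNP
  as ``SS_d = sum_i d_ik**2`` (:func:`nscm_ssd`).

Conventions
-----------
A SNP is held as genotype counts ``(n_AA, n_Aa, n_aa)`` per population,
where ``A`` is the counted allele: its sample frequency is
``p_hat = (2 n_AA + n_Aa) / (2 n_individuals)``.  The F_st estimator works
in *allele* units (``n_i`` = 2 x individuals, the ANOVA underlying the
estimator being over allele indicators); the dosage ANOVA and the NSCM
distance work in *individual* units.  ``theta_hat`` is reported raw: it is
legitimately negative near zero differentiation and is NaN for a locus
monomorphic in every population (MSP = MSG = 0 carries no information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "PopulationSample",
    "SnpDataset",
    "FstComponents",
    "AnovaDecomposition",
    "NscmComponents",
    "MeasureResult",
    "allele_frequency",
    "fst_weir",
    "fst_weir_frequencies",
    "chisq_homogeneity",
    "anova_f",
    "nscm_ssd",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PopulationSample:
    """Genotype counts of one population at one SNP.

    ``genotype_counts`` is ``(n_AA, n_Aa, n_aa)``: individuals homozygous
    for the counted allele, heterozygous, and homozygous for the other
    allele.  Counts must be non-negative and sum to ``n_individuals``.
    """

    population_id: str
    n_individuals: int
    genotype_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.genotype_counts) != 3:
            raise InvalidInputError("genotype_counts must be a triple (n_AA, n_Aa, n_aa)")
        if any(c < 0 for c in self.genotype_counts):
            raise InvalidInputError(f"negative genotype count in {self.genotype_counts}")
        if sum(self.genotype_counts) != self.n_individuals:
            raise InvalidInputError(
                f"genotype counts {self.genotype_counts} do not sum to "
                f"n_individuals={self.n_individuals}"
            )

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_individuals

    @property
    def allele_count(self) -> int:
        """Copies of the counted allele in the sample."""
        n_aa_hom, n_het, _ = self.genotype_counts
        return 2 * n_aa_hom + n_het


@dataclass(frozen=True)
class SnpDataset:
    """One SNP observed in ``s`` populations (ordered, unique labels)."""

    snp_id: str
    samples: tuple[PopulationSample, ...]

    def __init__(self, snp_id: str, samples: Sequence[PopulationSample]):
        object.__setattr__(self, "snp_id", snp_id)
        object.__setattr__(self, "samples", tuple(samples))
        ids = [s.population_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise InvalidInputError(f"duplicate population ids in SNP {snp_id}: {ids}")

    @property
    def n_populations(self) -> int:
        return len(self.samples)

    @property
    def n_individuals(self) -> int:
        return sum(s.n_individuals for s in self.samples)


@dataclass(frozen=True)
class FstComponents:
    """Intermediate quantities of the Weir-Cockerham estimator."""

    msp: float
    msg: float
    n_c: float
    p_bar: float
    theta_hat: float


@dataclass(frozen=True)
class AnovaDecomposition:
    """One-way fixed-effects ANOVA of allele dosages."""

    grand_mean: float
    group_effects: tuple[float, ...]
    ms_between: float
    ms_within: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class NscmComponents:
    """Standardized-distance components of one SNP within a panel."""

    snp_id: str
    pop_means: tuple[float, ...]
    overall_mean: float
    pooled_sd: float
    s0: float
    m: tuple[float, ...]
    d: tuple[float, ...]
    ss_d: float


@dataclass(frozen=True)
class MeasureResult:
    """Carrier for one measure's value (and tail probability, if defined)."""

    snp_id: str
    measure: Literal["fst", "chisq", "anova_f", "nscm_ssd"]
    value: float
    p_value: float | None = None


# ---------------------------------------------------------------------------
# operations


def allele_frequency(sample: PopulationSample) -> float:
    """Sample frequency of the counted allele, ``(2 n_AA + n_Aa) / 2n``."""
    if sample.n_individuals < 1:
        raise InvalidInputError(f"population {sample.population_id!r} has no individuals")
    return sample.allele_count / sample.n_alleles


def fst_weir_frequencies(
    p_hat: Sequence[float], n_alleles: Sequence[float]
) -> FstComponents:
    """Weir-Cockerham theta from observed allele frequencies.

    Parameters
    ----------
    p_hat
        Observed allele frequencies, one per population (``s >= 2``).
    n_alleles
        Sample sizes in allele units (2 x individuals for diploid data).

    Returns
    -------
    FstComponents
        MSP, MSG, the sample-size correction ``n_c``, the weighted mean
        frequency ``p_bar``, and ``theta_hat``.  ``theta_hat`` is NaN when
        MSP = MSG = 0 (monomorphic everywhere) and is never clamped.
    """
    p = np.asarray(p_hat, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    s = p.size
    if s < 2:
        raise InvalidInputError(f"need at least 2 populations, got {s}")
    if n.size != s:
        raise InvalidInputError("p_hat and n_alleles must have equal length")
    if np.any(n < 1):
        raise InvalidInputError("every population needs at least one sampled allele")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("allele frequencies must lie in [0, 1]")

    n_tot = n.sum()
    p_bar = float((n * p).sum() / n_tot)
    msp = float((n * (p - p_bar) ** 2).sum() / (s - 1))
    within_denom = (n - 1).sum()
    msg = float((n * p * (1 - p)).sum() / within_denom) if within_denom > 0 else math.nan
    n_c = float((n_tot - (n**2).sum() / n_tot) / (s - 1))
    denom = msp + (n_c - 1) * msg
    if denom == 0 or math.isnan(denom):
        theta = math.nan
    else:
        theta = (msp - msg) / denom
    return FstComponents(msp=msp, msg=msg, n_c=n_c, p_bar=p_bar, theta_hat=theta)


def fst_weir(dataset: SnpDataset) -> FstComponents:
    """Weir-Cockerham theta for one SNP, with ``n_i`` in allele units."""
    if dataset.n_populations < 2:
        raise InvalidInputError(
            f"SNP {dataset.snp_id}: need at least 2 populations, got {dataset.n_populations}"
        )
    for s in dataset.samples:
        if s.n_individuals < 1:
            raise InvalidInputError(
                f"SNP {dataset.snp_id}: population {s.population_id!r} is empty"
            )
    p = [allele_frequency(s) for s in dataset.samples]
    n = [s.n_alleles for s in dataset.samples]
    return fst_weir_frequencies(p, n)


def chisq_homogeneity(
    dataset: SnpDataset, table: Literal["allele", "genotype"] = "allele"
) -> MeasureResult:
    """Pearson chi-square test that allele frequencies are equal across populations.

    The default tests the ``2 x s`` table of allele counts
    ``(2 n_i p_hat_i, 2 n_i (1 - p_hat_i))`` with ``df = s - 1`` and no
    continuity correction, matching the null ``p_1 = ... = p_s``.  The
    ``genotype`` variant tests the ``3 x s`` genotype-count table instead
    (empty genotype classes dropped, df adjusted accordingly).
    """
    s = dataset.n_populations
    if s < 2:
        raise InvalidInputError(
            f"SNP {dataset.snp_id}: need at least 2 populations, got {s}"
        )
    if table == "allele":
        a = np.array([smp.allele_count for smp in dataset.samples], dtype=float)
        tot = np.array([smp.n_alleles for smp in dataset.samples], dtype=float)
        if np.any(tot == 0):
            raise InvalidInputError(f"SNP {dataset.snp_id}: population with no alleles")
        obs = np.stack([a, tot - a], axis=1)  # s x 2
    elif table == "genotype":
        obs = np.array([smp.genotype_counts for smp in dataset.samples], dtype=float)
    else:
        raise InvalidInputError(f"unknown table kind {table!r}")

    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[1] < 2:
        # one allele (or genotype class) absent everywhere: nothing to test
        return MeasureResult(dataset.snp_id, "chisq", value=0.0, p_value=1.0)
    x2, p_value, _, _ = stats.chi2_contingency(obs, correction=False)
    return MeasureResult(dataset.snp_id, "chisq", value=float(x2), p_value=float(p_value))


def _dosage_moments(dataset: SnpDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population (n, sum of dosages, sum of squared dosages).

    Dosages are counts of the counted allele per individual: ``n_AA``
    copies of 2, ``n_Aa`` copies of 1, ``n_aa`` copies of 0, so the sums
    are exact functions of the genotype counts.
    """
    n = np.array([s.n_individuals for s in dataset.samples], dtype=float)
    n_hom = np.array([s.genotype_counts[0] for s in dataset.samples], dtype=float)
    n_het = np.array([s.genotype_counts[1] for s in dataset.samples], dtype=float)
    return n, 2 * n_hom + n_het, 4 * n_hom + n_het


def anova_f(dataset: SnpDataset) -> AnovaDecomposition:
    """One-way fixed-effects ANOVA on allele dosages (0/1/2 per individual).

    Tests whether population mean dosages are equal.  Degenerate variance
    is not an error: ``ms_within = 0`` with unequal means yields
    ``F = +inf, p = 0``; all values identical yields ``F = NaN, p = 1``.
    """
    s = dataset.n_populations
    if s < 2:
        raise InvalidInputError(
            f"SNP {dataset.snp_id}: need at least 2 populations, got {s}"
        )
    n, dsum, dss = _dosage_moments(dataset)
    n_tot = n.sum()
    if n_tot <= s:
        raise InvalidInputError(
            f"SNP {dataset.snp_id}: ANOVA needs more individuals ({int(n_tot)}) "
            f"than populations ({s})"
        )
    group_means = dsum / n
    grand = dsum.sum() / n_tot
    ss_between = float((n * (group_means - grand) ** 2).sum())
    ss_within = float((dss - n * group_means**2).sum())
    df = (s - 1, int(n_tot) - s)
    ms_between = ss_between / df[0]
    ms_within = ss_within / df[1]
    if ms_within > 0:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, *df))
    elif ms_between > 0:
        f, p = math.inf, 0.0
    else:
        f, p = math.nan, 1.0
    return AnovaDecomposition(
        grand_mean=float(grand),
        group_effects=tuple(float(m - grand) for m in group_means),
        ms_between=ms_between,
        ms_within=ms_within,
        f_stat=f,
        df=df,
        p_value=p,
    )


def nscm_ssd(
    panel: Sequence[SnpDataset], m_mode: Literal["sqrt", "literal"] = "sqrt"
) -> list[NscmComponents]:
    """Nearest-shrunken-centroid standardized distances over a SNP panel.

    For SNP ``k`` and population ``i``::

        d_ik = (a_ik - a_k) / (m_i * (s_0 + s_k)),      SS_d = sum_i d_ik**2

    where ``a_ik`` is the population mean allele frequency (dosage / 2),
    ``a_k`` the overall mean, ``s_k`` the pooled within-population standard
    deviation (denominator ``n - s``), and ``s_0`` the median of ``s_k``
    over the panel, shared by all SNPs to keep extreme distances from
    blowing up when ``s_k`` is tiny.  ``m_i = sqrt(1/n_i + 1/n)`` in
    individual units, so that ``m_i * s_k`` estimates the standard error of
    the numerator; ``m_mode="literal"`` uses ``1/n_i + 1/n`` without the
    radical instead.

    All SNPs must share the population structure (same ids and sizes, in
    order).  A panel of a single SNP is allowed; its own ``s_k`` then
    serves as ``s_0``.
    """
    if len(panel) == 0:
        raise InvalidInputError("empty SNP panel")
    ref = [(s.population_id, s.n_individuals) for s in panel[0].samples]
    for ds in panel[1:]:
        if [(s.population_id, s.n_individuals) for s in ds.samples] != ref:
            raise InvalidInputError(
                f"SNP {ds.snp_id}: population structure differs from {panel[0].snp_id}"
            )
    if len(ref) < 2:
        raise InvalidInputError("need at least 2 populations")

    n = np.array([r[1] for r in ref], dtype=float)
    n_tot = n.sum()
    if m_mode == "sqrt":
        m = np.sqrt(1.0 / n + 1.0 / n_tot)
    elif m_mode == "literal":
        m = 1.0 / n + 1.0 / n_tot
    else:
        raise InvalidInputError(f"unknown m_mode {m_mode!r}")

    means, overall, sks = [], [], []
    for ds in panel:
        _, dsum, dss = _dosage_moments(ds)
        a_ik = dsum / (2 * n)  # frequency scale
        a_k = dsum.sum() / (2 * n_tot)
        # pooled within-population variance of dosage/2 values
        ss_within = (dss / 4 - n * a_ik**2).sum()
        sks.append(math.sqrt(max(ss_within, 0.0) / (n_tot - len(ref))))
        means.append(a_ik)
        overall.append(a_k)
    s0 = float(np.median(sks))

    out = []
    for ds, a_ik, a_k, s_k in zip(panel, means, overall, sks):
        scale = m * (s0 + s_k)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(
                scale > 0, (a_ik - a_k) / np.where(scale > 0, scale, 1.0),
                np.where(a_ik == a_k, 0.0, math.inf),
            )
        out.append(
            NscmComponents(
                snp_id=ds.snp_id,
                pop_means=tuple(float(x) for x in a_ik),
                overall_mean=float(a_k),
                pooled_sd=float(s_k),
                s0=s0,
                m=tuple(float(x) for x in m),
                d=tuple(float(x) for x in d),
                ss_d=float((d**2).sum()),
            )
        )
    return out
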