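"""Simulated inputs: HWE genotype draws, scenario grids, annotation fixtures.

The generators emulate the two kinds of input the analysis needs:

* **Benchmark inputs** — diallelic SNPs in three subpopulations under
  Hardy-Weinberg equilibrium.  Allele frequencies are equally spaced,
  ``p_2 - p_1 = p_3 - p_2 = d``, with ``p_1 ~ Uniform[0, min(0.5, 1-2d)]``
  (the upper bound exploits the symmetry ``p -> 1 - p``); genotype counts
  per population are one multinomial draw with cell probabilities
  ``(p^2, 2pq, q^2)``.  ``d = 0`` is the null (no differentiation).

* **Classification/enrichment fixtures** — allele-frequency tables,
  SNP-to-gene maps, and gene-set annotations shaped like a
  HapMap-frequencies-plus-PharmGKB input, with planted high/low
  differentiation labels and planted enriched terms so downstream recovery
  can be scored against ground truth.

All generators are driven by explicit seeds; per-scenario and
per-repetition streams are derived from one master seed through
``numpy.random.SeedSequence`` so runs are reproducible and repetitions
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .differentiation_classify import FrequencyRecord, SnpGeneMap
from .enrichment import GeneSet
from .errors import InvalidInputError
from .pd_measures import PopulationSample, SnpDataset

__all__ = [
    "SimulationScenario",
    "PlantedTruth",
    "AnnotationFixture",
    "make_p_vector",
    "draw_snp_dataset",
    "scenario_grid",
    "make_annotation_fixture",
    "scenario_rng",
]

#: sample-size triples of the two published scenarios (individuals)
SCENARIO_I_SIZES: tuple[tuple[int, int, int], ...] = (
    (100, 100, 100),
    (200, 200, 200),
    (400, 400, 400),
)
SCENARIO_II_SIZES: tuple[tuple[int, int, int], ...] = (
    (200, 100, 100),
    (100, 200, 100),
    (100, 100, 200),
)

DISTRIBUTION_D_GRID = (0.1, 0.2, 0.3)
SENS_SPEC_D_GRID = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)


@dataclass(frozen=True)
class SimulationScenario:
    """One benchmarking condition: sizes, frequency spacing, replication."""

    sample_sizes: tuple[int, int, int]
    d: float
    n_datasets: int
    n_repetitions: int
    seed: int

    def __post_init__(self) -> None:
        if self.d < 0 or 1 - 2 * self.d < 0:
            raise InvalidInputError(f"spacing d={self.d} leaves no valid p1 range")
        if any(n < 1 for n in self.sample_sizes):
            raise InvalidInputError(f"sample sizes must be >= 1, got {self.sample_sizes}")


def scenario_rng(scenario: SimulationScenario, repetition: int = 0) -> np.random.Generator:
    """Independent, reproducible stream for one repetition of a scenario."""
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, repetition]))


def make_p_vector(d: float, rng: np.random.Generator) -> tuple[float, float, float]:
    """Equally spaced allele frequencies ``(p1, p1 + d, p1 + 2d)``.

    ``p1 ~ Uniform[0, min(0.5, 1 - 2d)]`` so all three frequencies stay in
    ``[0, 1]``; the 0.5 cap removes mirror-image duplicates (relabeling
    the alleles maps ``{p}`` to ``{1 - p}``).
    """
    if d > 0.5:
        raise InvalidInputError(f"spacing d={d} exceeds 0.5; p3 = p1 + 2d would leave [0, 1]")
    if d < 0:
        raise InvalidInputError(f"spacing d={d} is negative")
    hi = min(0.5, 1 - 2 * d)
    p1 = float(rng.uniform(0.0, hi))
    return (p1, p1 + d, p1 + 2 * d)


def draw_snp_dataset(
    sample_sizes: Sequence[int],
    p: Sequence[float],
    rng: np.random.Generator,
    snp_id: str = "sim",
) -> SnpDataset:
    """One SNP of HWE genotype counts: multinomial ``(p^2, 2pq, q^2)`` per population."""
    if len(sample_sizes) != len(p):
        raise InvalidInputError("sample_sizes and p must have equal length")
    samples = []
    for i, (n_i, p_i) in enumerate(zip(sample_sizes, p), start=1):
        if not 0.0 <= p_i <= 1.0:
            raise InvalidInputError(f"allele frequency p_{i}={p_i} outside [0, 1]")
        if n_i < 1:
            raise InvalidInputError(f"sample size n_{i}={n_i} must be >= 1")
        q_i = 1.0 - p_i
        probs = np.array([p_i**2, 2 * p_i * q_i, q_i**2])
        probs /= probs.sum()
        counts = rng.multinomial(n_i, probs)
        samples.append(
            PopulationSample(
                population_id=f"POP{i}",
                n_individuals=int(n_i),
                genotype_counts=(int(counts[0]), int(counts[1]), int(counts[2])),
            )
        )
    return SnpDataset(snp_id=snp_id, samples=samples)


def _derive_seed(master_seed: int, index: int) -> int:
    state = np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def scenario_grid(
    kind: Literal["distribution_study", "sensitivity_specificity"],
    master_seed: int = 0,
) -> list[SimulationScenario]:
    """The published simulation grid for either study.

    ``distribution_study``: six size triples x d in {0.1, 0.2, 0.3}, 200
    datasets each, one repetition.  ``sensitivity_specificity``: the same
    six size triples x d in {0, 0.05, ..., 0.3}, 100 datasets x 100
    repetitions.  Each scenario carries a distinct sub-seed derived from
    the master seed by position.
    """
    if kind == "distribution_study":
        d_grid, n_datasets, n_reps = DISTRIBUTION_D_GRID, 200, 1
    elif kind == "sensitivity_specificity":
        d_grid, n_datasets, n_reps = SENS_SPEC_D_GRID, 100, 100
    else:
        raise InvalidInputError(f"unknown scenario kind {kind!r}")
    sizes = SCENARIO_I_SIZES + SCENARIO_II_SIZES
    return [
        SimulationScenario(
            sample_sizes=sz,
            d=d,
            n_datasets=n_datasets,
            n_repetitions=n_reps,
            seed=_derive_seed(master_seed, i),
        )
        for i, (sz, d) in enumerate((sz, d) for sz in sizes for d in d_grid)
    ]


# ---------------------------------------------------------------------------
# annotation fixtures


@dataclass(frozen=True)
class PlantedTruth:
    """Generating labels of an annotation fixture."""

    gene_labels: dict[str, str]          # gene -> "HD" | "LD"
    snp_spacing: dict[str, float]        # snp -> generative d
    planted_terms: dict[str, dict]       # term_id -> {k, K, n, N, fold}


@dataclass(frozen=True)
class AnnotationFixture:
    """Synthetic stand-in for a frequency-table + SNP-gene-map + GMT input."""

    frequency_table: list[FrequencyRecord]
    snp_gene_map: SnpGeneMap
    gene_sets: list[GeneSet]
    planted_truth: PlantedTruth


def make_annotation_fixture(
    n_genes: int = 600,
    n_snps: int = 900,
    frac_hd: float = 0.25,
    n_terms: int = 50,
    planted_terms: int = 1,
    seed: int = 0,
    *,
    n_alleles: int = 1000,
    d_hd: float = 0.4,
    term_size: int = 20,
    target_fold: float = 5.0,
    annotated_fraction: float = 0.5,
    hd_annotated_fraction: float = 0.15,
) -> AnnotationFixture:
    """Generate a frequency table, SNP-gene map, and gene sets with known truth.

    Each gene is labeled HD with probability ``frac_hd``.  Every gene
    carries at least one SNP (``n_snps >= n_genes``); an HD gene's first
    SNP is drawn at spacing ``d_hd`` (strong differentiation, F_st well
    above 0.25 at the default ``n_alleles``), every other SNP at ``d = 0``.
    Gene-set terms are drawn from an annotation pool covering
    ``annotated_fraction`` of the genes in which HD genes make up
    ``hd_annotated_fraction``; keeping the annotated HD share below
    ``1 / target_fold`` is what makes the planted fold reachable, since
    fold enrichment of an input of n genes against a background of N can
    never exceed N / n.  Each planted term has ``term_size`` genes, of
    which ``k = round(target_fold * term_size * n / N)`` are HD (n, N the
    realized annotated input/background sizes), so its true fold
    enrichment is ``target_fold`` up to rounding.
    """
    if not 0.0 <= frac_hd <= 1.0:
        raise InvalidInputError(f"frac_hd={frac_hd} outside [0, 1]")
    if planted_terms > n_terms:
        raise InvalidInputError("planted_terms cannot exceed n_terms")
    if n_snps < n_genes:
        raise InvalidInputError("need at least one SNP per gene (n_snps >= n_genes)")
    if n_alleles % 2 or n_alleles < 2:
        raise InvalidInputError("n_alleles must be a positive even number (diploid)")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    is_hd = rng.random(n_genes) < frac_hd
    gene_labels = {g: ("HD" if h else "LD") for g, h in zip(genes, is_hd)}

    # one SNP per gene, surplus SNPs spread uniformly
    snp_gene: list[tuple[str, str]] = []
    owners = list(range(n_genes)) + list(rng.integers(0, n_genes, size=n_snps - n_genes))
    per_gene_seen: dict[int, int] = {}
    records: list[FrequencyRecord] = []
    snp_spacing: dict[str, float] = {}
    n_ind = n_alleles // 2
    for j, gi in enumerate(owners):
        snp = f"rs{j + 1:06d}"
        gene = genes[gi]
        first = per_gene_seen.get(gi, 0) == 0
        per_gene_seen[gi] = per_gene_seen.get(gi, 0) + 1
        d = d_hd if (is_hd[gi] and first) else 0.0
        p = make_p_vector(d, rng)
        ds = draw_snp_dataset((n_ind, n_ind, n_ind), p, rng, snp_id=snp)
        for smp in ds.samples:
            records.append(
                FrequencyRecord(
                    snp_id=snp,
                    population_id=smp.population_id,
                    allele_freq=smp.allele_count / smp.n_alleles,
                    n_alleles=smp.n_alleles,
                )
            )
        snp_gene.append((snp, gene))
        snp_spacing[snp] = d

    gene_map = SnpGeneMap({snp: {gene} for snp, gene in snp_gene})

    # annotation pool with a controlled HD share
    hd_genes = [g for g in genes if gene_labels[g] == "HD"]
    ld_genes = [g for g in genes if gene_labels[g] == "LD"]
    pool_size = max(2, round(annotated_fraction * n_genes))
    n_pool_hd = min(len(hd_genes), round(hd_annotated_fraction * pool_size))
    pool_hd = list(rng.choice(hd_genes, size=n_pool_hd, replace=False)) if n_pool_hd else []
    n_pool_ld = min(len(ld_genes), pool_size - n_pool_hd)
    pool_ld = list(rng.choice(ld_genes, size=n_pool_ld, replace=False))
    pool = pool_hd + pool_ld

    gene_sets: list[GeneSet] = []
    for t in range(n_terms - planted_terms):
        size = int(rng.integers(10, 31))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        gene_sets.append(
            GeneSet(
                term_id=f"T{t + 1:04d}",
                term_name=f"random term {t + 1}",
                category="BP",
                genes=frozenset(members),
            )
        )

    annotated = set().union(*(gs.genes for gs in gene_sets)) if gene_sets else set(pool)
    planted: dict[str, dict] = {}
    for t in range(planted_terms):
        ann_hd = sorted(annotated & set(hd_genes))
        ann_other = sorted(annotated - set(hd_genes))
        n_in, n_bg = len(ann_hd), len(annotated)
        k = round(target_fold * term_size * n_in / n_bg)
        if k > min(term_size, n_in) or term_size - k > len(ann_other):
            raise InvalidInputError(
                f"planted fold {target_fold} at term size {term_size} is not "
                f"reachable with {n_in} annotated HD genes of {n_bg} annotated"
            )
        members = frozenset(
            list(rng.choice(ann_hd, size=k, replace=False))
            + list(rng.choice(ann_other, size=term_size - k, replace=False))
        )
        term_id = f"P{t + 1:04d}"
        gene_sets.append(
            GeneSet(term_id=term_id, term_name=f"planted enriched term {t + 1}",
                    category="BP", genes=members)
        )
        planted[term_id] = {
            "k": k, "K": term_size, "n": n_in, "N": n_bg,
            "fold": (k / n_in) / (term_size / n_bg) if n_in else float("nan"),
        }

    return AnnotationFixture(
        frequency_table=records,
        snp_gene_map=gene_map,
        gene_sets=gene_sets,
        planted_truth=PlantedTruth(
            gene_labels=gene_labels, snp_spacing=snp_spacing, planted_terms=planted
        ),
    )
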