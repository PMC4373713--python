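"""Simulation benchmark of the four PD measures.

Two studies over the published scenario grid:

* a **distribution study** — per condition, score a batch of simulated
  SNPs with all four measures and return the tidy table behind the
  box-plot comparison (p-value measures on the ``-log10 p`` scale);
* a **sensitivity/specificity study** — per repetition, the fraction of
  null (``d = 0``) datasets not rejected (specificity) and of
  differentiated (``d > 0``) datasets rejected (sensitivity), averaged
  over repetitions with a Monte-Carlo standard error.

Decision rules
--------------
The chi-square and ANOVA measures reject at a p-value threshold
(``alpha = 0.05`` by default; each simulated SNP is a single test, a BH
variant over a repetition's datasets is available).  F_st and SS_d have no
inherent test, so they reject above a value threshold.  The default rule
set compares sensitivities at matched size: the F_st threshold is a
Monte-Carlo critical value (null 0.95 quantile) calibrated per sample-size
configuration, while the SS_d threshold is the null 0.99 quantile
calibrated once at the reference configuration (100,100,100) and held
fixed — SS_d is standardized, so its null distribution barely moves with
sample size.  Wright's fixed boundary (theta > 0.05) remains available as
an alternative F_st rule.  Value-threshold measures evaluating to NaN
(monomorphic draws) never reject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .errors import ConfigurationError, InvalidInputError
from .synthetic_data import SimulationScenario, scenario_rng
from .enrichment import bh_adjust

__all__ = [
    "MEASURES",
    "DecisionRule",
    "RuleSet",
    "BenchmarkResult",
    "calibrate_value_threshold",
    "default_rules",
    "wright_fst_rule",
    "run_distribution_study",
    "evaluate_sensitivity_specificity",
    "rank_measures",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

MEASURES = ("chisq", "anova_f", "fst", "nscm_ssd")

#: sample-size configuration at which held-fixed thresholds are calibrated
REFERENCE_SIZES = (100, 100, 100)


@dataclass(frozen=True)
class DecisionRule:
    """How one measure turns a score into a rejection."""

    measure: str
    rule_kind: Literal["p_value_threshold", "value_threshold"]
    threshold: float
    use_bh: bool = False  # p-value rules only: BH over each repetition's datasets

    def __post_init__(self) -> None:
        if self.rule_kind == "p_value_threshold":
            if not 0.0 < self.threshold < 1.0:
                raise InvalidInputError(
                    f"p-value threshold must lie in (0, 1), got {self.threshold}"
                )
        elif self.rule_kind == "value_threshold":
            if math.isnan(self.threshold):
                raise InvalidInputError("value threshold must be a number")
        else:
            raise InvalidInputError(f"unknown rule kind {self.rule_kind!r}")


@dataclass(frozen=True)
class RuleSet:
    """Per-measure rules, optionally specialized by sample-size triple."""

    shared: Mapping[str, DecisionRule]
    by_size: Mapping[tuple[int, ...], Mapping[str, DecisionRule]] = field(default_factory=dict)

    def rules_for(self, sample_sizes: Sequence[int]) -> dict[str, DecisionRule]:
        merged = dict(self.shared)
        merged.update(self.by_size.get(tuple(sample_sizes), {}))
        return merged


@dataclass(frozen=True)
class BenchmarkResult:
    """Mean sensitivity or specificity of one measure in one condition."""

    scenario: SimulationScenario
    measure: str
    d: float
    metric: Literal["sensitivity", "specificity"]
    estimate: float
    mc_stderr: float


def _coerce_ruleset(rules: RuleSet | Mapping[str, DecisionRule]) -> RuleSet:
    if isinstance(rules, RuleSet):
        return rules
    return RuleSet(shared=dict(rules))


def _null_p1(rng: np.random.Generator, d: float, size: int) -> np.ndarray:
    hi = min(0.5, 1 - 2 * d)
    return rng.uniform(0.0, hi, size=size)


def _simulate_batch(
    rng: np.random.Generator, sample_sizes: Sequence[int], d: float, size: int
) -> np.ndarray:
    p1 = _null_p1(rng, d, size)
    p = np.stack([p1, p1 + d, p1 + 2 * d], axis=1)
    return _engine.draw_counts_batch(rng, np.asarray(sample_sizes), p)


def _measure_scores(
    counts: np.ndarray, n_ind: np.ndarray, chisq_table: str = "allele"
) -> dict[str, tuple[np.ndarray, np.ndarray | None]]:
    """Per measure: (statistic values, p-values or None) for a batch."""
    x2, p_chi = _engine.chisq_p_batch(counts, n_ind, table=chisq_table)
    f, p_f = _engine.anova_p_batch(counts, n_ind)
    theta = _engine.fst_theta_batch(counts, n_ind)
    ssd = _engine.nscm_ssd_batch(counts, n_ind)
    return {
        "chisq": (x2, p_chi),
        "anova_f": (f, p_f),
        "fst": (theta, None),
        "nscm_ssd": (ssd, None),
    }


def _apply_rule(
    rule: DecisionRule, values: np.ndarray, p_values: np.ndarray | None
) -> np.ndarray:
    if rule.rule_kind == "p_value_threshold":
        if p_values is None:
            raise ConfigurationError(
                f"measure {rule.measure!r} has no p-value; use a value threshold"
            )
        p = bh_adjust(p_values) if rule.use_bh else p_values
        with np.errstate(invalid="ignore"):
            return p <= rule.threshold
    with np.errstate(invalid="ignore"):
        return values > rule.threshold  # NaN compares False: never rejects


def calibrate_value_threshold(
    measure: str,
    sample_sizes: Sequence[int],
    quantile: float,
    n_null: int = 20000,
    seed: int = 0,
    chisq_table: str = "allele",
) -> float:
    """Null quantile of a measure's values under ``d = 0`` at given sizes.

    Used as a Monte-Carlo critical value: rejecting above the ``q``-th
    null quantile gives specificity ``q`` at the calibrated configuration.
    """
    if measure not in MEASURES:
        raise ConfigurationError(f"unknown measure {measure!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1_000_003]))
    counts = _simulate_batch(rng, sample_sizes, 0.0, n_null)
    values, _ = _measure_scores(counts, np.asarray(sample_sizes), chisq_table)[measure]
    return float(np.nanquantile(values, quantile))


def wright_fst_rule(threshold: float = 0.05) -> DecisionRule:
    """F_st rejection at Wright's fixed low-divergence boundary."""
    return DecisionRule("fst", "value_threshold", threshold)


def default_rules(
    scenarios: Sequence[SimulationScenario],
    master_seed: int = 0,
    *,
    alpha: float = 0.05,
    fst_rule: Literal["calibrated", "wright"] = "calibrated",
    fst_level: float = 0.95,
    nscm_quantile: float = 0.99,
    n_null: int = 20000,
    reference_sizes: Sequence[int] = REFERENCE_SIZES,
    chisq_table: str = "allele",
    use_bh: bool = False,
) -> RuleSet:
    """The default rule set for a scenario list.

    chi-square and ANOVA at ``alpha``; SS_d above its null
    ``nscm_quantile`` calibrated once at ``reference_sizes`` and held
    fixed; F_st either above a per-size null ``fst_level`` quantile
    (default, so sensitivities are compared at matched size) or above
    Wright's fixed 0.05 boundary.
    """
    shared = {
        "chisq": DecisionRule("chisq", "p_value_threshold", alpha, use_bh=use_bh),
        "anova_f": DecisionRule("anova_f", "p_value_threshold", alpha, use_bh=use_bh),
        "nscm_ssd": DecisionRule(
            "nscm_ssd",
            "value_threshold",
            calibrate_value_threshold(
                "nscm_ssd", reference_sizes, nscm_quantile, n_null, master_seed
            ),
        ),
    }
    by_size: dict[tuple[int, ...], dict[str, DecisionRule]] = {}
    if fst_rule == "wright":
        shared["fst"] = wright_fst_rule()
    elif fst_rule == "calibrated":
        for i, sizes in enumerate(sorted({tuple(s.sample_sizes) for s in scenarios})):
            thr = calibrate_value_threshold(
                "fst", sizes, fst_level, n_null, master_seed + 7919 * (i + 1)
            )
            by_size[sizes] = {"fst": DecisionRule("fst", "value_threshold", thr)}
    else:
        raise ConfigurationError(f"unknown fst_rule {fst_rule!r}")
    return RuleSet(shared=shared, by_size=by_size)


def run_distribution_study(
    scenarios: Sequence[SimulationScenario],
    chisq_table: str = "allele",
) -> pd.DataFrame:
    """Score ``n_datasets`` simulated SNPs per condition with all four measures.

    Returns a tidy frame (columns ``n1 n2 n3 d dataset measure value``);
    chi-square and ANOVA are reported as ``-log10 p``, F_st as theta, NSCM
    as SS_d — the axis conventions of the box-plot comparison.
    """
    rows = []
    for sc in scenarios:
        rng = scenario_rng(sc, 0)
        counts = _simulate_batch(rng, sc.sample_sizes, sc.d, sc.n_datasets)
        scores = _measure_scores(counts, np.asarray(sc.sample_sizes), chisq_table)
        for measure, (values, p) in scores.items():
            if p is not None:
                with np.errstate(divide="ignore"):
                    values = -np.log10(p)
            for i, v in enumerate(values):
                rows.append(
                    {
                        "n1": sc.sample_sizes[0],
                        "n2": sc.sample_sizes[1],
                        "n3": sc.sample_sizes[2],
                        "d": sc.d,
                        "dataset": i,
                        "measure": measure,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


def evaluate_sensitivity_specificity(
    scenarios: Sequence[SimulationScenario],
    rules: RuleSet | Mapping[str, DecisionRule],
    chisq_table: str = "allele",
) -> list[BenchmarkResult]:
    """Average sensitivity (``d > 0``) or specificity (``d = 0``) per condition.

    Per repetition the rejection fraction over the scenario's datasets is
    recorded; the estimate is the mean over repetitions and ``mc_stderr``
    the standard error over repetitions (0 when there is only one).
    """
    ruleset = _coerce_ruleset(rules)
    out: list[BenchmarkResult] = []
    for sc in scenarios:
        rset = ruleset.rules_for(sc.sample_sizes)
        missing = [m for m in MEASURES if m not in rset]
        if missing:
            raise ConfigurationError(f"no decision rule for measures {missing}")
        n_ind = np.asarray(sc.sample_sizes)
        fractions = {m: [] for m in MEASURES}
        n_nan = 0
        for rep in range(sc.n_repetitions):
            rng = scenario_rng(sc, rep)
            counts = _simulate_batch(rng, sc.sample_sizes, sc.d, sc.n_datasets)
            scores = _measure_scores(counts, n_ind, chisq_table)
            for m in MEASURES:
                values, p = scores[m]
                n_nan += int(np.isnan(values).sum())
                rejected = _apply_rule(rset[m], values, p)
                frac = rejected.mean()
                fractions[m].append(1.0 - frac if sc.d == 0 else frac)
        if n_nan:
            logger.debug(
                "scenario %s d=%.2f: %d NaN measure values (counted as non-rejections)",
                sc.sample_sizes, sc.d, n_nan,
            )
        metric = "specificity" if sc.d == 0 else "sensitivity"
        for m in MEASURES:
            fr = np.asarray(fractions[m])
            se = float(fr.std(ddof=1) / math.sqrt(len(fr))) if len(fr) > 1 else 0.0
            out.append(
                BenchmarkResult(
                    scenario=sc, measure=m, d=sc.d, metric=metric,
                    estimate=float(fr.mean()), mc_stderr=se,
                )
            )
    return out


def results_to_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tidy table of benchmark results."""
    return pd.DataFrame(
        [
            {
                "n1": r.scenario.sample_sizes[0],
                "n2": r.scenario.sample_sizes[1],
                "n3": r.scenario.sample_sizes[2],
                "d": r.d,
                "measure": r.measure,
                "metric": r.metric,
                "estimate": r.estimate,
                "mc_stderr": r.mc_stderr,
            }
            for r in results
        ]
    )


def rank_measures(results: Sequence[BenchmarkResult]) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Order measures by sensitivity per condition and check headline orderings.

    Returns the per-condition ordering table (rank 1 = most sensitive) and
    three flags, each allowed two combined Monte-Carlo standard errors of
    slack: ``fst_top_at_small_n`` (F_st weakly best at the smallest total
    size for the two smallest spacings), ``nscm_lowest`` (SS_d weakly
    worst everywhere), and ``middle_unbalance_least_sensitive`` (the
    middle-unbalanced configuration weakly below both end-unbalanced ones
    at every spacing).
    """
    df = results_to_frame(results)
    sens = df[df["metric"] == "sensitivity"].copy()
    if sens.empty:
        raise ConfigurationError("no sensitivity rows to rank")
    cover = sens.groupby(["n1", "n2", "n3", "d"])["measure"].nunique()
    if (cover != len(MEASURES)).any():
        raise ConfigurationError("sensitivity grid does not cover all measures")

    sens["rank"] = sens.groupby(["n1", "n2", "n3", "d"])["estimate"].rank(
        ascending=False, method="min"
    )
    order = sens.sort_values(["n1", "n2", "n3", "d", "rank"], ignore_index=True)

    def _slack(a: pd.Series, b: pd.Series) -> float:
        return 2.0 * math.hypot(float(a["mc_stderr"]), float(b["mc_stderr"]))

    flags: dict[str, bool] = {}
    grouped = {key: grp.set_index("measure") for key, grp in sens.groupby(["n1", "n2", "n3", "d"])}

    # NSCM weakly lowest everywhere
    ok = True
    for grp in grouped.values():
        n = grp.loc["nscm_ssd"]
        for m in MEASURES:
            if m != "nscm_ssd" and n["estimate"] > grp.loc[m]["estimate"] + _slack(n, grp.loc[m]):
                ok = False
    flags["nscm_lowest"] = ok

    # F_st weakly top at the smallest total size, two smallest spacings
    totals = sens["n1"] + sens["n2"] + sens["n3"]
    small = sens[totals == totals.min()]
    ds = sorted(small["d"].unique())[:2]
    ok = True
    for key, grp in grouped.items():
        n1, n2, n3, d = key
        if n1 + n2 + n3 != int(totals.min()) or d not in ds:
            continue
        f = grp.loc["fst"]
        for m in MEASURES:
            if m != "fst" and f["estimate"] < grp.loc[m]["estimate"] - _slack(f, grp.loc[m]):
                ok = False
    flags["fst_top_at_small_n"] = ok

    # middle-unbalanced weakly least sensitive among unbalanced triples
    ok = True
    for d in sorted(sens["d"].unique()):
        try:
            mid = {m: grouped[(100, 200, 100, d)].loc[m] for m in MEASURES}
            ends = [
                {m: grouped[k].loc[m] for m in MEASURES}
                for k in ((200, 100, 100, d), (100, 100, 200, d))
                if k in grouped
            ]
        except KeyError:
            continue
        for end in ends:
            for m in MEASURES:
                if mid[m]["estimate"] > end[m]["estimate"] + _slack(mid[m], end[m]):
                    ok = False
    flags["middle_unbalance_least_sensitive"] = ok
    return order, flags
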