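"""Re-randomization engine, endpoint regeneration and replicate summaries.

The core experiment re-allocates one fixed patient population many times:
each replicate draws a fresh inclusion-order permutation, runs every
configured allocation method on that *same* shuffled sequence (a paired
design, so method contrasts are not confounded by ordering noise), and
records the three imbalance measures. Optionally, each replicate also
regenerates the binary endpoint per patient by a Bernoulli draw at the
success rate of the patient's (stratum, allocated arm) cell, and measures
the per-arm efficacy bias against a reference (e.g. the published rate).

All randomness derives from a single root seed: replicate ``r`` of method
``m`` uses a child seed spawned from ``(seed, r, m)``, so a run is a pure
function of its inputs and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import (
    MinimizationParams,
    SPBRParams,
    allocate_minimization,
    allocate_spbr,
)
from .imbalance import imbalance_report
from .trial_core import (
    AllocationResult,
    ImbalanceReport,
    StratumRateTable,
    TrialPopulation,
    ValidationError,
)

METRICS = ("total", "marginal", "within_stratum")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one re-randomization experiment.

    ``methods`` maps method name ("SPBR", "MIN") to its parameter record;
    the seed fields inside those records are ignored — per-replicate seeds
    are spawned from ``seed``. ``reshuffle`` re-permutes the inclusion order
    each replicate (the study design); turning it off reduces replicate 0
    to a single allocator call on the original order.
    ``reference_efficacy`` maps arm label to the success proportion used as
    the bias baseline.
    """

    n_reps: int = 1000
    methods: Mapping[str, SPBRParams | MinimizationParams] = field(
        default_factory=lambda: {
            "SPBR": SPBRParams(block_size=4),
            "MIN": MinimizationParams(),
        }
    )
    reshuffle: bool = True
    seed: int = 0
    reference_efficacy: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        for name in self.methods:
            if name not in ("SPBR", "MIN"):
                raise ValidationError(f"unknown method {name!r}")


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number boxplot summary with 1.5 x IQR whiskers and outliers.

    Quartiles use the linear-interpolation rule, so summaries are
    bit-reproducible across platforms. Whiskers are the most extreme data
    points inside ``[q25 - 1.5 IQR, q75 + 1.5 IQR]``; points beyond are
    outliers.
    """

    n: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


@dataclass(frozen=True)
class SimulationSummary:
    """Replicate-level values plus boxplot statistics per (method, metric)."""

    replicates: pd.DataFrame
    stats: Mapping[tuple[str, str], BoxplotStats]

    def median(self, method: str, metric: str) -> float:
        return self.stats[(method, metric)].median

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (method, metric), s in self.stats.items():
            rows.append(
                {
                    "method": method,
                    "metric": metric,
                    "n": s.n,
                    "median": s.median,
                    "q25": s.q25,
                    "q75": s.q75,
                    "whisker_low": s.whisker_low,
                    "whisker_high": s.whisker_high,
                    "n_outliers": len(s.outliers),
                }
            )
        return pd.DataFrame(rows)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic 31-bit child seed spawned from the root and a key path."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _run_method(
    name: str,
    params: SPBRParams | MinimizationParams,
    population: TrialPopulation,
    seed: int,
) -> AllocationResult:
    if name == "SPBR":
        return allocate_spbr(population, SPBRParams(params.block_size, seed))
    return allocate_minimization(
        population,
        MinimizationParams(
            p_best=params.p_best,
            covariate_weights=params.covariate_weights,
            imbalance_criterion=params.imbalance_criterion,
            seed=seed,
        ),
    )


def rerandomize(
    population: TrialPopulation, config: SimulationConfig
) -> dict[str, list[tuple[AllocationResult, ImbalanceReport]]]:
    """Re-allocate the population ``n_reps`` times with every configured method.

    Within a replicate all methods face the identical shuffled inclusion
    order. Returns, per method, the list of (allocation, imbalance report)
    pairs in replicate order.
    """
    out: dict[str, list[tuple[AllocationResult, ImbalanceReport]]] = {
        m: [] for m in config.methods
    }
    ids = np.array(population.ids)
    for rep in range(config.n_reps):
        if config.reshuffle:
            rng = np.random.default_rng([config.seed, rep])
            order = list(ids[rng.permutation(len(ids))])
            pop = population.reordered(order)
        else:
            pop = population
        for mi, (name, params) in enumerate(config.methods.items()):
            alloc = _run_method(name, params, pop, _child_seed(config.seed, rep, mi))
            out[name].append((alloc, imbalance_report(pop, alloc)))
    return out


def estimate_stratum_rates(
    population: TrialPopulation,
    covariate_subset: Sequence[str] | None = None,
    arms: Mapping[str, str] | None = None,
    outcomes: Mapping[str, int] | None = None,
    per_arm: bool = True,
) -> StratumRateTable:
    """Observed success proportion per (stratum, arm) cell.

    Strata are combinations of levels over ``covariate_subset``, which
    defaults to every stratification variable except the center (the
    center's many small cells carry too little information to estimate a
    rate). ``arms`` and ``outcomes`` default to the population's stored
    original arm and outcome columns. Cells with zero patients are flagged
    empty, not errored: sparse strata are a property of the data. With
    ``per_arm=False`` arms are pooled within each stratum and every arm key
    of a stratum receives the pooled rate.
    """
    subset = (
        tuple(covariate_subset)
        if covariate_subset is not None
        else population.schema.non_center_names()
    )
    arm_labels = population.arms
    if arms is None:
        arms = {p[0]: p[3] for p in population.patients if p[3] is not None}
    if outcomes is None:
        outcomes = {p[0]: p[2] for p in population.patients if p[2] is not None}
    missing = [pid for pid in population.ids if pid not in arms or pid not in outcomes]
    if missing:
        raise ValidationError(
            f"{len(missing)} patient(s) lack an arm or outcome (first: {missing[0]!r})"
        )

    succ: dict[tuple[tuple[str, ...], str], int] = {}
    tot: dict[tuple[tuple[str, ...], str], int] = {}
    for pid, values, _o, _a in population.patients:
        stratum = tuple(values[n] for n in subset)
        key = (stratum, arms[pid]) if per_arm else (stratum, "*")
        succ[key] = succ.get(key, 0) + int(outcomes[pid])
        tot[key] = tot.get(key, 0) + 1

    all_strata: list[tuple[str, ...]] = [()]
    for name in subset:
        levels = population.schema.levels_of(name)
        all_strata = [s + (lvl,) for s in all_strata for lvl in levels]

    rates: dict[tuple[tuple[str, ...], str], float] = {}
    empty: set[tuple[tuple[str, ...], str]] = set()
    for stratum in all_strata:
        for arm in arm_labels:
            src = (stratum, arm) if per_arm else (stratum, "*")
            if tot.get(src, 0) == 0:
                empty.add((stratum, arm))
            else:
                rates[(stratum, arm)] = succ[src] / tot[src]
    return StratumRateTable(
        covariate_subset=subset, rates=rates, empty_cells=frozenset(empty)
    )


def regenerate_endpoint(
    population: TrialPopulation,
    allocation: AllocationResult,
    rate_table: StratumRateTable,
    rng: np.random.Generator | int,
    fallback: bool = True,
) -> dict[str, int]:
    """Draw a fresh binary endpoint per patient from the stratum-arm rate.

    Each patient's success probability is looked up at their level
    combination over the table's covariate subset and their allocated arm.
    A cell the table flags empty (or does not contain) falls back to the
    arm's marginal rate when ``fallback`` is on; otherwise an error names
    the stratum.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out: dict[str, int] = {}
    for pid, values, _o, _a in population.patients:
        stratum = tuple(values[n] for n in rate_table.covariate_subset)
        arm = allocation.arm_of[pid]
        p = rate_table.rate(stratum, arm)
        if p is None:
            if not fallback:
                raise ValidationError(
                    f"no success rate for stratum {stratum} arm {arm!r} "
                    f"and fallback is disabled"
                )
            p = rate_table.arm_marginal(arm)
        out[pid] = int(rng.random() < p)
    return out


def arm_proportions(
    outcomes: Mapping[str, int], arms: Mapping[str, str]
) -> dict[str, float | None]:
    """Observed success proportion per arm; None for arms with no patients."""
    succ: dict[str, int] = {}
    tot: dict[str, int] = {}
    for pid, arm in arms.items():
        tot[arm] = tot.get(arm, 0) + 1
        succ[arm] = succ.get(arm, 0) + int(outcomes[pid])
    return {arm: succ[arm] / tot[arm] for arm in tot}


def efficacy_bias(
    outcomes: Mapping[str, int],
    arms: Mapping[str, str],
    reference_efficacy: Mapping[str, float],
) -> dict[str, float | None]:
    """Per-arm bias: reference efficacy minus the simulated success proportion.

    The sign convention makes a simulated rate *below* the reference a
    positive bias. Arms present in the reference but holding zero patients
    get ``None`` (bias undefined for that arm).
    """
    props = arm_proportions(outcomes, arms)
    return {
        arm: (None if arm not in props else ref - props[arm])
        for arm, ref in reference_efficacy.items()
    }


def summarize(values: Sequence[float]) -> BoxplotStats:
    """Boxplot statistics of replicate values (linear-interpolation quartiles)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("summarize needs at least one value")
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return BoxplotStats(
        n=int(arr.size),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(x) for x in np.sort(outliers)),
    )


def run_simulation(
    population: TrialPopulation,
    config: SimulationConfig,
    rate_table: StratumRateTable | None = None,
) -> SimulationSummary:
    """Full experiment: re-randomize, measure imbalance, optionally bias.

    When a rate table is supplied, every replicate regenerates the endpoint
    under its allocation and records per-arm efficacy; when the config also
    carries a reference efficacy, the per-arm bias (reference minus
    simulated proportion) is recorded too.
    """
    results = rerandomize(population, config)
    arm_labels = population.arms
    rows = []
    for mi, (method, pairs) in enumerate(results.items()):
        for rep, (alloc, report) in enumerate(pairs):
            row: dict[str, object] = {"rep": rep, "method": method, **report.as_dict()}
            if rate_table is not None:
                rng = np.random.default_rng(
                    [config.seed, config.n_reps + rep, mi]
                )
                outcomes = regenerate_endpoint(population, alloc, rate_table, rng)
                props = arm_proportions(outcomes, dict(alloc.arm_of))
                for arm in arm_labels:
                    row[f"efficacy_{arm}"] = props.get(arm)
                if config.reference_efficacy is not None:
                    bias = efficacy_bias(
                        outcomes, dict(alloc.arm_of), config.reference_efficacy
                    )
                    for arm, b in bias.items():
                        row[f"bias_{arm}"] = b
            rows.append(row)
    replicates = pd.DataFrame(rows)

    stats: dict[tuple[str, str], BoxplotStats] = {}
    metric_cols = [
        c for c in replicates.columns if c not in ("rep", "method")
    ]
    for method in results:
        sub = replicates[replicates["method"] == method]
        for col in metric_cols:
            vals = sub[col].dropna()
            if len(vals):
                stats[(method, col)] = summarize(vals.to_numpy())
    return SimulationSummary(replicates=replicates, stats=stats)
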