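"""The three between-arm imbalance measures for stratified trials.

All three are raw patient counts, computed from an allocation at increasing
resolution:

* *total* — spread (max - min; absolute difference for two arms) of the
  overall arm totals;
* *marginal* — sum, over every covariate and every observed level of that
  covariate, of the spread of arm counts among patients at that level;
* *within-stratum* — sum, over every occupied combination of levels of all
  covariates, of the spread of arm counts inside that combination.

For two arms the spread reduces to the absolute count difference, so the
measures coincide with the classical worked definitions; for three or four
arms the range generalization applies at every level of aggregation.
Unoccupied strata contribute zero.
"""

from __future__ import annotations

import pandas as pd

from .trial_core import AllocationResult, ImbalanceReport, TrialPopulation


def _allocation_frame(
    population: TrialPopulation, allocation: AllocationResult
) -> pd.DataFrame:
    df = population.to_frame()
    df["arm"] = [allocation.arm_of[pid] for pid in df["id"]]
    return df


def _spread_sum(df: pd.DataFrame, by: list[str], arms: tuple[str, ...]) -> int:
    """Sum over groups of (max - min) per-arm count, missing arms counting 0."""
    per = (
        df.groupby(by + ["arm"], observed=True)
        .size()
        .unstack("arm", fill_value=0)
        .reindex(columns=list(arms), fill_value=0)
    )
    return int((per.max(axis=1) - per.min(axis=1)).sum())


def total_imbalance(population: TrialPopulation, allocation: AllocationResult) -> int:
    """Spread of the overall arm totals (|n_A - n_B| for two arms)."""
    if len(population) == 0:
        return 0
    df = _allocation_frame(population, allocation)
    counts = df["arm"].value_counts().reindex(list(population.arms), fill_value=0)
    return int(counts.max() - counts.min())


def marginal_imbalance(population: TrialPopulation, allocation: AllocationResult) -> int:
    """Sum over covariates and levels of the between-arm spread at each level."""
    if len(population) == 0:
        return 0
    df = _allocation_frame(population, allocation)
    return sum(
        _spread_sum(df, [name], population.arms) for name in population.schema.names
    )


def within_stratum_imbalance(
    population: TrialPopulation, allocation: AllocationResult
) -> int:
    """Sum over occupied full cross-classification cells of the arm-count spread."""
    if len(population) == 0:
        return 0
    df = _allocation_frame(population, allocation)
    return _spread_sum(df, list(population.schema.names), population.arms)


def imbalance_report(
    population: TrialPopulation, allocation: AllocationResult
) -> ImbalanceReport:
    """All three measures in one report."""
    return ImbalanceReport(
        total=total_imbalance(population, allocation),
        marginal=marginal_imbalance(population, allocation),
        within_stratum=within_stratum_imbalance(population, allocation),
    )
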