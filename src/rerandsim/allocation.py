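"""Sequential treatment-allocation procedures.

Two allocators are implemented, both pure functions of
``(population, params)`` with all randomness driven by the seed in the
parameter record:

* **Stratified permuted block randomization (SPBR)** — patients are grouped
  by their full covariate cross-classification; within each stratum arms are
  consumed from independently generated random permuted blocks, each block
  holding ``block_size / n_arms`` copies of every arm. Incomplete final
  blocks are simply truncated: with many small strata most blocks never
  complete, which is exactly the imbalance mechanism this package studies.

* **Pocock-Simon minimization** — each new patient is scored against every
  candidate arm by summing, over covariates, the imbalance (range or
  variance of the hypothetical per-arm counts at the patient's own level)
  that the assignment would create. The score-minimizing arm is chosen with
  probability ``p_best`` (the remaining probability split equally over the
  other arms); ties among minimizing arms are resolved uniformly with no
  biased coin applied.

Per-stratum randomness in SPBR is derived from the root seed together with
the stratum's index in the full cross-classification, so results are
reproducible regardless of the order in which strata are first seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trial_core import (
    AllocationResult,
    TrialPopulation,
    ValidationError,
)


@dataclass(frozen=True)
class SPBRParams:
    """Stratified permuted block randomization parameters.

    ``block_size`` must be a positive multiple of the number of arms; the
    conventional default is twice the number of arms, set via
    :meth:`with_default_block`.
    """

    block_size: int
    seed: int = 0

    @classmethod
    def with_default_block(cls, n_arms: int, seed: int = 0) -> "SPBRParams":
        return cls(block_size=2 * n_arms, seed=seed)


@dataclass(frozen=True)
class MinimizationParams:
    """Pocock-Simon minimization parameters.

    ``p_best`` is the probability of assigning the score-minimizing arm; the
    default 0.8 corresponds to a 20% random element. ``covariate_weights``
    maps covariate name to a non-negative weight (default: all equal).
    ``imbalance_criterion`` is ``"range"`` (max - min of the hypothetical
    per-arm counts, the classical choice) or ``"variance"``.
    """

    p_best: float = 0.8
    covariate_weights: Mapping[str, float] | None = None
    imbalance_criterion: str = "range"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_best <= 1.0):
            raise ValidationError(f"p_best must be in (0, 1], got {self.p_best}")
        if self.imbalance_criterion not in ("range", "variance"):
            raise ValidationError(
                f"imbalance_criterion must be 'range' or 'variance', "
                f"got {self.imbalance_criterion!r}"
            )
        if self.covariate_weights is not None:
            if any(w < 0 for w in self.covariate_weights.values()):
                raise ValidationError("covariate weights must be non-negative")
            if all(w == 0 for w in self.covariate_weights.values()):
                raise ValidationError("covariate weights must not all be zero")


def _stratum_index(population: TrialPopulation, values: Mapping[str, str]) -> int:
    """Mixed-radix index of a level combination in the full cross-classification."""
    idx = 0
    for name, levels in population.schema.covariates:
        idx = idx * len(levels) + levels.index(values[name])
    return idx


def allocate_spbr(population: TrialPopulation, params: SPBRParams) -> AllocationResult:
    """Allocate every patient by stratified permuted block randomization.

    Strata are the full cross-classification of all schema covariates. Each
    stratum consumes its own lazily generated sequence of uniformly random
    permuted blocks, seeded from ``(params.seed, stratum index)`` so the
    assignment inside one stratum is independent of all others.
    """
    n_arms = population.n_arms
    if params.block_size <= 0 or params.block_size % n_arms != 0:
        raise ValidationError(
            f"block_size {params.block_size} must be a positive multiple of {n_arms}"
        )
    arms = population.arms
    template = np.repeat(np.arange(n_arms), params.block_size // n_arms)

    buffers: dict[int, list[int]] = {}
    rngs: dict[int, np.random.Generator] = {}
    arm_of: dict[str, str] = {}
    for pid, values, _outcome, _arm in population.patients:
        s = _stratum_index(population, values)
        if s not in rngs:
            rngs[s] = np.random.default_rng([params.seed, s])
            buffers[s] = []
        if not buffers[s]:
            buffers[s] = list(rngs[s].permutation(template))
        arm_of[pid] = arms[buffers[s].pop(0)]

    return AllocationResult(
        arm_of=arm_of,
        method="SPBR",
        parameters={"block_size": params.block_size},
        seed=params.seed,
        inclusion_order=population.ids,
    )


def pocock_simon_scores(
    counts: Mapping[str, Sequence[int]],
    candidate_arm_index: int,
    params: MinimizationParams,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Imbalance score of assigning the next patient to one candidate arm.

    ``counts[covariate]`` holds the per-arm running counts of previously
    allocated patients sharing the new patient's level of that covariate.
    The score is the weighted sum over covariates of the chosen criterion
    applied to the hypothetical counts after adding the patient to
    ``candidate_arm_index``.
    """
    weights = weights if weights is not None else params.covariate_weights
    score = 0.0
    for name, per_arm in counts.items():
        w = 1.0 if weights is None else weights.get(name, 0.0)
        if w == 0.0:
            continue
        hyp = np.asarray(per_arm, dtype=float).copy()
        hyp[candidate_arm_index] += 1.0
        if params.imbalance_criterion == "range":
            crit = float(hyp.max() - hyp.min())
        else:
            crit = float(hyp.var())
        score += w * crit
    return score


def allocate_minimization(
    population: TrialPopulation,
    params: MinimizationParams,
    trace: bool = False,
) -> AllocationResult | tuple[AllocationResult, pd.DataFrame]:
    """Allocate every patient by Pocock-Simon minimization with a random element.

    Patients are processed in inclusion order. With ``trace=True`` a
    per-patient DataFrame is also returned, with one row per assignment:
    the scores of every arm, whether the minimum was tied, the index of the
    minimizing arm, and the arm actually assigned — useful for auditing how
    often the random element overrode the minimizer.
    """
    n_arms = population.n_arms
    arms = population.arms
    rng = np.random.default_rng(params.seed)
    names = population.schema.names

    # running per-(covariate, level) arm counts
    level_counts: dict[tuple[str, str], np.ndarray] = {}
    arm_of: dict[str, str] = {}
    rows = []
    for pid, values, _outcome, _arm in population.patients:
        counts = {}
        for name in names:
            key = (name, values[name])
            if key not in level_counts:
                level_counts[key] = np.zeros(n_arms, dtype=int)
            counts[name] = level_counts[key]
        scores = np.array(
            [pocock_simon_scores(counts, a, params) for a in range(n_arms)]
        )
        best = np.flatnonzero(np.isclose(scores, scores.min()))
        tied = len(best) > 1
        if tied:
            choice = int(rng.choice(best))
        else:
            probs = np.full(n_arms, (1.0 - params.p_best) / max(n_arms - 1, 1))
            probs[best[0]] = params.p_best
            choice = int(rng.choice(n_arms, p=probs))
        arm_of[pid] = arms[choice]
        for name in names:
            level_counts[(name, values[name])][choice] += 1
        if trace:
            rows.append(
                {
                    "id": pid,
                    **{f"score_{arms[a]}": scores[a] for a in range(n_arms)},
                    "tied": tied,
                    "min_arm": arms[int(best[0])],
                    "assigned": arms[choice],
                }
            )

    result = AllocationResult(
        arm_of=arm_of,
        method="MIN",
        parameters={
            "p_best": params.p_best,
            "imbalance_criterion": params.imbalance_criterion,
        },
        seed=params.seed,
        inclusion_order=population.ids,
    )
    if trace:
        return result, pd.DataFrame(rows)
    return result
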