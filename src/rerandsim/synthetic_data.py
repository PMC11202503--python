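"""Synthetic multicenter phase II trial populations with known outcome models.

Individual participant data from real phase II oncology trials is rarely
redistributable, so every pipeline stage here is exercised on generated
populations that mimic the *structure* of such trials: tens of recruiting
centers of unequal size, a handful of categorical stratification covariates,
24-376 patients, 2-4 arms, and a binary endpoint (e.g. 6-month
progression-free survival) with per-stratum success probabilities.

Center sizes are drawn once per population from a symmetric Dirichlet
distribution; a small ``center_size_concentration`` produces a few large and
many small centers, which is the regime where permuted blocks stay
incomplete and stratified block randomization loses balance. Covariates are
mutually independent by default; an optional ``association`` parameter
couples the first two non-center covariates for stress tests.

The generator is illustrative: defaults are chosen to be realistic for
multicenter digestive-oncology phase II trials, not to reconstruct any
specific study's covariate distributions or effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trial_core import (
    AllocationResult,
    CovariateSchema,
    StratumRateTable,
    TrialPopulation,
    ValidationError,
)


@dataclass(frozen=True)
class TrialSpec:
    """Recipe for one synthetic trial population.

    Parameters
    ----------
    n_patients, n_arms, n_centers
        Trial size; arms must be 2-4.
    center_size_concentration
        Dirichlet concentration for the center-size probability vector.
        Values near 1 give markedly unequal centers; large values approach
        equal sizes.
    covariates
        ``{name: level probabilities}`` for the non-center stratification
        covariates; levels are auto-labelled ``<name>1, <name>2, ...``
        unless probabilities are given as a ``{label: prob}`` mapping.
    include_center_as_covariate
        When True (default) the center is a stratification covariate named
        ``"center"`` and flagged as such in the schema.
    baseline_rate
        Success probability of the reference arm in every stratum.
    arm_effects
        Additive per-arm effect on the probability scale (first entry is the
        reference arm and is conventionally 0). Out-of-range sums are
        clamped to [0, 1] with a warning.
    stratum_effects
        Optional additive effect per level of one covariate,
        ``{covariate: {level: delta}}``, letting strata differ in prognosis.
    association
        Probability in [0, 1] with which the second covariate's level index
        is forced equal to the first's (mod its level count); 0 means
        independent.
    seed
        Root seed; identical specs yield identical populations.
    """

    n_patients: int = 109
    n_arms: int = 2
    n_centers: int = 30
    center_size_concentration: float = 1.0
    covariates: Mapping[str, Sequence[float] | Mapping[str, float]] = field(
        default_factory=lambda: {"smoker": {"no": 0.6, "yes": 0.4}}
    )
    include_center_as_covariate: bool = True
    baseline_rate: float = 0.4
    arm_effects: tuple[float, ...] = (0.0, 0.0)
    stratum_effects: Mapping[str, Mapping[str, float]] | None = None
    association: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if len(self.arm_effects) != self.n_arms:
            raise ValidationError(
                f"need {self.n_arms} arm effects, got {len(self.arm_effects)}"
            )
        for name, probs in self.covariates.items():
            p = list(probs.values()) if isinstance(probs, Mapping) else list(probs)
            if len(p) < 2:
                raise ValidationError(f"covariate {name!r} needs >= 2 levels")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValidationError(f"probabilities for {name!r} must sum to 1")

    def level_labels(self, name: str) -> tuple[str, ...]:
        probs = self.covariates[name]
        if isinstance(probs, Mapping):
            return tuple(probs.keys())
        return tuple(f"{name}{i + 1}" for i in range(len(probs)))

    def level_probs(self, name: str) -> np.ndarray:
        probs = self.covariates[name]
        if isinstance(probs, Mapping):
            return np.asarray(list(probs.values()), dtype=float)
        return np.asarray(probs, dtype=float)

    def schema(self) -> CovariateSchema:
        covs: list[tuple[str, tuple[str, ...]]] = []
        center = None
        if self.include_center_as_covariate:
            width = len(str(self.n_centers))
            covs.append(
                ("center", tuple(f"C{i + 1:0{width}d}" for i in range(self.n_centers)))
            )
            center = "center"
        for name in self.covariates:
            covs.append((name, self.level_labels(name)))
        return CovariateSchema(tuple(covs), center_covariate=center)


def generate_population(spec: TrialSpec) -> TrialPopulation:
    """Draw one population: unequal centers, i.i.d. covariates, random order."""
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema()

    center_probs = rng.dirichlet(
        np.full(spec.n_centers, spec.center_size_concentration)
    )
    n = spec.n_patients
    centers = rng.choice(spec.n_centers, size=n, p=center_probs)

    cov_names = list(spec.covariates)
    draws: dict[str, np.ndarray] = {}
    for name in cov_names:
        draws[name] = rng.choice(len(spec.level_probs(name)), size=n,
                                 p=spec.level_probs(name))
    if spec.association > 0 and len(cov_names) >= 2:
        first, second = cov_names[0], cov_names[1]
        forced = rng.random(n) < spec.association
        k = len(spec.level_labels(second))
        draws[second] = np.where(forced, draws[first] % k, draws[second])

    order = rng.permutation(n)
    width = len(str(n))
    patients = []
    for rank, i in enumerate(order):
        values: dict[str, str] = {}
        if spec.include_center_as_covariate:
            values["center"] = schema.levels_of("center")[centers[i]]
        for name in cov_names:
            values[name] = spec.level_labels(name)[draws[name][i]]
        patients.append((f"P{rank + 1:0{width}d}", values, None, None))
    return TrialPopulation(schema, tuple(patients), spec.n_arms)


def true_rate_table(spec: TrialSpec) -> StratumRateTable:
    """Ground-truth per-(stratum, arm) success rates implied by the outcome model.

    Strata enumerate the full cross-classification of the non-center
    covariates (the center never carries a prognostic effect in this model).
    Rates outside [0, 1] after adding effects are clamped with a warning.
    """
    schema = spec.schema()
    subset = schema.non_center_names()
    arms = ("A", "B", "C", "D")[: spec.n_arms]

    strata: list[tuple[str, ...]] = [()]
    for name in subset:
        strata = [s + (lvl,) for s in strata for lvl in spec.level_labels(name)]

    rates: dict[tuple[tuple[str, ...], str], float] = {}
    clamped = False
    for stratum in strata:
        base = spec.baseline_rate
        if spec.stratum_effects:
            for j, name in enumerate(subset):
                base += spec.stratum_effects.get(name, {}).get(stratum[j], 0.0)
        for a, arm in enumerate(arms):
            p = base + spec.arm_effects[a]
            if p < 0.0 or p > 1.0:
                clamped = True
                p = min(max(p, 0.0), 1.0)
            rates[(stratum, arm)] = p
    if clamped:
        warnings.warn(
            "outcome-model probabilities outside [0, 1] were clamped",
            stacklevel=2,
        )
    return StratumRateTable(covariate_subset=subset, rates=rates)


def example_allocation() -> tuple[TrialPopulation, AllocationResult]:
    """A 100-patient worked example: 3 centers x smoking status, 2 arms.

    The per-stratum arm counts are fixed (not random) and give arm totals of
    50/50, per-level margins that differ by at most one patient, yet sizable
    within-stratum differences — a compact illustration of how the three
    imbalance measures can disagree. Used throughout the docs and tests.
    """
    # (center, smoker) -> (n in arm A, n in arm B)
    cells = {
        ("C1", "non-smoker"): (7, 3),
        ("C1", "smoker"): (8, 12),
        ("C2", "non-smoker"): (3, 6),
        ("C2", "smoker"): (8, 6),
        ("C3", "non-smoker"): (9, 10),
        ("C3", "smoker"): (15, 13),
    }
    schema = CovariateSchema(
        (
            ("center", ("C1", "C2", "C3")),
            ("smoker", ("non-smoker", "smoker")),
        ),
        center_covariate="center",
    )
    patients = []
    arm_of = {}
    i = 0
    for (center, smoker), (n_a, n_b) in cells.items():
        for arm, count in (("A", n_a), ("B", n_b)):
            for _ in range(count):
                i += 1
                pid = f"P{i:03d}"
                patients.append((pid, {"center": center, "smoker": smoker}, None, arm))
                arm_of[pid] = arm
    population = TrialPopulation(schema, tuple(patients), n_arms=2)
    allocation = AllocationResult(
        arm_of=arm_of,
        method="SPBR",
        parameters={"fixed_example": True},
        seed=0,
        inclusion_order=population.ids,
    )
    return population, allocation
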