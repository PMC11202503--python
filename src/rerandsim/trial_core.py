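"""Domain types for trial populations, allocations and their on-disk formats.

The central objects are :class:`TrialPopulation` (an ordered list of patients
with categorical stratification covariates) and :class:`AllocationResult`
(an arm label per patient plus full provenance of how it was produced).
Patient tables are plain CSV, one row per patient in inclusion order;
covariate values are opaque strings, never coerced to numbers, because
stratification levels are labels rather than quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

DEFAULT_ARM_LABELS = ("A", "B", "C", "D")


class ValidationError(ValueError):
    """Raised when an input table, config or domain object is malformed."""


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered stratification covariates and their categorical levels.

    Parameters
    ----------
    covariates
        Ordered ``(name, levels)`` pairs. Every covariate needs at least two
        levels; names and within-covariate level labels must be unique.
    center_covariate
        Optional name of the covariate that represents the recruiting center.
        Centers are ordinary stratification variables for allocation purposes
        but are excluded by default when estimating per-stratum success rates,
        because many small centers leave too few patients per cell.
    """

    covariates: tuple[tuple[str, tuple[str, ...]], ...]
    center_covariate: str | None = None

    def __post_init__(self) -> None:
        names = [name for name, _ in self.covariates]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate covariate names in {names}")
        for name, levels in self.covariates:
            if len(levels) < 2:
                raise ValidationError(
                    f"covariate {name!r} has {len(levels)} level(s); need >= 2"
                )
            if len(set(levels)) != len(levels):
                raise ValidationError(f"covariate {name!r} has duplicate levels")
        if self.center_covariate is not None and self.center_covariate not in names:
            raise ValidationError(
                f"center_covariate {self.center_covariate!r} is not a covariate"
            )

    @classmethod
    def from_dict(
        cls,
        covariates: Mapping[str, Sequence[str]],
        center_covariate: str | None = None,
    ) -> "CovariateSchema":
        return cls(
            tuple((name, tuple(levels)) for name, levels in covariates.items()),
            center_covariate,
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.covariates)

    def levels_of(self, name: str) -> tuple[str, ...]:
        for cov, levels in self.covariates:
            if cov == name:
                return levels
        raise KeyError(name)

    def non_center_names(self) -> tuple[str, ...]:
        """Covariate names excluding the center variable (if flagged)."""
        return tuple(n for n in self.names if n != self.center_covariate)


@dataclass(frozen=True)
class TrialPopulation:
    """An ordered patient roster with categorical covariates.

    The order of ``patients`` is the inclusion order. Each patient record is
    ``(id, {covariate: level}, outcome, original_arm)`` where outcome is an
    optional 0/1 endpoint and original_arm the arm observed in the source
    trial, both ``None`` when absent.
    """

    schema: CovariateSchema
    patients: tuple[tuple[str, Mapping[str, str], int | None, str | None], ...]
    n_arms: int = 2

    def __post_init__(self) -> None:
        if self.n_arms not in (2, 3, 4):
            raise ValidationError(f"n_arms must be 2, 3 or 4, got {self.n_arms}")
        seen: set[str] = set()
        for row, (pid, values, outcome, _arm) in enumerate(self.patients):
            if pid in seen:
                raise ValidationError(f"duplicate patient id {pid!r} at row {row}")
            seen.add(pid)
            for name, levels in self.schema.covariates:
                if name not in values:
                    raise ValidationError(
                        f"row {row} (id {pid!r}): missing covariate {name!r}"
                    )
                if values[name] not in levels:
                    raise ValidationError(
                        f"row {row} (id {pid!r}): level {values[name]!r} not "
                        f"declared for covariate {name!r}"
                    )
            if outcome is not None and outcome not in (0, 1):
                raise ValidationError(
                    f"row {row} (id {pid!r}): outcome must be 0/1, got {outcome!r}"
                )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def arms(self) -> tuple[str, ...]:
        return DEFAULT_ARM_LABELS[: self.n_arms]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.patients)

    def values_of(self, pid: str) -> Mapping[str, str]:
        for p in self.patients:
            if p[0] == pid:
                return p[1]
        raise KeyError(pid)

    def to_frame(self) -> pd.DataFrame:
        """Patients as a DataFrame indexed by inclusion order."""
        rows = []
        for pid, values, outcome, arm in self.patients:
            row = {"id": pid, **{n: values[n] for n in self.schema.names}}
            if arm is not None:
                row["arm"] = arm
            if outcome is not None:
                row["outcome"] = outcome
            rows.append(row)
        return pd.DataFrame(rows)

    def stratum_of(self, pid: str, subset: Sequence[str] | None = None) -> tuple[str, ...]:
        """The patient's level combination over ``subset`` (default: all covariates)."""
        names = tuple(subset) if subset is not None else self.schema.names
        values = self.values_of(pid)
        return tuple(values[n] for n in names)

    def reordered(self, order: Sequence[str]) -> "TrialPopulation":
        """The same population with inclusion order replaced by ``order``."""
        if sorted(order) != sorted(self.ids):
            raise ValidationError("reorder must be a permutation of patient ids")
        by_id = {p[0]: p for p in self.patients}
        return TrialPopulation(self.schema, tuple(by_id[i] for i in order), self.n_arms)


@dataclass(frozen=True)
class AllocationResult:
    """Arm labels per patient plus the provenance needed to replay the run."""

    arm_of: Mapping[str, str]
    method: str  # "SPBR" or "MIN"
    parameters: Mapping[str, object]
    seed: int
    inclusion_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.method not in ("SPBR", "MIN"):
            raise ValidationError(f"unknown method {self.method!r}")
        if set(self.arm_of) != set(self.inclusion_order):
            raise ValidationError("arm_of and inclusion_order cover different patients")

    def arm_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for arm in self.arm_of.values():
            counts[arm] = counts.get(arm, 0) + 1
        return counts


@dataclass(frozen=True)
class ImbalanceReport:
    """The three imbalance measures: total, marginal and within-stratum.

    Total is the spread of the arm totals; marginal sums the per-level spread
    over every covariate margin; within-stratum sums the spread inside every
    occupied full cross-classification cell. All three are patient counts.
    """

    total: int
    marginal: int
    within_stratum: int

    def __post_init__(self) -> None:
        for name in ("total", "marginal", "within_stratum"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "marginal": self.marginal,
            "within_stratum": self.within_stratum,
        }


@dataclass(frozen=True)
class StratumRateTable:
    """Per-(stratum, arm) success probabilities used to regenerate endpoints.

    Keys are ``(stratum levels tuple, arm label)``; strata are combinations of
    levels over ``covariate_subset`` (by convention every stratification
    variable except the center). ``empty_cells`` records (stratum, arm) pairs
    that had no patients when the table was estimated from data.
    """

    covariate_subset: tuple[str, ...]
    rates: Mapping[tuple[tuple[str, ...], str], float]
    empty_cells: frozenset[tuple[tuple[str, ...], str]] = frozenset()

    def __post_init__(self) -> None:
        for key, p in self.rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"rate {p} for {key} outside [0, 1]")

    def rate(self, stratum: tuple[str, ...], arm: str) -> float | None:
        return self.rates.get((stratum, arm))

    def arm_marginal(self, arm: str) -> float:
        """Unweighted mean rate over the arm's non-empty strata (fallback rate)."""
        vals = [p for (s, a), p in self.rates.items() if a == arm]
        if not vals:
            raise KeyError(f"no rates for arm {arm!r}")
        return float(sum(vals) / len(vals))


# ---------------------------------------------------------------------------
# CSV / config I/O


def read_population(
    path: str | Path,
    schema: CovariateSchema | None = None,
    n_arms: int = 2,
) -> TrialPopulation:
    """Read a patient table (CSV, one row per patient in inclusion order).

    The file must have an ``id`` column; every other non-reserved column is a
    covariate. Optional ``arm`` and ``outcome`` columns carry the originally
    observed allocation and binary endpoint. When ``schema`` is None the
    covariate levels are inferred from the observed values (sorted
    lexicographically) and no covariate is flagged as the center.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    if "id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'id'")
    reserved = {"id", "arm", "outcome"}
    cov_cols = [c for c in df.columns if c not in reserved]
    if schema is None:
        schema = CovariateSchema(
            tuple((c, tuple(sorted(df[c].dropna().unique()))) for c in cov_cols)
        )
    else:
        for name in schema.names:
            if name not in df.columns:
                raise ValidationError(f"{path}: missing covariate column {name!r}")
    patients = []
    for row, rec in enumerate(df.to_dict("records")):
        pid = rec["id"]
        if pd.isna(pid):
            raise ValidationError(f"{path}: row {row}: missing id")
        values = {}
        for name in schema.names:
            v = rec[name]
            if pd.isna(v):
                raise ValidationError(f"{path}: row {row} (id {pid!r}): missing {name!r}")
            values[name] = str(v)
        outcome = rec.get("outcome")
        outcome = None if outcome is None or pd.isna(outcome) else int(outcome)
        arm = rec.get("arm")
        arm = None if arm is None or pd.isna(arm) else str(arm)
        patients.append((str(pid), values, outcome, arm))
    return TrialPopulation(schema, tuple(patients), n_arms)


def write_population(population: TrialPopulation, path: str | Path) -> None:
    """Write a patient table readable back by :func:`read_population`."""
    population.to_frame().to_csv(path, index=False)


def write_allocation(result: AllocationResult, path: str | Path) -> None:
    """Write an allocation as CSV (id, arm) with a provenance comment header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method: {result.method}\n")
        fh.write(f"# parameters: {json.dumps(dict(result.parameters), sort_keys=True)}\n")
        fh.write(f"# seed: {result.seed}\n")
        fh.write("id,arm\n")
        for pid in result.inclusion_order:
            fh.write(f"{pid},{result.arm_of[pid]}\n")


def read_allocation(path: str | Path) -> AllocationResult:
    """Read an allocation written by :func:`write_allocation`."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# ") and ":" in line:
            key, _, val = line[2:].partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, dtype=str, comment="#")
    order = tuple(df["id"])
    return AllocationResult(
        arm_of=dict(zip(df["id"], df["arm"])),
        method=meta.get("method", "SPBR"),
        parameters=json.loads(meta.get("parameters", "{}")),
        seed=int(meta.get("seed", 0)),
        inclusion_order=order,
    )


def read_config(path: str | Path) -> dict:
    """Read a trial-design config (YAML or JSON) into a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def population_from_frame(
    df: pd.DataFrame,
    schema: CovariateSchema | None = None,
    n_arms: int = 2,
) -> TrialPopulation:
    """Build a population from an in-memory DataFrame (same layout as the CSV)."""
    reserved = {"id", "arm", "outcome"}
    cov_cols = [c for c in df.columns if c not in reserved]
    if schema is None:
        schema = CovariateSchema(
            tuple((c, tuple(sorted(df[c].astype(str).unique()))) for c in cov_cols)
        )
    patients = []
    for rec in df.to_dict("records"):
        values = {n: str(rec[n]) for n in schema.names}
        outcome = rec.get("outcome")
        outcome = None if outcome is None or pd.isna(outcome) else int(outcome)
        arm = rec.get("arm")
        arm = None if arm is None or (isinstance(arm, float) and pd.isna(arm)) else str(arm)
        patients.append((str(rec["id"]), values, outcome, arm))
    return TrialPopulation(schema, tuple(patients), n_arms)
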