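"""Docking-affinity matrix triage.

Affinities are binding free energies in kcal/mol; more negative means
stronger predicted binding.  The pass criterion "approximately equal or
above -7 kcal/mol" is operationalized algebraically as
``affinity <= threshold`` with inclusive equality: "above" in the source
wording refers to binding strength, not to the signed number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import load_table, write_table

__all__ = [
    "DockingMatrix",
    "DockingFilterConfig",
    "EngineComparison",
    "count_passing_targets",
    "filter_candidates",
    "rank_by_aggregate",
    "compare_engines",
]


@dataclass
class DockingMatrix:
    """Drugs x targets affinity grid (kcal/mol) with an engine label.

    ``values`` is a DataFrame indexed by drug id with target-id columns.
    Missing cells are NaN (explicitly absent), never silently zero.
    """

    values: pd.DataFrame
    engine: str = "unknown"

    def __post_init__(self):
        with np.errstate(invalid="ignore"):
            arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("affinity grid contains non-finite (inf) values")
        self.values = self.values.astype(float)

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def targets(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, engine: str = "unknown") -> "DockingMatrix":
        df = load_table(path)
        df = df.set_index(df.columns[0])
        df.index.name = "Drug"
        return cls(values=df, engine=engine)

    def to_tsv(self, path: str | Path) -> Path:
        return write_table(self.values.reset_index(), path)


@dataclass(frozen=True)
class DockingFilterConfig:
    """Pass rule: affinity <= threshold on each of select_targets."""

    threshold: float = -7.0
    select_targets: tuple[str, ...] = ("APP", "ZEB2", "PAX6", "ETV6", "ST18")
    min_targets_passing: int = 1

    def __post_init__(self):
        if self.min_targets_passing > len(self.select_targets):
            raise ValueError(
                "min_targets_passing exceeds number of selected targets"
            )


@dataclass
class EngineComparison:
    """Cross-engine concordance summary.

    ``deltas`` is b - a over the shared grid; ``rho`` is the per-target
    Spearman rank correlation over shared drugs (NaN where fewer than 3
    shared finite pairs exist, with the target listed in
    ``undefined_targets``).
    """

    deltas: pd.DataFrame
    rho: pd.Series
    concordant_top_k: bool
    top_k: int
    undefined_targets: list[str] = field(default_factory=list)


def count_passing_targets(
    drug_row: Sequence[float] | pd.Series, config: DockingFilterConfig = DockingFilterConfig()
) -> int:
    """Number of affinities at or below the threshold (NaN cells ignored with a warning)."""
    arr = np.asarray(drug_row, dtype=float)
    n_absent = int(np.isnan(arr).sum())
    if n_absent:
        warnings.warn(f"{n_absent} absent affinity cell(s) ignored", stacklevel=2)
    return int(np.sum(arr[~np.isnan(arr)] <= config.threshold))


def filter_candidates(
    matrix: DockingMatrix, config: DockingFilterConfig = DockingFilterConfig()
) -> list[str]:
    """Drugs passing the threshold on >= min_targets_passing selected targets, in input order."""
    unknown = [t for t in config.select_targets if t not in matrix.values.columns]
    if unknown:
        raise KeyError(f"unknown target id(s): {', '.join(unknown)}")
    sub = matrix.values[list(config.select_targets)]
    passing = []
    for drug, row in sub.iterrows():
        if count_passing_targets(row, config) >= config.min_targets_passing:
            passing.append(drug)
    return passing


def rank_by_aggregate(matrix: DockingMatrix, axis: str = "drugs") -> list[str]:
    """Order ids by total binding strength (ascending algebraic sum of affinities).

    ``axis="drugs"`` sums each drug's row over all targets; ``axis="targets"``
    sums each target's column over all drugs.  More negative totals (stronger
    aggregate binding) come first; ties break lexicographically.
    """
    if axis == "drugs":
        sums = matrix.values.sum(axis=1)
    elif axis == "targets":
        sums = matrix.values.sum(axis=0)
    else:
        raise ValueError("axis must be 'drugs' or 'targets'")
    order = sorted(sums.index, key=lambda k: (sums[k], k))
    return list(order)


def compare_engines(
    a: DockingMatrix, b: DockingMatrix, top_k: int = 3
) -> EngineComparison:
    """Compare two engines on their shared drug/target grid.

    Per-target Spearman rho over shared drugs; per-pair deltas (b - a);
    ``concordant_top_k`` is True iff for every target the two engines' top-k
    drug sets (strongest binding first) share at least ceil(k/2) members.
    """
    drugs = [d for d in a.values.index if d in set(b.values.index)]
    targets = [t for t in a.values.columns if t in set(b.values.columns)]
    if not drugs or not targets:
        raise ValueError("no shared drugs/targets between engines")
    av = a.values.loc[drugs, targets]
    bv = b.values.loc[drugs, targets]
    deltas = bv - av
    rho = {}
    undefined = []
    concordant = True
    for t in targets:
        pair = pd.concat([av[t], bv[t]], axis=1).dropna()
        if len(pair) < 3:
            rho[t] = math.nan
            undefined.append(t)
            continue
        if pair.iloc[:, 0].nunique() == 1 or pair.iloc[:, 1].nunique() == 1:
            rho[t] = math.nan
            undefined.append(t)
            continue
        rho[t] = float(stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic)
        k = min(top_k, len(pair))
        top_a = set(pair.iloc[:, 0].nsmallest(k).index)
        top_b = set(pair.iloc[:, 1].nsmallest(k).index)
        if len(top_a & top_b) < math.ceil(k / 2):
            concordant = False
    return EngineComparison(
        deltas=deltas,
        rho=pd.Series(rho),
        concordant_top_k=concordant,
        top_k=top_k,
        undefined_targets=undefined,
    )
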