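"""Gated, ranked candidate reports.

Combines per-complex MD stability metrics with per-drug CNS profiles:
pharmacokinetic gates (permeability, efflux, optionally the safety window)
exclude drugs with recorded reasons; survivors are stably sorted by the
policy's ordered metric keys.  Every input complex appears exactly once in
the report, either ranked or excluded with at least one reason.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import write_table

__all__ = [
    "RankingPolicy",
    "CandidateReport",
    "apply_gates",
    "rank_candidates",
    "build_report",
    "parse_report",
    "validate_report_json",
    "SORT_KEY_COLUMNS",
]

# sort key -> (metric column, ascending?)
SORT_KEY_COLUMNS = {
    "protein_rmsd:asc": ("ProteinRMSDMean", True),
    "hbond_count:desc": ("HBondMean", False),
    "logbb:desc": ("logBB", False),
}


@dataclass(frozen=True)
class RankingPolicy:
    require_permeable: bool = True
    exclude_pgp: bool = True
    require_safety_window: bool = False
    sort_keys: tuple[str, ...] = ("protein_rmsd:asc", "hbond_count:desc", "logbb:desc")

    def __post_init__(self):
        if not self.sort_keys:
            raise ValueError("sort_keys must be non-empty")
        unknown = [k for k in self.sort_keys if k not in SORT_KEY_COLUMNS]
        if unknown:
            raise ValueError(
                f"unknown sort key(s): {', '.join(unknown)}; "
                f"choose from {sorted(SORT_KEY_COLUMNS)}"
            )

    def to_dict(self) -> dict:
        return {
            "require_permeable": self.require_permeable,
            "exclude_pgp": self.exclude_pgp,
            "require_safety_window": self.require_safety_window,
            "sort_keys": list(self.sort_keys),
        }


@dataclass
class CandidateReport:
    """Ranked candidates plus the exclusion log; together they cover every input complex."""

    ranked: pd.DataFrame
    exclusions: pd.DataFrame
    policy: RankingPolicy


def apply_gates(
    profiles: pd.DataFrame, policy: RankingPolicy = RankingPolicy()
) -> tuple[set[str], dict[str, list[str]]]:
    """Admit drugs through the pharmacokinetic gates.

    ``profiles`` must carry computed columns Drug, Permeable, PgpSubstrate
    and (if the safety gate is on) SafetyWindow.  Returns the admitted drug
    set and a reason log for every rejected drug.
    """
    admitted: set[str] = set()
    reasons: dict[str, list[str]] = {}
    for _, row in profiles.iterrows():
        drug = str(row["Drug"])
        why = []
        if policy.require_permeable and not bool(row["Permeable"]):
            why.append("not BBB permeable (computed logBB below the Moderate bin)")
        if policy.exclude_pgp and bool(row["PgpSubstrate"]):
            why.append("predicted P-gp efflux substrate")
        if policy.require_safety_window and not bool(row["SafetyWindow"]):
            why.append("outside the lipophilicity safety window")
        if why:
            reasons[drug] = why
        else:
            admitted.add(drug)
    return admitted, reasons


def rank_candidates(
    md: pd.DataFrame,
    profiles: pd.DataFrame,
    policy: RankingPolicy = RankingPolicy(),
) -> CandidateReport:
    """Rank drug-target complexes after gating.

    ``md`` rows (columns Complex, Drug, Target, ProteinRMSDMean, HBondMean,
    ...) are merged with computed CNS profiles by drug; a complex whose drug
    has no profile raises.  Admitted complexes are stably sorted by the
    policy's keys with NaN metrics last and lexicographic complex-id
    tie-break; rejected complexes land in the exclusion log.
    """
    have = set(profiles["Drug"].astype(str))
    missing = sorted(set(md["Drug"].astype(str)) - have)
    if missing:
        raise KeyError(f"no CNS profile for drug(s): {', '.join(missing)}")
    for key in policy.sort_keys:
        col = SORT_KEY_COLUMNS[key][0]
        if col not in md.columns and col != "logBB":
            raise KeyError(f"metric column {col!r} (sort key {key!r}) missing from MD table")

    admitted, reasons = apply_gates(profiles, policy)
    merged = md.merge(
        profiles[["Drug", "logBB", "Bin", "PgpSubstrate", "SafetyWindow", "Permeable"]],
        on="Drug",
        how="left",
        suffixes=("_printed", ""),
    )
    is_admitted = merged["Drug"].astype(str).isin(admitted)
    excluded = merged[~is_admitted].copy()
    excluded["Reasons"] = [
        "; ".join(reasons[str(d)]) for d in excluded["Drug"]
    ]
    kept = merged[is_admitted].copy()
    if len(kept):
        sort_cols, ascending = [], []
        for key in policy.sort_keys:
            col, asc = SORT_KEY_COLUMNS[key]
            sort_cols.append(col)
            ascending.append(asc)
        sort_cols.append("Complex")
        ascending.append(True)
        kept = kept.sort_values(
            by=sort_cols, ascending=ascending, kind="stable", na_position="last"
        ).reset_index(drop=True)
        kept.insert(0, "Rank", np.arange(1, len(kept) + 1))
    else:
        kept.insert(0, "Rank", pd.Series(dtype=int))
    return CandidateReport(
        ranked=kept.reset_index(drop=True),
        exclusions=excluded.reset_index(drop=True),
        policy=policy,
    )


def _clean(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def build_report(report: CandidateReport, fmt: str = "json") -> str:
    """Serialize a report to JSON or TSV text; JSON round-trips losslessly."""
    if fmt == "json":
        obj = {
            "policy": report.policy.to_dict(),
            "candidates": [
                {
                    "complex": str(r["Complex"]),
                    "drug": str(r["Drug"]),
                    "target": str(r["Target"]),
                    "rank": int(r["Rank"]),
                    "metrics": {
                        k: _clean(v)
                        for k, v in r.items()
                        if k not in ("Complex", "Drug", "Target", "Rank")
                    },
                }
                for _, r in report.ranked.iterrows()
            ],
            "exclusions": [
                {
                    "complex": str(r["Complex"]),
                    "drug": str(r["Drug"]),
                    "reasons": str(r["Reasons"]).split("; "),
                }
                for _, r in report.exclusions.iterrows()
            ],
        }
        return json.dumps(obj, indent=2, sort_keys=True)
    if fmt == "tsv":
        ranked = report.ranked.copy()
        ranked["Status"] = "ranked"
        ranked["Reasons"] = ""
        excl = report.exclusions.copy()
        excl["Status"] = "excluded"
        excl["Rank"] = -1
        combined = pd.concat([ranked, excl], ignore_index=True)
        return combined.to_csv(sep="\t", index=False)
    raise ValueError(f"unknown report format: {fmt!r}")


def parse_report(text: str) -> dict:
    """Parse a JSON report produced by :func:`build_report`."""
    obj = json.loads(text)
    validate_report_json(obj)
    return obj


def validate_report_json(obj: Mapping) -> None:
    """Structural validation against the shipped report schema (minimal checker)."""
    from .fixtures import load_report_schema

    schema = load_report_schema()
    for key in schema["required"]:
        if key not in obj:
            raise ValueError(f"report missing required key {key!r}")
    if not isinstance(obj["candidates"], list) or not isinstance(obj["exclusions"], list):
        raise ValueError("candidates and exclusions must be arrays")
    for cand in obj["candidates"]:
        for key in ("complex", "drug", "target", "rank"):
            if key not in cand:
                raise ValueError(f"candidate missing {key!r}")
        if not isinstance(cand["rank"], int) or cand["rank"] < 1:
            raise ValueError("candidate rank must be a positive integer")
    for excl in obj["exclusions"]:
        for key in ("complex", "drug", "reasons"):
            if key not in excl:
                raise ValueError(f"exclusion missing {key!r}")
        if not excl["reasons"]:
            raise ValueError("exclusion must carry at least one reason")
    pol = obj["policy"]
    for key in ("require_permeable", "exclude_pgp", "require_safety_window", "sort_keys"):
        if key not in pol:
            raise ValueError(f"policy missing {key!r}")
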