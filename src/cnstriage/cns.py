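"""Blood-brain-barrier and CNS suitability profiling.

Implements the linear empirical logBB model (Clark-type: a function of LogP
and TPSA only), the five permeability bins, the P-glycoprotein efflux
threshold rule, and the lipophilicity safety/toxicity windows, composed into
a per-drug :class:`CNSProfile`.

Conventions
-----------
* Bin boundaries are inclusive on the upper category (logBB = 0.7 is
  "Very high", -0.3 is "Moderate", -0.7 is "Low").
* The efflux rule is a conjunction of strict inequalities.
* Window bounds are inclusive.
* Reported logBB is rounded half-away-from-zero at 2 decimals; the raw
  value is kept internally and used for classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ClarkModel",
    "PermeabilityBins",
    "PgpRule",
    "CNSWindows",
    "DescriptorRecord",
    "CNSProfile",
    "compute_logbb",
    "classify_logbb",
    "predict_pgp",
    "window_membership",
    "profile_drug",
    "profile_table",
    "recompute_descriptors",
    "round_half_away",
    "PERMEABLE_BINS",
]

PERMEABLE_BINS = frozenset({"Very high", "High", "Moderate"})


@dataclass(frozen=True)
class ClarkModel:
    """Linear logBB model: logbb = logp_coeff*LogP + tpsa_coeff*TPSA + intercept."""

    logp_coeff: float = 0.152
    tpsa_coeff: float = -0.0148
    intercept: float = 0.139


@dataclass(frozen=True)
class PermeabilityBins:
    """Cut points partitioning the logBB line into five categories."""

    very_high: float = 0.7
    high: float = 0.3
    moderate: float = -0.3
    low: float = -0.7

    def __post_init__(self):
        if not (self.very_high > self.high > self.moderate > self.low):
            raise ValueError("bin boundaries must be strictly decreasing")


@dataclass(frozen=True)
class PgpRule:
    """Efflux-liability rule: LogP strictly above logp_min AND TPSA strictly below tpsa_max."""

    logp_min: float = 4.0
    tpsa_max: float = 75.0


@dataclass(frozen=True)
class CNSWindows:
    """Inclusive descriptor windows for safety and toxicity favourability."""

    safety_logp: tuple[float, float] = (3.0, 4.0)
    safety_tpsa: tuple[float, float] = (60.0, 75.0)
    tox_logd: tuple[float, float] = (1.0, 3.0)
    tox_logp: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self):
        for lo, hi in (self.safety_logp, self.safety_tpsa, self.tox_logd, self.tox_logp):
            if lo > hi:
                raise ValueError(f"window bounds out of order: ({lo}, {hi})")


@dataclass(frozen=True)
class DescriptorRecord:
    """Per-drug physicochemical descriptors.

    ``provenance`` distinguishes fixture values ("fixture") from values
    recomputed from structure ("computed"); computed values never replace
    fixture values implicitly.
    """

    drug: str
    logp: float
    tpsa: float
    mw: float = math.nan
    pka: float = math.nan
    logd: float = math.nan
    provenance: str = "fixture"

    def __post_init__(self):
        if not math.isnan(self.tpsa) and self.tpsa < 0:
            raise ValueError(f"{self.drug}: TPSA must be >= 0")
        if not math.isnan(self.mw) and self.mw <= 0:
            raise ValueError(f"{self.drug}: MW must be > 0")


@dataclass(frozen=True)
class CNSProfile:
    drug: str
    logbb: float
    logbb_2dp: float
    bin: str
    pgp_substrate: bool
    in_safety_window: bool
    in_tox_window: bool
    bbb_permeable: bool
    provenance: str = "computed"


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.005 -> 0.01, -0.005 -> -0.01)."""
    factor = 10.0 ** ndigits
    scaled = value * factor
    # nudge against binary representation error before the half-step
    return math.copysign(math.floor(abs(scaled) + 0.5 + 1e-9 * (abs(scaled) > 0)), scaled) / factor


def compute_logbb(logp: float, tpsa: float, model: ClarkModel = ClarkModel()) -> float:
    """Evaluate the linear logBB model; raises on non-finite input."""
    if not (math.isfinite(logp) and math.isfinite(tpsa)):
        raise ValueError("logp and tpsa must be finite")
    return model.logp_coeff * logp + model.tpsa_coeff * tpsa + model.intercept


def classify_logbb(logbb: float, bins: PermeabilityBins = PermeabilityBins()) -> str:
    """Map a logBB value to its permeability category (upper-inclusive bins)."""
    if not math.isfinite(logbb):
        raise ValueError("logbb must be finite")
    if logbb >= bins.very_high:
        return "Very high"
    if logbb >= bins.high:
        return "High"
    if logbb >= bins.moderate:
        return "Moderate"
    if logbb >= bins.low:
        return "Low"
    return "Very low"


def predict_pgp(logp: float, tpsa: float, rule: PgpRule = PgpRule()) -> bool:
    """True iff both strict conditions hold (LogP > logp_min and TPSA < tpsa_max)."""
    if not (math.isfinite(logp) and math.isfinite(tpsa)):
        raise ValueError("logp and tpsa must be finite")
    return logp > rule.logp_min and tpsa < rule.tpsa_max


def _in(value: float, window: tuple[float, float]) -> bool:
    return window[0] <= value <= window[1]


def window_membership(
    record: DescriptorRecord, windows: CNSWindows = CNSWindows()
) -> tuple[bool, bool]:
    """Return (safety flag, toxicity-favourable flag) for a descriptor record.

    Safety requires LogP and TPSA both inside their windows; toxicity
    favourability requires LogD and LogP inside theirs.  All inclusive.
    """
    safety = _in(record.logp, windows.safety_logp) and _in(record.tpsa, windows.safety_tpsa)
    tox = _in(record.logd, windows.tox_logd) and _in(record.logp, windows.tox_logp)
    return safety, tox


def profile_drug(
    record: DescriptorRecord,
    model: ClarkModel = ClarkModel(),
    bins: PermeabilityBins = PermeabilityBins(),
    rule: PgpRule = PgpRule(),
    windows: CNSWindows = CNSWindows(),
) -> CNSProfile:
    """Compose logBB, binning, efflux and window checks into one profile.

    ``bbb_permeable`` is True iff the computed bin is Moderate or better
    (logBB >= -0.3); this is the explicit rule used for all computed flags.
    """
    for name in ("logp", "tpsa", "logd"):
        if not math.isfinite(getattr(record, name)):
            raise ValueError(f"{record.drug}: missing or non-finite field '{name}'")
    logbb = compute_logbb(record.logp, record.tpsa, model)
    category = classify_logbb(logbb, bins)
    safety, tox = window_membership(record, windows)
    return CNSProfile(
        drug=record.drug,
        logbb=logbb,
        logbb_2dp=round_half_away(logbb, 2),
        bin=category,
        pgp_substrate=predict_pgp(record.logp, record.tpsa, rule),
        in_safety_window=safety,
        in_tox_window=tox,
        bbb_permeable=category in PERMEABLE_BINS,
    )


def profile_table(
    descriptors: pd.DataFrame,
    model: ClarkModel = ClarkModel(),
    bins: PermeabilityBins = PermeabilityBins(),
    rule: PgpRule = PgpRule(),
    windows: CNSWindows = CNSWindows(),
) -> pd.DataFrame:
    """Profile every row of a descriptor table (columns Drug, LogP, TPSA, LogD, ...).

    Output row order follows input; values are computed, never copied from
    any printed flag columns that may also be present.
    """
    rows = []
    for _, r in descriptors.iterrows():
        rec = DescriptorRecord(
            drug=str(r["Drug"]),
            logp=float(r["LogP"]),
            tpsa=float(r["TPSA"]),
            mw=float(r["MW"]) if "MW" in r else math.nan,
            pka=float(r["pKa"]) if "pKa" in r else math.nan,
            logd=float(r["LogD"]) if "LogD" in r else math.nan,
        )
        p = profile_drug(rec, model, bins, rule, windows)
        rows.append(
            {
                "Drug": p.drug,
                "logBB": p.logbb,
                "logBB2dp": p.logbb_2dp,
                "Bin": p.bin,
                "PgpSubstrate": int(p.pgp_substrate),
                "SafetyWindow": int(p.in_safety_window),
                "ToxWindow": int(p.in_tox_window),
                "Permeable": int(p.bbb_permeable),
            }
        )
    return pd.DataFrame(rows)


def recompute_descriptors(smiles: str, drug: str = "") -> DescriptorRecord:
    """Compute LogP (Crippen) and TPSA (Ertl) from a SMILES string via RDKit.

    Optional path: LogD and pKa are not derivable from topology alone and
    are left NaN.  The returned record carries provenance "computed" and is
    never used to overwrite fixture descriptors implicitly.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return DescriptorRecord(
        drug=drug or smiles,
        logp=Crippen.MolLogP(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        mw=Descriptors.MolWt(mol),
        provenance="computed",
    )
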