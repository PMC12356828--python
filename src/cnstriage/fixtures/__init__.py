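"""Packaged reference tables (as-printed provenance).

Three small fixtures ship with the package:

* ``table1_docking.tsv`` — 12 drugs x 5 targets binding affinities (kcal/mol).
* ``table2_descriptors.tsv`` — per-drug physicochemical descriptors plus the
  printed efflux/permeability flags, logBB and its interpretation.
* ``md_stability.tsv`` — per-complex trajectory stability summary
  (protein RMSD mean/SD, H-bond mean/SD, SASA, logBB).

Values are stored exactly as printed in their source tables; downstream
code recomputes derived quantities and never silently overwrites these.
Known quirk kept verbatim: Olaparib's printed BBB-permeability flag is 1
although its logBB (-0.78) falls below every permeability bin a
logBB-threshold rule would admit; computed flags therefore differ for that
row by design.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from ..io import load_table

__all__ = [
    "load_table1",
    "load_table2",
    "load_md_summary",
    "load_report_schema",
    "fixture_path",
    "fixture_checksum",
]

_TABLE1_COLUMNS = ["Drug", "APP", "PAX6", "ZEB2", "ETV6", "ST18"]
_TABLE2_COLUMNS = [
    "Drug", "LogP", "TPSA", "MW", "pKa", "LogD",
    "PgpEfflux", "BBBPermeability", "logBB", "logBBInterpretation",
    "DERTargetsAbove7", "StudiedInAD",
]
_MD_COLUMNS = [
    "Complex", "Drug", "Target",
    "ProteinRMSDMean", "ProteinRMSDSD", "HBondMean", "HBondSD",
    "ProteinSASA", "LigandSASA", "logBB",
]


def fixture_path(name: str) -> Path:
    return Path(str(resources.files(__package__).joinpath(name)))


def fixture_checksum(name: str) -> str:
    return hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()


def load_table1() -> pd.DataFrame:
    """Docking-affinity matrix fixture (drugs as rows, targets as columns)."""
    return load_table(fixture_path("table1_docking.tsv"), required=_TABLE1_COLUMNS)


def load_table2() -> pd.DataFrame:
    """Descriptor fixture with printed flags; 12 drug rows."""
    return load_table(fixture_path("table2_descriptors.tsv"), required=_TABLE2_COLUMNS)


def load_md_summary() -> pd.DataFrame:
    """Per-complex MD stability summary fixture (7 complexes)."""
    return load_table(fixture_path("md_stability.tsv"), required=_MD_COLUMNS)


def load_report_schema() -> dict:
    return json.loads(fixture_path("report_schema.json").read_text())
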