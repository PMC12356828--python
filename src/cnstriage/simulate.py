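"""Seeded synthetic inputs for every pipeline stage.

Generators produce data with exactly the statistical structure the
downstream stages assume: activity matrices on the z-score scale with
planted shifted regulators, count tables with exact low-quality cell
fractions, docking grids with planted strong binders, and geometric
trajectories with optional rigid drift, per-atom jitter and a scripted
ligand escape.  Identical spec + seed always reproduces identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .docking import DockingMatrix
from .regulators import ActivityMatrix
from .trajectory import BONDI_RADII, DEFAULT_RADIUS, AtomRecord, Trajectory

__all__ = [
    "ActivitySimSpec",
    "CountSimSpec",
    "DockingSimSpec",
    "TrajectorySimSpec",
    "generate_activity_matrix",
    "generate_count_matrix",
    "generate_docking_matrix",
    "generate_trajectory",
]


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ActivitySimSpec:
    n_regulators: int = 200
    n_metacells_per_group: int = 40
    n_clusters: int = 2
    planted_up: tuple[str, ...] = ()
    planted_down: tuple[str, ...] = ()
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regulators <= 0 or self.n_metacells_per_group <= 0:
            raise InvalidSpecError("dimensions must be positive")
        if self.n_clusters < 1:
            raise InvalidSpecError("n_clusters must be >= 1")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise InvalidSpecError("effect_size and noise_sd must be >= 0")
        if set(self.planted_up) & set(self.planted_down):
            raise InvalidSpecError("planted_up and planted_down must be disjoint")
        if len(self.planted_up) + len(self.planted_down) > self.n_regulators:
            raise InvalidSpecError("more planted regulators than n_regulators")


@dataclass(frozen=True)
class CountSimSpec:
    n_cells: int = 100
    umi_low_fraction: float = 0.0
    gene_low_fraction: float = 0.0
    n_genes: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise InvalidSpecError("n_cells must be positive")
        for f in (self.umi_low_fraction, self.gene_low_fraction):
            if not 0.0 <= f <= 1.0:
                raise InvalidSpecError("fractions must lie in [0, 1]")
        if round(self.umi_low_fraction * self.n_cells) + round(
            self.gene_low_fraction * self.n_cells
        ) > self.n_cells:
            raise InvalidSpecError("low-quality fractions exceed the cell count")
        if self.n_genes < 600:
            raise InvalidSpecError("n_genes must be >= 600 for the QC construction")


@dataclass(frozen=True)
class DockingSimSpec:
    n_drugs: int = 20
    n_targets: int = 5
    null_mean: float = -5.0
    null_sd: float = 1.0
    planted_binders: tuple[tuple[str, str], ...] = ()
    binder_shift: float = -3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs <= 0 or self.n_targets <= 0:
            raise InvalidSpecError("dimensions must be positive")
        if self.binder_shift > 0:
            raise InvalidSpecError("binder_shift must be <= 0")
        if self.null_sd < 0:
            raise InvalidSpecError("null_sd must be >= 0")


@dataclass(frozen=True)
class TrajectorySimSpec:
    n_frames: int = 50
    n_protein_atoms: int = 30
    n_ligand_atoms: int = 10
    fluctuation_sd: float = 0.1
    drift_per_frame: float = 0.0
    ligand_escape_frame: Optional[int] = None
    n_contacts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise InvalidSpecError("n_frames must be >= 2")
        if self.fluctuation_sd < 0:
            raise InvalidSpecError("fluctuation_sd must be >= 0")
        if self.n_contacts < 0:
            raise InvalidSpecError("n_contacts must be >= 0")
        if self.n_protein_atoms < max(self.n_contacts, 3):
            raise InvalidSpecError("n_protein_atoms too small for the requested contacts")
        if self.n_ligand_atoms < 2 * self.n_contacts:
            raise InvalidSpecError("n_ligand_atoms too small (need donor+H per contact)")


def _regulator_names(spec: ActivitySimSpec) -> list[str]:
    planted = list(spec.planted_up) + list(spec.planted_down)
    n_null = spec.n_regulators - len(planted)
    return planted + [f"R{i:04d}" for i in range(n_null)]


def generate_activity_matrix(spec: ActivitySimSpec) -> ActivityMatrix:
    """Activity z-score matrix with planted case-vs-control mean shifts.

    Planted-up regulators have case - control mean difference +effect_size
    in expectation (planted-down the negative); cluster labels are assigned
    round-robin within each group so clusters stay balanced.
    """
    rng = np.random.default_rng(spec.seed)
    regs = _regulator_names(spec)
    n_per = spec.n_metacells_per_group
    samples = [f"case_{i:04d}" for i in range(n_per)] + [
        f"ctrl_{i:04d}" for i in range(n_per)
    ]
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_regulators, 2 * n_per))
    for r in spec.planted_up:
        values[regs.index(r), :n_per] += spec.effect_size
    for r in spec.planted_down:
        values[regs.index(r), :n_per] -= spec.effect_size
    groups = ["case"] * n_per + ["control"] * n_per
    clusters = [f"c{i % spec.n_clusters}" for i in range(n_per)] * 2
    return ActivityMatrix(
        values=pd.DataFrame(values, index=pd.Index(regs, name="Regulator"), columns=samples),
        groups=pd.Series(groups, index=samples),
        clusters=pd.Series(clusters, index=samples),
    )


def generate_count_matrix(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell x gene count table with exact low-UMI / low-gene cell fractions.

    Returns ``(counts, truth)``.  Low-UMI cells are built with total counts
    <= 799 (but >= 500 detected genes); low-gene cells with < 500 detected
    genes (but >= 800 total counts); the two flagged sets are disjoint and
    placed first, remaining cells pass both thresholds.
    """
    rng = np.random.default_rng(spec.seed)
    n_low_umi = round(spec.umi_low_fraction * spec.n_cells)
    n_low_gene = round(spec.gene_low_fraction * spec.n_cells)
    counts = np.zeros((spec.n_cells, spec.n_genes), dtype=int)
    truth_rows = []
    for i in range(spec.n_cells):
        if i < n_low_umi:
            n_detected, low, high = 550, 1, 1  # total 550 <= 799
            flags = (True, False)
        elif i < n_low_umi + n_low_gene:
            n_detected, low, high = 450, 2, 4  # >= 900 UMIs, 450 genes < 500
            flags = (False, True)
        else:
            n_detected, low, high = 600, 2, 5  # >= 1200 UMIs, 600 genes
            flags = (False, False)
        genes = rng.choice(spec.n_genes, size=n_detected, replace=False)
        counts[i, genes] = rng.integers(low, high + 1, size=n_detected)
        truth_rows.append(
            {"Cell": f"cell_{i:05d}", "LowUMI": flags[0], "LowGene": flags[1],
             "PassesQC": not (flags[0] or flags[1])}
        )
    cells = [r["Cell"] for r in truth_rows]
    df = pd.DataFrame(
        counts, index=pd.Index(cells, name="Cell"),
        columns=[f"gene_{j:05d}" for j in range(spec.n_genes)],
    )
    return df, pd.DataFrame(truth_rows).set_index("Cell")


def generate_docking_matrix(spec: DockingSimSpec) -> DockingMatrix:
    """Docking grid with Normal(null_mean, null_sd) cells and shifted planted binders."""
    rng = np.random.default_rng(spec.seed)
    drugs = [f"D{i:03d}" for i in range(spec.n_drugs)]
    targets = [f"T{j:02d}" for j in range(spec.n_targets)]
    values = rng.normal(spec.null_mean, spec.null_sd, size=(spec.n_drugs, spec.n_targets))
    df = pd.DataFrame(values, index=pd.Index(drugs, name="Drug"), columns=targets)
    for drug, target in spec.planted_binders:
        if drug not in df.index or target not in df.columns:
            raise InvalidSpecError(f"planted binder ({drug}, {target}) outside the grid")
        df.loc[drug, target] += spec.binder_shift
    return DockingMatrix(values=df, engine="simulated")


def _element_radius(element: str) -> float:
    return BONDI_RADII.get(element.upper(), DEFAULT_RADIUS)


def _build_atoms(spec: TrajectorySimSpec, rng: np.random.Generator) -> tuple[list[AtomRecord], np.ndarray]:
    """Reference frame: protein acceptors + carbons, ligand donor/H contact pairs + carbons.

    Contact geometry is collinear along x (acceptor at x=0, hydrogen at 1.9,
    donor at 2.9) so each contact satisfies a 3.5 A / 120 degree criterion
    with margin.
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1
    k = spec.n_contacts
    # protein: k acceptor oxygens lined up along y, rest carbons off to -x
    for i in range(spec.n_protein_atoms):
        if i < k:
            pos = np.array([0.0, 4.0 * i, 0.0])
            atoms.append(AtomRecord(serial, "O", _element_radius("O"), "protein", "acceptor"))
        else:
            pos = np.array([-8.0, 4.0 * (k - 1) / 2.0, 0.0]) + rng.normal(0, 2.0, 3)
            atoms.append(AtomRecord(serial, "C", _element_radius("C"), "protein", "none"))
        coords.append(pos)
        serial += 1
    # ligand: donor nitrogen + its hydrogen per contact, rest carbons at +x
    for i in range(k):
        donor_serial = serial
        atoms.append(AtomRecord(serial, "N", _element_radius("N"), "ligand", "donor-heavy"))
        coords.append(np.array([2.9, 4.0 * i, 0.0]))
        serial += 1
        atoms.append(
            AtomRecord(serial, "H", _element_radius("H"), "ligand", "hydrogen",
                       bonded_heavy=donor_serial)
        )
        coords.append(np.array([1.9, 4.0 * i, 0.0]))
        serial += 1
    for _ in range(spec.n_ligand_atoms - 2 * k):
        atoms.append(AtomRecord(serial, "C", _element_radius("C"), "ligand", "none"))
        coords.append(np.array([6.0, 4.0 * (k - 1) / 2.0, 0.0]) + rng.normal(0, 1.5, 3))
        serial += 1
    return atoms, np.array(coords)


ESCAPE_STEP = 12.0  # A per frame; >= 10 required to defeat any 3.5 A criterion


def generate_trajectory(spec: TrajectorySimSpec) -> Trajectory:
    """Geometric trajectory: frame 0 reference, then jitter + drift + optional escape.

    Frame k adds isotropic Gaussian jitter (sd ``fluctuation_sd``) and a
    rigid translation of ``k * drift_per_frame`` A along x to every atom.
    If ``ligand_escape_frame`` is set, ligand atoms additionally translate
    ``ESCAPE_STEP`` A per frame along +x for frames beyond it.
    """
    rng = np.random.default_rng(spec.seed)
    atoms, ref = _build_atoms(spec, rng)
    ligand_idx = np.array([i for i, a in enumerate(atoms) if a.role == "ligand"])
    frames = np.empty((spec.n_frames, len(atoms), 3))
    frames[0] = ref
    xhat = np.array([1.0, 0.0, 0.0])
    for k in range(1, spec.n_frames):
        frame = ref + k * spec.drift_per_frame * xhat
        if spec.fluctuation_sd > 0:
            frame = frame + rng.normal(0.0, spec.fluctuation_sd, size=frame.shape)
        if spec.ligand_escape_frame is not None and k > spec.ligand_escape_frame:
            frame[ligand_idx] += ESCAPE_STEP * (k - spec.ligand_escape_frame) * xhat
        frames[k] = frame
    return Trajectory(coords=frames, atoms=atoms)
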