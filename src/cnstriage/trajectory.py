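"""Geometric trajectory analysis.

From-scratch implementations of the stability metrics used for complex
triage: Kabsch rigid-body superposition, per-frame RMSD series, Shrake-
Rupley solvent-accessible surface area on a deterministic Fibonacci sphere
lattice, geometric hydrogen-bond detection (donor-acceptor distance plus
angle at the hydrogen), and mean +/- population-SD stability summaries.

All lengths are Angstrom internally; the 0.35 nm distance cutoff enters as
3.5 A via an explicit conversion at the config boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import load_table, write_table

__all__ = [
    "BONDI_RADII",
    "DEFAULT_RADIUS",
    "AtomRecord",
    "Trajectory",
    "HBondCriterion",
    "SASAParams",
    "StabilitySummary",
    "kabsch_superpose",
    "rmsd_series",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "detect_hbonds",
    "hbond_count_series",
    "summarize_stability",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_trajectory_xyz",
    "write_atom_metadata",
    "read_atom_metadata",
]

# Bondi van der Waals radii (A); unknown elements fall back to 1.5 A.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "P": 1.80, "S": 1.80, "CL": 1.75,
    "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.5


@dataclass(frozen=True)
class AtomRecord:
    """Static per-atom metadata carried alongside coordinates."""

    serial: int
    element: str
    vdw_radius: float
    role: str = "other"  # protein | ligand | solvent | other
    hbond_class: str = "none"  # donor-heavy | hydrogen | acceptor | none
    bonded_heavy: int | None = None  # serial of attached heavy atom, hydrogens only

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")
        if self.hbond_class == "hydrogen" and self.bonded_heavy is None:
            raise ValueError(f"hydrogen atom {self.serial} lacks bonded_heavy")


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (A) plus per-atom metadata."""

    coords: np.ndarray
    atoms: list[AtomRecord]
    frame_spacing: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom count mismatch between coords and metadata")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def indices(self, role: str | None = None) -> np.ndarray:
        """Atom indices, optionally restricted to one role."""
        if role is None:
            return np.arange(self.n_atoms)
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.role == role], dtype=int
        )


@dataclass(frozen=True)
class HBondCriterion:
    """Fixed geometric criterion: D-A distance and D-H...A angle at the hydrogen.

    ``mode="fixed"`` applies both cutoffs independently.  ``mode="coupled"``
    uses a distance bound that tightens with angular deviation
    (r_DA <= max_da_distance - coupling * (180 - angle)^2), an alternative
    distance-angle coupled formulation.
    """

    max_da_distance: float = 3.5  # A (= 0.35 nm)
    min_dha_angle: float = 120.0  # degrees
    mode: str = "fixed"
    coupling: float = 0.00044  # A / deg^2, coupled mode only

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be > 0")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must be in (0, 180]")
        if self.mode not in ("fixed", "coupled"):
            raise ValueError("mode must be 'fixed' or 'coupled'")

    @classmethod
    def from_nm(cls, max_da_distance_nm: float, min_dha_angle: float = 120.0) -> "HBondCriterion":
        return cls(max_da_distance=10.0 * max_da_distance_nm, min_dha_angle=min_dha_angle)


@dataclass(frozen=True)
class SASAParams:
    probe_radius: float = 1.4  # A, water probe
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")


@dataclass(frozen=True)
class StabilitySummary:
    complex: str
    protein_rmsd_mean: float
    protein_rmsd_sd: float
    ligand_rmsd_mean: float
    ligand_rmsd_sd: float
    protein_sasa_mean: float
    ligand_sasa_mean: float
    hbond_mean: float
    hbond_sd: float


# ---------------------------------------------------------------------------
# superposition and RMSD

def _check_fit_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("fit selection needs >= 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("fit selection is degenerate (collinear or coincident atoms)")


def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    fit_selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The rotation is computed from ``fit_selection`` (all atoms when None)
    and applied to every mobile atom; a reflection, if favoured by the SVD,
    is corrected so the returned rotation is proper (det = +1).

    Returns ``(transformed_mobile, fitted_rmsd_over_fit_selection)``.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError("reference and mobile must have identical shapes")
    sel = np.arange(ref.shape[0]) if fit_selection is None else np.asarray(fit_selection)
    if sel.size == 0:
        raise ValueError("empty fit selection")
    ref_sel, mob_sel = ref[sel], mob[sel]
    _check_fit_selection(ref_sel)
    _check_fit_selection(mob_sel)
    ref_c = ref_sel.mean(axis=0)
    mob_c = mob_sel.mean(axis=0)
    h = (mob_sel - mob_c).T @ (ref_sel - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transformed = (mob - mob_c) @ rot.T + ref_c
    fitted = rmsd(ref_sel, transformed[sel])
    return transformed, fitted


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) coordinate RMSD between two equal-shape sets."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def rmsd_series(
    traj: Trajectory,
    measure_selection: Sequence[int],
    fit_selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame RMSD vs frame 0 over ``measure_selection``.

    When ``fit_selection`` is given, each frame is first superposed onto
    frame 0 using those atoms; pass None for raw (unfitted) RMSD.
    """
    measure = np.asarray(measure_selection, dtype=int)
    if measure.size == 0:
        raise ValueError("empty measure selection")
    ref = traj.coords[0]
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        if fit_selection is not None:
            frame, _ = kabsch_superpose(ref, frame, fit_selection)
        out[k] = rmsd(ref[measure], frame[measure])
    return out


# ---------------------------------------------------------------------------
# SASA

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic golden-angle lattice)."""
    i = np.arange(n)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate centered coordinates into a molecule-fixed principal-axes frame.

    Axis signs are fixed by the third moment along each axis, so the frame
    co-rotates with the molecule and the lattice-based SASA below becomes
    exactly invariant under rigid rotation and translation (up to floating-
    point error).  Degenerate cases (isotropic or planar-symmetric clouds)
    fall back to whatever orientation ``eigh`` returns.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    proj = centered @ vecs
    for k in range(3):
        if (proj[:, k] ** 3).sum() < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return centered @ vecs


def shrake_rupley_sasa(
    frame: np.ndarray,
    atoms: Sequence[AtomRecord],
    params: SASAParams = SASAParams(),
    group: Sequence[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Solvent-accessible surface area per atom of ``group`` and the group total (A^2).

    Each group atom scatters ``n_sphere_points`` lattice points on its
    probe-expanded sphere; a point counts as accessible iff it lies strictly
    outside every *other* atom's expanded sphere (all atoms act as
    occluders, group membership only selects whose area is reported).
    Coordinates are first mapped to a molecule-fixed principal-axes frame
    so the discretization does not break rigid-motion invariance.
    """
    coords = np.asarray(frame, dtype=float)
    if coords.shape[0] != len(atoms):
        raise ValueError("frame/atom count mismatch")
    coords = _canonical_frame(coords)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    expanded = radii + params.probe_radius
    sel = np.arange(len(atoms)) if group is None else np.asarray(group, dtype=int)
    unit = fibonacci_sphere(params.n_sphere_points)
    areas = np.zeros(sel.size)
    for out_i, i in enumerate(sel):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        # occluder prefilter: spheres that can reach this atom's surface
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        occ = np.where((d_centers < ri + expanded) & (np.arange(len(atoms)) != i))[0]
        accessible = np.ones(params.n_sphere_points, dtype=bool)
        for j in occ:
            dj = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= dj > expanded[j]
        frac = accessible.mean()
        areas[out_i] = 4.0 * math.pi * ri * ri * frac
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# hydrogen bonds

def _donor_hydrogen_pairs(atoms: Sequence[AtomRecord], members: set[int]):
    """(donor_index, hydrogen_index) pairs whose donor heavy atom is in ``members``."""
    by_serial = {a.serial: i for i, a in enumerate(atoms)}
    pairs = []
    for i, a in enumerate(atoms):
        if a.hbond_class != "hydrogen":
            continue
        if a.bonded_heavy is None:
            raise ValueError(f"hydrogen atom {a.serial} lacks bonded_heavy")
        d_idx = by_serial.get(a.bonded_heavy)
        if d_idx is None:
            raise ValueError(
                f"hydrogen atom {a.serial}: bonded_heavy {a.bonded_heavy} not present"
            )
        if d_idx in members and atoms[d_idx].hbond_class == "donor-heavy":
            pairs.append((d_idx, i))
    return pairs


def _angle_at_hydrogen(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """D-H...A angle in degrees, measured at the hydrogen."""
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    frame: np.ndarray,
    atoms: Sequence[AtomRecord],
    criterion: HBondCriterion = HBondCriterion(),
    between: tuple[Sequence[int], Sequence[int]] | None = None,
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor, hydrogen, acceptor) index triples.

    A bond requires donor in one group and acceptor in the other (both
    directions checked), donor-acceptor distance within the cutoff, and the
    angle at the hydrogen at or above the angular cutoff.  Each triple is
    reported at most once.
    """
    coords = np.asarray(frame, dtype=float)
    if between is None:
        group_a = {i for i, a in enumerate(atoms) if a.role == "protein"}
        group_b = {i for i, a in enumerate(atoms) if a.role == "ligand"}
    else:
        group_a, group_b = set(map(int, between[0])), set(map(int, between[1]))
    if group_a & group_b:
        raise ValueError("hydrogen-bond groups must be disjoint")
    bonds = []
    seen = set()
    for donors_in, acceptors_in in ((group_a, group_b), (group_b, group_a)):
        dh = _donor_hydrogen_pairs(atoms, donors_in)
        acceptors = [
            i for i in sorted(acceptors_in) if atoms[i].hbond_class == "acceptor"
        ]
        for d_idx, h_idx in dh:
            for a_idx in acceptors:
                if (d_idx, h_idx, a_idx) in seen:
                    continue
                dist = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
                angle = _angle_at_hydrogen(coords[d_idx], coords[h_idx], coords[a_idx])
                if criterion.mode == "fixed":
                    ok = dist <= criterion.max_da_distance and angle >= criterion.min_dha_angle
                else:
                    ok = dist <= criterion.max_da_distance - criterion.coupling * (180.0 - angle) ** 2
                if ok:
                    seen.add((d_idx, h_idx, a_idx))
                    bonds.append((d_idx, h_idx, a_idx))
    return bonds


def hbond_count_series(
    traj: Trajectory,
    criterion: HBondCriterion = HBondCriterion(),
    between: tuple[Sequence[int], Sequence[int]] | None = None,
) -> np.ndarray:
    """Per-frame hydrogen-bond counts between the two groups."""
    return np.array(
        [
            len(detect_hbonds(traj.coords[k], traj.atoms, criterion, between))
            for k in range(traj.n_frames)
        ]
    )


# ---------------------------------------------------------------------------
# summaries

def _mean_sd(series: np.ndarray) -> tuple[float, float]:
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    return float(arr.mean()), float(arr.std(ddof=0))


def summarize_stability(
    complex_id: str,
    protein_rmsd: np.ndarray,
    ligand_rmsd: np.ndarray,
    protein_sasa: np.ndarray,
    ligand_sasa: np.ndarray,
    hbond_counts: np.ndarray,
    frame_slice: slice = slice(None),
) -> StabilitySummary:
    """Mean and population SD of each metric, optionally over a frame slice
    (e.g. ``slice(50, None)`` to discard equilibration frames)."""
    pr_m, pr_s = _mean_sd(np.asarray(protein_rmsd)[frame_slice])
    lr_m, lr_s = _mean_sd(np.asarray(ligand_rmsd)[frame_slice])
    ps_m, _ = _mean_sd(np.asarray(protein_sasa)[frame_slice])
    ls_m, _ = _mean_sd(np.asarray(ligand_sasa)[frame_slice])
    hb_m, hb_s = _mean_sd(np.asarray(hbond_counts)[frame_slice])
    return StabilitySummary(
        complex=complex_id,
        protein_rmsd_mean=pr_m,
        protein_rmsd_sd=pr_s,
        ligand_rmsd_mean=lr_m,
        ligand_rmsd_sd=lr_s,
        protein_sasa_mean=ps_m,
        ligand_sasa_mean=ls_m,
        hbond_mean=hb_m,
        hbond_sd=hb_s,
    )


# ---------------------------------------------------------------------------
# serialization: multi-model PDB (via biotite) + atom-metadata TSV; XYZ alt.

def write_atom_metadata(atoms: Sequence[AtomRecord], path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "Serial": [a.serial for a in atoms],
            "Element": [a.element for a in atoms],
            "Radius": [a.vdw_radius for a in atoms],
            "Role": [a.role for a in atoms],
            "HBondClass": [a.hbond_class for a in atoms],
            "BondedHeavy": [a.bonded_heavy if a.bonded_heavy is not None else -1 for a in atoms],
        }
    )
    return write_table(df, path)


def read_atom_metadata(path: str | Path) -> list[AtomRecord]:
    df = load_table(
        path, required=["Serial", "Element", "Radius", "Role", "HBondClass", "BondedHeavy"]
    )
    return [
        AtomRecord(
            serial=int(r["Serial"]),
            element=str(r["Element"]),
            vdw_radius=float(r["Radius"]),
            role=str(r["Role"]),
            hbond_class=str(r["HBondClass"]),
            bonded_heavy=None if int(r["BondedHeavy"]) < 0 else int(r["BondedHeavy"]),
        )
        for _, r in df.iterrows()
    ]


def write_trajectory_pdb(traj: Trajectory, pdb_path: str | Path, meta_path: str | Path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL) plus a metadata sidecar TSV."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = traj.coords[0].astype(np.float32)
    template.chain_id = np.array(
        ["L" if a.role == "ligand" else "A" for a in traj.atoms]
    )
    template.res_id = np.array(
        [2 if a.role == "ligand" else 1 for a in traj.atoms]
    )
    template.res_name = np.array(
        ["LIG" if a.role == "ligand" else "ALA" for a in traj.atoms]
    )
    template.atom_name = np.array(
        [f"{a.element[:1]}{a.serial % 1000}" for a in traj.atoms]
    )
    template.element = np.array([a.element.upper() for a in traj.atoms])
    template.hetero = np.array([a.role == "ligand" for a in traj.atoms])
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    Path(pdb_path).parent.mkdir(parents=True, exist_ok=True)
    pdb.write(str(pdb_path))
    write_atom_metadata(traj.atoms, meta_path)


def read_trajectory_pdb(pdb_path: str | Path, meta_path: str | Path) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(pdb_path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    atoms = read_atom_metadata(meta_path)
    return Trajectory(coords=coords, atoms=atoms)


def write_trajectory_xyz(traj: Trajectory, xyz_path: str | Path, meta_path: str | Path) -> None:
    """XYZ alternative output (element + coordinates per frame block)."""
    lines = []
    for k in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"frame {k}")
        for a, (x, y, z) in zip(traj.atoms, traj.coords[k]):
            lines.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
    Path(xyz_path).parent.mkdir(parents=True, exist_ok=True)
    Path(xyz_path).write_text("\n".join(lines) + "\n")
    write_atom_metadata(traj.atoms, meta_path)
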