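"""Differential-regulator calling from activity z-score matrices.

Pipeline per regulator: Welch two-sample t per cluster mapped to a signed
normal quantile, weighted Stouffer combination across clusters, two-sided
normal p-value, Benjamini-Hochberg adjustment across regulators, and a
dual gate (q below the FDR threshold AND absolute combined score above the
association cutoff).  Cohort DER sets are intersected by exact region
membership.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import load_table, write_table

__all__ = [
    "CellQCThresholds",
    "ActivityMatrix",
    "DERCallingConfig",
    "qc_filter_cells",
    "cluster_zscores",
    "stouffer_combine",
    "bh_adjust",
    "call_ders",
    "intersect_ders",
]

Z_CLAMP = 38.0  # |z| beyond this underflows double-precision normal tails


@dataclass(frozen=True)
class CellQCThresholds:
    """Retention thresholds: keep a cell iff UMIs >= min_umis and detected genes >= min_genes."""

    min_umis: int = 800
    min_genes: int = 500

    def __post_init__(self):
        if self.min_umis <= 0 or self.min_genes <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class ActivityMatrix:
    """Regulator x sample activity z-scores with group and cluster labels.

    ``values``: DataFrame indexed by regulator, columns = sample ids.
    ``groups``: per-sample label, "case" or "control".
    ``clusters``: per-sample cluster id.
    """

    values: pd.DataFrame
    groups: pd.Series
    clusters: pd.Series

    def __post_init__(self):
        samples = list(self.values.columns)
        self.groups = pd.Series(self.groups, index=samples) if not isinstance(
            self.groups, pd.Series
        ) else self.groups.reindex(samples)
        self.clusters = pd.Series(self.clusters, index=samples) if not isinstance(
            self.clusters, pd.Series
        ) else self.clusters.reindex(samples)
        if self.groups.isna().any() or self.clusters.isna().any():
            raise ValueError("group/cluster labels must cover every sample")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group label(s): {bad}")
        counts = self.groups.value_counts()
        if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
            raise ValueError("need >= 2 samples per group overall")

    @classmethod
    def from_tsv(cls, activity_path: str | Path, meta_path: str | Path) -> "ActivityMatrix":
        values = load_table(activity_path).set_index("Regulator")
        meta = load_table(meta_path, required=["Sample", "Group", "Cluster"])
        meta = meta.set_index("Sample")
        return cls(
            values=values,
            groups=meta["Group"],
            clusters=meta["Cluster"],
        )

    def to_tsv(self, activity_path: str | Path, meta_path: str | Path) -> None:
        write_table(self.values.rename_axis("Regulator").reset_index(), activity_path)
        meta = pd.DataFrame(
            {"Sample": self.values.columns, "Group": self.groups.values, "Cluster": self.clusters.values}
        )
        write_table(meta, meta_path)


@dataclass(frozen=True)
class DERCallingConfig:
    fdr_threshold: float = 0.05
    min_abs_association: float = 1.5
    cluster_weighting: str = "sqrt-size"  # or "equal"

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.min_abs_association < 0:
            raise ValueError("min_abs_association must be >= 0")
        if self.cluster_weighting not in ("equal", "sqrt-size"):
            raise ValueError("cluster_weighting must be 'equal' or 'sqrt-size'")


def qc_filter_cells(
    counts: pd.DataFrame, thresholds: CellQCThresholds = CellQCThresholds()
) -> list:
    """Return ids of cells passing both QC thresholds.

    ``counts`` is cell x gene, non-negative integers.  Exclusion is strict
    "fewer than": a cell with exactly ``min_umis`` UMIs and ``min_genes``
    detected genes is retained.
    """
    if counts.size == 0:
        warnings.warn("empty count table; no cells retained", stacklevel=2)
        return []
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    umis = arr.sum(axis=1)
    genes = (arr > 0).sum(axis=1)
    keep = (umis >= thresholds.min_umis) & (genes >= thresholds.min_genes)
    return list(counts.index[keep])


def _welch_z(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Signed z for case-vs-control per row via Welch's t mapped through normal quantiles."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1, v2 = case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    z = np.empty(case.shape[0])
    degenerate = se2 == 0
    # zero pooled variance: equal means -> 0, unequal -> clamped infinity
    z[degenerate] = np.sign(diff[degenerate]) * Z_CLAMP
    ok = ~degenerate
    t = diff[ok] / np.sqrt(se2[ok])
    df = se2[ok] ** 2 / (
        (v1[ok] / n1) ** 2 / (n1 - 1) + (v2[ok] / n2) ** 2 / (n2 - 1)
    )
    # one-sided upper-tail survival in log space keeps precision for large |t|
    logsf = stats.t.logsf(np.abs(t), df)
    zmag = -stats.norm.ppf(np.exp(np.clip(logsf, -700, 0)))
    zmag = np.where(np.isfinite(zmag), zmag, Z_CLAMP)
    z[ok] = np.sign(t) * np.minimum(np.abs(zmag), Z_CLAMP)
    return z


def cluster_zscores(matrix: ActivityMatrix) -> pd.DataFrame:
    """Per-regulator, per-cluster signed z statistics (case minus control).

    Clusters with fewer than 2 samples in either group are dropped with a
    warning.  Sign is positive when the case mean exceeds the control mean.
    """
    result = {}
    for cluster in pd.unique(matrix.clusters):
        mask = matrix.clusters == cluster
        case_cols = matrix.values.columns[mask & (matrix.groups == "case")]
        ctrl_cols = matrix.values.columns[mask & (matrix.groups == "control")]
        if len(case_cols) < 2 or len(ctrl_cols) < 2:
            warnings.warn(
                f"cluster {cluster!r} dropped: needs >= 2 samples per group",
                stacklevel=2,
            )
            continue
        case = matrix.values[case_cols].to_numpy(dtype=float)
        ctrl = matrix.values[ctrl_cols].to_numpy(dtype=float)
        result[cluster] = _welch_z(case, ctrl)
    if not result:
        raise ValueError("no cluster satisfies the >= 2 samples per group requirement")
    return pd.DataFrame(result, index=matrix.values.index)


def stouffer_combine(
    z_values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted Stouffer combination: sum(w*z) / sqrt(sum(w^2)).

    With equal weights this reduces to sum(z)/sqrt(k).  Scale-invariant in
    the weights.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one z value")
    if weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != z.shape:
            raise ValueError("weights and z_values must have equal length")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    return float(np.dot(w, z) / math.sqrt(np.dot(w, w)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, clamped to [0, 1].

    Ties in rank are broken by input order (stable argsort).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_ders(
    matrix: ActivityMatrix, config: DERCallingConfig = DERCallingConfig()
) -> pd.DataFrame:
    """Call differential regulators from an activity matrix.

    Returns a DataFrame indexed by regulator with columns
    ``association_score`` (combined Stouffer Z), ``p_value`` (two-sided
    normal), ``q_value`` (BH across regulators), ``direction`` (up/down from
    the sign of Z) and ``significant`` (q < fdr AND |Z| > min_abs_association).
    """
    zs = cluster_zscores(matrix)
    if config.cluster_weighting == "sqrt-size":
        sizes = matrix.clusters.value_counts()
        weights = np.array([math.sqrt(sizes[c]) for c in zs.columns])
    else:
        weights = np.ones(zs.shape[1])
    w_norm = math.sqrt(float(np.dot(weights, weights)))
    combined = zs.to_numpy() @ weights / w_norm
    p = 2.0 * stats.norm.sf(np.abs(combined))
    q = bh_adjust(p)
    significant = (q < config.fdr_threshold) & (
        np.abs(combined) > config.min_abs_association
    )
    return pd.DataFrame(
        {
            "association_score": combined,
            "p_value": p,
            "q_value": q,
            "direction": np.where(combined >= 0, "up", "down"),
            "significant": significant,
        },
        index=zs.index.rename("Regulator"),
    )


def intersect_ders(sets: Mapping[str, Iterable]) -> tuple[pd.DataFrame, pd.Series]:
    """Exact region membership of named DER sets (Venn-style).

    Returns (membership, counts): ``membership`` has one row per DER with a
    boolean column per set and a ``region`` label joining the containing set
    names with '&'; ``counts`` maps each non-empty region to its size.
    """
    named = {name: set(s) for name, s in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least 2 named sets")
    universe = sorted(set().union(*named.values()))
    rows = []
    for item in universe:
        member = {name: item in s for name, s in named.items()}
        region = "&".join(name for name in named if member[name])
        rows.append({"DER": item, **member, "region": region})
    membership = pd.DataFrame(rows).set_index("DER") if rows else pd.DataFrame(
        columns=[*named, "region"]
    )
    counts = (
        membership["region"].value_counts().sort_index()
        if len(membership)
        else pd.Series(dtype=int)
    )
    return membership, counts
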