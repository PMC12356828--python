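"""End-to-end orchestration with strict config validation and provenance logging.

A pipeline run executes, in order: activity simulation -> regulator calling;
docking matrix (fixture or simulated) -> threshold triage; descriptor fixture
-> CNS profiling; trajectory simulation -> stability metrics; MD summary +
profiles -> gated ranking.  Every stage logs its configuration echo and the
SHA-256 of each file it writes, and all randomness derives from the single
global seed, so a fixed-seed run is reproducible checksum-for-checksum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cns, docking, fixtures, ranking, regulators, simulate, trajectory
from .io import sha256_file, write_table

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_ALLOWED_TOP = {
    "seed", "fixtures_only", "activity", "der", "docking_sim",
    "docking_filter", "trajectory", "ranking",
}
_ALLOWED_SECTION = {
    "activity": {
        "n_regulators", "n_metacells_per_group", "n_clusters",
        "planted_up", "planted_down", "effect_size", "noise_sd",
    },
    "der": {"fdr_threshold", "min_abs_association", "cluster_weighting"},
    "docking_sim": {
        "n_drugs", "n_targets", "null_mean", "null_sd",
        "planted_binders", "binder_shift",
    },
    "docking_filter": {"threshold", "select_targets", "min_targets_passing"},
    "trajectory": {
        "n_frames", "n_protein_atoms", "n_ligand_atoms", "fluctuation_sd",
        "drift_per_frame", "ligand_escape_frame", "n_contacts",
    },
    "ranking": {
        "require_permeable", "exclude_pgp", "require_safety_window", "sort_keys",
    },
}


@dataclass
class PipelineConfig:
    seed: int = 0
    fixtures_only: bool = False
    activity: dict = field(default_factory=dict)
    der: dict = field(default_factory=dict)
    docking_sim: dict = field(default_factory=dict)
    docking_filter: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    ranking: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _ALLOWED_TOP
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for section, allowed in _ALLOWED_SECTION.items():
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise ValueError(
                    f"unknown key(s) in section {section!r}: {', '.join(sorted(extra))}"
                )
        return cls(**raw)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)


def _log(log_path: Path, stage: str, config_echo: dict, outputs: list[Path]) -> None:
    entry = {
        "stage": stage,
        "config": config_echo,
        "outputs": {str(p.name): sha256_file(p) for p in outputs},
    }
    with log_path.open("a") as fh:
        fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages; returns a bundle of key results and output paths.

    Failures propagate wrapped with the failing stage's name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "provenance.jsonl"
    log_path.write_text("")
    bundle: dict[str, Any] = {"out_dir": str(out)}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # re-raise with stage context
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    rng = np.random.default_rng(config.seed)

    if not config.fixtures_only:
        def _activity():
            spec = simulate.ActivitySimSpec(
                seed=int(rng.integers(2**31)),
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in config.activity.items()
                },
            )
            matrix = simulate.generate_activity_matrix(spec)
            matrix.to_tsv(out / "activity.tsv", out / "activity_meta.tsv")
            ders = regulators.call_ders(
                matrix, regulators.DERCallingConfig(**config.der)
            )
            write_table(ders.reset_index(), out / "der_table.tsv")
            _log(log_path, "regulator_calling", {**config.activity, **config.der},
                 [out / "activity.tsv", out / "activity_meta.tsv", out / "der_table.tsv"])
            return ders
        bundle["ders"] = stage("regulator_calling")(_activity)

        def _docking_sim():
            spec = simulate.DockingSimSpec(
                seed=int(rng.integers(2**31)),
                **{
                    k: tuple(map(tuple, v)) if k == "planted_binders" else v
                    for k, v in config.docking_sim.items()
                },
            )
            mat = simulate.generate_docking_matrix(spec)
            mat.to_tsv(out / "docking_sim.tsv")
            _log(log_path, "docking_simulation", dict(config.docking_sim),
                 [out / "docking_sim.tsv"])
            return mat
        bundle["docking_sim"] = stage("docking_simulation")(_docking_sim)

        def _trajectory():
            spec = simulate.TrajectorySimSpec(
                seed=int(rng.integers(2**31)), **config.trajectory
            )
            traj = simulate.generate_trajectory(spec)
            trajectory.write_trajectory_pdb(
                traj, out / "trajectory.pdb", out / "trajectory_meta.tsv"
            )
            protein = traj.indices("protein")
            ligand = traj.indices("ligand")
            pr = trajectory.rmsd_series(traj, protein, protein)
            lr = trajectory.rmsd_series(traj, ligand, protein)
            hb = trajectory.hbond_count_series(traj)
            ps, ls = [], []
            params = trajectory.SASAParams()
            for k in range(traj.n_frames):
                ps.append(trajectory.shrake_rupley_sasa(traj.coords[k], traj.atoms, params, protein)[1])
                ls.append(trajectory.shrake_rupley_sasa(traj.coords[k], traj.atoms, params, ligand)[1])
            summary = trajectory.summarize_stability(
                "synthetic", pr, lr, np.array(ps), np.array(ls), hb
            )
            write_table(pd.DataFrame([asdict(summary)]), out / "trajectory_summary.tsv")
            series = pd.DataFrame(
                {"Frame": np.arange(traj.n_frames), "ProteinRMSD": pr,
                 "LigandRMSD": lr, "ProteinSASA": ps, "LigandSASA": ls, "HBonds": hb}
            )
            write_table(series, out / "trajectory_series.tsv")
            _log(log_path, "trajectory_metrics", dict(config.trajectory),
                 [out / "trajectory.pdb", out / "trajectory_meta.tsv",
                  out / "trajectory_summary.tsv", out / "trajectory_series.tsv"])
            return summary
        bundle["trajectory_summary"] = stage("trajectory_metrics")(_trajectory)

    def _triage():
        mat = docking.DockingMatrix(fixtures.load_table1().set_index("Drug"), engine="vina")
        cfg = docking.DockingFilterConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in config.docking_filter.items()
            }
        )
        passing = docking.filter_candidates(mat, cfg)
        write_table(pd.DataFrame({"Drug": passing}), out / "docking_candidates.tsv")
        _log(log_path, "docking_triage",
             {"threshold": cfg.threshold, "min_targets_passing": cfg.min_targets_passing,
              "select_targets": list(cfg.select_targets),
              "input": fixtures.fixture_checksum("table1_docking.tsv")},
             [out / "docking_candidates.tsv"])
        return passing
    bundle["docking_candidates"] = stage("docking_triage")(_triage)

    def _profiles():
        table2 = fixtures.load_table2()
        profiles = cns.profile_table(table2)
        write_table(profiles, out / "cns_profiles.tsv")
        _log(log_path, "cns_profiler",
             {"input": fixtures.fixture_checksum("table2_descriptors.tsv")},
             [out / "cns_profiles.tsv"])
        return profiles
    profiles = stage("cns_profiler")(_profiles)
    bundle["profiles"] = profiles

    def _rank():
        md = fixtures.load_md_summary()
        policy = ranking.RankingPolicy(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in config.ranking.items()
            }
        )
        report = ranking.rank_candidates(md, profiles, policy)
        (out / "report.json").write_text(ranking.build_report(report, "json"))
        (out / "report.tsv").write_text(ranking.build_report(report, "tsv"))
        _log(log_path, "integrative_ranking", policy.to_dict(),
             [out / "report.json", out / "report.tsv"])
        return report
    bundle["report"] = stage("integrative_ranking")(_rank)
    return bundle
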