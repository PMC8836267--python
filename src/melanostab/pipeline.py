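"""End-to-end analysis pipeline with a reproducible run manifest.

Stage order: structure acquisition (synthetic fixture or user PDB) →
disulfide detection → mutant bridge-breakage → stability screen →
pose QC / fingerprints / Kd (when pose inputs are supplied) → distance-map
fluctuation summary (when a trajectory is requested or supplied).  Every
numeric threshold used anywhere is logged in ``manifest.json`` together with
the seed and package versions, and results are written as plain TSV so that
two runs of the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .disulfide import DEFAULT_SS_CUTOFF, bridges_frame, broken_bridges, detect_disulfides
from .distmaps import DEFAULT_CHANGE_THRESHOLD, fluctuation_summary
from .mutation import MutationSpec
from .poses import (
    MAX_ZN_DISTANCE,
    ClusteringParams,
    cluster_poses,
    interaction_fingerprint,
    kd_from_energy,
    pose_validity,
    read_poses,
)
from .stability import ScreenConfig, import_ddg_table, report_table, screen_all
from .structure import Structure, read_structure
from .synth import FixtureSpec, jitter_trajectory, make_cys_fixture

logger = logging.getLogger(__name__)

#: The seven disulfide pairings of the Tyrp2 intra-melanosomal domain
#: (Cys-rich domain: five bridges; tyrosinase domain: two).
TYRP2_DISULFIDE_PAIRS = (
    (29, 40), (41, 61), (52, 95), (97, 106), (109, 118), (254, 257), (286, 299),
)
#: The OCA8-associated variants analyzed throughout.
OCA8_MUTATIONS = ("C40S", "C61W", "G59V")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_fixture_spec() -> FixtureSpec:
    """The Tyrp2-like Cys mini-domain: 300 residues, the seven bridges, Gly59.

    Cysteines sit at the fourteen bridge positions and residue 59 is glycine,
    so all three OCA8 variants (C40S, C61W, G59V) are applicable verbatim.
    """
    seq = ["A"] * 300
    for pair in TYRP2_DISULFIDE_PAIRS:
        for pos in pair:
            seq[pos - 1] = "C"
    seq[59 - 1] = "G"
    return FixtureSpec(n_residues=300, sequence="".join(seq),
                       disulfide_pairs=TYRP2_DISULFIDE_PAIRS)


@dataclass
class PipelineConfig:
    """Configuration of a full run.  At least one stage must be enabled."""

    pdb: str | None = None
    fixture: FixtureSpec | None = None
    mutations: tuple[str, ...] = OCA8_MUTATIONS
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    ddg_table: str | None = None
    poses_pdb: str | None = None
    energies: str | None = None
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    max_zn_distance: float = MAX_ZN_DISTANCE
    disulfide_cutoff: float = DEFAULT_SS_CUTOFF
    map_threshold: float = DEFAULT_CHANGE_THRESHOLD
    traj_snapshots: int = 0
    traj_sigma: float = 0.3
    run_disulfides: bool = True
    run_screen: bool = True
    run_poses: bool = False
    run_maps: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (self.run_disulfides or self.run_screen or self.run_poses or self.run_maps):
            raise ValueError("no pipeline stages enabled")
        if self.run_poses and not (self.poses_pdb and self.energies):
            raise ValueError("pose stage enabled but poses_pdb/energies not given")
        if self.run_maps and self.traj_snapshots < 1:
            raise ValueError("map stage enabled but traj_snapshots < 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fixture" in raw and raw["fixture"] is not None:
            fx = raw["fixture"]
            fx["disulfide_pairs"] = tuple(tuple(p) for p in fx.get("disulfide_pairs", ()))
            raw["fixture"] = FixtureSpec(**fx)
        if "screen" in raw and raw["screen"] is not None:
            raw["screen"] = ScreenConfig(**raw["screen"])
        if "clustering" in raw and raw["clustering"] is not None:
            raw["clustering"] = ClusteringParams(**raw["clustering"])
        if "mutations" in raw:
            raw["mutations"] = tuple(raw["mutations"])
        return cls(**raw)


def _manifest(config: PipelineConfig, seed: int) -> dict:
    import gemmi
    import numpy
    import scipy

    return {
        "melanostab": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "gemmi": gemmi.__version__,
        "seed": seed,
        "thresholds": {
            "disulfide_cutoff_A": config.disulfide_cutoff,
            "max_zn_distance_A": config.max_zn_distance,
            "rmsd_cutoff_A": config.clustering.rmsd_cutoff,
            "map_change_threshold_A": config.map_threshold,
            "critical_threshold": config.screen.critical_threshold,
            "temperature_K": config.screen.temperature,
        },
        "mutations": list(config.mutations),
    }


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 seed: int | None = None) -> dict[str, Path]:
    """Run all enabled stages; returns a name → output-file mapping.

    Deterministic for a fixed config and seed.  On stage failure, partial
    outputs are retained, a ``FAILED`` marker names the stage, and a
    :class:`PipelineError` is raised.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(_manifest(config, seed), indent=2) + "\n")
        outputs["manifest"] = manifest_path

        stage = "structure"
        if config.pdb:
            structure = read_structure(config.pdb)
        else:
            spec = config.fixture or default_fixture_spec()
            spec = dataclasses.replace(spec, seed=seed)
            structure = make_cys_fixture(spec)
        mutations = [MutationSpec.from_string(m) for m in config.mutations]

        bridges = detect_disulfides(structure, cutoff=config.disulfide_cutoff)
        if config.run_disulfides:
            stage = "disulfides"
            _write_tsv(bridges_frame(bridges), out / "bridges.tsv")
            outputs["bridges"] = out / "bridges.tsv"
            rows = [
                {
                    "mutation": str(m),
                    "broken_bridges": ";".join(str(b) for b in broken_bridges(bridges, m)),
                    "n_broken": len(broken_bridges(bridges, m)),
                }
                for m in mutations
            ]
            breakage = pd.DataFrame(rows, columns=["mutation", "broken_bridges", "n_broken"])
            _write_tsv(breakage, out / "bridge_breakage.tsv")
            outputs["bridge_breakage"] = out / "bridge_breakage.tsv"

        if config.run_screen:
            stage = "screen"
            screen_cfg = config.screen
            if config.ddg_table:
                screen_cfg = dataclasses.replace(
                    screen_cfg, engine="table", ddg_table=import_ddg_table(config.ddg_table))
            fmap = screen_all(structure, screen_cfg)
            _write_tsv(fmap.to_frame(), out / "foldability.tsv")
            outputs["foldability"] = out / "foldability.tsv"
            _write_tsv(report_table(fmap, mutations), out / "mutation_report.tsv")
            outputs["mutation_report"] = out / "mutation_report.tsv"

        if config.run_poses:
            stage = "poses"
            poses = read_poses(config.poses_pdb, config.energies)
            rows = []
            for pose in poses:
                verdict = pose_validity(pose, structure, config.max_zn_distance)
                fp = interaction_fingerprint(pose, structure)
                rows.append({
                    "pose_id": pose.pose_id,
                    "binding_energy": pose.binding_energy,
                    "kd_molar": kd_from_energy(pose.binding_energy,
                                               config.screen.temperature),
                    "valid": verdict.valid,
                    "reason": verdict.reason,
                    "min_oxygen_zn_A": round(verdict.min_oxygen_zn, 3),
                    "n_hbonds": len(fp.hbonds),
                    "n_hydrophobic": len(fp.hydrophobic),
                    "n_pipi": len(fp.pipi),
                    "contacting_residues": ";".join(sorted(fp.contacting_residues)),
                })
            _write_tsv(pd.DataFrame(rows), out / "poses.tsv")
            outputs["poses"] = out / "poses.tsv"
            clusters = cluster_poses(poses, config.clustering)
            cl_rows = [
                {"cluster": i + 1, "representative": c.representative.pose_id,
                 "size": len(c.members),
                 "binding_energy": c.representative.binding_energy}
                for i, c in enumerate(clusters)
            ]
            _write_tsv(pd.DataFrame(cl_rows), out / "pose_clusters.tsv")
            outputs["pose_clusters"] = out / "pose_clusters.tsv"

        if config.run_maps:
            stage = "maps"
            traj = jitter_trajectory(structure, config.traj_snapshots,
                                     config.traj_sigma, seed)
            summary = fluctuation_summary(traj, structure,
                                          threshold=config.map_threshold)
            _write_tsv(summary.per_snapshot, out / "distance_fluctuations.tsv")
            outputs["distance_fluctuations"] = out / "distance_fluctuations.tsv"
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(stage, exc) from exc
    return outputs
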