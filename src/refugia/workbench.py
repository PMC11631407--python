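"""Desk-scale orchestration: chain the model, the simulated experiment, the
fitness statistics and the variant pipeline on synthetic inputs, with a run
manifest recording the seed, per-stage checksums and self-check outcomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("refugia")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run; all fields have printable defaults."""

    seed: int = 0
    out_dir: str = "refugia_run"
    phase_grid: int = 100
    phase_r_max: float = 3.0
    phase_s_max: float = 3.0
    n_replicates: int = 6
    n_transfers: int = 20
    run_phase: bool = True
    run_simulation: bool = True
    run_fitness: bool = True
    run_variants: bool = True
    run_checks: bool = True
    permanova_permutations: int = 999

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class StageFailure(RuntimeError):
    """Aggregated stage errors, each prefixed with its stage name."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig | None = None) -> dict:
    """Execute every enabled stage; returns (and writes) the run manifest.

    Raises :class:`StageFailure` if any stage errors or any enabled
    self-check fails, after attempting all stages.
    """
    from . import genomediff, model, stats, synth, transfer

    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "checks": {}}
    errors: list[str] = []

    def stage(name: str, enabled: bool, fn):
        if not enabled:
            manifest["stages"][name] = {"skipped": True}
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **(result or {}),
            }
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        except Exception as exc:  # aggregate and report at the end
            errors.append(f"{name}: {exc}")
            manifest["stages"][name] = {"error": str(exc)}
            return None

    def do_phase():
        axis = np.linspace(0.0, config.phase_r_max, config.phase_grid)
        s_axis = np.linspace(0.0, config.phase_s_max, config.phase_grid)
        pd_ = model.phase_diagram(axis, s_axis)
        path = out / "phase.csv"
        pd_.to_frame().to_csv(path, index=False)
        return {"file": path.name, "sha256": _checksum(path)}

    def do_simulation():
        table = transfer.run_experiment(
            protocol=transfer.TransferProtocol(n_transfers=config.n_transfers),
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        path = out / "trajectories.csv"
        table.to_csv(path, index=False)
        survival = transfer.summarize_survival(table)
        survival.to_csv(out / "survival.csv", index=False)
        if config.run_checks:
            high = survival[survival["salinity"] == "high"]
            ok_cell = high[(high["nutrients"] == "high") & (high["mixing"] == "static")]
            manifest["checks"]["refuge_cell_survives"] = bool(
                (ok_cell["n_survived"] > 0).all()
            )
            ctrl = survival[survival["salinity"] == "control"]
            manifest["checks"]["control_cells_survive"] = bool(
                (ctrl["n_extinct"] == 0).all()
            )
        return {"file": path.name, "sha256": _checksum(path)}

    def do_fitness():
        assays = synth.make_competition_data(seed=config.seed)
        s_values = []
        for row in assays.itertuples(index=False):
            res = stats.malthusian_selection(
                stats.CompetitionAssay(
                    evolved_start=row.evolved_start,
                    evolved_end=row.evolved_end,
                    ancestor_start=row.ancestor_start,
                    ancestor_end=row.ancestor_end,
                    environment=row.environment,
                    replicate=row.replicate,
                )
            )
            s_values.append({"replicate": res.replicate,
                             "environment": res.environment, "S": res.S})
        frame = pd.DataFrame(s_values)
        path = out / "s_values.csv"
        frame.to_csv(path, index=False)
        if config.run_checks:
            means = frame.groupby("environment")["S"].mean()
            manifest["checks"]["fitness_signs"] = bool(
                means.get("high", 0) > 0 and means.get("control", 0) < 0
            )
        return {"file": path.name, "sha256": _checksum(path)}

    def do_variants():
        fx_dir = out / "gd_fixtures"
        fx_manifest = synth.make_gd_fixtures(fx_dir, seed=config.seed)
        res = genomediff.run_pipeline(fx_dir / "sample_sheet.csv", fx_dir)
        matrix = res["matrix"]
        matrix.incidence.to_csv(out / "matrix.csv")
        res["parallel"].to_csv(out / "parallel_loci.csv", index=False)
        perm = stats.permanova(
            stats.jaccard_matrix(matrix.incidence.to_numpy()),
            matrix.treatments.to_list(),
            n_perm=config.permanova_permutations,
            seed=config.seed,
        )
        if config.run_checks:
            manifest["checks"]["variant_counts"] = bool(
                res["n_pooled"] == 43
                and res["n_retained_unique"] == 35
                and len(res["unique_loci"]["control"]) == 5
                and len(res["unique_loci"]["high"]) == 16
                and len(res["parallel"]) == 1
            )
        return {
            "pooled": res["n_pooled"],
            "retained": res["n_retained_unique"],
            "permanova_F": round(perm.pseudo_F, 4),
            "permanova_p": perm.p_value,
            "sha256": _checksum(out / "matrix.csv"),
        }

    stage("phase", config.run_phase, do_phase)
    stage("simulation", config.run_simulation, do_simulation)
    stage("fitness", config.run_fitness, do_fitness)
    stage("variants", config.run_variants, do_variants)

    failed_checks = [k for k, ok in manifest["checks"].items() if not ok]
    manifest["ok"] = not errors and not failed_checks
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    if errors or failed_checks:
        raise StageFailure(
            "; ".join(errors + [f"check failed: {c}" for c in failed_checks])
        )
    return manifest
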