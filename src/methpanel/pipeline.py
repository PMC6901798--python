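"""End-to-end orchestration: one declarative config, deterministic artifacts.

``run_all`` executes the discovery flow — simulate (optional) → merge
(optional) → M-transform + batch adjust → differential methylation →
binarize → panel selection → external validation (optional) — writing every
intermediate artifact as TSV/JSON plus a run manifest holding the config
hash and every derived stage seed. Identical configs reproduce byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .binarization import binarize_matrix
from .classify_eval import validate_external
from .data_io import (
    BETA,
    MethylationMatrix,
    SampleSheet,
    manifest_from_sheet,
    merge_datasets,
    read_matrix,
    read_sample_sheet,
    write_dmp_table,
    write_matrix,
    write_sample_sheet,
)
from .diff_meth import DifferentialMethylation
from .exceptions import ConfigurationError
from .panel_selection import Panel, PanelSelector, SelectionConfig
from .preprocess import batch_adjust, beta_to_m
from .synthetic_data import SimulationConfig, simulate_cohort

log = logging.getLogger("methpanel")

STAGES = ("simulate", "merge", "adjust", "dmp", "binarize", "select", "validate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of ``"<master>:<stage>"`` (< 2^31)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Declarative configuration of a full run."""

    outdir: str = "methpanel_run"
    seed: int = 0
    logfc_threshold: float = 1.0
    adjp_threshold: float = 0.05
    corr_threshold: float = 0.7
    folds: int = 10
    trees: int = 500
    elimination_fraction: float = 0.2
    test_fraction: float = 0.2
    epsilon: float = 1e-6
    simulation: SimulationConfig | None = None
    validation_simulation: SimulationConfig | None = None
    matrices: list[str] = field(default_factory=list)
    sheets: list[str] = field(default_factory=list)
    cohort_names: list[str] = field(default_factory=list)
    validation_matrix: str | None = None
    validation_sheet: str | None = None

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            corr_threshold=self.corr_threshold,
            folds=self.folds,
            trees=self.trees,
            elimination_fraction=self.elimination_fraction,
            seed=stage_seed(self.seed, "select"),
        )

    def validate(self) -> None:
        self.selection_config().validate()
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )
        if not 0.0 < self.epsilon < 0.5:
            raise ConfigurationError(f"epsilon must be in (0, 0.5), got {self.epsilon}")
        if self.adjp_threshold <= 0 or self.adjp_threshold > 1:
            raise ConfigurationError(
                f"adjp_threshold must be in (0, 1], got {self.adjp_threshold}"
            )
        if self.logfc_threshold < 0:
            raise ConfigurationError("logfc_threshold must be >= 0")
        if self.simulation is None and not self.matrices:
            raise ConfigurationError("provide either a simulation section or input matrices")
        if self.matrices and len(self.matrices) != len(self.sheets):
            raise ConfigurationError("one sample sheet per input matrix required")
        if self.simulation is not None:
            self.simulation.validate()
        if self.validation_simulation is not None:
            self.validation_simulation.validate()

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        vsim = raw.pop("validation_simulation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = _simulation_from_dict(sim)
        if vsim is not None:
            cfg.validation_simulation = _simulation_from_dict(vsim)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        for key in ("simulation", "validation_simulation"):
            if out[key] is not None and "baseline_modes" in out[key]:
                out[key]["baseline_modes"] = list(out[key]["baseline_modes"])
        return out


def _simulation_from_dict(raw: dict[str, Any]) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    if "baseline_modes" in raw:
        raw = dict(raw)
        raw["baseline_modes"] = tuple(raw["baseline_modes"])
    return SimulationConfig(**raw)


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def config_hash(config: RunConfig) -> str:
    payload = config.to_dict()
    payload.pop("outdir", None)  # hash the scientific config, not the destination
    canon = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def panel_to_dict(panel: Panel) -> dict[str, Any]:
    return {
        "probe_ids": panel.probe_ids,
        "chosen_size": panel.chosen_size,
        "candidate_order": panel.candidate_order,
        "splits": {
            p: {
                "threshold": s.threshold,
                "low_mean": s.low_mean,
                "high_mean": s.high_mean,
            }
            for p, s in panel.splits.items()
        },
        "trace": panel.trace.rows.to_dict(orient="records"),
        "config": dataclasses.asdict(panel.config),
    }


def write_panel_json(panel: Panel, path: str | Path, extra: dict | None = None) -> None:
    payload = panel_to_dict(panel)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def load_panel_json(path: str | Path) -> Panel:
    from .binarization import ProbeSplit
    from .panel_selection import PanelTrace
    import pandas as pd

    raw = json.loads(Path(path).read_text())
    trace = PanelTrace(pd.DataFrame(raw.get("trace", [])))
    cfg = raw.get("config", {})
    return Panel(
        probe_ids=list(raw["probe_ids"]),
        splits={
            p: ProbeSplit(probe_id=p, **{k: float(v) for k, v in d.items()})
            for p, d in raw.get("splits", {}).items()
        },
        trace=trace,
        candidate_order=list(raw.get("candidate_order", raw["probe_ids"])),
        chosen_size=int(raw.get("chosen_size", len(raw["probe_ids"]))),
        config=SelectionConfig(**cfg) if cfg else SelectionConfig(),
    )


def _prepare_cohort(
    matrix: MethylationMatrix, sheet: SampleSheet, epsilon: float
) -> MethylationMatrix:
    """beta -> M (if needed) -> per-probe batch mean centering."""
    if matrix.value_space == BETA:
        matrix = beta_to_m(matrix, epsilon)
    adjusted, _ = batch_adjust(matrix, sheet)
    return adjusted


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full discovery/validation flow; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(config.seed, stage) for stage in STAGES}
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seeds": seeds,
    }

    # --- inputs: simulate or load + merge -------------------------------
    if config.simulation is not None:
        log.info("simulate: generating synthetic discovery cohort")
        sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
        matrix, sheet, truth = simulate_cohort(sim)
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False, lineterminator="\n")
        write_matrix(matrix, outdir / "matrix.tsv")
        write_sample_sheet(sheet, outdir / "sheet.tsv")
    else:
        mats = [read_matrix(p) for p in config.matrices]
        shs = [read_sample_sheet(p) for p in config.sheets]
        if len(mats) == 1:
            matrix, sheet = mats[0], shs[0]
        else:
            log.info("merge: combining %d cohorts by common probes", len(mats))
            names = config.cohort_names or [Path(p).stem for p in config.matrices]
            matrix, sheet = merge_datasets(mats, shs, names)
            write_matrix(matrix, outdir / "merged.tsv")
            write_sample_sheet(sheet, outdir / "merged_sheet.tsv")
    m = manifest_from_sheet(sheet)
    manifest["cohort"] = {"n_tumor": m.n_tumor, "n_normal": m.n_normal, "n_all": m.n_all}

    # --- adjust ----------------------------------------------------------
    log.info("adjust: logit2 transform + per-probe batch mean centering")
    adjusted = _prepare_cohort(matrix, sheet, config.epsilon)
    write_matrix(adjusted, outdir / "adjusted.tsv")

    # --- differential methylation ---------------------------------------
    log.info("dmp: moderated t-tests on %d probes", adjusted.shape[0])
    results = DifferentialMethylation(adjusted, sheet).fit()
    dmps = results.call_dmps(config.logfc_threshold, config.adjp_threshold)
    write_dmp_table(dmps, outdir / "dmps.tsv")
    manifest["dmp"] = {
        "n_probes": int(adjusted.shape[0]),
        "n_dmps": int(len(dmps)),
        "d0": results.moderation.d0 if np.isfinite(results.moderation.d0) else "inf",
        "s0_2": results.moderation.s0_2,
    }
    if dmps.empty:
        raise ConfigurationError("no probes passed the DMP thresholds; nothing to select")

    # --- binarize --------------------------------------------------------
    log.info("binarize: exact 2-means on %d DMPs", len(dmps))
    binary = binarize_matrix(adjusted, list(dmps["probe_id"]))
    binary.values.to_csv(outdir / "binary.tsv", sep="\t", index_label="sample_id", lineterminator="\n")

    # --- select ----------------------------------------------------------
    log.info("select: RF-RFE + correlation-filtered greedy build")
    labels = sheet.groups_for(binary.sample_ids)
    selection = PanelSelector(binary, labels, config.selection_config()).fit()
    panel = selection.panel
    write_panel_json(
        panel,
        outdir / "panel.json",
        extra={"thresholds": {"logfc": config.logfc_threshold, "adjp": config.adjp_threshold}},
    )
    panel.trace.rows.to_csv(
        outdir / "trace.tsv", sep="\t", index=False, float_format="%.6f", lineterminator="\n"
    )
    manifest["panel"] = {
        "probes": panel.probe_ids,
        "size": panel.chosen_size,
        "cv_accuracy": float(
            panel.trace.rows.loc[
                panel.trace.rows["n_features"] == panel.chosen_size, "cv_accuracy"
            ].iloc[0]
        ),
        "cv_kappa": float(
            panel.trace.rows.loc[
                panel.trace.rows["n_features"] == panel.chosen_size, "cv_kappa"
            ].iloc[0]
        ),
    }

    # --- validate --------------------------------------------------------
    val_matrix = val_sheet = None
    if config.validation_simulation is not None:
        log.info("validate: generating synthetic validation cohort")
        vsim = dataclasses.replace(config.validation_simulation, seed=seeds["validate"])
        val_matrix, val_sheet, _ = simulate_cohort(vsim)
    elif config.validation_matrix is not None:
        val_matrix = read_matrix(config.validation_matrix)
        val_sheet = read_sample_sheet(config.validation_sheet)
    if val_matrix is not None:
        adjusted_val = _prepare_cohort(val_matrix, val_sheet, config.epsilon)
        report = validate_external(
            adjusted_val,
            val_sheet,
            panel,
            config.selection_config(),
            test_fraction=config.test_fraction,
            seed=stage_seed(config.seed, "validate_split"),
            rose_seed=stage_seed(config.seed, "rose"),
        )
        (outdir / "validation.json").write_text(
            json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n"
        )
        manifest["validation"] = report.to_dict()

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return manifest
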