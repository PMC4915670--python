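"""Orchestration: the full method-comparison pipeline.

Per method and species the pipeline (1) removes size — GPA + shape ~ logCS
residuals for landmark methods, allometric standardization for distance
methods; (2) computes the repeatability and reproducibility Mantel tables;
(3) selects one random repeat per (individual, measurer) and runs CVA per
measurer (population detachment) and the crossed two-way site x measurer
PERMANOVA.  All randomness derives from a single seed through named
per-stage substreams, so a run is reproducible from its manifest.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import fit_allometry, recheck_decorrelation, standardize
from .concordance import (build_specimen_matrices, concordance_table,
                          group_and_compare)
from .datasets import DistanceDataset, LandmarkDataset, METHODS
from .separation import cva, permanova_two_way, select_random_repeat
from .shape import procrustes_fit, regress_out_size
from .synthetic import DesignSpec, generate_method_suite

log = logging.getLogger("morphocompare")


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Named substream: stable across runs and stage additions."""
    return np.random.SeedSequence([seed, zlib.crc32(stage.encode()) & 0x7FFFFFFF])


@dataclass
class PipelineConfig:
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    design: DesignSpec | None = None          # synthetic input when set
    inputs: dict[str, str] = field(default_factory=dict)  # method -> CSV path
    scale_template: str = "scale"
    n_perm_mantel: int = 9999
    n_perm_permanova: int = 9999
    alpha: float = 0.05
    allometry_pooling: tuple[str, ...] = ("site",)
    size_regression_pooling: tuple[str, ...] = ("species",)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}")


def _load_inputs(config: PipelineConfig) -> dict:
    from .tpsio import read_distances_csv, read_landmarks_csv
    if config.design is not None:
        design = DesignSpec(**{**asdict_design(config.design), "seed": config.seed})
        suite = generate_method_suite(design, config.scale_template)
        return {m: suite[m] for m in config.methods}
    if not config.inputs:
        raise ValueError("config needs either a synthetic design or input paths")
    out = {}
    for m in config.methods:
        if m not in config.inputs:
            raise ValueError(f"no input path for method {m}")
        if m in ("GMB", "GMS"):
            out[m] = read_landmarks_csv(config.inputs[m], method=m)
        else:
            out[m] = read_distances_csv(config.inputs[m], method=m)
    return out


def asdict_design(design: DesignSpec) -> dict:
    return asdict(design)


def size_corrected_variables(data: LandmarkDataset | DistanceDataset,
                             config: PipelineConfig,
                             ) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Per-species size removal; returns (labels, variables, extras)."""
    extras: dict = {}
    if isinstance(data, LandmarkDataset):
        frames = []
        label_frames = []
        for sp in sorted(data.labels["species"].unique()):
            sub = data.subset((data.labels["species"] == sp).to_numpy())
            fit = procrustes_fit(sub)
            res = regress_out_size(fit, pooling=config.size_regression_pooling)
            frames.append(res.variables)
            label_frames.append(res.labels)
            extras.setdefault("procrustes", {})[sp] = fit
        labels = pd.concat(label_frames, ignore_index=True)
        values = pd.concat(frames, ignore_index=True)
        return labels, values.to_numpy(float), extras
    # distance method: allometric standardization per species
    frames = []
    label_frames = []
    checks = []
    for sp in sorted(data.labels["species"].unique()):
        sub = data.subset((data.labels["species"] == sp).to_numpy())
        model = fit_allometry(sub, pooling=config.allometry_pooling)
        adj = standardize(sub, model)
        chk = recheck_decorrelation(adj, alpha=config.alpha)
        chk.insert(0, "species", sp)
        checks.append(chk)
        frames.append(adj.values)
        label_frames.append(adj.labels)
        extras.setdefault("allometry", {})[sp] = model
    extras["decorrelation"] = pd.concat(checks, ignore_index=True)
    labels = pd.concat(label_frames, ignore_index=True)
    values = pd.concat(frames, ignore_index=True)
    return labels, values.to_numpy(float), extras


@dataclass
class PipelineReport:
    config: PipelineConfig
    repeatability: pd.DataFrame
    reproducibility: pd.DataFrame
    level_summaries: dict
    permanova: dict          # (method, species) -> PermanovaTable
    cva: dict                # (method, species, measurer) -> CvaResult
    decorrelation: pd.DataFrame | None
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    datasets = _load_inputs(config)
    rep_tables = []
    repro_tables = []
    permanova_tables: dict = {}
    cva_results: dict = {}
    decorr_frames = []

    for method in config.methods:
        data = datasets[method]
        labels, values, extras = size_corrected_variables(data, config)
        log.info("%s: %d records, %d size-corrected variables",
                 method, len(labels), values.shape[1])
        if "decorrelation" in extras:
            chk = extras["decorrelation"].copy()
            chk.insert(0, "method", method)
            decorr_frames.append(chk)

        matrices = build_specimen_matrices(labels, values)
        for mode, sink in (("repeatability", rep_tables),
                           ("reproducibility", repro_tables)):
            table = concordance_table(
                matrices, mode, n_perm=config.n_perm_mantel,
                seed=stage_seed(config.seed, f"mantel/{method}/{mode}"))
            table.insert(0, "method", method)
            sink.append(table)
            log.info("%s %s: %d pairwise Mantel comparisons",
                     method, mode, len(table))

        for sp in sorted(labels["species"].unique()):
            mask = (labels["species"] == sp).to_numpy()
            analysis = select_random_repeat(
                labels.loc[mask].reset_index(drop=True), values[mask],
                seed=stage_seed(config.seed, f"repeat-choice/{method}/{sp}"))
            permanova_tables[(method, sp)] = permanova_two_way(
                analysis.values, analysis.labels["site"].to_numpy(),
                analysis.labels["measurer"].to_numpy(),
                n_perm=config.n_perm_permanova,
                seed=stage_seed(config.seed, f"permanova/{method}/{sp}"))
            for meas in sorted(analysis.labels["measurer"].unique()):
                mm = (analysis.labels["measurer"] == meas).to_numpy()
                cva_results[(method, sp, meas)] = cva(
                    analysis.values[mm],
                    analysis.labels["site"].to_numpy()[mm],
                    n_perm=config.n_perm_permanova,
                    seed=stage_seed(config.seed, f"cva/{method}/{sp}/{meas}"),
                    alpha=config.alpha)

    repeatability = pd.concat(rep_tables, ignore_index=True)
    reproducibility = pd.concat(repro_tables, ignore_index=True)
    level_summaries = {
        ("repeatability", lvl): group_and_compare(repeatability, lvl,
                                                  alpha=config.alpha)
        for lvl in ("measurer", "species", "method")
    }
    level_summaries.update({
        ("reproducibility", lvl): group_and_compare(reproducibility, lvl,
                                                    alpha=config.alpha)
        for lvl in ("species", "method")
    })

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "methods": list(config.methods),
        "n_perm_mantel": config.n_perm_mantel,
        "n_perm_permanova": config.n_perm_permanova,
        "alpha": config.alpha,
        "design": asdict_design(config.design) if config.design else None,
        "inputs": config.inputs,
    }
    report = PipelineReport(
        config=config, repeatability=repeatability,
        reproducibility=reproducibility, level_summaries=level_summaries,
        permanova=permanova_tables, cva=cva_results,
        decorrelation=pd.concat(decorr_frames, ignore_index=True)
        if decorr_frames else None,
        manifest=manifest)
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.repeatability.to_csv(out / "repeatability_mantel.csv", index=False)
    report.reproducibility.to_csv(out / "reproducibility_mantel.csv", index=False)
    for (mode, lvl), res in report.level_summaries.items():
        res["summaries"].to_csv(out / f"{mode}_level_{lvl}_summary.csv",
                                index=False)
        res["pairwise"].to_csv(out / f"{mode}_level_{lvl}_pairwise.csv",
                               index=False)
    perma_rows = []
    for (method, sp), tab in report.permanova.items():
        frame = tab.to_frame()
        frame.insert(0, "Species", sp)
        frame.insert(0, "Method", method)
        perma_rows.append(frame)
    if perma_rows:
        pd.concat(perma_rows, ignore_index=True).to_csv(
            out / "permanova_two_way.csv", index=False)
    cva_rows = []
    for (method, sp, meas), res in report.cva.items():
        cva_rows.append({
            "method": method, "species": sp, "measurer": meas,
            "detachment_class": res.detachment_class,
            "n_significant_pairs": res.n_significant_pairs,
            **{f"pct_var_cv{j + 1}": res.percent_variance[j]
               for j in range(len(res.percent_variance))},
        })
    if cva_rows:
        pd.DataFrame(cva_rows).to_csv(out / "cva_detachment.csv", index=False)
    if report.decorrelation is not None:
        report.decorrelation.to_csv(out / "sl_decorrelation_check.csv",
                                    index=False)
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=str) + "\n",
        encoding="utf-8")
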