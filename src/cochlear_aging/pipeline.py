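"""Pipeline orchestration: config schema, stage execution, run report.

A single config (YAML or dict) drives every stage on synthetic inputs with
known ground truth. Stages run in dependency order

    expression -> deg -> genesets        (transcriptomics chain)
    nlc | stiffness | cytology           (independent chains)

and each contributes a section to a machine-readable JSON report. The report
contains no timestamps, so identical config + seed gives byte-identical
reports. A failed stage is recorded as failed and independent stages still
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .cytology import (
    group_compare,
    holm_sidak,
    integrated_density_foldchange,
    survival_percentage,
)
from .degs import classify_deg, write_deg_table
from .errors import CochlearAgingError, ConfigurationError
from .expression import Thresholds, filter_expressed, write_matrix
from .genesets import concordant_subset, exclusive_top, rank_top_common, write_ranked_list
from .mechanics import axial_stiffness, trace_amplitude
from .nlc import TwoSineProtocol, cm_voltage_series, fit_nlc_recording
from .synthetic import (
    BoltzmannParams,
    CircuitParams,
    StudyDesign,
    gen_cochleogram,
    gen_expression_study,
    gen_fiber_traces,
    gen_fluorescence,
    gen_voltage_clamp_recording,
    write_fiber_traces_csv,
    write_recording_csv,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("cochlear_aging")

ALL_STAGES = ("expression", "deg", "genesets", "nlc", "stiffness", "cytology")

# fixed per-stage seed offsets on top of the run seed
_SEED_OFFSETS = {"expression": 1, "nlc": 2, "stiffness": 3, "cochleogram": 4, "fluorescence": 5}


def _from_mapping(cls, d: Mapping[str, Any], context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = {}
    for key, val in d.items():
        if isinstance(val, list):
            val = tuple(val)
        coerced[key] = val
    return cls(**coerced)


@dataclass(frozen=True)
class FiberConfig:
    kf: float = 2.0
    true_kc: float = 2.0
    Lf_amp: float = 50.0  # nm
    drive_freq: float = 100.0  # Hz
    noise_rms: float = 1.0  # nm


@dataclass(frozen=True)
class CochleogramConfig:
    locations: tuple[float, ...] = (300.0, 1200.0, 2100.0, 3000.0, 3900.0, 4800.0)
    baseline: Mapping[str, int] = field(default_factory=lambda: {"IHC": 50, "OHC": 150})
    survival: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "22mo": {"IHC": 0.90, "OHC": 0.75},
            "26mo": {"IHC": 0.80, "OHC": 0.55},
        }
    )
    baseline_age: str = "9mo"


@dataclass(frozen=True)
class FluorescenceConfig:
    targets: Mapping[str, float] = field(
        default_factory=lambda: {"TargetA": 1.0, "TargetB": -1.5, "TargetC": 0.0}
    )
    n_cells: int = 30
    baseline_age: str = "9mo"
    aged_age: str = "22mo"


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    thresholds: Thresholds = Thresholds()
    design: StudyDesign = StudyDesign()
    protocol: TwoSineProtocol = TwoSineProtocol()
    circuit: CircuitParams = CircuitParams()
    boltzmann: BoltzmannParams = BoltzmannParams()
    nlc_noise_rms_pA: float = 5.0
    fiber: FiberConfig = FiberConfig()
    cochleogram: CochleogramConfig = CochleogramConfig()
    fluorescence: FluorescenceConfig = FluorescenceConfig()

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if "deg" in self.stages and "expression" not in self.stages:
            raise ConfigurationError("stage 'deg' requires stage 'expression'")
        if "genesets" in self.stages and "deg" not in self.stages:
            raise ConfigurationError("stage 'genesets' requires stage 'deg'")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "thresholds": Thresholds,
            "design": StudyDesign,
            "protocol": TwoSineProtocol,
            "circuit": CircuitParams,
            "boltzmann": BoltzmannParams,
            "fiber": FiberConfig,
            "cochleogram": CochleogramConfig,
            "fluorescence": FluorescenceConfig,
        }
        built: dict[str, Any] = {}
        for key, subcls in sub.items():
            if key in d:
                val = d.pop(key)
                if not isinstance(val, Mapping):
                    raise ConfigurationError(f"config section {key!r} must be a mapping")
                built[key] = _from_mapping(subcls, val, key)
        return _from_mapping(cls, {**d, **built}, "pipeline config")

    def to_dict(self) -> dict[str, Any]:
        def normalize(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: normalize(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, Mapping):
                return {str(k): normalize(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [normalize(v) for v in obj]
            return obj

        return normalize(self)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    return PipelineConfig.from_dict(raw)


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _expression_and_deg(config: PipelineConfig, outdir: Path, report: dict) -> dict:
    """Run expression (+ optional deg, genesets); returns DEG tables by cell type."""
    design = dataclasses.replace(
        config.design, seed=config.seed + _SEED_OFFSETS["expression"]
    )
    study = gen_expression_study(design)
    write_matrix(study.counts, outdir / "counts.tsv")
    write_matrix(study.rpkm, outdir / "rpkm.tsv")
    study.write_truth_json(outdir / "truth.json")
    expressed = {}
    for ct in design.cell_types:
        for age in design.ages:
            _, n = filter_expressed(study.rpkm, (ct, age), config.thresholds)
            expressed[f"{ct}_{age}"] = n
    report["stages"]["expression"] = {
        "status": "ok",
        "n_genes": design.n_genes,
        "expressed": expressed,
        "artifacts": ["counts.tsv", "rpkm.tsv", "truth.json"],
    }
    if "deg" not in config.stages:
        return {}

    young, aged = design.ages
    tables = {}
    deg_section: dict[str, Any] = {"status": "ok", "per_cell_type": {}, "artifacts": []}
    for ct in design.cell_types:
        table, summary = classify_deg(study.rpkm, ct, young, aged, config.thresholds)
        tables[ct] = table
        fname = f"deg_{ct}.tsv"
        write_deg_table(table, outdir / fname)
        deg_section["artifacts"].append(fname)
        up_truth, down_truth = study.truth_sets(ct)
        called_up = set(table.index[table["status"] == "up"])
        called_down = set(table.index[table["status"] == "down"])
        n_correct = len(called_up & up_truth) + len(called_down & down_truth)
        n_called = len(called_up) + len(called_down)
        n_planted = len(up_truth) + len(down_truth)
        deg_section["per_cell_type"][ct] = {
            **summary,
            "sensitivity": n_correct / n_planted if n_planted else None,
            "empirical_fdr": (n_called - n_correct) / n_called if n_called else None,
        }
    report["stages"]["deg"] = deg_section

    if "genesets" in config.stages:
        gs: dict[str, Any] = {"status": "ok", "artifacts": []}
        a, b = design.cell_types[0], design.cell_types[1]
        ref_ct = design.cell_types[2] if len(design.cell_types) > 2 else None
        for direction in ("up", "down"):
            common = rank_top_common(tables[a], tables[b], direction, 200)
            write_ranked_list(common, outdir / f"top_common_{direction}.tsv")
            gs["artifacts"].append(f"top_common_{direction}.tsv")
            gs[f"n_common_{direction}"] = len(common)
            if ref_ct is not None:
                gs[f"n_concordant_{ref_ct}_{direction}"] = len(
                    concordant_subset(common, tables[ref_ct], direction)
                )
            for ct, other in ((a, b), (b, a)):
                excl = exclusive_top(tables[ct], tables[other], direction, 50)
                write_ranked_list(excl, outdir / f"top_exclusive_{ct}_{direction}.tsv")
                gs["artifacts"].append(f"top_exclusive_{ct}_{direction}.tsv")
                gs[f"n_exclusive_{ct}_{direction}"] = len(excl)
        report["stages"]["genesets"] = gs
    return tables


def _nlc_stage(config: PipelineConfig, outdir: Path, report: dict) -> None:
    rec = gen_voltage_clamp_recording(
        config.circuit,
        config.boltzmann,
        config.protocol,
        noise_rms_pA=config.nlc_noise_rms_pA,
        seed=config.seed + _SEED_OFFSETS["nlc"],
    )
    write_recording_csv(rec, outdir / "nlc_recording.csv")
    points = cm_voltage_series(rec)
    pts_frame = [
        {"v_mV": p.v, "cm_pF": p.cm, "rs_MOhm": p.rs_hat, "rm_MOhm": p.rm_hat, "ok": p.ok}
        for p in points
    ]
    fit = fit_nlc_recording(rec)
    truth = config.boltzmann
    rel = lambda est, true: abs(est - true) / abs(true) if true else None  # noqa: E731
    report["stages"]["nlc"] = {
        "status": "ok",
        "fit": {
            "qmax_fC": fit.qmax,
            "alpha_mV": fit.alpha,
            "vpk_mV": fit.vpk,
            "clin_pF": fit.clin,
            "charge_density_fC_per_pF": fit.charge_density,
            "rs_MOhm": fit.rs,
            "rm_MOhm": fit.rm,
            "rss_pF2": fit.rss,
            "n_points": fit.n_points,
            "converged": fit.converged,
            "bracketed": fit.bracketed,
        },
        "recovery_error": {
            "qmax_rel": rel(fit.qmax, truth.qmax),
            "alpha_rel": rel(fit.alpha, truth.alpha),
            "vpk_abs_mV": abs(fit.vpk - truth.vpk),
            "clin_rel": rel(fit.clin, config.circuit.clin),
        },
        "artifacts": ["nlc_recording.csv", "cm_points.json"],
    }
    with open(outdir / "cm_points.json", "w", encoding="utf-8") as fh:
        json.dump(pts_frame, fh, indent=1)


def _stiffness_stage(config: PipelineConfig, outdir: Path, report: dict) -> None:
    fb = config.fiber
    traces = gen_fiber_traces(
        kf=fb.kf,
        true_kc=fb.true_kc,
        Lf_amp=fb.Lf_amp,
        drive_freq=fb.drive_freq,
        noise_rms=fb.noise_rms,
        seed=config.seed + _SEED_OFFSETS["stiffness"],
    )
    write_fiber_traces_csv(traces, outdir / "fiber_traces.csv")
    lf = trace_amplitude(traces.free_trace, traces.drive_freq, traces.sample_rate)
    lc = trace_amplitude(traces.loaded_trace, traces.drive_freq, traces.sample_rate)
    result = axial_stiffness(traces.kf, lf, lc)
    report["stages"]["stiffness"] = {
        "status": "ok",
        "kf": fb.kf,
        "lf_nm": result.lf,
        "lc_nm": result.lc,
        "kc": result.kc,
        "true_kc": fb.true_kc,
        "kc_rel_error": abs(result.kc - fb.true_kc) / fb.true_kc if fb.true_kc else None,
        "physical": result.physical,
        "artifacts": ["fiber_traces.csv"],
    }


def _cytology_stage(config: PipelineConfig, outdir: Path, report: dict) -> None:
    cg = config.cochleogram
    counts = gen_cochleogram(
        cg.locations,
        dict(cg.baseline),
        {age: dict(m) for age, m in cg.survival.items()},
        seed=config.seed + _SEED_OFFSETS["cochleogram"],
        baseline_age=cg.baseline_age,
    )
    counts.to_csv(outdir / "cochleogram_counts.csv", index=False)
    baseline = counts[counts["age"] == cg.baseline_age]
    aged = counts[counts["age"] != cg.baseline_age]
    surv = survival_percentage(aged, baseline)
    surv.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    mean_percent = {
        f"{ct}_{age}": float(g["percent"].mean())
        for (ct, age), g in surv.groupby(["cell_type", "age"])
    }

    fl = config.fluorescence
    quant = gen_fluorescence(
        dict(fl.targets),
        n_cells=fl.n_cells,
        seed=config.seed + _SEED_OFFSETS["fluorescence"],
        baseline_age=fl.baseline_age,
        aged_age=fl.aged_age,
    )
    quant.to_csv(outdir / "fluorescence.csv", index=False)
    base_age = fl.baseline_age
    baseline_q = quant[quant["age"] == base_age]
    aged_q = quant[quant["age"] != base_age]
    fc = integrated_density_foldchange(aged_q, baseline_q)
    fc.to_csv(outdir / "fluorescence_foldchange.tsv", sep="\t", index=False)

    # per-target Student t on integrated density, Holm-Sidak across targets
    pvals, targets = [], []
    for target, g in quant.groupby("target"):
        a = g[g["age"] != base_age]
        b = g[g["age"] == base_age]
        cmp_ = group_compare(
            a["mean_gray"] * a["area"], b["mean_gray"] * b["area"]
        )
        pvals.append(cmp_.p)
        targets.append(target)
    adjusted = holm_sidak(pvals)
    report["stages"]["cytology"] = {
        "status": "ok",
        "survival_mean_percent": mean_percent,
        "true_survival": {
            f"{ct}_{age}": float(p)
            for age, m in cg.survival.items()
            for ct, p in sorted(m.items())
        },
        "fluorescence_log2fc": {
            r["target"]: r["log2fc"] for _, r in fc.iterrows()
        },
        "fluorescence_p_holm_sidak": dict(zip(targets, map(float, adjusted))),
        "artifacts": [
            "cochleogram_counts.csv", "survival.tsv",
            "fluorescence.csv", "fluorescence_foldchange.tsv",
        ],
    }


_INDEPENDENT = {
    "nlc": _nlc_stage,
    "stiffness": _stiffness_stage,
    "cytology": _cytology_stage,
}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute enabled stages and write artifacts plus report.json.

    Returns the report dict. A stage exception marks that stage (and its
    dependents) failed; independent stages still run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "stages": {},
    }
    if "expression" in config.stages:
        try:
            _expression_and_deg(config, outdir, report)
        except CochlearAgingError as exc:
            logger.error("transcriptomics chain failed: %s", exc)
            for name in ("expression", "deg", "genesets"):
                if name in config.stages and name not in report["stages"]:
                    report["stages"][name] = {"status": "failed", "error": str(exc)}
    for name, fn in _INDEPENDENT.items():
        if name not in config.stages:
            continue
        try:
            fn(config, outdir, report)
        except CochlearAgingError as exc:
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc)}

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
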