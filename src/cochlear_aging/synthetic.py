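"""Synthetic inputs with known ground truth for every pipeline stage.

Five generators mirror the five kinds of study input:

* negative-binomial replicate RNA-seq counts (with RPKM derived from counts,
  gene lengths and library sizes) for three cell types at two ages, with
  planted aged-vs-young effects;
* voltage-clamp current under the two-sine protocol, integrating the patch
  circuit ODE with a Boltzmann membrane capacitance;
* calibrated-fiber displacement traces for axial-stiffness measurement
  (series-spring inversion of kc = kf*(Lf-Lc)/Lc);
* binomial-survival cochleogram count tables;
* lognormal fluorescence quantification tables with planted fold changes.

Every generator takes an explicit seed and owns one NumPy RNG stream; equal
seeds give identical output. Units: mV, MOhm, pF, nA, ms throughout the
electrophysiology (mV/MOhm = nA, MOhm*pF = us).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ProtocolError
from .expression import ExpressionMatrix, compute_rpkm
from .nlc import Segment, TwoSineProtocol, VCRecording, boltzmann_capacitance

__all__ = [
    "StudyDesign",
    "ExpressionStudy",
    "CircuitParams",
    "BoltzmannParams",
    "FiberTraces",
    "gen_expression_study",
    "gen_voltage_clamp_recording",
    "gen_fiber_traces",
    "gen_cochleogram",
    "gen_fluorescence",
    "write_recording_csv",
    "write_fiber_traces_csv",
]


# --------------------------------------------------------------------------
# transcriptome generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic two-age, multi-cell-type expression study.

    Defaults emulate the real study's layout: IHC/OHC/SVC populations at a
    young and an aged time point, replicate RNA-seq libraries, lognormal
    baseline expression, negative-binomial counting noise, and a planted
    excess of downregulated over upregulated genes in the aged samples.
    """

    n_genes: int = 2000
    n_replicates_per_group: int = 3
    cell_types: tuple[str, ...] = ("IHC", "OHC", "SVC")
    ages: tuple[str, str] = ("young", "aged")
    frac_up: float = 0.10
    frac_down: float = 0.20
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    mean_log_expression: float = 1.5  # ln RPKM; median ~4.5 RPKM
    sd_log_expression: float = 2.5  # wide, so a left tail falls below background
    library_size: float = 2e7
    gene_length_range: tuple[int, int] = (500, 4000)
    seed: int = 0
    # optional explicit planted sets per cell type: {ct: (up_genes, down_genes)}
    planted: Mapping[str, tuple[Sequence[str], Sequence[str]]] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates_per_group <= 0:
            raise ConfigurationError("n_genes and n_replicates_per_group must be positive")
        if not (0 <= self.frac_up and 0 <= self.frac_down and self.frac_up + self.frac_down <= 1):
            raise ConfigurationError("need frac_up, frac_down >= 0 and frac_up + frac_down <= 1")
        if len(self.ages) != 2 or self.ages[0] == self.ages[1]:
            raise ConfigurationError("exactly two distinct ages are required")
        if self.effect_log2fc < 0 or self.nb_dispersion < 0:
            raise ConfigurationError("effect_log2fc and nb_dispersion must be >= 0")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("invalid gene_length_range")


@dataclass
class ExpressionStudy:
    """Synthetic study: counts, derived RPKM, and planted-truth labels."""

    design: StudyDesign
    counts: ExpressionMatrix
    rpkm: ExpressionMatrix
    library_sizes: pd.Series  # per sample
    truth: pd.DataFrame  # genes x cell types, values in {"up", "down", "null"}

    def truth_sets(self, cell_type: str) -> tuple[set[str], set[str]]:
        col = self.truth[cell_type]
        return set(col.index[col == "up"]), set(col.index[col == "down"])

    def write_truth_json(self, path) -> None:
        payload = {
            ct: {
                "up": sorted(self.truth.index[self.truth[ct] == "up"]),
                "down": sorted(self.truth.index[self.truth[ct] == "down"]),
            }
            for ct in self.truth.columns
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; dispersion 0 -> Poisson."""
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def gen_expression_study(design: StudyDesign) -> ExpressionStudy:
    """Generate replicate counts and RPKM with planted age effects.

    Exactly round(frac_up*n_genes) genes per cell type carry a
    +effect_log2fc shift of the aged group mean, and round(frac_down*n_genes)
    carry -effect_log2fc; all remaining genes are unchanged ("null").
    """
    rng = np.random.default_rng(design.seed)
    genes = pd.Index(
        [f"Gene{i:05d}" for i in range(1, design.n_genes + 1)], name="gene_symbol"
    )
    lo, hi = design.gene_length_range
    lengths = pd.Series(rng.integers(lo, hi + 1, design.n_genes), index=genes, name="length_bp")
    base_rpkm = rng.lognormal(design.mean_log_expression, design.sd_log_expression, design.n_genes)
    base_mu = base_rpkm * lengths.to_numpy() * design.library_size / 1e9  # expected counts

    n_up = round(design.frac_up * design.n_genes)
    n_down = round(design.frac_down * design.n_genes)
    truth = pd.DataFrame("null", index=genes, columns=list(design.cell_types))
    planted_idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ct in design.cell_types:
        if design.planted is not None:
            up_g, down_g = design.planted.get(ct, ((), ()))
            up = genes.get_indexer(pd.Index(up_g))
            down = genes.get_indexer(pd.Index(down_g))
            if (up < 0).any() or (down < 0).any():
                raise ConfigurationError(f"planted genes for {ct} not in the gene list")
        else:
            perm = rng.permutation(design.n_genes)
            up, down = perm[:n_up], perm[n_up:n_up + n_down]
        planted_idx[ct] = (up, down)
        truth.iloc[up, truth.columns.get_loc(ct)] = "up"
        truth.iloc[down, truth.columns.get_loc(ct)] = "down"

    young, aged = design.ages
    columns: dict[str, np.ndarray] = {}
    for ct in design.cell_types:
        up, down = planted_idx[ct]
        for age in design.ages:
            mu = base_mu.copy()
            if age == aged:
                mu[up] *= 2.0 ** design.effect_log2fc
                mu[down] *= 2.0 ** -design.effect_log2fc
            for rep in range(1, design.n_replicates_per_group + 1):
                columns[f"{ct}_{age}_rep{rep}"] = _nb_draw(rng, mu, design.nb_dispersion)

    values = pd.DataFrame(columns, index=genes, dtype=float)
    counts = ExpressionMatrix(values=values, kind="counts", gene_lengths=lengths)
    lib = pd.Series(design.library_size, index=values.columns, name="library_size")
    rpkm = compute_rpkm(counts, lib)
    return ExpressionStudy(design=design, counts=counts, rpkm=rpkm, library_sizes=lib, truth=truth)


# --------------------------------------------------------------------------
# voltage-clamp simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitParams:
    """Patch recording circuit: series resistance, membrane resistance, Clin."""

    rs: float = 10.0  # MOhm
    rm: float = 500.0  # MOhm
    clin: float = 7.0  # pF

    def __post_init__(self) -> None:
        if self.rs < 0 or self.rm <= 0 or self.clin <= 0:
            raise ConfigurationError("require Rs >= 0, Rm > 0, Clin > 0")


@dataclass(frozen=True)
class BoltzmannParams:
    """Two-state Boltzmann NLC: max charge, slope factor, peak voltage."""

    qmax: float = 800.0  # fC
    alpha: float = 33.0  # mV
    vpk: float = -70.0  # mV

    def __post_init__(self) -> None:
        if self.qmax < 0 or self.alpha <= 0:
            raise ConfigurationError("require Qmax >= 0 and alpha > 0")


def gen_voltage_clamp_recording(
    circuit: CircuitParams,
    boltzmann: BoltzmannParams,
    protocol: TwoSineProtocol,
    noise_rms_pA: float = 0.0,
    seed: int = 0,
) -> VCRecording:
    """Integrate the patch circuit under the two-sine protocol.

    The membrane obeys C(Vm) dVm/dt = (Vc - Vm)/Rs - Vm/Rm with total
    capacitance C(V) = Clin + (Qmax/alpha) e^x/(1+e^x)^2, x = (V-Vpk)/alpha.
    Fixed-step classical Runge-Kutta at the sample rate. Recorded current is
    I = (Vc - Vm)/Rs, or the total membrane current when Rs = 0 (membrane
    follows the command exactly). Gaussian noise of the stated RMS (pA) is
    added to the current. Each DC level starts from its DC steady state and
    includes the protocol's settle window before the analysis segment.
    """
    proto = protocol
    rng = np.random.default_rng(seed)
    fs = proto.sample_rate
    dt_ms = 1000.0 / fs
    f1, f2 = proto.effective_f1, proto.effective_f2
    amp = proto.amplitude
    rs, rm, clin = circuit.rs, circuit.rm, circuit.clin
    q, a, vpk = boltzmann.qmax, boltzmann.alpha, boltzmann.vpk

    n_settle = proto.n_settle_samples
    n_seg = proto.n_segment_samples
    n_per_level = n_settle + n_seg
    n_total = n_per_level * len(proto.dc_levels)

    vcmd = np.empty(n_total)
    current = np.empty(n_total)
    segments: list[Segment] = []

    def cap(v: float) -> float:
        return float(boltzmann_capacitance(v, q, a, vpk, clin))

    for li, dc in enumerate(proto.dc_levels):
        off = li * n_per_level
        t_s = np.arange(n_per_level) / fs  # local time within level, s
        w1, w2 = 2 * np.pi * f1, 2 * np.pi * f2
        vc = dc + amp * (np.sin(w1 * t_s) + np.sin(w2 * t_s))
        vcmd[off:off + n_per_level] = vc
        if rs == 0:
            # membrane is clamped to the command: I = Vc/Rm + C(Vc) dVc/dt
            dvc_dt = amp * (w1 * np.cos(w1 * t_s) + w2 * np.cos(w2 * t_s)) * 1e-3  # mV/ms
            c = boltzmann_capacitance(vc, q, a, vpk, clin)
            current[off:off + n_per_level] = vc / rm + c * dvc_dt * 1e-3  # pA -> nA
        else:
            def vc_at(ts: float) -> float:
                return dc + amp * (np.sin(w1 * ts) + np.sin(w2 * ts))

            def deriv(ts: float, vm: float) -> float:
                # mV/ms; RHS currents in nA -> pA factor 1000 against C in pF
                return 1000.0 * ((vc_at(ts) - vm) / rs - vm / rm) / cap(vm)

            vm = dc * rm / (rs + rm)  # DC steady state
            dt_s = 1.0 / fs
            for k in range(n_per_level):
                ts = k * dt_s
                current[off + k] = (vc[k] - vm) / rs
                k1 = deriv(ts, vm)
                k2 = deriv(ts + dt_s / 2, vm + dt_ms * k1 / 2)
                k3 = deriv(ts + dt_s / 2, vm + dt_ms * k2 / 2)
                k4 = deriv(ts + dt_s, vm + dt_ms * k3)
                vm += dt_ms * (k1 + 2 * k2 + 2 * k3 + k4) / 6
        segments.append(Segment(start=off + n_settle, stop=off + n_per_level, dc_mV=dc))

    if noise_rms_pA > 0:
        current = current + rng.normal(0.0, noise_rms_pA * 1e-3, n_total)
    time_ms = np.arange(n_total) * dt_ms
    return VCRecording(
        time_ms=time_ms, vcmd_mV=vcmd, current_nA=current,
        sample_rate=fs, protocol=proto, segments=segments,
    )


def write_recording_csv(recording: VCRecording, path) -> None:
    """Trace CSV (time_ms, vcmd_mV, current_nA) plus a segment sidecar JSON."""
    df = pd.DataFrame(
        {
            "time_ms": recording.time_ms,
            "vcmd_mV": recording.vcmd_mV,
            "current_nA": recording.current_nA,
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "sample_rate_Hz": recording.sample_rate,
        "segments": [
            {"start": s.start, "stop": s.stop, "dc_mV": s.dc_mV}
            for s in recording.segments
        ],
    }
    with open(f"{path}.segments.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


# --------------------------------------------------------------------------
# fiber-motion generator
# --------------------------------------------------------------------------

@dataclass
class FiberTraces:
    """Free and loaded calibrated-fiber motion on a shared time base."""

    kf: float  # fiber stiffness (opaque stiffness units)
    drive_freq: float  # Hz, snapped to an integer-cycle grid
    sample_rate: float  # Hz
    time_ms: np.ndarray
    free_trace: np.ndarray  # nm
    loaded_trace: np.ndarray  # nm
    true_kc: float | None = None

    def __post_init__(self) -> None:
        if self.kf <= 0:
            raise ConfigurationError("fiber stiffness kf must be positive")
        if not (len(self.time_ms) == len(self.free_trace) == len(self.loaded_trace)):
            raise ConfigurationError("fiber traces must share one time base")


def gen_fiber_traces(
    kf: float,
    true_kc: float,
    Lf_amp: float,
    drive_freq: float = 100.0,
    noise_rms: float = 0.0,
    seed: int = 0,
    sample_rate: float = 10_000.0,
    n_cycles: int = 20,
) -> FiberTraces:
    """Simulate fiber motion for the series-spring stiffness measurement.

    Inverting kc = kf*(Lf - Lc)/Lc, the loaded amplitude is
    Lc = kf*Lf/(kf + kc). Both traces are sinusoids at the drive frequency
    (snapped to an integer number of cycles in the window) plus Gaussian
    noise of the stated RMS (nm).
    """
    if kf <= 0 or true_kc < 0 or Lf_amp <= 0:
        raise ConfigurationError("require kf > 0, true_kc >= 0, Lf_amp > 0")
    if drive_freq <= 0 or drive_freq > sample_rate / 2:
        raise ProtocolError("drive frequency must be positive and below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(n_cycles * sample_rate / drive_freq))
    k = max(1, round(drive_freq * n / sample_rate))
    f_eff = k * sample_rate / n
    t_s = np.arange(n) / sample_rate
    lc = kf * Lf_amp / (kf + true_kc)
    carrier = np.sin(2 * np.pi * f_eff * t_s)
    free = Lf_amp * carrier + rng.normal(0.0, noise_rms, n)
    loaded = lc * carrier + rng.normal(0.0, noise_rms, n)
    return FiberTraces(
        kf=kf, drive_freq=f_eff, sample_rate=sample_rate,
        time_ms=t_s * 1000.0, free_trace=free, loaded_trace=loaded, true_kc=true_kc,
    )


def write_fiber_traces_csv(traces: FiberTraces, path) -> None:
    pd.DataFrame(
        {
            "time_ms": traces.time_ms,
            "free_displacement_nm": traces.free_trace,
            "loaded_displacement_nm": traces.loaded_trace,
        }
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# cochleogram and fluorescence generators
# --------------------------------------------------------------------------

def gen_cochleogram(
    locations: Sequence[float],
    baseline_counts: Mapping[str, int | Sequence[int]],
    survival_prob: Mapping[str, Mapping[str, float | Sequence[float]]],
    seed: int = 0,
    baseline_age: str = "9mo",
) -> pd.DataFrame:
    """Binomial-survival cochleogram counts.

    ``baseline_counts`` maps cell type -> count (scalar or per-location).
    ``survival_prob`` maps aged-age label -> {cell type -> survival
    probability (scalar or per-location)}. Baseline rows are returned
    unchanged; each aged count is Binomial(baseline, p). Columns:
    location_um, cell_type, age, count.
    """
    rng = np.random.default_rng(seed)
    locs = np.asarray(list(locations), dtype=float)
    rows: list[dict] = []
    base: dict[str, np.ndarray] = {}
    for ct, counts in baseline_counts.items():
        arr = np.broadcast_to(np.asarray(counts, dtype=int), locs.shape).copy()
        if (arr < 0).any():
            raise ConfigurationError("baseline counts must be non-negative")
        base[ct] = arr
        for loc, n in zip(locs, arr):
            rows.append(
                {"location_um": loc, "cell_type": ct, "age": baseline_age, "count": int(n)}
            )
    for age in survival_prob:
        for ct in base:
            if ct not in survival_prob[age]:
                raise ConfigurationError(f"survival_prob missing cell type {ct!r} for {age!r}")
            p = np.broadcast_to(np.asarray(survival_prob[age][ct], dtype=float), locs.shape)
            if ((p < 0) | (p > 1)).any():
                raise ConfigurationError("survival probabilities must lie in [0, 1]")
            drawn = rng.binomial(base[ct], p)
            for loc, n in zip(locs, drawn):
                rows.append(
                    {"location_um": loc, "cell_type": ct, "age": age, "count": int(n)}
                )
    return pd.DataFrame(rows)


def gen_fluorescence(
    targets: Mapping[str, float],
    n_cells: int = 30,
    seed: int = 0,
    cell_type: str = "IHC",
    baseline_age: str = "9mo",
    aged_age: str = "22mo",
    log_gray_mu: float = 4.6,  # ln a.u., ~100
    log_gray_sigma: float = 0.3,
    log_area_mu: float = 3.9,  # ln px^2, ~50
    log_area_sigma: float = 0.2,
) -> pd.DataFrame:
    """Per-cell fluorescence quantification with planted fold changes.

    ``targets`` maps target label -> true log2 fold change of aged vs
    baseline integrated density (applied to the mean gray value). Columns:
    target, cell_type, age, cell, mean_gray, area.
    """
    if n_cells < 2:
        raise ConfigurationError("need at least 2 cells per group")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for target, fc in targets.items():
        for age, scale in ((baseline_age, 1.0), (aged_age, 2.0 ** fc)):
            gray = scale * rng.lognormal(log_gray_mu, log_gray_sigma, n_cells)
            area = rng.lognormal(log_area_mu, log_area_sigma, n_cells)
            for k in range(n_cells):
                rows.append(
                    {
                        "target": target, "cell_type": cell_type, "age": age,
                        "cell": k + 1, "mean_gray": gray[k], "area": area[k],
                    }
                )
    return pd.DataFrame(rows)
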