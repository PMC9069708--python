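"""Nonlinear membrane capacitance from two-sine voltage clamp.

Outer hair cells carry a bell-shaped, voltage-dependent "nonlinear"
capacitance (NLC) generated by prestin charge movement — the electrical
signature of electromotility. The measurement chain implemented here:

1. A small two-sine stimulus (peak ``amplitude`` at f1 and f2 = 2*f1) rides on
   a series of DC holding levels spanning the voltage range of interest.
2. For each DC segment the complex admittance Y(f) = I(f)/V(f) is read off
   the discrete Fourier coefficients of command and current.
3. The admittance pair (Y(f1), Y(f2)) over-determines the three-element
   patch circuit — series resistance Rs, membrane resistance Rm, membrane
   capacitance Cm — which is solved exactly per segment.
4. Cm versus (series-resistance-corrected) membrane potential is fitted with
   the derivative of a two-state Boltzmann:

       Cm(V) = Clin + (Qmax/alpha) * e^x / (1+e^x)^2,   x = (V-Vpk)/alpha

   yielding Qmax (fC), slope factor alpha (mV), voltage at peak capacitance
   Vpk (mV) and linear capacitance Clin (pF); charge density = Qmax/Clin.

Internal unit system: mV, MOhm, pF, nA, ms (mV/MOhm = nA; MOhm*pF = us;
admittances in uS = nA/mV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import FitError, ModelMismatchError, ProtocolError, SpectralLeakageError

__all__ = [
    "TwoSineProtocol",
    "Segment",
    "VCRecording",
    "CmPoint",
    "NLCFit",
    "boltzmann_capacitance",
    "rc_admittance",
    "fourier_admittance",
    "solve_rc_from_admittance",
    "cm_voltage_series",
    "fit_boltzmann",
    "fit_nlc_recording",
]


# --------------------------------------------------------------------------
# protocol and recording containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoSineProtocol:
    """Two-sine stimulus protocol.

    f1, f2 : nominal stimulus frequencies in Hz (f2 must equal 2*f1 within
        0.5%). Synthesis and analysis snap each to the nearest integer-cycle
        DFT bin of the analysis window, so the Fourier coefficients are
        leakage-free by construction.
    amplitude : peak amplitude of each sine, mV.
    dc_levels : holding potentials (mV), one analysis segment per level.
    segment_duration : analysis window per DC level, s.
    settle_duration : extra time at the start of each DC level excluded from
        analysis, letting the RC transient from the DC step decay.
    sample_rate : Hz.
    """

    f1: float = 390.6
    f2: float = 781.2
    amplitude: float = 10.0
    dc_levels: tuple[float, ...] = tuple(range(-140, 61, 10))
    segment_duration: float = 10 / 390.6
    settle_duration: float = 2 / 390.6
    sample_rate: float = 50_000.0

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise ProtocolError("stimulus frequencies must be positive")
        if abs(self.f2 - 2 * self.f1) > 0.005 * self.f2:
            raise ProtocolError("two-sine protocol requires f2 = 2*f1")
        if self.sample_rate < 20 * self.f2:
            raise ProtocolError(
                f"sample_rate {self.sample_rate} Hz < 20*f2 = {20 * self.f2} Hz"
            )
        if len(self.dc_levels) == 0:
            raise ProtocolError("at least one DC level is required")
        if self.n_segment_samples < 3 or self.f1_cycles < 3:
            raise ProtocolError("segment must span at least 3 cycles of f1")

    @property
    def n_segment_samples(self) -> int:
        return int(round(self.segment_duration * self.sample_rate))

    @property
    def n_settle_samples(self) -> int:
        return int(round(self.settle_duration * self.sample_rate))

    @property
    def f1_cycles(self) -> int:
        return int(round(self.f1 * self.n_segment_samples / self.sample_rate))

    @property
    def effective_f1(self) -> float:
        """f1 snapped to the integer-cycle grid of the analysis window."""
        return self.f1_cycles * self.sample_rate / self.n_segment_samples

    @property
    def effective_f2(self) -> float:
        return 2 * self.effective_f1

    def command_segment(self, dc_mV: float) -> np.ndarray:
        """Command waveform for one DC level (settle + analysis window), mV."""
        n = self.n_settle_samples + self.n_segment_samples
        t = np.arange(n) / self.sample_rate  # s
        return (
            dc_mV
            + self.amplitude * np.sin(2 * np.pi * self.effective_f1 * t)
            + self.amplitude * np.sin(2 * np.pi * self.effective_f2 * t)
        )


@dataclass(frozen=True)
class Segment:
    start: int  # index of first analysis sample
    stop: int  # one past last analysis sample
    dc_mV: float


@dataclass
class VCRecording:
    """Voltage-clamp recording under the two-sine protocol (uniform sampling)."""

    time_ms: np.ndarray
    vcmd_mV: np.ndarray
    current_nA: np.ndarray
    sample_rate: float
    protocol: TwoSineProtocol
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        if len(self.vcmd_mV) != n or len(self.current_nA) != n:
            raise ProtocolError("time, command and current must share one grid")


@dataclass
class CmPoint:
    """One membrane-capacitance sample from one DC segment."""

    v: float  # mV, series-resistance-corrected membrane potential
    cm: float  # pF
    rs_hat: float  # MOhm
    rm_hat: float  # MOhm
    residual: float  # relative RC-model mismatch
    a1_eff: float = 0.0  # membrane-level excursion amplitude at f1, mV
    a2_eff: float = 0.0  # at f2, mV
    ok: bool = True


@dataclass
class NLCFit:
    """Two-state Boltzmann fit of Cm(V)."""

    qmax: float  # fC
    alpha: float  # mV
    vpk: float  # mV
    clin: float  # pF
    charge_density: float  # fC/pF
    rss: float  # residual sum of squares, pF^2
    n_points: int
    converged: bool
    bracketed: bool  # fitted Vpk inside the measured voltage span
    message: str = ""
    rs: float = math.nan  # MOhm, full-waveform fits only
    rm: float = math.nan  # MOhm, full-waveform fits only

    def curve(self, v: np.ndarray) -> np.ndarray:
        return boltzmann_capacitance(v, self.qmax, self.alpha, self.vpk, self.clin)


# --------------------------------------------------------------------------
# model functions
# --------------------------------------------------------------------------

def _bell(x: np.ndarray) -> np.ndarray:
    # e^x/(1+e^x)^2, even in x; evaluated via e^-|x| for stability
    e = np.exp(-np.abs(x))
    return e / (1.0 + e) ** 2


def boltzmann_capacitance(
    v: np.ndarray | float, qmax: float, alpha: float, vpk: float, clin: float
) -> np.ndarray | float:
    """Total capacitance Clin + NLC(v) in pF (qmax fC, alpha/vpk mV)."""
    x = (np.asarray(v, dtype=float) - vpk) / alpha
    out = clin + (qmax / alpha) * _bell(x)
    return out if out.ndim else float(out)


def rc_admittance(rs: float, rm: float, cm: float, f: float) -> complex:
    """Closed-form admittance (uS) of the Rs-(Rm||Cm) circuit at f (Hz)."""
    w = 2 * np.pi * f * 1e-6  # rad/us; MOhm*pF = us
    zm = rm / (1 + 1j * w * rm * cm)
    return 1.0 / (rs + zm)


# --------------------------------------------------------------------------
# admittance extraction
# --------------------------------------------------------------------------

def fourier_admittance(
    vcmd_mV: np.ndarray, current_nA: np.ndarray, sample_rate: float, f: float
) -> complex:
    """Y(f) = I(f)/V(f) in uS from the DFT coefficients of a segment.

    The window must contain an integer number (>=1) of cycles of f; otherwise
    spectral leakage would bias the coefficients and a SpectralLeakageError
    is raised.
    """
    v = np.asarray(vcmd_mV, dtype=float)
    i = np.asarray(current_nA, dtype=float)
    n = len(v)
    if len(i) != n:
        raise ProtocolError("command and current segments differ in length")
    cycles = f * n / sample_rate
    k = round(cycles)
    if k < 1 or abs(cycles - k) > 1e-6 * max(1.0, cycles):
        raise SpectralLeakageError(
            f"{f} Hz spans {cycles:.6f} cycles in a {n}-sample window; "
            "an integer cycle count is required"
        )
    if f > sample_rate / 2:
        raise ProtocolError("frequency above Nyquist")
    phase = np.exp(-2j * np.pi * k * np.arange(n) / n)
    vc = np.dot(v - v.mean(), phase)
    ic = np.dot(i - i.mean(), phase)
    if vc == 0:
        raise ProtocolError(f"command has no component at {f} Hz")
    return complex(ic / vc)


def solve_rc_from_admittance(
    y1: complex,
    y2: complex,
    f1: float,
    f2: float,
    rtol: float = 0.05,
) -> tuple[float, float, float, float]:
    """Solve (Rs, Rm, Cm) from admittances at two frequencies.

    Uses the exact inversion: with Z(f) = 1/Y(f), the membrane branch obeys
    G(f) = 1/(Z(f) - Rs) = 1/Rm + j*w*Cm, so Re G is frequency-independent.
    Rs is the root of Re G(f1) - Re G(f2); Rm and Cm then follow in closed
    form. Returns (Rs MOhm, Rm MOhm, Cm pF, residual); residual is the worst
    relative deviation between the fitted model admittance and the inputs.

    Raises ModelMismatchError when no RC model reproduces the pair within
    ``rtol``.
    """
    if f1 == f2:
        raise ModelMismatchError("two distinct frequencies are required")
    if not (np.isfinite(y1) and np.isfinite(y2)):
        raise ModelMismatchError("non-finite admittance input")
    z1, z2 = 1.0 / y1, 1.0 / y2
    w1, w2 = 2 * np.pi * f1 * 1e-6, 2 * np.pi * f2 * 1e-6
    rs_max = min(z1.real, z2.real)
    if rs_max <= 0:
        raise ModelMismatchError("admittance has non-positive real impedance")

    def gap(rs: float) -> float:
        return (1.0 / (z1 - rs)).real - (1.0 / (z2 - rs)).real

    grid = np.linspace(0.0, rs_max * (1 - 1e-9), 513)
    vals = np.array([gap(r) for r in grid])
    candidates = [0.0]
    sign = np.sign(vals)
    for a, b in zip(range(len(grid) - 1), range(1, len(grid))):
        if sign[a] == 0:
            candidates.append(grid[a])
        elif sign[a] * sign[b] < 0:
            candidates.append(optimize.brentq(gap, grid[a], grid[b], xtol=1e-12))

    best: tuple[float, float, float, float] | None = None
    for rs in candidates:
        g1 = 1.0 / (z1 - rs)
        g2 = 1.0 / (z2 - rs)
        gm = (g1.real + g2.real) / 2
        cm = (g1.imag / w1 + g2.imag / w2) / 2
        if gm <= 0 or cm <= 0:
            continue
        rm = 1.0 / gm
        res = max(
            abs(rc_admittance(rs, rm, cm, f1) - y1) / abs(y1),
            abs(rc_admittance(rs, rm, cm, f2) - y2) / abs(y2),
        )
        if best is None or res < best[3]:
            best = (rs, rm, cm, res)
    if best is None or best[3] > rtol:
        detail = f" (best residual {best[3]:.3g})" if best else ""
        raise ModelMismatchError(
            "no RC circuit is consistent with the admittance pair" + detail
        )
    return best


def cm_voltage_series(recording: VCRecording) -> list[CmPoint]:
    """Per-segment (Rs, Rm, Cm) solve; failed segments flagged, not fatal.

    The reported potential is first-order series-resistance corrected:
    v = dc - I_dc * Rs_hat, the DC membrane potential under the divider.
    ``a1_eff``/``a2_eff`` are the stimulus amplitudes seen at the membrane
    (command attenuated by the Rs/Zm divider), used downstream to undo the
    excursion-averaging bias of the Boltzmann fit.
    """
    proto = recording.protocol
    f1, f2 = proto.effective_f1, proto.effective_f2
    points: list[CmPoint] = []
    for seg in recording.segments:
        v = recording.vcmd_mV[seg.start:seg.stop]
        i = recording.current_nA[seg.start:seg.stop]
        try:
            y1 = fourier_admittance(v, i, recording.sample_rate, f1)
            y2 = fourier_admittance(v, i, recording.sample_rate, f2)
            rs, rm, cm, res = solve_rc_from_admittance(y1, y2, f1, f2)
        except (ModelMismatchError, ProtocolError) as exc:
            points.append(
                CmPoint(
                    v=seg.dc_mV, cm=np.nan, rs_hat=np.nan, rm_hat=np.nan,
                    residual=np.nan, ok=False,
                )
            )
            warnings.warn(f"segment at {seg.dc_mV} mV failed: {exc}", stacklevel=2)
            continue
        i_dc = float(np.mean(i))
        v_m = seg.dc_mV - i_dc * rs
        atten = []
        for f, w in ((f1, 2 * np.pi * f1 * 1e-6), (f2, 2 * np.pi * f2 * 1e-6)):
            zm = rm / (1 + 1j * w * rm * cm)
            atten.append(abs(zm / (rs + zm)))
        points.append(
            CmPoint(
                v=v_m, cm=cm, rs_hat=rs, rm_hat=rm, residual=res,
                a1_eff=proto.amplitude * atten[0],
                a2_eff=proto.amplitude * atten[1],
            )
        )
    return points


# --------------------------------------------------------------------------
# Boltzmann fit
# --------------------------------------------------------------------------

def _model_cm(
    theta: np.ndarray,
    v: np.ndarray,
    a1: np.ndarray | None,
    a2: np.ndarray | None,
    phases: np.ndarray | None,
) -> np.ndarray:
    qmax, alpha, vpk, clin = theta
    if phases is None or a1 is None:
        return clin + (qmax / alpha) * _bell((v - vpk) / alpha)
    # cycle-average the bell over the membrane-level two-sine excursion:
    # what the admittance solve actually reports is <C(V(t))> over a cycle.
    dv = a1[:, None] * np.sin(phases)[None, :] + a2[:, None] * np.sin(2 * phases)[None, :]
    x = (v[:, None] + dv - vpk) / alpha
    return clin + (qmax / alpha) * _bell(x).mean(axis=1)


def fit_boltzmann(
    points: Sequence[CmPoint] | tuple[np.ndarray, np.ndarray],
    use_excursion: bool = True,
    n_phases: int = 64,
    alpha_starts: Sequence[float] = (20.0, 33.0, 50.0),
) -> NLCFit:
    """Least-squares two-state Boltzmann fit of a Cm(V) series.

    ``points`` is either a CmPoint list (failed points skipped) or a plain
    ``(v, cm)`` array pair. With ``use_excursion`` and CmPoint input, the
    model is averaged over each point's membrane-level stimulus excursion
    before comparing to the measured (cycle-averaged) Cm, removing the
    bell-broadening bias of a finite stimulus amplitude.

    Multi-start initialization over ``alpha_starts`` with Clin0 = min(cm),
    Vpk0 = argmax(cm), Qmax0 = 4*alpha0*(max-min). Requires >=5 points; a
    non-bracketing voltage span sets ``bracketed=False`` with a warning.
    """
    a1 = a2 = None
    if isinstance(points, tuple):
        v = np.asarray(points[0], dtype=float)
        cm = np.asarray(points[1], dtype=float)
    else:
        good = [p for p in points if p.ok and np.isfinite(p.cm)]
        v = np.array([p.v for p in good])
        cm = np.array([p.cm for p in good])
        if use_excursion and any(p.a1_eff > 0 for p in good):
            a1 = np.array([p.a1_eff for p in good])
            a2 = np.array([p.a2_eff for p in good])
    if len(v) < 5:
        raise FitError(f"need >=5 usable Cm points, got {len(v)}")
    phases = (
        2 * np.pi * (np.arange(n_phases) + 0.5) / n_phases if a1 is not None else None
    )

    clin0 = float(cm.min())
    vpk0 = float(v[np.argmax(cm)])
    span = float(cm.max() - cm.min())
    lower = np.array([0.0, 0.5, vpk0 - 500.0, 1e-6])
    upper = np.array([np.inf, 500.0, vpk0 + 500.0, np.inf])

    best = None
    for alpha0 in alpha_starts:
        x0 = np.array([max(4 * alpha0 * span, 1e-3), alpha0, vpk0, max(clin0, 1e-3)])
        try:
            sol = optimize.least_squares(
                lambda th: _model_cm(th, v, a1, a2, phases) - cm,
                x0,
                bounds=(lower, upper),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("Boltzmann fit failed to converge from every start")

    qmax, alpha, vpk, clin = (float(t) for t in best.x)
    bracketed = bool(v.min() <= vpk <= v.max())
    if not bracketed:
        warnings.warn(
            "fitted Vpk lies outside the measured voltage span; "
            "parameters are poorly constrained",
            stacklevel=2,
        )
    rss = float(2 * best.cost)
    return NLCFit(
        qmax=qmax,
        alpha=alpha,
        vpk=vpk,
        clin=clin,
        charge_density=qmax / clin if clin > 0 else math.nan,
        rss=rss,
        n_points=len(v),
        converged=bool(best.success),
        bracketed=bracketed,
        message=best.message,
    )


# --------------------------------------------------------------------------
# full-waveform fit through the measurement chain
# --------------------------------------------------------------------------
#
# With f2 = 2*f1 the quadratic term of the voltage-dependent charge mixes
# energy between the two stimulus bins (f1+f1 -> f2, f2-f1 -> f1), so the
# per-segment RC solve is slightly biased wherever dC/dV is large. The
# full-waveform estimator removes that bias by modelling the measurement
# chain itself: for candidate circuit + Boltzmann parameters it computes the
# periodic steady state of the clamp ODE at every DC level (spectral
# collocation on one f1 cycle, Newton iteration), reads off the model
# admittances at f1 and f2 exactly as the analysis does, and least-squares
# matches them to the measured admittances.

_DERIV_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _spectral_deriv_matrix(n: int, period_ms: float) -> np.ndarray:
    key = (n, period_ms)
    if key not in _DERIV_CACHE:
        wk = 2j * np.pi * np.fft.fftfreq(n) * n / period_ms  # rad/ms
        if n % 2 == 0:
            wk[n // 2] = 0.0
        D = np.fft.ifft(np.fft.fft(np.eye(n), axis=0) * wk[:, None], axis=0).real
        _DERIV_CACHE[key] = D
    return _DERIV_CACHE[key]


def _periodic_admittances(
    rs: float, rm: float, qmax: float, alpha: float, vpk: float, clin: float,
    dc: float, amplitude: float, n: int, f1: float,
) -> tuple[complex, complex]:
    """Model admittances (Y(f1), Y(f2)) in the periodic steady state.

    Solves C(Vm) dVm/dt = 1000*((Vc-Vm)/Rs - Vm/Rm) on one f1 cycle of n
    samples by Newton iteration with a spectral time-derivative, then forms
    Y(f) = I(f)/Vc(f) at the two stimulus bins.
    """
    period_ms = 1000.0 / f1
    phi = 2 * np.pi * np.arange(n) / n
    vc = dc + amplitude * (np.sin(phi) + np.sin(2 * phi))
    e1 = np.exp(-1j * phi)
    if rs == 0:
        D = _spectral_deriv_matrix(n, period_ms)
        c = clin + (qmax / alpha) * _bell((vc - vpk) / alpha)
        i = vc / rm + c * (D @ vc) * 1e-3  # pA -> nA
        vc1, vc2 = np.dot(vc, e1), np.dot(vc, e1 * e1)
        return complex(np.dot(i, e1) / vc1), complex(np.dot(i, e1 * e1) / vc2)
    D = _spectral_deriv_matrix(n, period_ms)
    g = 1000.0 * (1.0 / rs + 1.0 / rm)
    rhs_lin = 1000.0 * vc / rs

    v = np.full(n, dc * rm / (rs + rm))
    # linear-response warm start with C fixed at the DC operating point
    c0 = clin + (qmax / alpha) * float(_bell(np.asarray((v[0] - vpk) / alpha)))
    for f, k in ((f1, 1), (2 * f1, 2)):
        h = rc_admittance(rs, rm, c0, f)
        zm = 1.0 / h - rs
        div = zm / (rs + zm)
        # response to A*sin(k*phi) = Re[-jA e^{jk*phi}] through the divider
        v = v + np.real(div * (-1j * amplitude) * np.exp(1j * k * phi))
    for _ in range(50):
        x = (v - vpk) / alpha
        bell = _bell(x)
        c = clin + (qmax / alpha) * bell
        dv = D @ v
        # d(bell)/dx = bell * (1 - 2*sigmoid(x)); sigmoid via bell identity
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        dc_dv = (qmax / alpha**2) * bell * (1.0 - 2.0 * sig)
        F = c * dv + g * v - rhs_lin
        if np.max(np.abs(F)) < 1e-9 * max(1.0, np.max(np.abs(rhs_lin))):
            break
        J = c[:, None] * D + np.diag(dc_dv * dv + g)
        v = v - np.linalg.solve(J, F)
    i = (vc - v) / rs
    vc1, vc2 = np.dot(vc, e1), np.dot(vc, e1 * e1)
    return complex(np.dot(i, e1) / vc1), complex(np.dot(i, e1 * e1) / vc2)


def fit_nlc_recording(recording: VCRecording, rtol_init: float = 0.05) -> NLCFit:
    """Fit the Boltzmann NLC plus (Rs, Rm) to a two-sine recording.

    Measures Y(f1), Y(f2) per DC segment, initializes from the per-segment
    RC solve and a point-level Boltzmann fit, then refines all six
    parameters (Qmax, alpha, Vpk, Clin, Rs, Rm) against the measured
    admittances through the periodic steady-state forward model. This is
    the pipeline estimator: it is unbiased by the two-sine harmonic mixing
    that limits the point-level fit.
    """
    proto = recording.protocol
    f1 = proto.effective_f1
    n = round(recording.sample_rate / f1)
    if abs(n * f1 - recording.sample_rate) > 1e-6 * recording.sample_rate:
        raise ProtocolError("sample rate must be an integer multiple of f1")

    ys: list[tuple[float, complex, complex]] = []
    for seg in recording.segments:
        v = recording.vcmd_mV[seg.start:seg.stop]
        i = recording.current_nA[seg.start:seg.stop]
        y1 = fourier_admittance(v, i, recording.sample_rate, f1)
        y2 = fourier_admittance(v, i, recording.sample_rate, 2 * f1)
        ys.append((seg.dc_mV, y1, y2))
    points = cm_voltage_series(recording)
    init = fit_boltzmann(points)
    good = [p for p in points if p.ok]
    rs0 = float(np.median([p.rs_hat for p in good]))
    rm0 = float(np.median([p.rm_hat for p in good]))

    y_obs = np.concatenate([[y1.real, y1.imag, y2.real, y2.imag] for _, y1, y2 in ys])
    scale = np.concatenate([[abs(y1), abs(y1), abs(y2), abs(y2)] for _, y1, y2 in ys])

    def residual(theta: np.ndarray) -> np.ndarray:
        qmax, alpha, vpk, clin, rs, rm = theta
        model = []
        for dc, _, _ in ys:
            m1, m2 = _periodic_admittances(
                rs, rm, qmax, alpha, vpk, clin, dc, proto.amplitude, n, f1
            )
            model.extend([m1.real, m1.imag, m2.real, m2.imag])
        return (np.array(model) - y_obs) / scale

    x0 = np.array([init.qmax, init.alpha, init.vpk, init.clin, max(rs0, 1e-3), rm0])
    lower = np.array([0.0, 0.5, init.vpk - 200.0, 1e-6, 0.0, 1e-3])
    upper = np.array([np.inf, 500.0, init.vpk + 200.0, np.inf, np.inf, np.inf])
    sol = optimize.least_squares(
        residual, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    if not sol.success:
        raise FitError(f"full-waveform NLC fit failed: {sol.message}")
    qmax, alpha, vpk, clin, rs, rm = (float(t) for t in sol.x)
    vspan = [p.v for p in good]
    bracketed = bool(min(vspan) <= vpk <= max(vspan)) if vspan else False
    if not bracketed:
        warnings.warn(
            "fitted Vpk lies outside the measured voltage span; "
            "parameters are poorly constrained",
            stacklevel=2,
        )
    return NLCFit(
        qmax=qmax,
        alpha=alpha,
        vpk=vpk,
        clin=clin,
        charge_density=qmax / clin if clin > 0 else math.nan,
        rss=float(2 * sol.cost),
        n_points=len(ys),
        converged=True,
        bracketed=bracketed,
        message=sol.message,
        rs=rs,
        rm=rm,
    )
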