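"""Outer hair cell axial stiffness from calibrated-fiber motion.

A glass fiber of known stiffness kf is loaded onto the cell's apical
surface. Comparing the free motion amplitude of the fiber tip (Lf) with the
loaded amplitude (Lc) gives the cell's axial stiffness through the
series-spring relation

    kc = kf * (Lf - Lc) / Lc.

Amplitudes are read off the Fourier coefficient at the drive frequency of
the detrended trace, which rejects DC offsets and broadband noise.
Stiffness units are opaque and carried from kf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ProtocolError

__all__ = ["StiffnessResult", "trace_amplitude", "axial_stiffness"]


@dataclass
class StiffnessResult:
    kf: float
    lf: float  # free-fiber amplitude
    lc: float  # loaded-fiber amplitude
    kc: float  # axial stiffness, units of kf
    physical: bool = True  # False when Lf < Lc (negative kc)


def trace_amplitude(trace, drive_freq: float, sample_rate: float) -> float:
    """Amplitude at the drive frequency: 2*|DFT coefficient|/N, detrended.

    Requires drive_freq below Nyquist and a trace spanning at least 3 drive
    cycles.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if drive_freq <= 0 or drive_freq > sample_rate / 2:
        raise ProtocolError("drive frequency must be positive and below Nyquist")
    if n * drive_freq / sample_rate < 3:
        raise ProtocolError("trace must span at least 3 cycles of the drive frequency")
    phase = np.exp(-2j * np.pi * drive_freq * np.arange(n) / sample_rate)
    coeff = np.dot(x - x.mean(), phase)
    return float(2.0 * np.abs(coeff) / n)


def axial_stiffness(kf: float, lf: float, lc: float) -> StiffnessResult:
    """kc = kf*(Lf - Lc)/Lc from the free and loaded amplitudes.

    Lc = 0 means the load did not move at all (infinitely stiff cell) and is
    a division error. Lf < Lc is non-physical for a passive series spring:
    the negative kc is reported with ``physical=False`` and a warning.
    """
    if kf <= 0:
        raise ConfigurationError("fiber stiffness kf must be positive")
    if lf < 0 or lc < 0:
        raise ConfigurationError("amplitudes must be non-negative")
    if lc == 0:
        raise ZeroDivisionError(
            "loaded amplitude is zero: stiffness unbounded (infinitely stiff cell)"
        )
    kc = kf * (lf - lc) / lc
    physical = lf >= lc
    if not physical:
        warnings.warn(
            "loaded amplitude exceeds free amplitude; negative stiffness "
            "reported with physical=False",
            stacklevel=2,
        )
    return StiffnessResult(kf=kf, lf=lf, lc=lc, kc=kc, physical=physical)
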