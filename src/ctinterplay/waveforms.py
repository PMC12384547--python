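"""Periodic longitudinal breathing waveforms for a moving thoracic target.

The tumour surrogate in the motion phantom travels along the scanner axis
(superior-inferior) with a programmable periodic trace.  Two shapes are
provided:

``sinusoid``
    A plain cosine.  Phase zero puts the target at the exhale peak.

``exhale_weighted``
    A ``cos^(2n)`` profile (n >= 1) that dwells near the exhale plateau and
    dips briefly to inhale, the flat-topped trace characteristic of free
    breathing.  ``exhale_power`` is *n*; the default n=2 gives a cos^4 dip.

All waveforms are centred so their time average over one period is zero,
which makes the mean (average-CT) target position the origin of the
longitudinal coordinate.  Positive displacement points toward the head
(exhale for a lung target pushed superiorly at exhale).

Amplitude convention: by default ``amplitude_mm`` is the PEAK-TO-PEAK
excursion (the convention of programmable respiratory phantoms); set
``amplitude_convention="peak"`` to read it as the half excursion instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .exceptions import InvalidWaveformError

__all__ = ["BreathingWaveform", "mean_abs_displacement"]

_SHAPES = ("sinusoid", "exhale_weighted")
_CONVENTIONS = ("peak_to_peak", "peak")


@dataclass(frozen=True)
class BreathingWaveform:
    """Periodic longitudinal displacement of a breathing target.

    Parameters
    ----------
    amplitude_mm
        Motion amplitude in mm; peak-to-peak by default (see
        ``amplitude_convention``).
    rate_bpm
        Breathing rate in breaths per minute; the period is ``60 / rate_bpm``
        seconds.
    shape
        ``"sinusoid"`` or ``"exhale_weighted"``.
    exhale_power
        The *n* of the ``cos^(2n)`` exhale-weighted profile (ignored for the
        sinusoid).
    phase_s
        Start-phase offset in seconds; ``displacement(t)`` is evaluated at
        ``t + phase_s``.
    amplitude_convention
        ``"peak_to_peak"`` (default) or ``"peak"``.
    """

    amplitude_mm: float
    rate_bpm: float
    shape: str = "sinusoid"
    exhale_power: int = 2
    phase_s: float = 0.0
    amplitude_convention: str = "peak_to_peak"

    def __post_init__(self) -> None:
        if not (self.rate_bpm > 0) or not math.isfinite(self.rate_bpm):
            raise InvalidWaveformError(
                f"rate_bpm must be positive and finite, got {self.rate_bpm}"
            )
        if self.amplitude_mm < 0 or not math.isfinite(self.amplitude_mm):
            raise InvalidWaveformError(
                f"amplitude_mm must be non-negative, got {self.amplitude_mm}"
            )
        if self.shape not in _SHAPES:
            raise InvalidWaveformError(
                f"shape must be one of {_SHAPES}, got {self.shape!r}"
            )
        if self.shape == "exhale_weighted" and self.exhale_power < 1:
            raise InvalidWaveformError("exhale_power must be >= 1")
        if self.amplitude_convention not in _CONVENTIONS:
            raise InvalidWaveformError(
                f"amplitude_convention must be one of {_CONVENTIONS}"
            )

    @property
    def period_s(self) -> float:
        return 60.0 / self.rate_bpm

    @property
    def peak_to_peak_mm(self) -> float:
        if self.amplitude_convention == "peak":
            return 2.0 * self.amplitude_mm
        return self.amplitude_mm

    def displacement(self, t):
        """Longitudinal displacement (mm) about the mean position at time t (s).

        Accepts scalars or arrays; returns the same shape.
        """
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise InvalidWaveformError("time values must be finite")
        pp = self.peak_to_peak_mm
        theta = 2.0 * np.pi * (t + self.phase_s) / self.period_s
        if self.shape == "sinusoid":
            out = 0.5 * pp * np.cos(theta)
        else:
            # Lujan-type profile: position = exhale - pp * sin^(2n)(theta/2),
            # mean-centred.  sin^(2n) has period pi in its argument, so
            # theta/2 keeps the breathing period at 60/rate, and phase zero
            # sits on the exhale plateau (as for the sinusoid).
            n = self.exhale_power
            c = math.comb(2 * n, n) / 4.0**n  # time average of sin^(2n)
            out = pp * (c - np.sin(0.5 * theta) ** (2 * n))
        return out if out.ndim else float(out)


def mean_abs_displacement(w: BreathingWaveform, samples: int = 200_001) -> float:
    """Time average of |displacement| over one period, by numerical quadrature.

    This is the uniform-phase mean absolute offset of the target from its
    mean position — the fast-scan (snapshot) limit of the alignment error.
    For a sinusoid of peak-to-peak amplitude A it equals A/pi.
    """
    t = np.linspace(0.0, w.period_s, samples)
    d = np.abs(w.displacement(t))
    return float(simpson(d, x=t) / w.period_s)
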