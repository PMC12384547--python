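"""Published phantom commissioning summaries used as reference inputs.

Mean (Sigma) and sample SD (sigma) of 10 repeated longitudinal alignments of
a 3 cm sphere in a programmable respiratory motion phantom, measured on a
CT-on-rail unit for two helical protocols across a 3 x 3 grid of
peak-to-peak motion amplitudes and breathing rates.  These are measurement
summaries (inputs to the margin and Welch analyses), not simulator output.
"""

from __future__ import annotations

from .margins import ConditionSummary

__all__ = [
    "REFERENCE_N_SCANS",
    "REFERENCE_AMPLITUDES_MM",
    "REFERENCE_RATES_BPM",
    "reference_phantom_summaries",
]

REFERENCE_N_SCANS = 10
REFERENCE_AMPLITUDES_MM = (5.0, 10.0, 15.0)
REFERENCE_RATES_BPM = (8.0, 20.0, 28.0)

# (protocol, amplitude_mm, rate_bpm) -> (Sigma mm, sigma mm)
_REFERENCE_TABLE: dict[tuple[str, float, float], tuple[float, float]] = {
    ("standard", 5.0, 28.0): (0.7, 0.68),
    ("standard", 5.0, 20.0): (1.6, 1.60),
    ("standard", 5.0, 8.0): (1.7, 1.25),
    ("standard", 10.0, 28.0): (1.3, 0.83),
    ("standard", 10.0, 20.0): (2.3, 1.64),
    ("standard", 10.0, 8.0): (4.3, 2.00),
    ("standard", 15.0, 28.0): (2.1, 1.60),
    ("standard", 15.0, 20.0): (3.2, 2.10),
    ("standard", 15.0, 8.0): (5.2, 2.00),
    ("slow", 5.0, 28.0): (1.0, 0.00),
    ("slow", 5.0, 20.0): (1.6, 0.52),
    ("slow", 5.0, 8.0): (1.3, 0.95),
    ("slow", 10.0, 28.0): (0.9, 0.74),
    ("slow", 10.0, 20.0): (1.4, 1.27),
    ("slow", 10.0, 8.0): (2.0, 1.70),
    ("slow", 15.0, 28.0): (1.6, 0.85),
    ("slow", 15.0, 20.0): (1.3, 0.68),
    ("slow", 15.0, 8.0): (1.6, 1.69),
}


def reference_phantom_summaries() -> list[ConditionSummary]:
    """The 18 measured (Sigma, sigma, n=10) condition summaries."""
    return [
        ConditionSummary(
            protocol=protocol,
            amplitude_mm=amp,
            rate_bpm=rate,
            n=REFERENCE_N_SCANS,
            sigma_sys_mm=sig_sys,
            sigma_rand_mm=sig_rand,
        )
        for (protocol, amp, rate), (sig_sys, sig_rand) in _REFERENCE_TABLE.items()
    ]
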