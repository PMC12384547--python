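"""Synthetic datasets: simulated phantom scans and a synthetic patient cohort.

The package needs two kinds of input data, neither of which requires any
download:

* **Phantom alignment datasets** — produced by the helical acquisition
  simulator over the factorial condition grid, optionally perturbed by a
  zero-mean manual-alignment jitter (the residual of centring a contour by
  eye; default SD 0.3 mm) and then quantised to the couch readout
  granularity.

* **Patient cohorts** — per-fraction bone and tumour couch-shift triplets
  for a CBCT-guided thoracic SBRT population.  The longitudinal
  bone-minus-tumour difference (target drift relative to the vertebral
  anatomy) is drawn from a normal distribution, default mean -1.9 mm and SD
  1.7 mm; lateral and vertical differences are zero-mean.  An optional
  contamination component widens the tails toward range-scale extremes, and
  an optional patient-level random intercept adds between-patient
  correlation; both are off by default so the default model is exactly the
  stated normal.

Every generator takes an explicit seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .acquisition import AlignmentRecord, ExperimentConfig, run_phantom_experiment, _quantize
from .exceptions import ConfigError
from .workflow import CBCT, ShiftTriplet

__all__ = [
    "PatientFractionRecord",
    "CohortModel",
    "generate_cohort",
    "generate_phantom_dataset",
]


@dataclass(frozen=True)
class PatientFractionRecord:
    """One guidance session: bone and tumour couch shifts for one fraction."""

    patient_id: str
    fraction_index: int
    modality: str
    bone: ShiftTriplet
    gtv: ShiftTriplet

    @property
    def difference(self) -> ShiftTriplet:
        return self.bone - self.gtv

    @property
    def longitudinal_difference_mm(self) -> float:
        return self.bone.longitudinal_mm - self.gtv.longitudinal_mm


@dataclass(frozen=True)
class CohortModel:
    """Generative model of a CBCT-guided thoracic SBRT cohort.

    ``mean_mm``/``sd_mm`` parameterise the longitudinal bone-minus-tumour
    difference; ``patient_sd_mm`` adds a per-patient random intercept on top
    of the fraction-level noise; ``outlier_fraction`` mixes in a wider
    normal (SD ``outlier_sd_mm``) to emulate occasional large drifts.
    """

    n_patients: int = 31
    fractions_per_patient: int = 4
    mean_mm: float = -1.9
    sd_mm: float = 1.7
    lateral_vertical_sd_mm: float = 1.5
    bone_setup_sd_mm: float = 3.0
    patient_sd_mm: float = 0.0
    outlier_fraction: float = 0.0
    outlier_sd_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.fractions_per_patient < 1:
            raise ConfigError("cohort must have >= 1 patient and >= 1 fraction")
        for attr in ("sd_mm", "lateral_vertical_sd_mm", "bone_setup_sd_mm",
                     "patient_sd_mm", "outlier_sd_mm"):
            if getattr(self, attr) < 0:
                raise ConfigError(f"{attr} must be non-negative")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ConfigError("outlier_fraction must lie in [0, 1]")


def generate_cohort(model: CohortModel) -> list[PatientFractionRecord]:
    """Draw a reproducible synthetic cohort from the generative model.

    Bone shifts per axis are zero-mean normal (setup error scale); tumour
    shifts are bone minus the drawn difference, so the bone-minus-tumour
    differences follow the stated model exactly.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_patients * model.fractions_per_patient
    intercepts = rng.normal(0.0, model.patient_sd_mm, size=model.n_patients)
    long_diff = model.mean_mm + np.repeat(intercepts, model.fractions_per_patient)
    long_diff = long_diff + rng.normal(0.0, model.sd_mm, size=n)
    if model.outlier_fraction > 0:
        is_outlier = rng.random(n) < model.outlier_fraction
        wide = rng.normal(model.mean_mm, model.outlier_sd_mm, size=n)
        long_diff = np.where(is_outlier, wide, long_diff)
    lat_diff = rng.normal(0.0, model.lateral_vertical_sd_mm, size=n)
    vert_diff = rng.normal(0.0, model.lateral_vertical_sd_mm, size=n)
    bone = rng.normal(0.0, model.bone_setup_sd_mm, size=(n, 3))

    records = []
    k = 0
    for pid in range(model.n_patients):
        for fx in range(model.fractions_per_patient):
            b = ShiftTriplet(*bone[k])
            g = ShiftTriplet(
                b.lateral_mm - lat_diff[k],
                b.longitudinal_mm - long_diff[k],
                b.vertical_mm - vert_diff[k],
            )
            records.append(
                PatientFractionRecord(
                    patient_id=f"P{pid + 1:03d}",
                    fraction_index=fx + 1,
                    modality=CBCT,
                    bone=b,
                    gtv=g,
                )
            )
            k += 1
    return records


def generate_phantom_dataset(
    config: ExperimentConfig,
    jitter_sd_mm: float = 0.3,
    readout_quantum_mm: float | None = None,
) -> list[AlignmentRecord]:
    """Simulated phantom dataset with manual-alignment jitter and readout.

    Runs the factorial experiment unquantised, adds zero-mean Gaussian
    jitter (manual centring residual), then quantises to the readout
    granularity.  The jitter stream is drawn from ``config.seed + 1`` so it
    is independent of the start-phase stream but still reproducible.
    """
    if jitter_sd_mm < 0:
        raise ConfigError("jitter_sd_mm must be non-negative")
    quantum = (
        config.readout_quantum_mm if readout_quantum_mm is None else readout_quantum_mm
    )
    raw = run_phantom_experiment(replace(config, readout_quantum_mm=0.0))
    rng = np.random.default_rng(config.seed + 1)
    jitter = (
        rng.normal(0.0, jitter_sd_mm, size=len(raw))
        if jitter_sd_mm > 0
        else np.zeros(len(raw))
    )
    out = []
    for rec, j in zip(raw, jitter):
        err = float(_quantize(np.asarray(rec.signed_error_mm + j), quantum))
        out.append(replace(rec, signed_error_mm=err))
    return out
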