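"""Run configuration: a YAML-serialisable bundle of all pipeline settings.

Defaults equal the study conditions: two helical protocols (standard and
slow), amplitudes 5/10/15 mm, rates 8/20/28 BPM, 10 repeats, 1 mm readout,
alpha 0.05, 5 mm stability threshold, and the default cohort model.  The
config round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .acquisition import SLOW_PROTOCOL, STANDARD_PROTOCOL, ExperimentConfig, ScanProtocol
from .exceptions import ConfigError
from .margins import MarginParameters
from .synthetic import CohortModel

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    jitter_sd_mm: float = 0.3
    margin: MarginParameters = field(default_factory=MarginParameters)
    alpha: float = 0.05
    stability_threshold_mm: float = 5.0
    cohort: CohortModel = field(default_factory=CohortModel)
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        d["experiment"]["protocols"] = [asdict(p) for p in self.experiment.protocols]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            exp = dict(d.pop("experiment", {}))
            protocols = exp.pop("protocols", None)
            if protocols is not None:
                exp["protocols"] = tuple(ScanProtocol(**p) for p in protocols)
            else:
                exp["protocols"] = (STANDARD_PROTOCOL, SLOW_PROTOCOL)
            margin = MarginParameters(**d.pop("margin", {}))
            cohort = CohortModel(**d.pop("cohort", {}))
            return cls(
                experiment=ExperimentConfig(**exp),
                margin=margin,
                cohort=cohort,
                **d,
            )
        except TypeError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self,
            experiment=dataclasses.replace(self.experiment, seed=seed),
            cohort=dataclasses.replace(self.cohort, seed=seed),
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError("configuration file must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
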