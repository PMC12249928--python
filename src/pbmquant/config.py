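"""Run configuration: one validated YAML document drives the demo pipeline.

Every block mirrors one analysis stage; unknown keys are rejected so a
typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as _PydanticError

from .errors import ConfigError


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortMotilityParams(_Block):
    """One simulated cohort; fields follow MotilityModelParams."""

    model: Literal["brownian", "prw", "ballistic", "stationary"] = "prw"
    step_sigma: float = 1.0
    speed: float = 0.4
    persistence_time: float = 30.0
    n_tracks: int = 30


class MotilityBlock(_Block):
    delta_t_min: float = 10.0
    n_steps: int = 36
    fit_max_lag_frac: float = 0.25
    fit_min_lags: int = 3
    control: CohortMotilityParams = CohortMotilityParams()
    # illustrative treatment effect: faster persistent migration
    treated: CohortMotilityParams = CohortMotilityParams(speed=0.7)


class WoundBlock(_Block):
    height: int = 320
    width: int = 320
    times_h: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    control_fractions: tuple[float, ...] = (0.30, 0.24, 0.18, 0.12)
    # thinnest gap kept wider than the texture window so it stays resolvable
    treated_fractions: tuple[float, ...] = (0.30, 0.20, 0.12, 0.06)
    noise_sigma: float = 4.0
    variance_window: int = 9
    closing_radius: int = 5


class MorphometricsBlock(_Block):
    height: int = 256
    width: int = 256
    n_nuclei: int = 60
    control_positive_fraction: float = 0.2
    treated_positive_fraction: float = 0.4
    n_puncta: int = 25
    puncta_axis_ratio: float = 3.0
    noise_sigma: float = 0.0


class QpcrBlock(_Block):
    genes: tuple[str, ...] = ("Gapdh", "Col1a1", "Acta2", "Fn1")
    reference_gene: str = "Gapdh"
    true_log2_fold: tuple[float, ...] = (0.0, 1.0, 0.5, -0.5)
    ct_noise_sd: float = 0.05
    n_replicates: int = 3
    n_samples: int = 3
    calibrator_condition: str = "control"


class DoseChannel(_Block):
    wavelength_nm: float
    power_mw: float


class DoseBlock(_Block):
    channels: tuple[DoseChannel, ...] = (
        DoseChannel(wavelength_nm=670, power_mw=13.6),
        DoseChannel(wavelength_nm=780, power_mw=3.71),
        DoseChannel(wavelength_nm=830, power_mw=61.1),
        DoseChannel(wavelength_nm=910, power_mw=11.1),
    )
    on_time_us: float = 1400.0
    off_time_us: float = 200.0
    duration_min: float = 20.0
    area_cm2: float = 1.0


class RunConfig(_Block):
    """Full demo-run configuration (all stage blocks are required)."""

    seed: int = 0
    outdir: Path = Path("pbmquant_demo")
    log_level: str = "INFO"
    motility: MotilityBlock
    wound: WoundBlock
    morphometrics: MorphometricsBlock
    qpcr: QpcrBlock
    dose: DoseBlock

    @classmethod
    def default(cls, seed: int = 0, outdir: str | Path = "pbmquant_demo") -> "RunConfig":
        return cls(
            seed=seed,
            outdir=Path(outdir),
            motility=MotilityBlock(),
            wound=WoundBlock(),
            morphometrics=MorphometricsBlock(),
            qpcr=QpcrBlock(),
            dose=DoseBlock(),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(doc)
        except _PydanticError as exc:
            missing = [
                ".".join(str(p) for p in e["loc"])
                for e in exc.errors()
                if e["type"] == "missing"
            ]
            if missing:
                raise ConfigError(f"missing config block(s): {', '.join(missing)}") from exc
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = yaml.safe_dump(
            yaml.safe_load(self.model_dump_json()), sort_keys=True
        )
        if path is not None:
            Path(path).write_text(doc, encoding="utf-8")
        return doc
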