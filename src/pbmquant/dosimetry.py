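"""Dosimetry for a pulsed multi-wavelength LED source.

For square-pulse operation the duty cycle is t_on/(t_on + t_off); the
time-averaged radiant power of the whole device is the duty cycle times
the summed per-channel output powers; session energy is average power ×
exposure time, and fluence is energy per illuminated area:

    duty = t_on / (t_on + t_off)
    P_avg = duty · Σ_λ P_λ
    E = P_avg · T
    fluence = E / A        [J/cm²]

The reported fluence is duty-cycle-inclusive: it is the energy actually
delivered during pulsed operation, not the continuous-wave equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ParameterError


@dataclass(frozen=True)
class LEDChannel:
    """One emitter: wavelength (nm) and output power.

    Power may be given in mW (default) or W/J·s⁻¹ (``unit='W'``);
    stored internally in watts.
    """

    wavelength_nm: float
    power: float
    unit: str = "mW"

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ParameterError("wavelength must be > 0")
        if self.power < 0:
            raise ParameterError("output power must be >= 0")
        if self.unit not in ("mW", "W"):
            raise ParameterError(f"unknown power unit {self.unit!r}")

    @property
    def power_w(self) -> float:
        return self.power / 1000.0 if self.unit == "mW" else self.power


@dataclass(frozen=True)
class PulseSpec:
    """Square-pulse timing in microseconds; off_time 0 = continuous wave."""

    on_time_us: float
    off_time_us: float

    def __post_init__(self) -> None:
        if self.on_time_us <= 0:
            raise ParameterError("on_time must be > 0")
        if self.off_time_us < 0:
            raise ParameterError("off_time must be >= 0")

    @property
    def duty_cycle(self) -> float:
        return self.on_time_us / (self.on_time_us + self.off_time_us)


@dataclass(frozen=True)
class DoseResult:
    """Session dose with per-channel breakdown (energies sum to the total)."""

    duty_cycle: float
    average_power_mw: float
    session_energy_j: float
    fluence_j_per_cm2: float
    duration_s: float
    area_cm2: float
    per_channel: pd.DataFrame  # wavelength_nm, power_mw, avg_power_mw, energy_j

    def to_frame(self) -> pd.DataFrame:
        return self.per_channel

    def summary(self) -> str:
        lines = [
            "Pulsed LED dose",
            "=" * 46,
            f"duty cycle        {self.duty_cycle:.4f}",
            f"average power     {self.average_power_mw:.3f} mW",
            f"session energy    {self.session_energy_j:.3f} J "
            f"({self.duration_s:.0f} s)",
            f"fluence           {self.fluence_j_per_cm2:.2f} J/cm^2 "
            f"over {self.area_cm2:g} cm^2",
            "-" * 46,
        ]
        for _, r in self.per_channel.iterrows():
            lines.append(
                f"  {r['wavelength_nm']:6.0f} nm  {r['power_mw']:7.2f} mW  "
                f"-> {r['energy_j']:7.3f} J"
            )
        return "\n".join(lines)


def compute_dose(
    channels: Sequence[LEDChannel],
    pulse: PulseSpec,
    duration_s: float,
    area_cm2: float,
) -> DoseResult:
    """Duty cycle, average power, session energy and fluence for one session."""
    if not channels:
        raise ParameterError("need at least one LED channel")
    if duration_s <= 0:
        raise ParameterError("duration must be > 0")
    if area_cm2 <= 0:
        raise ParameterError("area must be > 0")
    duty = pulse.duty_cycle
    rows = []
    for ch in channels:
        avg_w = duty * ch.power_w
        rows.append(
            {
                "wavelength_nm": ch.wavelength_nm,
                "power_mw": ch.power_w * 1000.0,
                "avg_power_mw": avg_w * 1000.0,
                "energy_j": avg_w * duration_s,
            }
        )
    per_channel = pd.DataFrame(rows)
    energy = float(per_channel["energy_j"].sum())
    return DoseResult(
        duty_cycle=duty,
        average_power_mw=float(per_channel["avg_power_mw"].sum()),
        session_energy_j=energy,
        fluence_j_per_cm2=energy / area_cm2,
        duration_s=duration_s,
        area_cm2=area_cm2,
        per_channel=per_channel,
    )


#: the study device: four pulsed diodes, 670/780/830/910 nm
DEFAULT_DEVICE = (
    LEDChannel(670, 13.6),
    LEDChannel(780, 3.71),
    LEDChannel(830, 61.1),
    LEDChannel(910, 11.1),
)
DEFAULT_PULSE = PulseSpec(on_time_us=1400, off_time_us=200)
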