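"""Run configuration for the simulator and the analysis pipeline.

All bench-level assumptions live here so that every stage of the pipeline
(simulation, spectral analysis, denoising, feature extraction, training)
reads from one declarative record.  Configurations round-trip through plain
dictionaries and can therefore be loaded from JSON or YAML files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: The five solution concentrations measured on the bench, in mg/mL.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.69, 0.81, 0.91, 1.03, 1.08)


@dataclass
class DielectricLaw:
    """Affine dielectric law for aqueous glucose solutions.

    Over the physiological range the real permittivity grows with glucose
    concentration while the loss tangent shrinks; the simplest law with both
    trends is affine in the concentration ``c`` (mg/mL)::

        eps_real(c)     = a0 + a1 * c          (a1 > 0)
        loss_tangent(c) = b0 - b1 * c          (b1 > 0)

    The default coefficients are bench assumptions chosen so that the
    back-plate return remains a visible fraction of the echo at 77 GHz
    through a centimetre of solution; they are not literature values for
    saline, which is considerably lossier at this frequency.
    """

    a0: float = 6.0
    a1: float = 0.4
    b0: float = 0.050
    b1: float = 0.025
    #: concentrations outside this range raise a ``ValueError``
    valid_range: tuple[float, float] = (0.5, 1.5)

    def eps_real(self, c: float) -> float:
        return self.a0 + self.a1 * c

    def loss_tangent(self, c: float) -> float:
        return self.b0 - self.b1 * c


@dataclass
class SimulationConfig:
    """Everything the synthetic-echo generator needs.

    Parameters
    ----------
    n_samples
        Beat-record length N.  The acquisition chain stores 64 complex
        samples per record.
    carrier_hz
        Radar carrier (77 GHz automotive band).
    thickness_m
        One-way propagation path through the solution.
    beat_freq_bins
        Beat-tone frequency expressed in DFT bins of the unpadded record.
        Kept in the lowest eighth of the band, and deliberately fractional
        so that the coarse DFT grid straddles the tone (the picket-fence
        situation the 16x zero-padding is meant to resolve).
    incidence_angle_rad
        Angle of incidence onto the solution surface.
    backplate_reflectivity
        Magnitude of the metal back-plate reflection, in [0, 1].
    snr_db
        Per-record signal-to-noise ratio of the additive thermal noise.
    drift_gain_sigma
        Log-normal sigma of the per-power-cycle multiplicative gain.
    drift_offset_sigma
        Std of the per-power-cycle complex DC offset, relative to the
        echo amplitude scale.
    antenna_gains
        Small fixed gain spread of the three transmit antennas.
    """

    n_samples: int = 64
    carrier_hz: float = 77e9
    thickness_m: float = 0.006
    beat_freq_bins: float = 3.3
    incidence_angle_rad: float = 0.0
    backplate_reflectivity: float = 0.9
    dielectric: DielectricLaw = field(default_factory=DielectricLaw)
    snr_db: float = 20.0
    drift_gain_sigma: float = 0.05
    drift_offset_sigma: float = 0.02
    antenna_gains: tuple[float, ...] = (1.0, 0.97, 1.03)
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    records_per_class: int = 200
    n_power_cycles: int = 8
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "dielectric" in d and isinstance(d["dielectric"], dict):
            law = d["dielectric"]
            if "valid_range" in law:
                law["valid_range"] = tuple(law["valid_range"])
            d["dielectric"] = DielectricLaw(**law)
        for key in ("antenna_gains", "concentrations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config() -> SimulationConfig:
    """Return the default bench configuration."""
    return SimulationConfig()


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a JSON or YAML file.

    The file may either be a flat mapping of config fields or nest them
    under a top-level ``simulate`` key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    if "simulate" in data:
        data = data["simulate"]
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    data = {"simulate": cfg.to_dict()}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))
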