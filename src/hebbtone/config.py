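"""Run configuration: one serializable object that fully determines a run.

A :class:`RunConfig` mirrors the command-line surface; it can be loaded from
a YAML or JSON file, overridden field-by-field from CLI flags, and is echoed
verbatim into every output sidecar so a run is reproducible from its own
artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .hebbnet import TrainingParams
from .lattice import C0_HZ, ToneLattice
from .stimuli import AmplitudeSignature, SweepSchedule

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field path."""


@dataclass(frozen=True)
class RunConfig:
    # lattice
    f_ref: float = C0_HZ
    resolution_cents: float = 10.0
    n_octaves: int = 10
    # signature
    n_harmonics: int = 5
    amplitudes: Optional[tuple[float, ...]] = None  # default: linear descent
    # schedule
    order: str = "ascending"
    n_sweeps: int = 3
    repetitions: int = 2
    # params
    eta: float = 1.0
    kappa: float = 0.02
    propagation_floor: float = 0.0
    transfer: str = "relative"
    seed: int = 0
    # model / storage
    model: str = "hebb"  # "hebb" | "terhardt"
    storage: str = "auto"
    # analysis
    tonic_cents: Optional[float] = None  # default: C4 (4800 cents) if in range
    window_cents: float = 1200.0
    k_top: int = 6
    tolerance_cents: Optional[float] = None
    # output
    out_dir: str = "hebbtone-out"

    # ------------------------------------------------------------------
    def lattice(self) -> ToneLattice:
        try:
            return ToneLattice(
                f_ref=self.f_ref,
                resolution_cents=self.resolution_cents,
                n_octaves=self.n_octaves,
            )
        except ValueError as exc:
            raise ConfigError(f"lattice: {exc}") from exc

    def signature(self) -> AmplitudeSignature:
        try:
            if self.amplitudes is not None:
                return AmplitudeSignature(tuple(self.amplitudes))
            return AmplitudeSignature.linear(self.n_harmonics)
        except ValueError as exc:
            raise ConfigError(f"signature: {exc}") from exc

    def schedule(self) -> SweepSchedule:
        try:
            return SweepSchedule(
                order=self.order,
                n_sweeps=self.n_sweeps,
                repetitions=self.repetitions,
                seed=self.seed,
            )
        except ValueError as exc:
            raise ConfigError(f"schedule: {exc}") from exc

    def params(self) -> TrainingParams:
        try:
            return TrainingParams(
                eta=self.eta,
                kappa=self.kappa,
                propagation_floor=self.propagation_floor,
                transfer=self.transfer,
                seed=self.seed,
            )
        except ValueError as exc:
            raise ConfigError(f"params: {exc}") from exc

    def tonic_index(self) -> int:
        lat = self.lattice()
        cents = self.tonic_cents
        if cents is None:
            cents = 4800.0 if lat.n_octaves >= 5 else lat.n_tones // 2 * lat.resolution_cents
        idx = cents / lat.resolution_cents
        if abs(idx - round(idx)) > 1e-9:
            raise ConfigError(
                f"analysis.tonic: {cents} cents is not a lattice point at "
                f"{lat.resolution_cents}-cent resolution"
            )
        if not 0 <= round(idx) < lat.n_tones:
            raise ConfigError(f"analysis.tonic: {cents} cents outside the lattice")
        return int(round(idx))

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if d["amplitudes"] is not None:
            d["amplitudes"] = list(d["amplitudes"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if data.get("amplitudes") is not None:
            data = {**data, "amplitudes": tuple(data["amplitudes"])}
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def override(self, **kwargs: Any) -> "RunConfig":
        """CLI flags take precedence over file values: None means 'keep'."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
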