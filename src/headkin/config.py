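"""Run configuration: one serializable object holding every tunable the
pipeline consumes, plus a content hash embedded in outputs for provenance."""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .errors import InvalidSpecError


@dataclass
class PipelineConfig:
    # channel-class filter
    cfc: float = 1000.0
    padding: str = "reflect"
    pad_ms: float = 10.0
    # spike screening (skull channels; the machine stream is not screened
    # unless screen_machine is set)
    min_peak: float = 100.0
    min_width_ms: float = 0.4
    max_neighbor_jump: float = 0.3
    neighborhood_ms: float = 1.0
    strict_spikes: bool = False
    screen_machine: bool = False
    # rise conventions
    rise_fraction: float = 0.05
    pre_window_ms: float = 4.0
    # reporting
    report_decimals: int = 1
    # IHC
    stain_preset: str = "hdab"
    app_threshold: float | None = None
    igg_threshold: float | None = None
    size_filter_um: tuple[float, float] = (2.0, 50.0)
    # randomness
    seed: int = 0

    def filter_spec(self):
        from .sigproc import FilterSpec

        return FilterSpec(cfc=self.cfc, padding=self.padding, pad_ms=self.pad_ms)

    def spike_params(self):
        from .kinmetrics import SpikeRejectionParams

        return SpikeRejectionParams(
            min_peak=self.min_peak,
            min_width_ms=self.min_width_ms,
            max_neighbor_jump=self.max_neighbor_jump,
            neighborhood_ms=self.neighborhood_ms,
            strict=self.strict_spikes,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_filter_um"] = list(d["size_filter_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        if "size_filter_um" in d:
            d = dict(d, size_filter_um=tuple(d["size_filter_um"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Short content hash of the canonical JSON rendering."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
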