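"""Run configuration: YAML or JSON, sections mirroring the processing
stages (io, kernels, topo, bins, smoothing, solar_reference, sampling,
assessment)."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from .brdf import NdviBinSpec, SMOOTHING_MODES
from .errors import ConfigurationError
from .kernels import KernelChoice, KernelShapeConstants
from .solar import SolarReferenceSpec


@dataclass
class LineConfig:
    reflectance: str
    observation: str
    name: str = ""

    def __post_init__(self):
        if not self.name:
            base = os.path.basename(self.reflectance)
            self.name = os.path.splitext(base)[0] or base


@dataclass
class RunConfig:
    lines: list  # list[LineConfig]
    output_dir: str = "."
    scale_divisor: float = 1.0
    obs_band_map: dict | None = None
    kernel_choice: KernelChoice = field(default_factory=KernelChoice)
    kernel_constants: KernelShapeConstants = field(default_factory=KernelShapeConstants)
    topo_enabled: bool = True
    topo_min_sample: int = 1000
    topo_b_threshold: float = 1e-6
    topo_seed: int = 0
    bins: NdviBinSpec = field(default_factory=NdviBinSpec)
    smoothing: str = "linear_interpolation"
    smoothing_range: tuple = (0.25, 0.85)
    solar_reference: SolarReferenceSpec = field(default_factory=SolarReferenceSpec)
    per_bin: int = 10000
    sampling_seed: int = 42
    band_subset: list | None = None
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.lines:
            raise ConfigurationError("config lists no flightlines")
        if self.smoothing not in SMOOTHING_MODES:
            raise ConfigurationError(f"unknown smoothing method {self.smoothing!r}")

    def validate_files(self):
        for line in self.lines:
            for path in (line.reflectance, line.observation):
                if not (os.path.exists(path) or os.path.exists(path + ".hdr")):
                    raise ConfigurationError(f"input file not found: {path}")

    def config_hash(self):
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _parse_date(value):
    if value is None or isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        if str(path).endswith(".json"):
            raw = json.load(fh)
        else:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("config file does not contain a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    io = raw.get("io", {})
    lines = [LineConfig(**entry) for entry in io.get("lines", [])]
    kern = raw.get("kernels", {})
    topo = raw.get("topo", {})
    bins = raw.get("bins", {})
    smooth = raw.get("smoothing", {})
    solar = raw.get("solar_reference", {})
    sampling = raw.get("sampling", {})
    assessment = raw.get("assessment", {})
    try:
        cfg = RunConfig(
            lines=lines,
            output_dir=io.get("output_dir", "."),
            scale_divisor=float(io.get("scale_divisor", 1.0)),
            obs_band_map=io.get("obs_band_map"),
            kernel_choice=KernelChoice(
                geometric=kern.get("geometric", "li_sparse"),
                volumetric=kern.get("volumetric", "ross_thick"),
            ),
            kernel_constants=KernelShapeConstants(
                b_over_r=float(kern.get("b_over_r", 10.0)),
                h_over_b=float(kern.get("h_over_b", 2.0)),
            ),
            topo_enabled=bool(topo.get("enabled", True)),
            topo_min_sample=int(topo.get("min_sample", 1000)),
            topo_b_threshold=float(topo.get("b_threshold", 1e-6)),
            topo_seed=int(topo.get("seed", 0)),
            bins=NdviBinSpec(
                mode=bins.get("mode", "dynamic"),
                n_bins=int(bins.get("n", 18)),
                lower_mask=float(bins.get("lower_mask", 0.05)),
                dynamic_upper=float(bins.get("dynamic_upper", 0.9)),
                edges=bins.get("edges"),
            ),
            smoothing=smooth.get("method", "linear_interpolation"),
            smoothing_range=tuple(smooth.get("range", (0.25, 0.85))),
            solar_reference=SolarReferenceSpec(
                mode=solar.get("mode", "none"),
                latitude=solar.get("latitude"),
                acquisition_date=_parse_date(solar.get("date")),
                season_start=_parse_date(solar.get("season_start")),
                season_end=_parse_date(solar.get("season_end")),
                fixed_value=solar.get("fixed_value"),
                line_weighted=bool(solar.get("line_weighted", False)),
            ),
            per_bin=int(sampling.get("per_bin", 10000)),
            sampling_seed=int(sampling.get("seed", 42)),
            band_subset=assessment.get("band_subset"),
            log_level=raw.get("log_level", "INFO"),
            raw=raw,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc
    return cfg


def dump_config_template(path):
    """Write a fully commented default config (convenience for `synth`)."""
    template = {
        "io": {"lines": [], "output_dir": "out", "scale_divisor": 1.0},
        "kernels": {"geometric": "li_sparse", "volumetric": "ross_thick",
                    "b_over_r": 10.0, "h_over_b": 2.0},
        "topo": {"enabled": True, "min_sample": 1000, "b_threshold": 1e-6, "seed": 0},
        "bins": {"mode": "dynamic", "n": 18, "lower_mask": 0.05, "dynamic_upper": 0.9},
        "smoothing": {"method": "linear_interpolation", "range": [0.25, 0.85]},
        "solar_reference": {"mode": "observed_mean"},
        "sampling": {"per_bin": 10000, "seed": 42},
        "assessment": {"band_subset": None},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(template, fh, sort_keys=False)
    return template
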