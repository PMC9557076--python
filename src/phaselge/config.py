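"""Pipeline configuration: strict-keyed YAML/JSON mirroring each stage's
parameters, resolved into the package's domain objects."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import phantom as phantom_mod
from .phantom import PhantomSpec
from .timing import CardiacTiming, SequenceParams

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


_SEQUENCE_KEYS = {
    "tr_ms", "flip_deg", "lines_per_segment", "offset_times_ms",
    "acq_window_fraction", "inv_efficiency", "recovery_beats",
}
_TIMING_KEYS = {"heart_rate_bpm", "rr_ms", "phase_duration_ms"}
_PHANTOM_KEYS = {
    "kind", "shape", "radius", "t1_blood_ms", "t1_myo_ms", "t1_scar_ms",
    "t1_short_ms", "t1_long_ms", "noise_sd", "baseline_snr", "snr_reference",
    "contraction",
}
_SYNTH_KEYS = {"t_syn_ms", "mode", "roi_stat", "null_compartment"}
_METRICS_KEYS = {"n_reconstruction_phases", "myo_compartment", "blood_compartment"}
_TOP_KEYS = {
    "sequence", "timing", "phantom", "synth", "metrics",
    "seed", "n_repetitions", "verbosity",
}


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    sequence: SequenceParams
    timing: CardiacTiming
    phantom: PhantomSpec | None
    synth: dict
    metrics: dict
    seed: int | None
    n_repetitions: int
    verbosity: int
    raw: dict

    def provenance(self) -> dict:
        return {"resolved_config": self.raw, "seed": self.seed}


def _build_timing(section: dict) -> CardiacTiming:
    _check_keys(section, _TIMING_KEYS, "timing")
    if "phase_duration_ms" not in section:
        raise ConfigError("timing.phase_duration_ms is required")
    if ("heart_rate_bpm" in section) == ("rr_ms" in section):
        raise ConfigError("set exactly one of timing.heart_rate_bpm / timing.rr_ms")
    if "heart_rate_bpm" in section:
        return CardiacTiming.from_heart_rate(
            section["heart_rate_bpm"], section["phase_duration_ms"]
        )
    rr = section["rr_ms"]
    rr = (rr,) if np.isscalar(rr) else tuple(rr)
    return CardiacTiming(rr_ms=rr, phase_duration_ms=section["phase_duration_ms"])


def _build_phantom(section: dict) -> PhantomSpec:
    _check_keys(section, _PHANTOM_KEYS, "phantom")
    kind = section.get("kind", "two_sphere")
    kwargs = {k: v for k, v in section.items() if k != "kind"}
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if "contraction" in kwargs:
        kwargs["contraction"] = np.asarray(kwargs["contraction"], float)
    builders = {
        "two_sphere": phantom_mod.two_sphere_phantom,
        "bottle": phantom_mod.bottle_phantom,
        "cardiac": phantom_mod.cardiac_phantom,
    }
    if kind not in builders:
        raise ConfigError(f"unknown phantom kind {kind!r}")
    try:
        return builders[kind](**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad phantom options for kind {kind!r}: {exc}") from exc


def load_config(path_or_dict) -> PipelineConfig:
    """Parse, validate (unknown keys rejected) and resolve a pipeline config."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        raw = (
            json.loads(text)
            if str(path_or_dict).endswith(".json")
            else yaml.safe_load(text)
        )
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    if "timing" not in raw:
        raise ConfigError("config section 'timing' is required")

    seq_section = dict(raw.get("sequence", {}))
    _check_keys(seq_section, _SEQUENCE_KEYS, "sequence")
    if "offset_times_ms" in seq_section and seq_section["offset_times_ms"] is not None:
        seq_section["offset_times_ms"] = tuple(seq_section["offset_times_ms"])
    sequence = SequenceParams(
        tr_ms=seq_section.pop("tr_ms", 5.0),
        flip_deg=seq_section.pop("flip_deg", 3.0),
        **seq_section,
    )

    timing = _build_timing(dict(raw["timing"]))
    phantom = _build_phantom(dict(raw["phantom"])) if "phantom" in raw else None

    synth = dict(raw.get("synth", {}))
    _check_keys(synth, _SYNTH_KEYS, "synth")
    metrics = dict(raw.get("metrics", {}))
    _check_keys(metrics, _METRICS_KEYS, "metrics")

    return PipelineConfig(
        sequence=sequence,
        timing=timing,
        phantom=phantom,
        synth=synth,
        metrics=metrics,
        seed=raw.get("seed"),
        n_repetitions=int(raw.get("n_repetitions", 1)),
        verbosity=int(raw.get("verbosity", 0)),
        raw=raw,
    )
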