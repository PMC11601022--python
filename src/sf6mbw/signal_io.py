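"""Recording/data model and file I/O.

The raw input of the whole pipeline is a pair of uniformly sampled traces:
flow at the sensor (L/s, inspiration positive) and raw molar mass (g/mol),
plus acquisition metadata.  The native device format is proprietary and
undocumented, so this package defines an open text dialect:

* a header block of ``# key: value`` comment lines carrying the metadata,
* followed by a CSV table with columns ``time_s,flow_lps,molar_mass_gmol``.

A ``flow_sign: expiration_positive`` header flips the flow on read.
Outcome reports are JSON documents validated against a shipped schema.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, RecordingFormatError
from .gas_physics import AmbientConditions

__all__ = [
    "RecordingMeta",
    "RawRecording",
    "AnalysisConfig",
    "read_recording",
    "write_recording",
    "write_outcomes",
    "read_outcomes",
    "validate_outcomes_document",
]

_COLUMNS = ("time_s", "flow_lps", "molar_mass_gmol")


@dataclass
class RecordingMeta:
    """Acquisition metadata attached to a raw recording."""

    ambient: AmbientConditions = field(default_factory=AmbientConditions)
    dead_space_ml: float = 4.6
    subject_weight_kg: float | None = None
    tracer_fraction: float = 0.04
    true_frc_ml: float | None = None  # simulations only
    flow_sign: str = "inspiration_positive"


@dataclass
class RawRecording:
    """Uniformly sampled flow + molar-mass traces.

    ``time`` is in seconds on a strictly increasing uniform grid (uniform
    within 1e-6 s), ``flow`` in L/s with inspiration positive, ``molar_mass``
    in g/mol and restricted to the physiological-plus-tracer window
    [20, 60] g/mol.
    """

    time: np.ndarray
    flow: np.ndarray
    molar_mass: np.ndarray
    sampling_rate_hz: float
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.molar_mass = np.asarray(self.molar_mass, dtype=float)
        n = self.time.size
        if self.flow.size != n or self.molar_mass.size != n:
            raise RecordingFormatError(
                f"trace lengths differ: time={n}, flow={self.flow.size}, "
                f"molar_mass={self.molar_mass.size}"
            )
        if n < 2:
            raise RecordingFormatError("recording shorter than 2 samples")
        if self.sampling_rate_hz <= 0:
            raise RecordingFormatError("sampling_rate_hz must be positive")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise RecordingFormatError(f"non-monotonic time at row {row}")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate_hz)) > 1e-6:
            raise RecordingFormatError("time grid not uniform at the declared sampling rate")
        mm_min, mm_max = float(np.min(self.molar_mass)), float(np.max(self.molar_mass))
        if mm_min < 20.0 or mm_max > 60.0:
            raise RecordingFormatError(
                f"molar mass outside [20, 60] g/mol (range {mm_min:.2f}..{mm_max:.2f})"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, with clinically sensible defaults.

    Dead space defaults to the infant apparatus value (4.6 mL; toddlers use
    9.6 mL), the end-of-test ratio to 2.5% of the initial end-tidal tracer
    concentration.  Every threshold is documented in docs/methods.md and can
    be loaded from / stored to YAML.
    """

    dead_space_ml: float = 4.6
    tracer_fraction: float = 0.04
    end_of_test_ratio: float = 0.025
    end_of_test_consensus: bool = False

    # breath detection
    min_breath_volume_ml: float = 2.0
    min_breath_duration_s: float = 0.3
    flow_hysteresis_fraction: float = 0.02
    end_tidal_window_fraction: float = 0.05

    # phase detection
    phase_jump_k: float = 5.0
    phase_jump_min_gmol: float = 0.15
    washin_plateau_breaths: int = 5
    washin_plateau_tolerance: float = 0.005

    # tidal change correction
    respirogram_bin_ml: float = 1.0
    boundary_breaths: int = 5
    boundary_min_separation_gmol: float = 0.05
    tcc_overrange_breath_fraction: float = 0.10

    # side chamber correction
    side_chamber_correction: bool = True
    side_chamber_scaling: str = "affine"  # or "multiplicative"
    # carry-over (normalised units) below which the chambers are treated as
    # absent; respirogram binning artefacts sit near 0.003, real chambers
    # an order of magnitude above
    chamber_detection_floor: float = 0.02
    extraction_denominator_min: float = 0.05
    clamp_ceiling_factor: float = 1.25

    # flow correction / outcomes
    volume_mode: str = "atp"  # "atp" (in-vitro) or "btps"
    sensor_temperature_k: float | None = None
    subtract_dead_space_from_cev: bool = True

    # QC thresholds (machine stand-ins for visual quality control)
    qc_clamped_fraction_max: float = 0.05
    qc_breath_volume_cv_max: float = 0.40
    qc_outcome_deviation_fraction: float = 0.25
    qc_min_accepted_trials: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.end_of_test_ratio < 1.0):
            raise ConfigError("end_of_test_ratio must be in (0, 1)")
        if self.dead_space_ml < 0:
            raise ConfigError("dead_space_ml must be >= 0")
        if not (0.0 < self.tracer_fraction < 0.5):
            raise ConfigError("tracer_fraction must be in (0, 0.5)")
        if self.side_chamber_scaling not in ("affine", "multiplicative"):
            raise ConfigError("side_chamber_scaling must be 'affine' or 'multiplicative'")
        if self.volume_mode not in ("atp", "btps"):
            raise ConfigError("volume_mode must be 'atp' or 'btps'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# raw recording files


def _meta_to_header(meta: RecordingMeta, sampling_rate_hz: float) -> list[str]:
    amb = meta.ambient
    lines = {
        "format": "sf6mbw-raw-v1",
        "sampling_rate_hz": sampling_rate_hz,
        "flow_sign": meta.flow_sign,
        "dead_space_ml": meta.dead_space_ml,
        "tracer_fraction": meta.tracer_fraction,
        "ambient_temperature_k": amb.temperature_k,
        "ambient_pressure_pa": amb.pressure_pa,
        "ambient_relative_humidity": amb.relative_humidity,
        "body_temperature_k": amb.body_temperature_k,
    }
    if meta.subject_weight_kg is not None:
        lines["subject_weight_kg"] = meta.subject_weight_kg
    if meta.true_frc_ml is not None:
        lines["true_frc_ml"] = meta.true_frc_ml
    return [f"# {k}: {v}" for k, v in lines.items()]


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording in the package's open CSV dialect."""
    path = Path(path)
    header = _meta_to_header(rec.meta, rec.sampling_rate_hz)
    df = pd.DataFrame(
        {"time_s": rec.time, "flow_lps": rec.flow, "molar_mass_gmol": rec.molar_mass}
    )
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_recording(path: str | Path, fmt: str = "csv") -> RawRecording:
    """Read a raw recording (CSV or TSV dialect) and validate it."""
    path = Path(path)
    if not path.exists():
        raise RecordingFormatError(f"file not found: {path}")
    if fmt not in ("csv", "tsv"):
        raise RecordingFormatError(f"unknown format {fmt!r}")
    meta_raw: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    for line in lines:
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta_raw[k.strip()] = v.strip()
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, comment="#", sep=sep)
    for col in _COLUMNS:
        if col not in df.columns:
            raise RecordingFormatError(f"missing column {col!r} in {path.name}")

    def _f(key: str, default: float | None) -> float | None:
        if key in meta_raw:
            return float(meta_raw[key])
        return default

    try:
        ambient = AmbientConditions(
            temperature_k=_f("ambient_temperature_k", 295.15),
            pressure_pa=_f("ambient_pressure_pa", 101325.0),
            relative_humidity=_f("ambient_relative_humidity", 0.5),
            body_temperature_k=_f("body_temperature_k", 310.15),
        )
    except ValueError as exc:
        raise RecordingFormatError(f"invalid ambient metadata: {exc}") from exc
    meta = RecordingMeta(
        ambient=ambient,
        dead_space_ml=_f("dead_space_ml", 4.6),
        subject_weight_kg=_f("subject_weight_kg", None),
        tracer_fraction=_f("tracer_fraction", 0.04),
        true_frc_ml=_f("true_frc_ml", None),
        flow_sign=meta_raw.get("flow_sign", "inspiration_positive"),
    )
    flow = df["flow_lps"].to_numpy(dtype=float)
    if meta.flow_sign == "expiration_positive":
        flow = -flow
        meta.flow_sign = "inspiration_positive"
    elif meta.flow_sign != "inspiration_positive":
        raise RecordingFormatError(f"unknown flow_sign {meta.flow_sign!r}")
    time = df["time_s"].to_numpy(dtype=float)
    sr = _f("sampling_rate_hz", None)
    if sr is None:
        dt = np.median(np.diff(time))
        if dt <= 0:
            raise RecordingFormatError("non-monotonic time")
        sr = 1.0 / dt
    if sr < 50.0:
        raise RecordingFormatError(f"sampling rate {sr:.1f} Hz below the 50 Hz minimum")
    return RawRecording(
        time=time,
        flow=flow,
        molar_mass=df["molar_mass_gmol"].to_numpy(dtype=float),
        sampling_rate_hz=float(sr),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# outcomes report


def write_outcomes(outcomes: Any, path: str | Path, config: AnalysisConfig | None = None) -> None:
    """Serialise an ``MBWOutcomes`` to a schema-conforming JSON document."""
    from . import __version__

    doc = outcomes.to_dict()
    doc["schema"] = "sf6mbw-outcomes-v1"
    doc["software_version"] = __version__
    if config is not None:
        doc["config"] = dataclasses.asdict(config)
    validate_outcomes_document(doc)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_outcomes(path: str | Path) -> dict[str, Any]:
    doc = json.loads(Path(path).read_text())
    validate_outcomes_document(doc)
    return doc


def _schema() -> dict[str, Any]:
    schema_path = Path(__file__).parent / "schemas" / "outcomes.schema.json"
    return json.loads(schema_path.read_text())


_TYPES = {"number": (int, float), "integer": int, "string": str, "boolean": bool,
          "array": list, "object": dict}


def validate_outcomes_document(doc: dict[str, Any]) -> None:
    """Check the outcomes document against the shipped schema.

    Implements the subset of JSON schema the shipped file uses (required
    keys and primitive types) so no external validator is needed.
    """
    schema = _schema()
    for key in schema.get("required", []):
        if key not in doc:
            raise RecordingFormatError(f"outcomes document missing required field {key!r}")
    for key, spec in schema.get("properties", {}).items():
        if key in doc and "type" in spec:
            expected = _TYPES[spec["type"]]
            value = doc[key]
            if spec["type"] == "number" and isinstance(value, bool):
                raise RecordingFormatError(f"field {key!r} must be a number")
            if value is not None and not isinstance(value, expected):
                raise RecordingFormatError(
                    f"field {key!r} has type {type(value).__name__}, expected {spec['type']}"
                )
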