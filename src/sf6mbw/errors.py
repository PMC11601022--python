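"""Typed errors raised by the analysis pipeline.

Every error carries a machine-readable ``category`` string that the CLI
emits alongside its non-zero exit code, so batch callers can triage
failures without parsing prose.
"""

from __future__ import annotations


class SF6MBWError(Exception):
    """Base class for all package errors."""

    category: str = "error"


class RecordingFormatError(SF6MBWError):
    category = "recording_format"


class ConfigError(SF6MBWError):
    category = "config"


class BreathDetectionError(SF6MBWError):
    category = "no_breaths"


class PhaseError(SF6MBWError):
    """Pre-phase, washin or washout could not be located."""

    category = "missing_phase"


class WashinIncompleteError(PhaseError):
    category = "washin_incomplete"


class InsufficientBoundaryBreathsError(SF6MBWError):
    category = "insufficient_boundary_breaths"


class BoundaryIndistinctError(SF6MBWError):
    """The 0% and 4% boundary respirograms are too close to divide by."""

    category = "boundary_traces_indistinct"


class ScalingDegenerateError(SF6MBWError):
    category = "scaling_anchors_degenerate"


class WashoutIncompleteError(SF6MBWError):
    category = "washout_incomplete"


class OutcomeError(SF6MBWError):
    category = "frc_invalid"
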