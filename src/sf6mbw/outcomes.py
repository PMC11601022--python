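"""Flow correction, end-of-test detection and the primary MBW outcomes.

The functional residual capacity follows from tracer conservation: the net
tracer volume expired past the sensor between washout start and end of test
equals the concentration drop times the gas volume distal to the sensor, so

    FRC = net expired SF6 volume / (c_et,initial - c_et,final) - dead space

with the apparatus dead space removed because it is flushed alongside the
lung.  The cumulative expired volume (CEV) is summed per breath to the
end-of-test breath, and the lung clearance index is LCI = CEV / FRC in
turnovers.  The test ends at the first breath whose end-tidal tracer
fraction falls below the end-of-test ratio (default 2.5%) of the initial
end-tidal fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .breaths import Breath
from .errors import OutcomeError, WashoutIncompleteError
from .gas_physics import AmbientConditions, btps_factor
from .sidechamber import SF6Signal
from .signal_io import AnalysisConfig, RawRecording

__all__ = [
    "MBWOutcomes",
    "btps_correct_flow",
    "detect_end_of_test",
    "compute_frc",
    "compute_cev_lci",
]


@dataclass
class MBWOutcomes:
    """Primary outcomes of one MBW trial."""

    frc_ml: float
    cev_ml: float
    lci_to: float
    end_of_test_breath: int  # position within the washout, 0-based
    breath_count_to_end: int
    initial_end_tidal_sf6: float
    final_end_tidal_sf6: float
    end_tidal_sf6: list[float]
    dead_space_ml: float
    clamped_sample_fraction: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frc_ml <= 0 or self.cev_ml <= 0:
            raise OutcomeError("FRC and CEV must be positive")
        if abs(self.lci_to - self.cev_ml / self.frc_ml) > 1e-9 * max(self.lci_to, 1.0):
            raise OutcomeError("LCI must equal CEV/FRC")

    def to_dict(self) -> dict[str, Any]:
        return {
            "frc_ml": self.frc_ml,
            "cev_ml": self.cev_ml,
            "lci_to": self.lci_to,
            "end_of_test_breath": self.end_of_test_breath,
            "breath_count_to_end": self.breath_count_to_end,
            "initial_end_tidal_sf6": self.initial_end_tidal_sf6,
            "final_end_tidal_sf6": self.final_end_tidal_sf6,
            "end_tidal_sf6": list(self.end_tidal_sf6),
            "dead_space_ml": self.dead_space_ml,
            "clamped_sample_fraction": self.clamped_sample_fraction,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "MBWOutcomes":
        keys = [f for f in cls.__dataclass_fields__]
        return cls(**{k: doc[k] for k in keys})


def btps_correct_flow(
    rec: RawRecording,
    breaths: list[Breath],
    cfg: AnalysisConfig | None = None,
    cond: AmbientConditions | None = None,
) -> np.ndarray:
    """Scale flow phase-wise to BTPS (or return it unchanged in ATP mode).

    Inspired gas is at ambient temperature and humidity, expired gas is
    assumed saturated and partially cooled to the sensor temperature
    (``cfg.sensor_temperature_k``, ambient if unset).  The in-vitro
    water-bath setup has no body compartment and uses ``volume_mode="atp"``.
    """
    cfg = cfg or AnalysisConfig()
    flow = rec.flow.copy()
    if cfg.volume_mode == "atp":
        return flow
    cond = cond or rec.meta.ambient
    f_in = btps_factor(cond, "inspiration")
    f_ex = btps_factor(cond, "expiration", sensor_temperature_k=cfg.sensor_temperature_k)
    for b in breaths:
        flow[b.i_insp : b.i_exp] *= f_in
        flow[b.i_exp : b.i_end] *= f_ex
    return flow


def detect_end_of_test(
    sf6: SF6Signal, ratio: float | None = None, consensus: bool = False
) -> int:
    """First washout breath whose end-tidal SF6 drops below ratio * initial.

    Returns the 0-based position within the washout breath sequence.  With
    ``consensus=True`` the two following breaths must stay below the
    threshold as well (consensus-guideline style); the default follows the
    single-breath rule.
    """
    ratio = 0.025 if ratio is None else ratio
    threshold = ratio * sf6.initial_end_tidal
    series = [sf6.end_tidal[b] for b in sf6.washout_breaths]
    n = len(series)
    for i, value in enumerate(series):
        if value < threshold:
            if not consensus:
                return i
            if all(series[j] < threshold for j in range(i, min(i + 3, n))) and i + 2 < n:
                return i
    raise WashoutIncompleteError(
        f"end-tidal SF6 never fell below {threshold:.5f} (washout incomplete)"
    )


def _net_expired_sf6_ml(
    sf6: SF6Signal, flow_corrected: np.ndarray, rec: RawRecording, stop_breath: int
) -> float:
    """Net expired tracer volume (mL) from washout start through stop_breath."""
    first = min(sf6.washout_breaths)
    sel = (sf6.breath >= first) & (sf6.breath <= stop_breath)
    f = flow_corrected[sf6.index[sel]] * 1000.0  # mL/s
    # integrate the unclamped trace: clamping at zero rectifies sensor noise
    # into a spurious re-inspired tracer volume
    c = sf6.sf6_unclamped[sel]
    dt = rec.dt
    expired = float(np.sum(c[f < 0] * (-f[f < 0])) * dt)
    reinspired = float(np.sum(c[f > 0] * f[f > 0]) * dt)
    return expired - reinspired


def compute_frc(
    sf6: SF6Signal,
    flow_corrected: np.ndarray,
    rec: RawRecording,
    end_index: int,
    dead_space_ml: float,
) -> float:
    """FRC in mL from tracer conservation over the washout."""
    stop_breath = sf6.washout_breaths[end_index]
    net = _net_expired_sf6_ml(sf6, flow_corrected, rec, stop_breath)
    c0 = sf6.initial_end_tidal
    c1 = sf6.end_tidal[stop_breath]
    if c0 <= c1:
        raise OutcomeError("end-tidal SF6 did not fall over the washout")
    frc = net / (c0 - c1) - dead_space_ml
    if frc <= 0.0:
        raise OutcomeError(
            f"FRC invalid: {frc:.1f} mL after subtracting {dead_space_ml} mL dead space"
        )
    return frc


def compute_cev_lci(
    frc_ml: float,
    flow_corrected: np.ndarray,
    rec: RawRecording,
    breaths: list[Breath],
    washout_breaths: tuple[int, ...],
    end_index: int,
    dead_space_ml: float,
    cfg: AnalysisConfig | None = None,
) -> tuple[float, float]:
    """Cumulative expired volume (mL) and LCI (turnovers).

    CEV sums the corrected expired volume of each washout breath through the
    end-of-test breath; by default one apparatus dead space per breath is
    removed so the LCI reflects alveolar gas turnover.
    """
    cfg = cfg or AnalysisConfig()
    used = washout_breaths[: end_index + 1]
    cev = 0.0
    for bi in used:
        b = breaths[bi]
        seg = flow_corrected[b.i_exp : b.i_end] * 1000.0
        cev += abs(float(np.trapezoid(seg, rec.time[b.i_exp : b.i_end])))
    if cfg.subtract_dead_space_from_cev:
        cev -= dead_space_ml * len(used)
    if cev <= 0.0:
        raise OutcomeError("CEV non-positive")
    return cev, cev / frc_ml
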