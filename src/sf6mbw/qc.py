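"""Trial/visit acceptability rules.

A visit is valid when at least two acceptable trials produced LCI and FRC
values within 25% of the accepted-set mean.  Trials first fail on hard
signal-quality flags (incomplete washin, excessive clamping, grossly
irregular breathing) — the machine-checkable stand-ins for visual quality
control — and the 25% rule is then applied iteratively: after each
exclusion the means are recomputed and all currently deviating trials are
dropped simultaneously, which makes the fixed point independent of trial
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .outcomes import MBWOutcomes
from .signal_io import AnalysisConfig

__all__ = ["TrialQC", "VisitQCResult", "assess_visit", "derive_trial_flags"]


@dataclass
class TrialQC:
    """One trial's outcomes plus its hard quality flags."""

    outcomes: MBWOutcomes
    flags: list[str] = field(default_factory=list)


@dataclass
class VisitQCResult:
    accepted: list[int]  # indices into the input trial list
    rejected_flags: dict[int, list[str]]
    rejected_deviation: list[int]
    valid: bool
    reasons: list[str]
    mean_lci: float | None = None
    mean_frc_ml: float | None = None


def derive_trial_flags(
    outcomes: MBWOutcomes,
    washin_complete: bool,
    washout_breath_volumes_ml: list[float] | None = None,
    cfg: AnalysisConfig | None = None,
) -> list[str]:
    """Automatic stand-ins for visual quality control."""
    cfg = cfg or AnalysisConfig()
    flags: list[str] = []
    if not washin_complete:
        flags.append("washin_incomplete")
    if outcomes.clamped_sample_fraction > cfg.qc_clamped_fraction_max:
        flags.append("clamping_excess")
    if washout_breath_volumes_ml and len(washout_breath_volumes_ml) >= 3:
        vols = np.asarray(washout_breath_volumes_ml)
        if float(np.std(vols) / np.mean(vols)) > cfg.qc_breath_volume_cv_max:
            flags.append("irregular_breathing")
    return flags


def assess_visit(trials: list[TrialQC], cfg: AnalysisConfig | None = None) -> VisitQCResult:
    """Apply the visit-acceptability rule to a set of trials.

    Flag-failed trials are dropped first; then trials deviating more than
    ``qc_outcome_deviation_fraction`` from the mean LCI *or* mean FRC of the
    remaining set are excluded, means recomputed, until a fixed point.
    """
    cfg = cfg or AnalysisConfig()
    tol = cfg.qc_outcome_deviation_fraction
    rejected_flags = {i: t.flags for i, t in enumerate(trials) if t.flags}
    current = [i for i, t in enumerate(trials) if not t.flags]
    rejected_dev: list[int] = []
    while len(current) >= 1:
        lci = np.array([trials[i].outcomes.lci_to for i in current])
        frc = np.array([trials[i].outcomes.frc_ml for i in current])
        dev = np.maximum(
            np.abs(lci - lci.mean()) / lci.mean(), np.abs(frc - frc.mean()) / frc.mean()
        )
        bad = dev > tol
        if not np.any(bad):
            break
        rejected_dev.extend(current[k] for k in np.nonzero(bad)[0])
        current = [i for k, i in enumerate(current) if not bad[k]]
    reasons: list[str] = []
    valid = len(current) >= cfg.qc_min_accepted_trials
    if not valid:
        reasons.append(
            f"fewer than {cfg.qc_min_accepted_trials} acceptable measurements "
            f"within {tol:.0%} of the measurement mean"
        )
    mean_lci = float(np.mean([trials[i].outcomes.lci_to for i in current])) if current else None
    mean_frc = float(np.mean([trials[i].outcomes.frc_ml for i in current])) if current else None
    return VisitQCResult(
        accepted=sorted(current),
        rejected_flags=rejected_flags,
        rejected_deviation=sorted(rejected_dev),
        valid=valid,
        reasons=reasons,
        mean_lci=mean_lci,
        mean_frc_ml=mean_frc,
    )
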