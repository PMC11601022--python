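"""End-to-end analysis: raw recording in, MBW outcomes out.

Runs the five algorithm stages in order — breath/phase detection, tidal
change correction, side-chamber correction, flow (BTPS) correction, outcome
calculation — and returns both the primary outcomes and every intermediate
product for inspection or plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breaths as _breaths
from . import outcomes as _outcomes
from . import sidechamber as _sc
from . import tidal as _tidal
from .errors import WashinIncompleteError
from .qc import derive_trial_flags
from .sidechamber import SF6Signal, SideChamberCurves
from .signal_io import AnalysisConfig, RawRecording
from .simulator import Scenario, simulate_recording

__all__ = ["AnalysisResult", "analyze_recording", "run_grid", "summarize_grid"]


@dataclass
class AnalysisResult:
    outcomes: _outcomes.MBWOutcomes
    breaths: list[_breaths.Breath]
    phases: _breaths.PhaseAnnotation
    respirograms: dict
    norm: _tidal.NormalizedSignal
    sf6: SF6Signal
    curves: SideChamberCurves | None
    flow_corrected: np.ndarray
    config: AnalysisConfig
    flags: list[str] = field(default_factory=list)


def config_for(rec: RawRecording, **overrides) -> AnalysisConfig:
    """An AnalysisConfig seeded from the recording's metadata."""
    base = dict(
        dead_space_ml=rec.meta.dead_space_ml, tracer_fraction=rec.meta.tracer_fraction
    )
    base.update(overrides)
    return AnalysisConfig(**base)


def analyze_recording(
    rec: RawRecording,
    cfg: AnalysisConfig | None = None,
    require_complete_washin: bool = True,
) -> AnalysisResult:
    """Run the full pipeline on one recording."""
    cfg = cfg or config_for(rec)
    breaths = _breaths.detect_breaths(rec, cfg)
    phases = _breaths.detect_phases(rec, breaths, cfg)
    if require_complete_washin and not phases.washin_complete:
        raise WashinIncompleteError(
            "washin incomplete: end-of-washin end-tidal plateau not reached"
        )
    respirograms = _tidal.build_respirograms(rec, breaths, phases, cfg)

    washout = list(range(*phases.washout))
    first_washin = phases.washin[0]
    last_washin = phases.washin[1] - 1
    norm = _tidal.apply_tcc(rec, breaths, respirograms, [last_washin] + washout, cfg)

    if cfg.side_chamber_correction:
        norm_anchor = _tidal.apply_tcc(rec, breaths, respirograms, [first_washin], cfg)
        sf6, curves = _sc.apply_side_chamber_correction(
            norm, norm_anchor, washout, first_washin, last_washin,
            cfg.tracer_fraction, cfg,
        )
    else:
        zeros = np.zeros_like(norm.x)
        sf6 = _sc.extract_sf6(
            norm, zeros, np.ones_like(zeros), cfg.tracer_fraction, washout,
            initial_breath=last_washin, cfg=cfg,
        )
        curves = None

    flow_corr = _outcomes.btps_correct_flow(rec, breaths, cfg, rec.meta.ambient)
    end_index = _outcomes.detect_end_of_test(
        sf6, cfg.end_of_test_ratio, cfg.end_of_test_consensus
    )
    frc = _outcomes.compute_frc(sf6, flow_corr, rec, end_index, cfg.dead_space_ml)
    cev, lci = _outcomes.compute_cev_lci(
        frc, flow_corr, rec, breaths, sf6.washout_breaths, end_index, cfg.dead_space_ml, cfg
    )
    stop_breath = sf6.washout_breaths[end_index]
    outcomes = _outcomes.MBWOutcomes(
        frc_ml=frc,
        cev_ml=cev,
        lci_to=lci,
        end_of_test_breath=end_index,
        breath_count_to_end=end_index + 1,
        initial_end_tidal_sf6=sf6.initial_end_tidal,
        final_end_tidal_sf6=sf6.end_tidal[stop_breath],
        end_tidal_sf6=[sf6.end_tidal[b] for b in sf6.washout_breaths],
        dead_space_ml=cfg.dead_space_ml,
        clamped_sample_fraction=sf6.clamped_fraction,
    )
    washout_vols = [breaths[b].expired_volume_ml for b in washout]
    flags = derive_trial_flags(outcomes, phases.washin_complete, washout_vols, cfg)
    outcomes.flags = list(flags)
    return AnalysisResult(
        outcomes=outcomes,
        breaths=breaths,
        phases=phases,
        respirograms=respirograms,
        norm=norm,
        sf6=sf6,
        curves=curves,
        flow_corrected=flow_corr,
        config=cfg,
        flags=flags,
    )


def run_grid(
    scenarios: list[Scenario], cfg_overrides: dict | None = None
) -> pd.DataFrame:
    """Simulate and analyse a list of scenarios; per-run FRC errors."""
    rows = []
    for sc in scenarios:
        rec, truth = simulate_recording(sc.config)
        cfg = config_for(rec, **(cfg_overrides or {}))
        result = analyze_recording(rec, cfg)
        err = (result.outcomes.frc_ml - truth.frc_true_ml) / truth.frc_true_ml * 100.0
        rows.append(
            dict(
                scenario=sc.name,
                size=sc.size,
                condition=sc.condition,
                replicate=sc.replicate,
                frc_true_ml=truth.frc_true_ml,
                frc_est_ml=result.outcomes.frc_ml,
                err_pct=err,
                abs_err_pct=abs(err),
                lci_to=result.outcomes.lci_to,
                cev_ml=result.outcomes.cev_ml,
            )
        )
    return pd.DataFrame(rows)


def summarize_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean/SD absolute FRC error plus an overall row."""
    g = (
        df.groupby(["condition", "size"], sort=False)
        .agg(n=("abs_err_pct", "size"), mean_abs_err_pct=("abs_err_pct", "mean"),
             sd_abs_err_pct=("abs_err_pct", "std"))
        .reset_index()
    )
    overall = pd.DataFrame(
        [dict(condition="overall", size="all", n=len(df),
              mean_abs_err_pct=df["abs_err_pct"].mean(),
              sd_abs_err_pct=df["abs_err_pct"].std())]
    )
    return pd.concat([g, overall], ignore_index=True)
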