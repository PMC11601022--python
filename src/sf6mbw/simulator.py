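"""Forward model of an infant SF6 washin/washout recording.

Emulates the in-vitro validation setup: a water-bath-heated lung model with
one or two ventilated compartments, a shared apparatus dead space between
the ultrasonic sensor and the model, a 4% SF6 washin followed by a washout,
and the two measurement artefacts the analysis must undo —

* tidal temperature/humidity swings at the sensor, which corrupt the
  speed-of-sound molar-mass conversion breath-periodically, and
* semi-accessible side chambers in the measurement path, modelled as a
  lumped first-order state flushed by through-flow, whose lagging content
  blends into the measured molar mass.

Gas transport is explicit: compartments are perfectly mixed and diluted by
a plug-flow dead space (a FIFO of gas parcels), so expired gas reaches the
sensor dead-space-first, exactly as a real expirogram does.  The recorded
molar mass is produced through the same ideal-gas relations the analysis
assumes: the true mixture's speed of sound is converted back to molar mass
with the device's *assumed* fixed temperature and adiabatic index, which is
what makes temperature and composition confound each other.

All tracer amounts are bookkept so conservation can be asserted to float
precision, and every random draw flows from the config seed.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .gas_physics import (
    R,
    SPECIES_CP,
    SPECIES_MOLAR_MASS,
    AmbientConditions,
    GasMixture,
    mixture_adiabatic_index,
    mixture_heat_capacity,
    mixture_molar_mass,
    saturation_vapor_pressure,
)
from .signal_io import RawRecording, RecordingMeta

__all__ = ["SimulationConfig", "GroundTruth", "Scenario", "simulate_recording", "condition_grid"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated trial.

    Defaults are the small-volume baseline of the in-vitro grid: FRC 80 mL,
    VT 30 mL, RR 30/min, bath at 32.5 degC, apparatus dead space 4.6 mL,
    4% SF6, 200 Hz sampling.
    """

    frc_ml: tuple[float, ...] = (80.0,)
    ventilation_fractions: tuple[float, ...] = (1.0,)
    vt_ml: float = 30.0
    rr_bpm: float = 30.0
    dead_space_ml: float = 4.6
    tracer_fraction: float = 0.04
    pre_breaths: int = 10
    washin_breaths: int | None = None  # None: sized so the washin completes
    washout_breaths: int | None = None  # None: sized past the end-of-test
    chamber_fraction: float = 0.10
    chamber_lambda_ml: float = 12.0
    chamber_two_state: bool = False
    bath_temperature_k: float = 305.65
    supply_temperature_k: float = 293.15
    tidal_temp_amplitude_k: float = 1.0
    temp_volume_constant_ml: float = 8.0
    humidity: bool = True
    ambient_relative_humidity: float = 0.5
    pressure_pa: float = 101325.0
    gas_exchange: bool = False
    flow_profile: str = "sine"  # "sine" | "square" | "harmonic"
    vt_jitter_fraction: float = 0.0
    noise_mm_sd: float = 0.02
    noise_flow_sd: float = 0.001
    sampling_rate_hz: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.frc_ml) != len(self.ventilation_fractions):
            raise ValueError("frc_ml and ventilation_fractions must have equal length")
        if abs(sum(self.ventilation_fractions) - 1.0) > 1e-9:
            raise ValueError("ventilation fractions must sum to 1")
        if any(v <= 0 for v in self.frc_ml) or self.vt_ml <= 0 or self.rr_bpm <= 0:
            raise ValueError("volumes and respiratory rate must be positive")
        if not (0.0 <= self.chamber_fraction < 0.5):
            raise ValueError("chamber_fraction must be in [0, 0.5)")
        if self.dead_space_ml < 0 or self.dead_space_ml >= self.vt_ml:
            raise ValueError("dead space must be in [0, VT)")
        if self.flow_profile not in ("sine", "square", "harmonic"):
            raise ValueError(f"unknown flow profile {self.flow_profile!r}")

    @property
    def total_frc_ml(self) -> float:
        return float(sum(self.frc_ml))


@dataclass
class GroundTruth:
    """Everything the analysis is *not* allowed to see."""

    frc_true_ml: float
    dead_space_ml: float
    tracer_fraction: float
    pre: tuple[int, int]
    washin: tuple[int, int]
    washout: tuple[int, int]
    breath_starts: np.ndarray  # sample index of each breath's inspiration
    end_tidal_sf6: np.ndarray  # mixed alveolar fraction at each breath end
    compartment_sf6: np.ndarray  # (n_breaths, n_compartments) end-expiratory
    chamber_state: np.ndarray  # per-sample chamber tracer fraction
    content_washout_start_ml: float
    content_final_ml: float
    net_expired_washout_ml: float

    @property
    def n_breaths(self) -> int:
        return len(self.breath_starts)


@dataclass(frozen=True)
class Scenario:
    name: str
    size: str  # "small" | "large"
    condition: str  # "standard" | "-T" | "+RR" | "+VT" | "+VI"
    replicate: int
    config: SimulationConfig


def _dilution_step(
    c: np.ndarray, c_ds: float, c_sup: float, frc: np.ndarray, vent: np.ndarray,
    vt: float, vd: float,
) -> tuple[np.ndarray, float]:
    """One breath of the well-mixed recursion used only to size the phases."""
    inflow = vent * (vd * c_ds + (vt - vd) * c_sup)
    c = (c * frc + inflow) / (frc + vent * vt)
    c_mix = float(np.sum(vent * c))
    return c, c_mix


def _plan_phase_lengths(cfg: SimulationConfig) -> tuple[int, int]:
    """Washin/washout breath counts from the breath-level dilution recursion."""
    frc = np.asarray(cfg.frc_ml)
    vent = np.asarray(cfg.ventilation_fractions)
    c_max = cfg.tracer_fraction
    if cfg.washin_breaths is None:
        c = np.zeros_like(frc)
        c_ds = 0.0
        n = 0
        while np.max(c_max - c) > 1e-3 * c_max and n < 500:
            c, c_ds = _dilution_step(c, c_ds, c_max, frc, vent, cfg.vt_ml, cfg.dead_space_ml)
            n += 1
        washin = n + 5
    else:
        washin = cfg.washin_breaths
    if cfg.washout_breaths is None:
        c = np.full_like(frc, c_max)
        c_ds = c_max
        n = 0
        c_mix = c_max
        while c_mix > 0.02 * c_max and n < 500:
            c, c_mix = _dilution_step(c, c_ds, 0.0, frc, vent, cfg.vt_ml, cfg.dead_space_ml)
            c_ds = c_mix
            n += 1
        washout = n + 6
    else:
        washout = cfg.washout_breaths
    return washin, washout


def _breath_flow(cfg: SimulationConfig, vt_ml: float) -> np.ndarray:
    """Clean flow samples (L/s) for one breath, inspiration then expiration."""
    sr = cfg.sampling_rate_hz
    half = max(int(round(0.5 * 60.0 / cfg.rr_bpm * sr)), 4)
    t = (np.arange(half) + 0.5) / half  # mid-sample phases in (0, 1)
    if cfg.flow_profile == "sine":
        shape = np.sin(np.pi * t)
    elif cfg.flow_profile == "square":
        ramp = np.minimum(1.0, np.minimum(t, 1.0 - t) / 0.08)
        shape = ramp
    else:  # harmonic: sine with a 2nd-harmonic distortion
        shape = np.sin(np.pi * t) + 0.15 * np.sin(2 * np.pi * t)
        shape = np.clip(shape, 0.0, None)
    # scale so the discrete integral is exactly vt_ml
    dt = 1.0 / sr
    shape = shape / (np.sum(shape) * dt)  # unit volume per half-breath
    amp = vt_ml / 1000.0
    return np.concatenate([amp * shape, -amp * shape])


class _PlugFlowDeadSpace:
    """FIFO of (volume, tracer fraction, alveolar fraction) gas parcels."""

    def __init__(self, volume_ml: float):
        self.parcels: deque[list[float]] = deque()
        if volume_ml > 0:
            self.parcels.append([volume_ml, 0.0, 0.0])
        self.volume_ml = volume_ml

    def push_pop(self, dv: float, c: float, alv: float, from_sensor: bool) -> tuple[float, float]:
        """Push a parcel on one end, pop dv from the other; return (c, alv)."""
        if dv <= 0.0:
            return c, alv
        if self.volume_ml <= 0.0:
            return c, alv
        if from_sensor:
            self.parcels.appendleft([dv, c, alv])
            pop = self.parcels.pop
            push_back = self.parcels.append
        else:
            self.parcels.append([dv, c, alv])
            pop = self.parcels.popleft
            push_back = self.parcels.appendleft
        need = dv
        got_c = 0.0
        got_a = 0.0
        while need > 1e-12:
            p = pop()
            if p[0] > need + 1e-12:
                p[0] -= need
                got_c += need * p[1]
                got_a += need * p[2]
                push_back(p)
                need = 0.0
            else:
                got_c += p[0] * p[1]
                got_a += p[0] * p[2]
                need -= p[0]
        return got_c / dv, got_a / dv

    def tracer_content_ml(self) -> float:
        return sum(p[0] * p[1] for p in self.parcels)


# species constants needed in the inner loop, pulled out once
_MM_AIR = mixture_molar_mass(GasMixture.dry_air())
_CP_AIR = mixture_heat_capacity(GasMixture.dry_air())
_GAMMA_DEV = mixture_adiabatic_index(GasMixture.dry_air())
_MM_SF6 = SPECIES_MOLAR_MASS["sf6"]
_CP_SF6 = SPECIES_CP["sf6"]
_MM_H2O = SPECIES_MOLAR_MASS["h2o"]
_CP_H2O = SPECIES_CP["h2o"]
_DMM_EXCH = 0.05 * (SPECIES_MOLAR_MASS["co2"] - SPECIES_MOLAR_MASS["o2"])
_DCP_EXCH = 0.05 * (SPECIES_CP["co2"] - SPECIES_CP["o2"])


def simulate_recording(cfg: SimulationConfig) -> tuple[RawRecording, GroundTruth]:
    """Run the forward model and return the recording plus ground truth."""
    washin_n, washout_n = _plan_phase_lengths(cfg)
    n_breaths = cfg.pre_breaths + washin_n + washout_n
    rng = np.random.default_rng(cfg.seed)
    sr = cfg.sampling_rate_hz
    dt = 1.0 / sr

    # assemble the clean flow trace breath by breath
    vts = np.full(n_breaths, cfg.vt_ml)
    if cfg.vt_jitter_fraction > 0:
        vts *= np.clip(1.0 + cfg.vt_jitter_fraction * rng.standard_normal(n_breaths), 0.5, 1.5)
    blocks = [_breath_flow(cfg, vt) for vt in vts]
    breath_starts = np.concatenate(([0], np.cumsum([len(b) for b in blocks])))[:-1]
    flow_clean = np.concatenate(blocks)
    n = flow_clean.size

    frc = list(cfg.frc_ml)
    vent = list(cfg.ventilation_fractions)
    ncomp = len(frc)
    c_comp = [0.0] * ncomp
    v_comp = list(frc)
    ds = _PlugFlowDeadSpace(cfg.dead_space_ml)

    c_max = cfg.tracer_fraction
    t_exp_target = cfg.bath_temperature_k
    t_insp_target = cfg.bath_temperature_k - cfg.tidal_temp_amplitude_k
    p = cfg.pressure_pa
    w_insp = cfg.ambient_relative_humidity * saturation_vapor_pressure(cfg.supply_temperature_k) / p
    w_exp = saturation_vapor_pressure(cfg.bath_temperature_k) / p if cfg.humidity else w_insp
    temp = 0.5 * (t_insp_target + t_exp_target)
    w = 0.5 * (w_insp + w_exp) if cfg.humidity else w_insp
    t_dev = cfg.bath_temperature_k

    f_ch = cfg.chamber_fraction
    lam = cfg.chamber_lambda_ml
    mm_ch = [float("nan"), float("nan")]  # initialised on first sample
    c_ch = 0.0
    chamber_state = np.zeros(n)
    mm_rep_arr = np.zeros(n)

    et_truth = np.zeros(n_breaths)
    comp_truth = np.zeros((n_breaths, ncomp))
    washout_first = cfg.pre_breaths + washin_n
    net_out_washout = 0.0
    content_washout_start = 0.0

    exp_m = math.exp
    breath_edges = list(breath_starts) + [n]
    for bi in range(n_breaths):
        lo, hi = breath_edges[bi], breath_edges[bi + 1]
        if bi < cfg.pre_breaths:
            c_sup = 0.0
        elif bi < washout_first:
            c_sup = c_max
        else:
            c_sup = 0.0
        in_washout = bi >= washout_first
        for k in range(lo, hi):
            f = flow_clean[k]
            dv = f * 1000.0 * dt  # mL, signed
            dvm = abs(dv)
            if dv > 0:  # inspiration: sensor sees supply gas
                c_sens, alv_sens = c_sup, 0.0
                c_in, _ = ds.push_pop(dv, c_sup, 0.0, from_sensor=True)
                for i in range(ncomp):
                    dvi = dv * vent[i]
                    c_comp[i] = (c_comp[i] * v_comp[i] + c_in * dvi) / (v_comp[i] + dvi)
                    v_comp[i] += dvi
                if in_washout:
                    net_out_washout -= c_sens * dvm
                t_target = t_insp_target
                w_target = w_insp
            else:  # expiration: compartments expel, sensor sees dead-space end
                c_mix = 0.0
                for i in range(ncomp):
                    dvi = dvm * vent[i]
                    v_comp[i] -= dvi
                    c_mix += vent[i] * c_comp[i]
                c_sens, alv_sens = ds.push_pop(dvm, c_mix, 1.0, from_sensor=False)
                if in_washout:
                    net_out_washout += c_sens * dvm
                t_target = t_exp_target
                w_target = w_exp
            # sensor-side temperature / humidity relax with through-flow
            relax_t = 1.0 - exp_m(-dvm / cfg.temp_volume_constant_ml)
            temp += (t_target - temp) * relax_t
            w += (w_target - w) * relax_t
            # true mixture -> reported molar mass with device-assumed T, gamma
            base_mm = _MM_AIR + (alv_sens * _DMM_EXCH if cfg.gas_exchange else 0.0)
            base_cp = _CP_AIR + (alv_sens * _DCP_EXCH if cfg.gas_exchange else 0.0)
            mm_true = (1.0 - w) * ((1.0 - c_sens) * base_mm + c_sens * _MM_SF6) + w * _MM_H2O
            cp = (1.0 - w) * ((1.0 - c_sens) * base_cp + c_sens * _CP_SF6) + w * _CP_H2O
            gamma_true = cp / (cp - R)
            mm_rep = mm_true * (_GAMMA_DEV * t_dev) / (gamma_true * temp)
            # side chamber(s): first-order toward the reported signal
            if f_ch > 0:
                if mm_ch[0] != mm_ch[0]:  # NaN: initialise at current signal
                    mm_ch[0] = mm_rep
                    mm_ch[1] = mm_rep
                if cfg.chamber_two_state:
                    r1 = 1.0 - exp_m(-dvm / lam)
                    r2 = 1.0 - exp_m(-dvm / (3.0 * lam))
                    mm_ch[0] += (mm_rep - mm_ch[0]) * r1
                    mm_ch[1] += (mm_rep - mm_ch[1]) * r2
                    mm_meas = (1.0 - f_ch) * mm_rep + f_ch * 0.5 * (mm_ch[0] + mm_ch[1])
                else:
                    mm_ch[0] += (mm_rep - mm_ch[0]) * (1.0 - exp_m(-dvm / lam))
                    mm_meas = (1.0 - f_ch) * mm_rep + f_ch * mm_ch[0]
            else:
                mm_meas = mm_rep
            c_ch += (c_sens - c_ch) * (1.0 - exp_m(-dvm / lam))
            chamber_state[k] = c_ch
            mm_rep_arr[k] = mm_meas
        # breath bookkeeping at end-expiration
        comp_truth[bi] = c_comp
        et_truth[bi] = sum(vent[i] * c_comp[i] for i in range(ncomp))
        if bi == washout_first - 1:
            content_washout_start = (
                sum(c_comp[i] * v_comp[i] for i in range(ncomp)) + ds.tracer_content_ml()
            )

    content_final = sum(c_comp[i] * v_comp[i] for i in range(ncomp)) + ds.tracer_content_ml()

    molar_mass = mm_rep_arr + cfg.noise_mm_sd * rng.standard_normal(n)
    flow = flow_clean + cfg.noise_flow_sd * rng.standard_normal(n)
    time = np.arange(n) * dt
    ambient = AmbientConditions(
        temperature_k=cfg.supply_temperature_k,
        pressure_pa=cfg.pressure_pa,
        relative_humidity=cfg.ambient_relative_humidity,
        body_temperature_k=310.15,
    )
    rec = RawRecording(
        time=time,
        flow=flow,
        molar_mass=molar_mass,
        sampling_rate_hz=sr,
        meta=RecordingMeta(
            ambient=ambient,
            dead_space_ml=cfg.dead_space_ml,
            tracer_fraction=cfg.tracer_fraction,
            true_frc_ml=cfg.total_frc_ml,
        ),
    )
    truth = GroundTruth(
        frc_true_ml=cfg.total_frc_ml,
        dead_space_ml=cfg.dead_space_ml,
        tracer_fraction=cfg.tracer_fraction,
        pre=(0, cfg.pre_breaths),
        washin=(cfg.pre_breaths, washout_first),
        washout=(washout_first, n_breaths),
        breath_starts=breath_starts,
        end_tidal_sf6=et_truth,
        compartment_sf6=comp_truth,
        chamber_state=chamber_state,
        content_washout_start_ml=content_washout_start,
        content_final_ml=content_final,
        net_expired_washout_ml=net_out_washout,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# the in-vitro condition grid


_SMALL = dict(frc_ml=(80.0,), vt_ml=30.0, rr_bpm=30.0)
_LARGE = dict(frc_ml=(210.0,), vt_ml=50.0, rr_bpm=20.0)
_VI_VENT = (0.7, 0.3)  # differential ventilation of the two subdivisions


def _condition(base: dict, condition: str) -> dict:
    d = dict(base)
    if condition == "standard":
        pass
    elif condition == "-T":
        d["bath_temperature_k"] = 293.15  # room temperature
    elif condition == "+RR":
        d["rr_bpm"] = d["rr_bpm"] * (1.66 if d["rr_bpm"] == 30.0 else 1.5)
    elif condition == "+VT":
        d["vt_ml"] = 50.0 if d["vt_ml"] == 30.0 else 80.0
    elif condition == "+VI":
        half = d["frc_ml"][0] / 2.0
        d["frc_ml"] = (half, half)
        d["ventilation_fractions"] = _VI_VENT
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return d


def condition_grid(replicates: int = 6, base_seed: int = 0) -> list[Scenario]:
    """The 2-volume x 5-condition in-vitro grid, ``replicates`` seeds per cell.

    Small baseline: FRC 80 mL, VT 30 mL, RR 30/min; large: FRC 210 mL,
    VT 50 mL, RR 20/min; variants: room temperature (-T), +66%/+50%
    respiratory rate (+RR), tidal volume 50/80 mL (+VT), and a two-
    compartment split with differential ventilation (+VI).
    """
    conditions = ("standard", "-T", "+RR", "+VT", "+VI")
    sizes = (("small", _SMALL), ("large", _LARGE))
    n_cells = len(conditions) * len(sizes)
    seeds = np.random.SeedSequence(base_seed).generate_state(n_cells * replicates) & 0x7FFFFFFF
    out: list[Scenario] = []
    k = 0
    for size, base in sizes:
        for condition in conditions:
            params = _condition(base, condition)
            for rep in range(replicates):
                cfg = SimulationConfig(seed=int(seeds[k]), **params)
                out.append(
                    Scenario(
                        name=f"{size}_{condition}_r{rep}",
                        size=size,
                        condition=condition,
                        replicate=rep,
                        config=cfg,
                    )
                )
                k += 1
    return out
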