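"""Gas-mixture physics underlying speed-of-sound molar-mass sensing.

An ultrasonic flowmeter measures the transit time of sound pulses across its
measurement path and converts it to the mean molar mass of the gas via

    c = sqrt(gamma * R * T / MM)

with ``c`` the speed of sound, ``gamma`` the adiabatic index (Cp/Cv), ``R``
the universal gas constant, ``T`` the absolute temperature and ``MM`` the
molar mass in kg/mol.  Everything in this module is an ideal-gas relation:
mixture molar mass and molar heat capacity are mole-fraction weighted, and
``gamma`` of a mixture follows from the mixed heat capacities
(gamma = Cp / (Cp - R)).  Real-gas corrections are out of scope; over the
composition and temperature range of an SF6 washout they are far below the
sensor noise floor.

Species constants are literature values (CRC Handbook / NIST WebBook,
molar heat capacities at 298 K).  Water vapour is carried as an explicit
species so that tidal humidity swings can be simulated rather than folded
into a correction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "R",
    "GasMixture",
    "AmbientConditions",
    "mixture_molar_mass",
    "mixture_heat_capacity",
    "mixture_adiabatic_index",
    "speed_of_sound",
    "molar_mass_from_speed",
    "saturation_vapor_pressure",
    "btps_factor",
    "SPECIES_MOLAR_MASS",
    "SPECIES_CP",
]

#: Universal gas constant, J/(mol K).
R = 8.314462618

#: Molar masses, g/mol (CRC Handbook).
SPECIES_MOLAR_MASS = {
    "n2": 28.014,
    "o2": 31.998,
    "co2": 44.009,
    "ar": 39.948,
    "sf6": 146.055,
    "h2o": 18.015,
}

#: Molar heat capacities Cp at constant pressure and 298 K, J/(mol K)
#: (NIST WebBook; SF6 is strongly polyatomic, hence its gamma is near 1.09).
SPECIES_CP = {
    "n2": 29.124,
    "o2": 29.378,
    "co2": 37.129,
    "ar": 20.786,
    "sf6": 97.0,
    "h2o": 33.58,
}

_DRY_AIR = {"n2": 0.7808, "o2": 0.2095, "co2": 0.0004, "ar": 0.0093}


@dataclass(frozen=True)
class GasMixture:
    """Mole fractions of the six species tracked by the analysis.

    Fractions must lie in [0, 1] and sum to one within 1e-9.
    """

    n2: float = 0.0
    o2: float = 0.0
    co2: float = 0.0
    ar: float = 0.0
    sf6: float = 0.0
    h2o: float = 0.0

    def __post_init__(self) -> None:
        total = 0.0
        for f in fields(self):
            x = getattr(self, f.name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"fraction {f.name}={x} outside [0, 1]")
            total += x
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1 within 1e-9")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @staticmethod
    def dry_air() -> "GasMixture":
        return GasMixture(**_DRY_AIR)

    @staticmethod
    def air_with_sf6(sf6_fraction: float) -> "GasMixture":
        """Dry air with the given SF6 mole fraction; air species scaled down."""
        if not (0.0 <= sf6_fraction <= 1.0):
            raise ValueError("sf6_fraction outside [0, 1]")
        scale = 1.0 - sf6_fraction
        return GasMixture(sf6=sf6_fraction, **{k: v * scale for k, v in _DRY_AIR.items()})

    def with_water(self, h2o_fraction: float) -> "GasMixture":
        """Replace part of the mixture with water vapour (total stays 1)."""
        if not (0.0 <= h2o_fraction < 1.0):
            raise ValueError("h2o_fraction outside [0, 1)")
        scale = 1.0 - h2o_fraction
        d = {k: v * scale for k, v in self.as_dict().items()}
        d["h2o"] = self.h2o * scale + h2o_fraction
        return GasMixture(**d)

    @staticmethod
    def blend(a: "GasMixture", b: "GasMixture", t: float) -> "GasMixture":
        """Mole-fraction interpolation (1-t)*a + t*b."""
        da, db = a.as_dict(), b.as_dict()
        return GasMixture(**{k: (1.0 - t) * da[k] + t * db[k] for k in da})


@dataclass(frozen=True)
class AmbientConditions:
    """Ambient and body-side conditions for BTPS volume conversion.

    temperature_k / body_temperature_k in [270, 320] K, pressure in
    [50, 110] kPa, relative humidity a fraction in [0, 1].
    """

    temperature_k: float = 295.15
    pressure_pa: float = 101325.0
    relative_humidity: float = 0.5
    body_temperature_k: float = 310.15

    def __post_init__(self) -> None:
        for name in ("temperature_k", "body_temperature_k"):
            t = getattr(self, name)
            if not (270.0 <= t <= 320.0):
                raise ValueError(f"{name}={t} outside [270, 320] K")
        if not (50e3 <= self.pressure_pa <= 110e3):
            raise ValueError(f"pressure_pa={self.pressure_pa} outside [50, 110] kPa")
        if not (0.0 <= self.relative_humidity <= 1.0):
            raise ValueError("relative_humidity outside [0, 1]")


def mixture_molar_mass(mix: GasMixture) -> float:
    """Mole-fraction weighted molar mass, g/mol."""
    return sum(x * SPECIES_MOLAR_MASS[k] for k, x in mix.as_dict().items())


def mixture_heat_capacity(mix: GasMixture) -> float:
    """Mole-fraction weighted molar heat capacity Cp, J/(mol K)."""
    return sum(x * SPECIES_CP[k] for k, x in mix.as_dict().items())


def mixture_adiabatic_index(mix: GasMixture) -> float:
    """gamma = Cp / Cv with Cv = Cp - R (ideal-gas mixing)."""
    cp = mixture_heat_capacity(mix)
    return cp / (cp - R)


def speed_of_sound(mix: GasMixture, temperature_k: float) -> float:
    """Speed of sound in m/s: sqrt(gamma * R * T / MM), MM in kg/mol."""
    if temperature_k <= 0.0:
        raise ValueError("temperature must be positive (kelvin)")
    gamma = mixture_adiabatic_index(mix)
    mm_kg = mixture_molar_mass(mix) / 1000.0
    return math.sqrt(gamma * R * temperature_k / mm_kg)


def molar_mass_from_speed(c: float, temperature_k: float, gamma: float) -> float:
    """Invert the speed-of-sound relation: MM = gamma R T / c^2, in g/mol.

    This is what the flowmeter firmware does with its *assumed* gamma and
    temperature; the simulator uses it to produce the confounded raw signal.
    """
    if c <= 0.0 or temperature_k <= 0.0:
        raise ValueError("speed and temperature must be positive")
    return 1000.0 * gamma * R * temperature_k / (c * c)


def saturation_vapor_pressure(temperature_k: float) -> float:
    """Saturation vapour pressure of water over liquid, Pa (Magnus formula).

    Valid over [270, 320] K; accuracy there is far below sensor noise.
    """
    if not (270.0 <= temperature_k <= 320.0):
        raise ValueError(f"temperature {temperature_k} K outside [270, 320] K")
    t = temperature_k - 273.15
    return 610.94 * math.exp(17.625 * t / (t + 243.04))


def btps_factor(
    cond: AmbientConditions,
    direction: str,
    sensor_temperature_k: float | None = None,
    sensor_relative_humidity: float | None = None,
) -> float:
    """Multiplicative factor converting sensor-condition volume to BTPS.

    ``direction`` is ``"inspiration"`` (gas at ambient temperature and
    humidity) or ``"expiration"`` (gas saturated, cooled to the sensor
    temperature, which defaults to ambient).  Explicit sensor temperature /
    humidity override the defaults.  The factor follows the standard
    ideal-gas form

        (T_body / T_sensor) * (P - P_H2O,sensor) / (P - P_sat(T_body))
    """
    if direction not in ("inspiration", "expiration"):
        raise ValueError("direction must be 'inspiration' or 'expiration'")
    p = cond.pressure_pa
    if direction == "inspiration":
        t_sensor = cond.temperature_k if sensor_temperature_k is None else sensor_temperature_k
        rh = cond.relative_humidity if sensor_relative_humidity is None else sensor_relative_humidity
    else:
        t_sensor = cond.temperature_k if sensor_temperature_k is None else sensor_temperature_k
        rh = 1.0 if sensor_relative_humidity is None else sensor_relative_humidity
    ph2o_sensor = rh * saturation_vapor_pressure(t_sensor)
    ph2o_body = saturation_vapor_pressure(cond.body_temperature_k)
    return (cond.body_temperature_k / t_sensor) * (p - ph2o_sensor) / (p - ph2o_body)
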