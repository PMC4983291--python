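"""Closed-form calculators for the pulse-level quantities of CO-CO TOCSY experiments.

A rectangular pulse with RF nutation frequency nu1 rotates an on-resonance spin
through 360 degrees in one nutation period 1/nu1.  A spin off resonance by
``delta_nu`` nutates about a tilted effective field of magnitude
sqrt(nu1**2 + delta_nu**2), so the rotation accumulated during the same pulse is
scaled by sqrt(1 + (delta_nu/nu1)**2).  Two special offset ratios matter for
CO-selective pulses applied in the presence of CA spins:

* ratio sqrt(15): an on-resonance 180 degree pulse gives CA an effective
  720 degree rotation (the MOCCA train condition), i.e. CA returns to its
  starting state after every mixing pulse;
* ratio sqrt(3): the same pulse gives CA an effective 360 degree rotation,
  a lower-power alternative with a wider inversion profile.

Inverting the same relations yields the RF field of a CA/CO band-selective
pulse from the CA-CO offset: |dOmega|/sqrt(15) for a 90 degree pulse and
|dOmega|/sqrt(3) for a 180 degree pulse.

Semi-constant-time and constant-time evolution delays are provided as the
standard three-delay schemes in which the net shift evolution equals the
nominal evolution time t while the total sequence duration grows more slowly
than t (semi-constant-time) or stays fixed (constant-time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RfField",
    "SctDelays",
    "PulseTimingConstants",
    "MOCCA_RF_KHZ",
    "SINC_SELECTIVE_US",
    "SQRT15",
    "SQRT3",
    "rect_pulse_duration",
    "effective_rotation",
    "selective_rf",
    "sct_delays",
    "field_report",
]

SQRT15 = math.sqrt(15.0)
SQRT3 = math.sqrt(3.0)

#: MOCCA-XY16 CO 180-degree pulse RF field (kHz) at each proton frequency (MHz).
MOCCA_RF_KHZ = {600: 4.68, 800: 6.23}

#: Sinc-shaped selective-pulse durations (us) by field: (90 deg, 180 deg).
#: Shaped-pulse durations depend on the sinc time-bandwidth factor and are kept
#: as calibration constants rather than computed from the rectangular rule.
SINC_SELECTIVE_US = {600: (87.8, 78.4), 800: (65.8, 58.8)}


@dataclass(frozen=True)
class RfField:
    """RF field strength expressed as a nutation frequency in kHz."""

    nu1_khz: float

    def __post_init__(self) -> None:
        if not self.nu1_khz > 0:
            raise ValueError(f"nu1 must be positive, got {self.nu1_khz}")


@dataclass(frozen=True)
class SctDelays:
    """The three delays (seconds) of a (semi-)constant-time evolution block."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) < -1e-15:
                raise ValueError(f"delay {name} is negative: {getattr(self, name)}")

    @property
    def evolution(self) -> float:
        """Net chemical-shift evolution time a + b - c."""
        return self.a + self.b - self.c

    @property
    def total(self) -> float:
        """Total wall-clock duration a + b + c of the block."""
        return self.a + self.b + self.c


@dataclass(frozen=True)
class PulseTimingConstants:
    """Fixed transfer delays and MOCCA train timing.

    ``mocca_period_us`` is the 180-degree pulse repetition period of the mixing
    train and includes the pulse itself, hence it can never be shorter than the
    pulse length ``mocca_pulse_us``.
    """

    delta_nh_ms: float = 5.4
    delta_nco_ms: float = 28.0
    delta_coca_ms: float = 9.1
    mocca_period_us: float = 500.0
    mocca_pulse_us: float = 107.0

    def __post_init__(self) -> None:
        for name in ("delta_nh_ms", "delta_nco_ms", "delta_coca_ms",
                     "mocca_period_us", "mocca_pulse_us"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mocca_period_us < self.mocca_pulse_us:
            raise ValueError("MOCCA repetition period must include the pulse length")


def rect_pulse_duration(flip_angle_deg: float, rf: RfField | float) -> float:
    """Duration (us) of a rectangular pulse with the given on-resonance flip angle.

    One full nutation period at ``nu1`` kHz lasts 1/nu1 ms, so a flip of
    ``flip_angle_deg`` degrees takes flip/360 of that.
    """
    nu1 = rf.nu1_khz if isinstance(rf, RfField) else float(rf)
    if not flip_angle_deg > 0:
        raise ValueError("flip angle must be positive")
    if not nu1 > 0:
        raise ValueError("RF field must be positive")
    return (flip_angle_deg / 360.0) * 1000.0 / nu1


def effective_rotation(offset_ratio: float, on_resonance_flip_deg: float = 180.0) -> float:
    """Rotation (degrees) about the tilted effective field for an off-resonance spin.

    ``offset_ratio`` is the resonance offset divided by the RF nutation
    frequency; the effective field exceeds the RF field by sqrt(1 + ratio**2).
    """
    if not on_resonance_flip_deg > 0:
        raise ValueError("on-resonance flip must be positive")
    return on_resonance_flip_deg * math.sqrt(1.0 + offset_ratio * offset_ratio)


def selective_rf(delta_omega_khz: float, flip_angle_deg: float) -> RfField:
    """RF field of a rectangular CA/CO band-selective pulse.

    The field is set from the CA-CO offset so that the off-band spin performs a
    full effective rotation during the pulse: |dOmega|/sqrt(15) for 90 degrees,
    |dOmega|/sqrt(3) for 180 degrees.
    """
    if not delta_omega_khz > 0:
        raise ValueError("CA-CO offset must be positive")
    if flip_angle_deg == 90:
        return RfField(delta_omega_khz / SQRT15)
    if flip_angle_deg == 180:
        return RfField(delta_omega_khz / SQRT3)
    raise ValueError(f"selective pulses are defined for 90 or 180 degrees, got {flip_angle_deg}")


def sct_delays(t: float, t_max: float, delta: float, mode: str = "semi_constant") -> SctDelays:
    """Delays of a (semi-)constant-time evolution block at evolution time ``t``.

    Semi-constant-time: a = (t + D)/2, b = t(1 - D/t_max)/2, c = D(1 - t/t_max)/2.
    Constant-time:      a = (t + D)/2, b = 0,                c = (D - t)/2.
    In both modes a + b - c = t exactly; in constant-time mode a + b + c = D.

    All times in seconds.  Constant-time mode requires t <= D (otherwise c
    would be negative); semi-constant-time requires t <= t_max.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if t < 0:
        raise ValueError("evolution time must be non-negative")
    if mode == "semi_constant":
        if t > t_max:
            raise ValueError(f"t={t} exceeds t_max={t_max}")
        if t_max <= 0:
            raise ValueError("t_max must be positive in semi-constant-time mode")
        a = (t + delta) / 2.0
        b = t * (1.0 - delta / t_max) / 2.0
        c = delta * (1.0 - t / t_max) / 2.0
        # With delta > t_max the scheme degenerates (b < 0); flag it.
        if b < -1e-15:
            raise ValueError("delta exceeds t_max: semi-constant-time scheme is infeasible")
        return SctDelays(a, max(b, 0.0), c)
    if mode == "constant":
        if t > delta:
            raise ValueError(f"constant-time mode needs t <= delta, got t={t}, delta={delta}")
        return SctDelays((t + delta) / 2.0, 0.0, (delta - t) / 2.0)
    raise ValueError(f"unknown mode {mode!r}")


def field_report(field_mhz: int) -> dict[str, float]:
    """Derived pulse quantities at a supported field (600 or 800 MHz).

    The CA-CO offset is not an independent input: it is recovered from the
    MOCCA 720-degree condition as sqrt(15) x nu1(MOCCA), which makes the report
    self-consistent with all printed pulse durations at that field.
    """
    if field_mhz not in MOCCA_RF_KHZ:
        raise ValueError(f"supported fields are {sorted(MOCCA_RF_KHZ)}, got {field_mhz}")
    mocca = RfField(MOCCA_RF_KHZ[field_mhz])
    delta_omega = SQRT15 * mocca.nu1_khz
    sel90 = selective_rf(delta_omega, 90)
    sel180 = selective_rf(delta_omega, 180)
    sinc90, sinc180 = SINC_SELECTIVE_US[field_mhz]
    return {
        "field_mhz": float(field_mhz),
        "mocca_rf_khz": mocca.nu1_khz,
        "mocca_180_us": rect_pulse_duration(180, mocca),
        "ca_effective_rotation_deg": effective_rotation(SQRT15, 180),
        "delta_omega_khz": delta_omega,
        "selective_90_rf_khz": sel90.nu1_khz,
        "selective_90_us": rect_pulse_duration(90, sel90),
        "selective_180_rf_khz": sel180.nu1_khz,
        "selective_180_us": rect_pulse_duration(180, sel180),
        "sinc_90_us": sinc90,
        "sinc_180_us": sinc180,
    }
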