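"""CO-CO TOCSY transfer during MOCCA-XY16 mixing.

In-phase polarization exchange between weakly coupled carbonyl spins under
ideal isotropic mixing is modelled as a quantum walk on the CO chain: the
effective Hamiltonian has nearest-neighbour matrix elements pi*J (rad/s) and
the fraction of polarization reaching site m from source s after mixing time t
is |U_ms|**2 with U = expm(-i H t).  For two spins this reduces to the textbook
TOCSY closed form (cos^2(pi J t), sin^2(pi J t)).

Relaxation during mixing is applied as a single exponential envelope
exp(-R(B0) * t).  CO transverse relaxation in the mixing train is dominated by
chemical-shift anisotropy, whose rate grows with the square of the static
field, so R(B0) = R600 * (B0/600)**2 with R600 the rate at 600 MHz.  This is
why a lower-field spectrometer can out-perform a higher-field one for long
CO-CO mixing periods.

The walk is windowed to +/-2 neighbours of the source: the mixing time is
attuned for i+/-1 transfer, and amplitude leaking further along the chain is
computed but never emitted as peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = ["MixingModel", "TransferProfile", "relaxation_rate", "chain_transfer",
           "cross_fraction", "compare_mixing_times", "WINDOW"]

#: Half-width of the chain window around the source spin.
WINDOW = 2

#: Default relaxation rate at 600 MHz: the 250 ms envelope is ~0.7.
DEFAULT_R600 = -math.log(0.7) / 0.25


@dataclass(frozen=True)
class MixingModel:
    """Parameters of the CO-CO mixing step.

    J_hz          effective CO-CO isotropic-mixing coupling (Hz)
    t_mix_ms      mixing time (ms)
    r600_per_s    effective relaxation rate during mixing at 600 MHz (1/s)
    b0_mhz        proton frequency of the spectrometer (MHz)
    """

    J_hz: float = 1.0
    t_mix_ms: float = 250.0
    r600_per_s: float = DEFAULT_R600
    b0_mhz: float = 600.0

    def __post_init__(self) -> None:
        if self.J_hz < 0 or self.t_mix_ms < 0 or self.r600_per_s < 0:
            raise ValueError("J, t_mix and R600 must be non-negative")
        if not self.b0_mhz > 0:
            raise ValueError("B0 must be positive")

    def with_field(self, b0_mhz: float) -> "MixingModel":
        return replace(self, b0_mhz=b0_mhz)


@dataclass(frozen=True)
class TransferProfile:
    """Transfer fractions by chain offset from the source (-2 .. +2).

    Fractions are dimensionless, each in [0, 1]; with relaxation they sum to
    less than one (amplitude is lost, never created).
    """

    fractions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for off, f in self.fractions.items():
            if not -1e-12 <= f <= 1.0 + 1e-12:
                raise ValueError(f"fraction at offset {off} outside [0,1]: {f}")

    def at_offset(self, offset: int) -> float:
        return self.fractions.get(offset, 0.0)

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))


def relaxation_rate(model: MixingModel) -> float:
    """Effective relaxation rate (1/s) during mixing at the model's field."""
    return model.r600_per_s * (model.b0_mhz / 600.0) ** 2


def chain_transfer(model: MixingModel, chain_length: int, source_index: int) -> TransferProfile:
    """Polarization fractions reaching each chain position near the source.

    The chain is restricted to the window [source-2, source+2] intersected with
    [0, chain_length-1]; the propagator of the tridiagonal coupling Hamiltonian
    (off-diagonal pi*J rad/s) is evaluated at t_mix, its moduli squared, and
    the relaxation envelope exp(-R t) applied.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    if not 0 <= source_index < chain_length:
        raise ValueError("source_index outside chain")
    t = model.t_mix_ms * 1e-3
    lo = max(0, source_index - WINDOW)
    hi = min(chain_length - 1, source_index + WINDOW)
    n = hi - lo + 1
    src = source_index - lo
    if n == 1 or model.J_hz == 0.0 or t == 0.0:
        env = math.exp(-relaxation_rate(model) * t)
        return TransferProfile({0: env} if n >= 1 else {})
    h = np.zeros((n, n))
    off = math.pi * model.J_hz
    for k in range(n - 1):
        h[k, k + 1] = h[k + 1, k] = off
    u = expm(-1j * h * t)
    env = math.exp(-relaxation_rate(model) * t)
    fracs = {}
    for m in range(n):
        offset = (m + lo) - source_index
        fracs[offset] = float(np.abs(u[m, src]) ** 2) * env
    return TransferProfile(fracs)


def cross_fraction(model: MixingModel) -> float:
    """Two-spin i+/-1 transfer fraction sin^2(pi J t) * exp(-R t)."""
    return chain_transfer(model, 2, 0).at_offset(1)


def compare_mixing_times(model: MixingModel, t_a_ms: float, t_b_ms: float):
    """Which of two mixing times yields the larger i+/-1 cross fraction.

    Returns ``(winner_ms, fraction_a, fraction_b)``; on an exact tie the first
    argument is reported as the winner.
    """
    if t_a_ms < 0 or t_b_ms < 0:
        raise ValueError("mixing times must be non-negative")
    fa = cross_fraction(replace(model, t_mix_ms=t_a_ms))
    fb = cross_fraction(replace(model, t_mix_ms=t_b_ms))
    return (t_a_ms if fa >= fb else t_b_ms), fa, fb
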