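"""Time-domain synthesis of peak lists on a Nyquist grid with NUS schedules.

The signal model is a sum of ideally phased complex exponentials, one per
peak and per dimension,

    d(t) = sum_p A_p * prod_d exp(+i 2 pi nu_{p,d} t_d - R_d t_d) + noise,

sampled at integer grid coordinates n_d with t_d = n_d / sw_d.  Quadrature is
ideal complex sampling in every dimension (the States-TPPI / echo-antiecho
bookkeeping of the acquisition adds no testable behaviour for reconstruction
correctness), so conjugate symmetry is NOT assumed anywhere downstream.
Frequencies live in [-sw/2, sw/2); a peak outside its window is an error --
folding is not modelled.

Schedules are sets of unique integer coordinates.  Two forms exist: plain
random subsets of a grid, and factorized products (full Cartesian grid over
leading "anchor" axes x a NUS subset of the trailing resolved axes).  The
product form mirrors acquisition in which the anchor evolution dimensions are
effectively resolved by the conventionally sampled HNCO base while sparse
sampling is spent on the new CO/N dimensions, and it is what keeps synthesis
and reconstruction fast (rank-one structure over peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import PeakList

__all__ = ["AxisDef", "SamplingSchedule", "TimeDomainSet", "make_schedule",
           "synthesize", "write_schedule", "read_schedule"]


@dataclass(frozen=True)
class AxisDef:
    """One spectral dimension of the simulated data.

    label        dimension label matching the peak-list dimension names
    sw_hz        spectral width (Hz)
    size         Nyquist grid size (points); max evolution time = size/sw
    obs_mhz      observe frequency (MHz), for ppm <-> Hz conversion
    carrier_ppm  carrier position (ppm) mapped to zero frequency
    """

    label: str
    sw_hz: float
    size: int
    obs_mhz: float
    carrier_ppm: float

    def __post_init__(self) -> None:
        if self.sw_hz <= 0 or self.size <= 0 or self.obs_mhz <= 0:
            raise ValueError("spectral width, grid size and observe frequency must be positive")

    @property
    def t_max_s(self) -> float:
        return self.size / self.sw_hz

    @property
    def default_decay(self) -> float:
        """Default decay rate 2/t_max (1/s): linewidth of about two grid cells."""
        return 2.0 / self.t_max_s

    def ppm_to_hz(self, ppm: float) -> float:
        return (ppm - self.carrier_ppm) * self.obs_mhz

    def hz_to_ppm(self, hz: float) -> float:
        return hz / self.obs_mhz + self.carrier_ppm


@dataclass
class SamplingSchedule:
    """Unique integer coordinates on an indirect-dimension grid.

    Either ``explicit`` holds an (M, D) index array, or ``factor`` holds
    (head_shape, tail_indices): the schedule is then the Cartesian product of
    the full head grid with the tail indices, in head-major order.
    """

    shape: tuple[int, ...]
    explicit: np.ndarray | None = None
    factor: tuple[tuple[int, ...], np.ndarray] | None = None
    seed: int | None = None
    mode: str = "explicit"

    def __post_init__(self) -> None:
        if (self.explicit is None) == (self.factor is None):
            raise ValueError("exactly one of explicit/factor must be given")
        if self.explicit is not None:
            idx = np.asarray(self.explicit, dtype=np.int64)
            if idx.ndim != 2 or idx.shape[1] != len(self.shape):
                raise ValueError("index array must be (M, ndim)")
            if (idx < 0).any() or (idx >= np.array(self.shape)).any():
                raise ValueError("schedule coordinates outside grid bounds")
            if len(np.unique(idx, axis=0)) != len(idx):
                raise ValueError("schedule contains duplicate coordinates")
            self.explicit = idx

    # -- constructors ------------------------------------------------------
    @classmethod
    def full(cls, shape: tuple[int, ...]) -> "SamplingSchedule":
        idx = np.indices(shape).reshape(len(shape), -1).T.astype(np.int64)
        return cls(shape=tuple(shape), explicit=idx, mode="full")

    @classmethod
    def uniform(cls, shape: tuple[int, ...], n_points: int, seed: int) -> "SamplingSchedule":
        total = int(np.prod(shape))
        if n_points > total:
            raise ValueError(f"n_points={n_points} exceeds grid size {total}")
        if n_points < 1:
            raise ValueError("n_points must be >= 1")
        rng = np.random.default_rng(seed)
        # Always include the zero-time coordinate (flat index 0).
        rest = rng.choice(total - 1, size=n_points - 1, replace=False) + 1
        flat = np.concatenate([[0], np.sort(rest)])
        idx = np.stack(np.unravel_index(flat, shape), axis=1).astype(np.int64)
        return cls(shape=tuple(shape), explicit=idx, seed=seed, mode="uniform")

    @classmethod
    def product(cls, head_shape: tuple[int, ...], tail: "SamplingSchedule") -> "SamplingSchedule":
        if tail.explicit is None:
            raise ValueError("tail schedule must be explicit")
        return cls(shape=tuple(head_shape) + tail.shape,
                   factor=(tuple(head_shape), tail.explicit),
                   seed=tail.seed, mode="product")

    # -- views -------------------------------------------------------------
    @property
    def n_points(self) -> int:
        if self.explicit is not None:
            return len(self.explicit)
        head_shape, tail_idx = self.factor
        return int(np.prod(head_shape)) * len(tail_idx)

    @property
    def indices(self) -> np.ndarray:
        """Materialized (M, D) index array (head-major for product schedules)."""
        if self.explicit is not None:
            return self.explicit
        head_shape, tail_idx = self.factor
        head = np.indices(head_shape).reshape(len(head_shape), -1).T.astype(np.int64)
        nh, nt = len(head), len(tail_idx)
        return np.concatenate([np.repeat(head, nt, axis=0),
                               np.tile(tail_idx, (nh, 1))], axis=1)


def make_schedule(axes: list[AxisDef], n_points: int, seed: int) -> SamplingSchedule:
    """Uniform-random NUS schedule over the grid spanned by ``axes``."""
    shape = tuple(a.size for a in axes)
    if n_points == int(np.prod(shape)):
        return SamplingSchedule.full(shape)
    return SamplingSchedule.uniform(shape, n_points, seed)


@dataclass
class TimeDomainSet:
    """Complex FID values at the scheduled grid points plus axis metadata."""

    values: np.ndarray
    schedule: SamplingSchedule
    axes: list[AxisDef]
    decay: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if len(self.values) != self.schedule.n_points:
            raise ValueError("one value per scheduled point required")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite FID values")

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.axes]

    def axis(self, label: str) -> AxisDef:
        for a in self.axes:
            if a.label == label:
                return a
        raise KeyError(label)


def _axis_vector(axis: AxisDef, nu_hz: float, decay: float) -> np.ndarray:
    """Per-grid-index complex evolution factors exp((i 2 pi nu - R) n / sw)."""
    n = np.arange(axis.size)
    z = (1j * 2.0 * np.pi * nu_hz - decay) / axis.sw_hz
    return np.exp(z * n)


def synthesize(peaks: PeakList, schedule: SamplingSchedule, axes: list[AxisDef],
               decay: dict[str, float] | None = None, noise_sigma: float = 0.0,
               seed: int = 0) -> TimeDomainSet:
    """Synthesize the complex FID of ``peaks`` at the scheduled grid points.

    ``axes`` select (by label) which peak dimensions become time axes; peak
    dimensions without an axis (e.g. the detected amide proton) are ignored.
    ``decay`` maps axis label -> R (1/s), default 2/t_max per axis.  Noise is
    complex Gaussian with total standard deviation ``noise_sigma`` per point.
    """
    if tuple(a.size for a in axes) != schedule.shape:
        raise ValueError("schedule shape does not match axis grid sizes")
    rates = {a.label: (decay or {}).get(a.label, a.default_decay) for a in axes}

    bad = []
    for p in peaks:
        for a in axes:
            nu = a.ppm_to_hz(p.positions[a.label])
            if not -a.sw_hz / 2 <= nu < a.sw_hz / 2:
                bad.append((p.assignment(), a.label, p.positions[a.label]))
    if bad:
        raise ValueError("peaks outside spectral window (no folding): "
                         + "; ".join(f"{lab} {dim}={ppm:.2f} ppm" for lab, dim, ppm in bad))

    npk = len(peaks.entries)
    vectors = [[_axis_vector(a, a.ppm_to_hz(p.positions[a.label]), rates[a.label])
                for a in axes] for p in peaks]

    if schedule.factor is not None:
        head_shape, tail_idx = schedule.factor
        nh = len(head_shape)
        ncells = int(np.prod(head_shape))
        a_mat = np.empty((npk, ncells), dtype=complex)
        b_mat = np.empty((npk, len(tail_idx)), dtype=complex)
        for p in range(npk):
            head = peaks.entries[p].amplitude * vectors[p][0]
            for d in range(1, nh):
                head = np.multiply.outer(head, vectors[p][d])
            a_mat[p] = head.ravel()
            tail = np.ones(len(tail_idx), dtype=complex)
            for d in range(nh, len(axes)):
                tail = tail * vectors[p][d][tail_idx[:, d - nh]]
            b_mat[p] = tail
        values = (a_mat.T @ b_mat).ravel()
    else:
        idx = schedule.indices
        values = np.zeros(len(idx), dtype=complex)
        for p in range(npk):
            term = peaks.entries[p].amplitude * np.ones(len(idx), dtype=complex)
            for d in range(len(axes)):
                term = term * vectors[p][d][idx[:, d]]
            values += term

    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        m = schedule.n_points
        values = values + noise_sigma / np.sqrt(2.0) * (
            rng.standard_normal(m) + 1j * rng.standard_normal(m))

    return TimeDomainSet(values=values, schedule=schedule, axes=list(axes),
                         decay=rates, noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------

def write_schedule(schedule: SamplingSchedule, path) -> None:
    """One line per point, space-separated integer indices (common NUS dialect)."""
    np.savetxt(path, schedule.indices, fmt="%d")


def read_schedule(path, shape: tuple[int, ...]) -> SamplingSchedule:
    idx = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return SamplingSchedule(shape=tuple(shape), explicit=idx, mode="explicit")


def write_timedomain(data: TimeDomainSet, path) -> None:
    """Indices + real + imag as TSV, one scheduled point per line."""
    idx = data.schedule.indices
    with open(path, "w") as fh:
        fh.write("\t".join(a.label for a in data.axes) + "\tre\tim\n")
        for row, v in zip(idx, data.values):
            fh.write("\t".join(str(int(i)) for i in row)
                     + f"\t{v.real:.8e}\t{v.imag:.8e}\n")
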