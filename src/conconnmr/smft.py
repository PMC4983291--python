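"""Sparse multidimensional Fourier transform cross-sections and peak picking.

Instead of reconstructing a full 4D/5D spectrum, the Fourier transform of the
sparsely sampled data is evaluated only on low-dimensional cross-sections:
the anchor dimensions are fixed at the exact (not grid-snapped) frequencies of
a 3D HNCO peak, and the remaining "resolved" dimensions are evaluated on a
dense frequency grid,

    S(w) = (1/M) sum_{sampled t} d(t) exp(-i 2 pi [nu_anchor . t_anchor + w . t_res]).

Sections are returned in magnitude mode; the synthetic model is ideally
phased, so magnitude display only avoids zero-order phase bookkeeping.
Unsampled grid points simply contribute nothing (zero-augmented transform);
incomplete sampling therefore leaks a pseudo-noise floor of spurious
intensity, which is estimated empirically (median off-peak magnitude) and
used to threshold the picker.  No artefact-cleaning algorithm is applied:
the threshold is the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from .nussim import AxisDef, TimeDomainSet

__all__ = ["AnchorPeak", "CrossSection", "cross_section",
           "sampling_noise_level", "pick_peaks"]


@dataclass(frozen=True)
class AnchorPeak:
    """An HNCO anchor: detection coordinates plus a label.

    ``truth_residue`` is optional provenance used only by the scoring stage.
    """

    label: str
    hn_ppm: float
    n_ppm: float
    co_ppm: float
    truth_residue: int | None = None

    def anchor_freqs(self) -> dict[str, float]:
        """ppm per anchor dimension label as used by the time-domain axes."""
        return {"HN": self.hn_ppm, "Nanc": self.n_ppm, "COanc": self.co_ppm}


@dataclass
class CrossSection:
    """Dense magnitude grid over 1 or 2 resolved axes at a fixed anchor."""

    anchor_label: str
    axes: list[AxisDef]
    freq_ppm: list[np.ndarray]      # per resolved axis, ppm of each grid column
    grid: np.ndarray                # magnitude values, shape = grid sizes
    m_points: int                   # number of sampled time-domain points

    def __post_init__(self) -> None:
        if self.grid.shape != tuple(len(f) for f in self.freq_ppm):
            raise ValueError("grid shape does not match frequency axes")
        if (self.grid < 0).any():
            raise ValueError("magnitude grid must be non-negative")

    @property
    def max(self) -> float:
        return float(self.grid.max())

    def write_tsv(self, path) -> None:
        """Plain matrix TSV: first row/column are the ppm axes."""
        with open(path, "w") as fh:
            if self.grid.ndim == 1:
                fh.write(f"# axis: {self.axes[0].label}\n")
                for ppm, v in zip(self.freq_ppm[0], self.grid):
                    fh.write(f"{ppm:.4f}\t{v:.6e}\n")
                return
            fh.write(f"# rows: {self.axes[0].label}, cols: {self.axes[1].label}\n")
            fh.write("ppm\t" + "\t".join(f"{p:.4f}" for p in self.freq_ppm[1]) + "\n")
            for ppm, row in zip(self.freq_ppm[0], self.grid):
                fh.write(f"{ppm:.4f}\t" + "\t".join(f"{v:.6e}" for v in row) + "\n")


def _freq_grid(axis: AxisDef, oversample: int) -> tuple[np.ndarray, np.ndarray]:
    """(Hz grid, ppm grid) spanning [-sw/2, sw/2) with oversample x size points."""
    g = axis.size * oversample
    hz = -axis.sw_hz / 2.0 + np.arange(g) * (axis.sw_hz / g)
    ppm = hz / axis.obs_mhz + axis.carrier_ppm
    return hz, ppm


def cross_section(data: TimeDomainSet, anchor: AnchorPeak | dict[str, float],
                  resolved_labels: list[str] | tuple[str, ...],
                  oversample: int = 2) -> CrossSection:
    """SMFT cross-section of ``data`` at a fixed anchor.

    ``anchor`` supplies exact frequencies (ppm) for every data axis not listed
    in ``resolved_labels``; for pure low-dimensional data an empty mapping is
    allowed.  The resolved axes are evaluated on a dense grid oversampled by
    ``oversample`` relative to their Nyquist grids.
    """
    if data.schedule.n_points == 0:
        raise ValueError("empty sampling schedule")
    anchor_label = anchor.label if isinstance(anchor, AnchorPeak) else "section"
    anchor_ppm = anchor.anchor_freqs() if isinstance(anchor, AnchorPeak) else dict(anchor)

    labels = data.labels
    resolved_labels = list(resolved_labels)
    if not 1 <= len(resolved_labels) <= 2:
        raise ValueError("cross-sections support 1 or 2 resolved axes")
    anchor_labels = [l for l in labels if l not in resolved_labels]
    missing = [l for l in anchor_labels if l not in anchor_ppm]
    if missing or sorted(resolved_labels + anchor_labels) != sorted(labels):
        raise ValueError(
            f"anchor dims {anchor_labels} + resolved dims {resolved_labels} "
            f"must cover the data dims {labels}; missing anchor values: {missing}")

    res_axes = [data.axis(l) for l in resolved_labels]
    res_pos = [labels.index(l) for l in resolved_labels]
    anchor_pos = [labels.index(l) for l in anchor_labels]
    m = data.schedule.n_points

    # Collapse the anchor dimensions: w_t = d(t) * exp(-i 2 pi nu_a t_a).
    fac = data.schedule.factor
    if fac is not None and set(anchor_pos) == set(range(len(fac[0]))):
        head_shape, tail_idx = fac
        vec = None
        for d, l in enumerate(labels[: len(head_shape)]):
            ax = data.axis(l)
            nu = ax.ppm_to_hz(anchor_ppm[l])
            v = np.exp(-1j * 2 * np.pi * nu * np.arange(ax.size) / ax.sw_hz)
            vec = v if vec is None else np.multiply.outer(vec, v)
        w = vec.ravel() @ data.values.reshape(len(vec.ravel()), len(tail_idx))
        res_idx = tail_idx[:, [labels.index(l) - len(head_shape) for l in resolved_labels]]
    else:
        idx = data.schedule.indices
        w = data.values.copy()
        for pos in anchor_pos:
            ax = data.axes[pos]
            nu = ax.ppm_to_hz(anchor_ppm[ax.label])
            v = np.exp(-1j * 2 * np.pi * nu * np.arange(ax.size) / ax.sw_hz)
            w = w * v[idx[:, pos]]
        res_idx = idx[:, res_pos]

    # Scatter onto the dense resolved grid (unique coordinates may collide
    # once anchor dims are collapsed; accumulation is the correct semantics).
    dense = np.zeros(tuple(a.size for a in res_axes), dtype=complex)
    np.add.at(dense, tuple(res_idx[:, d] for d in range(len(res_axes))), w)

    grids = [_freq_grid(a, oversample) for a in res_axes]
    mats = []
    for a, (hz, _) in zip(res_axes, grids):
        n = np.arange(a.size)
        mats.append(np.exp(-1j * 2 * np.pi * np.outer(hz, n) / a.sw_hz))
    if len(res_axes) == 1:
        spec = mats[0] @ dense
    else:
        spec = mats[0] @ dense @ mats[1].T
    return CrossSection(anchor_label=anchor_label, axes=res_axes,
                        freq_ppm=[g[1] for g in grids],
                        grid=np.abs(spec) / m, m_points=m)


def sampling_noise_level(section: CrossSection,
                         exclude_ppm: list[tuple[float, ...]] | None = None,
                         exclusion_radius_steps: int = 6,
                         n_positions: int = 100,
                         seed: int = 0) -> float:
    """Median magnitude at random off-peak positions: the sampling-noise floor.

    ``exclude_ppm`` lists known peak positions (one ppm tuple per resolved
    axis); grid cells within ``exclusion_radius_steps`` (about three
    linewidths at the default decay and oversampling) of any of them are
    excluded.  Without an exclusion list the floor is the median over random
    cells of the whole section, which is robust as long as peaks are sparse.
    """
    if n_positions < 10:
        raise ValueError("n_positions must be >= 10")
    rng = np.random.default_rng(seed)
    flat = section.grid.ravel()
    allowed = np.ones(flat.size, dtype=bool)
    if exclude_ppm:
        coords = np.stack(np.unravel_index(np.arange(flat.size), section.grid.shape), axis=1)
        for pos in exclude_ppm:
            steps = []
            for d, ppm in enumerate(pos):
                col = int(np.argmin(np.abs(section.freq_ppm[d] - ppm)))
                steps.append(np.abs(coords[:, d] - col))
            allowed &= np.maximum.reduce(steps) > exclusion_radius_steps
        if not allowed.any():
            raise ValueError("exclusion zones cover the whole section")
    pool = np.flatnonzero(allowed)
    take = rng.choice(pool, size=min(n_positions, len(pool)), replace=False)
    return float(np.median(flat[take]))


def _parabolic_offset(left: float, center: float, right: float) -> float:
    denom = left - 2.0 * center + right
    if denom >= 0:  # not a local max in continuous sense; keep the grid cell
        return 0.0
    off = 0.5 * (left - right) / denom
    return float(np.clip(off, -0.5, 0.5))


def pick_peaks(section: CrossSection, noise_level: float, threshold: float = 5.0,
               min_separation: int = 2) -> list[tuple[tuple[float, ...], float]]:
    """Local maxima above ``threshold`` x ``noise_level``, greedily accepted.

    Maxima are visited in height order; each accepted pick excludes further
    picks within ``min_separation`` grid steps (Chebyshev distance).  Positions
    are refined per axis by 3-point parabolic interpolation and returned in
    ppm, with the grid magnitude as height.  An empty list is a valid result.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    grid = section.grid
    cut = threshold * noise_level
    local_max = grid == maximum_filter(grid, size=3, mode="nearest")
    cand = np.argwhere(local_max & (grid > cut))
    if len(cand) == 0:
        return []
    order = np.argsort(-grid[tuple(cand.T)])
    cand = cand[order]
    accepted: list[np.ndarray] = []
    picks: list[tuple[tuple[float, ...], float]] = []
    for cell in cand:
        if any(np.max(np.abs(cell - a)) <= min_separation for a in accepted):
            continue
        accepted.append(cell)
        pos = []
        for d in range(grid.ndim):
            c = cell.copy()
            center = grid[tuple(c)]
            if 0 < cell[d] < grid.shape[d] - 1:
                c[d] = cell[d] - 1
                left = grid[tuple(c)]
                c[d] = cell[d] + 1
                right = grid[tuple(c)]
                off = _parabolic_offset(left, center, right)
            else:
                off = 0.0
            ppm_axis = section.freq_ppm[d]
            step = ppm_axis[1] - ppm_axis[0] if len(ppm_axis) > 1 else 0.0
            pos.append(float(ppm_axis[cell[d]] + off * step))
        picks.append((tuple(pos), float(grid[tuple(cell)])))
    return picks
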