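"""SMFT cross-sections: dense-FFT oracle, noise floor, peak picking."""

import numpy as np
import pytest

from conconnmr.nussim import AxisDef, SamplingSchedule, make_schedule, synthesize
from conconnmr.peaks import EXPERIMENTS, PeakEntry, PeakList
from conconnmr.smft import AnchorPeak, cross_section, pick_peaks, sampling_noise_level


def axes3d(n_anchor=8, n_res=16):
    return [AxisDef("COanc", 1200.0, n_anchor, 150.0, 176.0),
            AxisDef("COres", 1000.0, n_res, 150.0, 176.0),
            AxisDef("Nres", 800.0, n_res, 60.0, 121.0)]


def build_peaks(axes, entries, anchor_ppm=None):
    spec = EXPERIMENTS["HACACONCOCONH_5D"]
    out = []
    for pos, amp in entries:
        positions = {"HN": 8.3, "Nanc": 120.0, "COanc": anchor_ppm if anchor_ppm
                     is not None else 176.0}
        positions.update(pos)
        out.append(PeakEntry(positions, amp, 2, 2, "diagonal"))
    return PeakList(spec, out)


def grid_ppm(axis, k):
    """ppm of Nyquist-grid frequency cell k (fftshift convention)."""
    return axis.hz_to_ppm((k - axis.size // 2) * axis.sw_hz / axis.size)


class TestDenseFftOracle:
    def test_fully_sampled_plane_matches_fft(self):
        """On a fully sampled 3D grid, the cross-section at an on-grid anchor
        equals the matching plane of the dense FFT up to global scale."""
        axes = axes3d()
        anchor_row = 5
        anchor_ppm = grid_ppm(axes[0], anchor_row)
        rng = np.random.default_rng(0)
        entries = []
        for _ in range(5):
            entries.append(({"COres": float(rng.uniform(173.5, 178.5)),
                             "Nres": float(rng.uniform(116.0, 126.0))},
                            float(rng.uniform(0.3, 1.0))))
        pl = build_peaks(axes, entries, anchor_ppm=anchor_ppm)
        sched = make_schedule(axes, 8 * 16 * 16, seed=0)
        data = synthesize(pl, sched, axes)

        sec = cross_section(data, {"COanc": anchor_ppm}, ["COres", "Nres"], oversample=1)

        dense = np.zeros((8, 16, 16), dtype=complex)
        dense[tuple(sched.indices.T)] = data.values
        fft = np.fft.fftshift(np.abs(np.fft.fftn(dense)))
        plane = fft[anchor_row]
        scale = plane.max() / sec.grid.max()
        assert np.max(np.abs(sec.grid * scale - plane)) <= 1e-9 * plane.max()

    def test_single_tone_maximum_at_peak_cell(self):
        axes = axes3d()
        pl = build_peaks(axes, [({"COres": 175.2, "Nres": 122.4}, 1.0)])
        sched = make_schedule(axes, 8 * 16 * 16, seed=0)
        data = synthesize(pl, sched, axes)
        sec = cross_section(data, {"COanc": 176.0}, ["COres", "Nres"], oversample=2)
        i, j = np.unravel_index(np.argmax(sec.grid), sec.grid.shape)
        assert abs(sec.freq_ppm[0][i] - 175.2) <= axes[1].sw_hz / 16 / 150.0
        assert abs(sec.freq_ppm[1][j] - 122.4) <= axes[2].sw_hz / 16 / 60.0

    def test_empty_schedule_rejected(self):
        from conconnmr.nussim import TimeDomainSet

        axes = axes3d()
        empty_sched = SamplingSchedule(shape=tuple(a.size for a in axes),
                                       explicit=np.empty((0, 3), dtype=np.int64))
        data = TimeDomainSet(values=np.empty(0, dtype=complex),
                             schedule=empty_sched, axes=axes)
        with pytest.raises(ValueError, match="empty"):
            cross_section(data, {"COanc": 176.0}, ["COres", "Nres"])

    def test_dimension_mismatch_rejected(self):
        axes = axes3d()
        pl = build_peaks(axes, [({"COres": 175.2, "Nres": 122.4}, 1.0)])
        data = synthesize(pl, make_schedule(axes, 64, seed=0), axes)
        with pytest.raises(ValueError, match="anchor"):
            cross_section(data, {}, ["COres", "Nres"])


class TestInvariants:
    def test_energy_scales_with_sampled_points(self):
        """Parseval on the zero-augmented transform: unnormalized section
        energy grows linearly with the number of sampled points."""
        axes = axes3d()[1:]  # 2D data: no anchor collapse
        pl = build_peaks(axes, [({"COres": 175.3, "Nres": 122.1}, 1.0),
                                ({"COres": 176.8, "Nres": 118.7}, 0.6)])
        ratios = []
        for seed in range(20):
            energies = []
            for m in (80, 160):
                data = synthesize(pl, make_schedule(axes, m, seed=seed), axes)
                sec = cross_section(data, {}, ["COres", "Nres"], oversample=1)
                energies.append(np.sum((sec.grid * sec.m_points) ** 2))
            ratios.append(energies[1] / energies[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_shift_theorem(self):
        """Translating every peak translates the picked positions."""
        axes = axes3d()
        delta_co, delta_n = 0.8, 2.0
        base = [({"COres": 175.0, "Nres": 120.0}, 1.0)]
        moved = [({"COres": 175.0 + delta_co, "Nres": 120.0 + delta_n}, 1.0)]
        sched = make_schedule(axes, 8 * 16 * 16, seed=0)
        picks = []
        for entries in (base, moved):
            data = synthesize(build_peaks(axes, entries), sched, axes)
            sec = cross_section(data, {"COanc": 176.0}, ["COres", "Nres"])
            floor = sampling_noise_level(sec, n_positions=50, seed=0)
            picks.append(pick_peaks(sec, max(floor, 1e-9), threshold=5)[0][0])
        step_co = axes[1].sw_hz / 32 / 150.0
        step_n = axes[2].sw_hz / 32 / 60.0
        assert picks[1][0] - picks[0][0] == pytest.approx(delta_co, abs=step_co)
        assert picks[1][1] - picks[0][1] == pytest.approx(delta_n, abs=step_n)


class TestNoiseLevel:
    def test_fully_sampled_on_grid_tone_has_tiny_floor(self):
        axes = axes3d()
        pl = build_peaks(axes, [({"COres": grid_ppm(axes[1], 11),
                                  "Nres": grid_ppm(axes[2], 5)}, 1.0)],
                         anchor_ppm=grid_ppm(axes[0], 3))
        sched = make_schedule(axes, 8 * 16 * 16, seed=0)
        data = synthesize(pl, sched, axes,
                          decay={"COanc": 0.0, "COres": 0.0, "Nres": 0.0})
        sec = cross_section(data, {"COanc": grid_ppm(axes[0], 3)},
                            ["COres", "Nres"], oversample=1)
        level = sampling_noise_level(
            sec, exclude_ppm=[(grid_ppm(axes[1], 11), grid_ppm(axes[2], 5))],
            exclusion_radius_steps=1, n_positions=100, seed=1)
        assert level < 1e-6 * sec.max

    def test_subsampling_raises_the_floor(self):
        axes = axes3d()
        peak = ({"COres": grid_ppm(axes[1], 11), "Nres": grid_ppm(axes[2], 5)}, 1.0)
        pl = build_peaks(axes, [peak], anchor_ppm=grid_ppm(axes[0], 3))
        levels = []
        for m in (8 * 16 * 16, 8 * 16 * 16 // 4):
            data = synthesize(pl, make_schedule(axes, m, seed=2), axes,
                              decay={"COanc": 0.0, "COres": 0.0, "Nres": 0.0})
            sec = cross_section(data, {"COanc": grid_ppm(axes[0], 3)},
                                ["COres", "Nres"], oversample=1)
            levels.append(sampling_noise_level(
                sec, exclude_ppm=[(peak[0]["COres"], peak[0]["Nres"])],
                exclusion_radius_steps=1, n_positions=100, seed=1))
        assert levels[1] > levels[0]

    def test_pure_noise_floor_tracks_inverse_sqrt_m(self):
        """Monte-Carlo over 50 seeds: median magnitude of a pure-noise section
        is within a factor 3 of 1/sqrt(M) for unit noise."""
        axes = axes3d(n_anchor=4, n_res=8)[1:]  # 2D, 8x8 grid
        spec = EXPERIMENTS["HACACONCOCONH_5D"]
        m = 48
        levels = []
        for seed in range(50):
            empty = PeakList(spec, [])
            data = synthesize(empty, make_schedule(axes, m, seed=seed), axes,
                              noise_sigma=1.0, seed=seed)
            sec = cross_section(data, {}, ["COres", "Nres"], oversample=1)
            levels.append(sampling_noise_level(sec, n_positions=30, seed=seed))
        mean_level = np.mean(levels)
        assert 1 / np.sqrt(m) / 3 < mean_level < 3 / np.sqrt(m)


class TestPickPeaks:
    def make_section(self, entries, m=None, seed=0, oversample=1, no_decay=True):
        axes = axes3d(n_anchor=4)
        pl = build_peaks(axes, entries)
        m = m or 4 * 16 * 16
        decay = {a.label: 0.0 for a in axes} if no_decay else None
        data = synthesize(pl, make_schedule(axes, m, seed=seed), axes, decay=decay)
        return cross_section(data, {"COanc": 176.0}, ["COres", "Nres"],
                             oversample=oversample)

    def test_single_on_grid_peak_single_pick(self):
        axes = axes3d(n_anchor=4)
        target = (grid_ppm(axes[1], 11), grid_ppm(axes[2], 5))
        sec = self.make_section([({"COres": target[0], "Nres": target[1]}, 1.0)])
        picks = pick_peaks(sec, 1e-9, threshold=5)
        assert len(picks) == 1
        assert picks[0][0][0] == pytest.approx(target[0], abs=1e-6)
        assert picks[0][0][1] == pytest.approx(target[1], abs=1e-6)

    def test_two_separated_peaks_ordered_by_height(self):
        axes = axes3d(n_anchor=4)
        strong = (grid_ppm(axes[1], 12), grid_ppm(axes[2], 12))
        weak = (grid_ppm(axes[1], 4), grid_ppm(axes[2], 4))
        sec = self.make_section([({"COres": weak[0], "Nres": weak[1]}, 0.5),
                                 ({"COres": strong[0], "Nres": strong[1]}, 1.0)])
        picks = pick_peaks(sec, 1e-9, threshold=5)
        assert len(picks) == 2
        assert picks[0][1] > picks[1][1]
        assert picks[0][0][0] == pytest.approx(strong[0], abs=1e-6)

    def test_three_peaks_recovered_from_30_percent_sampling(self):
        axes = [AxisDef("COres", 1000.0, 64, 150.0, 176.0),
                AxisDef("Nres", 800.0, 64, 60.0, 121.0)]
        entries = [({"COres": 174.5, "Nres": 118.0}, 0.6),
                   ({"COres": 176.9, "Nres": 124.5}, 0.8),
                   ({"COres": 175.8, "Nres": 121.3}, 1.0)]
        pl = build_peaks(axes, entries)
        m = int(0.30 * 64 * 64)
        data = synthesize(pl, make_schedule(axes, m, seed=3), axes)
        sec = cross_section(data, {}, ["COres", "Nres"])
        floor = sampling_noise_level(sec, n_positions=100, seed=0)
        picks = pick_peaks(sec, floor, threshold=5)
        step_co = 1000.0 / 64 / 150.0
        step_n = 800.0 / 64 / 60.0
        assert len(picks) >= 3
        for e in entries:
            target = (e[0]["COres"], e[0]["Nres"])
            assert any(abs(p[0][0] - target[0]) <= step_co and
                       abs(p[0][1] - target[1]) <= step_n for p in picks)

    def test_threshold_must_exceed_one(self):
        sec = self.make_section([({"COres": 175.2, "Nres": 122.4}, 1.0)])
        with pytest.raises(ValueError):
            pick_peaks(sec, 0.1, threshold=0.5)
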