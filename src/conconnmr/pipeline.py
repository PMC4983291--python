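"""End-to-end synthetic pipeline: shifts -> peaks -> NUS data -> SMFT -> links.

The stages mirror a real acquisition-and-analysis round:

1. ground-truth shifts for the sequence (shiftgen);
2. expected peak content of the chosen experiment (peaks), with amplitudes
   from the mixing model at the configured field;
3. a NUS schedule on the resolved CO/N Nyquist grid and time-domain synthesis
   over anchor (N, CO) plus resolved dimensions (nussim);
4. one SMFT cross-section per HNCO anchor, thresholded peak picking (smft);
5. link assembly, proline bridging and chain building, scored against the
   ground truth in the Table row format (assign).

Everything is deterministic given the run seed: per-stage random streams are
spawned from it.  Axis defaults place the carbonyl and amide-nitrogen windows
generously around the random-coil ranges (prolines included) so that no
synthetic peak can fall outside a spectral window.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import assign, nussim, peaks as peaks_mod, shiftgen, smft
from .mixing import MixingModel
from .nussim import AxisDef, SamplingSchedule
from .smft import AnchorPeak

__all__ = ["RunConfig", "RunReport", "default_axes", "run_pipeline",
           "simulate_strips"]

# gyromagnetic ratios relative to 1H
_GAMMA = {"N": 0.101329118, "C": 0.251449530}


def default_axes(field_mhz: float, resolved_size: int = 64,
                 anchor_n_size: int = 64, anchor_co_size: int = 256) -> list[AxisDef]:
    """Axis definitions (anchor N, anchor CO, resolved CO, resolved N).

    Windows are matched to the coil shift ranges, as an experimentalist would
    set them: 13C' 10 ppm around 176 ppm, 15N 40 ppm around 121 ppm (wide
    enough for prolines near 137 ppm).  Grid sizes set the maximum evolution
    times via t_max = size / sw; the anchor dimensions default to finer grids
    than the resolved ones because they are conventionally sampled (resolving
    them costs no NUS points) and anchor separation is what keeps strips from
    bleeding into one another.
    """
    obs_n = field_mhz * _GAMMA["N"]
    obs_c = field_mhz * _GAMMA["C"]
    sw_n = 40.0 * obs_n
    sw_co = 10.0 * obs_c
    return [
        AxisDef("Nanc", sw_n, anchor_n_size, obs_n, 121.0),
        AxisDef("COanc", sw_co, anchor_co_size, obs_c, 176.0),
        AxisDef("COres", sw_co, resolved_size, obs_c, 176.0),
        AxisDef("Nres", sw_n, resolved_size, obs_n, 121.0),
    ]


@dataclass
class RunConfig:
    """Configuration of one synthetic run (YAML-serializable)."""

    sequence: str = ""
    fasta: str = ""                      # alternative sequence source
    seed: int = 0
    experiment: str = "HACACONCOCONH_5D"
    field_mhz: float = 600.0
    dispersion_scale: float = 1.0
    # mixing
    mixing_J_hz: float = 1.0
    mixing_t_mix_ms: float = 250.0
    mixing_R600_per_s: float = MixingModel().r600_per_s
    # sampling / grids
    n_points: int = 1100
    resolved_size: int = 64
    anchor_n_size: int = 64
    anchor_co_size: int = 256
    oversample: int = 2
    snr: float = 0.0                     # peak signal-to-noise; 0 = noiseless
    # analysis
    pick_threshold: float = 5.0
    min_separation: int = 2
    tol_co_ppm: float = 0.05
    tol_n_ppm: float = 0.2
    amplitude_floor: float = 0.01
    exchange_attenuation: dict = dc_field(default_factory=dict)
    outdir: str = ""
    write_timedomain: bool = False       # the FID table is large; opt in

    def resolved_sequence(self) -> str:
        if self.sequence:
            return self.sequence.upper()
        if self.fasta:
            return shiftgen.read_fasta(self.fasta)
        raise ValueError("config must provide a sequence or a FASTA path")

    def mixing_model(self) -> MixingModel:
        return MixingModel(J_hz=self.mixing_J_hz, t_mix_ms=self.mixing_t_mix_ms,
                           r600_per_s=self.mixing_R600_per_s, b0_mhz=self.field_mhz)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.experiment not in peaks_mod.EXPERIMENTS:
            raise ValueError(f"unsupported experiment {cfg.experiment!r}")
        if cfg.fasta and not Path(cfg.fasta).exists():
            raise ValueError(f"FASTA file not found: {cfg.fasta}")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunReport:
    """All stage outputs of one pipeline run."""

    config: RunConfig
    shifts: shiftgen.ShiftTable
    hnco: peaks_mod.PeakList
    peaklist: peaks_mod.PeakList
    schedule: SamplingSchedule
    strips: list[assign.Strip]
    graph: assign.LinkGraph
    chains: list[list[str]]
    stats: assign.LinkStats
    counts: dict[str, int]
    timings: dict[str, float]

    def log_lines(self, include_timings: bool = True) -> list[str]:
        lines = [f"stage counts: {self.counts}"]
        if include_timings:
            lines += ["stage seconds: " + ", ".join(f"{k}={v:.2f}"
                                                    for k, v in self.timings.items())]
        lines += [f"Backwards links {self.stats.backward_row}",
                  f"Forward links {self.stats.forward_row}"]
        return lines


def _expected_peak_height(amp: float, axes: list[AxisDef], schedule: SamplingSchedule,
                          decay: dict[str, float]) -> float:
    """Spectral height of a peak evaluated at its own exact frequencies.

    Frequency factors cancel exactly at the matching coordinates, so only the
    decay envelope averaged over the scheduled points survives.
    """
    head_shape, tail_idx = schedule.factor
    h = amp
    for d, ax in enumerate(axes[: len(head_shape)]):
        n = np.arange(ax.size)
        h *= float(np.mean(np.exp(-decay[ax.label] * n / ax.sw_hz)))
    tail = np.ones(len(tail_idx))
    for d, ax in enumerate(axes[len(head_shape):]):
        tail = tail * np.exp(-decay[ax.label] * tail_idx[:, d] / ax.sw_hz)
    return h * float(np.mean(tail))


def simulate_strips(cfg: RunConfig, shifts: shiftgen.ShiftTable,
                    peaklist: peaks_mod.PeakList):
    """Synthesize NUS data for ``peaklist`` and pick every anchor strip.

    Returns (strips, schedule, data, noise_floors).  Works for the 2D-resolved
    5D experiments and for each 1D-resolved 4D experiment (whose picks carry
    only one coordinate and are combined later).
    """
    resolved = list(peaklist.experiment.resolved)
    axes_all = default_axes(cfg.field_mhz, cfg.resolved_size,
                            cfg.anchor_n_size, cfg.anchor_co_size)
    axes = [a for a in axes_all if a.label in ("Nanc", "COanc") or a.label in resolved]
    anchor_axes = axes[:2]
    res_axes = axes[2:]

    seeds = np.random.SeedSequence(cfg.seed).generate_state(4)
    res_shape = tuple(a.size for a in res_axes)
    total = int(np.prod(res_shape))
    if len(res_axes) == 1:
        # Single resolved dimension (4D "1+3" runs): the grid is small enough
        # to sample conventionally, so the point budget is capped at full.
        n_points = min(cfg.n_points, total)
    else:
        n_points = cfg.n_points
        if n_points > total:
            raise ValueError(
                f"schedule stage: n_points={n_points} exceeds the resolved grid "
                f"({'x'.join(str(s) for s in res_shape)} = {total} points)")
    nus = nussim.make_schedule(res_axes, n_points, int(seeds[0]) % (2**31))
    schedule = SamplingSchedule.product(tuple(a.size for a in anchor_axes), nus)

    decay = {a.label: a.default_decay for a in axes}
    sigma = 0.0
    if cfg.snr > 0:
        hmax = max(_expected_peak_height(p.amplitude, axes, schedule, decay)
                   for p in peaklist)
        sigma = (hmax / cfg.snr) * np.sqrt(schedule.n_points)
    data = nussim.synthesize(peaklist, schedule, axes, decay=decay,
                             noise_sigma=sigma, seed=int(seeds[1]) % (2**31))

    anchors = [AnchorPeak(label=shifts.label(k), hn_ppm=shifts.shift(k, "HN"),
                          n_ppm=shifts.shift(k, "N"), co_ppm=shifts.shift(k - 1, "CO"),
                          truth_residue=k)
               for k in shifts.anchor_residues()]

    strips, floors = [], {}
    for j, anc in enumerate(anchors):
        section = smft.cross_section(data, anc, resolved, oversample=cfg.oversample)
        floor = smft.sampling_noise_level(section, n_positions=200,
                                          seed=(int(seeds[2]) + j) % (2**31))
        floor = max(floor, 1e-12 * max(section.max, 1.0))
        picks2d = smft.pick_peaks(section, floor, threshold=cfg.pick_threshold,
                                  min_separation=cfg.min_separation)
        floors[anc.label] = floor
        if resolved == ["COres", "Nres"]:
            picks = [assign.Pick(pos[0], pos[1], h) for pos, h in picks2d]
        else:
            picks = [(pos[0], h) for pos, h in picks2d]  # 1D picks, combined later
        strips.append((anc, picks))

    return strips, schedule, data, floors


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage in order; deterministic given cfg.seed."""
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def clock(name):
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    clock("shifts")
    sequence = cfg.resolved_sequence()
    shifts = shiftgen.generate_shifts(sequence, cfg.seed, cfg.dispersion_scale)
    done("shifts")

    clock("peaks")
    model = cfg.mixing_model()
    atten = {int(k): float(v) for k, v in (cfg.exchange_attenuation or {}).items()}
    hnco = peaks_mod.enumerate_peaks("HNCO_3D", shifts)
    is_4d_pair = cfg.experiment.startswith("HACACO_")
    if is_4d_pair:
        lists = [peaks_mod.enumerate_peaks(name, shifts, model, atten, cfg.amplitude_floor)
                 for name in ("HACACO_NCO_CONH_4D_CO", "HACACO_N_CO_CONH_4D_N")]
        peaklist = lists[0]
    else:
        peaklist = peaks_mod.enumerate_peaks(cfg.experiment, shifts, model, atten,
                                             cfg.amplitude_floor)
        lists = [peaklist]
    counts["peaks"] = sum(len(pl) for pl in lists)
    done("peaks")

    clock("reconstruct")
    if is_4d_pair:
        strips_co, schedule, data, floors = simulate_strips(cfg, shifts, lists[0])
        strips_n, _, _, _ = simulate_strips(cfg, shifts, lists[1])
        strips = []
        for (anc, co_picks), (_, n_picks) in zip(strips_co, strips_n):
            picks = assign.pair_complementary_picks(co_picks, n_picks)
            strips.append(assign.Strip(anchor=anc, picks=picks))
    else:
        raw, schedule, data, floors = simulate_strips(cfg, shifts, peaklist)
        strips = [assign.Strip(anchor=anc, picks=p) for anc, p in raw]
    counts["points_sampled"] = schedule.n_points
    counts["sections"] = len(strips)
    counts["picks"] = sum(len(s.picks) for s in strips)
    done("reconstruct")

    clock("link")
    graph = assign.build_links(strips, cfg.tol_co_ppm, cfg.tol_n_ppm)
    chains = assign.assemble_chains(graph)
    score_exp = ("HACACONCOCONH_5D" if is_4d_pair else cfg.experiment)
    stats = assign.score_links(graph, shifts, score_exp, cfg.tol_co_ppm, cfg.tol_n_ppm)
    counts["links"] = len(graph.edges)
    counts["ambiguities"] = len(graph.ambiguities)
    counts["chains"] = len(chains)
    done("link")

    report = RunReport(config=cfg, shifts=shifts, hnco=hnco, peaklist=peaklist,
                       schedule=schedule, strips=strips, graph=graph, chains=chains,
                       stats=stats, counts=counts, timings=timings)
    if outdir:
        _write_artifacts(report, lists, data, outdir)
    return report


def _write_artifacts(report: RunReport, lists, data, outdir: Path) -> None:
    cfg = report.config
    shiftgen.save_shifts(report.shifts, outdir / "shifts.tsv")
    report.hnco.write_tsv(outdir / "hnco_peaks.tsv")
    peaks_mod.write_sparky(report.hnco, outdir / "hnco_peaks.list", report.shifts)
    for pl in lists:
        pl.write_tsv(outdir / f"{pl.experiment.name}_peaks.tsv")
        peaks_mod.write_sparky(pl, outdir / f"{pl.experiment.name}_peaks.list",
                               report.shifts)
    head_shape, tail = report.schedule.factor
    nus = SamplingSchedule(shape=report.schedule.shape[len(head_shape):],
                           explicit=tail, mode="uniform")
    nussim.write_schedule(nus, outdir / "schedule.txt")
    if cfg.write_timedomain:
        nussim.write_timedomain(data, outdir / "timedomain.tsv")
    with open(outdir / "picks.tsv", "w") as fh:
        fh.write("strip\tCO_ppm\tN_ppm\theight\n")
        for s in report.strips:
            for p in s.picks:
                fh.write(f"{s.label}\t{p.co_ppm:.4f}\t{p.n_ppm:.4f}\t{p.height:.6e}\n")
    _write_assignment_map(report, outdir / "assignment_map.tsv")
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(report.log_lines(include_timings=False)) + "\n")


def _write_assignment_map(report: RunReport, path) -> None:
    """Residue -> (CO, N, HN) map with the bookkeeping category per residue.

    Categories: pair (CON pair assigned), only_CO, only_N, none.
    """
    truth = report.shifts
    graph = report.graph
    tol_co, tol_n = report.config.tol_co_ppm, report.config.tol_n_ppm
    with open(path, "w") as fh:
        fh.write("index\taa\tcategory\tCO_prev\tN\tHN\n")
        for i in range(1, len(truth) + 1):
            co_prev = truth.shift(i - 1, "CO") if i >= 2 else float("nan")
            have_pair = False
            for n in graph.nodes.values():
                if i >= 2 and assign._distance(n.co_ppm, n.n_ppm, co_prev,
                                               truth.shift(i, "N"),
                                               tol_co, tol_n) <= 1.0:
                    have_pair = True
                    break
            cat = "pair" if have_pair else "none"
            hn = truth.shift(i, "HN") if truth.has_hn(i) else float("nan")
            fh.write(f"{i}\t{truth.row(i)['aa']}\t{cat}\t{co_prev:.3f}\t"
                     f"{truth.shift(i, 'N'):.3f}\t{hn:.3f}\n")
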