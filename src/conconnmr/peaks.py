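"""Expected peak content of the HNCO-anchored CON-CON experiments.

Every supported experiment detects on the amide proton of an anchor residue k
(k >= 2, amide proton present) and carries the HNCO anchor coordinates
(HN_k, N_k, CO_{k-1}).  The higher-dimensional experiments add resolved
dimensions holding a sequential CON pair (CO_{i-1}, N_i) reached from the
anchor by CO-CO mixing, with i = k-1 (backward), k (diagonal) or k+1
(forward):

* (H)NCOCONH starts on the amide proton of the pair residue i, so pairs whose
  residue i is a proline are never observed and amide-exchange attenuation
  applies to the start residue;
* (HACA)CON(CO)CONH starts on HA/CA of residue i-1, which always exists, so
  proline pairs ARE observed and no exchange factor applies -- this is the
  experiment that bridges prolines;
* the two complementary "1+3" 4D experiments are the HACA experiment with the
  resolved pair reduced to its CO (or N) coordinate only.

Peak amplitudes are the chain-transfer fractions of the mixing model times the
start attenuation.  Dimension labels: HN, Nanc, COanc (anchor), COres, Nres
(resolved).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .mixing import MixingModel, chain_transfer
from .shiftgen import ShiftTable

__all__ = ["ExperimentSpec", "PeakEntry", "PeakList", "EXPERIMENTS",
           "enumerate_peaks", "eligible_pairs", "project_to_4d",
           "write_sparky", "read_sparky"]

ANCHOR_DIMS = ("HN", "Nanc", "COanc")


@dataclass(frozen=True)
class ExperimentSpec:
    """Static description of one supported experiment."""

    name: str
    start: str                      # "HN" (amide of pair residue) or "HACA"
    resolved: tuple[str, ...]       # subset of ("COres", "Nres")

    @property
    def dims(self) -> tuple[str, ...]:
        return ANCHOR_DIMS + self.resolved

    @property
    def dimensionality(self) -> int:
        return len(self.dims)

    @property
    def requires_hn_on_start(self) -> bool:
        return self.start == "HN"


EXPERIMENTS: dict[str, ExperimentSpec] = {
    "HNCO_3D": ExperimentSpec("HNCO_3D", start="HN", resolved=()),
    "HNCOCONH_5D": ExperimentSpec("HNCOCONH_5D", start="HN", resolved=("COres", "Nres")),
    "HACACONCOCONH_5D": ExperimentSpec("HACACONCOCONH_5D", start="HACA",
                                       resolved=("COres", "Nres")),
    "HACACO_NCO_CONH_4D_CO": ExperimentSpec("HACACO_NCO_CONH_4D_CO", start="HACA",
                                            resolved=("COres",)),
    "HACACO_N_CO_CONH_4D_N": ExperimentSpec("HACACO_N_CO_CONH_4D_N", start="HACA",
                                            resolved=("Nres",)),
}

_KINDS = {-1: "backward", 0: "diagonal", 1: "forward"}


@dataclass(frozen=True)
class PeakEntry:
    """One spectral peak with its provenance.

    positions  ppm per dimension label of the experiment
    amplitude  dimensionless, >= 0
    anchor_res residue k carrying the detection anchor
    pair_res   residue i of the CON pair (CO_{i-1}, N_i); 0 for pure HNCO peaks
    kind       diagonal / forward / backward / hnco
    """

    positions: dict[str, float]
    amplitude: float
    anchor_res: int
    pair_res: int
    kind: str

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def assignment(self, shifts: ShiftTable | None = None) -> str:
        def lab(i: int) -> str:
            return shifts.label(i) if shifts is not None else f"X{i}"

        if self.kind == "hnco":
            return f"{lab(self.anchor_res)}HN-N-{lab(self.anchor_res - 1)}CO"
        return (f"{lab(self.pair_res - 1)}CO-{lab(self.pair_res)}N"
                f"-anchor{lab(self.anchor_res)}")


def _spec(experiment: str | ExperimentSpec) -> ExperimentSpec:
    if isinstance(experiment, ExperimentSpec):
        return experiment
    try:
        return EXPERIMENTS[experiment]
    except KeyError:
        raise ValueError(
            f"unsupported experiment {experiment!r}; supported: {sorted(EXPERIMENTS)}"
        ) from None


@dataclass
class PeakList:
    """Peaks of one experiment, with lossless TSV round-trip."""

    experiment: ExperimentSpec
    entries: list[PeakEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def max_amplitude(self) -> float:
        return max((p.amplitude for p in self.entries), default=0.0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.entries:
            row = {"anchor_res": p.anchor_res, "pair_res": p.pair_res,
                   "kind": p.kind, "amplitude": p.amplitude}
            row.update({d: p.positions[d] for d in self.experiment.dims})
            rows.append(row)
        cols = ["anchor_res", "pair_res", "kind", "amplitude", *self.experiment.dims]
        return pd.DataFrame(rows, columns=cols)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read_tsv(cls, path, experiment: str | ExperimentSpec) -> "PeakList":
        spec = _spec(experiment)
        df = pd.read_csv(path, sep="\t")
        entries = [
            PeakEntry(
                positions={d: float(r[d]) for d in spec.dims},
                amplitude=float(r["amplitude"]),
                anchor_res=int(r["anchor_res"]),
                pair_res=int(r["pair_res"]),
                kind=str(r["kind"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(spec, entries)


def enumerate_peaks(experiment: str | ExperimentSpec,
                    shifts: ShiftTable,
                    model: MixingModel | None = None,
                    exchange_attenuation: dict[int, float] | None = None,
                    amplitude_floor: float = 0.01) -> PeakList:
    """Exact expected peak list of ``experiment`` for a ground-truth table.

    ``exchange_attenuation`` maps residue index -> factor in (0, 1] applied to
    amide-start peaks whose start residue is listed (defaults to 1 everywhere).
    Peaks weaker than ``amplitude_floor`` times the strongest peak are dropped.
    """
    spec = _spec(experiment)
    model = model or MixingModel()
    atten = exchange_attenuation or {}
    n = len(shifts)
    anchors = shifts.anchor_residues()

    entries: list[PeakEntry] = []
    if spec.name == "HNCO_3D":
        for k in anchors:
            entries.append(PeakEntry(
                positions={"HN": shifts.shift(k, "HN"), "Nanc": shifts.shift(k, "N"),
                           "COanc": shifts.shift(k - 1, "CO")},
                amplitude=1.0, anchor_res=k, pair_res=0, kind="hnco"))
        return PeakList(spec, entries)

    profile_cache: dict[int, dict[int, float]] = {}

    def transfer(src_res_co: int, dst_res_co: int) -> float:
        # CO chain position of residue r's carbonyl is r-1 (0-based).
        if src_res_co not in profile_cache:
            prof = chain_transfer(model, n, src_res_co - 1)
            profile_cache[src_res_co] = prof.fractions
        return profile_cache[src_res_co].get(dst_res_co - src_res_co, 0.0)

    for k in anchors:
        for i in (k - 1, k, k + 1):
            if not 2 <= i <= n:
                continue
            if spec.requires_hn_on_start:
                if not shifts.has_hn(i):
                    continue  # proline pair residues are invisible to the HN start
                start_factor = atten.get(i, 1.0)
            else:
                start_factor = 1.0  # HA/CA of residue i-1 always exists
            amp = transfer(i - 1, k - 1) * start_factor
            if amp <= 0.0:
                continue
            positions = {"HN": shifts.shift(k, "HN"), "Nanc": shifts.shift(k, "N"),
                         "COanc": shifts.shift(k - 1, "CO")}
            if "COres" in spec.resolved:
                positions["COres"] = shifts.shift(i - 1, "CO")
            if "Nres" in spec.resolved:
                positions["Nres"] = shifts.shift(i, "N")
            entries.append(PeakEntry(positions, amp, anchor_res=k, pair_res=i,
                                     kind=_KINDS[i - k]))

    floor = amplitude_floor * max((p.amplitude for p in entries), default=0.0)
    entries = [p for p in entries if p.amplitude >= floor]
    return PeakList(spec, entries)


def eligible_pairs(experiment: str | ExperimentSpec, sequence: str) -> list[tuple[int, int]]:
    """Sequential pairs (i-1, i) observable in principle by ``experiment``.

    A pair is eligible when the experiment can place it in some strip: an
    anchor must exist within the mixing window (k in {i-1, i, i+1} with an
    amide proton and k >= 2), and for the amide-start experiment the pair
    residue i itself must carry an amide proton.  The count is the denominator
    of the forward/backward link statistics.
    """
    spec = _spec(experiment)
    sequence = sequence.upper()
    n = len(sequence)

    def has_hn(r: int) -> bool:
        return 2 <= r <= n and sequence[r - 1] != "P"

    pairs = []
    for i in range(2, n + 1):
        if spec.requires_hn_on_start and sequence[i - 1] == "P":
            continue
        if not any(has_hn(k) for k in (i - 1, i, i + 1)):
            continue
        pairs.append((i - 1, i))
    return pairs


def project_to_4d(peaks_5d: PeakList, which: str) -> PeakList:
    """Project the HACA 5D peak list onto one of its complementary 4Ds.

    ``which`` is "CO" or "N".  Provenance and amplitudes are preserved; only
    the other resolved coordinate is dropped.
    """
    if peaks_5d.experiment.resolved != ("COres", "Nres"):
        raise ValueError("projection is defined for a 5D peak list")
    if which == "CO":
        spec, drop = EXPERIMENTS["HACACO_NCO_CONH_4D_CO"], "Nres"
    elif which == "N":
        spec, drop = EXPERIMENTS["HACACO_N_CO_CONH_4D_N"], "COres"
    else:
        raise ValueError("which must be 'CO' or 'N'")
    entries = [replace(p, positions={d: v for d, v in p.positions.items() if d != drop})
               for p in peaks_5d.entries]
    return PeakList(spec, entries)


# ---------------------------------------------------------------------------
# Sparky list dialect
# ---------------------------------------------------------------------------

def write_sparky(peaks: PeakList, path, shifts: ShiftTable | None = None) -> None:
    """Write peaks in the Sparky list dialect.

    The assignment string encodes provenance (pair and anchor residues); one
    w-column per dimension in the experiment's dimension order, plus a final
    height column.
    """
    dims = peaks.experiment.dims
    with open(path, "w") as fh:
        header = f"{'Assignment':>28s}" + "".join(f"{'w' + str(j + 1):>11s}"
                                                  for j in range(len(dims)))
        fh.write(header + f"{'Height':>13s}\n")
        for p in peaks.entries:
            line = f"{p.assignment(shifts):>28s}"
            line += "".join(f"{p.positions[d]:11.3f}" for d in dims)
            line += f"{p.amplitude:13.5f}"
            fh.write(line + "\n")


def read_sparky(path, experiment: str | ExperimentSpec) -> list[tuple[dict[str, float], float]]:
    """Read a Sparky list written by :func:`write_sparky`.

    Returns (positions, height) tuples; provenance is carried only by the
    assignment string, so use the TSV format when lossless round-trips matter.
    """
    spec = _spec(experiment)
    out = []
    with open(path) as fh:
        header = fh.readline()
        if "Assignment" not in header:
            raise ValueError(f"{path} line 1: not a Sparky list (missing Assignment header)")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 1 + len(spec.dims) + 1:
                raise ValueError(f"{path} line {ln}: expected {len(spec.dims)} w-columns")
            vals = [float(v) for v in parts[1:]]
            out.append((dict(zip(spec.dims, vals[:-1])), vals[-1]))
    return out
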