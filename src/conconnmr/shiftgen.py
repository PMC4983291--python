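"""Synthetic ground-truth chemical shifts with IDP-like statistics.

Disordered chains average out conformational contributions to chemical shifts,
so each nucleus sits near its residue-type random-coil value with a narrow
spread dominated by sequence-neighbour effects.  The generator draws every
shift from a Gaussian centred on a bundled random-coil mean for the residue
type, with a per-nucleus standard deviation scaled by ``dispersion_scale``.
Consequences that matter downstream:

* CO and N are the best-dispersed nuclei (the basis of the CON-CON strategy);
* repeated residue types produce near-degenerate (CO, N) anchor pairs -- the
  realistic overlap challenge;
* prolines have no amide proton but do have N, CO, CA, HA, and their amide
  nitrogen (~137 ppm) sits far above every other residue type, which is what
  makes proline gaps recognizable in the linking stage.

The random-coil means/SDs bundled here are literature-style configuration
data, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ShiftTable", "RANDOM_COIL_PPM", "NUCLEUS_SIGMA_PPM", "NUCLEUS_WINDOW_PPM",
           "generate_shifts", "load_shifts", "save_shifts", "read_fasta",
           "random_idp_sequence"]

NUCLEI = ("HN", "N", "CO", "CA", "HA")

#: Random-coil chemical shifts (ppm) per residue type: HN, N, CO, CA, HA.
RANDOM_COIL_PPM: dict[str, dict[str, float]] = {
    "A": {"HN": 8.24, "N": 123.8, "CO": 177.8, "CA": 52.5, "HA": 4.32},
    "R": {"HN": 8.23, "N": 120.5, "CO": 176.3, "CA": 56.0, "HA": 4.34},
    "N": {"HN": 8.40, "N": 118.7, "CO": 175.2, "CA": 53.1, "HA": 4.74},
    "D": {"HN": 8.34, "N": 120.4, "CO": 176.3, "CA": 54.2, "HA": 4.64},
    "C": {"HN": 8.32, "N": 118.8, "CO": 174.6, "CA": 58.2, "HA": 4.55},
    "Q": {"HN": 8.32, "N": 119.8, "CO": 176.0, "CA": 55.7, "HA": 4.34},
    "E": {"HN": 8.42, "N": 120.2, "CO": 176.6, "CA": 56.6, "HA": 4.35},
    "G": {"HN": 8.33, "N": 108.8, "CO": 174.9, "CA": 45.1, "HA": 3.96},
    "H": {"HN": 8.42, "N": 118.2, "CO": 174.1, "CA": 55.0, "HA": 4.73},
    "I": {"HN": 8.00, "N": 119.9, "CO": 176.4, "CA": 61.1, "HA": 4.17},
    "L": {"HN": 8.16, "N": 121.8, "CO": 177.6, "CA": 55.1, "HA": 4.34},
    "K": {"HN": 8.29, "N": 120.4, "CO": 176.6, "CA": 56.2, "HA": 4.32},
    "M": {"HN": 8.28, "N": 119.6, "CO": 176.3, "CA": 55.4, "HA": 4.48},
    "F": {"HN": 8.30, "N": 120.3, "CO": 175.8, "CA": 57.7, "HA": 4.62},
    "P": {"HN": float("nan"), "N": 136.8, "CO": 177.3, "CA": 63.3, "HA": 4.42},
    "S": {"HN": 8.31, "N": 115.7, "CO": 174.6, "CA": 58.3, "HA": 4.47},
    "T": {"HN": 8.15, "N": 113.6, "CO": 174.7, "CA": 61.8, "HA": 4.35},
    "W": {"HN": 8.25, "N": 121.3, "CO": 176.1, "CA": 57.5, "HA": 4.66},
    "Y": {"HN": 8.12, "N": 120.3, "CO": 175.9, "CA": 57.9, "HA": 4.55},
    "V": {"HN": 8.03, "N": 119.2, "CO": 176.3, "CA": 62.2, "HA": 4.12},
}

#: Per-nucleus standard deviation (ppm) at dispersion_scale = 1.  Sequence
#: context spreads amide 15N far more than 13C' in coil ensembles.
NUCLEUS_SIGMA_PPM = {"HN": 0.15, "N": 2.0, "CO": 0.4, "CA": 0.4, "HA": 0.08}

#: Plausible windows (ppm) enforced on every stored shift.
NUCLEUS_WINDOW_PPM = {
    "HN": (6.0, 11.0),
    "N": (100.0, 140.0),
    "CO": (165.0, 185.0),
    "CA": (40.0, 70.0),
    "HA": (3.0, 6.0),
}

_TSV_COLUMNS = ["index", "aa", "HN", "N", "CO", "CA", "HA"]


@dataclass
class ShiftTable:
    """Per-residue backbone chemical shifts; the ground truth of a synthetic run.

    Backed by a DataFrame with columns index (1-based), aa, HN, N, CO, CA, HA;
    NaN marks an absent shift (proline or N-terminal amide proton).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def sequence(self) -> str:
        return "".join(self.df["aa"])

    def __len__(self) -> int:
        return len(self.df)

    def row(self, i: int) -> pd.Series:
        """Row for 1-based residue index i."""
        return self.df.iloc[i - 1]

    def shift(self, i: int, nucleus: str) -> float:
        return float(self.row(i)[nucleus])

    def is_proline(self, i: int) -> bool:
        return self.row(i)["aa"] == "P"

    def has_hn(self, i: int) -> bool:
        return bool(np.isfinite(self.row(i)["HN"]))

    def label(self, i: int) -> str:
        return f"{self.row(i)['aa']}{i}"

    def anchor_residues(self) -> list[int]:
        """Residues that carry an HNCO anchor: amide proton present and i >= 2."""
        return [i for i in range(2, len(self) + 1) if self.has_hn(i)]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if list(self.df.columns) != _TSV_COLUMNS:
            raise ValueError(f"shift table must have columns {_TSV_COLUMNS}")
        if len(self.df) == 0:
            raise ValueError("shift table is empty")
        expected = list(range(1, len(self.df) + 1))
        if list(self.df["index"]) != expected:
            raise ValueError("residue indices must be 1..N contiguous")
        for pos, (_, r) in enumerate(self.df.iterrows(), start=1):
            aa = r["aa"]
            if aa not in RANDOM_COIL_PPM:
                raise ValueError(f"unknown residue {aa!r} at position {pos}")
            if aa == "P" and np.isfinite(r["HN"]):
                raise ValueError(f"proline at position {pos} must not carry an HN shift")
            if aa != "P" and pos > 1 and not np.isfinite(r["HN"]):
                raise ValueError(f"non-proline internal residue {pos} lacks an HN shift")
            for nuc in ("N", "CO", "CA", "HA"):
                if not np.isfinite(r[nuc]):
                    raise ValueError(f"residue {pos} lacks a {nuc} shift")
            for nuc in NUCLEI:
                v = r[nuc]
                if np.isfinite(v):
                    lo, hi = NUCLEUS_WINDOW_PPM[nuc]
                    if not lo <= v <= hi:
                        raise ValueError(
                            f"{nuc} shift {v} of residue {pos} outside window [{lo}, {hi}]")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        a, b = self.df, other.df
        if list(a["aa"]) != list(b["aa"]):
            return False
        for nuc in NUCLEI:
            x, y = a[nuc].to_numpy(), b[nuc].to_numpy()
            same_nan = np.isnan(x) == np.isnan(y)
            close = np.isclose(x, y, rtol=0, atol=1e-6) | np.isnan(x)
            if not (same_nan & close).all():
                return False
        return True


def generate_shifts(sequence: str, seed: int, dispersion_scale: float = 1.0) -> ShiftTable:
    """Draw an IDP-like shift table for ``sequence``, deterministic in ``seed``.

    Each shift ~ Normal(random-coil mean, sigma * dispersion_scale), clipped to
    its nucleus's plausible window.  The amide proton is omitted for prolines
    and the N-terminal residue.  Duplicate (CO, N) pairs are allowed -- they
    are the realistic overlap challenge, not an error.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    sequence = sequence.upper()
    for pos, aa in enumerate(sequence, start=1):
        if aa not in RANDOM_COIL_PPM:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    if dispersion_scale < 0:
        raise ValueError("dispersion_scale must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for pos, aa in enumerate(sequence, start=1):
        row: dict[str, object] = {"index": pos, "aa": aa}
        for nuc in NUCLEI:
            mean = RANDOM_COIL_PPM[aa][nuc]
            if not np.isfinite(mean) or (nuc == "HN" and pos == 1):
                row[nuc] = float("nan")
                continue
            lo, hi = NUCLEUS_WINDOW_PPM[nuc]
            sigma = NUCLEUS_SIGMA_PPM[nuc] * dispersion_scale
            row[nuc] = float(np.clip(mean + sigma * rng.standard_normal(), lo, hi))
        rows.append(row)
    return ShiftTable(pd.DataFrame(rows, columns=_TSV_COLUMNS))


def save_shifts(table: ShiftTable, path) -> None:
    """Write a shift table as TSV; absent shifts become empty cells."""
    df = table.df.copy()
    for nuc in NUCLEI:
        df[nuc] = df[nuc].map(lambda v: "" if not np.isfinite(v) else f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def load_shifts(path) -> ShiftTable:
    """Read a shift-table TSV (header index,aa,HN,N,CO,CA,HA; empty = absent)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"aa": str})
    except Exception as exc:  # noqa: BLE001 - surface file/parse context
        raise ValueError(f"cannot parse shift table {path}: {exc}") from exc
    if list(df.columns) != _TSV_COLUMNS:
        raise ValueError(f"{path}: expected columns {_TSV_COLUMNS}, got {list(df.columns)}")
    for nuc in NUCLEI:
        df[nuc] = pd.to_numeric(df[nuc], errors="coerce")
    df["index"] = df["index"].astype(int)
    try:
        return ShiftTable(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_fasta(path) -> str:
    """Sequence of the first record of a FASTA file."""
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        return str(record.seq).upper()
    raise ValueError(f"no FASTA records in {path}")


def random_idp_sequence(length: int, n_prolines: int | None = None, seed: int = 0) -> str:
    """Random IDP-like sequence with a controlled proline count.

    Prolines (default ~10 % of residues, the typical IDP abundance) are placed
    at internal positions 3..length-2 with pairwise separation >= 2, so every
    proline is flanked by residues able to carry anchors or bridge peaks.
    """
    if length < 5:
        raise ValueError("sequence must have at least 5 residues")
    if n_prolines is None:
        n_prolines = round(0.1 * length)
    rng = np.random.default_rng(seed)
    non_p = [a for a in RANDOM_COIL_PPM if a != "P"]
    seq = list(rng.choice(non_p, size=length))
    placed: list[int] = []
    candidates = list(range(3, length - 1))  # 1-based internal positions
    rng.shuffle(candidates)
    for pos in candidates:
        if len(placed) == n_prolines:
            break
        if all(abs(pos - q) >= 2 for q in placed):
            placed.append(pos)
    if len(placed) < n_prolines:
        raise ValueError(f"cannot place {n_prolines} separated prolines in {length} residues")
    for pos in placed:
        seq[pos - 1] = "P"
    return "".join(seq)
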