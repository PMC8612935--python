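"""Readers and writers for GAM table formats.

All genomic coordinates are 0-based half-open (BED convention).  The
segregation / coverage table dialect is a TSV with a ``chrom  start  stop``
header followed by one column per nuclear-profile (NP) sample; gzip input is
handled transparently by pandas.  Chromosome names are matched literally —
no ``chr`` prefix munging is ever attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COORD_COLUMNS = ["chrom", "start", "stop"]


@dataclass(frozen=True)
class GenomicWindow:
    """A fixed-size genomic bin, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid window {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a chrom/start/stop frame (sorted, unique)."""
    if list(windows.columns[:3]) != COORD_COLUMNS:
        raise ValueError(
            f"expected leading columns {COORD_COLUMNS}, got {list(windows.columns[:3])}"
        )
    if (windows["start"] >= windows["stop"]).any():
        bad = windows[windows["start"] >= windows["stop"]].iloc[0]
        raise ValueError(f"window with start >= stop: {bad['chrom']}:{bad['start']}-{bad['stop']}")
    dup = windows.duplicated(subset=COORD_COLUMNS)
    if dup.any():
        first = windows[dup].iloc[0]
        raise ValueError(
            f"duplicate window row {first['chrom']}:{first['start']}-{first['stop']}"
        )
    return windows


def _is_sorted(windows: pd.DataFrame) -> bool:
    key = list(zip(windows["chrom"], windows["start"]))
    return all(key[i] <= key[i + 1] for i in range(len(key) - 1))


def infer_bin_size(windows: pd.DataFrame) -> int:
    """Modal window length; the last window of a chromosome may be shorter."""
    lengths = (windows["stop"] - windows["start"]).to_numpy()
    values, counts = np.unique(lengths, return_counts=True)
    return int(values[np.argmax(counts)])


@dataclass
class SegregationTable:
    """Boolean detection matrix: genomic windows x NP samples."""

    windows: pd.DataFrame          # columns chrom, start, stop
    samples: list[str]
    detection: np.ndarray          # bool, shape (n_windows, n_samples)
    bin_size: int

    def __post_init__(self) -> None:
        self.windows = _check_windows(self.windows.reset_index(drop=True))
        self.detection = np.asarray(self.detection)
        if self.detection.dtype != bool:
            uniq = np.unique(self.detection)
            if not np.isin(uniq, [0, 1]).all():
                raise ValueError(f"detection matrix not boolean; found values {uniq[:5]}")
            self.detection = self.detection.astype(bool)
        if self.detection.shape != (len(self.windows), len(self.samples)):
            raise ValueError(
                f"detection shape {self.detection.shape} does not match "
                f"{len(self.windows)} windows x {len(self.samples)} samples"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.windows["chrom"]))

    def chrom_mask(self, chrom: str) -> np.ndarray:
        mask = (self.windows["chrom"] == chrom).to_numpy()
        if not mask.any():
            raise KeyError(
                f"chromosome {chrom!r} not in table; available: {self.chromosomes}"
            )
        return mask

    def for_chromosome(self, chrom: str) -> "SegregationTable":
        mask = self.chrom_mask(chrom)
        return SegregationTable(
            self.windows[mask], self.samples, self.detection[mask], self.bin_size
        )

    def detection_frequency(self) -> np.ndarray:
        """Per-window fraction of samples in which the window is positive."""
        return self.detection.mean(axis=1)


@dataclass
class CoverageTable:
    """Non-negative nucleotide counts per window per sample."""

    windows: pd.DataFrame
    samples: list[str]
    nucleotides: np.ndarray        # int, shape (n_windows, n_samples)
    bin_size: int

    def __post_init__(self) -> None:
        self.windows = _check_windows(self.windows.reset_index(drop=True))
        self.nucleotides = np.asarray(self.nucleotides)
        if (self.nucleotides < 0).any():
            raise ValueError("coverage counts must be non-negative")


@dataclass
class IntervalTrack:
    """BED-like records (chrom, start, end, value[, name]); value may be NaN."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"IntervalTrack missing columns {sorted(missing)}")


def _read_table(path: str | Path, expect_boolean: bool) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != COORD_COLUMNS:
        raise ValueError(
            f"{path}: expected header starting with {COORD_COLUMNS}, got {list(df.columns[:3])}"
        )
    samples = list(df.columns[3:])
    values = df[samples].to_numpy()
    if expect_boolean:
        bad = ~np.isin(values, [0, 1])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: non-boolean cell {values[i, j]!r} at window "
                f"{df.iloc[i]['chrom']}:{df.iloc[i]['start']} sample {samples[j]!r}"
            )
    windows = df[COORD_COLUMNS].copy()
    if not _is_sorted(windows):
        warnings.warn(f"{path}: windows not sorted by (chrom, start); sorting")
        order = np.lexsort((windows["start"].to_numpy(), windows["chrom"].to_numpy()))
        windows = windows.iloc[order].reset_index(drop=True)
        values = values[order]
    return windows, samples, values


def read_segregation_table(path: str | Path) -> SegregationTable:
    """Read a GAM segregation TSV (``chrom start stop`` + 0/1 sample columns)."""
    windows, samples, values = _read_table(path, expect_boolean=True)
    return SegregationTable(windows, samples, values.astype(bool), infer_bin_size(windows))


def write_segregation_table(table: SegregationTable, path: str | Path) -> None:
    values = pd.DataFrame(table.detection.astype(int), columns=table.samples)
    pd.concat([table.windows.reset_index(drop=True), values], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_coverage_table(path: str | Path) -> CoverageTable:
    """Read a per-window nucleotide-coverage TSV (same layout, integer cells)."""
    windows, samples, values = _read_table(path, expect_boolean=False)
    return CoverageTable(windows, samples, values.astype(np.int64), infer_bin_size(windows))


def write_coverage_table(table: CoverageTable, path: str | Path) -> None:
    values = pd.DataFrame(table.nucleotides, columns=table.samples)
    pd.concat([table.windows.reset_index(drop=True), values], axis=1).to_csv(
        path, sep="\t", index=False
    )


def write_bedgraph(track: IntervalTrack, path: str | Path) -> int:
    """Write a 4-column bedGraph; rows with missing values are skipped.

    Returns the number of lines written.  Overlapping intervals on the same
    chromosome are an error (bedGraph requires disjoint intervals).
    """
    df = track.data
    order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy()))
    df = df.iloc[order]
    same_chrom = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    overlap = same_chrom & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])
    if overlap.any():
        i = int(np.flatnonzero(overlap)[0]) + 1
        raise ValueError(
            f"overlapping intervals on {df.iloc[i]['chrom']} at {df.iloc[i]['start']}"
        )
    keep = df[np.isfinite(df["value"].to_numpy(dtype=float))]
    with open(path, "w") as fh:
        for row in keep.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{_fmt(row.value)}\n")
    return len(keep)


def _fmt(x: float) -> str:
    # round-trip reals to >= 9 significant digits, ints without a decimal point
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def read_bedgraph(path: str | Path) -> IntervalTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    return IntervalTrack(df)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene annotation (>= 4 columns: chrom start end gene_id).

    Strand is ignored.  Gene ids must be unique; a negative or zero length is
    an error.  Returns a frame with columns chrom/start/end/gene_id/length.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: gene annotation needs >= 4 columns")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene_id"]
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"{path}: non-positive gene length for {bad['gene_id']!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    df["length"] = df["end"] - df["start"]
    return df.reset_index(drop=True)


def check_same_chromosomes(a: Iterable[str], b: Iterable[str]) -> None:
    """Literal chromosome-name comparison between two inputs."""
    sa, sb = set(a), set(b)
    if sa != sb:
        raise ValueError(f"chromosome name sets differ: {sorted(sa)} vs {sorted(sb)}")


def save_matrices(path: str | Path, matrices: dict[str, np.ndarray]) -> None:
    """Persist per-chromosome matrices as an npz archive with NaN masks."""
    arrays: dict[str, np.ndarray] = {}
    for chrom, values in matrices.items():
        values = np.asarray(values, dtype=float)
        arrays[f"values/{chrom}"] = values
        arrays[f"mask/{chrom}"] = ~np.isfinite(values)
    np.savez_compressed(path, **arrays)


def load_matrices(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as archive:
        chroms = [k.split("/", 1)[1] for k in archive.files if k.startswith("values/")]
        out = {}
        for chrom in chroms:
            values = archive[f"values/{chrom}"]
            values[archive[f"mask/{chrom}"]] = np.nan
            out[chrom] = values
    return out


def write_matrix_text(matrix: np.ndarray, path: str | Path) -> None:
    """Dense text export for small matrices (NaN marks masked entries)."""
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.9g")


def read_matrix_text(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def make_windows(chrom_sizes: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Tile chromosomes into fixed-size windows (last window may be short)."""
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + bin_size, size))))
    return pd.DataFrame(rows, columns=COORD_COLUMNS)
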