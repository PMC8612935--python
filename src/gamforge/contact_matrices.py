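"""Co-segregation, NPMI and distance-normalized contact matrices.

The contact strength between two windows x and y is the normalized pointwise
mutual information of their detection across NP samples,

    PMI  = log( p(x,y) / (p(x) p(y)) )
    NPMI = PMI / (-log p(x,y))        in [-1, 1],

computed with the natural log (NPMI is invariant to the base).  Entries with
p(x,y) = 0 or a zero marginal are undefined and carried as NaN; they are
excluded from every downstream mean.  Distance normalization converts each
intra-chromosomal diagonal to Z-scores (population sd), which makes matrices
from different datasets subtractable into a differential matrix D.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SegregationTable

logger = logging.getLogger(__name__)


@dataclass
class CosegMatrix:
    chrom: str
    bin_size: int
    joint: np.ndarray      # p(x,y), symmetric, diagonal = marginal
    marginal: np.ndarray   # p(x)
    n_samples: int


@dataclass
class NPMIMatrix:
    chrom: str
    bin_size: int
    values: np.ndarray     # NaN where undefined

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class ZScoreMatrix:
    chrom: str
    bin_size: int
    values: np.ndarray
    diag_means: np.ndarray = field(default=None)  # per-distance statistics used
    diag_sds: np.ndarray = field(default=None)


@dataclass
class DifferentialContactSet:
    """Top differential contacts between two Z-score matrices (D = zA - zB)."""

    contacts: pd.DataFrame  # chrom, i, j, start_i, start_j, D, direction in {A, B}
    n_filtered_pairs: int
    params: dict


def cosegregation(seg: SegregationTable, chrom: str) -> CosegMatrix:
    """Joint and marginal detection frequencies for one chromosome."""
    sub = seg.for_chromosome(chrom)
    d = sub.detection.astype(np.float64)
    n = sub.n_samples
    joint = (d @ d.T) / n
    marginal = d.mean(axis=1)
    return CosegMatrix(chrom, seg.bin_size, joint, marginal, n)


def npmi(coseg: CosegMatrix) -> NPMIMatrix:
    """Normalized pointwise mutual information of a co-segregation matrix."""
    j = coseg.joint
    px = coseg.marginal
    outer = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(j) - np.log(outer)
        values = pmi / (-np.log(j))
    undefined = (j <= 0) | (outer <= 0) | (j >= 1)  # -log p(x,y) = 0 when j = 1
    values[undefined] = np.nan
    return NPMIMatrix(coseg.chrom, coseg.bin_size, values)


def npmi_from_segregation(seg: SegregationTable, chrom: str) -> NPMIMatrix:
    return npmi(cosegregation(seg, chrom))


def distance_zscore(m: NPMIMatrix) -> ZScoreMatrix:
    """Z-score each off-diagonal distance of the matrix independently.

    Degenerate diagonals (sd 0 or fewer than 2 finite entries) map to zeros;
    NaN entries stay NaN.  The main diagonal is always degenerate by this
    rule and maps to zeros.
    """
    v = m.values
    n = v.shape[0]
    out = np.full_like(v, np.nan, dtype=float)
    means = np.full(n, np.nan)
    sds = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(v, offset=d).copy()
        finite = np.isfinite(diag)
        z = np.full(diag.shape, np.nan)
        if finite.sum() >= 2:
            mu = diag[finite].mean()
            sd = diag[finite].std(ddof=0)
            means[d], sds[d] = mu, sd
            # relative tolerance guards against float noise on constant diagonals
            if sd > 1e-12 * max(1.0, abs(mu)) and d > 0:
                z[finite] = (diag[finite] - mu) / sd
            else:
                z[finite] = 0.0
        elif finite.any():
            z[finite] = 0.0
        idx = np.arange(n - d)
        out[idx, idx + d] = z
        out[idx + d, idx] = z
    return ZScoreMatrix(m.chrom, m.bin_size, out, means, sds)


def low_detection_windows(freq: np.ndarray, percentile: float = 2.0) -> np.ndarray:
    """Boolean mask of windows below the given percentile of the per-window
    detection-frequency distribution (taken over detected windows only)."""
    freq = np.asarray(freq, dtype=float)
    detected = freq > 0
    if not detected.any():
        return np.ones_like(freq, dtype=bool)
    cutoff = np.percentile(freq[detected], percentile)
    return ~detected | (freq < cutoff)


def differential_contacts(
    zA: ZScoreMatrix,
    zB: ZScoreMatrix,
    npmiA: NPMIMatrix,
    npmiB: NPMIMatrix,
    freqA: np.ndarray,
    freqB: np.ndarray,
    d_min: int = 500_000,
    d_max: int = 5_000_000,
    npmi_floor: float = 0.15,
    quantile: float = 0.05,
    low_detection_percentile: float = 2.0,
    starts: np.ndarray | None = None,
) -> DifferentialContactSet:
    """Top-quantile differential contacts D = zA - zB on filtered pairs.

    Pairs survive when: both windows clear the low-detection filter in both
    datasets (union of removals); genomic distance within [d_min, d_max];
    NPMI above the floor in at least one dataset; Z finite in both.
    """
    if zA.bin_size != zB.bin_size or zA.values.shape != zB.values.shape:
        raise ValueError("bin size / shape mismatch between datasets")
    n = zA.values.shape[0]
    bad = low_detection_windows(freqA, low_detection_percentile) | low_detection_windows(
        freqB, low_detection_percentile
    )
    ii, jj = np.triu_indices(n, k=1)
    dist = (jj - ii) * zA.bin_size
    keep = (
        (dist >= d_min)
        & (dist <= d_max)
        & ~bad[ii]
        & ~bad[jj]
        & ((npmiA.values[ii, jj] > npmi_floor) | (npmiB.values[ii, jj] > npmi_floor))
        & np.isfinite(zA.values[ii, jj])
        & np.isfinite(zB.values[ii, jj])
    )
    ii, jj = ii[keep], jj[keep]
    D = zA.values[ii, jj] - zB.values[ii, jj]
    params = dict(
        d_min=d_min, d_max=d_max, npmi_floor=npmi_floor, quantile=quantile,
        low_detection_percentile=low_detection_percentile,
    )
    columns = ["chrom", "i", "j", "start_i", "start_j", "D", "direction"]
    if len(D) == 0 or np.nanmax(np.abs(D)) == 0:
        if len(D) and np.nanmax(np.abs(D)) == 0:
            warnings.warn("differential matrix is identically zero; returning empty sets")
        return DifferentialContactSet(pd.DataFrame(columns=columns), len(D), params)
    n_top = math.ceil(quantile * len(D))
    order = np.argsort(-D, kind="stable")
    rows = []
    if starts is None:
        starts = np.arange(n) * zA.bin_size
    for idx in order[:n_top]:
        rows.append((zA.chrom, ii[idx], jj[idx], starts[ii[idx]], starts[jj[idx]], D[idx], "A"))
    for idx in order[::-1][:n_top]:
        rows.append((zA.chrom, ii[idx], jj[idx], starts[ii[idx]], starts[jj[idx]], D[idx], "B"))
    return DifferentialContactSet(pd.DataFrame(rows, columns=columns), len(D), params)


def aggregate_pileup(
    zscores: dict[str, ZScoreMatrix],
    contacts: pd.DataFrame,
    radius: int = 4,
) -> float:
    """Mean Z over square patches around each contact, averaged by chromosome.

    For each chromosome, Z values over every contact's (2r+1)^2 patch
    (truncated at matrix edges, finite cells only) are pooled and averaged;
    the per-chromosome means are then averaged over chromosomes.
    """
    per_chrom = []
    for chrom, group in contacts.groupby("chrom"):
        z = zscores[chrom].values
        n = z.shape[0]
        cells = []
        for i, j in zip(group["i"], group["j"]):
            r0, r1 = max(0, i - radius), min(n, i + radius + 1)
            c0, c1 = max(0, j - radius), min(n, j + radius + 1)
            patch = z[r0:r1, c0:c1]
            cells.append(patch[np.isfinite(patch)].ravel())
        pooled = np.concatenate(cells) if cells else np.array([])
        if pooled.size:
            per_chrom.append(pooled.mean())
    if not per_chrom:
        raise ValueError("no finite patch values for any contact")
    return float(np.mean(per_chrom))
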