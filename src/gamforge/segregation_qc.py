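"""Window calling and per-sample quality control for GAM nuclear profiles.

Positive windows are called per sample from nucleotide coverage by choosing,
over the integer percentiles of the positive-coverage distribution, the
threshold that minimizes the fraction of *orphan* windows — positive windows
flanked by negative neighbours, a proxy for spurious detections.  Sample QC
combines the orphan fraction, uniquely mapped read counts and a cross-well
contamination score (maximum Jaccard index to any sample on the same
collection plate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CoverageTable, SegregationTable

logger = logging.getLogger(__name__)

# QC pass thresholds (all strict inequalities)
MAX_ORPHAN_FRACTION = 0.70
MIN_MAPPED_READS = 50_000
MAX_PLATE_JACCARD = 0.4


@dataclass
class WindowCallResult:
    sample: str
    chosen_percentile: int
    threshold: float
    detection: np.ndarray        # bool per window
    orphan_fraction: float


@dataclass
class SampleQCReport:
    sample: str
    orphan_fraction: float
    mapped_reads: int
    max_jaccard_to_platemates: float
    passed: bool = False

    def evaluate(self) -> "SampleQCReport":
        for name in ("orphan_fraction", "mapped_reads", "max_jaccard_to_platemates"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError(f"sample {self.sample!r}: missing QC metric {name}")
        self.passed = (
            self.orphan_fraction < MAX_ORPHAN_FRACTION
            and self.mapped_reads > MIN_MAPPED_READS
            and self.max_jaccard_to_platemates < MAX_PLATE_JACCARD
        )
        return self


def orphan_fraction(detection: np.ndarray, chroms: np.ndarray | None = None) -> float:
    """Fraction of positive windows whose adjacent windows are both negative.

    ``chroms`` groups windows by chromosome so that neighbours are never taken
    across a chromosome junction.  A positive window at a chromosome edge has
    a single neighbour; it counts as an orphan when that neighbour is
    negative (conservative reading of the flanking rule).
    """
    detection = np.asarray(detection, dtype=bool)
    if chroms is None:
        chroms = np.zeros(len(detection), dtype=int)
    chroms = np.asarray(chroms)
    n_pos = 0
    n_orphan = 0
    for chrom in pd.unique(chroms):
        d = detection[chroms == chrom]
        if not d.any():
            continue
        # pad with negatives: edge positives orphan unless inner neighbour positive
        padded = np.concatenate([[False], d, [False]])
        left = padded[:-2]
        right = padded[2:]
        orphan = d & ~left & ~right
        n_pos += int(d.sum())
        n_orphan += int(orphan.sum())
    return n_orphan / n_pos if n_pos else 0.0


def call_windows(
    coverage: np.ndarray,
    chroms: np.ndarray | None = None,
    sample: str = "",
    percentiles: np.ndarray | None = None,
) -> WindowCallResult:
    """Choose the coverage threshold that minimizes the orphan fraction.

    Candidate thresholds are the integer percentiles (1-99) of the strictly
    positive coverage values, with percentile 0 taken as threshold zero (no
    filtering: every covered window positive); detection is strict
    (coverage > threshold).  Ties in orphan fraction are broken toward the
    lowest percentile, which retains the most windows.
    """
    coverage = np.asarray(coverage)
    if (coverage < 0).any():
        raise ValueError("coverage must be non-negative")
    positive = coverage[coverage > 0]
    if positive.size == 0:
        logger.warning("sample %r: all-zero coverage; empty detection", sample)
        return WindowCallResult(sample, 0, 0.0, np.zeros(len(coverage), dtype=bool), 0.0)
    if percentiles is None:
        percentiles = np.arange(100)
    best: WindowCallResult | None = None
    for q in percentiles:
        threshold = float(np.percentile(positive, q)) if q > 0 else 0.0
        detection = coverage > threshold
        frac = orphan_fraction(detection, chroms)
        if best is None or frac < best.orphan_fraction:
            best = WindowCallResult(sample, int(q), threshold, detection, frac)
    assert best is not None
    return best


def call_windows_table(cov: CoverageTable) -> SegregationTable:
    """Apply :func:`call_windows` to every sample of a coverage table."""
    chroms = cov.windows["chrom"].to_numpy()
    detection = np.zeros(cov.nucleotides.shape, dtype=bool)
    for j, sample in enumerate(cov.samples):
        detection[:, j] = call_windows(cov.nucleotides[:, j], chroms, sample).detection
    return SegregationTable(cov.windows, list(cov.samples), detection, cov.bin_size)


def pairwise_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two detection vectors; 0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return int((a & b).sum()) / union


def plate_contamination_scores(
    seg: SegregationTable, plates: dict[str, str]
) -> dict[str, float]:
    """Max Jaccard of each sample to any other sample on the same plate."""
    scores: dict[str, float] = {}
    by_plate: dict[str, list[int]] = {}
    for j, s in enumerate(seg.samples):
        by_plate.setdefault(plates[s], []).append(j)
    for members in by_plate.values():
        for j in members:
            others = [k for k in members if k != j]
            scores[seg.samples[j]] = max(
                (pairwise_jaccard(seg.detection[:, j], seg.detection[:, k]) for k in others),
                default=0.0,
            )
    return scores


def qc_filter(reports: list[SampleQCReport]) -> list[SampleQCReport]:
    """Evaluate pass flags and return the passing subset."""
    for r in reports:
        r.evaluate()
    passed = [r for r in reports if r.passed]
    logger.info("QC: %d/%d samples passed", len(passed), len(reports))
    return passed


def qc_report_table(
    seg: SegregationTable,
    mapped_reads: dict[str, int],
    plates: dict[str, str],
) -> pd.DataFrame:
    """Build per-sample QC reports from a segregation table and metadata."""
    chroms = seg.windows["chrom"].to_numpy()
    jaccard = plate_contamination_scores(seg, plates)
    reports = [
        SampleQCReport(
            sample=s,
            orphan_fraction=orphan_fraction(seg.detection[:, j], chroms),
            mapped_reads=int(mapped_reads[s]),
            max_jaccard_to_platemates=jaccard[s],
        ).evaluate()
        for j, s in enumerate(seg.samples)
    ]
    return pd.DataFrame([vars(r) for r in reports])


def pair_sampling_coverage(seg: SegregationTable) -> float:
    """Fraction of intrachromosomal pairs of detected windows co-detected
    in at least one sample.

    Pairs involving never-detected windows are excluded from the denominator.
    """
    chroms = seg.windows["chrom"].to_numpy()
    n_pairs = 0
    n_sampled = 0
    for chrom in pd.unique(chroms):
        d = seg.detection[chroms == chrom]
        detected = d.any(axis=1)
        d = d[detected]
        m = d.shape[0]
        if m < 2:
            continue
        co = (d.astype(np.int32) @ d.astype(np.int32).T) > 0
        iu = np.triu_indices(m, k=1)
        n_pairs += len(iu[0])
        n_sampled += int(co[iu].sum())
    return n_sampled / n_pairs if n_pairs else 1.0
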