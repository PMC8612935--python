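"""A/B compartment calling from co-segregation matrices.

Per chromosome (conventionally at 250-kb bins): the observed matrix O is
divided by the expected contact E(d) at each genomic distance d; a Pearson
correlation matrix C between columns of O/E is built (pairwise-complete to
tolerate missing entries); PCA is run on C and, among the first three
components, the one correlating best with GC content is taken, oriented so
the correlation is positive.  Bins with positive values are A compartment
(open, GC-rich), negative are B.  Values are rescaled per chromosome so that
A spans (0, 1] and B spans [-1, 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CompartmentTrack:
    chrom: str
    bin_size: int
    values: np.ndarray           # normalized eigenvector, NaN = missing
    labels: np.ndarray           # 'A' / 'B' / '' per bin
    pc_index: int                # which of the first 3 components was used (0-based)
    gc_correlation: float        # Pearson r with GC after sign fixing


def observed_expected(observed: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its finite-entry mean; NaN where E(d) = 0."""
    o = np.asarray(observed, dtype=float)
    n = o.shape[0]
    out = np.full_like(o, np.nan)
    for d in range(n):
        diag = np.diagonal(o, offset=d)
        finite = np.isfinite(diag)
        if not finite.any():
            continue
        e = diag[finite].mean()
        vals = np.full(diag.shape, np.nan)
        if e != 0:
            vals[finite] = diag[finite] / e
        idx = np.arange(n - d)
        out[idx, idx + d] = vals
        out[idx + d, idx] = vals
    return out


def pairwise_correlation(oe: np.ndarray, min_finite_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation between columns of O/E.

    Columns with fewer than ``min_finite_frac`` finite entries are dropped.
    Returns (C, kept_index).
    """
    oe = np.asarray(oe, dtype=float)
    finite_frac = np.isfinite(oe).mean(axis=0)
    kept = np.flatnonzero(finite_frac >= min_finite_frac)
    sub = pd.DataFrame(oe[np.ix_(kept, kept)])
    corr = sub.corr(method="pearson", min_periods=2).to_numpy()
    return corr, kept


def _pca_scores(c: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Row scores of the first principal components of C (column-centred SVD)."""
    c = np.where(np.isfinite(c), c, 0.0)
    centred = c - c.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, len(s))
    return u[:, :k] * s[:k]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return 0.0
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def compartment_eigenvector(
    oe: np.ndarray,
    gc: np.ndarray,
    chrom: str = "",
    bin_size: int = 250_000,
    min_finite_frac: float = 0.5,
) -> CompartmentTrack:
    """Call A/B compartments from an O/E matrix and a per-bin GC track."""
    n = oe.shape[0]
    if len(gc) != n:
        raise ValueError("GC track length does not match matrix size")
    values = np.full(n, np.nan)
    labels = np.array([""] * n, dtype=object)
    if np.isfinite(oe).sum() < 10:
        warnings.warn(f"{chrom}: too few finite bins for compartment calling")
        return CompartmentTrack(chrom, bin_size, values, labels, -1, 0.0)
    c, kept = pairwise_correlation(oe, min_finite_frac)
    finite_c = c[np.isfinite(c)]
    if finite_c.size == 0 or finite_c.std() == 0:
        warnings.warn(f"{chrom}: degenerate correlation matrix; chromosome set missing")
        return CompartmentTrack(chrom, bin_size, values, labels, -1, 0.0)
    scores = _pca_scores(c)
    rs = [_pearson(scores[:, k], np.asarray(gc, dtype=float)[kept]) for k in range(scores.shape[1])]
    best = int(np.argmax(np.abs(rs)))
    ev = scores[:, best] * np.sign(rs[best] if rs[best] != 0 else 1.0)
    # normalize: A side to (0, 1], B side to [-1, 0)
    pos = ev > 0
    neg = ev < 0
    norm = ev.astype(float)
    if pos.any():
        norm[pos] = ev[pos] / ev[pos].max()
    if neg.any():
        norm[neg] = ev[neg] / abs(ev[neg].min())
    values[kept] = norm
    lab = np.where(norm > 0, "A", np.where(norm < 0, "B", ""))
    labels[kept] = lab
    return CompartmentTrack(chrom, bin_size, values, labels, best, abs(rs[best]))


TRANSITION_CLASSES = ("A->A", "A->B", "B->A", "B->B")


def replicate_consensus(track1: CompartmentTrack, track2: CompartmentTrack) -> np.ndarray:
    """Labels kept only where two replicates agree ('' elsewhere)."""
    agree = (track1.labels == track2.labels) & (track1.labels != "")
    out = np.array([""] * len(track1.labels), dtype=object)
    out[agree] = track1.labels[agree]
    return out


def compartment_transitions(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-bin transition classes between two datasets and their fractions.

    Bins undefined in either dataset get '' and are excluded from fractions.
    """
    labels_a = np.asarray(labels_a, dtype=object)
    labels_b = np.asarray(labels_b, dtype=object)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label tracks have different lengths")
    defined = (labels_a != "") & (labels_b != "")
    classes = np.array([""] * len(labels_a), dtype=object)
    classes[defined] = [f"{a}->{b}" for a, b in zip(labels_a[defined], labels_b[defined])]
    n = int(defined.sum())
    fractions = {
        c: (float((classes == c).sum()) / n if n else np.nan) for c in TRANSITION_CLASSES
    }
    return classes, fractions
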