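"""TF-motif feature pairs on differential contacts.

Windows are annotated with boolean motif features: a window carries motif f
when an accessible-chromatin peak supported by at least 10% of single
nuclei overlaps the window and contains at least one hit of f.  Unordered
motif pairs are then scored on the two direction classes of a differential
contact set by (i) an enrichment ratio of contact frequencies and (ii) the
information gain of the class label given pair presence.  Pairs involved in
at least 20% of a cell type's contacts form the edges of a motif
co-occurrence network (community detection itself is delegated to standard
graph packages).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_PEAK_SUPPORT = 0.10


@dataclass
class WindowFeatureTable:
    windows: pd.DataFrame            # chrom, start, stop
    features: list[str]              # motif names
    presence: np.ndarray             # bool (n_windows, n_features)

    def feature_vector(self, window_index: int) -> np.ndarray:
        return self.presence[window_index]


def _overlaps(starts_a, ends_a, start_b, end_b) -> np.ndarray:
    return (np.asarray(starts_a) < end_b) & (np.asarray(ends_a) > start_b)


def annotate_windows(
    windows: pd.DataFrame,
    peaks: pd.DataFrame,            # chrom, start, end, support (fraction of nuclei)
    motif_hits: pd.DataFrame,       # chrom, start, end, motif
    min_support: float = MIN_PEAK_SUPPORT,
) -> WindowFeatureTable:
    """Boolean windows x motifs table from peaks and motif hit intervals."""
    features = sorted(motif_hits["motif"].unique())
    f_index = {f: k for k, f in enumerate(features)}
    presence = np.zeros((len(windows), len(features)), dtype=bool)
    passing = peaks[peaks["support"] >= min_support]
    for chrom, chrom_peaks in passing.groupby("chrom"):
        w_mask = (windows["chrom"] == chrom).to_numpy()
        if not w_mask.any():
            continue
        w_idx = np.flatnonzero(w_mask)
        w_start = windows["start"].to_numpy()[w_mask]
        w_stop = windows["stop"].to_numpy()[w_mask]
        chrom_hits = motif_hits[motif_hits["chrom"] == chrom]
        for peak in chrom_peaks.itertuples(index=False):
            in_peak = chrom_hits[
                _overlaps(chrom_hits["start"], chrom_hits["end"], peak.start, peak.end)
            ]
            if in_peak.empty:
                continue
            hit_windows = w_idx[_overlaps(w_start, w_stop, peak.start, peak.end)]
            for motif in in_peak["motif"].unique():
                presence[hit_windows, f_index[motif]] = True
    return WindowFeatureTable(windows.reset_index(drop=True), features, presence)


def enumerate_pairs(features: list[str]) -> list[tuple[str, str]]:
    """All unordered motif pairs including homotypic: C(F,2) + F."""
    hetero = list(itertools.combinations(sorted(features), 2))
    homo = [(f, f) for f in sorted(features)]
    return hetero + homo


def pair_presence_matrix(
    contacts: pd.DataFrame, feats: WindowFeatureTable
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Boolean (n_contacts, n_pairs) presence of each motif pair on each contact.

    A heterotypic pair (f1, f2) is present when f1 sits on one window and f2
    on the other, in either orientation; a homotypic pair needs the motif on
    both windows.
    """
    pairs = enumerate_pairs(feats.features)
    f_index = {f: k for k, f in enumerate(feats.features)}
    a = feats.presence[contacts["i"].to_numpy()]
    b = feats.presence[contacts["j"].to_numpy()]
    out = np.zeros((len(contacts), len(pairs)), dtype=bool)
    for p, (f1, f2) in enumerate(pairs):
        k1, k2 = f_index[f1], f_index[f2]
        if f1 == f2:
            out[:, p] = a[:, k1] & b[:, k1]
        else:
            out[:, p] = (a[:, k1] & b[:, k2]) | (a[:, k2] & b[:, k1])
    return out, pairs


def count_pair_contacts(
    contacts: pd.DataFrame, feats: WindowFeatureTable, pair: tuple[str, str]
) -> int:
    """Number of contacts carrying one specific unordered motif pair."""
    presence, pairs = pair_presence_matrix(contacts, feats)
    key = tuple(sorted(pair)) if pair[0] != pair[1] else pair
    return int(presence[:, pairs.index(key)].sum())


def enrichment_score(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """(count_a/total_a) / (count_b/total_b); +inf sentinel when count_b = 0
    and count_a > 0, NaN when both counts are 0."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("contact totals must be positive")
    if count_b == 0:
        return np.inf if count_a > 0 else np.nan
    return (count_a / total_a) / (count_b / total_b)


def _entropy(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(pair_present: np.ndarray, class_label: np.ndarray) -> float:
    """Entropy (bits) of the class label removed by pair presence/absence."""
    pair_present = np.asarray(pair_present, dtype=bool)
    class_label = np.asarray(class_label)
    classes = np.unique(class_label)
    if len(classes) < 2:
        warnings.warn("single class present; information gain is 0")
        return 0.0
    n = len(class_label)
    h_class = _entropy(np.array([(class_label == c).sum() for c in classes]))
    h_cond = 0.0
    for group in (pair_present, ~pair_present):
        if group.sum() == 0:
            continue
        counts = np.array([(class_label[group] == c).sum() for c in classes])
        h_cond += (group.sum() / n) * _entropy(counts)
    return h_class - h_cond


def feature_pair_stats(
    contacts: pd.DataFrame,          # columns i, j, direction in {A, B}
    feats: WindowFeatureTable,
) -> pd.DataFrame:
    """Counts, enrichment and information gain for every motif pair."""
    presence, pairs = pair_presence_matrix(contacts, feats)
    direction = contacts["direction"].to_numpy()
    is_a = direction == "A"
    total_a, total_b = int(is_a.sum()), int((~is_a).sum())
    rows = []
    for p, (f1, f2) in enumerate(pairs):
        count_a = int(presence[is_a, p].sum())
        count_b = int(presence[~is_a, p].sum())
        enr = (
            enrichment_score(count_a, total_a, count_b, total_b)
            if total_a and total_b
            else np.nan
        )
        rows.append(
            dict(
                f1=f1, f2=f2, homotypic=f1 == f2,
                count_A=count_a, count_B=count_b,
                total_A=total_a, total_B=total_b,
                enrichment=enr,
                information_gain=information_gain(presence[:, p], direction),
            )
        )
    return pd.DataFrame(rows)


def select_top_pairs(
    stats: pd.DataFrame, n_ig: int = 10, n_enrich_a: int = 5, n_enrich_b: int = 5
) -> pd.DataFrame:
    """Union of top pairs by information gain, A-enrichment and B-enrichment.

    Ties are broken by (f1, f2) lexicographic order for determinism.
    B-enrichment ranks by the inverse ratio (B-skewed pairs first).
    """
    s = stats.copy()
    s["_name"] = list(zip(s["f1"], s["f2"]))
    with np.errstate(divide="ignore"):
        s["_inv_enrichment"] = 1.0 / s["enrichment"]
    top_ig = s.sort_values(["information_gain", "_name"], ascending=[False, True]).head(n_ig)
    # A-enrichment: +inf sentinels sort first, NaN last
    top_a = s.sort_values(["enrichment", "_name"], ascending=[False, True], na_position="last").head(n_enrich_a)
    top_b = s.sort_values(["_inv_enrichment", "_name"], ascending=[False, True], na_position="last").head(n_enrich_b)
    out = pd.concat([top_ig, top_a, top_b]).drop_duplicates(subset=["f1", "f2"])
    return out.drop(columns=["_name", "_inv_enrichment"]).reset_index(drop=True)


def pair_network_edges(
    stats: pd.DataFrame,
    total_contacts: int,
    count_column: str = "count_A",
    min_fraction: float = 0.20,
) -> pd.DataFrame:
    """Edge table (motif, motif, weight) for pairs involved in at least
    ``min_fraction`` of a cell type's contacts; weight = contact count."""
    if total_contacts <= 0:
        raise ValueError("total contact count must be positive")
    threshold = min_fraction * total_contacts
    passing = stats[stats[count_column] >= threshold]
    return pd.DataFrame(
        dict(source=passing["f1"].to_numpy(),
             target=passing["f2"].to_numpy(),
             weight=passing[count_column].to_numpy())
    ).reset_index(drop=True)


def prefilter_motifs(
    window_fraction: dict[str, float],
    de_neglog_padj: dict[str, float],
    min_window_fraction: float = 0.05,
    min_de: float = 3.0,
) -> list[str]:
    """Shortlist motifs present in > 5% of windows whose TF is strongly
    differentially expressed (-log10 adjusted p > 3)."""
    return sorted(
        f for f, frac in window_fraction.items()
        if frac > min_window_fraction and de_neglog_padj.get(f, 0.0) > min_de
    )
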