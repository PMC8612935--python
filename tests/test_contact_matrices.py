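import math

import numpy as np
import pandas as pd
import pytest

from gamforge.contact_matrices import (
    aggregate_pileup,
    cosegregation,
    differential_contacts,
    distance_zscore,
    low_detection_windows,
    npmi,
    npmi_from_segregation,
    CosegMatrix,
    NPMIMatrix,
    ZScoreMatrix,
)
from gamforge.io_formats import SegregationTable, make_windows
from .conftest import random_segregation


def seg_from_detection(detection, chrom="chr1", bin_size=50_000):
    detection = np.asarray(detection, dtype=bool)
    windows = make_windows({chrom: detection.shape[0] * bin_size}, bin_size)
    samples = [f"S{j}" for j in range(detection.shape[1])]
    return SegregationTable(windows, samples, detection, bin_size)


def brute_force_npmi(detection):
    """Independent oracle: per-pair counting loops, log base 10."""
    n_windows, n_samples = detection.shape
    out = np.full((n_windows, n_windows), np.nan)
    for x in range(n_windows):
        for y in range(n_windows):
            nx = sum(detection[x])
            ny = sum(detection[y])
            nxy = sum(detection[x, s] and detection[y, s] for s in range(n_samples))
            px, py, pxy = nx / n_samples, ny / n_samples, nxy / n_samples
            if pxy == 0 or px == 0 or py == 0 or pxy == 1:
                continue
            out[x, y] = math.log10(pxy / (px * py)) / (-math.log10(pxy))
    return out


class TestCosegregation:
    def test_counting_example(self):
        # x in samples {0,1}; y in {0,1,2}; 4 samples
        det = np.array([[1, 1, 0, 0], [1, 1, 1, 0]])
        m = cosegregation(seg_from_detection(det), "chr1")
        assert m.marginal[0] == 0.5
        assert m.marginal[1] == 0.75
        assert m.joint[0, 1] == 0.5

    def test_never_detected_window(self):
        det = np.array([[0, 0, 0], [1, 1, 0]])
        m = cosegregation(seg_from_detection(det), "chr1")
        assert m.marginal[0] == 0.0
        assert (m.joint[0] == 0).all()

    def test_matches_double_loop_oracle(self, rng):
        det = rng.random((10, 15)) < 0.4
        m = cosegregation(seg_from_detection(det), "chr1")
        n = det.shape[1]
        for x in range(10):
            for y in range(10):
                expected = sum(det[x, s] and det[y, s] for s in range(n)) / n
                assert m.joint[x, y] == pytest.approx(expected)
        assert np.allclose(np.diag(m.joint), m.marginal)

    def test_empty_chromosome_is_error(self, tiny_seg):
        with pytest.raises(KeyError):
            cosegregation(tiny_seg, "chrZ")


class TestNPMI:
    def test_perfect_cooccurrence_is_one(self):
        det = np.array([[1, 1, 0, 0], [1, 1, 0, 0]])
        m = npmi(cosegregation(seg_from_detection(det), "chr1"))
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_independence_is_zero(self):
        # p(x)=p(y)=0.5, p(x,y)=0.25
        det = np.array([[1, 1, 0, 0], [1, 0, 1, 0]])
        m = npmi(cosegregation(seg_from_detection(det), "chr1"))
        assert m.values[0, 1] == pytest.approx(0.0)

    def test_partial_overlap_value(self):
        # p(x)=0.5, p(y)=0.75, p(x,y)=0.5 -> ln(4/3)/ln(2)
        det = np.array([[1, 1, 0, 0], [1, 1, 1, 0]])
        m = npmi(cosegregation(seg_from_detection(det), "chr1"))
        assert m.values[0, 1] == pytest.approx(math.log(4 / 3) / math.log(2))

    def test_matches_base10_oracle_and_bounds(self, rng):
        """NPMI is log-base invariant and bounded in [-1, 1]."""
        det = rng.random((12, 25)) < 0.35
        ours = npmi(cosegregation(seg_from_detection(det), "chr1")).values
        oracle = brute_force_npmi(det)
        assert np.array_equal(np.isnan(ours), np.isnan(oracle))
        assert np.allclose(ours[np.isfinite(ours)], oracle[np.isfinite(oracle)],
                           atol=1e-12)
        finite = ours[np.isfinite(ours)]
        assert (finite >= -1 - 1e-12).all() and (finite <= 1 + 1e-12).all()

    def test_zero_joint_masked(self):
        det = np.array([[1, 0], [0, 1]])
        m = npmi(cosegregation(seg_from_detection(det), "chr1"))
        assert np.isnan(m.values[0, 1])


class TestDistanceZscore:
    def test_three_value_diagonal(self):
        v = np.full((4, 4), np.nan)
        for i, x in enumerate([0.1, 0.2, 0.3]):
            v[i, i + 1] = v[i + 1, i] = x
        z = distance_zscore(NPMIMatrix("chr1", 50_000, v))
        got = [z.values[i, i + 1] for i in range(3)]
        assert got == pytest.approx([-math.sqrt(1.5), 0.0, math.sqrt(1.5)])

    def test_constant_diagonal_degenerates_to_zero(self):
        v = np.ones((5, 5)) * 0.4
        z = distance_zscore(NPMIMatrix("chr1", 50_000, v))
        assert (z.values == 0).all()

    def test_matches_per_diagonal_oracle(self, rng):
        v = rng.random((15, 15))
        v = (v + v.T) / 2
        v[2, 5] = v[5, 2] = np.nan
        z = distance_zscore(NPMIMatrix("chr1", 50_000, v)).values
        for d in range(1, 15):
            diag = np.array([v[i, i + d] for i in range(15 - d)])
            finite = np.isfinite(diag)
            if finite.sum() < 2 or diag[finite].std() == 0:
                continue
            expected = (diag - diag[finite].mean()) / diag[finite].std(ddof=0)
            got = np.array([z[i, i + d] for i in range(15 - d)])
            assert np.allclose(got[finite], expected[finite])
        assert np.array_equal(np.isnan(z), np.isnan(v))


def _diff_inputs(rng, n=20, bin_size=50_000, boost=None):
    detA = rng.random((n, 60)) < 0.4
    detB = detA.copy()
    segA = seg_from_detection(detA, bin_size=bin_size)
    segB = seg_from_detection(detB, bin_size=bin_size)
    na = npmi_from_segregation(segA, "chr1")
    nb = npmi_from_segregation(segB, "chr1")
    za, zb = distance_zscore(na), distance_zscore(nb)
    if boost is not None:
        # distinct tiny perturbations everywhere (no rank ties), one big boost
        noise = rng.normal(scale=1e-3, size=(n, n))
        noise = (noise + noise.T) / 2
        za.values = za.values + noise
        i, j = boost
        za.values[i, j] = za.values[j, i] = za.values[i, j] + 3.0
    return za, zb, na, nb, segA.detection_frequency(), segB.detection_frequency()


class TestDifferentialContacts:
    def test_identical_datasets_give_empty_sets(self, rng):
        za, zb, na, nb, fa, fb = _diff_inputs(rng)
        with pytest.warns(UserWarning, match="identically zero"):
            result = differential_contacts(za, zb, na, nb, fa, fb,
                                           d_min=100_000, d_max=900_000)
        assert result.contacts.empty

    def test_boosted_pair_ranks_first(self, rng):
        za, zb, na, nb, fa, fb = _diff_inputs(rng, boost=(4, 12))
        result = differential_contacts(za, zb, na, nb, fa, fb,
                                       d_min=100_000, d_max=900_000, npmi_floor=-1.0)
        top_a = result.contacts[result.contacts["direction"] == "A"].iloc[0]
        assert (top_a["i"], top_a["j"]) == (4, 12)

    def test_top_set_size_is_ceil_quantile(self, rng):
        za, zb, na, nb, fa, fb = _diff_inputs(rng, boost=(4, 12))
        result = differential_contacts(za, zb, na, nb, fa, fb,
                                       d_min=100_000, d_max=900_000, quantile=0.05, npmi_floor=-1.0)
        expected = math.ceil(0.05 * result.n_filtered_pairs)
        assert (result.contacts["direction"] == "A").sum() == expected
        assert (result.contacts["direction"] == "B").sum() == expected

    def test_swapping_datasets_negates_d_and_swaps_sets(self, rng):
        za, zb, na, nb, fa, fb = _diff_inputs(rng, boost=(4, 12))
        fwd = differential_contacts(za, zb, na, nb, fa, fb,
                                    d_min=100_000, d_max=900_000, npmi_floor=-1.0)
        rev = differential_contacts(zb, za, nb, na, fb, fa,
                                    d_min=100_000, d_max=900_000, npmi_floor=-1.0)
        fwd_a = fwd.contacts[fwd.contacts["direction"] == "A"]
        rev_b = rev.contacts[rev.contacts["direction"] == "B"]
        assert set(zip(fwd_a["i"], fwd_a["j"])) == set(zip(rev_b["i"], rev_b["j"]))
        merged = fwd.contacts.merge(rev.contacts, on=["i", "j"], suffixes=("_f", "_r"))
        assert np.allclose(merged["D_f"], -merged["D_r"])

    def test_bin_size_mismatch_is_error(self, rng):
        za, zb, na, nb, fa, fb = _diff_inputs(rng)
        zb.bin_size = 250_000
        with pytest.raises(ValueError, match="mismatch"):
            differential_contacts(za, zb, na, nb, fa, fb)

    def test_low_detection_filter_uses_second_percentile(self):
        freq = np.array([0.0, 0.001, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        bad = low_detection_windows(freq, 2.0)
        assert bad[0] and bad[1]
        assert not bad[2:].any()


class TestAggregatePileup:
    def _z(self, values):
        return ZScoreMatrix("chr1", 50_000, np.asarray(values, dtype=float))

    def test_constant_matrix(self):
        z = self._z(np.full((20, 20), 1.7))
        contacts = pd.DataFrame(dict(chrom=["chr1"], i=[8], j=[12]))
        assert aggregate_pileup({"chr1": z}, contacts) == pytest.approx(1.7)

    def test_single_hot_cell(self):
        v = np.zeros((30, 30))
        v[10, 20] = 9.0
        contacts = pd.DataFrame(dict(chrom=["chr1"], i=[10], j=[20]))
        assert aggregate_pileup({"chr1": self._z(v)}, contacts, radius=4) == (
            pytest.approx(9 / 81))

    def test_chromosomes_averaged(self):
        za = self._z(np.full((20, 20), 2.0))
        zb = self._z(np.full((20, 20), 4.0))
        contacts = pd.DataFrame(dict(chrom=["chr1", "chr2"], i=[8, 8], j=[12, 12]))
        assert aggregate_pileup({"chr1": za, "chr2": zb}, contacts) == pytest.approx(3.0)

    def test_edge_patch_truncated(self):
        v = np.zeros((10, 10))
        v[0, 9] = 5.0
        contacts = pd.DataFrame(dict(chrom=["chr1"], i=[0], j=[9]))
        # patch rows 0..4, cols 5..9 -> 25 cells
        assert aggregate_pileup({"chr1": self._z(v)}, contacts, radius=4) == (
            pytest.approx(5 / 25))
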