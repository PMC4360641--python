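"""ROH detection, LD pruning and permutation burden testing."""

import numpy as np
import pandas as pd
import pytest

from trioexome._types import ROHParams, ROHSegment
from trioexome.roh import (
    detect_roh,
    detect_roh_cohort,
    ld_prune,
    read_bed_intervals,
    roh_burden_association,
    segments_to_bed,
)

SMALL = ROHParams(min_length_bp=1000, window_snps=5, max_het_per_window=1,
                  max_missing_per_window=1, min_snps=5, prune_r2=0.9,
                  prune_window=5)


# ---------------------------------------------------------------- pruning

def test_ld_prune_drops_duplicate_snp():
    rng = np.random.default_rng(0)
    x = rng.binomial(2, 0.4, 200)
    y = rng.binomial(2, 0.4, 200)
    dosages = np.vstack([x, x, y])  # row 1 is a perfect copy of row 0
    kept = ld_prune(dosages, SMALL)
    assert kept.tolist() == [0, 2]


def test_ld_prune_keeps_independent_snps():
    rng = np.random.default_rng(1)
    dosages = rng.binomial(2, 0.4, size=(20, 500))
    kept = ld_prune(dosages, SMALL)
    assert kept.tolist() == list(range(20))  # independent draws: r^2 ~ 0


def test_ld_prune_window_limit():
    """A perfect copy outside the pruning window is not removed."""
    rng = np.random.default_rng(2)
    x = rng.binomial(2, 0.4, 200)
    fillers = rng.binomial(2, 0.4, size=(5, 200))
    dosages = np.vstack([x, *fillers, x])  # copies 6 apart, window 5
    kept = ld_prune(dosages, SMALL)
    assert kept.tolist() == list(range(7))


def test_ld_prune_monomorphic_kept():
    dosages = np.vstack([np.zeros(50), np.zeros(50)])
    assert ld_prune(dosages, SMALL).tolist() == [0, 1]


# --------------------------------------------------------------- detection

def test_detect_roh_simple_run():
    n = 30
    dosages = np.zeros(n, dtype=int)
    positions = np.arange(n) * 100 + 1
    segs = detect_roh(dosages, positions, "1", "S1", SMALL)
    assert len(segs) == 1
    s = segs[0]
    assert (s.start, s.end, s.n_snps) == (1, 2901, 30)


def test_detect_roh_het_cluster_splits_run():
    """Every 5-SNP window covering marker 12 holds >=2 hets, so the run splits
    there; single isolated hets are tolerated per window."""
    dosages = np.zeros(30, dtype=int)
    dosages[[10, 12, 14]] = 1
    positions = np.arange(30) * 100 + 1
    segs = detect_roh(dosages, positions, "1", "S1", SMALL)
    assert [(s.start, s.end) for s in segs] == [(1, 1101), (1301, 2901)]
    assert all(not (s.start <= 1201 <= s.end) for s in segs)


def test_detect_roh_min_length_filter():
    dosages = np.zeros(10, dtype=int)
    positions = np.arange(10) * 10 + 1  # spans 91 bp < 1000
    assert detect_roh(dosages, positions, "1", "S1", SMALL) == []


def test_detect_roh_short_input():
    assert detect_roh(np.zeros(3, dtype=int), np.array([1, 2, 3]), "1", "S", SMALL) == []


def test_detect_roh_unsorted_errors():
    with pytest.raises(ValueError, match="sorted"):
        detect_roh(np.zeros(6, dtype=int), np.array([1, 5, 3, 7, 9, 11]), "1", "S", SMALL)


def test_detect_roh_missing_tolerance():
    dosages = np.zeros(30, dtype=int)
    dosages[15] = -1  # one missing call allowed per window
    positions = np.arange(30) * 100 + 1
    segs = detect_roh(dosages, positions, "1", "S1", SMALL)
    assert len(segs) == 1 and segs[0].n_snps == 30


def test_detect_roh_cohort_per_chrom():
    dosages = np.zeros((20, 2), dtype=int)
    dosages[:, 1] = 1  # sample 2 is all-het: no ROH
    positions = np.concatenate([np.arange(10) * 200 + 1, np.arange(10) * 200 + 1])
    chroms = np.array(["1"] * 10 + ["2"] * 10)
    segs = detect_roh_cohort(dosages, positions, chroms, ["A", "B"], SMALL)
    assert {(s.sample_id, s.chrom) for s in segs} == {("A", "1"), ("A", "2")}


def test_bed_round_trip(tmp_path):
    segs = [ROHSegment(sample_id="A", chrom="5", start=1001, end=5000, n_snps=120)]
    p = tmp_path / "r.bed"
    segments_to_bed(segs, p)
    assert p.read_text() == "5\t1000\t5000\tA\t120\n"
    df = read_bed_intervals(p)
    assert df.loc[0, "start"] == 1001 and df.loc[0, "end"] == 5000


# ----------------------------------------------------------------- burden

def _seg(sample, start=1_000_000, end=4_000_000, chrom="1"):
    return ROHSegment(sample_id=sample, chrom=chrom, start=start, end=end, n_snps=200)


def test_burden_enriched_cases():
    samples = [f"S{i}" for i in range(12)]
    labels = [1] * 6 + [0] * 6
    segments = [_seg(s) for s in samples[:6]]  # every case, no control
    res = roh_burden_association(segments, samples, labels, n_perm=2000, seed=3)
    # only 1/C(12,6) label assignments put all six segments in cases
    assert res.burden_p["n_segments"] < 0.01
    assert res.burden_observed["n_segments"] == pytest.approx(1.0)
    assert res.per_locus.loc[0, "corrected_p"] < 0.01
    assert res.per_locus.loc[0, "case_coverage"] == 1.0


def test_burden_exchangeable_null():
    """With symmetric burden the one-sided p cannot be small."""
    samples = [f"S{i}" for i in range(10)]
    labels = [1] * 5 + [0] * 5
    segments = [_seg(s) for s in samples]  # identical burden everywhere
    res = roh_burden_association(segments, samples, labels, n_perm=500, seed=1)
    assert res.burden_p["total_length"] == 1.0


def test_burden_deterministic_given_seed():
    samples = [f"S{i}" for i in range(8)]
    labels = [1, 1, 1, 1, 0, 0, 0, 0]
    segments = [_seg(s) for s in samples[:3]]
    a = roh_burden_association(segments, samples, labels, n_perm=300, seed=9)
    b = roh_burden_association(segments, samples, labels, n_perm=300, seed=9)
    assert a.burden_p == b.burden_p
    assert a.per_locus.equals(b.per_locus)


def test_burden_genes_spanned():
    intervals = pd.DataFrame(
        {"chrom": ["1", "1", "2"], "start": [1_500_000, 10_000_000, 1],
         "end": [2_000_000, 11_000_000, 100], "name": ["G1", "G2", "G3"]}
    )
    samples = ["A", "B"]
    res = roh_burden_association([_seg("A")], samples, [1, 0], n_perm=10,
                                 seed=0, intervals=intervals)
    # segment 1:1,000,000-4,000,000 overlaps only G1
    assert res.burden_observed["genes_spanned"] == pytest.approx(1.0)


def test_burden_requires_both_groups():
    with pytest.raises(ValueError):
        roh_burden_association([], ["A", "B"], [1, 1], n_perm=10)


def test_burden_p_never_zero():
    samples = [f"S{i}" for i in range(6)]
    res = roh_burden_association([_seg(samples[0])], samples, [1, 1, 1, 0, 0, 0],
                                 n_perm=100, seed=4)
    assert all(p >= 1 / 101 for p in res.burden_p.values())
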