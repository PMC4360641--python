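"""Runs-of-homozygosity detection and case/control permutation burden testing.

Detection follows the classic sliding-window scheme: windows of
``window_snps`` consecutive markers are flagged homozygous when they contain
at most ``max_het_per_window`` heterozygous and ``max_missing_per_window``
missing calls; maximal stretches of markers covered by at least one flagged
window become segments, kept if they span at least ``min_length_bp`` and
``min_snps`` markers.  Before detection, markers in strong local linkage
disequilibrium (r^2 above ``prune_r2`` within a ``prune_window``-SNP window)
are removed so segment SNP counts reflect independent information.

The burden/association analysis codes segments as intervals and compares
cases against controls by label permutation: per-sample burden statistics
(segment count, total length, genes spanned) use a one-sided
case-minus-control mean difference; per-locus association p-values are
corrected genome-wide with the permutation max-statistic distribution.
Empirical p-values are (b + 1) / (n_perm + 1), so no p-value is ever zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._types import ROHParams, ROHSegment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(
    dosages: np.ndarray, params: Optional[ROHParams] = None
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of kept SNPs.

    ``dosages`` is (n_snps, n_samples) with -1 for missing.  For each SNP,
    the squared genotype correlation is computed against every kept SNP
    within ``prune_window`` positions to its left; the later SNP of any pair
    with r^2 above ``prune_r2`` is removed.  Monomorphic SNPs (undefined
    r^2) are kept and logged.
    """
    params = params or ROHParams()
    dosages = np.asarray(dosages, dtype=float)
    dosages = np.where(dosages < 0, np.nan, dosages)
    n_snps = dosages.shape[0]
    kept: list = []
    n_mono = 0
    for i in range(n_snps):
        x = dosages[i]
        if np.nanstd(x) == 0.0:
            n_mono += 1
            kept.append(i)
            continue
        drop = False
        for j in reversed(kept):
            if i - j >= params.prune_window:
                break
            y = dosages[j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 2:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0.0 or ys.std() == 0.0:
                continue
            r = np.corrcoef(xs, ys)[0, 1]
            if r * r > params.prune_r2:
                drop = True
                break
        if not drop:
            kept.append(i)
    if n_mono:
        logger.info("ld_prune: %d monomorphic SNPs kept (undefined r^2)", n_mono)
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# ROH detection
# ---------------------------------------------------------------------------


def detect_roh(
    dosages: np.ndarray,
    positions: np.ndarray,
    chrom: str,
    sample_id: str,
    params: Optional[ROHParams] = None,
) -> list:
    """Detect runs of homozygosity for one sample on one chromosome.

    ``dosages`` is a 1-D vector (0/1/2, -1 missing) over position-sorted
    markers.  Returns non-overlapping :class:`ROHSegment` records.
    """
    params = params or ROHParams()
    dosages = np.asarray(dosages)
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    n = len(dosages)
    w = params.window_snps
    if n < w:
        return []
    het = (dosages == 1).astype(np.int64)
    miss = (dosages < 0).astype(np.int64)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    n_windows = n - w + 1
    starts = np.arange(n_windows)
    flagged = ((ch[starts + w] - ch[starts]) <= params.max_het_per_window) & (
        (cm[starts + w] - cm[starts]) <= params.max_missing_per_window
    )
    covered = np.zeros(n, dtype=bool)
    for s in starts[flagged]:
        covered[s : s + w] = True
    segments = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and covered[j + 1]:
            j += 1
        start, end = int(positions[i]), int(positions[j])
        n_snps = j - i + 1
        if end - start + 1 >= params.min_length_bp and n_snps >= params.min_snps:
            segments.append(
                ROHSegment(sample_id=sample_id, chrom=chrom, start=start, end=end, n_snps=n_snps)
            )
        i = j + 1
    return segments


def detect_roh_cohort(
    dosages: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    samples: Sequence[str],
    params: Optional[ROHParams] = None,
) -> list:
    """Run :func:`detect_roh` per sample per chromosome over a SNP matrix."""
    params = params or ROHParams()
    segments = []
    chroms = np.asarray(chroms)
    for c in pd.unique(chroms):
        on_c = chroms == c
        pos_c = np.asarray(positions)[on_c]
        order = np.argsort(pos_c, kind="mergesort")
        for j, sid in enumerate(samples):
            segments.extend(
                detect_roh(dosages[on_c, j][order], pos_c[order], str(c), sid, params)
            )
    return segments


def segments_to_bed(segments: Sequence[ROHSegment], path) -> None:
    """Write segments as BED (0-based half-open)."""
    lines = [
        f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.sample_id}\t{s.n_snps}"
        for s in segments
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a BED interval list (e.g. gene spans) into 1-based inclusive rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]) + 1,
                    "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else "",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Burden / association permutation analysis
# ---------------------------------------------------------------------------


@dataclass
class BurdenResult:
    """Permutation burden p-values plus the per-locus association table."""

    n_perm: int
    burden_p: dict  # statistic name -> one-sided empirical p
    burden_observed: dict  # statistic name -> observed case-control difference
    per_locus: pd.DataFrame  # locus, case/control coverage, corrected p


def _per_sample_burden(
    segments: Sequence[ROHSegment],
    samples: Sequence[str],
    intervals: Optional[pd.DataFrame],
) -> pd.DataFrame:
    idx = {s: k for k, s in enumerate(samples)}
    count = np.zeros(len(samples))
    length = np.zeros(len(samples))
    genes = np.zeros(len(samples))
    for seg in segments:
        k = idx[seg.sample_id]
        count[k] += 1
        length[k] += seg.length
        if intervals is not None and len(intervals):
            hit = (
                (intervals["chrom"] == seg.chrom)
                & (intervals["start"] <= seg.end)
                & (intervals["end"] >= seg.start)
            )
            genes[k] += int(hit.sum())
    return pd.DataFrame(
        {"sample_id": list(samples), "n_segments": count, "total_length": length, "genes_spanned": genes}
    )


def roh_burden_association(
    segments: Sequence[ROHSegment],
    samples: Sequence[str],
    labels: Sequence[int],
    n_perm: int = 100_000,
    seed: int = 0,
    intervals: Optional[pd.DataFrame] = None,
) -> BurdenResult:
    """Case/control ROH burden and locus association by label permutation.

    ``labels`` holds 1 for cases and 0 for controls.  Burden statistics are
    one-sided (cases exceeding controls).  Per-locus coverage is evaluated
    on the atomic intervals induced by segment breakpoints; the genome-wide
    corrected p-value for each locus compares its observed statistic with
    the permutation distribution of the maximum statistic over all loci.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both cases and controls")
    rng = np.random.default_rng(seed)
    n_cases = int(labels.sum())
    n_controls = len(labels) - n_cases

    burden = _per_sample_burden(segments, samples, intervals)
    stat_cols = ["n_segments", "total_length"] + (
        ["genes_spanned"] if intervals is not None else []
    )

    # per-locus coverage matrix: atomic intervals from segment breakpoints
    loci = []
    cover_rows = []
    seg_by_chrom: dict = {}
    for seg in segments:
        seg_by_chrom.setdefault(seg.chrom, []).append(seg)
    idx = {s: k for k, s in enumerate(samples)}
    for chrom in sorted(seg_by_chrom):
        segs = seg_by_chrom[chrom]
        cuts = sorted({s.start for s in segs} | {s.end + 1 for s in segs})
        for a, b in zip(cuts[:-1], cuts[1:]):
            cov = np.zeros(len(samples), dtype=bool)
            any_cover = False
            for s in segs:
                if s.start <= a and s.end >= b - 1:
                    cov[idx[s.sample_id]] = True
                    any_cover = True
            if any_cover:
                loci.append((chrom, a, b - 1))
                cover_rows.append(cov)
    cover = np.array(cover_rows, dtype=float) if cover_rows else np.zeros((0, len(samples)))

    B = burden[stat_cols].to_numpy(dtype=float)

    def burden_stats(lab: np.ndarray) -> np.ndarray:
        return B[lab].mean(axis=0) - B[~lab].mean(axis=0)

    def locus_stats(lab: np.ndarray) -> np.ndarray:
        if cover.shape[0] == 0:
            return np.zeros(0)
        return cover[:, lab].mean(axis=1) - cover[:, ~lab].mean(axis=1)

    obs_burden = burden_stats(labels)
    obs_locus = locus_stats(labels)

    exceed_burden = np.zeros(len(stat_cols), dtype=np.int64)
    exceed_locus = np.zeros(len(obs_locus), dtype=np.int64)
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        pb = burden_stats(perm_labels)
        exceed_burden += pb >= obs_burden
        if len(obs_locus):
            exceed_locus += locus_stats(perm_labels).max() >= obs_locus
    burden_p = {
        name: float((exceed_burden[k] + 1) / (n_perm + 1))
        for k, name in enumerate(stat_cols)
    }
    per_locus = pd.DataFrame(
        loci, columns=["chrom", "start", "end"]
    )
    if len(obs_locus):
        per_locus["case_coverage"] = cover[:, labels].mean(axis=1)
        per_locus["control_coverage"] = cover[:, ~labels].mean(axis=1)
        per_locus["statistic"] = obs_locus
        per_locus["corrected_p"] = (exceed_locus + 1) / (n_perm + 1)
    else:
        for c in ("case_coverage", "control_coverage", "statistic", "corrected_p"):
            per_locus[c] = pd.Series(dtype=float)
    return BurdenResult(
        n_perm=n_perm,
        burden_p=burden_p,
        burden_observed={name: float(obs_burden[k]) for k, name in enumerate(stat_cols)},
        per_locus=per_locus,
    )
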