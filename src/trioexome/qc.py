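"""Site- and sample-level quality control.

The Hardy-Weinberg test is the exact (Levene-Haldane) test rather than the
chi-square approximation: with a small number of founders the asymptotic
test is unreliable in exactly the tail the p < 1e-4 exclusion rule uses.
The two-sided p-value is the total probability of heterozygote counts whose
conditional probability (given the allele counts) does not exceed that of
the observed count.
"""

from __future__ import annotations

import logging
from math import lgamma, log
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._types import AnnotatedVariant, Consequence, GenotypeCall, QCThresholds, REPLACEMENT_CLASSES

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def dosage_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Convert an object matrix of GenotypeCall to int8 dosages (-1 missing)."""
    out = np.empty(genotypes.shape, dtype=np.int8)
    it = np.nditer(out, flags=["multi_index"], op_flags=["writeonly"])
    for x in it:
        d = genotypes[it.multi_index].dosage
        x[...] = -1 if d is None else d
    return out


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Levene-Haldane distribution).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities not exceeding that of the observed
    configuration.  Symmetric in the two homozygote counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_minor = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    # log P(h) up to a shared constant: the heterozygote-count pmf given
    # fixed allele counts is 2^h * n! / (hom_minor! h! hom_major!) * const
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * log(2.0)
        - np.array([lgamma(h + 1) for h in hets])
        - np.array([lgamma(h + 1) for h in hom_minor])
        - np.array([lgamma(h + 1) for h in hom_major])
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def apply_site_filters(
    dosages: np.ndarray,
    thresholds: QCThresholds,
    labels: Optional[np.ndarray] = None,
    founder_mask: Optional[np.ndarray] = None,
    skip_rules: Optional[set] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply call-rate, MAF, HWE and differential-missingness site filters.

    ``dosages`` is a (n_sites, n_samples) int matrix with -1 for missing
    calls (see :func:`dosage_matrix`).  ``labels`` (1 = case, 0 = control)
    enables the two-sided Fisher exact missingness test.  ``founder_mask``
    restricts the HWE test to independent individuals (in trio cohorts the
    children are not independent draws, so HWE runs on parents only).
    ``skip_rules`` names rules to omit (e.g. the candidate-variant track
    must keep rare alleles, so it skips "maf").

    Returns a kept-site boolean mask and an exclusion log recording the
    first rule that fired per excluded site.
    """
    dosages = np.asarray(dosages)
    if dosages.size == 0:
        raise ValueError("empty cohort")
    skip = skip_rules or set()
    n_sites, n_samples = dosages.shape
    missing = dosages < 0
    keep = np.ones(n_sites, dtype=bool)
    records = []

    hwe_cols = (
        np.ones(n_samples, dtype=bool) if founder_mask is None else np.asarray(founder_mask)
    )
    for i in range(n_sites):
        row = dosages[i]
        obs = row[~missing[i]]
        call_rate = len(obs) / n_samples
        if "call_rate" not in skip and call_rate < thresholds.min_call_rate:
            keep[i] = False
            records.append((i, "call_rate", call_rate, np.nan))
            continue
        if len(obs) == 0:
            keep[i] = False
            records.append((i, "call_rate", 0.0, np.nan))
            continue
        af = obs.mean() / 2.0
        maf = min(af, 1.0 - af)
        if "maf" not in skip and maf < thresholds.min_maf:
            keep[i] = False
            records.append((i, "maf", maf, np.nan))
            continue
        founders = row[hwe_cols & ~missing[i]]
        if "hwe" not in skip and len(founders):
            p_hwe = hwe_exact_test(
                int((founders == 0).sum()),
                int((founders == 1).sum()),
                int((founders == 2).sum()),
            )
            if p_hwe < thresholds.hwe_alpha:
                keep[i] = False
                records.append((i, "hwe", np.nan, p_hwe))
                continue
        if labels is not None and "missingness" not in skip:
            lab = np.asarray(labels).astype(bool)
            table = [
                [int(missing[i][lab].sum()), int((~missing[i][lab]).sum())],
                [int(missing[i][~lab].sum()), int((~missing[i][~lab]).sum())],
            ]
            _, p_miss = stats.fisher_exact(table, alternative="two-sided")
            if p_miss < thresholds.missingness_alpha:
                keep[i] = False
                records.append((i, "missingness", np.nan, p_miss))
                continue
    log = pd.DataFrame(records, columns=["site_index", "rule", "statistic", "p"])
    return keep, log


def tstv_ratio(variants: Sequence[AnnotatedVariant]) -> float:
    """Transition/transversion ratio over a variant set (SNVs only).

    Indels are skipped (count reported in the log); returns NaN when there
    are no transversions.
    """
    ts = tv = skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        if (v.ref, v.alt) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if skipped:
        logger.warning("tstv_ratio: skipped %d non-SNV records", skipped)
    if tv == 0:
        return float("nan")
    return ts / tv


def replacement_silent_ratio(variants: Sequence[AnnotatedVariant]) -> float:
    """Protein-altering over synonymous count; NaN when no synonymous variants."""
    replacement = sum(1 for v in variants if v.consequence in REPLACEMENT_CLASSES)
    silent = sum(1 for v in variants if v.consequence is Consequence.SYNONYMOUS)
    if silent == 0:
        return float("nan")
    return replacement / silent


def per_individual_ratios(
    variants: Sequence[AnnotatedVariant],
    dosages: np.ndarray,
    samples: Sequence[str],
) -> pd.DataFrame:
    """Per-individual Ts/Tv and replacement:silent ratios over carried variants."""
    rows = []
    variants = list(variants)
    for j, sid in enumerate(samples):
        carried = [v for i, v in enumerate(variants) if dosages[i, j] > 0]
        rows.append(
            {
                "sample_id": sid,
                "n_variants": len(carried),
                "tstv": tstv_ratio(carried),
                "replacement_silent": replacement_silent_ratio(carried),
            }
        )
    return pd.DataFrame(rows)
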