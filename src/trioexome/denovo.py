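"""Pedigree-aware de novo calling from genotype likelihoods, and the
Poisson model of per-trio de novo counts.

The caller computes the joint posterior over the 27 trio genotype
configurations at a biallelic site: parental genotypes carry a
Hardy-Weinberg population prior at the site's annotated MAF, transmission
allows a per-allele germline mutation with probability ``mu``, and the read
evidence enters through each member's Phred-scaled genotype likelihoods.
A de novo call is emitted when the posterior mass on configurations in
which the child carries an allele absent from both parents exceeds the
calling threshold.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._types import (
    AnnotatedVariant,
    Consequence,
    DeNovoCall,
    DeNovoPrior,
    GenotypeCall,
    PoissonFit,
    TrioPedigree,
)
from .io import parse_impact

logger = logging.getLogger(__name__)


def _transmission_tensor(mu: float) -> np.ndarray:
    """T[gf, gm, gc] = P(child genotype | parent genotypes) with mutation mu."""
    # probability a gamete from genotype g carries the alt allele
    p_alt = np.array([mu, 0.5, 1.0 - mu])
    T = np.empty((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = p_alt[gf], p_alt[gm]
            T[gf, gm, 0] = (1 - pf) * (1 - pm)
            T[gf, gm, 1] = pf * (1 - pm) + (1 - pf) * pm
            T[gf, gm, 2] = pf * pm
    return T


def _denovo_mask() -> np.ndarray:
    """Configurations where the child carries an allele absent from both parents."""
    mask = np.zeros((3, 3, 3), dtype=bool)
    for gc in range(3):
        mask[0, 0, gc] = gc >= 1  # alt allele in neither parent
        mask[2, 2, gc] = mask[2, 2, gc] or gc <= 1  # ref allele in neither parent
    return mask


_DENOVO_MASK = _denovo_mask()


def _likelihood(call: GenotypeCall) -> Optional[np.ndarray]:
    if call.pl is None:
        return None
    return np.power(10.0, -np.asarray(call.pl, dtype=float) / 10.0)


def _hwe_prior(maf: float) -> np.ndarray:
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def site_prior_maf(variant: Optional[AnnotatedVariant], prior: DeNovoPrior) -> float:
    """Population MAF for the parental prior; novel sites fall back to the
    prior's default so fully novel alleles still get a proper prior."""
    if variant is None or variant.max_maf <= 0.0:
        return prior.default_maf
    return variant.max_maf


def trio_joint_posterior(
    child: GenotypeCall,
    father: GenotypeCall,
    mother: GenotypeCall,
    maf: float,
    prior: DeNovoPrior,
) -> Optional[np.ndarray]:
    """Posterior over the 27 trio configurations, indexed [gf, gm, gc].

    Returns None (no-call) when any member lacks genotype likelihoods.
    """
    Lc, Lf, Lm = _likelihood(child), _likelihood(father), _likelihood(mother)
    if Lc is None or Lf is None or Lm is None:
        return None
    pg = _hwe_prior(maf)
    T = _transmission_tensor(prior.mu)
    joint = (
        pg[:, None, None]
        * pg[None, :, None]
        * T
        * Lf[:, None, None]
        * Lm[None, :, None]
        * Lc[None, None, :]
    )
    total = joint.sum()
    if total == 0.0:
        return None
    return joint / total


def denovo_posterior(joint: np.ndarray) -> float:
    """Posterior mass on child-carries-an-allele-absent-from-both-parents."""
    return float(joint[_DENOVO_MASK].sum())


def call_de_novo(
    variants: Sequence[AnnotatedVariant],
    genotypes: np.ndarray,
    samples: Sequence[str],
    trios: Sequence[TrioPedigree],
    prior: Optional[DeNovoPrior] = None,
    threshold: float = 0.5,
) -> list:
    """Scan the cohort and emit de novo candidates above the posterior threshold."""
    prior = prior or DeNovoPrior()
    col = {sid: j for j, sid in enumerate(samples)}
    calls = []
    T = _transmission_tensor(prior.mu)
    for i, v in enumerate(variants):
        pg = _hwe_prior(site_prior_maf(v, prior))
        outer_parents = pg[:, None] * pg[None, :]
        for trio in trios:
            child = genotypes[i, col[trio.child_id]]
            father = genotypes[i, col[trio.father_id]]
            mother = genotypes[i, col[trio.mother_id]]
            Lc, Lf, Lm = _likelihood(child), _likelihood(father), _likelihood(mother)
            if Lc is None or Lf is None or Lm is None:
                continue
            joint = (
                (outer_parents * Lf[:, None] * Lm[None, :])[:, :, None]
                * T
                * Lc[None, None, :]
            )
            total = joint.sum()
            if total == 0.0:
                continue
            post = float(joint[_DENOVO_MASK].sum() / total)
            if post > threshold:
                calls.append(
                    DeNovoCall(
                        trio_id=trio.child_id,
                        variant=v,
                        posterior=post,
                        coding=v.consequence is not Consequence.OTHER,
                        consequence=v.consequence,
                    )
                )
    return calls


def classify_coding(calls: Iterable) -> dict:
    """Tally de novo candidates by consequence class.

    Initiator-codon variants count as missense (they alter the protein
    start, reported with the missense tally); a variant annotated both
    missense and splice-site counts as splice-site.  Accepts DeNovoCall
    objects, Consequence values, or impact label strings.
    """
    counts = {"missense": 0, "splice_site": 0, "nonsense": 0, "synonymous": 0, "other": 0}
    for item in calls:
        if isinstance(item, DeNovoCall):
            csq = item.consequence
        elif isinstance(item, Consequence):
            csq = item
        else:
            csq = parse_impact(str(item))
            if csq is Consequence.OTHER:
                logger.warning("unknown consequence label %r counted as other", item)
        if csq in (Consequence.MISSENSE, Consequence.INITIATOR_CODON):
            counts["missense"] += 1
        elif csq is Consequence.SPLICE_SITE:
            counts["splice_site"] += 1
        elif csq is Consequence.NONSENSE:
            counts["nonsense"] += 1
        elif csq is Consequence.SYNONYMOUS:
            counts["synonymous"] += 1
        else:
            counts["other"] += 1
    return counts


def per_trio_counts(calls: Iterable, trios: Sequence[TrioPedigree]) -> pd.Series:
    """Count coding de novo calls per trio (zeros included)."""
    s = pd.Series(0, index=[t.child_id for t in trios], dtype=int)
    for c in calls:
        if c.trio_id in s.index:
            s[c.trio_id] += 1
    return s


def poisson_fit_test(counts: Sequence[int]) -> PoissonFit:
    """Fit per-trio event counts to a Poisson and test the fit.

    lambda-hat is the sample mean; goodness of fit is a chi-square on the
    binned counts {0, 1, >=2} against Poisson(lambda-hat) masses with one
    degree of freedom left after estimating the mean.  Counts in this regime
    rarely exceed 2, so the three bins avoid near-empty expected cells.
    """
    counts = np.asarray(list(counts), dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least two trios")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lam = counts.mean()
    if lam == 0.0:
        return PoissonFit(lambda_hat=0.0, gof_statistic=0.0, gof_p=1.0)
    n = len(counts)
    obs = np.array([(counts == 0).sum(), (counts == 1).sum(), (counts >= 2).sum()])
    p0 = np.exp(-lam)
    p1 = lam * p0
    expected = n * np.array([p0, p1, max(1.0 - p0 - p1, 1e-300)])
    stat = float((((obs - expected) ** 2) / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return PoissonFit(lambda_hat=float(lam), gof_statistic=stat, gof_p=max(p, np.finfo(float).tiny))
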