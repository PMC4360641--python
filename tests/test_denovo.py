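"""De novo posterior against an independent brute-force oracle."""

import itertools
import math

import numpy as np
import pytest

from trioexome._types import (
    AnnotatedVariant,
    Consequence,
    DeNovoCall,
    DeNovoPrior,
    GenotypeCall,
    TrioPedigree,
)
from trioexome.denovo import (
    call_de_novo,
    classify_coding,
    denovo_posterior,
    per_trio_counts,
    poisson_fit_test,
    site_prior_maf,
    trio_joint_posterior,
)


def brute_posterior(pl_c, pl_f, pl_m, maf, mu):
    """Scalar-loop re-derivation of the 27-configuration de novo posterior."""
    def lik(pl):
        return [10.0 ** (-x / 10.0) for x in pl]

    def gamete(g):
        # P(gamete carries alt | genotype), with per-allele mutation mu
        return [mu, 0.5, 1.0 - mu][g]

    prior = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2]
    Lc, Lf, Lm = lik(pl_c), lik(pl_f), lik(pl_m)
    total = denovo = 0.0
    for gf, gm, gc in itertools.product(range(3), repeat=3):
        pf, pm = gamete(gf), gamete(gm)
        trans = [
            (1 - pf) * (1 - pm),
            pf * (1 - pm) + (1 - pf) * pm,
            pf * pm,
        ][gc]
        w = prior[gf] * prior[gm] * trans * Lf[gf] * Lm[gm] * Lc[gc]
        total += w
        child_has_novel = (gf == 0 and gm == 0 and gc >= 1) or (
            gf == 2 and gm == 2 and gc <= 1
        )
        if child_has_novel:
            denovo += w
    return denovo / total


def _call(pl, gt=(0, 0)):
    return GenotypeCall(allele_a=gt[0], allele_b=gt[1], pl=tuple(pl))


PRIOR = DeNovoPrior()


def test_posterior_matches_brute_force_random():
    rng = np.random.default_rng(8)
    for _ in range(1000):
        pls = [
            tuple(int(x) for x in rng.integers(0, 80, 3) * (rng.random(3) < 0.9))
            for _ in range(3)
        ]
        # normalize so min PL is 0 as emitted by callers
        pls = [tuple(int(v - min(p)) for v in p) for p in pls]
        maf = float(rng.uniform(1e-5, 0.4))
        joint = trio_joint_posterior(_call(pls[0]), _call(pls[1]), _call(pls[2]),
                                     maf, PRIOR)
        got = denovo_posterior(joint)
        want = brute_posterior(pls[0], pls[1], pls[2], maf, PRIOR.mu)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-15)


def test_posterior_normalizes():
    joint = trio_joint_posterior(_call((40, 0, 40)), _call((0, 40, 80)),
                                 _call((0, 40, 80)), 1e-4, PRIOR)
    assert joint.sum() == pytest.approx(1.0, rel=1e-12)


def test_confident_denovo_high_posterior():
    # child clearly het, both parents clearly hom-ref at a novel site;
    # child evidence must exceed the ~2*mu prior penalty (PL 120 ~ 1e-12)
    joint = trio_joint_posterior(
        _call((120, 0, 120)), _call((0, 120, 240)), _call((0, 120, 240)),
        PRIOR.default_maf, PRIOR,
    )
    assert denovo_posterior(joint) > 0.99


def test_inherited_het_low_posterior():
    joint = trio_joint_posterior(
        _call((90, 0, 90)), _call((90, 0, 90)), _call((0, 90, 180)),
        0.01, PRIOR,
    )
    assert denovo_posterior(joint) < 1e-3


def test_uniform_likelihoods_recover_prior():
    """Flat PLs leave the posterior equal to the model prior of a de novo
    configuration, which at mu=1e-8 is tiny."""
    flat = _call((0, 0, 0))
    joint = trio_joint_posterior(flat, flat, flat, 1e-4, PRIOR)
    assert denovo_posterior(joint) < 1e-6


def test_mu_zero_gives_zero_posterior():
    joint = trio_joint_posterior(
        _call((90, 0, 90)), _call((0, 90, 180)), _call((0, 90, 180)),
        1e-4, DeNovoPrior(mu=0.0),
    )
    assert denovo_posterior(joint) == 0.0


def test_missing_pl_is_no_call():
    nopl = GenotypeCall(allele_a=0, allele_b=0)
    assert trio_joint_posterior(_call((40, 0, 40)), nopl, _call((0, 40, 80)),
                                1e-4, PRIOR) is None


def test_posterior_decreases_with_maf():
    """A higher population MAF makes the inherited explanation more likely."""
    args = (_call((60, 0, 60)), _call((0, 30, 60)), _call((0, 90, 180)))
    post = [
        denovo_posterior(trio_joint_posterior(*args, maf, PRIOR))
        for maf in (1e-5, 1e-3, 1e-1)
    ]
    assert post[0] > post[1] > post[2]


def test_site_prior_maf_fallback():
    novel = AnnotatedVariant(chrom="1", pos=1, ref="A", alt="G")
    known = AnnotatedVariant(chrom="1", pos=1, ref="A", alt="G", maf_esp=0.01)
    assert site_prior_maf(novel, PRIOR) == PRIOR.default_maf
    assert site_prior_maf(None, PRIOR) == PRIOR.default_maf
    assert site_prior_maf(known, PRIOR) == 0.01


def test_call_de_novo_threshold():
    v = AnnotatedVariant(chrom="1", pos=100, ref="A", alt="G", gene="X",
                         consequence=Consequence.MISSENSE)
    trio = TrioPedigree(family_id="F", child_id="C1", father_id="F1", mother_id="M1")
    genotypes = np.empty((1, 3), dtype=object)
    genotypes[0, 0] = _call((120, 0, 120), gt=(0, 1))
    genotypes[0, 1] = _call((0, 120, 240))
    genotypes[0, 2] = _call((0, 120, 240))
    calls = call_de_novo([v], genotypes, ["C1", "F1", "M1"], [trio])
    assert len(calls) == 1 and calls[0].posterior > 0.99
    # an impossible threshold suppresses the call
    assert call_de_novo([v], genotypes, ["C1", "F1", "M1"], [trio],
                        threshold=1.0) == []


def test_classify_coding_labels():
    counts = classify_coding([
        "Missense", "missense, splice site", "Initiator codon", "Nonsense",
        Consequence.SYNONYMOUS,
    ])
    assert counts == {"missense": 2, "splice_site": 1, "nonsense": 1,
                      "synonymous": 1, "other": 0}


def test_per_trio_counts_includes_zeros():
    trios = [
        TrioPedigree(family_id=f"F{i}", child_id=f"C{i}", father_id=f"F{i}a",
                     mother_id=f"M{i}") for i in range(3)
    ]
    v = AnnotatedVariant(chrom="1", pos=1, ref="A", alt="G")
    calls = [DeNovoCall(trio_id="C0", variant=v, posterior=0.9, coding=True,
                        consequence=Consequence.MISSENSE)] * 2
    s = per_trio_counts(calls, trios)
    assert s.tolist() == [2, 0, 0]


def test_poisson_fit_oracle():
    # 44 trios, counts matching lambda-hat 17/44
    counts = [0] * 30 + [1] * 11 + [2] * 3
    fit = poisson_fit_test(counts)
    lam = 17 / 44
    assert fit.lambda_hat == pytest.approx(lam)
    p0, p1 = math.exp(-lam), lam * math.exp(-lam)
    expected = 44 * np.array([p0, p1, 1 - p0 - p1])
    stat = (((np.array([30, 11, 3]) - expected) ** 2) / expected).sum()
    assert fit.gof_statistic == pytest.approx(stat, rel=1e-12)


def test_poisson_trivial_cases():
    fit = poisson_fit_test([0, 0, 0, 0])
    assert fit.lambda_hat == 0.0 and fit.gof_p == 1.0
    with pytest.raises(ValueError):
        poisson_fit_test([1])
    with pytest.raises(ValueError):
        poisson_fit_test([1, -1])
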