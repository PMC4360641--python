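"""Phasing and Mendelian classification against hand-worked oracles."""

import itertools

import pytest

from trioexome._types import (
    AnnotatedVariant,
    Consequence,
    FilterPolicy,
    GenotypeCall,
    InheritanceClass,
)
from trioexome.inheritance import (
    classify_homozygous_recessive,
    estimate_carrier_rate,
    find_compound_hets,
    intersect_known_genes,
    phase_trio,
    variant_passes,
)


def G(a, b):
    return GenotypeCall(allele_a=a, allele_b=b)


# ---------------------------------------------------------------- phasing

def test_phase_table_exhaustive():
    """Brute-force oracle: enumerate ordered parental transmissions and compare."""
    genos = [(0, 0), (0, 1), (1, 1)]
    for (c, f, m) in itertools.product(genos, repeat=3):
        ph = phase_trio(G(*c), G(*f), G(*m))
        assignments = {
            (pa, ma)
            for pa in set(f)
            for ma in set(m)
            if tuple(sorted((pa, ma))) == tuple(sorted(c))
        }
        if not assignments:
            assert not ph.mendelian_consistent
        elif len(assignments) == 1:
            pa, ma = next(iter(assignments))
            assert ph.mendelian_consistent
            assert (ph.paternal_allele, ph.maternal_allele) == (pa, ma)
        else:
            assert ph.mendelian_consistent
            assert ph.paternal_allele is None and ph.maternal_allele is None


def test_triple_het_is_ambiguous():
    ph = phase_trio(G(0, 1), G(0, 1), G(0, 1))
    assert ph.mendelian_consistent and ph.paternal_allele is None


def test_missing_child_genotype_propagates():
    assert phase_trio(GenotypeCall(allele_a=None, allele_b=None), G(0, 1), G(0, 0)) is None


def test_missing_parent_genotype_is_ambiguous():
    ph = phase_trio(G(0, 1), GenotypeCall(allele_a=None, allele_b=None), G(0, 0))
    assert ph.mendelian_consistent and ph.paternal_allele is None


# ------------------------------------------------- homozygous recessive

def _tf_variant():
    return AnnotatedVariant(
        chrom="3", pos=133496032, ref="G", alt="A", gene="TF",
        consequence=Consequence.MISSENSE, maf_esp=0.003691, maf_1kg=0.0032,
        damage_scores={"sift": 0.0, "pph2": 0.999}, conserved=True,
    )


def test_hom_recessive_positive():
    call = classify_homozygous_recessive(
        "#30", G(1, 1), G(0, 1), G(0, 1), _tf_variant(), FilterPolicy()
    )
    assert call is not None
    assert call.klass is InheritanceClass.HOM_RECESSIVE
    assert call.gene == "TF" and call.trio_id == "#30"
    assert "maf" in call.filter_provenance


@pytest.mark.parametrize(
    "child,father,mother",
    [
        (G(0, 1), G(0, 1), G(0, 1)),  # child het
        (G(1, 1), G(1, 1), G(0, 1)),  # homozygous parent
        (G(1, 1), G(0, 0), G(0, 1)),  # Mendelian violation
    ],
)
def test_hom_recessive_negative(child, father, mother):
    assert classify_homozygous_recessive(
        "#30", child, father, mother, _tf_variant(), FilterPolicy()
    ) is None


def test_hom_recessive_maf_filter():
    common = AnnotatedVariant(
        chrom="3", pos=1, ref="G", alt="A", gene="TF",
        consequence=Consequence.MISSENSE, maf_esp=0.05, maf_1kg=0.02,
    )
    assert classify_homozygous_recessive(
        "#30", G(1, 1), G(0, 1), G(0, 1), common, FilterPolicy()
    ) is None


def test_hom_recessive_not_on_x():
    v = _tf_variant()
    v = AnnotatedVariant(chrom="X", pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
                         consequence=v.consequence, maf_esp=v.maf_esp, maf_1kg=v.maf_1kg,
                         damage_scores=v.damage_scores, conserved=v.conserved)
    assert classify_homozygous_recessive(
        "#30", G(1, 1), G(0, 1), G(0, 1), v, FilterPolicy()
    ) is None


def test_variant_passes_missing_maf_treated_rare():
    novel = AnnotatedVariant(chrom="1", pos=1, ref="A", alt="G", gene="X",
                             consequence=Consequence.NONSENSE)
    provenance = variant_passes(novel, FilterPolicy())
    assert provenance and "maf" in provenance


# ------------------------------------------------------ compound hets

def _gene_variant(pos, gene="ABCA2"):
    return AnnotatedVariant(
        chrom="9", pos=pos, ref="C", alt="T", gene=gene,
        consequence=Consequence.MISSENSE, maf_esp=0.001, maf_1kg=0.001,
        damage_scores={"sift": 0.0, "pph2": 0.99}, conserved=True,
    )


def _phase_all(child, father, mother):
    return [phase_trio(c, f, m) for c, f, m in zip(child, father, mother)]


def test_comp_het_pair_opposite_origins():
    v1, v2 = _gene_variant(100), _gene_variant(200)
    phased = _phase_all(
        [G(0, 1), G(0, 1)],
        [G(0, 1), G(0, 0)],   # v1 paternal
        [G(0, 0), G(0, 1)],   # v2 maternal
    )
    calls = find_compound_hets("#13", [v1, v2], phased, FilterPolicy())
    assert len(calls) == 1
    call = calls[0]
    assert call.klass is InheritanceClass.COMP_HET
    assert call.variants == (v1, v2)  # paternal first
    assert call.phase_assumed is False


def test_comp_het_same_parent_rejected():
    v1, v2 = _gene_variant(100), _gene_variant(200)
    phased = _phase_all(
        [G(0, 1), G(0, 1)],
        [G(0, 1), G(0, 1)],
        [G(0, 0), G(0, 0)],
    )
    assert find_compound_hets("#13", [v1, v2], phased, FilterPolicy()) == []


def test_comp_het_two_ambiguous_rejected():
    v1, v2 = _gene_variant(100), _gene_variant(200)
    phased = _phase_all(
        [G(0, 1), G(0, 1)],
        [G(0, 1), G(0, 1)],   # both triple het -> both ambiguous
        [G(0, 1), G(0, 1)],
    )
    assert find_compound_hets("#13", [v1, v2], phased, FilterPolicy()) == []


def test_comp_het_ambiguous_plus_definite_is_phase_assumed():
    v1, v2 = _gene_variant(100), _gene_variant(200)
    phased = _phase_all(
        [G(0, 1), G(0, 1)],
        [G(0, 1), G(0, 1)],   # v1 triple het: ambiguous; v2 paternal
        [G(0, 1), G(0, 0)],
    )
    calls = find_compound_hets("#13", [v1, v2], phased, FilterPolicy())
    assert len(calls) == 1 and calls[0].phase_assumed is True
    assert calls[0].variants == (v2, v1)  # definite paternal variant first


def test_three_variants_two_pairs():
    """Three hets (two paternal, one maternal) form exactly two cross pairs."""
    vs = [_gene_variant(p) for p in (100, 200, 300)]
    phased = _phase_all(
        [G(0, 1)] * 3,
        [G(0, 1), G(0, 1), G(0, 0)],
        [G(0, 0), G(0, 0), G(0, 1)],
    )
    calls = find_compound_hets("#13", vs, phased, FilterPolicy())
    assert len(calls) == 2
    assert {tuple(v.pos for v in c.variants) for c in calls} == {(100, 300), (200, 300)}


def test_comp_het_different_genes_never_paired():
    v1 = _gene_variant(100, gene="A")
    v2 = _gene_variant(200, gene="B")
    phased = _phase_all(
        [G(0, 1), G(0, 1)],
        [G(0, 1), G(0, 0)],
        [G(0, 0), G(0, 1)],
    )
    assert find_compound_hets("#13", [v1, v2], phased, FilterPolicy()) == []


def test_comp_het_input_order_invariant():
    v1, v2 = _gene_variant(100), _gene_variant(200)
    child, father, mother = (
        [G(0, 1), G(0, 1)], [G(0, 1), G(0, 0)], [G(0, 0), G(0, 1)]
    )
    fwd = find_compound_hets("#13", [v1, v2], _phase_all(child, father, mother),
                             FilterPolicy())
    rev = find_compound_hets("#13", [v2, v1],
                             _phase_all(child[::-1], father[::-1], mother[::-1]),
                             FilterPolicy())
    assert fwd == rev


# ------------------------------------------------------- misc helpers

def test_carrier_rate_closed_form():
    # q_hom = 1e-4 -> q = 0.01 -> carrier rate 2*0.01*0.99
    assert estimate_carrier_rate(1e-4) == pytest.approx(2 * 0.01 * 0.99)
    with pytest.raises(ValueError):
        estimate_carrier_rate(0.0)
    with pytest.raises(ValueError):
        estimate_carrier_rate(1.0)


def test_intersect_known_genes():
    calls = [
        classify_homozygous_recessive(
            "#30", G(1, 1), G(0, 1), G(0, 1), _tf_variant(), FilterPolicy()
        ),
        classify_homozygous_recessive(
            "#07", G(1, 1), G(0, 1), G(0, 1), _gene_variant(100), FilterPolicy()
        ),
    ]
    flagged, counts = intersect_known_genes(calls, ["tf", "SOD1"])
    assert counts == {"TF": 1}
    assert flagged[0].known_gene is True and flagged[1].known_gene is False
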