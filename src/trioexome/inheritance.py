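"""Recessive-candidate detection: trio phasing, homozygous-recessive and
compound-heterozygote classification, damage filtering, carrier-rate algebra.

Phasing is deterministic single-site transmission logic: the parental origin
of each child allele is assigned whenever Mendelian transmission forces it.
The one unresolvable biallelic case is the triple heterozygote (child and
both parents 0/1), which is marked ambiguous.  For compound-het detection an
ambiguous-phase variant may pair only with a variant of definite opposite
origin; such pairs are reported in a lower-confidence "phase-assumed" tier.
"""

from __future__ import annotations

from collections import Counter
from itertools import product
from math import sqrt
from typing import Iterable, Optional, Sequence

from ._types import (
    AMBIGUOUS,
    AnnotatedVariant,
    Consequence,
    FilterPolicy,
    GenotypeCall,
    InheritanceCall,
    InheritanceClass,
    PhasedTrioGenotype,
)

_AUTOSOMES = {str(c) for c in range(1, 23)} | {f"chr{c}" for c in range(1, 23)}

_LOF = frozenset({Consequence.NONSENSE, Consequence.SPLICE_SITE})


def is_autosomal(chrom: str) -> bool:
    return chrom in _AUTOSOMES


def phase_trio(
    child: GenotypeCall, father: GenotypeCall, mother: GenotypeCall
) -> Optional[PhasedTrioGenotype]:
    """Assign parental origin to the child's alleles at one biallelic site.

    Returns None when the child genotype is missing.  Mendelian violations
    are flagged (``mendelian_consistent=False``) and left unphased.
    """
    if child.is_missing:
        return None
    if father.is_missing or mother.is_missing:
        # cannot certify transmission without both parents
        return PhasedTrioGenotype(AMBIGUOUS, AMBIGUOUS, mendelian_consistent=True)

    c = {child.allele_a, child.allele_b}
    f = {father.allele_a, father.allele_b}
    m = {mother.allele_a, mother.allele_b}

    # enumerate transmissions consistent with the child genotype
    assignments = {
        (pa, ma)
        for pa, ma in product(f, m)
        if {pa, ma} == c or (pa == ma and c == {pa})
    }
    if not assignments:
        return PhasedTrioGenotype(AMBIGUOUS, AMBIGUOUS, mendelian_consistent=False)
    if len(assignments) == 1:
        pa, ma = next(iter(assignments))
        return PhasedTrioGenotype(pa, ma, mendelian_consistent=True)
    return PhasedTrioGenotype(AMBIGUOUS, AMBIGUOUS, mendelian_consistent=True)


def _passes_rarity(v: AnnotatedVariant, policy: FilterPolicy) -> bool:
    # max of the reported panel MAFs; never-reported treated as rare (0)
    return v.max_maf < policy.max_maf


def _passes_consequence(v: AnnotatedVariant, policy: FilterPolicy) -> bool:
    return v.consequence in policy.allowed_consequences


def _passes_damage(v: AnnotatedVariant, policy: FilterPolicy) -> bool:
    if not policy.require_damaging:
        return True
    if v.consequence in _LOF:
        return True  # loss of function bypasses the score rules
    sift = v.damage_scores.get("sift")
    pph2 = v.damage_scores.get("pph2")
    return (sift is not None and sift < policy.sift_max) or (
        pph2 is not None and pph2 >= policy.pph2_min
    )


def _passes_conservation(v: AnnotatedVariant, policy: FilterPolicy) -> bool:
    if not policy.require_conserved:
        return True
    return v.conserved is not False  # missing conservation does not exclude


def variant_passes(v: AnnotatedVariant, policy: FilterPolicy) -> list:
    """Return the list of filter rules the variant passes (empty on failure)."""
    provenance = []
    for name, fn in (
        ("maf", _passes_rarity),
        ("consequence", _passes_consequence),
        ("damage", _passes_damage),
        ("conservation", _passes_conservation),
    ):
        if not fn(v, policy):
            return []
        provenance.append(name)
    return provenance


def classify_homozygous_recessive(
    trio_id: str,
    child: GenotypeCall,
    father: GenotypeCall,
    mother: GenotypeCall,
    variant: AnnotatedVariant,
    policy: FilterPolicy,
) -> Optional[InheritanceCall]:
    """Call a homozygous-recessive candidate at one autosomal site.

    Requires child 1/1 with both parents heterozygous carriers and the
    variant passing the rarity/consequence/damage policy.  A child 1/1 with
    a non-carrier parent is a Mendelian violation, not a recessive call.
    """
    if not is_autosomal(variant.chrom):
        return None
    if not (child.is_hom_alt and father.is_het and mother.is_het):
        return None
    provenance = variant_passes(variant, policy)
    if not provenance:
        return None
    return InheritanceCall(
        trio_id=trio_id,
        variants=(variant,),
        klass=InheritanceClass.HOM_RECESSIVE,
        gene=variant.gene,
        filter_provenance=["hom_recessive"] + provenance,
    )


def find_compound_hets(
    trio_id: str,
    variants: Sequence[AnnotatedVariant],
    phased: Sequence[Optional[PhasedTrioGenotype]],
    policy: FilterPolicy,
) -> list:
    """Find compound-heterozygote pairs for one trio.

    ``variants`` and ``phased`` are aligned per site.  A pair requires two
    policy-passing heterozygous variants in the same gene with opposite
    parental origins of the alt allele; a variant of ambiguous phase may
    only partner a definite-origin variant (pair marked phase-assumed).
    Output is deterministically ordered and independent of input order.
    """
    by_gene: dict = {}
    for v, ph in zip(variants, phased):
        if ph is None or not ph.mendelian_consistent:
            continue
        if not is_autosomal(v.chrom):
            continue
        if ph.is_phased:
            if ph.paternal_allele == 1 and ph.maternal_allele == 0:
                origin = "paternal"
            elif ph.maternal_allele == 1 and ph.paternal_allele == 0:
                origin = "maternal"
            else:
                continue  # hom ref/alt: not a het carrier site
        else:
            origin = "ambiguous"
        provenance = variant_passes(v, policy)
        if not provenance:
            continue
        by_gene.setdefault(v.gene, []).append((v, origin, provenance))

    calls = []
    for gene in sorted(g for g in by_gene if g):
        entries = sorted(by_gene[gene], key=lambda e: (e[0].pos, e[0].alt))
        for i, (v1, o1, p1) in enumerate(entries):
            for v2, o2, p2 in entries[i + 1 :]:
                if {o1, o2} == {"paternal", "maternal"}:
                    assumed = False
                elif (
                    "ambiguous" in (o1, o2)
                    and {o1, o2} != {"ambiguous"}
                ):
                    assumed = True  # one definite origin, partner assumed trans
                else:
                    continue  # cis pair or two ambiguous variants
                if o1 == "maternal" or (o1 == "ambiguous" and o2 == "paternal"):
                    pair = (v2, v1)
                    prov = p2 + p1
                else:
                    pair = (v1, v2)
                    prov = p1 + p2
                calls.append(
                    InheritanceCall(
                        trio_id=trio_id,
                        variants=pair,
                        klass=InheritanceClass.COMP_HET,
                        gene=gene,
                        filter_provenance=["comp_het"] + sorted(set(prov)),
                        phase_assumed=assumed,
                    )
                )
    return calls


def apply_damage_filters(
    calls: Iterable[InheritanceCall], policy: FilterPolicy
) -> list:
    """Keep calls whose every member variant satisfies the damage and
    conservation rules of the policy."""
    kept = []
    for call in calls:
        if all(
            _passes_damage(v, policy) and _passes_conservation(v, policy)
            for v in call.variants
        ):
            kept.append(call)
    return kept


def estimate_carrier_rate(genotype_frequency: float) -> float:
    """Heterozygous-carrier fraction from a recessive genotype frequency.

    Hardy-Weinberg inversion: q = sqrt(q^2), carrier rate 2q(1-q).
    """
    if genotype_frequency <= 0 or genotype_frequency >= 1:
        raise ValueError("genotype frequency must be in (0, 1)")
    q = sqrt(genotype_frequency)
    return 2.0 * q * (1.0 - q)


def intersect_known_genes(
    calls: Sequence[InheritanceCall], gene_list: Iterable[str]
) -> tuple[list, Counter]:
    """Flag calls whose gene is in a known-susceptibility list.

    Symbols are compared case-insensitively.  Returns the calls (flags set
    in place) and a per-gene Counter of flagged calls.
    """
    known = {g.strip().upper() for g in gene_list if g.strip()}
    counts: Counter = Counter()
    for call in calls:
        hit = call.gene.upper() in known
        call.known_gene = hit
        if hit:
            counts[call.gene.upper()] += 1
    return list(calls), counts


def read_gene_list(path) -> set:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.upper())
    return out
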