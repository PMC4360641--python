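"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Consequence(enum.Enum):
    """Coding consequence class of a variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    INITIATOR_CODON = "initiator_codon"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes counted as protein-altering ("replacement") alleles.
REPLACEMENT_CLASSES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.SPLICE_SITE,
        Consequence.INITIATOR_CODON,
    }
)


@dataclass(frozen=True)
class TrioPedigree:
    """An affected child together with both unaffected parents."""

    family_id: str
    child_id: str
    father_id: str
    mother_id: str
    child_affected: bool = True

    def __post_init__(self) -> None:
        ids = {self.child_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(
                f"trio {self.family_id}: child/father/mother ids must be distinct"
            )


@dataclass(frozen=True)
class AnnotatedVariant:
    """A biallelic site with its functional annotation.

    Population minor-allele frequencies come from two reference panels
    (ESP and 1000 Genomes); either may be missing (None) for alleles never
    reported in the panel.  ``damage_scores`` maps score names (``sift``,
    ``pph2``) to values; ``conserved`` is a tri-state flag.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    maf_esp: Optional[float] = None
    maf_1kg: Optional[float] = None
    damage_scores: dict = field(default_factory=dict)
    conserved: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"{self.chrom}:{self.pos} alt equals ref")
        for maf in (self.maf_esp, self.maf_1kg):
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise ValueError(f"MAF out of [0,1]: {maf}")

    @property
    def max_maf(self) -> float:
        """Largest reported population MAF; unreported frequencies count as 0."""
        return max(self.maf_esp or 0.0, self.maf_1kg or 0.0)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid genotype call with optional quality annotations.

    ``allele_a``/``allele_b`` are allele indices (0 = ref, 1 = alt) or None
    for a missing call.  ``pl`` is the Phred-scaled likelihood triple for
    genotypes (0/0, 0/1, 1/1) with minimum entry 0.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    phased: bool = False
    gq: Optional[float] = None
    pl: Optional[tuple] = None
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pl is not None:
            if len(self.pl) != 3:
                raise ValueError("PL must have exactly 3 entries for a biallelic site")
            if min(self.pl) != 0:
                raise ValueError("normalised PL must have minimum entry 0")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None or self.allele_b is None

    @property
    def dosage(self) -> Optional[int]:
        """Count of alt alleles (0, 1 or 2), or None when missing."""
        if self.is_missing:
            return None
        return self.allele_a + self.allele_b

    @property
    def is_het(self) -> bool:
        return self.dosage == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.dosage == 0

    @property
    def is_hom_alt(self) -> bool:
        return self.dosage == 2


#: Marker used in PhasedTrioGenotype when the parental origin is unresolvable.
AMBIGUOUS = None


@dataclass(frozen=True)
class PhasedTrioGenotype:
    """Transmission phase of a child genotype at one site.

    ``paternal_allele``/``maternal_allele`` are allele indices when the
    origin is forced by Mendelian transmission and None (ambiguous) when it
    is not (the triple-heterozygote case).  Mendelian violations are flagged
    and left unphased.
    """

    paternal_allele: Optional[int]
    maternal_allele: Optional[int]
    mendelian_consistent: bool

    @property
    def is_phased(self) -> bool:
        return self.paternal_allele is not None and self.maternal_allele is not None


class InheritanceClass(enum.Enum):
    HOM_RECESSIVE = "hom_recessive"
    COMP_HET = "comp_het"
    DE_NOVO = "de_novo"


@dataclass
class InheritanceCall:
    """A classified candidate variant (or comp-het pair) in one trio.

    For compound heterozygotes ``variants`` is an ordered pair with the
    paternal-origin member first; otherwise a single-element tuple.
    ``phase_assumed`` marks comp-het pairs where one member's origin was
    ambiguous and inferred from its partner (lower confidence tier).
    """

    trio_id: str
    variants: tuple
    klass: InheritanceClass
    gene: str
    filter_provenance: list = field(default_factory=list)
    phase_assumed: bool = False
    known_gene: bool = False

    def __post_init__(self) -> None:
        n = len(self.variants)
        if self.klass is InheritanceClass.COMP_HET and n != 2:
            raise ValueError("compound-het call needs exactly two variants")
        if self.klass is not InheritanceClass.COMP_HET and n != 1:
            raise ValueError(f"{self.klass.value} call needs exactly one variant")


@dataclass(frozen=True)
class ROHSegment:
    """A run of homozygosity (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, sample SD, optional range) for one group."""

    n: int
    mean: float
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sd is not None and self.n < 2:
            raise ValueError("sd requires n >= 2")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class FilterPolicy:
    """Candidate-variant filter: rarity, consequence, deleteriousness.

    Defaults encode the rare-damaging regime: global MAF below 1 % in both
    reference panels and a protein-altering consequence.  ``sift_max`` and
    ``pph2_min`` are the tools' conventional damaging cut-offs; a
    nonsense/splice consequence bypasses the score rules.
    """

    max_maf: float = 0.01
    allowed_consequences: frozenset = REPLACEMENT_CLASSES
    require_damaging: bool = False
    require_conserved: bool = False
    sift_max: float = 0.05
    pph2_min: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.max_maf <= 1.0):
            raise ValueError("max_maf must be in (0, 1]")


@dataclass
class QCThresholds:
    """Site/sample QC cut-offs (call rate, MAF, HWE, differential missingness)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_alpha: float = 1e-4
    missingness_alpha: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha", "missingness_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class ROHParams:
    """Runs-of-homozygosity detection and LD-pruning parameters.

    The length floor (>2 Mb) and the pruning rule (r^2 > 0.9 within a
    50-SNP window) define the segment regime; window allowances follow the
    conventional sliding-window settings.
    """

    min_length_bp: int = 2_000_000
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_snps: int = 100
    prune_r2: float = 0.9
    prune_window: int = 50

    def __post_init__(self) -> None:
        for name in (
            "min_length_bp",
            "window_snps",
            "min_snps",
            "prune_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DeNovoPrior:
    """Per-site, per-gamete germline mutation probability for the trio caller."""

    mu: float = 1e-8
    #: HWE prior MAF used for sites whose annotated population MAF is missing.
    default_maf: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu < 1.0):
            raise ValueError("mu must be in [0, 1)")


@dataclass(frozen=True)
class DeNovoCall:
    """An emitted de novo candidate with its posterior probability."""

    trio_id: str
    variant: AnnotatedVariant
    posterior: float
    coding: bool = True
    consequence: Consequence = Consequence.OTHER


@dataclass(frozen=True)
class PoissonFit:
    """Poisson fit of per-trio event counts with a goodness-of-fit test."""

    lambda_hat: float
    gof_statistic: float
    gof_p: float
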