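"""Synthetic trio-cohort generator with a known truth table.

Emulates the study regime: a cohort of case-unaffected-parents trios
genotyped over exome coding space, with

* background sites drawn from a U-shaped allele-frequency spectrum
  (a common bulk plus a rare tail), parents at Hardy-Weinberg and children
  inheriting one allele per parent by fair coin;
* per-child coding de novo events, Poisson with mean ``denovo_rate_per_exome``,
  placed at otherwise-monomorphic sites (the printed de novo variants are
  mostly novel alleles);
* planted compound-heterozygous and homozygous-recessive genotype
  configurations in dedicated genes, annotated as rare and protein-altering;
* optional runs-of-homozygosity tracts in designated carriers, realised as
  identity-by-descent so Mendelian consistency is preserved;
* Phred-scaled genotype likelihoods from a binomial read model at a
  configured mean depth.

Everything is reproducible from the config seed; per-stage substreams are
derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._types import AnnotatedVariant, Consequence, GenotypeCall, TrioPedigree
from .io import write_pedigree, write_vcf_cohort

#: Sequencing error rate of the binomial read model (per-read miscall).
READ_ERROR = 0.01

_BASES = ("A", "C", "G", "T")


@dataclass
class MAFSpectrum:
    """Mixture spectrum: a common bulk Uniform(lo, hi) plus a rare tail.

    Exome site-frequency spectra are U-shaped; the rare tail uses an
    exponential with the given scale, truncated below ``rare_max`` so rare
    background sites stay far below the candidate-rarity cut-off.
    """

    p_rare: float = 0.3
    common_lo: float = 0.05
    common_hi: float = 0.5
    rare_scale: float = 0.001
    rare_max: float = 0.005

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rare = rng.random(n) < self.p_rare
        maf = rng.uniform(self.common_lo, self.common_hi, size=n)
        tail = np.minimum(rng.exponential(self.rare_scale, size=n), self.rare_max)
        maf[rare] = np.maximum(tail[rare], 1e-5)
        return maf


@dataclass
class ROHTract:
    chrom: str
    start: int
    length: int
    carriers: tuple = ()


@dataclass
class SimulationConfig:
    """Study conditions for one simulated trio cohort.

    Defaults follow the cohort being emulated: 44 trios and a coding de novo
    rate of 17/44 events per child.  ``depth_mean=None`` produces noise-free
    (sharp) genotype likelihoods; a finite depth simulates reads.
    """

    n_trios: int = 44
    n_sites: int = 2000
    seed: int = 0
    maf_spectrum: MAFSpectrum = field(default_factory=MAFSpectrum)
    denovo_rate_per_exome: float = 17.0 / 44.0
    n_planted_comp_het_genes: int = 14
    n_planted_hom_rec_genes: int = 9
    roh_tracts: list = field(default_factory=list)
    genotype_error_rate: float = 0.0
    depth_mean: Optional[float] = 30.0
    sites_per_gene: int = 10
    site_spacing_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.denovo_rate_per_exome < 0:
            raise ValueError("de novo rate must be non-negative")
        if min(self.n_trios, self.n_sites) < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.genotype_error_rate <= 1.0):
            raise ValueError("genotype_error_rate must be in [0, 1]")


@dataclass
class SimulatedCohort:
    variants: list
    genotypes: np.ndarray  # (n_sites, n_samples) of GenotypeCall
    samples: list
    trios: list
    truth: pd.DataFrame
    config: SimulationConfig


TRUTH_COLUMNS = ["event_id", "trio_id", "gene", "klass", "chrom", "pos", "origin"]


def _pl_from_reads(dosage: np.ndarray, depth_mean: Optional[float], rng) -> tuple:
    """Simulate reads and return (PL array (..., 3), GQ, DP) for true dosages."""
    if depth_mean is None:
        pl = np.full(dosage.shape + (3,), 255, dtype=np.int32)
        np.put_along_axis(pl, dosage[..., None].astype(np.int64), 0, axis=-1)
        gq = np.full(dosage.shape, 99, dtype=np.int32)
        dp = np.full(dosage.shape, 99, dtype=np.int32)
        return pl, gq, dp
    dp = rng.poisson(depth_mean, size=dosage.shape)
    p_alt = np.array([READ_ERROR, 0.5, 1.0 - READ_ERROR])[dosage]
    k = rng.binomial(dp, p_alt)
    # log10 likelihood of k alt reads out of dp under each genotype; the
    # binomial coefficient is genotype-independent and cancels on normalising
    ll = np.empty(dosage.shape + (3,), dtype=np.float64)
    for g, p in enumerate((READ_ERROR, 0.5, 1.0 - READ_ERROR)):
        ll[..., g] = k * np.log10(p) + (dp - k) * np.log10(1.0 - p)
    pl = np.rint(-10.0 * (ll - ll.max(axis=-1, keepdims=True))).astype(np.int32)
    pl = np.minimum(pl, 255)
    sorted_pl = np.sort(pl, axis=-1)
    gq = sorted_pl[..., 1]  # second-smallest PL
    return pl, gq, dp


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one trio cohort with genotypes, likelihoods and truth table."""
    rng = np.random.default_rng(config.seed)
    # independent substreams so each stage is reproducible in isolation
    rng_sites, rng_trans, rng_denovo, rng_reads, rng_err, rng_annot = (
        np.random.default_rng(s) for s in rng.integers(0, 2**31 - 1, size=6)
    )

    n_trios, n_sites = config.n_trios, config.n_sites
    n_ch = config.n_planted_comp_het_genes
    n_hr = config.n_planted_hom_rec_genes

    trios = [
        TrioPedigree(
            family_id=f"FAM{t + 1:03d}",
            child_id=f"C{t + 1:03d}",
            father_id=f"F{t + 1:03d}",
            mother_id=f"M{t + 1:03d}",
        )
        for t in range(n_trios)
    ]
    samples = []
    for t in trios:
        samples.extend([t.child_id, t.father_id, t.mother_id])
    n_samples = 3 * n_trios
    child_cols = np.arange(0, n_samples, 3)
    father_cols = child_cols + 1
    mother_cols = child_cols + 2

    # --- site layout -------------------------------------------------------
    # planted comp-het genes (2 sites each), hom-rec genes (1 site), a pool
    # of monomorphic sites for de novo events, then background genes
    denovo_counts = (
        rng_denovo.poisson(config.denovo_rate_per_exome, size=n_trios)
        if config.denovo_rate_per_exome > 0
        else np.zeros(n_trios, dtype=np.int64)
    )
    n_dn = int(denovo_counts.sum())
    n_planted = 2 * n_ch + n_hr + n_dn
    if n_planted > n_sites:
        raise ValueError(
            f"planted events need {n_planted} sites but n_sites={n_sites}"
        )

    chrom = np.empty(n_sites, dtype=object)
    pos = np.empty(n_sites, dtype=np.int64)
    gene = np.empty(n_sites, dtype=object)
    half = (n_sites + 1) // 2
    chrom[:half] = "1"
    chrom[half:] = "2"
    pos[:half] = (np.arange(half) + 1) * config.site_spacing_bp
    pos[half:] = (np.arange(n_sites - half) + 1) * config.site_spacing_bp

    # interleave planted sites among background positions deterministically
    order = rng_sites.permutation(n_sites)
    ch_sites = order[: 2 * n_ch].reshape(n_ch, 2)
    hr_sites = order[2 * n_ch : 2 * n_ch + n_hr]
    dn_sites = order[2 * n_ch + n_hr : n_planted]
    bg_sites = order[n_planted:]

    gene[:] = ""
    for g in range(n_ch):
        gene[ch_sites[g]] = f"CHGENE{g + 1:03d}"
    for g in range(n_hr):
        gene[hr_sites[g]] = f"HRGENE{g + 1:03d}"
    for i, s in enumerate(dn_sites):
        gene[s] = f"DNGENE{i + 1:03d}"
    for i, s in enumerate(np.sort(bg_sites)):
        gene[s] = f"BGGENE{i // config.sites_per_gene + 1:04d}"

    maf = np.zeros(n_sites)
    maf[bg_sites] = config.maf_spectrum.sample(len(bg_sites), rng_sites)
    # planted recessive sites: rare in the population but present in carriers
    maf[ch_sites.ravel()] = 0.001
    maf[hr_sites] = 0.001
    # de novo sites stay monomorphic (population MAF 0)

    # --- parental genotypes (HWE) and transmission -------------------------
    parent_cols = np.sort(np.concatenate([father_cols, mother_cols]))
    a1 = np.zeros((n_sites, n_samples), dtype=np.int8)
    a2 = np.zeros((n_sites, n_samples), dtype=np.int8)
    pmat = maf[:, None]
    a1[:, parent_cols] = rng_trans.random((n_sites, len(parent_cols))) < pmat
    a2[:, parent_cols] = rng_trans.random((n_sites, len(parent_cols))) < pmat
    # children: paternal allele into a1, maternal into a2
    pick_f = rng_trans.random((n_sites, n_trios)) < 0.5
    pick_m = rng_trans.random((n_sites, n_trios)) < 0.5
    a1[:, child_cols] = np.where(pick_f, a1[:, father_cols], a2[:, father_cols])
    a2[:, child_cols] = np.where(pick_m, a1[:, mother_cols], a2[:, mother_cols])

    truth_rows = []
    event_id = 0

    # --- planted compound hets --------------------------------------------
    for g in range(n_ch):
        t = g % n_trios
        s_pat, s_mat = ch_sites[g]
        for s in (s_pat, s_mat):  # reset the carrier trio to hom-ref first
            for col in (child_cols[t], father_cols[t], mother_cols[t]):
                a1[s, col] = a2[s, col] = 0
        a1[s_pat, father_cols[t]] = 1  # father carrier, transmits alt
        a1[s_pat, child_cols[t]] = 1
        a1[s_mat, mother_cols[t]] = 1  # mother carrier, transmits alt
        a2[s_mat, child_cols[t]] = 1
        event_id += 1
        for s, origin in ((s_pat, "paternal"), (s_mat, "maternal")):
            truth_rows.append(
                (event_id, trios[t].child_id, gene[s], "comp_het", chrom[s],
                 int(pos[s]), origin)
            )

    # --- planted homozygous recessives ------------------------------------
    for g in range(n_hr):
        t = (g * 2 + 1) % n_trios
        s = hr_sites[g]
        a1[s, father_cols[t]], a2[s, father_cols[t]] = 1, 0
        a1[s, mother_cols[t]], a2[s, mother_cols[t]] = 1, 0
        a1[s, child_cols[t]] = a2[s, child_cols[t]] = 1
        event_id += 1
        truth_rows.append(
            (event_id, trios[t].child_id, gene[s], "hom_recessive", chrom[s],
             int(pos[s]), "both")
        )

    # --- de novo events ----------------------------------------------------
    cursor = 0
    for t in range(n_trios):
        for _ in range(int(denovo_counts[t])):
            s = dn_sites[cursor]
            cursor += 1
            a1[s, child_cols[t]] = 1  # mutation on the paternal haplotype
            event_id += 1
            truth_rows.append(
                (event_id, trios[t].child_id, gene[s], "de_novo", chrom[s],
                 int(pos[s]), "de_novo")
            )

    # --- ROH tracts (identity-by-descent, Mendelian-consistent) ------------
    col_of = {sid: j for j, sid in enumerate(samples)}
    for tract in config.roh_tracts:
        tr = tract if isinstance(tract, ROHTract) else ROHTract(*tract)
        in_tract = (
            (chrom == tr.chrom)
            & (pos >= tr.start)
            & (pos < tr.start + tr.length)
        )
        for sid in tr.carriers:
            j = col_of[sid]
            hom = a1[in_tract, j].copy()
            a2[in_tract, j] = hom
            if j % 3 == 0:  # child: keep parents consistent with autozygosity
                t = j // 3
                a1[in_tract, father_cols[t]] = hom
                a2[in_tract, mother_cols[t]] = hom

    dosage = (a1 + a2).astype(np.int8)

    # --- genotype errors and likelihoods -----------------------------------
    emitted = dosage.copy()
    if config.genotype_error_rate > 0:
        flip = rng_err.random(dosage.shape) < config.genotype_error_rate
        shift = rng_err.integers(1, 3, size=dosage.shape)
        emitted[flip] = (dosage[flip] + shift[flip]) % 3
    pl, gq, dp = _pl_from_reads(dosage, config.depth_mean, rng_reads)

    genotypes = np.empty((n_sites, n_samples), dtype=object)
    for i in range(n_sites):
        for j in range(n_samples):
            d = int(emitted[i, j])
            genotypes[i, j] = GenotypeCall(
                allele_a=0 if d < 2 else 1,
                allele_b=0 if d == 0 else 1,
                gq=float(gq[i, j]),
                pl=tuple(int(x) for x in pl[i, j] - pl[i, j].min()),
                depth=int(dp[i, j]),
            )

    planted = np.zeros(n_sites, dtype=bool)
    planted[ch_sites.ravel()] = True
    planted[hr_sites] = True
    denovo_site = np.zeros(n_sites, dtype=bool)
    denovo_site[dn_sites] = True
    variants = spike_annotations(
        chrom, pos, gene, maf, planted, denovo_site, rng_annot
    )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedCohort(
        variants=variants,
        genotypes=genotypes,
        samples=samples,
        trios=trios,
        truth=truth,
        config=config,
    )


def spike_annotations(
    chrom: np.ndarray,
    pos: np.ndarray,
    gene: np.ndarray,
    maf: np.ndarray,
    planted: np.ndarray,
    denovo_site: np.ndarray,
    rng: np.random.Generator,
) -> list:
    """Attach gene/consequence/MAF/damage annotations to simulated sites.

    Planted recessive sites become rare (< 1 % in both panels) protein-altering
    variants with damaging scores; de novo sites are novel (no panel MAF);
    background sites carry their spectrum MAF and mixed consequences.
    """
    n = len(pos)
    # annotation panels report limited precision; 6 significant digits also
    # survive the float32 INFO encoding of a VCF round trip exactly
    maf = np.array([float(f"{m:.6g}") for m in maf])
    consequences = rng.choice(
        [Consequence.SYNONYMOUS, Consequence.MISSENSE, Consequence.OTHER],
        p=[0.3, 0.45, 0.25],
        size=n,
    )
    refs = rng.choice(_BASES, size=n)
    variants = []
    for i in range(n):
        ref = refs[i]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
        if planted[i]:
            csq = Consequence.NONSENSE if rng.random() < 0.15 else Consequence.MISSENSE
            v = AnnotatedVariant(
                chrom=chrom[i], pos=int(pos[i]), ref=ref, alt=alt,
                gene=gene[i], consequence=csq,
                maf_esp=float(maf[i]), maf_1kg=float(maf[i]),
                damage_scores={"sift": 0.001, "pph2": 0.99}, conserved=True,
            )
        elif denovo_site[i]:
            v = AnnotatedVariant(
                chrom=chrom[i], pos=int(pos[i]), ref=ref, alt=alt,
                gene=gene[i], consequence=Consequence.MISSENSE,
                maf_esp=None, maf_1kg=None,
                damage_scores={"sift": 0.01, "pph2": 0.95}, conserved=True,
            )
        else:
            v = AnnotatedVariant(
                chrom=chrom[i], pos=int(pos[i]), ref=ref, alt=alt,
                gene=gene[i], consequence=consequences[i],
                maf_esp=float(maf[i]), maf_1kg=float(maf[i]),
                damage_scores={}, conserved=bool(rng.random() < 0.3),
            )
        variants.append(v)
    return variants


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write VCF + PED + truth TSV (+ config) for a simulated cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.txt",
    }
    write_vcf_cohort(cohort.variants, cohort.genotypes, cohort.samples, paths["vcf"])
    write_pedigree(cohort.trios, paths["ped"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = cohort.config
    lines = [
        f"n_trios={cfg.n_trios}",
        f"n_sites={cfg.n_sites}",
        f"seed={cfg.seed}",
        f"denovo_rate_per_exome={cfg.denovo_rate_per_exome}",
        f"n_planted_comp_het_genes={cfg.n_planted_comp_het_genes}",
        f"n_planted_hom_rec_genes={cfg.n_planted_hom_rec_genes}",
        f"genotype_error_rate={cfg.genotype_error_rate}",
        f"depth_mean={cfg.depth_mean}",
    ]
    paths["config"].write_text("\n".join(lines) + "\n")
    return paths
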