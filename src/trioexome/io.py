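"""Reading and writing the cohort formats: VCF, PED, candidate tables, fixtures.

VCF handling is biallelic downstream: multiallelic records are decomposed on
read into one record per ALT allele, with genotypes (and PL triples) re-coded
against that ALT.  Coordinates are 1-based inclusive throughout, as in VCF.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._types import (
    AnnotatedVariant,
    Consequence,
    GenotypeCall,
    GroupSummary,
    InheritanceCall,
    InheritanceClass,
    TrioPedigree,
)

_INFO_KEYS = ("GENE", "CSQCLASS", "MAF_ESP", "MAF_1KG", "SIFT", "PPH2", "CONSERVED")

#: SHA-256 digests of the packaged fixture tables (guards against corruption).
_FIXTURE_SHA256 = {
    "table1.tsv": "cb09a4eb81500f7297634e7d786f11573c297e28d122235d999c462fb6359b4e",
    "table2.tsv": "d364650cfbbdffc60c9898d98ed6f9afaf13528584bbbc7fa7011b98c6e4b499",
    "table3.tsv": "bdc808924a460f15fadb49149a14b8761b6a94d8fce5ef48c1ee4981d3bc33ee",
    "summary_stats.tsv": "8867b663a59344939e29e11ee0237ed0e47665111dbee2ed721399f95d8498a7",
}

_IMPACT_TO_CONSEQUENCE = {
    "missense": Consequence.MISSENSE,
    "nonsense": Consequence.NONSENSE,
    "splice site": Consequence.SPLICE_SITE,
    "missense, splice site": Consequence.SPLICE_SITE,
    "missense, initiator codon": Consequence.INITIATOR_CODON,
    "initiator codon": Consequence.INITIATOR_CODON,
    "synonymous": Consequence.SYNONYMOUS,
}

_INHERITANCE_LABEL = {
    InheritanceClass.HOM_RECESSIVE: "Homozygous",
    InheritanceClass.COMP_HET: "Cpd Het",
    InheritanceClass.DE_NOVO: "De novo",
}


class VCFParseError(ValueError):
    pass


def parse_impact(label: str) -> Consequence:
    """Map a human-readable impact label to a consequence class."""
    return _IMPACT_TO_CONSEQUENCE.get(label.strip().lower(), Consequence.OTHER)


def chrom_sort_key(chrom: str) -> tuple:
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _info_float(rec, key: str) -> Optional[float]:
    v = rec.INFO.get(key)
    if v is None:
        return None
    try:
        # htslib stores INFO floats as float32; writing used %g (6 sig. digits),
        # so re-rounding recovers the original double exactly
        return float(f"{float(v):.6g}")
    except (TypeError, ValueError):
        return None


def _decompose_pl(pl_row: Optional[np.ndarray], alt_index: int) -> Optional[tuple]:
    """Extract the (0/0, 0/k, k/k) PL triple for ALT number ``alt_index``."""
    if pl_row is None:
        return None
    k = alt_index
    idx = (0, k * (k + 1) // 2, k * (k + 1) // 2 + k)
    if max(idx) >= len(pl_row):
        return None
    triple = [int(pl_row[i]) for i in idx]
    if any(t < 0 for t in triple):  # cyvcf2 encodes missing as negative
        return None
    m = min(triple)
    return tuple(t - m for t in triple)


def read_vcf_cohort(path) -> tuple[list[AnnotatedVariant], np.ndarray, list[str]]:
    """Read a multi-sample VCF into variants and a site x sample genotype matrix.

    Returns ``(variants, genotypes, samples)`` where ``genotypes`` is an
    object array of :class:`GenotypeCall` with shape (n_sites, n_samples).
    Multiallelic records are split into one biallelic record per ALT; at a
    split record, sample alleles equal to other ALTs are re-coded as REF.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    rows: list[list[GenotypeCall]] = []
    for rec in vcf:
        if "GT" not in (rec.FORMAT or []):
            raise VCFParseError(
                f"record {rec.CHROM}:{rec.POS} has no GT field"
            )
        gts = rec.genotypes  # [[a, b, phased], ...]

        def fmt(key):
            try:
                return rec.format(key)
            except KeyError:  # field not declared in the header
                return None

        pl = fmt("PL")
        gq = fmt("GQ")
        dp = fmt("DP")
        damage = {}
        sift = _info_float(rec, "SIFT")
        pph2 = _info_float(rec, "PPH2")
        if sift is not None:
            damage["sift"] = sift
        if pph2 is not None:
            damage["pph2"] = pph2
        conserved_raw = rec.INFO.get("CONSERVED")
        conserved = None if conserved_raw is None else bool(int(conserved_raw))
        gene = rec.INFO.get("GENE") or ""
        csq = rec.INFO.get("CSQCLASS")
        consequence = Consequence(csq) if csq else Consequence.OTHER
        for alt_index, alt in enumerate(rec.ALT, start=1):
            variants.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=gene,
                    consequence=consequence,
                    maf_esp=_info_float(rec, "MAF_ESP"),
                    maf_1kg=_info_float(rec, "MAF_1KG"),
                    damage_scores=damage,
                    conserved=conserved,
                )
            )
            row = []
            for j in range(len(samples)):
                a, b = gts[j][0], gts[j][1]
                phased = bool(gts[j][2])

                def recode(x: int) -> Optional[int]:
                    if x < 0:
                        return None
                    return 1 if x == alt_index else 0

                aa, bb = recode(a), recode(b)
                if aa is None or bb is None:
                    aa = bb = None
                row.append(
                    GenotypeCall(
                        allele_a=aa,
                        allele_b=bb,
                        phased=phased,
                        gq=None if gq is None or gq[j] < 0 else float(np.ravel(gq[j])[0]),
                        pl=_decompose_pl(None if pl is None else pl[j], alt_index),
                        depth=None if dp is None or dp[j] < 0 else int(np.ravel(dp[j])[0]),
                    )
                )
            rows.append(row)
    genotypes = np.empty((len(rows), len(samples)), dtype=object)
    for i, row in enumerate(rows):
        genotypes[i, :] = row
    return variants, genotypes, samples


def _format_gt(call: GenotypeCall) -> str:
    if call.is_missing:
        gt = "./."
    else:
        sep = "|" if call.phased else "/"
        gt = f"{call.allele_a}{sep}{call.allele_b}"
    gq = "." if call.gq is None else f"{int(call.gq)}"
    pl = "." if call.pl is None else ",".join(str(int(p)) for p in call.pl)
    dp = "." if call.depth is None else str(call.depth)
    return f"{gt}:{gq}:{pl}:{dp}"


def write_vcf_cohort(
    variants: Sequence[AnnotatedVariant],
    genotypes: np.ndarray,
    samples: Sequence[str],
    path,
) -> None:
    """Write biallelic records with annotations as a plain-text VCF 4.2."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=MAF_ESP,Number=1,Type=Float,Description="ESP minor allele frequency">',
        '##INFO=<ID=MAF_1KG,Number=1,Type=Float,Description="1000 Genomes minor allele frequency">',
        '##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">',
        '##INFO=<ID=PPH2,Number=1,Type=Float,Description="PolyPhen2 score">',
        '##INFO=<ID=CONSERVED,Number=1,Type=Integer,Description="Site conserved flag">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    chroms = sorted({v.chrom for v in variants}, key=chrom_sort_key)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for i, v in enumerate(variants):
        info = []
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.consequence is not Consequence.OTHER:
            info.append(f"CSQCLASS={v.consequence.value}")
        if v.maf_esp is not None:
            info.append(f"MAF_ESP={v.maf_esp:g}")
        if v.maf_1kg is not None:
            info.append(f"MAF_1KG={v.maf_1kg:g}")
        if "sift" in v.damage_scores:
            info.append(f"SIFT={v.damage_scores['sift']:g}")
        if "pph2" in v.damage_scores:
            info.append(f"PPH2={v.damage_scores['pph2']:g}")
        if v.conserved is not None:
            info.append(f"CONSERVED={int(v.conserved)}")
        fields = [
            v.chrom,
            str(v.pos),
            ".",
            v.ref,
            v.alt,
            ".",
            "PASS",
            ";".join(info) or ".",
            "GT:GQ:PL:DP",
        ]
        fields.extend(_format_gt(genotypes[i, j]) for j in range(len(samples)))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------


def read_pedigree(path) -> list[TrioPedigree]:
    """Parse a 6-column PED file into affected-child trios.

    Emits one trio per affected child whose father and mother are both
    declared and present in the file; children with a missing parent are
    dropped with a warning.  Parents are required to be coded unaffected.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"PED line {lineno}: expected 6 columns, got {len(parts)}")
        rows.append(parts[:6])
    ids = [r[1] for r in rows]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated sample id(s) in PED: {', '.join(dup)}")
    by_id = {r[1]: r for r in rows}
    trios = []
    for fam, sid, father, mother, _sex, pheno in rows:
        if pheno != "2":  # only affected children found a trio
            continue
        if father in ("0", "") or mother in ("0", ""):
            warnings.warn(
                f"affected sample {sid} has a missing parent; trio excluded",
                stacklevel=2,
            )
            continue
        if father not in by_id or mother not in by_id:
            warnings.warn(
                f"affected sample {sid}: parent not present in PED; trio excluded",
                stacklevel=2,
            )
            continue
        parents_affected = by_id[father][5] == "2" or by_id[mother][5] == "2"
        trios.append(
            TrioPedigree(
                family_id=fam,
                child_id=sid,
                father_id=father,
                mother_id=mother,
                child_affected=True,
            )
        )
        if parents_affected:
            warnings.warn(f"family {fam}: parent coded affected", stacklevel=2)
    return trios


def write_pedigree(trios: Sequence[TrioPedigree], path) -> None:
    lines = []
    for t in trios:
        lines.append(f"{t.family_id}\t{t.father_id}\t0\t0\t1\t1")
        lines.append(f"{t.family_id}\t{t.mother_id}\t0\t0\t2\t1")
        lines.append(f"{t.family_id}\t{t.child_id}\t{t.father_id}\t{t.mother_id}\t0\t2")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


@dataclass
class CohortFixtures:
    """The packaged cohort tables: per-patient clinical/count records
    (``table1``), validated recessive variants (``table2``), coding de novo
    variants (``table3``) and printed group summaries (``summary_stats``)."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    summary_stats: dict


class FixtureIntegrityError(RuntimeError):
    pass


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("trioexome.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(
            f"packaged fixture {name} fails its checksum (got {digest})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype={"trio_id": str})


def load_fixtures() -> CohortFixtures:
    """Load the packaged cohort tables and verify their integrity.

    Asserted at load: 44 patients, 37 validated recessive variant rows
    (9 homozygous + 28 compound het), 17 coding de novo rows, and agreement
    between the per-patient counts and the variant tables.
    """
    t1 = _read_packaged("table1.tsv")
    t2 = _read_packaged("table2.tsv")
    t3 = _read_packaged("table3.tsv")
    ss = _read_packaged("summary_stats.tsv")

    if len(t1) != 44 or len(t2) != 37 or len(t3) != 17:
        raise FixtureIntegrityError("fixture row counts are not 44/37/17")
    n_hom = int((t2["inheritance"] == "Homozygous").sum())
    if n_hom != 9 or int(t1["n_homozygous"].sum()) != 9:
        raise FixtureIntegrityError("homozygous recessive totals do not sum to 9")
    n_ch_rows = int((t2["inheritance"] == "Cpd Het").sum())
    if n_ch_rows != 28 or int(t1["n_comp_het_genes"].sum()) * 2 != 28:
        raise FixtureIntegrityError("compound-het totals inconsistent with 28 rows")
    if int(t1["n_de_novo"].sum()) != 17:
        raise FixtureIntegrityError("coding de novo counts do not sum to 17")

    summaries = {
        r["name"]: GroupSummary(
            n=int(r["n"]), mean=float(r["mean"]), sd=float(r["sd"]),
            min=float(r["min"]), max=float(r["max"]),
        )
        for _, r in ss.iterrows()
    }
    return CohortFixtures(table1=t1, table2=t2, table3=t3, summary_stats=summaries)


# ---------------------------------------------------------------------------
# Candidate output
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = [
    "gene",
    "trio_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "inheritance",
    "impact",
    "maf_esp",
    "maf_1kg",
    "phase_assumed",
    "known_gene",
    "filters_passed",
]


def candidates_to_frame(calls: Sequence[InheritanceCall]) -> pd.DataFrame:
    """Flatten classified calls into a deterministic per-variant table."""
    rows = []
    for call in calls:
        for v in call.variants:
            rows.append(
                {
                    "gene": call.gene,
                    "trio_id": call.trio_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "inheritance": _INHERITANCE_LABEL[call.klass],
                    "impact": v.consequence.value,
                    "maf_esp": "NR" if v.maf_esp is None else f"{v.maf_esp:g}",
                    "maf_1kg": "NR" if v.maf_1kg is None else f"{v.maf_1kg:g}",
                    "phase_assumed": call.phase_assumed,
                    "known_gene": call.known_gene,
                    "filters_passed": ",".join(call.filter_provenance),
                }
            )
    df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["chrom", "pos", "trio_id"],
            key=lambda s: s.map(lambda x: chrom_sort_key(x)) if s.name == "chrom" else s,
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def write_candidates(calls: Sequence[InheritanceCall], path) -> None:
    """Write classified calls as a TSV sorted by (chrom, pos, trio id)."""
    df = candidates_to_frame(calls)
    df.to_csv(path, sep="\t", index=False)
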