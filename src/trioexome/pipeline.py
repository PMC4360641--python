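"""End-to-end orchestration: QC -> phasing -> recessive/comp-het -> de novo
-> tabulation, with deterministic outputs keyed by a config hash."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._types import (
    DeNovoPrior,
    FilterPolicy,
    InheritanceCall,
    QCThresholds,
    TrioPedigree,
)
from . import denovo as dn
from . import inheritance as inh
from . import io as cio
from . import stats as cstats
from .qc import apply_site_filters, dosage_matrix

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf: str = ""
    ped: str = ""
    out_dir: str = "trioexome_out"
    gene_list: Optional[str] = None
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    prior: DeNovoPrior = field(default_factory=DeNovoPrior)
    denovo_threshold: float = 0.5
    qc: QCThresholds = field(default_factory=QCThresholds)
    #: the <1% population-MAF site filter belongs to the array/ROH QC track;
    #: the candidate track must keep rare variants, so it skips that rule
    qc_skip_rules: tuple = ("maf",)
    seed: int = 0
    n_perm: int = 100_000

    def config_hash(self) -> str:
        """Hash of the analytic parameters; file locations are excluded so
        identical analyses of the same data hash identically."""
        payload = asdict(self)
        for key in ("vcf", "ped", "out_dir", "gene_list"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def classify_cohort(
    variants: Sequence,
    genotypes: np.ndarray,
    samples: Sequence[str],
    trios: Sequence[TrioPedigree],
    policy: FilterPolicy,
) -> list:
    """Phase every trio and emit homozygous-recessive and comp-het calls."""
    col = {sid: j for j, sid in enumerate(samples)}
    calls: list[InheritanceCall] = []
    for trio in trios:
        jc, jf, jm = col[trio.child_id], col[trio.father_id], col[trio.mother_id]
        phased = [
            inh.phase_trio(genotypes[i, jc], genotypes[i, jf], genotypes[i, jm])
            for i in range(len(variants))
        ]
        for i, v in enumerate(variants):
            ph = phased[i]
            if ph is None or not ph.mendelian_consistent:
                continue
            call = inh.classify_homozygous_recessive(
                trio.child_id,
                genotypes[i, jc],
                genotypes[i, jf],
                genotypes[i, jm],
                v,
                policy,
            )
            if call is not None:
                calls.append(call)
        calls.extend(inh.find_compound_hets(trio.child_id, variants, phased, policy))
    return calls


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full classification pipeline and write its reports.

    Returns a results dict with the classified calls, de novo calls, QC log,
    per-trio de novo counts, the Poisson fit, and the burden tabulation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()

    try:
        trios = cio.read_pedigree(config.ped)
        if not trios:
            raise ValueError("pedigree yields no complete trios")
    except Exception as exc:
        raise StageError("pedigree", exc) from exc

    try:
        variants, genotypes, samples = cio.read_vcf_cohort(config.vcf)
    except Exception as exc:
        raise StageError("vcf", exc) from exc

    try:
        dosages = dosage_matrix(genotypes)
        founder = np.ones(len(samples), dtype=bool)
        child_ids = {t.child_id for t in trios}
        for j, sid in enumerate(samples):
            founder[j] = sid not in child_ids
        keep, qc_log = apply_site_filters(
            dosages,
            config.qc,
            founder_mask=founder,
            skip_rules=set(config.qc_skip_rules),
        )
        logger.info(
            "site_qc: kept %d/%d sites (call_rate>=%g, hwe_alpha=%g)",
            int(keep.sum()), len(keep), config.qc.min_call_rate, config.qc.hwe_alpha,
        )
    except Exception as exc:
        raise StageError("site_qc", exc) from exc

    kept_idx = np.flatnonzero(keep)
    kept_variants = [variants[i] for i in kept_idx]
    kept_genotypes = genotypes[kept_idx]

    try:
        calls = classify_cohort(kept_variants, kept_genotypes, samples, trios, config.policy)
        if config.gene_list:
            inh.intersect_known_genes(calls, inh.read_gene_list(config.gene_list))
        logger.info(
            "classify: %d recessive/comp-het calls (max_maf=%g)",
            len(calls), config.policy.max_maf,
        )
    except Exception as exc:
        raise StageError("classify", exc) from exc

    try:
        dn_calls = dn.call_de_novo(
            kept_variants,
            kept_genotypes,
            samples,
            trios,
            prior=config.prior,
            threshold=config.denovo_threshold,
        )
        counts = dn.per_trio_counts(dn_calls, trios)
        fit = dn.poisson_fit_test(counts.to_numpy())
        coding_tally = dn.classify_coding(dn_calls)
        logger.info(
            "denovo: %d calls (mu=%g, threshold=%g), lambda_hat=%.4f",
            len(dn_calls), config.prior.mu, config.denovo_threshold, fit.lambda_hat,
        )
    except Exception as exc:
        raise StageError("denovo", exc) from exc

    try:
        from ._types import InheritanceClass

        per_patient = pd.DataFrame(
            {
                "trio_id": [t.child_id for t in trios],
                "n_homozygous": [
                    sum(
                        1
                        for c in calls
                        if c.trio_id == t.child_id and c.klass is InheritanceClass.HOM_RECESSIVE
                    )
                    for t in trios
                ],
                "n_comp_het_genes": [
                    sum(
                        1
                        for c in calls
                        if c.trio_id == t.child_id and c.klass is InheritanceClass.COMP_HET
                    )
                    for t in trios
                ],
                "n_de_novo": counts.to_numpy(),
            }
        )
        burden = cstats.tabulate_inheritance_burden(per_patient)
    except Exception as exc:
        raise StageError("tabulate", exc) from exc

    # --- reports -----------------------------------------------------------
    _write_tsv(cio.candidates_to_frame(calls), out / "candidates.tsv", h)
    dn_frame = pd.DataFrame(
        [
            {
                "gene": c.variant.gene,
                "trio_id": c.trio_id,
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "impact": c.consequence.value,
                "posterior": round(c.posterior, 6),
            }
            for c in sorted(dn_calls, key=lambda c: (cio.chrom_sort_key(c.variant.chrom), c.variant.pos, c.trio_id))
        ],
        columns=["gene", "trio_id", "chrom", "pos", "impact", "posterior"],
    )
    _write_tsv(dn_frame, out / "denovo.tsv", h)
    _write_tsv(qc_log, out / "qc_exclusions.tsv", h)
    _write_tsv(per_patient, out / "per_patient_counts.tsv", h)
    report = {
        "config_hash": h,
        "n_trios": len(trios),
        "n_sites_input": len(variants),
        "n_sites_kept": int(keep.sum()),
        "burden": burden,
        "denovo_lambda_hat": fit.lambda_hat,
        "denovo_gof_p": fit.gof_p,
        "denovo_coding_tally": coding_tally,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {
        "calls": calls,
        "denovo_calls": dn_calls,
        "per_patient": per_patient,
        "burden": burden,
        "poisson_fit": fit,
        "qc_log": qc_log,
        "report": report,
    }
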