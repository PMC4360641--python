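"""Cohort descriptive statistics, summary-based t-tests, inheritance burden
tabulation, and EASE-style gene-set enrichment with FDR control.

The t-test operates on published group summaries (n, mean, SD) rather than
raw values, using the pooled-variance Student form: the parental-age
comparisons reproduce from the printed summaries only under pooling.

The enrichment statistic is the conservative EASE score: the one-sided
hypergeometric upper-tail p-value of the 2x2 membership table after
removing one hit from the gene list, so single-gene overlaps can never be
significant.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats as sps

from ._types import GroupSummary


def cohort_summary(values: Sequence[float]) -> GroupSummary:
    """n, mean, sample SD (n-1 denominator) and range of a value vector."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    return GroupSummary(
        n=int(values.size),
        mean=float(values.mean()),
        sd=sd,
        min=float(values.min()),
        max=float(values.max()),
    )


def summary_ttest(g1: GroupSummary, g2: GroupSummary) -> tuple[float, int, float]:
    """Unpaired two-tailed pooled-variance t-test from group summaries.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("both groups need n >= 2")
    if g1.sd is None or g2.sd is None or (g1.sd == 0 and g2.sd == 0):
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return float(t), g1.n + g2.n - 2, float(p)


def tabulate_inheritance_burden(table: pd.DataFrame) -> dict:
    """Per-class patient counts, variant totals and cohort percentages.

    ``table`` needs one row per patient with columns ``n_homozygous``,
    ``n_comp_het_genes`` (compound-het gene pairs; two variants each) and
    ``n_de_novo``.  "Multi-variant" patients carry two or more events
    summed across the three classes.  Percentages are of the cohort size,
    rounded to the nearest integer.
    """
    if len(table) == 0:
        raise ValueError("empty cohort")
    n = len(table)
    hom = table["n_homozygous"].to_numpy()
    ch = table["n_comp_het_genes"].to_numpy()
    dn = table["n_de_novo"].to_numpy()
    events = hom + ch + dn

    def pct(k: int) -> int:
        return int(round(100.0 * k / n))

    out = {
        "n_patients": n,
        "patients_homozygous": int((hom > 0).sum()),
        "patients_comp_het": int((ch > 0).sum()),
        "patients_de_novo": int((dn > 0).sum()),
        "patients_multi_variant": int((events >= 2).sum()),
        "patients_two_de_novo": int((dn == 2).sum()),
        "variants_homozygous": int(hom.sum()),
        "variants_comp_het": int(ch.sum()) * 2,
        "variants_de_novo": int(dn.sum()),
    }
    out["pct_homozygous"] = pct(out["patients_homozygous"])
    out["pct_comp_het"] = pct(out["patients_comp_het"])
    out["pct_de_novo"] = pct(out["patients_de_novo"])
    out["pct_multi_variant"] = pct(out["patients_multi_variant"])
    return out


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentResult:
    category: str
    hits_in_list: int
    list_size: int
    hits_in_background: int
    background_size: int
    ease_p: float
    fdr: float
    significant: bool


def ease_score(
    hits_in_list: int, list_size: int, hits_in_background: int, background_size: int
) -> float:
    """EASE p-value: hypergeometric upper tail with one list hit removed.

    P(X >= hits - 1) for X ~ Hypergeom(background_size, hits_in_background,
    list_size); equals 1 whenever the list has at most one hit.
    """
    k = hits_in_list - 1
    if k <= 0:
        return 1.0
    return float(
        sps.hypergeom.sf(k - 1, background_size, hits_in_background, list_size)
    )


def ease_enrichment(
    list_genes: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.1,
) -> list:
    """EASE enrichment of a gene list against categories, with BH FDR.

    A category is significant when its EASE p is below ``p_threshold`` and
    its BH q-value below ``fdr_threshold``.  The gene list must be a subset
    of the background.
    """
    background = {g.upper() for g in background}
    if not background:
        raise ValueError("empty background")
    genes = {g.upper() for g in list_genes}
    if not genes <= background:
        raise ValueError("gene list must be a subset of the background")
    rows = []
    for cat in sorted(category_map):
        members = {g.upper() for g in category_map[cat]} & background
        hits = len(genes & members)
        rows.append((cat, hits, len(members)))
    pvals = [
        ease_score(hits, len(genes), n_members, len(background))
        for _, hits, n_members in rows
    ]
    qvals = bh_fdr(pvals) if pvals else np.array([])
    results = []
    for (cat, hits, n_members), p, q in zip(rows, pvals, qvals):
        results.append(
            EnrichmentResult(
                category=cat,
                hits_in_list=hits,
                list_size=len(genes),
                hits_in_background=n_members,
                background_size=len(background),
                ease_p=p,
                fdr=float(q),
                significant=bool(p < p_threshold and q < fdr_threshold),
            )
        )
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "hits_in_list": r.hits_in_list,
                "list_size": r.list_size,
                "hits_in_background": r.hits_in_background,
                "background_size": r.background_size,
                "ease_p": r.ease_p,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def read_category_map(path) -> dict:
    """Two-column TSV (category, gene) -> mapping category -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["category", "gene"])
    out: dict = {}
    for cat, gene in df.itertuples(index=False):
        out.setdefault(str(cat), set()).add(str(gene).upper())
    return out
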