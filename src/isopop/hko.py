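"""Human-knockout (HKO) detection and characterization.

A putative HKO variant is a predicted loss-of-function variant — one of the
eight VEP high-impact consequence terms with CADD phred >= 20 — carried in
the homozygous-alternative state by at least one individual in at least one
population.  A variant is a TOTAL knockout when every transcript of its gene
is affected, otherwise PARTIAL.  Cross-population overlaps are computed on
the gene level after restriction to an external membership list (a
gnomAD-style stand-in, to guard against private false positives), and the
intolerance of HKO genes is compared with the genome-wide background via a
Wilcoxon rank-sum test on RVIS scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationRecord, CohortDataset, VariantKey
from .simulate import BENIGN_TERMS, HIGH_IMPACT_TERMS

KNOWN_TERMS = set(HIGH_IMPACT_TERMS) | set(BENIGN_TERMS) | {
    "stop_retained_variant", "inframe_deletion", "inframe_insertion",
    "5_prime_UTR_variant", "downstream_gene_variant", "intergenic_variant",
    "splice_region_variant", "non_coding_transcript_variant",
}


def classify_lof(annotation: AnnotationRecord, cadd_min: float = 20.0) -> bool:
    """True iff the consequence is one of the eight high-impact terms and
    CADD phred >= ``cadd_min``.  Consequence terms outside the known VEP
    vocabulary are treated as non-LoF with a warning."""
    term = annotation.consequence
    if term not in KNOWN_TERMS:
        warnings.warn(f"unknown consequence term {term!r}; treated as non-LoF")
        return False
    return term in HIGH_IMPACT_TERMS and annotation.cadd_phred >= cadd_min


@dataclass
class HkoRecord:
    """One putative knockout variant with its per-population homozygotes."""

    key: VariantKey
    gene: str
    classification: str  # "TOTAL" | "PARTIAL"
    populations_with_homozygote: frozenset[str]
    homozygote_counts: dict[str, int]
    in_external_list: bool


def detect_hko(
    cohorts: dict[str, CohortDataset],
    annotations: dict[VariantKey, AnnotationRecord],
    external_sites: set[VariantKey] | None = None,
    cadd_min: float = 20.0,
) -> tuple[list[HkoRecord], pd.DataFrame]:
    """Scan all cohorts for putative human-knockout variants.

    For every LoF-classified variant, populations with at least one
    homozygous-alternative (dosage 2) individual are recorded; missing
    genotypes are ignored.  Classification is TOTAL when the affected
    transcripts cover all of the gene's transcripts.  Also returns the
    per-individual count of TOTAL-HKO variants carried homozygously.
    """
    external_sites = external_sites or set()
    key_index = {
        pop: {k: j for j, k in enumerate(ds.keys)} for pop, ds in cohorts.items()
    }
    records: list[HkoRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lof_keys = [k for k, a in annotations.items() if classify_lof(a, cadd_min)]
    for key in lof_keys:
        ann = annotations[key]
        hom_counts: dict[str, int] = {}
        for pop, ds in cohorts.items():
            j = key_index[pop].get(key)
            if j is None:
                continue
            n_hom = int((ds.genotypes[:, j] == 2).sum())
            if n_hom > 0:
                hom_counts[pop] = n_hom
        if not hom_counts:
            continue
        total = len(ann.affected_transcripts) == ann.n_transcripts
        records.append(
            HkoRecord(
                key=key, gene=ann.gene,
                classification="TOTAL" if total else "PARTIAL",
                populations_with_homozygote=frozenset(hom_counts),
                homozygote_counts=hom_counts,
                in_external_list=key in external_sites,
            )
        )

    per_individual = []
    total_keys = {r.key for r in records if r.classification == "TOTAL"}
    for pop, ds in cohorts.items():
        cols = [key_index[pop][k] for k in total_keys if k in key_index[pop]]
        counts = (
            (ds.genotypes[:, cols] == 2).sum(axis=1) if cols else np.zeros(ds.n_samples, dtype=int)
        )
        for sid, c in zip(ds.sample_ids, counts):
            per_individual.append(
                {"population": pop, "sample_id": sid, "n_total_hko": int(c)}
            )
    return records, pd.DataFrame(per_individual)


def hko_overlap(
    records: list[HkoRecord],
    restrict_to_external: bool = True,
) -> pd.DataFrame:
    """Per-population private and all-population-shared HKO gene counts.

    Variants are first restricted to those present in the external
    membership list (when requested), then collapsed to genes per
    population.  A gene is private to a population when no other population
    carries any HKO in it.
    """
    use = [r for r in records if r.in_external_list] if restrict_to_external else records
    if not use:
        warnings.warn("no HKO records remain after external-list restriction")
        return pd.DataFrame(
            columns=["population", "n_genes", "n_private", "n_all_population_shared"]
        )
    pops = sorted({p for r in use for p in r.populations_with_homozygote})
    genes = {
        p: {r.gene for r in use if p in r.populations_with_homozygote} for p in pops
    }
    inter = set.intersection(*genes.values()) if genes else set()
    rows = []
    for p in pops:
        others = set().union(*(genes[q] for q in pops if q != p)) if len(pops) > 1 else set()
        rows.append(
            {
                "population": p,
                "n_genes": len(genes[p]),
                "n_private": len(genes[p] - others),
                "n_all_population_shared": len(inter),
            }
        )
    return pd.DataFrame(rows)


def rvis_test(
    hko_genes: set[str],
    all_genes: set[str],
    rvis: dict[str, float],
) -> dict[str, float]:
    """Compare RVIS of HKO genes against the whole scored gene set.

    Wilcoxon rank-sum (Mann–Whitney U, normal approximation with tie
    correction), two-sided.  Genes without an RVIS score are dropped.  When
    every score on both sides is identical the comparison is degenerate and
    reported as statistic at the null midpoint with p = 1.
    """
    from scipy.stats import mannwhitneyu

    x = np.array([rvis[g] for g in hko_genes if g in rvis], dtype=np.float64)
    y = np.array([rvis[g] for g in all_genes if g in rvis], dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one RVIS-scored gene on each side")
    out = {
        "n_hko": int(x.size),
        "n_all": int(y.size),
        "median_hko": float(np.median(x)),
        "median_all": float(np.median(y)),
    }
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # all tied: zero-variance null
        out["statistic"] = float(x.size * y.size / 2.0)
        out["p_value"] = 1.0
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    out["statistic"] = float(res.statistic)
    out["p_value"] = float(res.pvalue)
    return out
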