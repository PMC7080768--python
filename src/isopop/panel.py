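"""Reference-panel site selection and cross-resource sharing spectra.

A cohort's sites enter the imputation reference panel if they are well
supported internally (alternative allele count AC >= 2 and mean per-genotype
read depth >= 5) or, for singletons (AC = 1), if the same variant —
matched exactly on (chrom, pos, ref, alt) — is seen in another study cohort
or in an external resource (1000G/UK10K/gnomAD-style site lists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CohortDataset, VariantKey

logger = logging.getLogger(__name__)


@dataclass
class SiteStats:
    """Per-site allele counts and depth summary within one cohort."""

    key: VariantKey
    ac: int
    an: int
    mean_dp: float  # NaN when no called genotype has a depth

    @property
    def af(self) -> float:
        return self.ac / self.an if self.an > 0 else float("nan")

    @property
    def maf(self) -> float:
        af = self.af
        return min(af, 1.0 - af) if np.isfinite(af) else float("nan")


def compute_site_stats(dataset: CohortDataset) -> list[SiteStats]:
    """AC/AN and mean depth per site, over non-missing genotypes only.

    AC counts alternative alleles among called genotypes; AN is twice the
    number of called genotypes.  ``mean_dp`` averages depth over samples with
    a called genotype (all-missing sites get AN = 0 and NaN depth and are
    excluded by downstream rules).
    """
    g = dataset.genotypes
    called = g != MISSING
    ac = np.where(called, g, 0).sum(axis=0)
    an = 2 * called.sum(axis=0)
    if dataset.depths is not None:
        dp = dataset.depths.astype(np.float64)
        usable = called & (dataset.depths != MISSING)
        with np.errstate(invalid="ignore"):
            mean_dp = np.where(
                usable.sum(axis=0) > 0,
                np.where(usable, dp, 0.0).sum(axis=0) / np.maximum(usable.sum(axis=0), 1),
                np.nan,
            )
    else:
        mean_dp = np.full(dataset.n_sites, np.nan)
    return [
        SiteStats(key=k, ac=int(a), an=int(n), mean_dp=float(d))
        for k, a, n, d in zip(dataset.keys, ac, an, mean_dp)
    ]


def select_panel_sites(
    cohorts: list[tuple[str, list[SiteStats]]],
    externals: list[set[VariantKey]] | None = None,
    min_ac: int = 2,
    min_dp: float = 5.0,
) -> tuple[dict[str, set[VariantKey]], pd.DataFrame]:
    """Apply the panel inclusion rule per cohort.

    A site is retained in cohort c iff

    (a) AC >= ``min_ac`` and mean DP >= ``min_dp``, or
    (b) AC == 1 and the identical variant is present among another cohort's
        sites or in at least one external resource.

    Sites with AC == 0 (or AN == 0) are never retained.  Returns the
    per-cohort retained key sets and a retention report (one row per cohort
    with counts and the retained proportion).
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    externals = externals or []
    ext_union: set[VariantKey] = set().union(*externals) if externals else set()
    cohort_keys = {pop: {s.key for s in stats if s.ac > 0} for pop, stats in cohorts}

    retained: dict[str, set[VariantKey]] = {}
    rows = []
    for pop, stats in cohorts:
        other = set()
        for other_pop, keys in cohort_keys.items():
            if other_pop != pop:
                other |= keys
        keep: set[VariantKey] = set()
        n_rule_a = n_rule_b = 0
        for s in stats:
            if s.an == 0 or s.ac == 0:
                continue
            if s.ac >= min_ac and np.isfinite(s.mean_dp) and s.mean_dp >= min_dp:
                keep.add(s.key)
                n_rule_a += 1
            elif s.ac == 1 and (s.key in other or s.key in ext_union):
                keep.add(s.key)
                n_rule_b += 1
        if not stats:
            logger.warning("cohort %s has no sites; retained set empty", pop)
        retained[pop] = keep
        n_total = sum(1 for s in stats if s.ac > 0)
        rows.append(
            {
                "population": pop,
                "n_sites": n_total,
                "retained": len(keep),
                "rule_a": n_rule_a,
                "rule_b_singleton_rescue": n_rule_b,
                "proportion_retained": len(keep) / n_total if n_total else float("nan"),
            }
        )
    return retained, pd.DataFrame(rows)


def sharing_spectrum(
    cohorts: list[tuple[str, list[SiteStats]]],
    externals: list[set[VariantKey]] | None = None,
    maf_bins: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Classify each cohort's segregating sites by sharing category and MAF.

    Categories partition each cohort's sites: ``external`` (present in any
    external resource), ``cohort_shared`` (absent externally but present in
    another study cohort) and ``private`` (this cohort only).  MAF bins are
    half-open ``(lo, hi]`` intervals on the cohort's own MAF.
    """
    if maf_bins is None:
        maf_bins = [(0.0, 0.005), (0.005, 0.01), (0.01, 0.05), (0.05, 0.5)]
    for (lo, hi) in maf_bins:
        if not (0.0 <= lo < hi <= 0.5):
            raise ValueError(f"invalid MAF bin ({lo}, {hi}]")
    for (a, b), (c, d) in zip(maf_bins, maf_bins[1:]):
        if b > c:
            raise ValueError("MAF bins overlap")
    externals = externals or []
    ext_union: set[VariantKey] = set().union(*externals) if externals else set()
    cohort_keys = {pop: {s.key for s in stats if s.ac > 0} for pop, stats in cohorts}

    rows = []
    for pop, stats in cohorts:
        other = set()
        for other_pop, keys in cohort_keys.items():
            if other_pop != pop:
                other |= keys
        for lo, hi in maf_bins:
            counts = {"private": 0, "cohort_shared": 0, "external": 0}
            for s in stats:
                if s.ac == 0 or s.an == 0:
                    continue
                m = s.maf
                in_bin = (lo < m <= hi) or (lo == 0.0 and m == 0.0)
                if not in_bin:
                    continue
                if s.key in ext_union:
                    counts["external"] += 1
                elif s.key in other:
                    counts["cohort_shared"] += 1
                else:
                    counts["private"] += 1
            rows.append(
                {
                    "population": pop, "maf_lo": lo, "maf_hi": hi,
                    "private": counts["private"],
                    "cohort_shared": counts["cohort_shared"],
                    "external": counts["external"],
                    "total": sum(counts.values()),
                }
            )
    return pd.DataFrame(rows)
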