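"""Imputation-quality metrics and GWAS variant-QC / meta-analysis rules.

Implements the IMPUTE-type info score (statistical information about the
allele-frequency estimate carried by the posterior genotype probabilities),
the truth-vs-dosage concordance r² stratified by MAF, the well-imputed
tabulation at an info-score threshold, the two-band MAF/info QC filter used
before association testing, and a sample-size-weighted (Stouffer) meta-
analysis with a direction-consistency filter and Bonferroni significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, PosteriorGenotypes

DEFAULT_MAF_BINS: list[tuple[float, float]] = [
    (0.0, 0.005),
    (0.005, 0.01),
    (0.01, 0.05),
    (0.05, 0.5),
]


def info_score(probs: np.ndarray) -> float:
    """IMPUTE info score for one site from N posterior triples.

    With e_i = p_i1 + 2 p_i2, f_i = p_i1 + 4 p_i2 and theta = sum(e_i)/(2N):

        info = 1 - sum(f_i - e_i^2) / (2 N theta (1 - theta))

    clamped to [0, 1].  When the estimated frequency is 0 or 1 the score is
    defined as 1 (a monomorphic call carries full information about itself).
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
        raise ValueError("need an (N, 3) array of posterior triples")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("invalid posterior triples")
    n = p.shape[0]
    e = p[:, 1] + 2.0 * p[:, 2]
    f = p[:, 1] + 4.0 * p[:, 2]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    raw = 1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta))
    return float(min(1.0, max(0.0, raw)))


def _truth_maf(truth: np.ndarray) -> np.ndarray:
    called = truth != MISSING
    an = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, np.where(called, truth, 0).sum(axis=0) / np.maximum(an, 1), np.nan)
    return np.minimum(af, 1.0 - af)


def _bin_index(maf: float, bins: list[tuple[float, float]]) -> int:
    """Half-open (lo, hi] bins; MAF 0 falls in the lowest bin."""
    for b, (lo, hi) in enumerate(bins):
        if (lo < maf <= hi) or (lo == 0.0 and maf == 0.0):
            return b
    return -1


def concordance_r2_by_maf(
    truth: np.ndarray,
    posteriors: PosteriorGenotypes,
    maf_bins: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-MAF-bin mean squared Pearson correlation between true dosage and
    imputed expected dosage.

    Per site, r² is computed across samples with a called truth genotype;
    sites where either vector has zero variance are excluded from the mean
    and counted in ``n_excluded``.  Bins are assigned by truth-panel MAF.
    Note r² is sign-blind: a perfectly anti-correlated dosage also scores 1.
    """
    truth = np.asarray(truth)
    if truth.shape != (posteriors.n_samples, posteriors.n_sites):
        raise ValueError("truth matrix not aligned with posteriors")
    if maf_bins is None:
        maf_bins = DEFAULT_MAF_BINS
    dosage = posteriors.expected_dosage()
    maf = _truth_maf(truth)

    per_bin_r2: list[list[float]] = [[] for _ in maf_bins]
    n_excluded = [0] * len(maf_bins)
    for j in range(truth.shape[1]):
        b = _bin_index(float(maf[j]), maf_bins) if np.isfinite(maf[j]) else -1
        if b < 0:
            continue
        called = truth[:, j] != MISSING
        t = truth[called, j].astype(np.float64)
        d = dosage[called, j]
        if t.size < 2 or np.var(t) == 0.0 or np.var(d) == 0.0:
            n_excluded[b] += 1
            continue
        r = np.corrcoef(t, d)[0, 1]
        per_bin_r2[b].append(float(r * r))
    return pd.DataFrame(
        {
            "maf_lo": [lo for lo, _ in maf_bins],
            "maf_hi": [hi for _, hi in maf_bins],
            "n_sites": [len(v) for v in per_bin_r2],
            "n_excluded": n_excluded,
            "mean_r2": [float(np.mean(v)) if v else np.nan for v in per_bin_r2],
        }
    )


def well_imputed_table(
    info_scores: np.ndarray,
    mafs: np.ndarray,
    maf_bins: list[tuple[float, float]] | None = None,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Count and proportion of sites with info >= threshold per MAF bin.

    The default lowest bin (MAF <= 0.5%) is the rare class on which
    study-specific reference panels improve the most.
    """
    if maf_bins is None:
        maf_bins = DEFAULT_MAF_BINS
    info_scores = np.asarray(info_scores, dtype=np.float64)
    mafs = np.asarray(mafs, dtype=np.float64)
    if info_scores.shape != mafs.shape:
        raise ValueError("info scores and MAFs must align")
    rows = []
    for lo, hi in maf_bins:
        in_bin = np.array([
            _bin_index(float(m), maf_bins) == maf_bins.index((lo, hi))
            if np.isfinite(m) else False
            for m in mafs
        ])
        total = int(in_bin.sum())
        n_well = int((info_scores[in_bin] >= threshold).sum()) if total else 0
        rows.append(
            {
                "maf_lo": lo, "maf_hi": hi, "threshold": threshold,
                "n_well_imputed": n_well, "n_total": total,
                "proportion": n_well / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def gwas_qc_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Variant QC before association testing, on columns ``maf`` and ``info``.

    Keep a variant iff (MAF >= 1% and info > 0.4) or (0.1% <= MAF < 1% and
    info >= 0.8).  Variants with MAF < 0.1% are dropped regardless of info.
    The common band excludes info == 0.4 exactly (scores <= 0.4 are removed);
    the rare band keeps info == 0.8.
    """
    if not {"maf", "info"} <= set(variants.columns):
        raise ValueError("need columns: maf, info")
    maf = variants["maf"].to_numpy(dtype=np.float64)
    info = variants["info"].to_numpy(dtype=np.float64)
    keep = ((maf >= 0.01) & (info > 0.4)) | ((maf >= 0.001) & (maf < 0.01) & (info >= 0.8))
    return variants.loc[keep].copy()


@dataclass
class CohortAssoc:
    """One cohort's association result for one variant."""

    population: str
    z: float
    n: int

    @property
    def sign(self) -> int:
        return 0 if self.z == 0 else (1 if self.z > 0 else -1)


def meta_analyze(
    per_variant: dict[str, list[CohortAssoc]],
    n_tests: int,
    min_concordant: int = 2,
) -> pd.DataFrame:
    """Sample-size-weighted (Stouffer) meta-analysis with direction filter.

    Per variant, meta z = sum(sqrt(n_i) z_i) / sqrt(sum n_i) over the cohorts
    carrying it, with a two-sided normal p.  A variant is excluded (flagged,
    not dropped) unless at least ``min_concordant`` cohorts carry it with the
    same effect sign.  Significance is Bonferroni: p < 0.05 / n_tests.
    """
    from scipy.stats import norm

    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    rows = []
    for vid, cohorts in per_variant.items():
        if not cohorts:
            rows.append(
                {"variant": vid, "n_cohorts": 0, "meta_z": np.nan, "p": np.nan,
                 "excluded": True, "reason": "absent_from_all_cohorts",
                 "significant": False}
            )
            continue
        w = np.sqrt([c.n for c in cohorts])
        z = np.array([c.z for c in cohorts])
        meta_z = float((w * z).sum() / np.sqrt((w**2).sum()))
        p = float(2.0 * norm.sf(abs(meta_z)))
        pos = sum(1 for c in cohorts if c.sign > 0)
        neg = sum(1 for c in cohorts if c.sign < 0)
        concordant = max(pos, neg) >= min_concordant
        reason = "" if concordant else (
            "single_cohort" if len(cohorts) < min_concordant else "direction_discordant"
        )
        rows.append(
            {
                "variant": vid, "n_cohorts": len(cohorts), "meta_z": meta_z, "p": p,
                "excluded": not concordant, "reason": reason,
                "significant": concordant and p < 0.05 / n_tests,
            }
        )
    return pd.DataFrame(rows)
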