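"""Population structure: LD pruning, PCA, pairwise Fst, ROH, inbreeding.

The Fst estimator is Weir & Cockerham (1984), aggregated genome-wide as the
ratio of summed variance components (ratio of averages).  ROH detection
follows the PLINK sliding-window heuristic; the inbreeding coefficient is
the method-of-moments excess-homozygosity estimator PLINK reports as F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING


def _maf_from_genotypes(g: np.ndarray) -> np.ndarray:
    called = g != MISSING
    an = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, np.where(called, g, 0).sum(axis=0) / np.maximum(an, 1), np.nan)
    return np.minimum(af, 1.0 - af)


def _impute_mean(g: np.ndarray) -> np.ndarray:
    """Per-site mean imputation of missing genotypes (float output)."""
    x = g.astype(np.float64)
    x[g == MISSING] = np.nan
    means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    idx = np.where(np.isnan(x))
    x[idx] = means[idx[1]]
    return x


def _genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (mean-imputed)."""
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: np.ndarray,
    window_sites: int = 200,
    step_sites: int = 50,
    r2_max: float = 0.4,
    maf_min: float = 0.02,
) -> np.ndarray:
    """PLINK ``--indep-pairwise``-style LD pruning; returns kept site indices.

    Sites with MAF < ``maf_min`` are removed first.  Then a window of
    ``window_sites`` surviving sites slides in steps of ``step_sites``;
    within each window, while any pair of kept sites has genotype r² >
    ``r2_max``, the later member of the first offending pair (site order) is
    removed.  The result does not depend on sample ordering.
    """
    g = np.asarray(genotypes)
    n_sites = g.shape[1]
    maf = _maf_from_genotypes(g)
    kept = np.zeros(n_sites, dtype=bool)
    kept[np.isfinite(maf) & (maf >= maf_min)] = True
    x = _impute_mean(g)

    start = 0
    while start < n_sites:
        window = [j for j in range(start, min(start + window_sites, n_sites)) if kept[j]]
        if len(window) > 1:
            cols = x[:, window]
            sd = cols.std(axis=0)
            nonconst = sd > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (cols - cols.mean(axis=0)) / np.where(nonconst, sd, 1.0)
            r2 = (z.T @ z / cols.shape[0]) ** 2
            r2[~nonconst, :] = 0.0
            r2[:, ~nonconst] = 0.0
            alive = list(range(len(window)))
            removed = True
            while removed:
                removed = False
                for ai, a in enumerate(alive):
                    for b in alive[ai + 1:]:
                        if r2[a, b] > r2_max:
                            kept[window[b]] = False
                            alive.remove(b)
                            removed = True
                            break
                    if removed:
                        break
        start += step_sites
    return np.flatnonzero(kept)


def pca(genotypes: np.ndarray, n_components: int = 10):
    """PCA of a genotype matrix in the standard array scaling.

    Columns are centered and divided by sqrt(2 p (1-p)) with p the
    alternative-allele frequency; missing genotypes are mean-imputed per
    site before scaling.  Returns (coordinates, variance_explained,
    loadings); component signs follow the convention that each component's
    largest-magnitude loading is positive.
    """
    g = np.asarray(genotypes)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 sites")
    x = _impute_mean(g)
    p = x.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    use = (scale > 0) & (x.var(axis=0) > 0)
    if not use.any():
        raise ValueError("genotype matrix has no variable site")
    z = (x[:, use] - 2.0 * p[use]) / scale[use]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, s.size)
    var = s**2
    explained = var[:k] / var.sum()
    coords = u[:, :k] * s[:k]
    loadings = vt[:k]
    for c in range(k):
        if loadings[c, np.argmax(np.abs(loadings[c]))] < 0:
            loadings[c] = -loadings[c]
            coords[:, c] = -coords[:, c]
    return coords, explained, loadings


def _wc_components(g1: np.ndarray, g2: np.ndarray):
    """Weir–Cockerham (1984) per-locus variance components a, b, c for two
    populations, vectorized over loci.  Loci with < 2 called samples in
    either population or monomorphic across both return NaN components."""
    r = 2.0
    comps = []
    for g in (g1, g2):
        called = g != MISSING
        n = called.sum(axis=0).astype(np.float64)  # diploid sample sizes
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, g, 0).sum(axis=0) / (2.0 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, np.where(called, g == 1, False).sum(axis=0) / np.maximum(n, 1), np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(pbar)
    mono = (pbar == 0.0) | (pbar == 1.0)
    for arr in (a, b, c):
        arr[bad | mono] = np.nan
    return a, b, c


def fst_weir_cockerham(g1: np.ndarray, g2: np.ndarray) -> tuple[float, int]:
    """Genome-wide Weir–Cockerham Fst between two genotype matrices sharing
    a site list: sum(a) / sum(a + b + c) over usable loci.  Returns
    (fst, n_loci_used)."""
    a, b, c = _wc_components(np.asarray(g1), np.asarray(g2))
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if ok.sum() == 0 or denom == 0.0:
        return float("nan"), int(ok.sum())
    return float(a[ok].sum() / denom), int(ok.sum())


def pairwise_fst(populations: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Weir–Cockerham Fst over >= 2 populations sharing a key list.

    Returns (fst_matrix, n_loci_matrix) as labelled DataFrames; the diagonal
    is 0.  Small negative estimates are possible and left as-is.
    """
    labels = list(populations)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    fst = pd.DataFrame(0.0, index=labels, columns=labels)
    nloci = pd.DataFrame(0, index=labels, columns=labels)
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            f, n = fst_weir_cockerham(populations[x], populations[y])
            fst.loc[x, y] = fst.loc[y, x] = f
            nloci.loc[x, y] = nloci.loc[y, x] = n
    return fst, nloci


@dataclass
class RohSegment:
    """One run of homozygosity; coordinates 1-based inclusive."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_sites: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class RohParams:
    """PLINK-style ROH scan parameters (PLINK documentation defaults)."""

    window_sites: int = 50
    max_het_per_window: int = 1
    min_sites: int = 100
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    # PLINK --homozyg-window-threshold default: a site joins a run when at
    # least this fraction of the windows covering it is homozygous-compatible
    hom_window_fraction: float = 0.05


def detect_roh(
    genotypes: np.ndarray,
    positions: np.ndarray,
    sample_ids: list[str],
    params: RohParams | None = None,
    chrom: str = "1",
) -> tuple[list[RohSegment], pd.DataFrame]:
    """Sliding-window ROH detection, one chromosome at a time.

    Per sample, every window of ``window_sites`` consecutive sites is scored
    homozygous-compatible when it contains at most ``max_het_per_window``
    heterozygous calls; a site is flagged when at least
    ``hom_window_fraction`` of the windows covering it are compatible.
    Maximal runs of flagged, non-heterozygous sites (inter-site gaps at most
    ``max_gap_bp``) that satisfy ``min_sites`` and ``min_length_bp`` become
    segments.  Returns the segments and per-sample totals.
    """
    if params is None:
        params = RohParams()
    g = np.asarray(genotypes)
    positions = np.asarray(positions, dtype=np.int64)
    n_samples, n_sites = g.shape
    if n_sites != positions.size:
        raise ValueError("positions must align with genotype columns")
    if n_sites > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")

    w = min(params.window_sites, n_sites)
    segments: list[RohSegment] = []
    for s in range(n_samples):
        het = (g[s] == 1).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(het)))
        n_windows = n_sites - w + 1
        win_het = csum[w:] - csum[:-w]  # het count per window start
        win_ok = win_het <= params.max_het_per_window
        ok_csum = np.concatenate(([0], np.cumsum(win_ok.astype(np.int64))))
        flagged = np.zeros(n_sites, dtype=bool)
        for j in range(n_sites):
            lo = max(0, j - w + 1)
            hi = min(j, n_windows - 1)
            if hi < lo:
                continue
            n_cover = hi - lo + 1
            n_good = ok_csum[hi + 1] - ok_csum[lo]
            flagged[j] = n_good >= params.hom_window_fraction * n_cover

        run_ok = flagged & (g[s] != 1)
        j = 0
        while j < n_sites:
            if not run_ok[j]:
                j += 1
                continue
            k = j
            while (
                k + 1 < n_sites
                and run_ok[k + 1]
                and positions[k + 1] - positions[k] <= params.max_gap_bp
            ):
                k += 1
            n_called_hom = int(((g[s, j : k + 1] == 0) | (g[s, j : k + 1] == 2)).sum())
            length = int(positions[k] - positions[j] + 1)
            if n_called_hom >= params.min_sites and length >= params.min_length_bp:
                segments.append(
                    RohSegment(
                        sample_id=sample_ids[s], chrom=chrom,
                        start=int(positions[j]), end=int(positions[k]),
                        n_sites=n_called_hom,
                    )
                )
            j = k + 1

    totals = []
    for sid in sample_ids:
        segs = [x for x in segments if x.sample_id == sid]
        totals.append(
            {
                "sample_id": sid,
                "n_segments": len(segs),
                "total_length_bp": sum(x.length_bp for x in segs),
            }
        )
    return segments, pd.DataFrame(totals)


def inbreeding_f(
    genotypes: np.ndarray,
    allele_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Method-of-moments inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (L - E_hom), with E_hom = sum(1 - 2 p_i (1 - p_i))
    over the L sites called in the sample; p defaults to the pooled-sample
    alternative-allele frequency.  Samples where L == E_hom return NaN.
    """
    g = np.asarray(genotypes)
    if allele_freqs is None:
        called = g != MISSING
        an = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            allele_freqs = np.where(
                an > 0, np.where(called, g, 0).sum(axis=0) / np.maximum(an, 1), np.nan
            )
    p = np.asarray(allele_freqs, dtype=np.float64)
    out = np.empty(g.shape[0])
    for s in range(g.shape[0]):
        called = (g[s] != MISSING) & np.isfinite(p)
        L = int(called.sum())
        e_hom = float((1.0 - 2.0 * p[called] * (1.0 - p[called])).sum())
        o_hom = int(((g[s, called] == 0) | (g[s, called] == 2)).sum())
        denom = L - e_hom
        out[s] = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else np.nan
    return out
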