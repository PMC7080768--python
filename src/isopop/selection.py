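"""Haplotype-based selection scans: EHH, iHS, gene-level candidate calling.

EHH(x) for a core allele is the probability that two randomly drawn carrier
haplotypes are identical over the interval from the core site out to x.  iHH
integrates EHH over physical distance (trapezoid rule) until it decays below
a cutoff; iHS is ln(iHH_ancestral / iHH_derived), standardized within
derived-allele-frequency bins so that extreme scores are comparable across
frequencies.  Genes accumulate evidence through the count of markers with
|standardized iHS| over a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HaplotypePanel, VariantKey


def _homozygosity(groups: np.ndarray) -> float:
    """Probability two distinct rows fall in the same group: sum C(n_h,2)/C(n,2)."""
    n = groups.size
    if n < 2:
        return float("nan")
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_curve(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    core_allele: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EHH among carriers of ``core_allele`` at ``core_index``, both sides.

    Returns (left, right) DataFrames with columns ``site_index``,
    ``distance_bp`` and ``ehh``; each starts at the core (distance 0,
    EHH = 1) and is monotonically non-increasing outward.  Requires at least
    two carrier haplotypes.
    """
    h = np.asarray(haplotypes)
    positions = np.asarray(positions, dtype=np.int64)
    carriers = np.flatnonzero(h[:, core_index] == core_allele)
    if carriers.size < 2:
        raise ValueError("EHH undefined with fewer than two carriers")
    sub = h[carriers]

    def walk(indices):
        rows = [{"site_index": core_index, "distance_bp": 0, "ehh": 1.0}]
        groups = np.zeros(carriers.size, dtype=np.int64)
        for j in indices:
            codes = groups * 2 + sub[:, j]
            _, groups = np.unique(codes, return_inverse=True)
            rows.append(
                {
                    "site_index": int(j),
                    "distance_bp": int(abs(positions[j] - positions[core_index])),
                    "ehh": _homozygosity(groups),
                }
            )
        return pd.DataFrame(rows)

    left = walk(range(core_index - 1, -1, -1))
    right = walk(range(core_index + 1, h.shape[1]))
    return left, right


@dataclass
class IhsResult:
    """Per-site iHS scan result; ``valid`` is False when the EHH integral
    could not be completed (reason in ``reason``)."""

    key: VariantKey
    derived_freq: float
    ihh_ancestral: float = float("nan")
    ihh_derived: float = float("nan")
    ihs_unstd: float = float("nan")
    ihs_std: float = float("nan")
    valid: bool = False
    reason: str = ""
    site_index: int = -1
    pos: int = field(default=0)


try:  # numba accelerates the per-site EHH extension ~100x
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard runtime dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=False)
def _ihh_side_kernel(
    haps, carriers, positions, core_index, step,
    ehh_cutoff, max_gap_bp, max_extend_bp,
):  # pragma: no cover - exercised through ihs_scan
    """Trapezoid EHH integral from the core outward (step = +1 or -1).

    Returns (area, code): code 0 = reached the cutoff (or the extension
    cap, which truncates but stays valid), 1 = chromosome edge before the
    cutoff, 2 = inter-marker gap above the limit.  Group refinement uses a
    first-seen relabelling per marker, O(carriers) per step.
    """
    n = carriers.size
    n_sites = positions.size
    groups = np.zeros(n, dtype=np.int64)
    new_groups = np.zeros(n, dtype=np.int64)
    n_groups = 1
    ehh_prev = 1.0
    pos_prev = positions[core_index]
    area = 0.0
    pair_total = n * (n - 1) / 2.0
    j = core_index + step
    while True:
        if j < 0 or j >= n_sites:
            return area, 1
        gap = positions[j] - pos_prev
        if gap < 0:
            gap = -gap
        if gap > max_gap_bp:
            return area, 2
        # split every group by the allele carried at marker j
        seen = np.full((n_groups, 2), -1, dtype=np.int64)
        n_new = 0
        for c in range(n):
            a = haps[carriers[c], j]
            g = groups[c]
            if seen[g, a] < 0:
                seen[g, a] = n_new
                n_new += 1
            new_groups[c] = seen[g, a]
        tmp = groups
        groups = new_groups
        new_groups = tmp
        n_groups = n_new
        counts = np.zeros(n_groups, dtype=np.int64)
        for c in range(n):
            counts[groups[c]] += 1
        same = 0.0
        for k in range(n_groups):
            same += counts[k] * (counts[k] - 1) / 2.0
        ehh = same / pair_total
        area += 0.5 * (ehh_prev + ehh) * gap
        if ehh < ehh_cutoff:
            return area, 0
        dist = positions[j] - positions[core_index]
        if dist < 0:
            dist = -dist
        if dist >= max_extend_bp:
            return area, 0
        ehh_prev = ehh
        pos_prev = positions[j]
        j += step


_SIDE_REASONS = {0: "", 1: "edge", 2: "gap"}


def _ihh_one_side(
    haps: np.ndarray,
    carriers: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    step: int,
    ehh_cutoff: float,
    max_gap_bp: int,
    max_extend_bp: int,
) -> tuple[float, str]:
    area, code = _ihh_side_kernel(
        haps, carriers, positions, core_index, step,
        ehh_cutoff, float(max_gap_bp), float(max_extend_bp),
    )
    return float(area), _SIDE_REASONS[int(code)]


def ihs_scan(
    panel: HaplotypePanel,
    ancestral_is_ref: bool = True,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    max_extend_bp: int = 2_000_000,
    max_gap_bp: int = 200_000,
) -> list[IhsResult]:
    """Unstandardized iHS for every site with MAF > ``maf_min``.

    Per site, iHH for the ancestral-allele carriers and the derived-allele
    carriers is the trapezoid integral of EHH against physical distance,
    summed over both directions, each direction truncated at the first
    marker where EHH < ``ehh_cutoff``.  Sites whose integral hits the
    chromosome edge or an inter-marker gap > ``max_gap_bp`` before the
    cutoff are flagged invalid.  The ancestral allele is the REF allele
    (synthetic truth) unless ``ancestral_is_ref`` is False, which swaps the
    labels (scores negate).
    """
    h = panel.haplotypes
    positions = panel.positions
    n = h.shape[0]
    keys = panel.keys
    derived = 1 if ancestral_is_ref else 0
    freq = (h == derived).sum(axis=0) / n

    results: list[IhsResult] = []
    for j in range(h.shape[1]):
        df = float(freq[j])
        maf = min(df, 1.0 - df)
        res = IhsResult(
            key=keys[j], derived_freq=df, site_index=j, pos=int(positions[j])
        )
        if maf <= maf_min:
            res.reason = "low_maf"
            results.append(res)
            continue
        ihh = {}
        reason = ""
        for allele, label in ((1 - derived, "ancestral"), (derived, "derived")):
            carriers = np.flatnonzero(h[:, j] == allele)
            if carriers.size < 2:
                reason = "few_carriers"
                break
            total = 0.0
            for step in (-1, 1):
                area, why = _ihh_one_side(
                    h, carriers, positions, j, step, ehh_cutoff, max_gap_bp, max_extend_bp
                )
                total += area
                if why:
                    reason = why
            ihh[label] = total
            if reason:
                break
        if reason:
            res.reason = reason
            results.append(res)
            continue
        res.ihh_ancestral = ihh["ancestral"]
        res.ihh_derived = ihh["derived"]
        if ihh["ancestral"] > 0 and ihh["derived"] > 0:
            res.ihs_unstd = float(np.log(ihh["ancestral"] / ihh["derived"]))
            res.valid = True
        else:
            res.reason = "zero_ihh"
        results.append(res)
    return results


def standardize_ihs(results: list[IhsResult], n_freq_bins: int = 50) -> list[IhsResult]:
    """Standardize iHS within derived-allele-frequency bins (in place).

    Each occupied bin's valid scores get mean 0 and SD 1 (population SD);
    bins with fewer than two valid sites or zero spread are flagged
    unstandardizable (``ihs_std`` stays NaN, reason recorded).
    """
    edges = np.linspace(0.0, 1.0, n_freq_bins + 1)
    valid = [r for r in results if r.valid]
    bins = np.clip(
        np.searchsorted(edges, [r.derived_freq for r in valid], side="right") - 1,
        0, n_freq_bins - 1,
    )
    for b in range(n_freq_bins):
        members = [r for r, rb in zip(valid, bins) if rb == b]
        if not members:
            continue
        scores = np.array([r.ihs_unstd for r in members])
        if len(members) < 2 or scores.std() == 0.0:
            for r in members:
                r.ihs_std = float("nan")
                r.reason = "unstandardizable_bin"
            continue
        mu, sd = scores.mean(), scores.std()
        for r in members:
            r.ihs_std = float((r.ihs_unstd - mu) / sd)
    return results


@dataclass
class GeneSelectionCall:
    """Gene-level selection evidence in one population."""

    gene: str
    population: str
    n_markers_over_threshold: int
    threshold: float
    min_markers: int
    candidate: bool


def gene_selection_candidates(
    results: list[IhsResult],
    gene_intervals: list[tuple[str, str, int, int]],
    population: str,
    ihs_threshold: float = 2.0,
    min_markers: int = 20,
) -> list[GeneSelectionCall]:
    """Call genes under putative selection: at least ``min_markers`` markers
    inside the gene interval with |standardized iHS| >= ``ihs_threshold``.

    Intervals are 1-based inclusive; overlapping genes are allowed and a
    marker may count toward several genes.
    """
    hits = [
        (r.pos, abs(r.ihs_std))
        for r in results
        if r.valid and np.isfinite(r.ihs_std) and abs(r.ihs_std) >= ihs_threshold
    ]
    calls = []
    for gene, _chrom, start, end in gene_intervals:
        n = sum(1 for pos, _ in hits if start <= pos <= end)
        calls.append(
            GeneSelectionCall(
                gene=gene, population=population,
                n_markers_over_threshold=n, threshold=ihs_threshold,
                min_markers=min_markers, candidate=n >= min_markers,
            )
        )
    return calls


def selection_overlap(
    candidate_sets: dict[str, set[str]],
    reference: str | None = None,
) -> pd.DataFrame:
    """Shared/private structure of per-population candidate gene sets.

    For each population, the private fraction is the share of its candidate
    genes absent from the designated ``reference`` population's set (or,
    when no reference is given, absent from every other population).  The
    all-population intersection is reported on each row.
    """
    if len(candidate_sets) < 2:
        raise ValueError("need candidate sets for at least two populations")
    pops = list(candidate_sets)
    inter = set.intersection(*(set(candidate_sets[p]) for p in pops))
    rows = []
    for p in pops:
        mine = set(candidate_sets[p])
        if reference is not None and p != reference:
            other = set(candidate_sets[reference])
        else:
            other = set().union(*(set(candidate_sets[q]) for q in pops if q != p))
        private = mine - other
        rows.append(
            {
                "population": p,
                "n_candidates": len(mine),
                "n_private": len(private),
                "private_fraction": len(private) / len(mine) if mine else float("nan"),
                "n_all_population_shared": len(inter),
            }
        )
    return pd.DataFrame(rows)
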