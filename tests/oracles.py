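"""Independent brute-force oracles used by the test suite.

Everything here is written as plain-Python arithmetic over small inputs,
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations


def pearson_r2_oracle(x, y) -> float:
    """Squared Pearson correlation from the raw-sums textbook formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return (num / den) ** 2


def wc_fst_oracle(geno1, geno2) -> float:
    """Two-population Weir–Cockerham (1984) Fst, ratio-of-averages over
    loci, from scalar arithmetic.  ``genoX`` are lists of per-locus lists of
    diploid dosages (0/1/2, None = missing)."""
    num = den = 0.0
    for g1, g2 in zip(geno1, geno2):
        d1 = [g for g in g1 if g is not None]
        d2 = [g for g in g2 if g is not None]
        if len(d1) < 2 or len(d2) < 2:
            continue
        n1, n2 = float(len(d1)), float(len(d2))
        p1 = sum(d1) / (2 * n1)
        p2 = sum(d2) / (2 * n2)
        h1 = sum(1 for g in d1 if g == 1) / n1
        h2 = sum(1 for g in d2 if g == 1) / n2
        r = 2.0
        nbar = (n1 + n2) / r
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def inbreeding_oracle(genotypes, freqs) -> float:
    """Excess-homozygosity F for one sample from scalar arithmetic.

    ``genotypes``: list of dosages (None = missing); ``freqs``: per-site
    alternative allele frequency.
    """
    o_hom = 0
    e_hom = 0.0
    L = 0
    for g, p in zip(genotypes, freqs):
        if g is None:
            continue
        L += 1
        e_hom += 1.0 - 2.0 * p * (1.0 - p)
        if g in (0, 2):
            o_hom += 1
    return (o_hom - e_hom) / (L - e_hom)


def ehh_oracle(haplotypes, core, allele, upto) -> float:
    """EHH over the inclusive marker interval [min(core, upto),
    max(core, upto)] among carriers of ``allele`` at ``core``, by direct
    enumeration of distinct extended haplotypes."""
    carriers = [h for h in haplotypes if h[core] == allele]
    n = len(carriers)
    lo, hi = min(core, upto), max(core, upto)
    counts: dict[tuple, int] = {}
    for h in carriers:
        key = tuple(h[lo : hi + 1])
        counts[key] = counts.get(key, 0) + 1
    pairs = sum(c * (c - 1) // 2 for c in counts.values())
    return pairs / (n * (n - 1) // 2)


def ihh_oracle(
    haplotypes, positions, core, allele,
    ehh_cutoff=0.05, max_gap_bp=10**12, max_extend_bp=10**12,
):
    """Trapezoid EHH integral, both directions summed, by brute force.

    Mirrors the documented contract: each direction accumulates trapezoids
    marker-by-marker and stops after the first marker whose EHH falls below
    the cutoff (or truncates at ``max_extend_bp``); returns None if an edge
    or an oversized gap is hit first.
    """
    n_sites = len(positions)
    total = 0.0
    for step in (1, -1):
        prev_ehh = 1.0
        prev_pos = positions[core]
        j = core + step
        while True:
            if j < 0 or j >= n_sites:
                return None  # edge
            gap = abs(positions[j] - prev_pos)
            if gap > max_gap_bp:
                return None  # gap
            e = ehh_oracle(haplotypes, core, allele, j)
            total += 0.5 * (prev_ehh + e) * gap
            if e < ehh_cutoff:
                break
            if abs(positions[j] - positions[core]) >= max_extend_bp:
                break
            prev_ehh, prev_pos = e, positions[j]
            j += step
    return total


def ld_prune_oracle(genotypes, window_sites, step_sites, r2_max, maf_min):
    """Exhaustive re-application of the pruning rule with scalar loops.

    ``genotypes``: list of per-sample lists.  Returns kept column indices.
    """
    n_samples = len(genotypes)
    n_sites = len(genotypes[0])
    kept = []
    for j in range(n_sites):
        col = [genotypes[s][j] for s in range(n_samples)]
        p = sum(col) / (2 * len(col))
        if min(p, 1 - p) >= maf_min:
            kept.append(j)
    keep_flag = {j: True for j in kept}
    start = 0
    while start < n_sites:
        window = [j for j in kept if start <= j < start + window_sites and keep_flag[j]]
        changed = True
        while changed:
            changed = False
            for a, b in combinations(window, 2):
                xa = [genotypes[s][a] for s in range(n_samples)]
                xb = [genotypes[s][b] for s in range(n_samples)]
                va = len(set(xa)) > 1
                vb = len(set(xb)) > 1
                r2 = pearson_r2_oracle(xa, xb) if (va and vb) else 0.0
                if r2 > r2_max:
                    keep_flag[b] = False
                    window.remove(b)
                    changed = True
                    break
        start += step_sites
    return [j for j in kept if keep_flag[j]]


def drifted_oracle(x_rows, y_rows, ac_lo, ac_hi, rare_af):
    """Exhaustive drifted-set enumeration on toy tables.

    Rows are (key, ac, an); a variant is drifted in X when ac_lo <= AC_X <=
    ac_hi and AF in Y (0 when absent) is below ``rare_af``.
    """
    y_af = {k: (ac / an if an else 0.0) for k, ac, an in y_rows}
    out = set()
    for k, ac, an in x_rows:
        if ac_lo <= ac <= ac_hi and y_af.get(k, 0.0) < rare_af:
            out.add(k)
    return out
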