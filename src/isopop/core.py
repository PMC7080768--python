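"""Core containers shared across the pipeline.

Coordinates are 1-based throughout, matching VCF convention. Genotypes are
coded as alternative-allele dosage ``{0, 1, 2}`` with ``-1`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

MISSING = -1


class VariantKey(NamedTuple):
    """Exact identity of a biallelic variant: (chrom, pos, ref, alt).

    Two records refer to the same variant iff all four fields match exactly;
    no allele harmonization or left-normalization is attempted.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")


@dataclass
class CohortDataset:
    """Genotypes for one population cohort, aligned to a variant-key list.

    Attributes
    ----------
    population_id : str
        Cohort label.
    sample_ids : list of str
    keys : list of VariantKey
        One per site, same order as the genotype columns.
    genotypes : ndarray of shape (n_samples, n_sites)
        Alt-allele dosage 0/1/2, ``-1`` for missing.
    depths : ndarray or None
        Per-genotype read depth, same shape; ``-1`` for missing.
    haplotypes : ndarray or None
        Phased 0/1 matrix of shape (2 * n_samples, n_sites) when phase is
        available; row ``2i`` and ``2i+1`` are the two haplotypes of sample i.
    phased : bool
        Whether the source genotypes were phased.
    """

    population_id: str
    sample_ids: list[str]
    keys: list[VariantKey]
    genotypes: np.ndarray
    depths: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    phased: bool = False

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_samples, n_sites = self.genotypes.shape
        if n_samples != len(self.sample_ids):
            raise ValueError("genotype rows != number of samples")
        if n_sites != len(self.keys):
            raise ValueError("genotype columns != number of variant keys")
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.genotypes.shape:
                raise ValueError("depth matrix shape mismatch")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * n_samples, n_sites):
                raise ValueError("haplotype matrix must have 2 rows per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.keys)

    @property
    def positions(self) -> np.ndarray:
        return np.array([k.pos for k in self.keys], dtype=np.int64)


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrix for one population.

    Rows come in pairs (two per diploid sample); columns follow ``positions``,
    which must be strictly increasing 1-based coordinates on ``chrom``.
    Allele 0 is ``ref`` (treated as ancestral by the synthetic truth), allele 1
    is ``alt`` (derived).
    """

    population_id: str
    sample_ids: list[str]
    haplotypes: np.ndarray
    positions: np.ndarray
    ref_alleles: list[str]
    alt_alleles: list[str]
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n_hap, n_sites = self.haplotypes.shape
        if n_hap % 2 != 0:
            raise ValueError("haplotype row count must be even (two per sample)")
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError("need exactly two haplotypes per sample")
        if n_sites != len(self.positions):
            raise ValueError("columns != number of positions")
        if len(self.ref_alleles) != n_sites or len(self.alt_alleles) != n_sites:
            raise ValueError("allele lists must match site count")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        for r, a in zip(self.ref_alleles, self.alt_alleles):
            if not r or not a or r == a:
                raise ValueError("alleles must be non-empty and ref != alt")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(self.chrom, int(p), r, a)
            for p, r, a in zip(self.positions, self.ref_alleles, self.alt_alleles)
        ]

    def genotypes(self) -> np.ndarray:
        """Collapse haplotype pairs to dosage genotypes (n_samples, n_sites)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def to_dataset(self, depths: np.ndarray | None = None) -> CohortDataset:
        return CohortDataset(
            population_id=self.population_id,
            sample_ids=list(self.sample_ids),
            keys=self.keys,
            genotypes=self.genotypes(),
            depths=depths,
            haplotypes=self.haplotypes.copy(),
            phased=True,
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation of one variant, VEP-style.

    ``affected_transcripts`` is the subset of the gene's transcripts on which
    the consequence is predicted; ``n_transcripts`` is the gene total.
    """

    key: VariantKey
    gene: str
    n_transcripts: int
    affected_transcripts: frozenset[str]
    consequence: str
    cadd_phred: float

    def __post_init__(self) -> None:
        if self.cadd_phred < 0:
            raise ValueError("CADD phred score cannot be negative")
        if len(self.affected_transcripts) > self.n_transcripts:
            raise ValueError("affected transcripts exceed gene transcript count")


@dataclass
class PosteriorGenotypes:
    """Imputation output: per sample/site genotype posterior triples.

    ``probs`` has shape (n_samples, n_sites, 3) with the probabilities of
    dosage 0, 1 and 2; each triple must sum to 1.
    """

    sample_ids: list[str]
    keys: list[VariantKey]
    probs: np.ndarray
    tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probs must have shape (n_samples, n_sites, 3)")
        if self.probs.shape[0] != len(self.sample_ids):
            raise ValueError("probs rows != number of samples")
        if self.probs.shape[1] != len(self.keys):
            raise ValueError("probs columns != number of keys")
        if np.any(self.probs < -self.tol):
            raise ValueError("negative posterior probability")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > self.tol):
            raise ValueError("posterior triples must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.keys)

    def expected_dosage(self) -> np.ndarray:
        """E[dosage] = p1 + 2*p2 per sample/site, shape (n_samples, n_sites)."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def hard_calls(self, threshold: float = 0.0) -> np.ndarray:
        """Best-guess genotypes; ``-1`` where the max posterior < threshold."""
        calls = np.argmax(self.probs, axis=2).astype(np.int8)
        if threshold > 0:
            calls[self.probs.max(axis=2) < threshold] = MISSING
        return calls


def folded_sfs(genotype_or_haplotypes: np.ndarray) -> np.ndarray:
    """Folded site-frequency spectrum from a 0/1 haplotype matrix.

    Returns counts of sites per minor-allele count 1..floor(n/2); monomorphic
    sites are ignored.
    """
    h = np.asarray(genotype_or_haplotypes)
    n = h.shape[0]
    ac = h.sum(axis=0)
    mac = np.minimum(ac, n - ac)
    out = np.zeros(n // 2, dtype=np.int64)
    for c in mac:
        if 1 <= c <= n // 2:
            out[int(c) - 1] += 1
    return out
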