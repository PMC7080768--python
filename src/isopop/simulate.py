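"""Synthetic multi-population cohorts with the structure the analyses assume.

The generator emulates a set of isolated populations derived from a common
base pool: the base panel is built as Li–Stephens-style recombinant mosaics of
a small set of founder haplotypes (geometric switch distances give realistic
LD decay), isolates are derived through founder bottlenecks (drift, long ROH,
elevated inbreeding, nonzero Fst), sweeps can be planted as homogenized
haplotype flanks around a focal allele, sites receive VEP-like annotations
with a CADD-like two-component score mixture, and imputation output is
emulated by corrupting true genotypes into posterior triples with
MAF-dependent noise.

Every operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import MISSING, AnnotationRecord, HaplotypePanel, PosteriorGenotypes, VariantKey

HIGH_IMPACT_TERMS = (
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "transcript_ablation",
    "transcript_amplification",
)

BENIGN_TERMS = (
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
)

_BASES = ("A", "C", "G", "T")


@dataclass
class SweepSpec:
    """A planted selective sweep: focal position, carrier fraction and the
    flank (bp, each side) homogenized among carriers."""

    focal_pos: int
    carrier_fraction: float = 0.5
    flank_bp: int = 500_000

    def validate(self) -> None:
        if not (0.0 < self.carrier_fraction < 1.0):
            raise ValueError("carrier_fraction must be in (0, 1)")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


@dataclass
class AnnotationSpec:
    """Parameters of the synthetic VEP-like annotation layer.

    ``p_high_impact`` is the probability a site receives one of the eight
    high-impact consequence terms.  CADD-like phred scores come from a
    two-component mixture: a gamma bulk (low scores) and a shifted
    exponential right tail, with the tail weight depending on impact class so
    all four CADD bins (0–5, 5–15, 15–20, >20) are populated.  Scores are
    synthetic stand-ins and are never interpreted as real CADD.
    """

    p_high_impact: float = 0.01
    high_impact_terms: tuple[str, ...] = HIGH_IMPACT_TERMS
    benign_terms: tuple[str, ...] = BENIGN_TERMS
    n_genes: int = 100
    transcripts_per_gene: tuple[int, int] = (1, 8)
    p_all_transcripts: float = 0.5
    cadd_bulk_shape: float = 2.0
    cadd_bulk_scale: float = 2.5
    cadd_tail_shift: float = 15.0
    cadd_tail_scale: float = 6.0
    p_tail_benign: float = 0.06
    p_tail_high_impact: float = 0.7

    def validate(self) -> None:
        for p in (self.p_high_impact, self.p_all_transcripts,
                  self.p_tail_benign, self.p_tail_high_impact):
            if not (0.0 <= p <= 1.0):
                raise ValueError("annotation probabilities must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        lo, hi = self.transcripts_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid transcripts_per_gene range")


@dataclass
class PosteriorNoise:
    """MAF-dependent imputation-error model.

    Per site, the miscall probability is ``rate * (1 - 2*maf*(1-maf))``:
    rare sites (small MAF) are imputed worse than common ones, the standard
    behaviour of reference-panel imputation.  With probability eps the
    posterior mode is drawn from the Hardy–Weinberg genotype distribution
    instead of the truth, and a fraction eps/2 of posterior mass is spread
    over the HWE prior (soft calls).
    """

    rate: float = 0.1

    def validate(self) -> None:
        if self.rate < 0:
            raise ValueError("noise rate cannot be negative")

    def site_error(self, maf: np.ndarray) -> np.ndarray:
        return np.clip(self.rate * (1.0 - 2.0 * maf * (1.0 - maf)), 0.0, 0.99)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort set."""

    seed: int = 0
    n_founders: int = 40
    n_haplotypes_base: int = 200
    n_sites: int = 20_000
    chrom_length_bp: int = 20_000_000
    mutation_rate_per_copy: float = 2e-4
    recombination_switch_rate_per_bp: float = 5e-6
    bottleneck_founders: tuple[int, ...] = (20, 40, 80)
    n_isolate_generations: int = 2
    n_out_haplotypes: int = 100
    mean_depth: float = 10.0
    missing_rate: float = 0.0
    sweep: SweepSpec | None = None
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)
    posterior_noise: PosteriorNoise = field(default_factory=PosteriorNoise)

    def validate(self) -> None:
        for name in ("n_founders", "n_haplotypes_base", "n_sites", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mutation_rate_per_copy < 0 or self.recombination_switch_rate_per_bp < 0:
            raise ValueError("rates cannot be negative")
        if any(b <= 0 for b in self.bottleneck_founders):
            raise ValueError("bottleneck founder counts must be positive")
        if self.n_isolate_generations < 0:
            raise ValueError("n_isolate_generations cannot be negative")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.sweep is not None:
            self.sweep.validate()
        self.annotation.validate()
        self.posterior_noise.validate()


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    refs = [_BASES[i] for i in ref_idx]
    alts = [_BASES[(i + o) % 4] for i, o in zip(ref_idx, alt_off)]
    return refs, alts


def _mosaic_rows(
    rng: np.random.Generator,
    founders: np.ndarray,
    positions: np.ndarray,
    n_out: int,
    switch_rate_per_bp: float,
    mutation_rate: float,
    first_rows_in_order: bool = False,
) -> np.ndarray:
    """Build n_out recombinant mosaics of the founder rows.

    Copying switches founder with probability 1 - exp(-rate * gap_bp) between
    adjacent sites, then per-site mutations flip alleles with probability
    ``mutation_rate``.  With both rates zero each output row is a verbatim
    founder copy; if ``first_rows_in_order`` the first ``len(founders)`` rows
    copy founders 0..k-1 in order (used to realize exact permutations).
    """
    n_f, n_sites = founders.shape
    gaps = np.diff(positions).astype(np.float64)
    p_switch = -np.expm1(-switch_rate_per_bp * gaps) if n_sites > 1 else np.empty(0)
    out = np.empty((n_out, n_sites), dtype=np.int8)
    for h in range(n_out):
        if first_rows_in_order and h < n_f:
            start = h
        else:
            start = int(rng.integers(0, n_f))
        if n_sites > 1 and switch_rate_per_bp > 0:
            switches = rng.random(n_sites - 1) < p_switch
            seg = np.concatenate(([0], np.cumsum(switches)))
            n_seg = int(seg[-1]) + 1
            donors = np.concatenate(([start], rng.integers(0, n_f, size=n_seg - 1)))
            out[h] = founders[donors[seg], np.arange(n_sites)]
        else:
            out[h] = founders[start]
    if mutation_rate > 0:
        flips = rng.random(out.shape) < mutation_rate
        out ^= flips.astype(np.int8)
    return out


def simulate_founders(config: SimConfig) -> HaplotypePanel:
    """Simulate the base (pre-isolation) haplotype panel.

    Founder haplotypes carry derived alleles at counts drawn from a neutral
    ~1/k spectrum; the output haplotypes are recombinant founder mosaics plus
    new (mostly singleton) mutations, which gives the rare-heavy folded SFS
    downstream tests rely on.  Monomorphic columns are dropped.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_f = config.n_founders
    positions = np.sort(
        rng.choice(config.chrom_length_bp, size=config.n_sites, replace=False) + 1
    ).astype(np.int64)

    founders = np.zeros((n_f, config.n_sites), dtype=np.int8)
    if n_f > 1:
        ks = np.arange(1, n_f)
        w = 1.0 / ks
        counts = rng.choice(ks, size=config.n_sites, p=w / w.sum())
        for j, k in enumerate(counts):
            founders[rng.choice(n_f, size=int(k), replace=False), j] = 1

    haps = _mosaic_rows(
        rng, founders, positions, config.n_haplotypes_base,
        config.recombination_switch_rate_per_bp, config.mutation_rate_per_copy,
    )
    refs, alts = _random_alleles(rng, config.n_sites)

    ac = haps.sum(axis=0)
    keep = (ac > 0) & (ac < haps.shape[0])
    if not keep.any():
        keep = np.ones(config.n_sites, dtype=bool)  # degenerate configs keep all
    n_samples = config.n_haplotypes_base // 2
    if config.n_haplotypes_base % 2:
        haps = haps[:-1]
    return HaplotypePanel(
        population_id="BASE",
        sample_ids=[f"BASE_S{i:04d}" for i in range(n_samples)],
        haplotypes=haps[:, keep],
        positions=positions[keep],
        ref_alleles=[r for r, k in zip(refs, keep) if k],
        alt_alleles=[a for a, k in zip(alts, keep) if k],
        chrom="1",
    )


def derive_isolate(
    base: HaplotypePanel,
    n_bottleneck_founders: int,
    n_generations: int,
    n_out: int,
    seed: int,
    population_id: str = "ISOLATE",
    mutation_rate_per_copy: float = 2e-4,
    recombination_switch_rate_per_bp: float = 5e-6,
) -> HaplotypePanel:
    """Derive an isolated population from the base panel via a founder
    bottleneck.

    ``n_bottleneck_founders`` haplotypes are drawn without replacement;
    ``n_out`` output haplotypes are recombinant mosaics of those founders,
    with the switch and mutation rates scaled by ``n_generations`` (the
    number of generations only sets the recombination/mutation opportunity,
    not an explicit Wright–Fisher pedigree).  Fewer founders ⇒ more drift,
    longer ROH, larger Fst versus the base.  All base sites are retained so
    the key space stays shared.
    """
    if n_bottleneck_founders > base.n_haplotypes:
        raise ValueError("bottleneck larger than the base panel")
    if n_bottleneck_founders <= 0 or n_out <= 0:
        raise ValueError("founder and output counts must be positive")
    if n_out % 2:
        raise ValueError("n_out must be even (two haplotypes per sample)")
    rng = np.random.default_rng(seed)
    founder_idx = rng.permutation(base.n_haplotypes)[:n_bottleneck_founders]
    founders = base.haplotypes[founder_idx]
    haps = _mosaic_rows(
        rng, founders, base.positions, n_out,
        recombination_switch_rate_per_bp * n_generations,
        min(mutation_rate_per_copy * n_generations, 0.5),
        first_rows_in_order=True,
    )
    return HaplotypePanel(
        population_id=population_id,
        sample_ids=[f"{population_id}_S{i:04d}" for i in range(n_out // 2)],
        haplotypes=haps,
        positions=base.positions.copy(),
        ref_alleles=list(base.ref_alleles),
        alt_alleles=list(base.alt_alleles),
        chrom=base.chrom,
    )


def plant_sweep(
    panel: HaplotypePanel,
    focal_pos: int,
    carrier_fraction: float,
    flank_bp: int,
    seed: int,
    private_mutation_rate: float = 5e-4,
) -> HaplotypePanel:
    """Plant a partial selective sweep at ``focal_pos``.

    A derived allele is assigned to ``ceil(carrier_fraction * 2N)`` randomly
    chosen haplotypes; within ``flank_bp`` on each side of the focal site the
    carriers' haplotypes are replaced by one shared template (plus a few
    injected private mutations), mimicking the extended haplotype
    homozygosity signature of recent positive selection.  Non-carriers are
    untouched.  If no site exists at ``focal_pos`` a new column is inserted.
    """
    if not (0.0 < carrier_fraction < 1.0):
        raise ValueError("carrier_fraction must be in (0, 1)")
    if not (panel.positions[0] <= focal_pos <= panel.positions[-1]):
        raise ValueError("focal position outside the panel's coordinate range")
    rng = np.random.default_rng(seed)

    haps = panel.haplotypes.copy()
    positions = panel.positions.copy()
    refs = list(panel.ref_alleles)
    alts = list(panel.alt_alleles)

    hit = np.searchsorted(positions, focal_pos)
    if hit >= len(positions) or positions[hit] != focal_pos:
        haps = np.insert(haps, hit, 0, axis=1)
        positions = np.insert(positions, hit, focal_pos)
        refs.insert(hit, "A")
        alts.insert(hit, "G")
    focal = int(np.searchsorted(positions, focal_pos))

    n_hap = haps.shape[0]
    n_carriers = math.ceil(carrier_fraction * n_hap)
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    haps[:, focal] = 0
    haps[carriers, focal] = 1

    in_flank = (np.abs(positions - focal_pos) <= flank_bp) & (
        np.arange(len(positions)) != focal
    )
    flank_idx = np.flatnonzero(in_flank)
    if flank_idx.size:
        template = haps[carriers[0], flank_idx].copy()
        for c in carriers:
            row = template.copy()
            if private_mutation_rate > 0:
                flips = rng.random(row.shape) < private_mutation_rate
                row ^= flips.astype(np.int8)
            haps[c, flank_idx] = row
    return HaplotypePanel(
        population_id=panel.population_id,
        sample_ids=list(panel.sample_ids),
        haplotypes=haps,
        positions=positions,
        ref_alleles=refs,
        alt_alleles=alts,
        chrom=panel.chrom,
    )


def gene_intervals(spec: AnnotationSpec, chrom_length_bp: int, chrom: str = "1"):
    """Tile ``spec.n_genes`` equal gene intervals over the chromosome.

    Returns a list of (gene_id, chrom, start, end) with 1-based inclusive
    coordinates.
    """
    size = chrom_length_bp // spec.n_genes
    out = []
    for g in range(spec.n_genes):
        start = g * size + 1
        end = chrom_length_bp if g == spec.n_genes - 1 else (g + 1) * size
        out.append((f"GENE{g + 1:04d}", chrom, start, end))
    return out


def annotate_sites(
    panel: HaplotypePanel, spec: AnnotationSpec, seed: int,
    chrom_length_bp: int | None = None,
) -> list[AnnotationRecord]:
    """Annotate every panel site with gene, transcripts, consequence and a
    CADD-like phred score (synthetic stand-in)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    length = chrom_length_bp if chrom_length_bp is not None else int(panel.positions[-1])
    genes = gene_intervals(spec, length, panel.chrom)
    gene_size = max(length // spec.n_genes, 1)

    lo, hi = spec.transcripts_per_gene
    n_tx = rng.integers(lo, hi + 1, size=spec.n_genes)

    records: list[AnnotationRecord] = []
    keys = panel.keys
    for j, key in enumerate(keys):
        g = min((key.pos - 1) // gene_size, spec.n_genes - 1)
        gene_id = genes[g][0]
        k = int(n_tx[g])
        tx_names = [f"{gene_id}_T{t + 1}" for t in range(k)]

        high = rng.random() < spec.p_high_impact
        if high:
            cons = spec.high_impact_terms[int(rng.integers(len(spec.high_impact_terms)))]
            p_tail = spec.p_tail_high_impact
        else:
            cons = spec.benign_terms[int(rng.integers(len(spec.benign_terms)))]
            p_tail = spec.p_tail_benign
        if rng.random() < p_tail:
            cadd = spec.cadd_tail_shift + rng.exponential(spec.cadd_tail_scale)
        else:
            cadd = rng.gamma(spec.cadd_bulk_shape, spec.cadd_bulk_scale)

        if k == 1 or rng.random() < spec.p_all_transcripts:
            affected = frozenset(tx_names)
        else:
            m = int(rng.integers(1, k))  # proper nonempty subset
            affected = frozenset(rng.choice(tx_names, size=m, replace=False).tolist())
        records.append(
            AnnotationRecord(
                key=key, gene=gene_id, n_transcripts=k,
                affected_transcripts=affected, consequence=cons,
                cadd_phred=float(cadd),
            )
        )
    return records


def plant_cadd_enrichment(
    records: list[AnnotationRecord],
    enriched_keys: set[VariantKey],
    spec: AnnotationSpec,
    seed: int,
    p_tail: float = 0.5,
) -> list[AnnotationRecord]:
    """Promote mid-range CADD scores of ``enriched_keys`` into the heavy
    right tail (>= 20) with probability ``p_tail``.

    Only scores in [5, 20) are promoted, so the low-CADD (0–5) class keeps
    its membership — planting a deleterious excess without disturbing the
    putatively neutral bin, the truth signal behind the DVxy contrast.
    """
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        if (
            r.key in enriched_keys
            and 5.0 <= r.cadd_phred < 20.0
            and rng.random() < p_tail
        ):
            cadd = 20.0 + rng.exponential(spec.cadd_tail_scale)
            r = AnnotationRecord(
                key=r.key, gene=r.gene, n_transcripts=r.n_transcripts,
                affected_transcripts=r.affected_transcripts,
                consequence=r.consequence, cadd_phred=float(cadd),
            )
        out.append(r)
    return out


def corrupt_to_posteriors(
    true_genotypes: np.ndarray,
    noise: PosteriorNoise,
    seed: int,
    sample_ids: list[str] | None = None,
    keys: list[VariantKey] | None = None,
) -> PosteriorGenotypes:
    """Corrupt true genotypes into imputation-like posterior triples.

    See :class:`PosteriorNoise` for the error model.  With ``rate = 0`` the
    posteriors are degenerate at the truth; missing genotypes receive the
    site's Hardy–Weinberg prior.
    """
    noise.validate()
    g = np.asarray(true_genotypes)
    if not np.isin(g, [0, 1, 2, MISSING]).all():
        raise ValueError("genotypes must be 0/1/2 or missing (-1)")
    rng = np.random.default_rng(seed)
    n_samples, n_sites = g.shape

    called = g != MISSING
    an = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, np.where(called, g, 0).sum(axis=0) / np.maximum(an, 1), 0.5)
    maf = np.minimum(p, 1.0 - p)
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)  # (n_sites, 3)

    eps = noise.site_error(maf)  # (n_sites,)
    miscall = rng.random(g.shape) < eps[None, :]
    u = rng.random(g.shape)
    cum = np.cumsum(hwe, axis=1)
    hwe_draw = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2).astype(np.int8)
    mode = np.where(called & ~miscall, g, hwe_draw).astype(np.int8)

    soft = (eps / 2.0)[None, :, None]
    onehot = np.zeros((n_samples, n_sites, 3))
    idx = np.indices(g.shape)
    onehot[idx[0], idx[1], mode] = 1.0
    probs = (1.0 - soft) * onehot + soft * hwe[None, :, :]
    # missing truth: pure HWE prior
    miss_s, miss_j = np.nonzero(~called)
    probs[miss_s, miss_j] = hwe[miss_j]
    probs /= probs.sum(axis=2, keepdims=True)

    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    if keys is None:
        keys = [VariantKey("1", j + 1, "A", "G") for j in range(n_sites)]
    return PosteriorGenotypes(sample_ids=sample_ids, keys=keys, probs=probs)


def _simulate_depths(rng: np.random.Generator, shape, mean_depth: float) -> np.ndarray:
    return rng.poisson(mean_depth, size=shape).astype(np.int32)


def generate_cohort_set(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate the full synthetic bundle on disk.

    Writes, per isolate population, a VCF (GT + DP), an annotation TSV and a
    posterior-genotype TSV; plus one external-resource site list (a random
    subset of the union of emitted sites, standing in for 1000G/gnomAD
    membership), one gene→RVIS table, and a JSON manifest recording seeds and
    paths.  Returns the manifest dict.
    """
    from . import io as io_mod

    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)

    base = simulate_founders(config)
    if config.sweep is not None:
        base = plant_sweep(
            base, config.sweep.focal_pos, config.sweep.carrier_fraction,
            config.sweep.flank_bp, seed=int(master.integers(2**31)),
        )

    manifest: dict = {"seed": config.seed, "populations": {}, "chrom_length_bp": config.chrom_length_bp}
    union_keys: list[VariantKey] = []
    seen = set()
    for i, n_bott in enumerate(config.bottleneck_founders):
        pop = f"POP{i + 1}"
        pop_seed = int(master.integers(2**31))
        panel = derive_isolate(
            base, n_bott, config.n_isolate_generations, config.n_out_haplotypes,
            seed=pop_seed, population_id=pop,
            mutation_rate_per_copy=config.mutation_rate_per_copy,
            recombination_switch_rate_per_bp=config.recombination_switch_rate_per_bp,
        )
        rng = np.random.default_rng(pop_seed + 1)
        ds = panel.to_dataset(
            depths=_simulate_depths(rng, (panel.n_haplotypes // 2, panel.n_sites), config.mean_depth)
        )
        if config.missing_rate > 0:
            mask = rng.random(ds.genotypes.shape) < config.missing_rate
            ds.genotypes[mask] = MISSING
        vcf_path = out / f"{pop}.vcf"
        io_mod.write_vcf(ds, vcf_path)

        ann = annotate_sites(panel, config.annotation, seed=pop_seed + 2,
                             chrom_length_bp=config.chrom_length_bp)
        ann_path = out / f"{pop}.annotations.tsv"
        io_mod.write_annotations(ann, ann_path)

        post = corrupt_to_posteriors(
            ds.genotypes, config.posterior_noise, seed=pop_seed + 3,
            sample_ids=ds.sample_ids, keys=ds.keys,
        )
        post_path = out / f"{pop}.posteriors.tsv"
        io_mod.write_posteriors(post, post_path)

        manifest["populations"][pop] = {
            "seed": pop_seed,
            "bottleneck_founders": n_bott,
            "vcf": vcf_path.name,
            "annotations": ann_path.name,
            "posteriors": post_path.name,
        }
        for k in ds.keys:
            if k not in seen:
                seen.add(k)
                union_keys.append(k)

    # external resources carry nearly all common variation but few
    # cohort-private rare alleles: membership probability follows pooled AC
    ext_rng = np.random.default_rng(config.seed + 997)
    pooled_ac: dict[VariantKey, int] = {}
    for pop in manifest["populations"]:
        ds = io_mod.read_vcf(out / manifest["populations"][pop]["vcf"], population_id=pop)
        g = ds.genotypes
        ac = np.where(g != MISSING, g, 0).sum(axis=0)
        for key, a in zip(ds.keys, ac):
            pooled_ac[key] = pooled_ac.get(key, 0) + int(a)
    ext_keys = [
        k for k in union_keys
        if ext_rng.random() < (0.9 if pooled_ac.get(k, 0) > 3 else 0.15)
    ]
    if not ext_keys:
        ext_keys = union_keys[:1]
    ext_path = out / "external_sites.tsv"
    io_mod.write_site_list(ext_keys, ext_path)
    manifest["external_sites"] = ext_path.name

    genes = gene_intervals(config.annotation, config.chrom_length_bp)
    rvis = {g[0]: float(v) for g, v in zip(genes, ext_rng.normal(0.0, 1.0, len(genes)))}
    rvis_path = out / "rvis.tsv"
    io_mod.write_rvis(rvis, rvis_path)
    manifest["rvis"] = rvis_path.name
    genes_path = out / "genes.tsv"
    io_mod.write_gene_intervals(genes, genes_path)
    manifest["genes"] = genes_path.name

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
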