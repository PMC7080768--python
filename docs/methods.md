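# Methods

`isopop` re-implements, as a tested pipeline, the cohort-characterization
analyses used to describe genetically isolated populations from whole-genome
sequence data: reference-panel site selection, imputation-quality metrics,
population-structure statistics, haplotype-based selection scans, drifted
deleterious-variant enrichment and human-knockout detection. Because cohort
WGS data of this kind are not publicly redistributable, the package ships a
synthetic-cohort generator whose output has the statistical structure the
analyses assume; every analysis stage is exercised end to end on generated
data.

All coordinates are 1-based (VCF convention). Genotypes are alt-allele
dosages 0/1/2 with −1 for missing. Variants are identified by exact
`(chrom, pos, ref, alt)` match everywhere; no allele harmonization or
left-normalization is performed and multiallelic records are excluded at
ingest.

## Synthetic cohorts

**Base panel.** Founder haplotypes (default 40) carry derived alleles at
counts drawn from a neutral-like ~1/k spectrum. Output haplotypes (default
200, i.e. 100 diploid samples) are Li–Stephens-style recombinant mosaics of
the founders: while copying, the donor switches with probability
`1 − exp(−r·gap)` between adjacent sites (default switch rate `r = 5e-6`/bp,
mean donor-segment length 200 kb), and each copied allele mutates with
probability `2e-4`. The mosaic gives realistic LD decay — which EHH/iHS and
ROH need — without the cost of a full coalescent-with-recombination model;
genealogical exactness is not required by any downstream statistic. New
mutations are predominantly singletons, producing the rare-heavy folded SFS
(bin counts fall with minor-allele count; Spearman ρ ≈ −0.87 at the
defaults). Monomorphic columns are dropped. Default chromosome: 20 000
polymorphic sites on 20 Mb (≈1 site/kb).

**Isolates.** An isolate draws `n` founder haplotypes from the base without
replacement (defaults 20/40/80 for three populations) and re-mosaics them
into the output panel, with switch and mutation rates scaled by a
generation count. Isolation is therefore modelled as discrete founder
resampling, not per-generation Wright–Fisher; the generation count only
sets the recombination/mutation opportunity. The default is 2 generations:
larger values fragment within-sample founder sharing faster than drift
accumulates, and the isolates then fail to show the long runs of
homozygosity that distinguish real isolates from outbred references. At the
defaults, isolates show Fst against the base that grows as the bottleneck
tightens (≈0.02 at 20 founders vs ≈0.001 at 80) and 2–3× the base's total
ROH length.

**Planted sweeps.** A partial sweep at a focal position assigns the derived
allele to `⌈carrier_fraction·2N⌉` haplotypes and replaces the carriers'
haplotypes within ±`flank_bp` (default 500 kb) by one shared template plus
rare private mutations (5e-4/site). This reproduces the extended-haplotype
signature that iHS detects, with known truth.

**Annotations.** Genes are tiled as equal intervals (default 100 per
chromosome, 1–8 transcripts each). Each site receives one consequence term —
one of the eight VEP high-impact terms with probability 0.01, otherwise a
common benign term — and a CADD-like phred score from a two-component
mixture: a Gamma(2, 2.5) bulk and a 15 + Exp(6) right tail (tail weight 0.06
for benign, 0.7 for high-impact terms, so that high-impact calls usually
clear the CADD ≥ 20 knockout filter and all four CADD bins are populated).
The scores are synthetic stand-ins and are never interpreted as real CADD.
`plant_cadd_enrichment` promotes mid-range scores (5–20) of a chosen
variant set into the ≥20 tail; promotion leaves the 0–5 class untouched, so
a planted deleterious excess does not disturb the putatively neutral bin.

**Imputation posteriors.** True genotypes are corrupted into posterior
triples with a MAF-dependent miscall probability
`eps = rate·(1 − 2·maf·(1−maf))` (default rate 0.1): with probability `eps`
the posterior mode is drawn from the site's Hardy–Weinberg distribution
instead of the truth, and `eps/2` of the mass is spread over the HWE prior.
Rarer sites are imputed worse, the canonical behaviour of reference-panel
imputation. With rate 0 the posteriors are degenerate at the truth and all
quality metrics are exactly 1.

**External resources.** The stand-in for 1000G/gnomAD membership is a site
list drawn from the union of cohort sites with frequency-dependent
probability (0.9 for pooled AC > 3, 0.15 otherwise): public resources
contain nearly all common variation but few cohort-private rare alleles.
A gene→RVIS table is drawn N(0, 1).

**What the generator does not emulate.** Real demography (the paper-scale
cohorts have no published demographic parameters, so defaults were chosen
for testability, not historical realism), sequencing error, genotyping
batch effects, X chromosome, multiallelic sites, indel-specific error
modes, and real CADD/VEP behaviour. Passing tests therefore demonstrate
algorithmic correctness and qualitative behaviour under controlled truth,
not performance on real cohorts.

## Reference-panel site selection

A cohort site enters the panel iff (a) AC ≥ 2 and mean per-genotype read
depth ≥ 5, or (b) AC = 1 and the identical variant is present in another
study cohort or an external resource. AC is computed per cohort, never on
the pooled data. The depth rule is interpreted as the site's mean depth
over samples with called genotypes — the common site-level QC reading,
well-defined under missingness (per-carrier minima would be an alternative;
the choice is surfaced as `min_dp`). The module stops at retained-site
lists and reports; merging retained sites into a haplotype reference
(IMPUTE-style cross-imputation) is out of scope. The sharing spectrum
partitions each cohort's segregating sites into external / shared-with-
another-cohort / private, by cohort MAF bin.

## Imputation metrics and GWAS rules

The info score is the IMPUTE-type measure: with `e_i = p_i1 + 2 p_i2`,
`f_i = p_i1 + 4 p_i2`, `θ = Σe_i/2N`,
`info = 1 − Σ(f_i − e_i²) / (2N·θ(1−θ))`, clamped to [0, 1]; `θ ∈ {0,1}`
is defined as info 1. Concordance r² is the squared Pearson correlation
between true dosage and posterior expected dosage per site (sign-blind by
construction), averaged within truth-MAF bins; zero-variance sites are
excluded and counted. Which genotypes are masked for evaluation is left to
the caller — the synthetic runs evaluate all sites. Default MAF bins are
(0, 0.5%], (0.5%, 1%], (1%, 5%], (5%, 50%]; at small sample sizes callers
should pass bins their AN can resolve. Variant QC before association keeps
(MAF ≥ 1% and info > 0.4) or (0.1% ≤ MAF < 1% and info ≥ 0.8); the rare
band is applied on imputed MAF. Meta-analysis is sample-size-weighted
Stouffer (weights √n) with a two-sided normal p; variants lacking ≥2
cohorts with the same effect sign are flagged excluded, and significance is
Bonferroni at 0.05/n_tests.

## Population structure

LD pruning is PLINK `--indep-pairwise`-style (window 200 sites, step 50,
r² > 0.4 removes the later site; MAF < 0.02 removed first). PCA centers
columns and scales by √(2p(1−p)) with per-site mean imputation of missing
genotypes; component signs follow a largest-loading-positive convention.
Pairwise Fst is the Weir–Cockerham (1984) two-population estimator,
aggregated genome-wide as the ratio of summed variance components
(ratio of averages); loci monomorphic across both populations are skipped
and small negative estimates are reported as-is. ROH detection follows the
PLINK sliding-window heuristic with the documentation defaults (window 50
sites, ≤1 heterozygote per window, window threshold 0.05, min 100 sites /
1 Mb, max gap 1 Mb), all surfaced in `RohParams` — the published analysis
defers its exact settings to an unavailable supplement, so the PLINK
defaults stand in. The inbreeding coefficient is the method-of-moments
excess-homozygosity F = (O_hom − E_hom)/(L − E_hom).

## Selection scans

EHH for a core allele is the probability that two random carrier
haplotypes are identical from the core out to a marker; it starts at 1 and
is non-increasing. iHH integrates EHH against physical distance by the
trapezoid rule, each direction stopping after the first marker below the
EHH cutoff (default 0.05); sites whose integral reaches the chromosome
edge or an inter-marker gap > 200 kb before the cutoff are flagged invalid
rather than penalized, and extension is capped at 2 Mb (truncation, still
valid) — selscan-compatible choices where the published analysis is
silent. Only sites with MAF > 0.05 are scored. iHS = ln(iHH_A/iHH_D) is
standardized to mean 0, SD 1 within 50 equal-width derived-allele-frequency
bins (bins with <2 valid sites are flagged unstandardizable). In synthetic
runs the REF allele is ancestral by construction; for real VCFs REF is
assumed ancestral unless an ancestral-allele annotation is supplied — a
documented limitation. Genes are called candidates when ≥20 markers inside
the gene interval have |standardized iHS| ≥ 2 (or 2.5 for the stricter
set); a marker may count toward overlapping genes. On neutral panels
≈2.3% of sites fall in each |iHS| ≥ 2 tail, as expected for a
standardized, near-normal score.

The per-site EHH extension is a numba kernel (first-seen group relabelling,
O(carriers) per marker); a 200-haplotype, 20k-site scan takes a few
seconds on one core.

## Drifted deleterious variants

Variants are cross-classified by AC class and CADD bin. The printed class
labels 1–2 / 3–5 / 5–10 / >10 overlap at 5; they are resolved as the
disjoint intervals [1,2], [3,5], (5,10], (10,∞). CADD bins are [0,5),
[5,15), [15,20), [20,∞). A variant is *drifted* in X relative to Y when its
AC in X lies in the class of interest and its frequency in Y is below 0.5%
(absent counts as 0). DVxy for a CADD bin is the ratio of drifted-variant
counts in the two directions, with an SD from 1000 bootstrap resamples of
the combined drifted list (resampling variants with replacement and
recomputing the ratio; resamples with an empty denominator are skipped).
Enrichment is called when dvxy − sd > 1. The statistic's exact published
form lives in a companion paper that is not available here; this
operationalization — a directional drifted-count ratio with variant
bootstrap — reproduces the reported qualitative behaviour (≈1 at low CADD,
above 1 + sd at high CADD against a reference population) and is isolated
behind one function so it can be swapped. Whether the original normalizes
by a neutral category or sums allele counts rather than variant counts
cannot be resolved from the primary text. The DV ratio contrasts
population-specific against shared drifted variants
(|X only| / |X ∩ Y|), both sets computed against a common reference.

A note on calibration: on exchangeable data the drifted-count split is
binomial, so a ±1·bootstrap-SD interval around dvxy covers 1 in roughly
68–85% of replicates depending on set size — a property of one-sigma
intervals, not of the implementation. The test suite records this
behaviour explicitly.

## Human knockouts

A variant is a putative loss-of-function when its consequence is one of
the eight VEP high-impact terms (frameshift, splice acceptor, splice
donor, stop gained, stop lost, start lost, transcript ablation, transcript
amplification) *and* CADD ≥ 20; unknown consequence terms are treated as
non-LoF with a warning. A knockout requires ≥1 homozygous-alternative
individual in ≥1 population (missing genotypes ignored; no extra
genotype-quality filter beyond upstream calling QC). TOTAL means every
transcript of the gene is affected, otherwise PARTIAL. Overlap analyses
first restrict to variants present in the external (gnomAD-style) list to
guard against private false positives, then collapse variants to genes per
population. The intolerance comparison is a two-sided Wilcoxon rank-sum
(Mann–Whitney U, asymptotic normal approximation with tie correction, via
scipy) between RVIS scores of knockout genes and all scored genes; an
all-tied comparison is degenerate and reported as the null midpoint with
p = 1.

## Problem sizes and numerical choices

Tests and the acceptance script use 200-haplotype panels with 20 000 sites
on 20 Mb (the generator defaults) for simulation-based properties, and
2 000–8 000-site panels for cheaper monotonicity checks; statistical
properties are asserted over 10–20 seeded replicates as majorities or
rate bands. Bootstrap and simulation seeds are always explicit; identical
seeds give bit-identical outputs everywhere, including written files.
Degenerate inputs (all-missing sites, monomorphic panels, empty drifted
sets, zero-variance rank tests, <2 carriers of an allele) return flagged
values or raise typed errors rather than propagating NaN silently.

## Known limitations

Single-chromosome simulation; ROH and selection scans assume one
chromosome per call (callers loop). The iHS scan treats REF as ancestral
on real data unless told otherwise. The DVxy form is a documented
operationalization (above). Inbreeding F of simulated isolates is near 0
rather than elevated: the mosaic pairs haplotypes independently, so excess
homozygosity appears as ROH burden rather than genome-wide F — a generator
property, not an estimator defect.
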