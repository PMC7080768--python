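"""Readers and writers for the standard formats the pipeline touches.

VCF ingest uses cyvcf2; the VCF writer emits plain VCF 4.2 text (GT plus DP
when depths are present).  Tabular inputs — annotation tables, external site
lists, gene→RVIS maps, gene intervals, posterior triples — are TSVs read
through pandas.  All coordinates are 1-based.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, AnnotationRecord, CohortDataset, PosteriorGenotypes, VariantKey

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene",
    "n_transcripts", "affected_transcripts", "consequence", "cadd_phred",
]
SITE_LIST_COLUMNS = ["chrom", "pos", "ref", "alt"]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


def read_vcf(
    path: str | Path,
    require_phase: bool = False,
    population_id: str | None = None,
    multiallelic: str = "skip",
) -> CohortDataset:
    """Load a biallelic multi-sample VCF into a :class:`CohortDataset`.

    Parameters
    ----------
    require_phase : bool
        If True, any unphased heterozygous genotype raises an error and the
        phased haplotype matrix is populated.
    multiallelic : {"skip", "error"}
        Policy for rows with more than one ALT allele; "skip" drops them
        with a logged warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    gt_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    any_dp = False
    all_phased = True

    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            if multiallelic == "skip":
                logger.warning(
                    "skipping multiallelic record %s:%s (%s>%s)",
                    rec.CHROM, rec.POS, rec.REF, ",".join(rec.ALT),
                )
                continue
            raise VcfParseError(f"multiallelic record at line ~{i + 1}: {rec.CHROM}:{rec.POS}")
        key = VariantKey(str(rec.CHROM), int(rec.POS), str(rec.REF), str(rec.ALT[0]))
        try:
            key.validate()
        except ValueError as exc:
            raise VcfParseError(f"record {i + 1}: {exc}") from exc

        gts = rec.genotypes  # [[a0, a1, phased], ...]
        dosage = np.empty(len(samples), dtype=np.int8)
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for s, g in enumerate(gts):
            a = [x for x in g[:-1] if x is not None]
            phased = bool(g[-1])
            if len(a) != 2 or any(x < 0 for x in a):
                dosage[s] = MISSING
                hap[2 * s : 2 * s + 2] = 0
                all_phased = False
                continue
            if not phased and a[0] != a[1]:
                all_phased = False
                if require_phase:
                    raise VcfParseError(
                        f"unphased genotype for sample {samples[s]} at "
                        f"{key.chrom}:{key.pos} but phased input required"
                    )
            dosage[s] = a[0] + a[1]
            hap[2 * s] = a[0]
            hap[2 * s + 1] = a[1]
        keys.append(key)
        gt_rows.append(dosage)
        hap_rows.append(hap)

        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_dp = True
            dp_rows.append(np.where(dp[:, 0] < 0, MISSING, dp[:, 0]).astype(np.int32))
        else:
            dp_rows.append(np.full(len(samples), MISSING, dtype=np.int32))

    n_sites = len(keys)
    genotypes = (
        np.stack(gt_rows, axis=1) if n_sites else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depths = (
        np.stack(dp_rows, axis=1) if (n_sites and any_dp) else None
    )
    haplotypes = None
    if all_phased and n_sites:
        haplotypes = np.stack(hap_rows, axis=1)
        haplotypes[np.repeat(genotypes == MISSING, 2, axis=0)] = 0
    return CohortDataset(
        population_id=population_id or path.stem,
        sample_ids=samples,
        keys=keys,
        genotypes=genotypes,
        depths=depths,
        haplotypes=haplotypes,
        phased=all_phased,
    )


def write_vcf(dataset: CohortDataset, path: str | Path) -> None:
    """Write a :class:`CohortDataset` as VCF 4.2 (GT, plus DP when present).

    Records are emitted sorted by (chrom, pos); if the input keys were not
    sorted this is logged.  Phased datasets use ``|`` separators, unphased
    use ``/``.
    """
    path = Path(path)
    order = sorted(range(dataset.n_sites), key=lambda j: (dataset.keys[j].chrom, dataset.keys[j].pos))
    if order != list(range(dataset.n_sites)):
        logger.warning("input sites were not coordinate-sorted; sorting on write")

    sep = "|" if dataset.phased else "/"
    has_dp = dataset.depths is not None
    fmt = "GT:DP" if has_dp else "GT"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for chrom in dict.fromkeys(k.chrom for k in dataset.keys):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.sample_ids)
        if dataset.n_samples
        else "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    )
    for j in order:
        k = dataset.keys[j]
        fields = [k.chrom, str(k.pos), ".", k.ref, k.alt, ".", "PASS", "."]
        if dataset.n_samples:
            fields.append(fmt)
            for s in range(dataset.n_samples):
                g = int(dataset.genotypes[s, j])
                if g == MISSING:
                    gt = f".{sep}."
                elif dataset.haplotypes is not None:
                    gt = f"{dataset.haplotypes[2 * s, j]}{sep}{dataset.haplotypes[2 * s + 1, j]}"
                else:
                    gt = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[g]
                if has_dp:
                    d = int(dataset.depths[s, j])
                    gt += ":" + ("." if d == MISSING else str(d))
                fields.append(gt)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def _keys_from_frame(df: pd.DataFrame) -> list[VariantKey]:
    return [
        VariantKey(str(c), int(p), str(r), str(a))
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Read an annotation TSV keyed by VariantKey; duplicate keys keep the
    last row (warned)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out: dict[VariantKey, AnnotationRecord] = {}
    for row, key in zip(df.itertuples(index=False), _keys_from_frame(df)):
        if key in out:
            warnings.warn(f"duplicate annotation key {key}; last row wins")
        affected = frozenset(
            t for t in str(row.affected_transcripts).split(",") if t and t != "nan"
        )
        out[key] = AnnotationRecord(
            key=key, gene=str(row.gene), n_transcripts=int(row.n_transcripts),
            affected_transcripts=affected, consequence=str(row.consequence),
            cadd_phred=float(row.cadd_phred),
        )
    return out


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.key.chrom, "pos": r.key.pos, "ref": r.key.ref, "alt": r.key.alt,
            "gene": r.gene, "n_transcripts": r.n_transcripts,
            "affected_transcripts": ",".join(sorted(r.affected_transcripts)),
            "consequence": r.consequence, "cadd_phred": f"{r.cadd_phred:.4f}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_list(path: str | Path) -> set[VariantKey]:
    """Read a 4-column site list into a key set (duplicates collapse)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SITE_LIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site list missing columns: {sorted(missing)}")
    return set(_keys_from_frame(df))


def write_site_list(keys, path: str | Path) -> None:
    pd.DataFrame(
        [{"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt} for k in keys],
        columns=SITE_LIST_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_rvis(path: str | Path) -> dict[str, float]:
    """Read a gene→RVIS TSV.  Lookups for absent genes should use ``.get``,
    which returns None — never assume 0 for an unscored gene."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "rvis"} <= set(df.columns):
        raise ValueError("RVIS table must have columns: gene, rvis")
    out: dict[str, float] = {}
    for row in df.itertuples(index=False):
        g = str(row.gene)
        if g in out:
            warnings.warn(f"duplicate RVIS gene {g}; last row wins")
        out[g] = float(row.rvis)
    return out


def write_rvis(rvis: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(rvis.items()), columns=["gene", "rvis"]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_tables(annotation_path, site_list_path, rvis_path):
    """Convenience loader for the three auxiliary tables."""
    return (
        read_annotations(annotation_path),
        read_site_list(site_list_path),
        read_rvis(rvis_path),
    )


def read_gene_intervals(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Gene intervals as (gene, chrom, start, end), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"gene", "chrom", "start", "end"} <= set(df.columns):
        raise ValueError("gene interval table must have columns: gene, chrom, start, end")
    return [
        (str(r.gene), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_gene_intervals(genes, path: str | Path) -> None:
    pd.DataFrame(
        [{"gene": g, "chrom": c, "start": s, "end": e} for g, c, s, e in genes]
    ).to_csv(path, sep="\t", index=False)


def read_posteriors(path: str | Path) -> PosteriorGenotypes:
    """Read posterior triples from the Oxford GEN-style TSV written by
    :func:`write_posteriors` (three probability columns per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    keys = _keys_from_frame(df)
    prob_cols = [c for c in df.columns if c not in SITE_LIST_COLUMNS]
    if len(prob_cols) % 3 != 0:
        raise ValueError("posterior table must have 3 probability columns per sample")
    sample_ids = [prob_cols[i][: -len("_p0")] for i in range(0, len(prob_cols), 3)]
    probs = df[prob_cols].to_numpy(dtype=np.float64).reshape(len(keys), len(sample_ids), 3)
    probs = probs.transpose(1, 0, 2)
    probs = probs / probs.sum(axis=2, keepdims=True)  # undo rounding on write
    return PosteriorGenotypes(sample_ids=sample_ids, keys=keys, probs=probs)


def write_posteriors(post: PosteriorGenotypes, path: str | Path) -> None:
    cols: dict[str, object] = {
        "chrom": [k.chrom for k in post.keys],
        "pos": [k.pos for k in post.keys],
        "ref": [k.ref for k in post.keys],
        "alt": [k.alt for k in post.keys],
    }
    for s, sid in enumerate(post.sample_ids):
        for g in range(3):
            cols[f"{sid}_p{g}"] = np.round(post.probs[s, :, g], 6)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
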