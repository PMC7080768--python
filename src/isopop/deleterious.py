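"""Drifted deleterious-variant enrichment between a study population and a
reference.

Variants are cross-classified by alternative-allele-count class (1–2, 3–5,
5–10, >10, resolved as the disjoint intervals [1,2], [3,5], (5,10], (10,∞))
and CADD-phred bin ([0,5), [5,15), [15,20), [20,∞)).  A variant is "drifted"
in population X relative to Y when its AC in X falls in the class of
interest while it is rare (AF below a threshold, default 0.5%) in Y.  The
DVxy statistic is the ratio of drifted-variant counts in the two directions
within one CADD bin, with a bootstrap standard deviation over the combined
drifted-variant list; enrichment is called when dvxy - sd > 1.  The DV
ratio contrasts population-specific and shared drifted variants against a
common reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationRecord, VariantKey
from .panel import SiteStats

AC_CLASSES: dict[str, tuple[float, float]] = {
    # closed/half-open bounds resolving the overlapping printed labels
    "1-2": (1, 2),       # [1, 2]
    "3-5": (3, 5),       # [3, 5]
    "5-10": (6, 10),     # (5, 10]
    ">10": (11, np.inf), # (10, inf)
}

CADD_BINS: dict[str, tuple[float, float]] = {
    "0-5": (0.0, 5.0),
    "5-15": (5.0, 15.0),
    "15-20": (15.0, 20.0),
    ">20": (20.0, np.inf),
}


def ac_class(ac: int) -> str | None:
    """AC class label, or None for non-segregating (AC = 0) variants."""
    if ac < 0:
        raise ValueError("negative allele count")
    for label, (lo, hi) in AC_CLASSES.items():
        if lo <= ac <= hi:
            return label
    return None


def cadd_bin(score: float) -> str:
    """CADD bin label; bins are [lo, hi) except the open-ended top bin."""
    if score < 0:
        raise ValueError("negative CADD score")
    for label, (lo, hi) in CADD_BINS.items():
        if lo <= score < hi:
            return label
    return ">20"


def bin_variants(
    stats: list[SiteStats],
    annotations: dict[VariantKey, AnnotationRecord],
) -> pd.DataFrame:
    """Cross-classify every annotated segregating variant into one AC-class ×
    CADD-bin cell.  Multiallelic exclusion is assumed upstream (the dataset
    model only carries biallelic records)."""
    rows = []
    for s in stats:
        if s.ac == 0:
            continue
        ann = annotations.get(s.key)
        if ann is None:
            continue
        rows.append(
            {
                "chrom": s.key.chrom, "pos": s.key.pos,
                "ref": s.key.ref, "alt": s.key.alt,
                "ac": s.ac, "ac_class": ac_class(s.ac),
                "cadd_phred": ann.cadd_phred, "cadd_bin": cadd_bin(ann.cadd_phred),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ac", "ac_class", "cadd_phred", "cadd_bin"]
    )


def drifted_variants(
    x_stats: list[SiteStats],
    y_stats: list[SiteStats],
    ac_class_label: str = "3-5",
    rare_af_threshold: float = 0.005,
) -> set[VariantKey]:
    """Variants drifted in X relative to Y.

    Drifted: AC in X falls inside ``ac_class_label`` while the variant is
    rare in Y (AF_Y < ``rare_af_threshold``; absent from Y counts as
    AF_Y = 0).  Swap the arguments for the opposite direction.
    """
    if ac_class_label not in AC_CLASSES:
        raise ValueError(f"unknown AC class {ac_class_label!r}")
    lo, hi = AC_CLASSES[ac_class_label]
    y_af = {s.key: s.af for s in y_stats if s.an > 0}
    out = set()
    for s in x_stats:
        if not (lo <= s.ac <= hi):
            continue
        af_y = y_af.get(s.key, 0.0)
        if not np.isfinite(af_y):
            af_y = 0.0
        if af_y < rare_af_threshold:
            out.add(s.key)
    return out


@dataclass
class DvxyEstimate:
    """Directional drifted-count ratio between population X and reference Y."""

    population_x: str
    population_y: str
    ac_class: str
    cadd_bin: str
    d_x: int
    d_y: int
    dvxy: float  # NaN when d_y == 0
    sd: float
    n_boot: int
    seed: int

    @property
    def enriched(self) -> bool:
        """The decision rule: enrichment in X when dvxy - sd > 1."""
        return bool(np.isfinite(self.dvxy) and self.dvxy - self.sd > 1.0)

    @property
    def spans_one(self) -> bool:
        """True when dvxy +/- sd covers 1 (no direction distinguishable)."""
        return bool(
            np.isfinite(self.dvxy)
            and self.dvxy - self.sd <= 1.0 <= self.dvxy + self.sd
        )


def dvxy(
    x_stats: list[SiteStats],
    y_stats: list[SiteStats],
    annotations: dict[VariantKey, AnnotationRecord],
    ac_class_label: str = "3-5",
    cadd_bin_label: str = ">20",
    n_boot: int = 1000,
    seed: int = 0,
    rare_af_threshold: float = 0.005,
    population_x: str = "X",
    population_y: str = "Y",
) -> DvxyEstimate:
    """The DVxy enrichment statistic for one AC-class × CADD-bin cell.

    dvxy = |drifted in X, in bin| / |drifted in Y, in bin|; the bootstrap SD
    resamples the combined drifted-variant list with replacement ``n_boot``
    times and recomputes the ratio (resamples with an empty denominator are
    skipped).  ``dvxy`` is NaN when no variant is drifted in Y.
    """
    lo, hi = CADD_BINS[cadd_bin_label]

    def in_bin(key: VariantKey) -> bool:
        ann = annotations.get(key)
        return ann is not None and lo <= ann.cadd_phred < hi

    dx_keys = {k for k in drifted_variants(x_stats, y_stats, ac_class_label, rare_af_threshold) if in_bin(k)}
    dy_keys = {k for k in drifted_variants(y_stats, x_stats, ac_class_label, rare_af_threshold) if in_bin(k)}
    d_x, d_y = len(dx_keys), len(dy_keys)

    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(d_x, dtype=np.int8), np.zeros(d_y, dtype=np.int8)])
    ratios = []
    if labels.size:
        for _ in range(n_boot):
            draw = labels[rng.integers(0, labels.size, size=labels.size)]
            bx = int(draw.sum())
            by = int(draw.size - bx)
            if by > 0:
                ratios.append(bx / by)
    sd = float(np.std(ratios)) if ratios else float("nan")
    return DvxyEstimate(
        population_x=population_x, population_y=population_y,
        ac_class=ac_class_label, cadd_bin=cadd_bin_label,
        d_x=d_x, d_y=d_y,
        dvxy=d_x / d_y if d_y > 0 else float("nan"),
        sd=sd, n_boot=n_boot, seed=seed,
    )


def dv_ratio(drifted_x: set[VariantKey], drifted_y: set[VariantKey]) -> float:
    """Ratio of population-specific to shared drifted variants.

    |drifted in X only| / |drifted in both X and Y|; both sets must be
    computed against the same common reference.  Returns inf when the sets
    are disjoint but X has private drifted variants, NaN when both counts
    are zero.
    """
    only_x = len(drifted_x - drifted_y)
    both = len(drifted_x & drifted_y)
    if both == 0:
        return float("inf") if only_x else float("nan")
    return only_x / both


def dvxy_table(
    populations: dict[str, list[SiteStats]],
    reference: str,
    annotations: dict[VariantKey, AnnotationRecord],
    ac_classes: tuple[str, ...] = ("1-2", "3-5"),
    cadd_bins: tuple[str, ...] = ("0-5", "5-15", "15-20", ">20"),
    n_boot: int = 1000,
    seed: int = 0,
    rare_af_threshold: float = 0.005,
) -> pd.DataFrame:
    """DVxy of every non-reference population against ``reference``, over a
    grid of AC classes and CADD bins."""
    if reference not in populations:
        raise ValueError(f"reference population {reference!r} missing")
    rows = []
    for i, (pop, stats) in enumerate(populations.items()):
        if pop == reference:
            continue
        for ac_lab in ac_classes:
            for cadd_lab in cadd_bins:
                est = dvxy(
                    stats, populations[reference], annotations,
                    ac_class_label=ac_lab, cadd_bin_label=cadd_lab,
                    n_boot=n_boot, seed=seed + 1000 * i,
                    rare_af_threshold=rare_af_threshold,
                    population_x=pop, population_y=reference,
                )
                rows.append(
                    {
                        "population": pop, "reference": reference,
                        "ac_class": ac_lab, "cadd_bin": cadd_lab,
                        "d_x": est.d_x, "d_y": est.d_y,
                        "dvxy": est.dvxy, "sd": est.sd,
                        "enriched": est.enriched,
                    }
                )
    return pd.DataFrame(rows)
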