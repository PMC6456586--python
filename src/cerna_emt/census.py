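"""MRE-pool census: counting miRNA response elements over a time course.

The abundance of binding sites ("MREs") available to a miRNA is estimated by
multiplying each transcript's abundance by its annotated site count, per seed
class. TPM-scale censuses can be anchored to absolute copies/cell using a
qPCR calibration point, after which stoichiometry between a candidate ceRNA
and its miRNA can be read off directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import (
    SITE_CLASSES,
    AbsoluteAnchors,
    ExpressionTimeCourse,
    SiteAnnotation,
    ValidationError,
)

logger = logging.getLogger("cerna_emt")


@dataclass(frozen=True)
class MreCensus:
    """Per-time, per-site-class MRE totals with per-gene contributions.

    ``per_gene_contrib`` has shape (n_genes, n_classes, n_times); totals are
    the gene-sums and are stored redundantly for convenience.
    """

    mirna_id: str
    source: str
    times: np.ndarray
    gene_ids: tuple
    site_classes: tuple
    per_gene_contrib: np.ndarray
    unit_tag: str = "TPM"
    variant_label: str = "full"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "site_classes", tuple(self.site_classes))
        contrib = np.asarray(self.per_gene_contrib, dtype=float)
        object.__setattr__(self, "per_gene_contrib", contrib)
        expected = (len(self.gene_ids), len(self.site_classes), self.times.size)
        if contrib.shape != expected:
            raise ValidationError(
                f"per_gene_contrib shape {contrib.shape} != genes x classes x times {expected}"
            )
        if np.any(contrib < 0):
            raise ValidationError("negative MRE contribution")

    @property
    def per_class_totals(self) -> np.ndarray:
        """site_class x time matrix of MRE totals (gene sums)."""
        return self.per_gene_contrib.sum(axis=0)

    @property
    def grand_total(self) -> np.ndarray:
        """All-class MRE total per time."""
        return self.per_class_totals.sum(axis=0)

    def time_index(self, t: float) -> int:
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} h not in census times {self.times.tolist()}")
        return int(idx[0])

    def class_pools(self, t: float) -> dict:
        """Mapping site_class -> total MRE abundance at time ``t``."""
        j = self.time_index(t)
        return {c: float(v) for c, v in zip(self.site_classes, self.per_class_totals[:, j])}

    def fold_expansion(self, t0: float, t1: float) -> float:
        """Ratio of all-class MRE totals, total(t1)/total(t0)."""
        g = self.grand_total
        i0, i1 = self.time_index(t0), self.time_index(t1)
        if g[i0] <= 0:
            raise ValidationError(f"zero MRE total at t0={t0} h; fold expansion undefined")
        return float(g[i1] / g[i0])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.gene_ids):
            for ci, c in enumerate(self.site_classes):
                for ti, t in enumerate(self.times):
                    v = self.per_gene_contrib[gi, ci, ti]
                    if v != 0:
                        rows.append((t, c, g, v))
        return pd.DataFrame(rows, columns=["time_h", "site_class", "gene_id", "contribution"])


@dataclass(frozen=True)
class CopyCalibration:
    """Single-point linear calibration from relative abundance to copies/cell."""

    anchor_species: str
    anchor_time: float
    measured_copies: float
    measured_abundance: float

    def __post_init__(self):
        if self.measured_abundance <= 0:
            raise ValidationError("measured_abundance must be > 0 to define a scale")
        if self.measured_copies <= 0:
            raise ValidationError("measured_copies must be > 0")

    @property
    def scale(self) -> float:
        return self.measured_copies / self.measured_abundance


def extrapolate_from_foldchange(
    base_expr: ExpressionTimeCourse, fc: ExpressionTimeCourse
) -> ExpressionTimeCourse:
    """Extrapolate a TPM time course from a baseline TPM and fold changes.

    value(g, t) = base(g, t=0) x fc(g, t). Genes absent from either input
    are dropped (logged); an empty intersection is an error.
    """
    if base_expr.unit_tag != "TPM":
        raise ValidationError(f"base expression must be TPM, got {base_expr.unit_tag}")
    if fc.unit_tag != "FOLD_CHANGE":
        raise ValidationError(f"fold-change input must be FOLD_CHANGE, got {fc.unit_tag}")
    common = [g for g in fc.gene_ids if g in set(base_expr.gene_ids)]
    if not common:
        raise ValidationError("no genes shared between baseline TPM and fold-change matrix")
    dropped = (len(base_expr.gene_ids) - len(common)) + (len(fc.gene_ids) - len(common))
    if dropped:
        logger.info("extrapolate_from_foldchange: dropped %d unshared gene rows", dropped)
    j0 = fc.time_index(0.0) if np.any(np.isclose(fc.times, 0.0)) else None
    if j0 is not None:
        fc0 = np.array([fc.row(g)[j0] for g in common])
        if not np.allclose(fc0, 1.0, rtol=1e-6):
            logger.warning("fold changes at t=0 are not all 1 (max dev %.3g)", np.max(np.abs(fc0 - 1)))
    base0 = np.array([base_expr.row(g)[0] for g in common])
    values = base0[:, None] * np.stack([fc.row(g) for g in common])
    return ExpressionTimeCourse(common, fc.times, values, "TPM")


def estimate_mre_timecourse(
    expr: ExpressionTimeCourse, sites: SiteAnnotation, mirna_id: str, source: str
) -> MreCensus:
    """Census of a miRNA's MRE pool: contribution(g, c, t) = expr(g,t) x n_sites(g,c)."""
    if expr.unit_tag not in ("TPM", "COPIES"):
        raise ValidationError(f"census needs TPM or COPIES expression, got {expr.unit_tag}")
    sub = sites.for_mirna(mirna_id, source)
    if sub.empty:
        raise ValidationError(f"no sites annotated for miRNA {mirna_id!r} (source {source!r})")
    n_sites = np.zeros((len(expr.gene_ids), len(SITE_CLASSES)))
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    class_index = {c: i for i, c in enumerate(SITE_CLASSES)}
    skipped = 0
    for row in sub.itertuples(index=False):
        gi = gene_index.get(row.gene_id)
        if gi is None:
            skipped += 1
            continue
        n_sites[gi, class_index[row.site_class]] += row.n_sites
    if skipped:
        logger.info("census: %d annotated genes absent from expression matrix", skipped)
    contrib = n_sites[:, :, None] * expr.values[:, None, :]
    return MreCensus(
        mirna_id=mirna_id,
        source=source,
        times=expr.times,
        gene_ids=expr.gene_ids,
        site_classes=SITE_CLASSES,
        per_gene_contrib=contrib,
        unit_tag=expr.unit_tag,
    )


def anchor_census(census: MreCensus, calib: CopyCalibration) -> MreCensus:
    """Convert a TPM-scale census to copies/cell via a qPCR calibration point.

    Several calibrations may be combined beforehand with
    :func:`combine_calibrations` (geometric mean of scales).
    """
    scale = calib.scale
    if not np.isfinite(scale) or scale <= 0:
        raise ValidationError(f"calibration scale must be finite and > 0, got {scale}")
    return replace(
        census, per_gene_contrib=census.per_gene_contrib * scale, unit_tag="COPIES"
    )


def combine_calibrations(calibs) -> CopyCalibration:
    """Combine several single-point calibrations by geometric mean of scales."""
    calibs = list(calibs)
    if not calibs:
        raise ValidationError("no calibrations to combine")
    if len(calibs) == 1:
        return calibs[0]
    scales = np.array([c.scale for c in calibs])
    gm = float(np.exp(np.mean(np.log(scales))))
    logger.info("combined %d calibrations; geometric-mean scale %.6g", len(calibs), gm)
    return CopyCalibration(
        anchor_species="+".join(c.anchor_species for c in calibs),
        anchor_time=calibs[0].anchor_time,
        measured_copies=gm,
        measured_abundance=1.0,
    )


def copies_from_reads(query_reads: float, anchor_reads: float, anchor_copies: float) -> float:
    """Absolute copies of a query species from normalized read counts.

    Assumes a linear relationship between normalized read counts and
    molecule numbers: copies = anchor_copies x query_reads / anchor_reads.
    """
    if anchor_reads <= 0:
        raise ValidationError(f"anchor_reads must be > 0, got {anchor_reads}")
    if query_reads < 0:
        raise ValidationError("query_reads must be >= 0")
    return anchor_copies * query_reads / anchor_reads


def functional_mirna_filter(mirna_copies: dict, cutoff: float = 100.0) -> list:
    """miRNAs abundant enough to repress targets: copies > cutoff, descending.

    The default cutoff of 100 copies/cell reflects the observation that
    lowly expressed miRNAs are diluted out by their target-site pool.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    kept = [(m, c) for m, c in mirna_copies.items() if c > cutoff]
    kept.sort(key=lambda mc: (-mc[1], mc[0]))
    return [m for m, _ in kept]


def candidate_regulators(
    de_table: pd.DataFrame,
    predicted: set,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> list:
    """Differentially expressed miRNAs that are also predicted regulators.

    Both gates are strict inequalities: fdr < fdr_cutoff and
    |log2fc| > lfc_cutoff.
    """
    required = {"mirna", "log2fc", "fdr"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValidationError(f"DE table missing columns: {sorted(missing)}")
    passing = de_table[
        (de_table.fdr < fdr_cutoff) & (de_table.log2fc.abs() > lfc_cutoff)
    ]
    hits = [m for m in passing.mirna if m in predicted]
    return sorted(set(hits), key=hits.index)


def dominant_cerna_fraction(census: MreCensus, t0: float, t1: float) -> dict:
    """Share of the MRE-pool *expansion* attributable to each gene.

    Only genes whose all-class contribution increases between t0 and t1 count
    toward the denominator; shrinking genes get fraction 0.
    """
    i0, i1 = census.time_index(t0), census.time_index(t1)
    per_gene = census.per_gene_contrib.sum(axis=1)  # genes x times, all classes
    delta = per_gene[:, i1] - per_gene[:, i0]
    positive = np.clip(delta, 0.0, None)
    total_up = positive.sum()
    if total_up <= 0:
        raise ValidationError(f"no MRE expansion between {t0} h and {t1} h")
    return {g: float(p / total_up) for g, p in zip(census.gene_ids, positive)}


def stoichiometry_ratio(
    anchors: AbsoluteAnchors, species_a: str, species_b: str, time_h: float
) -> tuple:
    """Copy-number fold ratio a/b at a time point, to 2 decimals.

    Returns (ratio, percent_excess) where percent_excess = 100 x (ratio - 1).
    """
    a = anchors.copies(species_a, time_h)
    b = anchors.copies(species_b, time_h)
    ratio = round(a / b, 2)
    return ratio, round(100.0 * (a / b - 1.0), 0)
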