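"""Tabular and configuration I/O for the ceRNA/EMT analysis pipeline.

All on-disk artifacts are plain text: tab-separated tables for expression
time courses, binding-site annotations and absolute copy-number anchors,
and YAML for run configuration. Identifiers are matched case-sensitively
and exactly; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cerna_emt")

#: Canonical seed-match categories, ordered by decreasing binding affinity.
SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "other")

#: Recognised abundance units for expression matrices.
UNITS = ("TPM", "FOLD_CHANGE", "COPIES")

SOURCES = ("targetscan", "pictar")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass(frozen=True)
class ExpressionTimeCourse:
    """Gene x time abundance matrix.

    Parameters
    ----------
    gene_ids : sequence of str
        Row identifiers, case-sensitive, unique.
    times : 1-D array of float
        Sampling times in hours; non-negative, strictly increasing.
    values : 2-D array, shape (n_genes, n_times)
        Non-negative abundances in the unit named by ``unit_tag``.
    unit_tag : {"TPM", "FOLD_CHANGE", "COPIES"}
    """

    gene_ids: tuple
    times: np.ndarray
    values: np.ndarray
    unit_tag: str

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.unit_tag not in UNITS:
            raise ValidationError(f"unknown unit_tag {self.unit_tag!r}; expected one of {UNITS}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_id in expression matrix")
        if not self.gene_ids:
            raise ValidationError("no genes: expression matrix body is empty")
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError("times must be a non-empty 1-D sequence")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be non-negative and strictly increasing")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.times.size} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("negative abundance in expression matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=self.times)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present") from None
        return self.values[i]

    def time_index(self, t: float) -> int:
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} h not in time course {self.times.tolist()}")
        return int(idx[0])


@dataclass(frozen=True)
class SiteAnnotation:
    """Per-gene miRNA binding-site counts by site class and prediction source.

    ``table`` has columns gene_id, mirna_id, site_class, n_sites, source with
    no duplicate (gene_id, mirna_id, site_class, source) keys.
    """

    table: pd.DataFrame

    KEY = ["gene_id", "mirna_id", "site_class", "source"]
    COLUMNS = ["gene_id", "mirna_id", "site_class", "n_sites", "source"]

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"site annotation missing columns: {missing}")
        df = df[self.COLUMNS]
        df["n_sites"] = pd.to_numeric(df["n_sites"])
        if (df["n_sites"] < 0).any():
            bad = df.loc[df["n_sites"] < 0].iloc[0]
            raise ValidationError(f"negative n_sites for {tuple(bad[self.KEY])}")
        if (df["n_sites"] % 1 != 0).any():
            raise ValidationError("n_sites must be integers")
        df["n_sites"] = df["n_sites"].astype(int)
        unknown_class = ~df["site_class"].isin(SITE_CLASSES)
        if unknown_class.any():
            for cls in sorted(df.loc[unknown_class, "site_class"].unique()):
                logger.warning("unknown site_class %r mapped to 'other'", cls)
            df.loc[unknown_class, "site_class"] = "other"
            df = df.groupby(self.KEY, as_index=False, sort=False)["n_sites"].sum()[self.COLUMNS]
        bad_source = ~df["source"].isin(SOURCES)
        if bad_source.any():
            raise ValidationError(
                f"unknown source(s): {sorted(df.loc[bad_source, 'source'].unique())}"
            )
        dup = df.duplicated(self.KEY, keep=False)
        if dup.any():
            keys = df.loc[dup, self.KEY].drop_duplicates().apply(tuple, axis=1).tolist()
            raise ValidationError(f"duplicate site-annotation key(s): {keys}")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def for_mirna(self, mirna_id: str, source: str) -> pd.DataFrame:
        sub = self.table[(self.table.mirna_id == mirna_id) & (self.table.source == source)]
        return sub.reset_index(drop=True)

    def mirnas(self) -> set:
        return set(self.table.mirna_id)


@dataclass(frozen=True)
class AbsoluteAnchors:
    """Absolute qPCR copy-number measurements: (species_id, time_h, copies_per_cell)."""

    table: pd.DataFrame

    COLUMNS = ["species_id", "time_h", "copies_per_cell"]

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"anchors table missing columns: {missing}")
        df = df[self.COLUMNS]
        df["time_h"] = pd.to_numeric(df["time_h"])
        df["copies_per_cell"] = pd.to_numeric(df["copies_per_cell"])
        if (df["copies_per_cell"] <= 0).any():
            raise ValidationError("copies_per_cell must be > 0")
        if df.duplicated(["species_id", "time_h"]).any():
            raise ValidationError("duplicate (species_id, time_h) anchor")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def copies(self, species_id: str, time_h: float) -> float:
        sel = self.table[
            (self.table.species_id == species_id) & np.isclose(self.table.time_h, time_h)
        ]
        if sel.empty:
            raise KeyError(f"no anchor for species {species_id!r} at {time_h} h")
        return float(sel.copies_per_cell.iloc[0])


# Default analysis thresholds: functional-miRNA copy cutoff and the
# differential-expression gates used for candidate-regulator selection.
_CONFIG_DEFAULTS = dict(
    seed=0,
    copies_cutoff=100.0,
    fdr_cutoff=0.05,
    lfc_cutoff=1.0,
    occupancy_rtol=1e-10,
    occupancy_max_iter=200,
    ode_rtol=1e-8,
    ode_atol=1e-10,
    paths={},
)


@dataclass(frozen=True)
class RunConfig:
    """Run-level thresholds, solver tolerances and file paths."""

    seed: int = 0
    copies_cutoff: float = 100.0
    fdr_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    occupancy_rtol: float = 1e-10
    occupancy_max_iter: int = 200
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("occupancy_rtol", "ode_rtol", "ode_atol"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("copies_cutoff", "fdr_cutoff", "lfc_cutoff"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, unit_tag: str) -> ExpressionTimeCourse:
    """Read a gene x time TSV (header: gene_id, then numeric hours)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValidationError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df.empty:
        raise ValidationError(f"{path}: no genes")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric time column header ({exc})") from None
    values = np.empty((len(df), times.size))
    for j, col in enumerate(df.columns[1:]):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.loc[numeric.isna()].iloc[0]
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r}, gene {row['gene_id']!r}"
            )
        values[:, j] = numeric.to_numpy()
    return ExpressionTimeCourse(df["gene_id"].tolist(), times, values, unit_tag)


def write_expression(course: ExpressionTimeCourse, path) -> None:
    df = course.to_frame()
    df.columns = [format(t, "g") for t in course.times]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_site_annotation(path) -> SiteAnnotation:
    """Read a site TSV. pictar rows lacking a site_class get '7mer-m8'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "site_class" not in df.columns and set(df.columns) >= {"gene_id", "mirna_id", "n_sites"}:
        df["site_class"] = "7mer-m8"
    if "source" in df.columns and "site_class" in df.columns:
        blank = df["site_class"].isna() & (df["source"] == "pictar")
        df.loc[blank, "site_class"] = "7mer-m8"
    return SiteAnnotation(df)


def write_site_annotation(sites: SiteAnnotation, path) -> None:
    sites.table.to_csv(path, sep="\t", index=False)


def read_anchors(path) -> AbsoluteAnchors:
    return AbsoluteAnchors(pd.read_csv(path, sep="\t"))


def write_anchors(anchors: AbsoluteAnchors, path) -> None:
    anchors.table.to_csv(path, sep="\t", index=False)


def read_config(path) -> RunConfig:
    """Read a YAML run configuration; absent keys take documented defaults."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"{path}: malformed YAML ({exc})") from None
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    merged = {**_CONFIG_DEFAULTS, **raw}
    return RunConfig(**merged)


def write_config(config: RunConfig, path) -> None:
    data = {k: getattr(config, k) for k in _CONFIG_DEFAULTS}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
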