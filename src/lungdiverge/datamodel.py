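"""Core data containers shared by all pipeline stages.

Matrices are pandas DataFrames (probes/genes x samples) wrapped together
with their genomic annotation.  Internal coordinates are 1-based inclusive
(array annotation convention); BED export is 0-based half-open and the
conversion is centralized in :mod:`lungdiverge.io`.

Missing values are encoded as NaN and are always distinct from a neutral
(0) copy-number state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

SUBTYPES = ("AC", "SqCC")
REFERENCE_GROUPS = ("normal_lung", "bronchial")
VALID_GROUPS = SUBTYPES + REFERENCE_GROUPS

STATE_GAIN = 1
STATE_NEUTRAL = 0
STATE_LOSS = -1

ANNOTATION_COLUMNS = ["chromosome", "start", "end"]


def _check_annotation(annotation: pd.DataFrame, *, n_probes: int | None = None) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    if annotation.index.has_duplicates:
        dups = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids in annotation: {dups[:5]}")
    bad = annotation["start"] >= annotation["end"]
    if bad.any():
        raise ValueError(
            f"probes with start >= end: {annotation.index[bad].tolist()[:5]}"
        )
    if n_probes is not None and len(annotation) != n_probes:
        raise ValueError(
            f"annotation has {len(annotation)} probes, matrix has {n_probes}"
        )


def sort_genomically(annotation: pd.DataFrame) -> pd.DataFrame:
    """Sort probes by (chromosome, start); chromosomes lexicographically."""
    return annotation.sort_values(["chromosome", "start"], kind="stable")


@dataclass
class ProbeStateMatrix:
    """Per-probe, per-sample copy-number state in {-1, 0, +1, NaN}.

    ``states``: DataFrame indexed by probe_id, columns = sample ids, float
    dtype with NaN for missing.  ``annotation``: DataFrame indexed by
    probe_id with chromosome / start / end (1-based inclusive).
    """

    annotation: pd.DataFrame
    states: pd.DataFrame

    def __post_init__(self) -> None:
        _check_annotation(self.annotation, n_probes=len(self.states))
        if not self.annotation.index.equals(self.states.index):
            raise ValueError("annotation and state matrix probe ids differ")
        vals = self.states.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid state {vals[r, c]!r} at probe "
                f"{self.states.index[r]!r}, sample {self.states.columns[c]!r}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)

    def sorted(self) -> "ProbeStateMatrix":
        ann = sort_genomically(self.annotation)
        return ProbeStateMatrix(ann, self.states.loc[ann.index])


@dataclass
class BetaMatrix:
    """Methylation beta-values in [0, 1] with per-cell detection p-values.

    ``annotation`` may carry an ``is_cpg_island`` boolean column.
    """

    annotation: pd.DataFrame
    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_annotation(self.annotation, n_probes=len(self.beta))
        if not self.annotation.index.equals(self.beta.index):
            raise ValueError("annotation and beta matrix probe ids differ")
        vals = self.beta.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("beta values outside [0, 1]")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.beta.index) or list(
                self.detection_p.columns
            ) != list(self.beta.columns):
                raise ValueError("detection_p not aligned with beta matrix")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes/probes x samples.

    ``annotation``: indexed by probe id with at least a ``symbol`` column;
    chromosome / start / end are required only for region mapping.
    """

    annotation: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if "symbol" not in self.annotation.columns:
            raise ValueError("expression annotation needs a 'symbol' column")
        if not self.annotation.index.equals(self.values.index):
            raise ValueError("annotation and expression matrix ids differ")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    ``table``: DataFrame indexed by sample_id with column ``subtype`` in
    {AC, SqCC, normal_lung, bronchial} and optional ``survival_time``
    (months), ``event`` (0/1), ``stage``, ``sex``, ``smoking``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "subtype" not in self.table.columns:
            raise ValueError("clinical table needs a 'subtype' column")
        bad = ~self.table["subtype"].isin(VALID_GROUPS)
        if bad.any():
            raise ValueError(
                f"unknown subtype labels: "
                f"{sorted(self.table.loc[bad, 'subtype'].unique())}"
            )
        if "survival_time" in self.table.columns:
            has_t = self.table["survival_time"].notna()
            if (self.table.loc[has_t, "survival_time"] < 0).any():
                raise ValueError("negative survival times")
            if "event" not in self.table.columns or self.table.loc[
                has_t, "event"
            ].isna().any():
                raise ValueError("event status required wherever survival_time set")

    def samples_of(self, group: str) -> list[str]:
        return list(self.table.index[self.table["subtype"] == group])

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, with their default values.

    Distances are base pairs; alphas are significance levels on
    BH-adjusted p-values unless noted.
    """

    max_impute_distance: int = 10_000_000
    aggregation_similarity: float = 0.90
    region_alpha: float = 0.01
    merge_gap: int = 1_000_000
    min_group_freq: float = 0.20
    min_freq_diff: float = 0.10
    detection_alpha: float = 0.05
    delta_beta: float = 0.15
    meth_alpha: float = 0.05
    meth_max_missing_frac: float = 0.50
    expr_region_alpha: float = 0.001
    expr_vs_normal_alpha: float = 0.001
    meth_expr_alpha: float = 0.05
    survival_alpha: float = 0.05
    min_projection_gene_frac: float = 0.50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "region_alpha", "detection_alpha", "meth_alpha", "expr_region_alpha",
            "expr_vs_normal_alpha", "meth_expr_alpha", "survival_alpha",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.max_impute_distance <= 0 or self.merge_gap <= 0:
            raise ValueError("distances must be positive")
        if not (0.0 < self.aggregation_similarity <= 1.0):
            raise ValueError("aggregation_similarity outside (0, 1]")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GenomicRegion:
    """A run of adjacent probes with per-subtype region-level state counts."""

    chromosome: str
    start: int
    end: int
    probe_ids: list[str]
    # per-subtype counts of samples whose region-level state is gain /
    # neutral / loss; missing samples are excluded
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    # per-sample region-level state (NaN = missing), aligned to cohort order
    sample_states: pd.Series | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DifferentialRegion:
    """A subtype-specific copy-number region after testing and filtering."""

    chromosome: str
    start: int
    end: int
    probe_ids: list[str]
    p: float
    q: float
    significant: bool
    direction: str  # "gain" or "loss"
    assigned_subtype: str  # "AC", "SqCC", or "both_opposite"
    freq_assigned: float
    freq_other: float
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.q < self.p - 1e-12:
            raise ValueError("adjusted p below raw p")


def load_reference_cohort_composition() -> pd.DataFrame:
    """Published NSCLC cohort composition (169 AC, 92 SqCC): stage, sex and
    smoking counts with the percentages as printed in the source table."""
    from importlib.resources import files

    path = files("lungdiverge").joinpath("data/cohort_composition.tsv")
    with path.open() as handle:
        return pd.read_csv(handle, sep="\t")


def clinical_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage composition of a cohort from a count table.

    ``counts``: DataFrame with columns ``group``, ``variable``, ``level``,
    ``count``.  Returns the same rows plus a ``percent`` column computed
    within each (group, variable) over levels with known values; percentages
    are rounded to one decimal place, mirroring how cohort tables print
    them.
    """
    required = {"group", "variable", "level", "count"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    out = counts.copy()
    totals = out.groupby(["group", "variable"])["count"].transform("sum")
    out["percent"] = (out["count"] / totals * 100).round(1)
    return out
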