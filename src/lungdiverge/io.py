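"""Readers and writers for the pipeline's on-disk formats.

All matrices travel as TSV (diff-able, language-neutral); genomic tracks as
BED / bedGraph.  Internal coordinates are 1-based inclusive; BED output is
0-based half-open.  The conversion lives in :func:`to_bed_interval` /
:func:`from_bed_interval` and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    BetaMatrix,
    ClinicalTable,
    DifferentialRegion,
    ExpressionMatrix,
    PipelineConfig,
    ProbeStateMatrix,
    sort_genomically,
)

log = logging.getLogger("lungdiverge")

_STATE_TOKENS = {"-1": -1.0, "0": 0.0, "1": 1.0, "+1": 1.0, "NA": np.nan}

#: float format that round-trips IEEE doubles exactly through text
FLOAT_FMT = "%.17g"


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV annotation: probe_id, chromosome, start, end
    and optional extra columns (is_cpg_island, symbol...)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if "probe_id" not in ann.columns:
        raise ValueError(f"{path}: annotation needs a 'probe_id' column")
    ann = ann.set_index("probe_id")
    if "is_cpg_island" in ann.columns:
        ann["is_cpg_island"] = ann["is_cpg_island"].astype(bool)
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_state_matrix(path: str | Path, annotation_path: str | Path) -> ProbeStateMatrix:
    """Read a probe-state TSV (values in {-1, 0, 1, NA}) plus annotation.

    Probes are returned in genome order.  Unknown value tokens and probe-id
    mismatches between the two files are errors.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    states = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for probe, token in raw[col].items():
            token = token.strip()
            if token not in _STATE_TOKENS:
                raise ValueError(
                    f"{path}: invalid state value {token!r} at probe "
                    f"{probe!r}, sample {col!r}"
                )
            states.at[probe, col] = _STATE_TOKENS[token]
    ann = read_annotation(annotation_path)
    missing = states.index.difference(ann.index)
    if len(missing):
        raise ValueError(
            f"{annotation_path}: annotation missing probe ids: "
            f"{missing.tolist()[:10]}"
        )
    ann = sort_genomically(ann.loc[states.index])
    return ProbeStateMatrix(ann, states.loc[ann.index])


def write_state_matrix(m: ProbeStateMatrix, path: str | Path) -> None:
    out = m.states.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_float_matrix(path: str | Path) -> pd.DataFrame:
    """Read a float TSV with a correctly-rounded parser so that writes via
    :data:`FLOAT_FMT` round-trip bit-exactly."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def read_beta_matrix(
    path: str | Path,
    annotation_path: str | Path,
    detection_path: str | Path | None = None,
) -> BetaMatrix:
    beta = read_float_matrix(path)
    ann = read_annotation(annotation_path)
    missing = beta.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing probe ids: {missing.tolist()[:10]}")
    ann = sort_genomically(ann.loc[beta.index])
    beta = beta.loc[ann.index]
    det = None
    if detection_path is not None:
        det = read_float_matrix(detection_path).loc[ann.index]
    return BetaMatrix(ann, beta, det)


def write_float_matrix(values: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> None:
    values.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_expression_matrix(path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    values = read_float_matrix(path)
    ann = read_annotation(annotation_path)
    missing = values.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing probe ids: {missing.tolist()[:10]}")
    return ExpressionMatrix(ann.loc[values.index], values)


def read_clinical(path: str | Path) -> ClinicalTable:
    table = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ClinicalTable(table)


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    c.table.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# thresholded state calling (plumbing-level stand-in for a segmentation tool)
# ---------------------------------------------------------------------------

def threshold_call_states(
    log2_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    gain_cut: float,
    loss_cut: float,
) -> ProbeStateMatrix:
    """Call gain/neutral/loss from a segmented log2-ratio matrix.

    state = +1 where value >= gain_cut, -1 where value <= loss_cut, else 0;
    NaN propagates.  Boundary values are inclusive.
    """
    if gain_cut <= loss_cut:
        raise ValueError(f"gain_cut ({gain_cut}) must exceed loss_cut ({loss_cut})")
    if not (gain_cut > 0 > loss_cut):
        raise ValueError("need gain_cut > 0 > loss_cut")
    vals = log2_matrix.to_numpy(dtype=float)
    states = np.where(vals >= gain_cut, 1.0, np.where(vals <= loss_cut, -1.0, 0.0))
    states[np.isnan(vals)] = np.nan
    ann = sort_genomically(annotation.loc[log2_matrix.index])
    return ProbeStateMatrix(
        ann, pd.DataFrame(states, index=log2_matrix.index, columns=log2_matrix.columns).loc[ann.index]
    )


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Sequence[DifferentialRegion], path: str | Path) -> None:
    """Write differential regions as BED; name = subtype:direction,
    score = -log10(q) capped at 1000."""
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    ordered = sorted(regions, key=lambda r: (r.chromosome, r.start, r.assigned_subtype))
    for r in ordered:
        b_start, b_end = to_bed_interval(r.start, r.end)
        score = 1000.0 if r.q <= 0 else min(-np.log10(r.q), 1000.0)
        lines.append(
            f"{r.chromosome}\t{b_start}\t{b_end}\t"
            f"{r.assigned_subtype}:{r.direction}\t{score:g}\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bedgraph(
    annotation: pd.DataFrame, values: pd.Series, path: str | Path, track_name: str
) -> None:
    """Per-probe frequency track as bedGraph (0-based half-open)."""
    lines = [f'track type=bedGraph name="{track_name}"']
    ann = annotation.loc[values.index]
    for probe, v in values.items():
        b_start, b_end = to_bed_interval(int(ann.at[probe, "start"]), int(ann.at[probe, "end"]))
        lines.append(f"{ann.at[probe, 'chromosome']}\t{b_start}\t{b_end}\t{v:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def regions_to_frame(regions: Iterable[DifferentialRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "n_probes": len(r.probe_ids),
            "p": r.p,
            "q": r.q,
            "significant": r.significant,
            "direction": r.direction,
            "assigned_subtype": r.assigned_subtype,
            "freq_assigned": r.freq_assigned,
            "freq_other": r.freq_other,
        }
        for subtype, c in r.counts.items():
            for state, v in c.items():
                row[f"{subtype}_{state}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a flat key/value YAML config; keyword overrides win.

    The resolved configuration is logged so every run records its
    thresholds and RNG seed.
    """
    mapping: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            mapping.update(loaded)
    mapping.update({k: v for k, v in overrides.items() if v is not None})
    config = PipelineConfig.from_mapping(mapping)
    log.info("resolved config: %s", config.to_dict())
    return config
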