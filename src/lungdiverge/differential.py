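"""Subtype-specific copy-number region calling.

Aggregated regions are tested for gain/neutral/loss disparity between the
two tumor subtypes with an exact 3x2 Fisher test, BH-corrected over the
number of distinct regions (significant at q <= 0.01), merged across small
gaps when direction and significance agree, and finally filtered on
alteration frequency: the assigned subtype must be altered in more than 20%
of its samples and exceed the other subtype's same-direction frequency by
more than 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna import _modal_state, aggregate_regions, impute_missing_states
from .datamodel import (
    SUBTYPES,
    ClinicalTable,
    DifferentialRegion,
    GenomicRegion,
    PipelineConfig,
    ProbeStateMatrix,
)
from .stats import TestResult, bh_adjust, fisher_exact_3x2

_STATES = ("gain", "neutral", "loss")


@dataclass
class TestedRegion:
    """A genomic region with its disparity test attached."""

    __test__ = False  # not a pytest class despite the name

    region: GenomicRegion
    p: float
    q: float = float("nan")
    significant: bool = False


@dataclass
class StageCounts:
    """Bookkeeping of how many regions survive each stage."""

    tested: int = 0
    significant: int = 0
    merged: int = 0
    filtered: int = 0


def test_region_disparity(region: GenomicRegion) -> TestResult:
    """Exact 3x2 Fisher test of the region's per-subtype state counts."""
    table = [
        [region.counts[st][state] for st in SUBTYPES] for state in _STATES
    ]
    return fisher_exact_3x2(table)


def adjust_and_flag(
    tested: list[TestedRegion], alpha: float = 0.01
) -> list[TestedRegion]:
    """BH over the number of distinct regions; significant iff q <= alpha."""
    if not tested:
        return tested
    qs = bh_adjust([t.p for t in tested])
    for t, q in zip(tested, qs):
        t.q = float(q)
        t.significant = bool(q <= alpha)
    return tested


def _region_frequencies(region: GenomicRegion) -> dict[str, dict[str, float]]:
    """Alteration frequencies per subtype over non-missing samples."""
    freqs: dict[str, dict[str, float]] = {}
    for st in SUBTYPES:
        c = region.counts[st]
        n = sum(c.values())
        freqs[st] = {
            state: (c[state] / n if n else 0.0) for state in _STATES
        }
    return freqs


def region_direction(region: GenomicRegion) -> str:
    """The alteration state (gain or loss) with the largest absolute
    between-subtype frequency difference."""
    f = _region_frequencies(region)
    diffs = {
        state: abs(f["AC"][state] - f["SqCC"][state]) for state in ("gain", "loss")
    }
    # tie -> gain (deterministic; relevant only for perfectly balanced regions)
    return max(("gain", "loss"), key=lambda s: (diffs[s], s == "gain"))


def merge_adjacent(
    tested: list[TestedRegion], max_gap: int = 1_000_000,
    matrix: ProbeStateMatrix | None = None, clinical: ClinicalTable | None = None,
) -> list[TestedRegion]:
    """Merge consecutive same-chromosome regions when the gap between them
    is at most ``max_gap`` bp and both direction and significance flag
    match.

    Counts of a merged region are recomputed from the pooled member probes
    (modal state over the union); p and q are the minimum over members,
    retained for reporting only — significance was decided before merging.
    """
    if not tested:
        return tested
    ordered = sorted(tested, key=lambda t: (t.region.chromosome, t.region.start))
    merged: list[TestedRegion] = [ordered[0]]
    for t in ordered[1:]:
        prev = merged[-1]
        gap = t.region.start - prev.region.end - 1
        same = (
            t.region.chromosome == prev.region.chromosome
            and gap <= max_gap
            and t.significant == prev.significant
            and region_direction(t.region) == region_direction(prev.region)
        )
        if not same:
            merged.append(t)
            continue
        merged[-1] = _pool(prev, t, matrix, clinical)
    return merged


def _pool(
    a: TestedRegion, b: TestedRegion,
    matrix: ProbeStateMatrix | None, clinical: ClinicalTable | None,
) -> TestedRegion:
    probe_ids = a.region.probe_ids + b.region.probe_ids
    if matrix is not None and clinical is not None:
        block = matrix.states.loc[probe_ids].to_numpy(dtype=float)
        states = _modal_state(block)
        samples = matrix.samples
        sample_states = pd.Series(states, index=samples)
        counts = {}
        for st in SUBTYPES:
            members = [s for s in clinical.samples_of(st) if s in samples]
            sub = sample_states.loc[members].to_numpy()
            counts[st] = {
                "gain": int((sub == 1.0).sum()),
                "neutral": int((sub == 0.0).sum()),
                "loss": int((sub == -1.0).sum()),
            }
    else:
        # fall back to summing member counts when probe states are unavailable
        counts = {
            st: {
                s: a.region.counts[st][s] + b.region.counts[st][s] for s in _STATES
            }
            for st in SUBTYPES
        }
        sample_states = None
    region = GenomicRegion(
        chromosome=a.region.chromosome,
        start=a.region.start,
        end=b.region.end,
        probe_ids=probe_ids,
        counts=counts,
        sample_states=sample_states,
    )
    return TestedRegion(
        region=region,
        p=min(a.p, b.p),
        q=min(a.q, b.q),
        significant=a.significant,
    )


def apply_frequency_filters(
    tested: list[TestedRegion],
    min_group_freq: float = 0.20,
    min_diff: float = 0.10,
) -> list[DifferentialRegion]:
    """Keep significant regions whose dominant alteration frequency in the
    assigned subtype is strictly above ``min_group_freq`` and exceeds the
    other subtype's same-direction frequency by strictly more than
    ``min_diff``.

    A region passing in opposite directions for the two subtypes is emitted
    once per subtype with ``assigned_subtype='both_opposite'``.
    """
    out: list[DifferentialRegion] = []
    for t in tested:
        if not t.significant:
            continue
        f = _region_frequencies(t.region)
        claims = []  # (subtype, direction, freq, other_freq)
        for st in SUBTYPES:
            other = "SqCC" if st == "AC" else "AC"
            best: tuple[str, str, float, float] | None = None
            for direction in ("gain", "loss"):
                freq, other_freq = f[st][direction], f[other][direction]
                passes = freq > min_group_freq and freq - other_freq > min_diff
                if passes and (best is None or freq - other_freq > best[2] - best[3]):
                    best = (st, direction, freq, other_freq)
            if best is not None:
                claims.append(best)
        if not claims:
            continue
        both = len(claims) == 2
        for st, direction, freq, other_freq in claims:
            out.append(
                DifferentialRegion(
                    chromosome=t.region.chromosome,
                    start=t.region.start,
                    end=t.region.end,
                    probe_ids=list(t.region.probe_ids),
                    p=t.p,
                    q=t.q,
                    significant=True,
                    direction=direction,
                    assigned_subtype="both_opposite" if both else st,
                    freq_assigned=freq,
                    freq_other=other_freq,
                    counts=t.region.counts,
                )
            )
    return out


@dataclass
class RegionCallResult:
    regions: list[DifferentialRegion]
    tested: list[TestedRegion]
    stage_counts: StageCounts = field(default_factory=StageCounts)


def call_subtype_specific_regions(
    matrix: ProbeStateMatrix,
    clinical: ClinicalTable,
    config: PipelineConfig | None = None,
) -> RegionCallResult:
    """Full pipeline: impute -> aggregate -> test -> BH flag -> merge ->
    frequency filter.  Deterministic composition of the stage functions."""
    config = config or PipelineConfig()
    imputed = impute_missing_states(matrix, config.max_impute_distance)
    regions = aggregate_regions(imputed, clinical, config.aggregation_similarity)
    tested = [TestedRegion(r, test_region_disparity(r).p) for r in regions]
    tested = adjust_and_flag(tested, config.region_alpha)
    counts = StageCounts(
        tested=len(tested), significant=sum(t.significant for t in tested)
    )
    merged = merge_adjacent(tested, config.merge_gap, imputed, clinical)
    counts.merged = len(merged)
    final = apply_frequency_filters(merged, config.min_group_freq, config.min_freq_diff)
    counts.filtered = len(final)
    return RegionCallResult(regions=final, tested=merged, stage_counts=counts)
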