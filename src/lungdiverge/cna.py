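"""Copy-number landscape: imputation, instability summaries, region
aggregation and alteration-frequency tracks.

Probe states (+1 gain, 0 neutral, -1 loss, NaN missing) are aggregated into
genomic regions when adjacent probes carry the same state in at least a
configurable fraction of samples within each tumor subtype independently;
the resulting shared region set feeds the between-subtype disparity tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    SUBTYPES,
    ClinicalTable,
    GenomicRegion,
    ProbeStateMatrix,
)
from .stats import mann_whitney

_STATE_NAMES = {1: "gain", 0: "neutral", -1: "loss"}


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing_states(
    m: ProbeStateMatrix, max_dist: int = 10_000_000
) -> ProbeStateMatrix:
    """Fill missing states from the nearest non-missing probe on the same
    chromosome within ``max_dist`` bp (midpoint distance), per sample.

    Equidistant neighbours with conflicting states leave the cell missing;
    imputation never crosses a chromosome boundary.
    """
    ann = m.annotation
    states = m.states.to_numpy(dtype=float).copy()
    mid = ((ann["start"].to_numpy() + ann["end"].to_numpy()) / 2.0).astype(float)
    chroms = ann["chromosome"].to_numpy()

    out = states.copy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = mid[idx]
        block = states[idx, :]
        filled = block.copy()
        for j in range(block.shape[1]):
            col = block[:, j]
            miss = np.isnan(col)
            if not miss.any() or miss.all():
                continue
            known = np.flatnonzero(~miss)
            for i in np.flatnonzero(miss):
                d = np.abs(pos[known] - pos[i])
                dmin = d.min()
                if dmin > max_dist:
                    continue
                nearest = known[d == dmin]
                vals = np.unique(col[nearest])
                if len(vals) == 1:
                    filled[i, j] = vals[0]
                # conflicting equidistant neighbours: stay missing
        out[idx, :] = filled
    return ProbeStateMatrix(
        ann, pd.DataFrame(out, index=m.states.index, columns=m.states.columns)
    )


# ---------------------------------------------------------------------------
# per-sample instability
# ---------------------------------------------------------------------------

@dataclass
class InstabilitySummary:
    """Per-sample state fractions and between-subtype comparisons."""

    fractions: pd.DataFrame  # samples x (fraction_gain, fraction_neutral, fraction_loss)
    comparisons: pd.Series  # index gain/neutral/loss -> two-sided Mann-Whitney p


def instability_summary(
    m: ProbeStateMatrix, clinical: ClinicalTable
) -> InstabilitySummary:
    """Fraction of non-missing probes in each state per sample, and a
    two-sided Mann-Whitney comparison of each fraction between AC and SqCC."""
    vals = m.states.to_numpy(dtype=float)
    n_known = (~np.isnan(vals)).sum(axis=0)
    if (n_known == 0).any():
        bad = [s for s, n in zip(m.samples, n_known) if n == 0]
        raise ValueError(f"samples with all probes missing: {bad}")
    rows = {}
    for state, name in _STATE_NAMES.items():
        rows[f"fraction_{name}"] = (vals == state).sum(axis=0) / n_known
    fractions = pd.DataFrame(rows, index=m.samples)

    comparisons = {}
    ac = [s for s in clinical.samples_of("AC") if s in fractions.index]
    sq = [s for s in clinical.samples_of("SqCC") if s in fractions.index]
    for name in _STATE_NAMES.values():
        res = mann_whitney(
            fractions.loc[ac, f"fraction_{name}"],
            fractions.loc[sq, f"fraction_{name}"],
            "two_sided",
        )
        comparisons[name] = res.p
    return InstabilitySummary(fractions, pd.Series(comparisons))


# ---------------------------------------------------------------------------
# region aggregation
# ---------------------------------------------------------------------------

def _adjacent_similarity_ok(
    a: np.ndarray, b: np.ndarray, groups: list[np.ndarray], similarity: float
) -> bool:
    """Merge criterion between two adjacent probe state vectors: within each
    subtype independently, the fraction of samples (non-missing at both
    probes) with identical state must reach ``similarity``."""
    for g in groups:
        xa, xb = a[g], b[g]
        known = ~(np.isnan(xa) | np.isnan(xb))
        if known.sum() == 0:
            continue  # no evidence against merging in this group
        frac = (xa[known] == xb[known]).mean()
        if frac < similarity:
            return False
    return True


def _modal_state(block: np.ndarray) -> np.ndarray:
    """Per-sample modal member-probe state; ties -> neutral; all-missing -> NaN."""
    n_samples = block.shape[1]
    out = np.full(n_samples, np.nan)
    for j in range(n_samples):
        col = block[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = {s: int((col == s).sum()) for s in (-1.0, 0.0, 1.0)}
        best = max(counts.values())
        winners = [s for s, c in counts.items() if c == best]
        out[j] = winners[0] if len(winners) == 1 else 0.0
    return out


def aggregate_regions(
    m: ProbeStateMatrix,
    clinical: ClinicalTable,
    similarity: float = 0.90,
) -> list[GenomicRegion]:
    """Merge genomically adjacent probes into regions.

    Two adjacent probes join the same region only if, within each tumor
    subtype separately, at least ``similarity`` of samples carry the same
    state at both probes.  A region's per-sample state is the modal state
    of its member probes (ties resolved to neutral); per-subtype
    gain/neutral/loss counts are taken over samples with a non-missing
    region state.
    """
    if not (0.0 < similarity <= 1.0):
        raise ValueError("similarity must be in (0, 1]")
    if len(m.states) == 0:
        raise ValueError("empty state matrix")
    m = m.sorted()
    samples = m.samples
    sample_pos = {s: i for i, s in enumerate(samples)}
    groups = [
        np.asarray([sample_pos[s] for s in clinical.samples_of(st) if s in sample_pos])
        for st in SUBTYPES
    ]
    vals = m.states.to_numpy(dtype=float)
    ann = m.annotation
    chroms = ann["chromosome"].to_numpy()

    regions: list[GenomicRegion] = []
    start_i = 0
    for i in range(1, len(ann) + 1):
        boundary = (
            i == len(ann)
            or chroms[i] != chroms[i - 1]
            or not _adjacent_similarity_ok(vals[i - 1], vals[i], groups, similarity)
        )
        if boundary:
            block = vals[start_i:i, :]
            member_ids = list(m.states.index[start_i:i])
            region_states = _modal_state(block)
            counts = {}
            for st, g in zip(SUBTYPES, groups):
                sub = region_states[g]
                counts[st] = {
                    "gain": int((sub == 1.0).sum()),
                    "neutral": int((sub == 0.0).sum()),
                    "loss": int((sub == -1.0).sum()),
                }
            regions.append(
                GenomicRegion(
                    chromosome=str(chroms[start_i]),
                    start=int(ann["start"].iloc[start_i]),
                    end=int(ann["end"].iloc[i - 1]),
                    probe_ids=member_ids,
                    counts=counts,
                    sample_states=pd.Series(region_states, index=samples),
                )
            )
            start_i = i
    return regions


# ---------------------------------------------------------------------------
# frequency tracks
# ---------------------------------------------------------------------------

def frequency_tracks(
    m: ProbeStateMatrix, clinical: ClinicalTable
) -> pd.DataFrame:
    """Per-probe gain and loss frequencies per subtype group.

    Frequencies are over non-missing samples; columns are
    ``{subtype}_gain`` and ``{subtype}_loss``.
    """
    vals = m.states.to_numpy(dtype=float)
    out = {}
    for st in SUBTYPES:
        cols = [i for i, s in enumerate(m.samples) if s in set(clinical.samples_of(st))]
        block = vals[:, cols]
        n_known = (~np.isnan(block)).sum(axis=1)
        denom = np.where(n_known == 0, 1, n_known)
        out[f"{st}_gain"] = np.where(n_known == 0, 0.0, (block == 1.0).sum(axis=1) / denom)
        out[f"{st}_loss"] = np.where(n_known == 0, 0.0, (block == -1.0).sum(axis=1) / denom)
    return pd.DataFrame(out, index=m.states.index)
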