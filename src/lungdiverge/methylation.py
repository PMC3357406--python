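"""Differential DNA methylation between tumor subtypes.

Beta-values (methylated / total signal, in [0, 1]) are first masked on
their detection p-value, then expressed as differentials against the mean
of the matched normal reference compartment (lung parenchyma for AC,
bronchial epithelium for SqCC).  A probe is aberrant in a tumor when
|delta-beta| >= 0.15; per-probe hyper/unchanged/hypo frequencies are then
compared between subtypes with the exact 3x2 Fisher test and BH-corrected
over the tested probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, ClinicalTable
from .stats import bh_adjust, fisher_exact_3x2, mann_whitney

log = logging.getLogger("lungdiverge")

#: maps tumor subtype -> normal reference group whose mean profile is
#: subtracted (explicit config, not inferred from the data)
DEFAULT_REFERENCE_MAP = {"AC": "normal_lung", "SqCC": "bronchial"}

_CALLS = ("hyper", "unchanged", "hypo")


def filter_by_detection(b: BetaMatrix, alpha: float = 0.05) -> BetaMatrix:
    """Mask beta cells whose detection p-value exceeds ``alpha``.

    The boundary is inclusive: detection p == alpha is kept.
    """
    if b.detection_p is None:
        return b
    masked = b.beta.where(b.detection_p.to_numpy() <= alpha)
    return BetaMatrix(b.annotation, masked, b.detection_p)


@dataclass
class DifferentialMethylProfile:
    """Per-probe, per-tumor-sample methylation differentials.

    ``delta``: tumor beta minus mean reference beta; ``calls``: strings in
    {hyper, unchanged, hypo} with NaN-backed missing encoded as None.
    """

    delta: pd.DataFrame
    calls: pd.DataFrame  # object dtype: "hyper" / "unchanged" / "hypo" / NaN
    threshold: float

    @property
    def samples(self) -> list[str]:
        return list(self.delta.columns)


def differential_beta(
    tumors: BetaMatrix,
    reference: BetaMatrix,
    delta: float = 0.15,
) -> DifferentialMethylProfile:
    """Delta-beta profile of tumors against the averaged reference.

    call = hyper where delta-beta >= threshold, hypo where <= -threshold
    (boundaries inclusive), unchanged otherwise; missing propagates.  A
    probe with no non-missing reference value is an error.
    """
    if not tumors.beta.index.equals(reference.beta.index):
        raise ValueError("tumor and reference matrices must share probes")
    ref_mean = reference.beta.mean(axis=1, skipna=True)
    empty = ref_mean.isna()
    if empty.any():
        raise ValueError(
            f"probes with empty reference: {ref_mean.index[empty].tolist()[:10]}"
        )
    d = tumors.beta.sub(ref_mean, axis=0)
    arr = d.to_numpy(dtype=float)
    calls = np.full(arr.shape, None, dtype=object)
    calls[arr >= delta] = "hyper"
    calls[arr <= -delta] = "hypo"
    calls[(arr > -delta) & (arr < delta)] = "unchanged"
    return DifferentialMethylProfile(
        delta=d,
        calls=pd.DataFrame(calls, index=d.index, columns=d.columns),
        threshold=delta,
    )


# ---------------------------------------------------------------------------
# global summaries (CpG-island vs non-island strata)
# ---------------------------------------------------------------------------

@dataclass
class GlobalMethylationSummary:
    """Per-sample mean beta by CpG-island stratum plus group comparisons."""

    sample_means: pd.DataFrame  # samples x (island, non_island), plus group col
    comparisons: pd.DataFrame  # rows: (stratum, group_a, group_b, p)


def global_methylation_summary(
    b: BetaMatrix,
    clinical: ClinicalTable,
    group_pairs: list[tuple[str, str]] | None = None,
) -> GlobalMethylationSummary:
    """Mean beta per sample over island and non-island probes, and
    two-sided Mann-Whitney comparisons between the requested group pairs.

    Defaults compare AC vs SqCC tumors and the two normal compartments —
    the contrast in which central-airway samples (SqCC, bronchial) show
    lower methylation off-island than peripheral samples.
    """
    if "is_cpg_island" not in b.annotation.columns:
        raise ValueError("annotation lacks 'is_cpg_island'")
    island = b.annotation["is_cpg_island"].astype(bool)
    if island.all() or (~island).all():
        raise ValueError("need probes both inside and outside CpG islands")
    strata = {"island": island, "non_island": ~island}
    means = pd.DataFrame(
        {name: b.beta.loc[mask.to_numpy()].mean(axis=0) for name, mask in strata.items()}
    )
    means["group"] = [
        clinical.table.at[s, "subtype"] if s in clinical.table.index else "?"
        for s in means.index
    ]

    if group_pairs is None:
        group_pairs = [("AC", "SqCC"), ("normal_lung", "bronchial")]
    rows = []
    for ga, gb in group_pairs:
        for stratum in strata:
            xa = means.loc[means["group"] == ga, stratum].dropna()
            xb = means.loc[means["group"] == gb, stratum].dropna()
            if len(xa) == 0 or len(xb) == 0:
                continue
            res = mann_whitney(xa, xb, "two_sided")
            rows.append(
                {"stratum": stratum, "group_a": ga, "group_b": gb, "p": res.p}
            )
    return GlobalMethylationSummary(means, pd.DataFrame(rows))


def global_delta_summary(
    profiles: dict[str, DifferentialMethylProfile],
    annotation: pd.DataFrame,
) -> GlobalMethylationSummary:
    """Analogous per-sample summary of delta-beta profiles by stratum,
    comparing the subtypes' differential (tumor minus reference) levels."""
    island = annotation["is_cpg_island"].astype(bool)
    frames = []
    for subtype, prof in profiles.items():
        means = pd.DataFrame(
            {
                "island": prof.delta.loc[island.to_numpy()].mean(axis=0),
                "non_island": prof.delta.loc[(~island).to_numpy()].mean(axis=0),
            }
        )
        means["group"] = subtype
        frames.append(means)
    all_means = pd.concat(frames)
    rows = []
    subtypes = list(profiles)
    if len(subtypes) == 2:
        ga, gb = subtypes
        for stratum in ("island", "non_island"):
            res = mann_whitney(
                all_means.loc[all_means["group"] == ga, stratum].dropna(),
                all_means.loc[all_means["group"] == gb, stratum].dropna(),
                "two_sided",
            )
            rows.append({"stratum": stratum, "group_a": ga, "group_b": gb, "p": res.p})
    return GlobalMethylationSummary(all_means, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# per-probe disparity
# ---------------------------------------------------------------------------

@dataclass
class DifferentialMethylProbe:
    """Per-probe between-subtype methylation disparity result."""

    probe_id: str
    counts: dict[str, dict[str, int]]  # subtype -> {hyper, unchanged, hypo}
    p: float
    q: float
    significant: bool
    dominant_subtype: str
    direction: str  # "hyper" or "hypo"

    def __post_init__(self) -> None:
        if self.q < self.p - 1e-12:
            raise ValueError("adjusted p below raw p")


def _call_counts(calls_row: np.ndarray) -> dict[str, int]:
    return {c: int((calls_row == c).sum()) for c in _CALLS}


def test_probe_methylation_disparity(
    profile_ac: DifferentialMethylProfile,
    profile_sqcc: DifferentialMethylProfile,
    alpha: float = 0.05,
    max_missing_frac: float = 0.50,
) -> list[DifferentialMethylProbe]:
    """Per-probe exact 3x2 test of (hyper, unchanged, hypo) x (AC, SqCC).

    Probes missing in more than ``max_missing_frac`` of either subtype are
    excluded from testing (and logged); BH runs over the tested probes;
    significant iff q < alpha.  Dominant subtype and direction come from
    the largest hyper/hypo frequency difference.
    """
    if not profile_ac.calls.index.equals(profile_sqcc.calls.index):
        raise ValueError("profiles must share probes")
    results: list[DifferentialMethylProbe] = []
    raw_p: list[float] = []
    skipped: list[str] = []
    ac_arr = profile_ac.calls.to_numpy(dtype=object)
    sq_arr = profile_sqcc.calls.to_numpy(dtype=object)
    n_ac, n_sq = ac_arr.shape[1], sq_arr.shape[1]
    for i, probe in enumerate(profile_ac.calls.index):
        ac_row, sq_row = ac_arr[i], sq_arr[i]
        c_ac, c_sq = _call_counts(ac_row), _call_counts(sq_row)
        if (
            n_ac - sum(c_ac.values()) > max_missing_frac * n_ac
            or n_sq - sum(c_sq.values()) > max_missing_frac * n_sq
            or sum(c_ac.values()) + sum(c_sq.values()) == 0
        ):
            skipped.append(probe)
            continue
        table = [[c_ac[c], c_sq[c]] for c in _CALLS]
        p = fisher_exact_3x2(table).p
        raw_p.append(p)

        f_ac = {c: c_ac[c] / max(sum(c_ac.values()), 1) for c in _CALLS}
        f_sq = {c: c_sq[c] / max(sum(c_sq.values()), 1) for c in _CALLS}
        best = max(
            (("AC", d, f_ac[d] - f_sq[d]) for d in ("hyper", "hypo")),
            key=lambda x: x[2],
        )
        best_sq = max(
            (("SqCC", d, f_sq[d] - f_ac[d]) for d in ("hyper", "hypo")),
            key=lambda x: x[2],
        )
        dominant = best if best[2] >= best_sq[2] else best_sq
        results.append(
            DifferentialMethylProbe(
                probe_id=probe,
                counts={"AC": c_ac, "SqCC": c_sq},
                p=p,
                q=float("nan"),
                significant=False,
                dominant_subtype=dominant[0],
                direction=dominant[1],
            )
        )
    if skipped:
        log.info("methylation disparity: %d probes untestable, excluded", len(skipped))
    if results:
        qs = bh_adjust(raw_p)
        for r, q in zip(results, qs):
            r.q = float(q)
            r.significant = bool(q < alpha)
    return results


def methyl_probes_to_frame(probes: list[DifferentialMethylProbe]) -> pd.DataFrame:
    rows = []
    for r in probes:
        row = {
            "probe_id": r.probe_id,
            "p": r.p,
            "q": r.q,
            "significant": r.significant,
            "dominant_subtype": r.dominant_subtype,
            "direction": r.direction,
        }
        for st, c in r.counts.items():
            for call, v in c.items():
                row[f"{st}_{call}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
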