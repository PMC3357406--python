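"""Expression integration: from subtype-specific DNA lesions to candidate
genes with direction-concordant expression changes.

Copy-number route: genes overlapping a differential region are tested
between subtypes with a one-tailed Mann-Whitney test whose tail matches
the lesion direction (gain -> assigned subtype higher, loss -> lower),
BH-corrected within the region's probe family (q <= 0.001), then validated
against normal tissue with a one-tailed Welch t test (p < 0.001) and a
fold-change direction gate.

Methylation route: genes linked to differentially methylated probes are
tested the same way with the expected direction opposite to the
methylation change (hyper -> down, hypo -> up) at the 0.05 level.

Finally, candidate lists are combined into per-subtype concerted (both
mechanisms, same direction) and cross-subtype diametric gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datamodel import (
    SUBTYPES,
    ClinicalTable,
    DifferentialRegion,
    ExpressionMatrix,
)
from .methylation import DifferentialMethylProbe
from .stats import DegenerateDataError, bh_adjust, mann_whitney, welch_t

log = logging.getLogger("lungdiverge")


@dataclass
class CandidateGene:
    """A gene whose expression matches its subtype-specific DNA lesion."""

    symbol: str
    subtype: str
    mechanism: str  # "copy_number", "methylation", or "both"
    expected_direction: str  # "up" or "down"
    link: str  # region key or methylation probe id
    subtype_p: float
    subtype_q: float
    vs_normal_p: float = float("nan")
    fold_change: float = float("nan")
    pass_subtype: bool = False
    pass_vs_normal: bool = False

    @property
    def retained(self) -> bool:
        return self.pass_subtype and self.pass_vs_normal


def _region_key(r: DifferentialRegion) -> str:
    return f"{r.chromosome}:{r.start}-{r.end}:{r.assigned_subtype}:{r.direction}"


def _direction_of_region(r: DifferentialRegion) -> str:
    return "up" if r.direction == "gain" else "down"


def _claim_subtype(r: DifferentialRegion) -> str:
    """The subtype whose expression is expected to move: for both_opposite
    regions the claim was emitted per subtype, recoverable from frequencies."""
    if r.assigned_subtype in SUBTYPES:
        return r.assigned_subtype
    # both_opposite: the subtype with the higher frequency of this region's
    # direction is the claimant
    freqs = {}
    for st in SUBTYPES:
        c = r.counts[st]
        n = sum(c.values())
        freqs[st] = c[r.direction] / n if n else 0.0
    return max(SUBTYPES, key=lambda s: freqs[s])


# ---------------------------------------------------------------------------
# gene-to-region mapping
# ---------------------------------------------------------------------------

def map_genes_to_regions(
    genes: pd.DataFrame, regions: list[DifferentialRegion]
) -> dict[str, list[str]]:
    """Assign expression probes to regions by any genomic overlap.

    ``genes``: annotation indexed by probe id with symbol / chromosome /
    start / end.  Returns region key -> list of probe ids; a probe spanning
    two regions is assigned to both (logged).
    """
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        # 1-based inclusive -> half-open for the interval tree
        trees.setdefault(r.chromosome, IntervalTree()).addi(
            r.start, r.end + 1, _region_key(r)
        )
    out: dict[str, list[str]] = {_region_key(r): [] for r in regions}
    multi = 0
    for probe_id, row in genes.iterrows():
        tree = trees.get(str(row["chromosome"]))
        if tree is None:
            continue
        hits = tree.overlap(int(row["start"]), int(row["end"]) + 1)
        if len(hits) > 1:
            multi += 1
        for hit in hits:
            out[hit.data].append(probe_id)
    if multi:
        log.info("map_genes_to_regions: %d probes span multiple regions", multi)
    return out


# ---------------------------------------------------------------------------
# per-region expression testing
# ---------------------------------------------------------------------------

@dataclass
class RegionGeneResult:
    symbol: str
    probe_id: str
    p: float
    q: float
    significant: bool


def test_region_genes(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    region: DifferentialRegion,
    probe_ids: list[str],
    alpha: float = 0.001,
) -> list[RegionGeneResult]:
    """One-tailed Mann-Whitney per probe with the tail matching the
    region's direction; BH with family = probes mapped to this region;
    collapse to gene by minimum p; significant iff q <= alpha."""
    if not probe_ids:
        log.info("region %s has no mapped expression probes", _region_key(region))
        return []
    claimant = _claim_subtype(region)
    other = "SqCC" if claimant == "AC" else "AC"
    x_cols = [s for s in clinical.samples_of(claimant) if s in expr.values.columns]
    y_cols = [s for s in clinical.samples_of(other) if s in expr.values.columns]
    tail = "one_sided_greater" if region.direction == "gain" else "one_sided_less"
    pvals = []
    for pid in probe_ids:
        res = mann_whitney(
            expr.values.loc[pid, x_cols], expr.values.loc[pid, y_cols], tail
        )
        pvals.append(res.p)
    qs = bh_adjust(pvals)

    by_gene: dict[str, RegionGeneResult] = {}
    for pid, p, q in zip(probe_ids, pvals, qs):
        sym = str(expr.annotation.at[pid, "symbol"])
        cand = RegionGeneResult(sym, pid, float(p), float(q), bool(q <= alpha))
        if sym not in by_gene or cand.p < by_gene[sym].p:
            by_gene[sym] = cand
    return list(by_gene.values())


# ---------------------------------------------------------------------------
# tumor-vs-normal validation
# ---------------------------------------------------------------------------

def validate_vs_normal(
    candidates: list[CandidateGene],
    expr_tumors: ExpressionMatrix,
    clinical: ClinicalTable,
    expr_normals: ExpressionMatrix,
    alpha: float = 0.001,
) -> list[CandidateGene]:
    """One-tailed Welch t of each candidate's subtype tumors against the
    normal pool, tail = expected direction; pass iff p < alpha AND the
    linear-scale fold change agrees with the expected direction.

    Gene matching across matrices is by symbol, case-insensitive; with
    multiple probes the strongest p is used.
    """
    norm_by_symbol: dict[str, list[str]] = {}
    for pid, row in expr_normals.annotation.iterrows():
        norm_by_symbol.setdefault(str(row["symbol"]).upper(), []).append(pid)
    tum_by_symbol: dict[str, list[str]] = {}
    for pid, row in expr_tumors.annotation.iterrows():
        tum_by_symbol.setdefault(str(row["symbol"]).upper(), []).append(pid)

    for cand in candidates:
        sym = cand.symbol.upper()
        tum_probes = tum_by_symbol.get(sym, [])
        norm_probes = norm_by_symbol.get(sym, [])
        if not tum_probes or not norm_probes:
            log.info("candidate %s has no probes for vs-normal test", cand.symbol)
            continue
        cols = [
            s for s in clinical.samples_of(cand.subtype)
            if s in expr_tumors.values.columns
        ]
        tail = "one_sided_greater" if cand.expected_direction == "up" else "one_sided_less"
        best_p, best_fc = np.inf, np.nan
        for tp in tum_probes:
            tum_vals = expr_tumors.values.loc[tp, cols].to_numpy(dtype=float)
            for npid in norm_probes:
                norm_vals = expr_normals.values.loc[npid].to_numpy(dtype=float)
                try:
                    res = welch_t(tum_vals, norm_vals, tail)
                except DegenerateDataError:
                    log.info("zero-variance degenerate groups for %s", cand.symbol)
                    continue
                if res.p < best_p:
                    best_p = res.p
                    # linear-scale ratio of un-logged means
                    best_fc = float(
                        np.exp2(tum_vals.mean()) / np.exp2(norm_vals.mean())
                    )
        if not np.isfinite(best_p):
            continue
        cand.vs_normal_p = float(best_p)
        cand.fold_change = best_fc
        direction_ok = (
            best_fc > 1.0 if cand.expected_direction == "up" else best_fc < 1.0
        )
        cand.pass_vs_normal = bool(best_p < alpha and direction_ok)
    return candidates


# ---------------------------------------------------------------------------
# copy-number route wrapper
# ---------------------------------------------------------------------------

def copy_number_candidates(
    regions: list[DifferentialRegion],
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    expr_normals: ExpressionMatrix,
    region_alpha: float = 0.001,
    vs_normal_alpha: float = 0.001,
) -> list[CandidateGene]:
    """Full copy-number integration: map genes, test per region, validate
    against normals; returns all candidates with their pass flags."""
    gene_map = map_genes_to_regions(expr.annotation, regions)
    candidates: list[CandidateGene] = []
    for region in regions:
        results = test_region_genes(
            expr, clinical, region, gene_map[_region_key(region)], region_alpha
        )
        claimant = _claim_subtype(region)
        for res in results:
            candidates.append(
                CandidateGene(
                    symbol=res.symbol,
                    subtype=claimant,
                    mechanism="copy_number",
                    expected_direction=_direction_of_region(region),
                    link=_region_key(region),
                    subtype_p=res.p,
                    subtype_q=res.q,
                    pass_subtype=res.significant,
                )
            )
    passing = [c for c in candidates if c.pass_subtype]
    validate_vs_normal(passing, expr, clinical, expr_normals, vs_normal_alpha)
    return candidates


# ---------------------------------------------------------------------------
# methylation route
# ---------------------------------------------------------------------------

def integrate_methylation_expression(
    methyl_probes: list[DifferentialMethylProbe],
    probe_genes: pd.Series,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    expr_normals: ExpressionMatrix,
    alpha: float = 0.05,
) -> list[CandidateGene]:
    """Candidate genes from significant differentially methylated probes.

    ``probe_genes`` maps methylation probe id -> gene symbol.  Expected
    expression direction is opposite to the methylation change in the
    dominant subtype; the subtype comparison is BH-corrected over all
    methylation-linked genes tested, then the tumor-vs-normal Welch test
    and fold-change gate are applied at the same ``alpha``.
    """
    expr_by_symbol: dict[str, list[str]] = {}
    for pid, row in expr.annotation.iterrows():
        expr_by_symbol.setdefault(str(row["symbol"]).upper(), []).append(pid)

    candidates: list[CandidateGene] = []
    pvals: list[float] = []
    untested: list[str] = []
    for probe in methyl_probes:
        if not probe.significant:
            continue
        symbol = probe_genes.get(probe.probe_id)
        if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)):
            continue
        symbol = str(symbol)
        probes = expr_by_symbol.get(symbol.upper(), [])
        if not probes:
            untested.append(symbol)
            continue
        subtype = probe.dominant_subtype
        other = "SqCC" if subtype == "AC" else "AC"
        direction = "down" if probe.direction == "hyper" else "up"
        tail = "one_sided_greater" if direction == "up" else "one_sided_less"
        x_cols = [s for s in clinical.samples_of(subtype) if s in expr.values.columns]
        y_cols = [s for s in clinical.samples_of(other) if s in expr.values.columns]
        best = min(
            (
                mann_whitney(expr.values.loc[pid, x_cols], expr.values.loc[pid, y_cols], tail).p
                for pid in probes
            ),
        )
        pvals.append(best)
        candidates.append(
            CandidateGene(
                symbol=symbol,
                subtype=subtype,
                mechanism="methylation",
                expected_direction=direction,
                link=probe.probe_id,
                subtype_p=float(best),
                subtype_q=float("nan"),
            )
        )
    if untested:
        log.info(
            "methylation integration: %d genes without expression probes", len(untested)
        )
    if candidates:
        qs = bh_adjust(pvals)
        for cand, q in zip(candidates, qs):
            cand.subtype_q = float(q)
            cand.pass_subtype = bool(q < alpha)
        passing = [c for c in candidates if c.pass_subtype]
        validate_vs_normal(passing, expr, clinical, expr_normals, alpha)
    return candidates


# ---------------------------------------------------------------------------
# concerted / diametric lists
# ---------------------------------------------------------------------------

@dataclass
class ConcertedLists:
    """Combined candidate gene sets with per-gene provenance."""

    concerted: dict[str, list[str]] = field(default_factory=dict)  # subtype -> genes
    diametric: list[str] = field(default_factory=list)
    union: pd.DataFrame = field(default_factory=pd.DataFrame)


def concerted_gene_lists(
    cn_candidates: list[CandidateGene],
    meth_candidates: list[CandidateGene],
) -> ConcertedLists:
    """Build (a) per-subtype concerted genes altered by both mechanisms in
    the same direction, (b) cross-subtype diametric genes (one mechanism
    per subtype, opposite directions), and (c) the deduplicated union
    signature with provenance."""
    cn = [c for c in cn_candidates if c.retained]
    meth = [c for c in meth_candidates if c.retained]

    def keyset(cands: list[CandidateGene]) -> dict[tuple[str, str, str], CandidateGene]:
        return {(c.symbol.upper(), c.subtype, c.expected_direction): c for c in cands}

    cn_keys, meth_keys = keyset(cn), keyset(meth)
    concerted: dict[str, list[str]] = {st: [] for st in SUBTYPES}
    for (sym, st, direction), cand in cn_keys.items():
        if (sym, st, direction) in meth_keys:
            concerted[st].append(cand.symbol)

    # diametric: a gene claimed in both subtypes with opposite directions,
    # through one mechanism in each
    by_symbol: dict[str, list[CandidateGene]] = {}
    for c in cn + meth:
        by_symbol.setdefault(c.symbol.upper(), []).append(c)
    diametric = []
    for sym, cands in by_symbol.items():
        claims = {(c.subtype, c.expected_direction, c.mechanism) for c in cands}
        subtype_dirs = {(s, d) for s, d, _ in claims}
        if len({s for s, _ in subtype_dirs}) == 2 and len({d for _, d in subtype_dirs}) == 2:
            mechs = {s: {m for s2, _, m in claims if s2 == s} for s in SUBTYPES}
            if mechs["AC"] != mechs["SqCC"] or len(mechs["AC"]) == 1:
                diametric.append(cands[0].symbol)

    rows = []
    for c in cn + meth:
        rows.append(
            {
                "symbol": c.symbol,
                "subtype": c.subtype,
                "mechanism": c.mechanism,
                "direction": c.expected_direction,
                "link": c.link,
            }
        )
    union = pd.DataFrame(rows)
    if not union.empty:
        union = (
            union.groupby("symbol", sort=True)
            .agg(
                subtypes=("subtype", lambda s: "+".join(sorted(set(s)))),
                mechanisms=("mechanism", lambda s: "+".join(sorted(set(s)))),
                directions=("direction", lambda s: "+".join(sorted(set(s)))),
                links=("link", lambda s: ";".join(sorted(set(s)))),
            )
            .reset_index()
        )
    return ConcertedLists(concerted=concerted, diametric=sorted(diametric), union=union)


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "symbol": c.symbol,
                "subtype": c.subtype,
                "mechanism": c.mechanism,
                "direction": c.expected_direction,
                "link": c.link,
                "subtype_p": c.subtype_p,
                "subtype_q": c.subtype_q,
                "vs_normal_p": c.vs_normal_p,
                "fold_change": c.fold_change,
                "pass_subtype": c.pass_subtype,
                "pass_vs_normal": c.pass_vs_normal,
                "retained": c.retained,
            }
            for c in candidates
        ]
    )
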