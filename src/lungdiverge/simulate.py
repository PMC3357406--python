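"""Seeded synthetic two-subtype multi-omic cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes: two
tumor subtypes (AC, SqCC) with planted subtype-specific copy-number
lesions applied at a given penetrance plus random passenger segments and
missing probes; methylation beta-values drawn around per-compartment
baselines with planted hyper/hypomethylation shifts against the matched
normal reference; expression coupled additively (log2 scale) to
copy-number dosage and, with opposite sign, to methylation direction; and
exponential survival with per-gene, per-subtype log-hazard effects.

It does NOT emulate dye bias, batch effects, or correlation structure
between neighbouring methylation probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    BetaMatrix,
    ClinicalTable,
    ExpressionMatrix,
    ProbeStateMatrix,
)
from . import io as ld_io


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int  # bp
    cn_spacing: int  # bp between copy-number probes
    meth_spacing: int  # bp between methylation probes
    gene_spacing: int  # bp between genes

    def __post_init__(self) -> None:
        if min(self.cn_spacing, self.meth_spacing, self.gene_spacing) <= 0:
            raise ValueError("probe spacings must be positive")


@dataclass(frozen=True)
class CnLesion:
    """A planted subtype-specific copy-number segment."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    direction: str  # "gain" or "loss"
    subtype: str  # target subtype
    penetrance: float

    def __post_init__(self) -> None:
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must be in (0, 1]")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class MethLesion:
    """A planted subtype-specific methylation shift at one probe."""

    probe_id: str
    direction: str  # "hyper" or "hypo"
    subtype: str
    penetrance: float
    magnitude: float  # |delta-beta|, >= 0.15 for a detectable lesion

    def __post_init__(self) -> None:
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must be in (0, 1]")
        if not (0.0 < self.magnitude <= 1.0):
            raise ValueError("magnitude must be in (0, 1]")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class CoupledGene:
    """A gene whose expression tracks a planted lesion.

    ``lesion_index`` points into planted_cn_lesions (mechanism
    copy_number) or planted_meth_probes (mechanism methylation).  The
    effect is in units of the expression noise SD, applied on the log2
    scale with the dosage sign (gain up, loss down) or the opposite of the
    methylation direction (hyper down, hypo up).
    """

    symbol: str
    mechanism: str  # "copy_number" or "methylation"
    lesion_index: int
    effect_sd: float

    def __post_init__(self) -> None:
        if self.mechanism not in ("copy_number", "methylation"):
            raise ValueError(f"bad mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class SurvivalSpec:
    baseline_hazard: float = 0.02  # events per month
    censoring_max: float = 120.0  # months; independent uniform censoring
    # subtype -> {gene symbol -> log hazard ratio per SD of expression}
    gene_log_hr: dict = field(default_factory=dict)


@dataclass
class CohortSpec:
    n_AC: int = 30
    n_SqCC: int = 30
    n_normal_lung: int = 15
    n_bronchial: int = 12
    genome: list[ChromosomeSpec] = field(default_factory=list)
    planted_cn_lesions: list[CnLesion] = field(default_factory=list)
    passenger_rate: float = 1.0  # expected random segments per tumor sample
    passenger_length_range: tuple[int, int] = (200_000, 20_000_000)
    missing_rate: float = 0.02
    planted_meth_probes: list[MethLesion] = field(default_factory=list)
    coupled_genes: list[CoupledGene] = field(default_factory=list)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    expr_noise_sd: float = 0.5
    cn_log2_shift: float = 0.55
    cn_log2_noise_sd: float = 0.15
    beta_concentration: float = 150.0  # Beta-distribution concentration
    # per-compartment (island, non-island) beta baselines; the central-airway
    # compartment (SqCC / bronchial) sits slightly below the peripheral one
    # off-island, so the global island/non-island contrast is reproducible
    beta_baselines: dict = field(
        default_factory=lambda: {
            "AC": (0.12, 0.75),
            "normal_lung": (0.12, 0.75),
            "SqCC": (0.11, 0.65),
            "bronchial": (0.11, 0.65),
        }
    )
    detection_fail_rate: float = 0.01
    island_fraction: float = 1.0 / 3.0  # realized as every round(1/f)-th probe
    rng_seed: int = 0

    def validate(self) -> None:
        chrom_len = {c.name: c.length for c in self.genome}
        if not chrom_len:
            raise ValueError("genome must list at least one chromosome")
        for lesion in self.planted_cn_lesions:
            if lesion.chromosome not in chrom_len:
                raise ValueError(f"lesion on unknown chromosome {lesion.chromosome}")
            if not (1 <= lesion.start < lesion.end <= chrom_len[lesion.chromosome]):
                raise ValueError(f"lesion {lesion} outside chromosome bounds")
        meth_ids = set(meth_probe_annotation(self.genome, self.island_fraction).index)
        for m in self.planted_meth_probes:
            if m.probe_id not in meth_ids:
                raise ValueError(f"planted methylation probe {m.probe_id} not in genome")
        for g in self.coupled_genes:
            n = (
                len(self.planted_cn_lesions)
                if g.mechanism == "copy_number"
                else len(self.planted_meth_probes)
            )
            if not (0 <= g.lesion_index < n):
                raise ValueError(f"coupled gene {g.symbol} references lesion {g.lesion_index}")


# ---------------------------------------------------------------------------
# deterministic genome layout
# ---------------------------------------------------------------------------

def cn_probe_annotation(genome: list[ChromosomeSpec]) -> pd.DataFrame:
    rows = []
    for c in genome:
        n = c.length // c.cn_spacing
        for i in range(n):
            start = 1 + i * c.cn_spacing
            rows.append(
                {
                    "probe_id": f"cn_{c.name}_{i:05d}",
                    "chromosome": c.name,
                    "start": start,
                    "end": start + 999,
                }
            )
    return pd.DataFrame(rows).set_index("probe_id")


def meth_probe_annotation(
    genome: list[ChromosomeSpec], island_fraction: float = 1.0 / 3.0
) -> pd.DataFrame:
    """Methylation probes on a fixed grid; island status is a deterministic
    stripe so that island/non-island strata interleave along the genome."""
    period = max(int(round(1.0 / island_fraction)), 1)
    rows = []
    for c in genome:
        n = c.length // c.meth_spacing
        for i in range(n):
            start = 1 + i * c.meth_spacing
            rows.append(
                {
                    "probe_id": f"me_{c.name}_{i:05d}",
                    "chromosome": c.name,
                    "start": start,
                    "end": start + 49,
                    "is_cpg_island": (i % period) == 0,
                }
            )
    return pd.DataFrame(rows).set_index("probe_id")


def gene_annotation(genome: list[ChromosomeSpec]) -> pd.DataFrame:
    rows = []
    for c in genome:
        n = c.length // c.gene_spacing
        for i in range(n):
            start = 1 + i * c.gene_spacing
            rows.append(
                {
                    "probe_id": f"ex_{c.name}_{i:04d}",
                    "symbol": f"G{c.name.upper()}_{i:04d}",
                    "chromosome": c.name,
                    "start": start,
                    "end": start + c.gene_spacing // 3,
                }
            )
    return pd.DataFrame(rows).set_index("probe_id")


def genes_in_interval(
    genes: pd.DataFrame, chromosome: str, start: int, end: int
) -> list[str]:
    hit = (
        (genes["chromosome"] == chromosome)
        & (genes["start"] <= end)
        & (genes["end"] >= start)
    )
    return genes.loc[hit, "symbol"].tolist()


def nearest_gene(genes: pd.DataFrame, chromosome: str, pos: int) -> str:
    sub = genes[genes["chromosome"] == chromosome]
    mid = (sub["start"] + sub["end"]) / 2.0
    return str(sub["symbol"].iloc[int(np.argmin(np.abs(mid - pos)))])


def map_probes_to_nearest_genes(
    genes: pd.DataFrame, probe_ann: pd.DataFrame
) -> pd.Series:
    """Vectorized probe -> nearest gene symbol (midpoint distance, same
    chromosome)."""
    out = pd.Series(index=probe_ann.index, dtype=object)
    for chrom, sub in genes.groupby("chromosome"):
        probes = probe_ann[probe_ann["chromosome"] == chrom]
        if probes.empty:
            continue
        mid = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        order = np.argsort(mid)
        mid_sorted = mid[order]
        symbols = sub["symbol"].to_numpy()[order]
        pos = ((probes["start"] + probes["end"]) / 2.0).to_numpy()
        right = np.searchsorted(mid_sorted, pos)
        left = np.clip(right - 1, 0, len(mid_sorted) - 1)
        right = np.clip(right, 0, len(mid_sorted) - 1)
        use_right = np.abs(mid_sorted[right] - pos) < np.abs(mid_sorted[left] - pos)
        out.loc[probes.index] = symbols[np.where(use_right, right, left)]
    return out


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What was planted, and who carries it in the emitted data."""

    cn_lesions: list[CnLesion]
    cn_carriers: list[list[str]]  # per lesion: samples carrying it in emitted states
    meth_lesions: list[MethLesion]
    meth_carriers: list[list[str]]
    # per coupled gene: symbol, mechanism, subtype, expected expression direction
    coupled: pd.DataFrame
    meth_probe_genes: pd.Series  # methylation probe id -> gene symbol


@dataclass
class SyntheticCohort:
    cn: ProbeStateMatrix
    cn_log2: pd.DataFrame
    methylation: BetaMatrix
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: GroundTruth
    spec: CohortSpec

    def expression_for(self, groups: tuple[str, ...]) -> ExpressionMatrix:
        cols = [
            s for s in self.expression.samples
            if self.clinical.table.at[s, "subtype"] in groups
        ]
        return ExpressionMatrix(self.expression.annotation, self.expression.values[cols])

    def beta_for(self, group: str) -> BetaMatrix:
        cols = self.clinical.samples_of(group)
        cols = [s for s in cols if s in self.methylation.beta.columns]
        det = None
        if self.methylation.detection_p is not None:
            det = self.methylation.detection_p[cols]
        return BetaMatrix(self.methylation.annotation, self.methylation.beta[cols], det)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_ids(spec: CohortSpec) -> dict[str, list[str]]:
    return {
        "AC": [f"AC{i:03d}" for i in range(spec.n_AC)],
        "SqCC": [f"SQ{i:03d}" for i in range(spec.n_SqCC)],
        "normal_lung": [f"NL{i:03d}" for i in range(spec.n_normal_lung)],
        "bronchial": [f"BR{i:03d}" for i in range(spec.n_bronchial)],
    }


def _beta_draw(rng: np.random.Generator, mu: np.ndarray, conc: float) -> np.ndarray:
    mu = np.clip(mu, 0.02, 0.98)
    return rng.beta(mu * conc, (1.0 - mu) * conc)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full paired cohort from one seeded generator."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    ids = _sample_ids(spec)
    tumor_ids = ids["AC"] + ids["SqCC"]
    subtype_of = {s: st for st, ss in ids.items() for s in ss}

    # ----- copy number -----
    cn_ann = cn_probe_annotation(spec.genome)
    n_probes = len(cn_ann)
    states = np.zeros((n_probes, len(tumor_ids)))
    chrom_arr = cn_ann["chromosome"].to_numpy()
    start_arr = cn_ann["start"].to_numpy()
    end_arr = cn_ann["end"].to_numpy()
    chrom_names = [c.name for c in spec.genome]
    chrom_lengths = np.array([c.length for c in spec.genome], dtype=float)

    # passengers first, planted lesions afterwards so that lesion carriers
    # always show the lesion in the emitted states
    for j, sid in enumerate(tumor_ids):
        for _ in range(rng.poisson(spec.passenger_rate)):
            ci = rng.choice(len(chrom_names), p=chrom_lengths / chrom_lengths.sum())
            lo, hi = spec.passenger_length_range
            length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            seg_start = int(rng.integers(1, max(int(chrom_lengths[ci]) - length, 2)))
            mask = (
                (chrom_arr == chrom_names[ci])
                & (start_arr <= seg_start + length)
                & (end_arr >= seg_start)
            )
            states[mask, j] = rng.choice([-1.0, 1.0])

    for lesion in spec.planted_cn_lesions:
        targets = ids[lesion.subtype]
        carry = rng.random(len(targets)) < lesion.penetrance
        mask = (
            (chrom_arr == lesion.chromosome)
            & (start_arr <= lesion.end)
            & (end_arr >= lesion.start)
        )
        val = 1.0 if lesion.direction == "gain" else -1.0
        for sid, c in zip(targets, carry):
            if c:
                states[mask, tumor_ids.index(sid)] = val

    # missingness
    miss = rng.random(states.shape) < spec.missing_rate
    states_missing = states.copy()
    states_missing[miss] = np.nan

    # carriers recomputed from the emitted states: a sample carries a lesion
    # iff every non-missing probe in the interval shows the lesion direction
    cn_carriers: list[list[str]] = []
    for lesion in spec.planted_cn_lesions:
        mask = (
            (chrom_arr == lesion.chromosome)
            & (start_arr <= lesion.end)
            & (end_arr >= lesion.start)
        )
        val = 1.0 if lesion.direction == "gain" else -1.0
        carriers = []
        for j, sid in enumerate(tumor_ids):
            block = states_missing[mask, j]
            known = block[~np.isnan(block)]
            if known.size and (known == val).all():
                carriers.append(sid)
        cn_carriers.append(carriers)

    cn = ProbeStateMatrix(
        cn_ann, pd.DataFrame(states_missing, index=cn_ann.index, columns=tumor_ids)
    )
    log2 = (
        spec.cn_log2_shift * states
        + rng.normal(0.0, spec.cn_log2_noise_sd, states.shape)
    )
    log2[miss] = np.nan
    cn_log2 = pd.DataFrame(log2, index=cn_ann.index, columns=tumor_ids)

    # ----- methylation -----
    me_ann = meth_probe_annotation(spec.genome, spec.island_fraction)
    genes = gene_annotation(spec.genome)
    meth_samples = tumor_ids + ids["normal_lung"] + ids["bronchial"]
    island = me_ann["is_cpg_island"].to_numpy()

    base = {
        group: np.where(island, lo, hi)
        for group, (lo, hi) in spec.beta_baselines.items()
    }
    mu = np.column_stack([base[subtype_of[s]] for s in meth_samples])

    probe_pos = {p: i for i, p in enumerate(me_ann.index)}
    meth_planted: list[np.ndarray] = []
    for m in spec.planted_meth_probes:
        targets = ids[m.subtype]
        carry = rng.random(len(targets)) < m.penetrance
        meth_planted.append(carry)
        shift = m.magnitude if m.direction == "hyper" else -m.magnitude
        row = probe_pos[m.probe_id]
        for sid, c in zip(targets, carry):
            if c:
                mu[row, meth_samples.index(sid)] += shift
    beta = _beta_draw(rng, mu, spec.beta_concentration)
    detection = rng.uniform(0.0, 0.04, beta.shape)
    fail = rng.random(beta.shape) < spec.detection_fail_rate
    detection[fail] = rng.uniform(0.051, 1.0, int(fail.sum()))
    meth = BetaMatrix(
        me_ann,
        pd.DataFrame(beta, index=me_ann.index, columns=meth_samples),
        pd.DataFrame(detection, index=me_ann.index, columns=meth_samples),
    )
    meth_carriers = [
        [sid for sid, c in zip(ids[m.subtype], carry) if c]
        for m, carry in zip(spec.planted_meth_probes, meth_planted)
    ]
    meth_probe_genes = map_probes_to_nearest_genes(genes, me_ann)

    # ----- expression -----
    expr_samples = tumor_ids + ids["bronchial"]
    n_genes = len(genes)
    baseline = rng.normal(8.0, 1.0, n_genes)
    expr = np.tile(baseline[:, None], (1, len(expr_samples))) + rng.normal(
        0.0, spec.expr_noise_sd, (n_genes, len(expr_samples))
    )
    symbol_row = {sym: i for i, sym in enumerate(genes["symbol"])}

    coupled_rows = []
    for g in spec.coupled_genes:
        row = symbol_row[g.symbol]
        effect = g.effect_sd * spec.expr_noise_sd
        if g.mechanism == "copy_number":
            lesion = spec.planted_cn_lesions[g.lesion_index]
            sign = 1.0 if lesion.direction == "gain" else -1.0
            carriers = set(cn_carriers[g.lesion_index])
            direction = "up" if lesion.direction == "gain" else "down"
        else:
            m = spec.planted_meth_probes[g.lesion_index]
            lesion = m
            sign = -1.0 if m.direction == "hyper" else 1.0
            carriers = set(meth_carriers[g.lesion_index])
            direction = "down" if m.direction == "hyper" else "up"
        for j, sid in enumerate(expr_samples):
            if sid in carriers:
                expr[row, j] += sign * effect
        coupled_rows.append(
            {
                "symbol": g.symbol,
                "mechanism": g.mechanism,
                "subtype": lesion.subtype,
                "direction": direction,
                "effect_sd": g.effect_sd,
                "lesion_index": g.lesion_index,
            }
        )
    expression = ExpressionMatrix(
        genes, pd.DataFrame(expr, index=genes.index, columns=expr_samples)
    )

    # ----- clinical + survival -----
    clin = _clinical_table(spec, ids, rng)
    table = clin.table
    for st in ("AC", "SqCC"):
        members = ids[st]
        cols = [expr_samples.index(s) for s in members]
        log_hr = np.zeros(len(members))
        for sym, beta_g in spec.survival.gene_log_hr.get(st, {}).items():
            vals = expr[symbol_row[sym], cols]
            z = (vals - vals.mean()) / (vals.std(ddof=0) or 1.0)
            log_hr = log_hr + beta_g * z
        hazard = spec.survival.baseline_hazard * np.exp(log_hr)
        event_t = rng.exponential(1.0 / hazard)
        censor_t = rng.uniform(0.0, spec.survival.censoring_max, len(members))
        observed = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        table.loc[members, "survival_time"] = observed
        table.loc[members, "event"] = event
    clinical = ClinicalTable(table)

    truth = GroundTruth(
        cn_lesions=list(spec.planted_cn_lesions),
        cn_carriers=cn_carriers,
        meth_lesions=list(spec.planted_meth_probes),
        meth_carriers=meth_carriers,
        coupled=pd.DataFrame(coupled_rows),
        meth_probe_genes=meth_probe_genes,
    )
    return SyntheticCohort(cn, cn_log2, meth, expression, clinical, truth, spec)


def _clinical_table(
    spec: CohortSpec, ids: dict[str, list[str]], rng: np.random.Generator
) -> ClinicalTable:
    """Clinical covariates with margins loosely matching an NSCLC cohort
    (AC skews female and never-smoker; SqCC male and ever-smoker)."""
    rows = []
    profiles = {
        "AC": {
            "stage": (["I", "II", "III", "IV"], [0.45, 0.24, 0.14, 0.17]),
            "sex": (["F", "M"], [0.63, 0.37]),
            "smoking": (["current", "ex", "never"], [0.29, 0.48, 0.23]),
        },
        "SqCC": {
            "stage": (["I", "II", "III", "IV"], [0.36, 0.36, 0.16, 0.12]),
            "sex": (["F", "M"], [0.28, 0.72]),
            "smoking": (["current", "ex", "never"], [0.33, 0.66, 0.01]),
        },
    }
    for group, members in ids.items():
        for sid in members:
            row = {"sample_id": sid, "subtype": group}
            if group in profiles:
                for var, (levels, probs) in profiles[group].items():
                    row[var] = rng.choice(levels, p=probs)
            rows.append(row)
    table = pd.DataFrame(rows).set_index("sample_id")
    table["survival_time"] = np.nan
    table["event"] = np.nan
    return ClinicalTable(table)


def _pick_meth_lesions(
    meth_ann: pd.DataFrame,
    wanted: list[tuple[str, str, int]],
    penetrance: float,
    magnitude: float,
) -> list[MethLesion]:
    """Place each (direction, subtype) lesion at the first probe at or
    after the given index whose island status allows the shift: hyper on
    island probes (room to rise), hypo off-island (room to fall)."""
    island = meth_ann["is_cpg_island"].to_numpy()
    ids = list(meth_ann.index)
    lesions = []
    for direction, subtype, start_idx in wanted:
        want_island = direction == "hyper"
        i = start_idx
        while island[i % len(ids)] != want_island:
            i += 1
        lesions.append(
            MethLesion(ids[i % len(ids)], direction, subtype, penetrance, magnitude)
        )
    return lesions


# ---------------------------------------------------------------------------
# the desk-scale default cohort
# ---------------------------------------------------------------------------

def default_paper_like_spec(rng_seed: int = 0) -> CohortSpec:
    """A desk-scale cohort: 5 chromosomes (~2000 CN probes, ~3000
    methylation probes, ~1500 genes), 30 tumors per subtype, planted
    lesions spanning three orders of magnitude in size (65 Mb down to
    50 kb), methylation shifts of 0.3 at 70% penetrance, and
    dosage/methylation-coupled genes at 1.5 noise-SD effect size."""
    genome = [
        ChromosomeSpec(f"chr{i + 1}", 100_000_000, 250_000, 166_000, 333_000)
        for i in range(5)
    ]
    lesions = [
        CnLesion("chr1", 10_000_001, 75_000_000, "gain", "SqCC", 0.65),  # 65 Mb
        CnLesion("chr2", 20_000_001, 25_000_000, "loss", "AC", 0.60),  # 5 Mb
        CnLesion("chr3", 40_000_001, 40_500_000, "loss", "SqCC", 0.60),  # 0.5 Mb
        CnLesion("chr4", 60_000_001, 68_000_000, "gain", "AC", 0.55),  # 8 Mb
        # 50 kb focal peak positioned over a single probe
        CnLesion("chr5", 50_000_001, 50_050_000, "gain", "SqCC", 0.60),
    ]
    genes = gene_annotation(genome)
    meth_ann = meth_probe_annotation(genome)

    def pick_genes(lesion: CnLesion, k: int) -> list[str]:
        inside = genes_in_interval(genes, lesion.chromosome, lesion.start, lesion.end)
        step = max(len(inside) // k, 1)
        return inside[::step][:k]

    coupled = []
    for li, lesion in enumerate(lesions):
        for sym in pick_genes(lesion, 2):
            coupled.append(CoupledGene(sym, "copy_number", li, 1.5))

    # methylation lesions follow the canonical cancer pattern:
    # hypermethylation hits CpG-island probes (low baseline, can rise),
    # hypomethylation hits non-island probes (high baseline, can fall)
    meth_lesions = _pick_meth_lesions(
        meth_ann,
        [
            ("hyper", "SqCC", 120),
            ("hypo", "SqCC", 840),
            ("hyper", "AC", 1500),
            ("hypo", "AC", 2200),
            ("hyper", "SqCC", 2700),
        ],
        penetrance=0.7,
        magnitude=0.30,
    )
    for mi, m in enumerate(meth_lesions):
        sym = nearest_gene(
            genes, meth_ann.at[m.probe_id, "chromosome"], int(meth_ann.at[m.probe_id, "start"])
        )
        coupled.append(CoupledGene(sym, "methylation", mi, 1.5))

    # one gene with a subtype-restricted hazard (threefold per SD in SqCC
    # only), mirroring subtype-opposite prognostic behaviour
    hazard_gene = coupled[0].symbol
    survival = SurvivalSpec(
        baseline_hazard=0.02,
        censoring_max=120.0,
        gene_log_hr={"SqCC": {hazard_gene: float(np.log(3.0))}, "AC": {}},
    )
    return CohortSpec(
        n_AC=30,
        n_SqCC=30,
        n_normal_lung=15,
        n_bronchial=12,
        genome=genome,
        planted_cn_lesions=lesions,
        passenger_rate=1.0,
        missing_rate=0.02,
        planted_meth_probes=meth_lesions,
        coupled_genes=coupled,
        survival=survival,
        rng_seed=rng_seed,
    )


def lineage_driver_spec(rng_seed: int = 0) -> CohortSpec:
    """A focused strong-effect cohort for end-to-end gene recovery.

    Emulates near-clonal lineage-restricted driver lesions (the 3q-gain /
    SOX2 archetype): focal 5-6 Mb segments at 90% penetrance in their
    subtype, each carrying two dosage-coupled genes at 3 noise-SD effect
    (a 1.5 log2-unit, ~2.8-fold shift in carriers) among ~17 bystanders,
    plus matched near-clonal methylation lesions.  Weakly penetrant,
    weakly coupled alterations are deliberately absent: this cohort asks
    whether clearly driven genes survive the pipeline's stringent
    direction-matched thresholds, not where its detection limit lies.
    """
    genome = [
        ChromosomeSpec(f"chr{i + 1}", 60_000_000, 250_000, 166_000, 333_000)
        for i in range(3)
    ]
    lesions = [
        CnLesion("chr1", 10_000_001, 16_000_000, "gain", "SqCC", 0.9),
        CnLesion("chr2", 30_000_001, 35_000_000, "loss", "AC", 0.9),
        CnLesion("chr3", 5_000_001, 11_000_000, "gain", "AC", 0.9),
        CnLesion("chr3", 40_000_001, 45_000_000, "loss", "SqCC", 0.9),
    ]
    genes = gene_annotation(genome)
    coupled = []
    for li, lesion in enumerate(lesions):
        inside = genes_in_interval(genes, lesion.chromosome, lesion.start, lesion.end)
        step = max(len(inside) // 2, 1)
        for sym in inside[::step][:2]:
            coupled.append(CoupledGene(sym, "copy_number", li, 3.0))

    meth_ann = meth_probe_annotation(genome)
    meth_lesions = _pick_meth_lesions(
        meth_ann,
        [("hyper", "SqCC", 130), ("hypo", "AC", 401), ("hypo", "SqCC", 700)],
        penetrance=0.9,
        magnitude=0.30,
    )
    for mi, m in enumerate(meth_lesions):
        sym = nearest_gene(
            genes, meth_ann.at[m.probe_id, "chromosome"], int(meth_ann.at[m.probe_id, "start"])
        )
        coupled.append(CoupledGene(sym, "methylation", mi, 3.0))
    return CohortSpec(
        n_AC=30,
        n_SqCC=30,
        n_normal_lung=15,
        n_bronchial=12,
        genome=genome,
        planted_cn_lesions=lesions,
        passenger_rate=0.5,
        missing_rate=0.02,
        planted_meth_probes=meth_lesions,
        coupled_genes=coupled,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cohort(c: SyntheticCohort, directory: str | Path) -> None:
    """Write every matrix as TSV, ground truth as TSV + BED, and a
    manifest recording the spec and seed."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ld_io.write_state_matrix(c.cn, d / "cn_states.tsv")
    ld_io.write_annotation(c.cn.annotation, d / "cn_annotation.tsv")
    ld_io.write_float_matrix(c.cn_log2, d / "cn_log2.tsv")
    ld_io.write_float_matrix(c.methylation.beta, d / "beta.tsv")
    ld_io.write_float_matrix(c.methylation.detection_p, d / "detection_p.tsv")
    ld_io.write_annotation(c.methylation.annotation, d / "meth_annotation.tsv")
    ld_io.write_float_matrix(c.expression.values, d / "expression.tsv")
    ld_io.write_annotation(c.expression.annotation, d / "expr_annotation.tsv")
    ld_io.write_clinical(c.clinical, d / "clinical.tsv")

    truth_rows = []
    bed_lines = ["#chrom\tstart\tend\tname"]
    for lesion, carriers in zip(c.truth.cn_lesions, c.truth.cn_carriers):
        truth_rows.append(
            {
                "kind": "cn",
                "locus": f"{lesion.chromosome}:{lesion.start}-{lesion.end}",
                "direction": lesion.direction,
                "subtype": lesion.subtype,
                "penetrance": lesion.penetrance,
                "carriers": ",".join(carriers),
            }
        )
        b_start, b_end = ld_io.to_bed_interval(lesion.start, lesion.end)
        bed_lines.append(
            f"{lesion.chromosome}\t{b_start}\t{b_end}\t"
            f"{lesion.subtype}:{lesion.direction}"
        )
    for m, carriers in zip(c.truth.meth_lesions, c.truth.meth_carriers):
        truth_rows.append(
            {
                "kind": "methylation",
                "locus": m.probe_id,
                "direction": m.direction,
                "subtype": m.subtype,
                "penetrance": m.penetrance,
                "carriers": ",".join(carriers),
            }
        )
    pd.DataFrame(truth_rows).to_csv(d / "ground_truth.tsv", sep="\t", index=False)
    (d / "ground_truth.bed").write_text("\n".join(bed_lines) + "\n")
    c.truth.coupled.to_csv(d / "coupled_genes.tsv", sep="\t", index=False)

    manifest = {
        "rng_seed": c.spec.rng_seed,
        "n_AC": c.spec.n_AC,
        "n_SqCC": c.spec.n_SqCC,
        "n_normal_lung": c.spec.n_normal_lung,
        "n_bronchial": c.spec.n_bronchial,
        "chromosomes": [
            {"name": ch.name, "length": ch.length, "cn_spacing": ch.cn_spacing}
            for ch in c.spec.genome
        ],
        "n_cn_lesions": len(c.spec.planted_cn_lesions),
        "n_meth_lesions": len(c.spec.planted_meth_probes),
        "n_coupled_genes": len(c.spec.coupled_genes),
    }
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
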