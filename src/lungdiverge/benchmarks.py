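"""End-to-end evaluation of the pipeline on seeded synthetic cohorts.

These routines quantify the properties the pipeline is designed to have:
false-positive control on null cohorts, recovery of planted lesions and
dosage/methylation-coupled genes, subtype discrimination of the derived
signature, and subtype-restricted survival detection.  They are used both
by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import differential, integration, methylation, signature, simulate
from .datamodel import BetaMatrix, ClinicalTable
from .stats import roc_auc

#: headline counts reported for the original 261-tumor NSCLC cohort; used
#: only for arithmetic consistency checks of the printed percentages
REPORTED_COUNTS = {
    "regions_sqcc_specific": 205,
    "regions_ac_specific": 89,
    "cis_overlapping_sqcc_alterations": 186,
    "cis_assessable_sqcc_alterations": 204,
    "sqcc_genes_in_regions": 4669,
    "sqcc_genes_expressed_concordant": 797,
    "ac_genes_in_regions": 2050,
    "ac_genes_expressed_concordant": 171,
}


def _beta_subset(cohort: simulate.SyntheticCohort, group: str) -> BetaMatrix:
    b = methylation.filter_by_detection(cohort.methylation)
    cols = [s for s in cohort.clinical.samples_of(group) if s in b.beta.columns]
    det = b.detection_p[cols] if b.detection_p is not None else None
    return BetaMatrix(b.annotation, b.beta[cols], det)


def methylation_probes_for(cohort: simulate.SyntheticCohort, shared_reference=False):
    """Run the differential methylation stage of the pipeline."""
    profiles = {}
    for subtype, ref in methylation.DEFAULT_REFERENCE_MAP.items():
        if shared_reference:
            ref = "normal_lung"
        profiles[subtype] = methylation.differential_beta(
            _beta_subset(cohort, subtype), _beta_subset(cohort, ref)
        )
    return methylation.test_probe_methylation_disparity(
        profiles["AC"], profiles["SqCC"]
    )


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_region_spec(seed: int) -> simulate.CohortSpec:
    """Both subtypes drawn from one passenger-only alteration process."""
    genome = [
        simulate.ChromosomeSpec(f"chr{i + 1}", 50_000_000, 250_000, 400_000, 500_000)
        for i in range(2)
    ]
    return simulate.CohortSpec(
        n_AC=25, n_SqCC=25, n_normal_lung=8, n_bronchial=8,
        genome=genome, passenger_rate=2.0, missing_rate=0.02, rng_seed=seed,
    )


def null_methylation_spec(seed: int) -> simulate.CohortSpec:
    """Noisy beta-values from one shared process; both subtypes are called
    against the SAME reference pool so their calls are exchangeable."""
    genome = [simulate.ChromosomeSpec("chr1", 30_000_000, 250_000, 100_000, 500_000)]
    flat = {g: (0.30, 0.60) for g in ("AC", "SqCC", "normal_lung", "bronchial")}
    return simulate.CohortSpec(
        n_AC=25, n_SqCC=25, n_normal_lung=8, n_bronchial=8,
        genome=genome, passenger_rate=0.0, beta_concentration=12.0,
        beta_baselines=flat, rng_seed=seed,
    )


def region_null_calibration(n_seeds: int = 50, base_seed: int = 0) -> dict:
    flagged = tested = 0
    for i in range(n_seeds):
        cohort = simulate.generate_cohort(null_region_spec(base_seed + i))
        result = differential.call_subtype_specific_regions(cohort.cn, cohort.clinical)
        flagged += result.stage_counts.significant
        tested += result.stage_counts.tested
    return {"flagged": flagged, "tested": tested,
            "rate": flagged / tested if tested else 0.0}


def methylation_null_calibration(n_seeds: int = 50, base_seed: int = 0) -> dict:
    fractions = []
    for i in range(n_seeds):
        cohort = simulate.generate_cohort(null_methylation_spec(base_seed + i))
        probes = methylation_probes_for(cohort, shared_reference=True)
        fractions.append(float(np.mean([p.significant for p in probes])))
    return {"mean_fraction": float(np.mean(fractions)),
            "max_fraction": float(np.max(fractions))}


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

def region_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Sensitivity of the region caller for the planted lesions of the
    default cohort, requiring the correct direction and subtype."""
    hits = located = total = 0
    for i in range(n_seeds):
        cohort = simulate.generate_cohort(
            simulate.default_paper_like_spec(base_seed + i)
        )
        regions = differential.call_subtype_specific_regions(
            cohort.cn, cohort.clinical
        ).regions
        for lesion in cohort.truth.cn_lesions:
            total += 1
            overlapping = [
                r for r in regions
                if r.chromosome == lesion.chromosome
                and r.start <= lesion.end and r.end >= lesion.start
            ]
            if overlapping:
                located += 1
            if any(
                r.direction == lesion.direction
                and r.assigned_subtype in (lesion.subtype, "both_opposite")
                for r in overlapping
            ):
                hits += 1
    return {
        "sensitivity": hits / total,
        "direction_accuracy": hits / located if located else 0.0,
        "n_lesions": total,
    }


def run_integration(cohort: simulate.SyntheticCohort):
    """Copy-number and methylation candidate genes for a cohort."""
    regions = differential.call_subtype_specific_regions(
        cohort.cn, cohort.clinical
    ).regions
    expr_t = cohort.expression_for(("AC", "SqCC"))
    expr_n = cohort.expression_for(("bronchial",))
    cn = integration.copy_number_candidates(
        regions, expr_t, cohort.clinical, expr_n
    )
    probes = methylation_probes_for(cohort)
    meth = integration.integrate_methylation_expression(
        probes, cohort.truth.meth_probe_genes, expr_t, cohort.clinical, expr_n
    )
    return cn, meth


def integration_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Precision/recall of retained genes against the planted coupled
    genes on the strong-effect (lineage-driver) cohort."""
    precisions, recalls = [], []
    for i in range(n_seeds):
        cohort = simulate.generate_cohort(simulate.lineage_driver_spec(base_seed + i))
        cn, meth = run_integration(cohort)
        kept = {c.symbol for c in cn + meth if c.retained}
        truth = set(cohort.truth.coupled["symbol"])
        tp = len(kept & truth)
        precisions.append(tp / len(kept) if kept else 1.0)
        recalls.append(tp / len(truth))
    return {
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
    }


# ---------------------------------------------------------------------------
# signature evaluation
# ---------------------------------------------------------------------------

@dataclass
class SignatureEvaluation:
    auc_training: float
    auc_projected: float
    auc_permuted_mean: float
    n_signature_genes: int


def evaluate_signature(seed: int = 0, n_permutations: int = 50) -> SignatureEvaluation:
    """Derive the signature from one strong-effect cohort, evaluate PC1
    separation on it, project a second independently generated cohort
    through the frozen model, and measure the permutation null."""
    cohort = simulate.generate_cohort(simulate.lineage_driver_spec(seed))
    cn, meth = run_integration(cohort)
    lists = integration.concerted_gene_lists(cn, meth)
    genes = list(lists.union["symbol"]) if len(lists.union) else []
    if len(genes) < 2:  # fall back to the planted truth, should not happen
        genes = list(cohort.truth.coupled["symbol"])
    expr = cohort.expression_for(("AC", "SqCC"))
    labels = (cohort.clinical.table.loc[expr.samples, "subtype"] == "SqCC").astype(int)
    model = signature.fit_pca_signature(expr, labels, genes)
    training = signature.evaluate_separation(model.training_scores["PC1"], labels)

    held_out = simulate.generate_cohort(
        simulate.lineage_driver_spec(seed + 104_729)  # independent draw
    )
    expr2 = held_out.expression_for(("AC", "SqCC"))
    labels2 = (
        held_out.clinical.table.loc[expr2.samples, "subtype"] == "SqCC"
    ).astype(int)
    scores2 = signature.project_samples(model, expr2, center_mode="test")
    projected = signature.evaluate_separation(scores2["PC1"], labels2)

    rng = np.random.default_rng(seed)
    perm_aucs = [
        roc_auc(
            model.training_scores["PC1"].to_numpy(),
            rng.permutation(labels.to_numpy()),
        )
        for _ in range(n_permutations)
    ]
    return SignatureEvaluation(
        auc_training=training.auc,
        auc_projected=projected.auc,
        auc_permuted_mean=float(np.mean(perm_aucs)),
        n_signature_genes=len(genes),
    )


def survival_asymmetry(n_seeds: int = 20, base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Detection rates of the planted SqCC-restricted hazard gene in its
    own subtype context versus the other subtype."""
    target = offtarget = 0
    for i in range(n_seeds):
        cohort = simulate.generate_cohort(
            simulate.default_paper_like_spec(base_seed + i)
        )
        hazard_genes = [
            g for st in ("AC", "SqCC")
            for g in cohort.spec.survival.gene_log_hr.get(st, {})
        ]
        expr = cohort.expression_for(("AC", "SqCC"))
        results = signature.survival_screen(
            expr, cohort.clinical, hazard_genes, contexts=("AC", "SqCC")
        )
        by_context = {r.context: r for r in results}
        if by_context["SqCC"].p < alpha:
            target += 1
        if by_context["AC"].p < alpha:
            offtarget += 1
    return {
        "target_detection_rate": target / n_seeds,
        "offtarget_detection_rate": offtarget / n_seeds,
    }


# ---------------------------------------------------------------------------
# reported-count arithmetic
# ---------------------------------------------------------------------------

def reported_arithmetic() -> dict:
    """Percentages implied by the reported cohort and results counts."""
    from .datamodel import clinical_summary, load_reference_cohort_composition

    comp = clinical_summary(load_reference_cohort_composition())

    def pct(group, variable, level):
        row = comp.query(
            "group == @group and variable == @variable and level == @level"
        )
        return float(row["percent"].iloc[0])

    c = REPORTED_COUNTS
    return {
        "ac_stage1_percent": pct("AC", "stage", "I"),
        "sqcc_male_percent": pct("SqCC", "sex", "Male"),
        "ac_never_smoker_percent": pct("AC", "smoking", "Non-smoker"),
        "total_differential_regions": (
            c["regions_sqcc_specific"] + c["regions_ac_specific"]
        ),
        "cis_overlap_percent": round(
            100.0 * c["cis_overlapping_sqcc_alterations"]
            / c["cis_assessable_sqcc_alterations"], 1
        ),
        "sqcc_concordant_gene_percent": round(
            100.0 * c["sqcc_genes_expressed_concordant"] / c["sqcc_genes_in_regions"], 1
        ),
        "ac_concordant_gene_percent": round(
            100.0 * c["ac_genes_expressed_concordant"] / c["ac_genes_in_regions"], 1
        ),
    }
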