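"""Evaluate the derived gene signature: PCA separation and survival.

The signature (union of retained candidate genes) is fitted by PCA on the
discovery cohort; PC1 scores are scored by ROC AUC against the subtype
labels, then an independently generated cohort is projected through the
frozen loadings.  Finally each planted hazard gene is screened by
comparing survival between its top and bottom expression tertiles with a
two-sided log-rank test, separately per subtype.
"""

from lungdiverge import signature, simulate
from lungdiverge.benchmarks import evaluate_signature

ev = evaluate_signature(seed=1)
print(f"signature of {ev.n_signature_genes} genes derived from the discovery cohort")
print(f"PC1 AUC, discovery cohort : {ev.auc_training:.4f}")
print(f"PC1 AUC, projected cohort : {ev.auc_projected:.4f}")
print(f"PC1 AUC, labels permuted  : {ev.auc_permuted_mean:.3f}")
# AUC near 1 means PC1 orders samples almost perfectly by subtype; the
# permuted value near 0.5 shows the separation is label-driven, not an
# artifact of the projection.

cohort = simulate.generate_cohort(simulate.default_paper_like_spec(rng_seed=1))
hazard_genes = [
    g for st in ("AC", "SqCC") for g in cohort.spec.survival.gene_log_hr.get(st, {})
]
expr = cohort.expression_for(("AC", "SqCC"))
print(f"\ntertile survival screen for planted hazard gene {hazard_genes}:")
for r in signature.survival_screen(expr, cohort.clinical, hazard_genes,
                                   contexts=("AC", "SqCC", "NSCLC")):
    print(
        f"  context {r.context:5s} p = {r.p:.4f}  ({r.direction},"
        f" n = {r.n_low}+{r.n_high})"
    )
# The gene's hazard effect was planted in SqCC only: it should reach
# p < 0.05 in the SqCC context and stay null in AC, the asymmetric
# pattern the screen is built to expose.
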