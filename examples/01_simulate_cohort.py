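"""Generate the default synthetic two-subtype cohort and look inside it.

The cohort pairs copy-number states, methylation beta-values, log2
expression and clinical/survival data for 30 AC and 30 SqCC tumors plus
two normal reference compartments, with planted subtype-specific lesions
recorded as ground truth.
"""

from lungdiverge import simulate

spec = simulate.default_paper_like_spec(rng_seed=1)
cohort = simulate.generate_cohort(spec)

print(f"copy-number probes : {len(cohort.cn.states)}")
print(f"methylation probes : {len(cohort.methylation.beta)}")
print(f"genes              : {len(cohort.expression.values)}")
print(f"samples            : {cohort.clinical.table['subtype'].value_counts().to_dict()}")

print("\nplanted copy-number lesions (ground truth):")
for lesion, carriers in zip(cohort.truth.cn_lesions, cohort.truth.cn_carriers):
    size_mb = (lesion.end - lesion.start + 1) / 1e6
    print(
        f"  {lesion.chromosome}:{lesion.start}-{lesion.end} "
        f"({size_mb:.2f} Mb) {lesion.direction} in {lesion.subtype}, "
        f"penetrance {lesion.penetrance:.2f}, {len(carriers)} carriers"
    )
# Each lesion is applied per target-subtype sample with the stated
# penetrance; the carrier count therefore fluctuates binomially around
# penetrance x 30.

simulate.write_cohort(cohort, "scratch/example_cohort")
print("\ncohort written to scratch/example_cohort/ (TSV + BED + manifest)")
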