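"""Call subtype-specific copy-number regions on the synthetic cohort.

Probe states are imputed (10 Mb nearest-neighbour), aggregated into
regions (90% within-subtype similarity), tested with the exact 3x2 Fisher
test, BH-corrected over regions (q <= 0.01), merged across <= 1 Mb gaps,
and filtered to regions altered in >20% of the assigned subtype with a
>10% frequency difference.
"""

from lungdiverge import differential, simulate
from lungdiverge.cna import instability_summary

cohort = simulate.generate_cohort(simulate.default_paper_like_spec(rng_seed=1))

inst = instability_summary(cohort.cn, cohort.clinical)
print("per-state instability comparison (two-sided Mann-Whitney p):")
for state, p in inst.comparisons.items():
    print(f"  {state:8s} AC vs SqCC p = {p:.3g}")
# Small p here means one subtype carries globally more of that state; with
# planted lesions the gain fraction differs, unlike a null cohort.

result = differential.call_subtype_specific_regions(cohort.cn, cohort.clinical)
sc = result.stage_counts
print(
    f"\nregions: {sc.tested} tested, {sc.significant} significant, "
    f"{sc.filtered} reported after merging and frequency filters"
)
for r in result.regions:
    print(
        f"  {r.chromosome}:{r.start}-{r.end}  {r.direction} in "
        f"{r.assigned_subtype}  freq {r.freq_assigned:.2f} vs {r.freq_other:.2f}"
        f"  q = {r.q:.2g}"
    )
# Every reported region should match a planted lesion in location,
# direction and subtype; the frequencies echo the planted penetrance.
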