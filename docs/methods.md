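# Methods

This note records the models, thresholds and design choices behind
`lungdiverge`, and what the synthetic evaluation does and does not show.

## Statistical primitives

**Exact 3×2 Fisher test.** For a table with rows (gain, neutral, loss) —
or (hyper, unchanged, hypo) — and columns (AC, SqCC), the null is the
multivariate hypergeometric distribution over all tables with the
observed margins. A table with fixed margins is determined by its first
column (a₁, a₂, a₃), so enumeration is a double loop; probabilities are
computed in log space from `gammaln`. The two-sided p-value sums the
probabilities of all tables at most as probable as the observed one,
with a relative tolerance of 1e−12 on the comparison — the convention
used by standard exact-test implementations. Results are memoized on the
count tuple, which makes per-probe testing over thousands of probes
cheap because null cohorts produce many repeated tables. The test suite
checks every table with total ≤ 8 against an exact-rational oracle.

**Benjamini–Hochberg.** Step-up adjustment returning monotone adjusted
values in input order. The `family_size` parameter makes corrections
over a declared family explicit — the pipeline corrects region tests
over the number of distinct regions and per-region expression tests over
the probes mapped to that region, which can exceed the length of the
p-value list actually passed in.

**Mann–Whitney U.** Exact enumeration of the U distribution (the classic
count recurrence) when the pooled sample is tie-free and has at most
`MW_EXACT_MAX_N = 30` observations; otherwise the normal approximation
with tie-corrected variance and a 0.5 continuity correction. The cutoff
is deliberately generous: the recurrence is cheap there, and the exact
branch then covers the per-region expression tests at the default cohort
size (10–30 samples per group) whenever the data are tie-free. Fully
tied data return p = 1 (no evidence either way) rather than an error, so
that degenerate comparisons of identical groups behave sensibly.

**Welch t, log-rank, ROC AUC.** Standard forms: Satterthwaite degrees of
freedom; (O−E)²/V with hypergeometric variance summed over distinct
event times and simultaneous risk-set handling of ties; the
Mann–Whitney AUC estimator P(s⁺ > s⁻) + ½P(tie). Each is cross-checked
in the tests against scipy, lifelines and scikit-learn respectively —
those libraries serve as oracles only, never as the implementation.

## Copy-number region calling

Internal coordinates are 1-based inclusive (array annotation
convention); BED/bedGraph output is 0-based half-open, converted in one
place. Missing states (NaN) are distinct from neutral (0) end to end.

*Imputation* fills a missing cell from the nearest non-missing probe on
the same chromosome within 10 Mb (midpoint distance), per sample;
equidistant neighbours with conflicting states leave the cell missing —
imputation must not invent signal.

*Aggregation* merges adjacent probes when, within **each** tumor subtype
independently, the fraction of samples (non-missing at both probes) with
identical state is ≥ 0.90. The criterion could alternatively pool all
samples; requiring both subtypes is the conservative reading and yields
the single shared region set the downstream between-group test needs. A
region's per-sample state is the modal state of its member probes, ties
resolved to neutral (robust and direction-neutral); per-subtype counts
run over samples with a non-missing region state, and frequencies use
the non-missing denominator.

*Testing and filtering* follow the order: Fisher per region → BH over
distinct regions, significant at q ≤ 0.01 (inclusive, as printed) →
merge runs of regions ≤ 1 Mb apart that share direction and significance
flag (merged p/q = member minimum, kept for reporting only — significance
was decided pre-merge) → frequency filters with strict inequalities
(> 20% in the assigned subtype, > 10% same-direction difference). A
region direction is the state (gain or loss) with the largest absolute
between-subtype frequency difference. A region whose two subtypes each
clear the filters in opposite directions is emitted once per subtype and
labelled `both_opposite` — the pattern where a locus is gained in one
subtype and lost in the other.

## Methylation

Detection-p masking is inclusive at 0.05. Δβ is computed against the
*mean* of the matched reference compartment — lung parenchyma for AC
tumors, bronchial epithelium for SqCC — with the mapping held in
explicit configuration, not inferred. Calls use the inclusive |Δβ| ≥
0.15 threshold. The per-probe between-subtype comparison uses a single
3-category (hyper/unchanged/hypo) exact test rather than two 2×2 tests,
mirroring the copy-number design; BH runs over the tested probes (probes
missing in > 50% of either subtype are excluded and logged), significant
at q < 0.05 (strict).

A consequence of the per-subtype reference design, visible in the null
simulations: because each subtype's calls depend on its own noisy
reference mean, the two subtypes' call processes are *not* exchangeable
even when tumor β-values are drawn from one distribution, and the
disparity test then legitimately detects reference-driven call-rate
differences. The null-calibration check therefore calls both subtypes
against the same reference pool, which makes the calls exchangeable and
isolates the Fisher+BH false-positive behaviour being verified.

## Expression integration

Genes map to regions by any interval overlap. The subtype comparison is
one-tailed with the tail fixed by the lesion (gain → assigned subtype
higher; loss → lower), BH-corrected within the region's probe family,
collapsed to genes by minimum p, significant at q ≤ 0.001. Validation
against normal tissue uses a one-tailed Welch t (p < 0.001) plus a
direction-only fold-change gate evaluated on the linear scale after
un-logging means (no magnitude cut — none is defensible without a
calibrated platform). Methylation-linked genes use expected direction
opposite to the methylation change and a single BH family of all
methylation-linked genes tested, at 0.05. Cross-platform gene matching
is by symbol, case-insensitive. One normal pool (bronchial expression)
serves both subtypes' vs-normal tests, configurable by passing any other
`ExpressionMatrix`.

Union/concerted/diametric accounting: concerted genes appear in both
mechanism lists for the same subtype and direction; diametric genes are
claimed by both subtypes in opposite directions through different
mechanisms; the union deduplicates by symbol with per-gene provenance.

## Signature evaluation

PCA standardizes genes (z-score) with training statistics by default;
components come from the SVD of the standardized matrix, loadings are
unit-norm with the largest-magnitude loading forced positive (a
deterministic sign convention, since PC polarity is arbitrary).
Projection offers two centering modes: `training` (frozen statistics;
projecting the training set reproduces training scores exactly) and
`test` (per-gene standardization with the test set's own statistics,
which absorbs per-gene platform offsets and is the meaningful choice for
cross-platform cohorts). Missing model genes are dropped with the
remaining loading sub-vector renormalized; below 50% shared genes the
projection refuses. AUC is reported orientation-free as max(AUC, 1−AUC)
with the chosen polarity recorded.

The survival screen sorts each gene's expression with a stable sort
(ties at tertile boundaries resolve by input order, logged behaviour),
takes the bottom and top ⌊n/3⌋ samples, and runs the two-sided log-rank
test per context (AC, SqCC, pooled NSCLC). The reported direction is the
tertile with more observed than expected events.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
from a single seeded `numpy` generator (no ambient RNG state):

- **Copy number**: states start neutral; random passenger segments
  (Poisson rate 1/sample, log-uniform lengths 0.2–20 Mb) are applied
  first, then planted lesions with Bernoulli(penetrance) in the target
  subtype, so carriers always show the lesion in the emitted states.
  Ground-truth carriers are recomputed *from the emitted states* (every
  non-missing lesion probe showing the lesion direction), which keeps
  recorded truth and data consistent by construction even with 2%
  missingness. An optional log2 matrix shifts by ±0.55 per state with
  0.15 SD noise.
- **Methylation**: β ~ Beta(μκ, (1−μ)κ) with κ = 150 around
  per-compartment baselines — islands ≈ 0.11–0.12 everywhere, off-island
  0.75 for the peripheral compartment (AC / lung parenchyma) and 0.65
  for the central one (SqCC / bronchial), reproducing the global
  island/non-island contrast in which central-airway samples are
  hypomethylated off-island. Planted shifts of ±0.30 at 70% penetrance
  are placed on island probes for hypermethylation and off-island probes
  for hypomethylation (the canonical cancer pattern, and the only
  placement where a 0.30 shift fits inside [0, 1]).
- **Expression**: gene baseline ~ N(8, 1) log2 units, noise SD 0.5,
  additive coupling of ±(effect × noise SD) in carriers — dosage sign
  for copy-number lesions, opposite sign to Δβ for methylation.
- **Survival**: exponential with hazard 0.02/month ×
  exp(Σ log-HR × z-expression), independent uniform censoring over 120
  months.
- **Clinical covariates** (stage, sex, smoking) are sampled with margins
  loosely matching a real NSCLC cohort (AC skews female/never-smoker).

Two first-class configurations exist. `default_paper_like_spec()` is the
landscape-scale cohort: 5 chromosomes (~2,000 CN probes, ~3,000
methylation probes, ~1,500 genes), 30 tumors per subtype, five lesions
spanning 65 Mb down to 50 kb at penetrance 0.55–0.65, coupled genes at
1.5 noise-SD effect. `lineage_driver_spec()` is the focused strong-effect
cohort used for end-to-end gene recovery and signature evaluation: 5–6 Mb
lesions at 90% penetrance, each carrying two dosage-coupled genes at 3
noise-SD effect (~2.8-fold in carriers) among ~17 bystanders — the
near-clonal, strongly selected lineage-driver archetype (the 3q/SOX2
pattern in SqCC). The distinction is deliberate: under the pipeline's
stringent direction-matched thresholds (per-region q ≤ 0.001), weakly
penetrant, weakly coupled genes are *correctly* not recovered — the
published procedure itself retained only 8–17% of genes in regions — so
gene-level recovery is measured where the planted signal is strong
enough to be detectable in principle, while region-level recovery and
false-positive calibration use the landscape cohort and null cohorts
respectively.

The generator does **not** model dye bias, batch effects, probe-level
spatial correlation of methylation, or tumor purity. Passing tests
therefore demonstrate the pipeline's logic and calibration under its own
assumptions, not performance on raw array data; the upstream steps the
pipeline expects (normalization, segmentation) are out of its scope, and
`threshold_call_states` is only a plumbing-level caller for segmented
log2 ratios, with thresholds as configuration since no universal values
exist.

## Problem sizes and determinism

The evaluation suite runs null calibration over 50 seeded cohorts per
data type, recovery over 20 seeds, and a 50-permutation AUC null —
scales chosen so the full check completes in well under a minute on one
CPU while keeping binomial error on the measured rates small. All
randomness flows from explicit seeds; the reproduction script derives
every seed from its `--seed` argument.

## Known limitations

- The aggregation similarity criterion compares adjacent probes
  per-subtype; whether the original procedure pooled samples instead is
  not documented, and the pooled variant would merge slightly more.
- Merged-region p-values are the member minimum and are reporting-only;
  re-testing merged regions would be circular after selection.
- The survival screen is univariate (no stage/sex adjustment) by design.
- Percentage checks against the published cohort table allow ±0.15
  because that table itself rounds inconsistently (truncation in some
  rows, rounding in others).
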