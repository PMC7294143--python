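# Methods

This note records the models, conventions and numerical choices behind the
pipeline, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Comparative-Ct model and sign convention

A qPCR cycle-threshold value is inversely log-proportional to template
amount: one cycle less means twice the input. We define relative expression
within a sample as 2^−(Ct_target − Ct_reference) and the case/control fold
change as 2^−ΔΔCt with ΔΔCt = ΔCt_case − ΔCt_control. Write-ups of panel
experiments sometimes print the exponent with the opposite ordering of the
internal-control and sample terms; read literally that would invert the
universal convention and make "up-regulated" fold changes smaller than 1.
We implement the standard convention — it is the only reading under which
up-regulated consensus averages above 1 are coherent — and state it
explicitly wherever a fold change is produced.

## Censoring

"Undetermined" reactions are modelled as left-censoring of expression:
a cell is censored when its Ct exceeds `ct_max` (default 40, *strict*
inequality; a Ct of exactly 40 is kept). Values above the threshold are
retained in the matrix alongside the flag, so censoring is reversible and
monotone in the threshold. In the paired screen an assay is excluded from a
pair only when both members are censored; a singly-censored target is
imputed at `impute_ct` (default 40, i.e. at the detection limit) and the
resulting record is flagged, because screens that retain such assays
necessarily impute something. Imputed fold changes are conservative: they
bound expression at the detection limit.

## Inter-plate calibration and spike-in QC

The calibrator (UniSp3, triplicates averaged arithmetically) is aligned by
an additive shift per plate to the global mean — the standard panel
convention; the named calibrator does not itself determine the arithmetic,
and an additive shift on the Ct scale is a multiplicative correction on
expression, preserves within-plate contrasts exactly, and leaves censoring
flags untouched. Spike-in QC is advisory: a sample is flagged when any
spike-in deviates from the cohort median of that assay by more than
`max_dev` (default 2.0 cycles — a conservative, commonly used panel
screening bound); no sample is excluded automatically because exclusion is
a study-level decision.

## Reference selection

Candidates are summarized by detectability and CV% = 100·SD/mean on the Ct
scale with the sample (n−1) SD — with that convention the printed
mean/SD/CV triples of typical cohort reports reproduce exactly, and it is
the estimator for cohort statistics. Eligibility requires full
detectability (a single undetermined reading disqualifies) and mean
Ct ≤ 35 as the abundance bound (Ct 35 is the usual single-copy-regime
limit); both are configurable. Ties on CV break toward the lower mean Ct
(more template, more robust), then lexicographically for determinism. CVs
are computed on calibrated Ct by default; a raw-Ct path exists because the
choice is not observable from printed summaries.

## Direction calls and consensus

Direction thresholds default to 1.5 and 1/1.5: in the consensus tables this
package emulates, the smallest printed up-average is 1.651 and the largest
down-average 0.516, so this pair reproduces the printed partition with
margin while remaining a conventional fold-change cut. Averaging across
pairs is the arithmetic mean of per-pair ratios — the scale on which such
tables print extreme averages (hundreds-fold), which a geometric mean of
modest per-pair shifts cannot reach; a geometric option exists. Calls are
made on cross-pair averages, not per-pair unanimity, matching how screen
tables are reported. The consensus is the strict intersection of the calls
under every reference normalization, so the up and down lists are disjoint
by construction.

## Validation statistics

Exact two-sided p-values for the rank tests are defined as
min(1, 2·min(lower tail, upper tail)) over the permutation distribution of
the midrank sum, computed by an integer subset-sum dynamic program (doubled
midranks), which is exact under ties. Exact mode is the default up to
n₁+n₂ = 25 (Mann–Whitney) or 20 non-zero pairs (Wilcoxon) and refuses
larger inputs rather than silently approximating; the normal mode uses the
tie-corrected approximation without continuity correction. The two
conventions differ by the point mass at the observed statistic: at group
sizes below ~15 that alone can move a mid-range p by a few hundredths, so
closeness checks between the two modes are meaningful only from about 15
observations per group (verified by enumeration).

Chi-square is Pearson's without continuity correction — validated by exact
reproduction of the 3×2 stage-table p = .0449 — and Fisher's exact p sums
hypergeometric probabilities not exceeding the observed table's. The t test
is pooled-variance by default with Welch as an option. No multiple-testing
correction is applied anywhere by default (a Benjamini–Hochberg helper
exists but is off), matching the validation design of a handful of
pre-specified candidates.

## ROC, cut-offs and dichotomization

AUC is computed by the rank identity U/(n₁·n₂) with ties counted ½ — exact
under ties, and equal to trapezoidal integration of the empirical curve (a
test asserts the identity to 1e-9). The optimal cut-off maximizes Youden's
J; ties break toward higher specificity (fewer false positives in a
screening context) and then the higher cut-off. Positivity is *strictly
greater than* the cut-off, so a score at the cut-off is negative. A
closest-to-corner criterion is available. Multi-site metastatic patients
count once in every site row of the site-association table, which is why
its row sums can exceed the patient count.

## Survival

The Kaplan–Meier estimator uses the events-before-censorings tie
convention. The log-rank statistic accumulates observed-minus-expected
events with the hypergeometric variance at each distinct event time and is
referred to χ²(1); a label-permutation p-value is available and agrees with
the χ² reference within Monte-Carlo error in tests. Patients without a
documented progression are censored at their recorded follow-up (the
generator censors at 60 months, a five-year window); deaths without
documented progression are treated as censorings by default since the
alternative is not identifiable from summary-level descriptions.

## Synthetic-data generator

The generator emulates the study *design*, not any patient's data.

Profiling pairs: Ct(a, member) = μ_a + b_{a,pair} + plate + shift + ε with
pair-level biological effects b ~ N(0, σ_pair = 1.3 cycles) shared by both
members of a matched pair — they cancel in ΔΔCt, which is what matched
pairing is for — and technical noise ε ~ N(0, σ_ct = 0.4 cycles), a typical
qPCR repeatability figure. Filler assays fall into abundance classes
(abundant / borderline / absent) whose proportions (177/371 of 752, with
the borderline mean Ct at N(40.15, 1.3)) were derived in closed form so the
expected per-pair detected count is 364 and the expected three-pair
intersection 269 — the scale of the emulated screen; the +0.15 offset
compensates the smoothing of the censor boundary by technical noise, since
a pair is excluded only when both members censor. Planted biomarkers shift
case Ct by −log2FC; the default planted set is the emulated consensus table
(13 up, 6 down, fold changes from 0.006 to 321).

Validation cohort: per-patient biological variation is independent per cell
(σ_bio = 1.0 cycles for targets; for the reference assays it is chosen so
their total across-sample SD matches the configured targets of 1.424 and
1.466 cycles, hence CVs of ≈ 6.1% and 5.2%). The metastasis-group shift for
each designated biomarker is calibrated through the binormal identity
AUC = Φ(δ/(s√2)) with s the per-sample ΔCt SD, so the expected empirical
AUC equals the target (0.70 by default, the regime of the emulated study);
verified to within 0.003 over 400 seeds. Clinical covariates are sampled
near the emulated cohort's margins, with stage mildly associated with group
and everything else independent of the biomarkers — deliberately simple.

Survival: times are exponential with hazard h₀·HR^positive (h₀ = 0.005 per
month, giving ≈ 35% events in 60 months; HR = 3 by default), where *true*
positivity is the realized relative expression of the primary biomarker
split at the cohort median. Tying the hazard to the biomarker rather than
to the group label keeps the null (HR = 1) exactly null for the log-rank
calibration checks; the cost is that the generated `group` and `event`
columns are correlated only through the biomarker, unlike a real cohort
where group *is* the five-year metastasis outcome.

Paired tissue: per-pair log2 tumour/adjacent ratios are sign·|N(1.0, 0.5)|
with the sign down-regulated at the configured fraction (32/43 and 33/43 by
default), so a fraction of 0.5 is an exactly sign-symmetric null on the log
scale.

What passing tests on these data do **not** show: robustness to
amplification-efficiency differences between assays, to hemolysis or other
pre-analytical artefacts, to batch structure beyond additive plate offsets,
or to non-Gaussian biological variation — none of which the generator
models.

## Designed test conditions

Two recovery checks deserve explicit framing.

*Fold-change recovery* is tested at the default noise: a planted ΔΔCt of −3
is recovered by the cross-pair average fold change within 20% (median over
50 seeds). The arithmetic mean of lognormal per-pair ratios is biased
upward by ≈ e^{(σ·ln2)²} − 1 ≈ 17% at ΔΔCt noise SD 0.8 cycles, so the
median across seeds is the right summary; the bias itself is a property of
arithmetic averaging of ratios, documented here rather than hidden.

*Exact consensus recovery* (truth set recovered with no misses and no false
calls in ≥ 95% of seeds) is tested with planted |log2 FC| ≥ 2 and
σ_ct = 0.1 cycles. At the default σ_ct = 0.4 and the emulated table's
weakest average (1.651, only 0.14 log2 units above the 1.5 threshold),
exact set recovery is statistically impossible: the cross-pair average has
log2 SD ≈ 2σ_ct/√3 ≈ 0.46, giving a per-seed miss rate of ~10% on the
weakest assay and on the order of one false consensus call per seed from
the ~730 null assays. The recovery test therefore isolates the screen's
set logic from the noise floor; the default-noise behaviour (planted set
recovered plus a handful of borderline false calls) is what the worked
example shows and is the reason the design includes a validation cohort.

## Problem sizes

Tests and the acceptance script run the panel at its full 752-assay size
(generation and screening take ~0.1 s per seed); seed counts per check are
50 (fold-change recovery), 200 (AUC calibration), 100 (consensus recovery),
500–600 (type-I error of log-rank and exact Mann–Whitney), chosen so
Monte-Carlo error is small against each tolerance.

## Known limitations

- Ct values are taken as given; amplification curves, melting curves and
  RDML are out of scope, as is any automatic sample exclusion on QC.
- The screen is purely fold-change based at n = 3 pairs — no moderated or
  shrinkage statistics; that is the design being emulated, not a
  recommendation.
- Optimal cut-offs are selected in-sample with no cross-validation and AUCs
  carry no confidence intervals, again matching the emulated design.
- The generator draws survival and expression from parametric families
  (exponential, Gaussian on the Ct scale); real cohorts are messier.
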