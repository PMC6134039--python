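# Methods

## The analysis

`metaboflow` implements the statistical pipeline of a dietary-probiotic
feeding trial in fish, where CE-TOFMS (capillary electrophoresis
time-of-flight mass spectrometry) metabolite panels are compared between a
control-fed and a probiotic-fed group across three compartments: the feed
pellet, the intestinal mucus and the serum. The pipeline answers three
questions: which metabolites change with the probiotic diet, where those
metabolites come from (feed vs. host/microbiota), and whether they reach the
systemic circulation unchanged.

### Normalization

CE-TOFMS relative peak areas are comparable across samples only after
division by the spiked internal standard of the ionization mode
(methionine sulfone in cation mode, D-camphor-10-sulfonic acid in anion
mode). Normalization is area ÷ same-sample standard area, with no
sample-weight correction: only the internal standards are part of the table
contract, and a weight correction, if ever needed, is a separate
preprocessing step on the raw tables. Non-detect (ND) cells are a
first-class state, never zero: a zero would manufacture infinite ratios.
Normalization is idempotent (the returned table carries unit standards) and
scale-equivariant (rescaling one sample's areas and standard together is a
no-op), both property-tested.

### Differential classification

Per metabolite, the Pro/Con ratio is mean(probiotic) / mean(control) over
detected replicates, and significance is a two-sided Welch unequal-variance
t-test. With fewer than two detected replicates in either group the p-value
is *absent*, not 1. Zero variance in both groups (reachable with cv = 0
fixtures) takes the limit convention p = 1 for equal means, 0 otherwise,
with an explicit numerical tolerance because normalization round-off leaves
variances near but not exactly zero.

The fold-change thresholds are data-derived the way the study derived them:
the upper threshold is the maximum finite ratio among provisionally
significant (p < 0.05) increased metabolites floored to 2 decimals, the
lower is the minimum among significantly decreased metabolites floored to 1
decimal (so extremes 1.202 / 0.830 give 1.20 / 0.8), with fallback to those
defaults when a side is empty. A useful consequence of the floor: no
metabolite in the derivation set can sit strictly below the derived lower
bound, so the strict DOWN clause cannot fire on noise in the very panel
that produced the threshold.

The composite call is then:

* UP — (p < 0.05 and ratio ≥ upper) or (ratio ≥ 1.5 and p < 0.1) or
  detected only in the probiotic group;
* DOWN — the exact mirror (p < 0.05 and ratio < lower, or ratio ≤ 1/1.5
  with p < 0.1, or control-only detection);
* SAME otherwise; UNDETECTED when every cell is ND.

Note the `Thresholds` container does not require upper ≤ 1.5: on strongly
separated data the derived upper exceeds the loose 1.5-fold bound and the
loose clause simply dominates over the intermediate range. The call is
monotone in the ratio at fixed p (property-tested). No multiple-testing
correction is applied by default, matching the raw-p reporting convention
of this kind of study; a Benjamini–Hochberg flag exists.

The whole-metabolome distribution-shift test is Wilcoxon–Mann–Whitney on
per-metabolite group means (one value per metabolite per group), exact by
enumeration for combined n ≤ 12 without ties and tie-corrected normal
approximation otherwise, with a one-sided `con_less` variant for the
right-skew direction.

### Compartment flow

Membership of a compartment is ≥ 1 non-ND cell in either group there;
identity across compartments is the case-insensitive, whitespace-normalized
display name (base name plus branch number — peaks sharing a candidate name
get branches 1..k in input order). Intestinal metabolites then partition
into groups a–e jointly with pellet membership (a: UP absent from feed;
b: UP present in feed; c/d: the SAME analogues; e: feed-only compounds);
intestinal DOWN metabolites fall outside the a–e scheme and are reported in
a separate `down` bucket rather than merged. Shared intestine/serum
metabolites split into transport categories by ratio concordance:
category i when max(r_int, r_ser)/min(r_int, r_ser) ≤ 1.3, category ii
otherwise or when either ratio is non-finite; intestine-only metabolites
are category iii; serum-only metabolites are flagged separately. The 1.3
default is a reconstruction — no quantitative criterion is published for
"similar ratios" — chosen because it cleanly separates the worked example
pairs (citrulline 1.64/2.04 → i at discrepancy 1.24; carnitine 1.48/0.98 →
ii at 1.51); it is a config knob, reported alongside every output, and the
max/min form makes the assignment symmetric in the two compartments.

### Multivariate views

Sample-level PCA and hierarchical clustering mirror the usual QC views.
Rows (metabolites) are autoscaled; zero-variance rows are dropped; ND is
replaced by half the metabolite's minimum observed value (autoscaling
cannot carry NaN; half-minimum is the standard left-censor stand-in) or
rows can be dropped. Defaults are Euclidean distance with Ward linkage —
the most common metabolomics choices; distance (Euclidean/correlation) and
linkage (Ward/average/complete) are flags and every artifact records the
settings used. Dendrograms export as rooted Newick with branch lengths
equal to merge-height differences, so leaf-to-root distance equals the root
merge height.

### Growth metrics

SGR = 100·(ln w_final − ln w_initial)/days (the standard aquaculture
definition; the trial spans 16 weeks = 112 days), additive over subperiods
by construction. FE = wet-weight gain ÷ dry feed given (uneaten feed is
unquantified). The ration schedule feeds 3 % of group biomass per day,
re-based at each biweekly weighing. SGR is computed only from supplied
series; the pipeline does not attempt to reconcile a printed group SGR with
printed endpoint weights when the two disagree (for these endpoint weights
the log formula gives ≈ 0.62 %/day for the probiotic group and ≈ 0.54 for
the control).

## The synthetic study generator

The trial's raw tables were never deposited, so the generator *is* the
study conditions: every layer size is the printed one (pellet 148 cation +
92 anion compounds; intestine 200 metabolites, 110 cation; serum 171, 103
cation; 122 shared intestine/serum, 78 intestine-only, 49 serum-only), and
the planted classes are the printed counts (53 intestinal UP split 9
pellet-absent + 44 pellet-present, 0 intestinal DOWN, 5 serum UP, 6 serum
DOWN, 45 concordant + 77 discordant shared metabolites). Two dietary groups
× 3 pooled replicates per compartment; the pooling of nine fish per
replicate appears only as the small replicate cv (0.05) of the pools.

Abundances are lognormal (positive, right-skewed, the usual shape of MS
peak areas; no distribution is published): each metabolite draws a baseline
exp(N(3, 1)), and each replicate multiplies the group mean by exp(N(0,
cv)). Planted UP species multiply the probiotic mean by up_fold = 2.0 in
the target compartment, DOWN by 0.5. Raw tables are written with per-sample
lognormal internal standards (exp(N(6.9, 0.05)) ≈ 1000) multiplied in, so
the normalization stage does real work on generator output.

Two structural choices are not pinned by the printed counts and are fixed
here as generator defaults: (1) how the 53 intestinal-UP metabolites
overlap serum — 5 are the serum-UP set (concordant, category i), 6 are the
serum-DOWN set (fold 0.5 in serum, strongly discordant — the pattern of the
glucuronic-acid-type rows with intestinal increase and serum decrease), 35
more are shared with unchanged serum (discordant), 7 are intestine-only;
(2) how many unchanged intestinal metabolites occur in the feed (group d)
— 100, leaving 47 in group c and 96 feed-only compounds. Both are config
fields (`up_shared_discordant`, `same_pellet_present`).

Realizing the 77 discordant shared metabolites requires 36
discordant-but-unchanged pairs. Their folds (1.28 intestinal / 0.80 serum,
a planted fold ratio of 1.6) were chosen from the noise model: the sampled
log-ratio noise has sd ≈ cv·√(2/3) ≈ 0.041 per compartment, so each side
sits ≥ 3.6 sd from the nearest classification boundary (1.5 loose-UP,
0.667 loose-DOWN) and the pair sits 3.6 sd above the 1.3 concordance
boundary. That leaves a ~1 % per-seed chance that one metabolite somewhere
crosses a boundary; across seeds 1–100 exactly one seed (23) misassigns a
single transport category. The generator therefore exposes
`verify_separability=True`, which re-runs the differential and flow stages
on the generated bundle and raises loudly on any mismatch instead of
silently resampling — determinism stays auditable, and an unlucky seed is
an error, not a quietly different dataset.

ND censoring (`nd_rate`) is per-cell and off by default: in the emulated
study, every member of a compartment panel is detected within that panel,
and ND arises structurally across compartments (a metabolite absent from
serum simply has no serum row), which is how the published tables show it.

What the generator does *not* emulate: instrument drift, migration-time
variation, batch effects, correlated metabolite blocks, missing-not-at-
random censoring, or individual fish (only pooled replicates). Passing the
planted-truth tests therefore demonstrates that the statistical machinery
is correct under the declared noise model at the declared effect sizes —
not that real CE-TOFMS data of arbitrary quality would be classified with
zero error.

The synthetic growth series draws 48 fish per group on a biweekly 0–112 d
grid, per-fish exponential growth with rates normal around the group rate
implied by the target endpoint means (165 → 329.98 g probiotic, → 301.06 g
control), initial weights lognormal around 165 g (cv 6 %), per-fish SGR sd
0.15 %/day.

## Problem sizes and numerics

The full fixture (640 metabolite rows across 6 tables, 36 samples) runs the
entire pipeline in a few seconds on one CPU; the null-calibration panels
use 2000–3000 null metabolites. Floor rounding in threshold derivation adds
1e-9 before flooring to avoid binary-representation misfloors (1.20 × 100 =
119.999…). Welch's zero-variance convention triggers when both group
variances fall below (1e-9 × mean)². PCA requires k ≤ min(rows, samples−1)
and reports scores up to per-component sign.

## Known limitations

* Category i/ii counts are reproducible only on the synthetic fixture; the
  published 45/77 split cannot be derived from the published tables alone.
* The exact-enumeration rank-sum branch deactivates in the presence of ties
  (the tie-corrected normal approximation is used instead), even at small n.
* The generator's feasibility checks reject impossible cation/anion layer
  allocations rather than searching for an alternative assignment; unusual
  configs may need manual mode counts.
* Growth FE from the 3 %-biomass schedule is ~0.2 for these endpoint
  weights; reconciling it with an externally printed FE would require the
  actual feed consumption records, which the pipeline does not model.
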