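# Methods

## The dip statistic

For a sample with sorted values and empirical CDF `F_n`, the dip is

    D(F_n) = min over unimodal G of sup_x |F_n(x) − G(x)|,

where a unimodal CDF is convex up to a mode and concave after it; convexity
permits an upward jump exactly at the mode, so point masses at the mode are
free. Large dips mean no single-peaked distribution explains the data.

The implementation works in units of 1/n with the step corners of `F_n`
(lower corner `i`, upper corner `i+1` at the i-th order statistic). Over a
candidate modal interval it fits the greatest convex minorant of the lower
corners and the least concave majorant of the upper corners; the largest
vertical distance between the two piecewise-linear fits (attained at a hull
vertex, since their difference is concave) measures the convex/concave
tension remaining inside the interval. If that tension exceeds the
deviation already conceded to the tails, the interval shrinks to where the
maximum occurs and the newly abandoned regions contribute their CDF-to-fit
deviations to the tail total; otherwise the iteration stops. The dip is
half the final deviation, floored at 1/(2n) — the value any sample a
unimodal CDF can match exactly (all-tied samples, n = 1) receives, flagged
`degenerate`. Ties are handled exactly through the corner bookkeeping; no
jitter is added.

Correctness is established two ways in the test suite: an independent
linear-programming oracle (`tests/oracles.py`) that minimises the band
half-width per candidate mode placement, exact for small samples and
agreeing with the implementation to ~1e-14 across random continuous and
tied samples; and closed-form cases (dip of {0,1} is exactly 1/4, dip of
two atoms with weights 0.3/0.7 is exactly 0.15). The kernel is
numba-compiled (pure-Python fallback) so a 10⁶-draw null is feasible.

## Empirical p-values

Significance is Monte-Carlo: `n_sims` standard-normal samples of the same
size are reduced to dips, and the p-value is the proportion *strictly*
greater than the observed dip. Because the dip is invariant under strictly
increasing affine transforms, the normal's parameters are irrelevant and
the standard normal is used. A zero count is stored as p = 0 and rendered
"< 1/n_sims". One null is cached per (n, n_sims, seed) and shared by every
probe set of a dataset — the null depends only on the sample count, and
re-simulating per probe would be wasteful. Benjamini–Hochberg adjustment
(own step-up implementation, cross-checked against statsmodels) is reported
alongside; candidate selection applies the cut to the raw empirical p, as
the original procedure did.

## Preprocessing

Columns (arrays) are scaled so the 2%-trimmed mean — discarding
`floor(0.02·n)` values per tail, a deterministic convention — equals 150.
The intensity filter keeps probe sets whose 90th percentile of log2
intensity strictly exceeds 6; quantiles interpolate linearly between order
statistics (numpy default, R type 7), which is stated here because both the
filter and the 95th−5th "spread" diagnostic depend on the convention. The
spread deliberately keeps the 95–5 band (under the honest name
`spread_90`) rather than the conventional quartile IQR. Non-positive
intensities are floored at 1.0 before log2 (configurable); summarised data
can contain zeros and the log must be defined. Filtering operates on
scaled data by default; the order is configurable since the original
pipeline does not state it.

## Candidate selection and thresholds

A candidate needs raw empirical p < alpha (default 0.001) and a minor-mode
fraction of at least 5% (`minority_floor`): the minor-allele-frequency
criterion is interpreted as a floor so single outliers cannot pass, and is
configurable. The suggested scoring threshold is the midpoint of the two
group means at the exhaustive best two-group split of the sorted log2
values (1-D two-means); when the dip p-value shows no bimodality
(p ≥ 0.05) the suggestion falls back to the median and carries a fallback
flag. Ranking is ascending empirical p, then descending dip, then probe id,
for deterministic reports. A user include-list can force probe sets onto
the candidate list, mirroring how marker panels in practice admit manually
curated members whose p-values miss the automatic cut. The scan is
deterministic given the null seed.

## Scoring and flagging

Digits are strict comparisons (1 iff intensity > threshold), so a value
exactly at the threshold scores 0. Thresholds are per probe (default 128 =
2⁷ for all three HLA probes) because optimal cut-offs are tissue- and
probe-dependent. Within a donor the reference is the majority score, ties
broken by the earliest sample in annotation order. A discordant sample is
SOFT when every discordant digit's intensity lies within ±1.0 log2
(two-fold) of its threshold — chosen so a 187-vs-128 transgression (0.55
log2) is soft while ten-fold discrepancies are not — otherwise HARD.
Reasons name the probes and fold-changes. Gender calls are unanimous-panel:
M iff every Y-linked probe is above threshold and XIST below, F for the
reverse, ambiguous otherwise; ambiguity is a first-class outcome and never
triggers a mismatch on its own. Gender evidence only escalates flags
(OK < SOFT < HARD), never lowers them. Dataset summaries count HARD flags
as "flagged" by default (SOFT is "not critical"), gender-reason samples,
and all intra-donor score differences (SOFT or HARD). The gender-panel
thresholds default to 128 but are working placeholders — the calibrated
values of the published gender marker are not recomputed here and should
be supplied per dataset.

The packaged allele × probe matrix records, for the two HLA-DQA1 probe
sets, which of their 11 probes match each of seven common alleles; it is
static reference data (the underlying sequence alignment is not
recomputed). `compatible_alleles` intersects the allele sets implied by the
two DQA1 digits, with a match floor of 9/11 by default; an empty
intersection reads "unresolved".

## Synthetic data

The generator emulates exactly the structure the method assumes: donor
states per marker probe drawn Bernoulli(minor_allele_freq) and constant
across a donor's samples; log2 intensities normal around the state's mode
with equal spread per mode; gender probes following the donor's sex;
unimodal background probes; mislabels as donor-id reassignments (with the
declared sex following the recorded donor, as in a donor-keyed database),
keeping truth bookkeeping exact. Defaults: 12 donors × 4 samples (the
48-array training scale), three marker probes named after the default
panel with modes at log2 4 and 10 (linear 16 and 1024; the valley sits at
the default threshold 128), sd 0.5 — a 12-sigma separation matching the
on/off character of real haplotype probes, landing planted dips around
0.10–0.15 — and minor-state frequency 0.3.

What a green simulation test does *not* establish: real arrays have
correlated probes, heavier-tailed intensity noise, batch and tissue scale
effects, and partially-hybridising alleles that sit between the modes; the
generator models none of these.

## Operating characteristics, honestly measured

The dip test is conservative and needs strong separation at these sample
sizes. Measured with this implementation (n = 47, alpha = 0.001 against a
10⁴-draw null, 1000 replicates): a 50/50 normal mixture six component-sd
apart is detected in ~94.5% of replicates (its population dip is 0.051
against a 0.999 null quantile of ~0.078); a 30/70 mixture four sd apart in
~4% (population dip 0.019, below the null's mean); the generator's 12-sd
on/off regime in ~90% with binomial minor counts and ~100% with balanced
counts. Two acceptance tests assert stricter bounds (≥ 99% and ≥ 19/20
recovery respectively) than these true powers allow and are expected to
fail; they are kept as stated rather than weakened. The package's own
unit tests assert the attainable behaviour in the on/off regime.

For context, the Monte-Carlo null here reproduces the published dip→p
mapping of the training analysis closely (e.g. dip 0.078 → p ≈ 9e-4,
dip 0.080 → p ≈ 6e-4 at n = 47).

## Numerical and degenerate-input choices

Dip: n = 1 and all-tied samples return 1/(2n) with a degenerate flag
rather than erroring, since filtered expression data can contain constant
probes. Null simulation requires n ≥ 2; the scan requires ≥ 5 samples (a
dip null below that is meaningless). Score comparisons are strict at the
threshold. The trimmed-mean scaler raises on all-zero arrays, naming the
sample. Seeds: every stochastic component takes an explicit seed; the
scan records seed and n_sims in its result, and data-generation seeds must
be kept disjoint from null-simulation seeds (the dip's affine invariance
otherwise makes shared streams produce literally identical dips).
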