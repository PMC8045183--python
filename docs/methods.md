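# Methods

`scoreval` implements the statistical machinery of an analytical-validation
study for a continuous diagnostic classifier score — the kind of score a
genomic risk classifier produces from a patient specimen and maps, together
with a physician's pre-test risk assessment, onto a post-test risk category.
The package does not model genes, reads or the classifier itself: the score
is the atomic input, and every analysis operates on score tables.

## Score domain and decision policy

Scores live on a continuous, zero-centred scale whose nominal training-set
span is 4.57 units; SDs are routinely expressed as percentages of this range.
Pre-test risk groups are low (malignancy probability < 10%), intermediate
(10–60%) and high (> 60%). The classifier moves a patient at most one level:
low → {very low, low}, intermediate → {low, intermediate, high},
high → {high, very high}. Because the commercial decision boundaries are not
public, the package ships a surrogate policy —

| cut | default |
|---|---|
| low group, down-classification | −0.5 |
| intermediate group, down | −0.3 |
| intermediate group, up | +0.9 |
| high group, up | +1.2 |

— every value overridable from YAML/JSON config. The analyses validate score
behaviour *relative to* boundaries (distances, crossings, flip rates), so
their logic is unchanged under any monotone relabelling of the cuts. A score
falling exactly on a cut keeps the un-reclassified category by default
(`boundary_rule: stay`), the conservative convention; `reclassify` is
available.

Performance metrics treat down-classification as the test-negative event on
the pooled low + intermediate arm (configurable to the intermediate arm
alone): sensitivity = P(not down | malignant), specificity =
P(down | benign), NPV = P(benign | down). The up-classification PPVs
condition on intermediate→high and high→very-high calls respectively. A
metric with an empty denominator is reported as an explicit undefined state
(`None`/NaN), never silently 0 — at extreme injected noise the PPV
denominators can legitimately empty out, and a requirement evaluated on an
undefined median counts as a failure.

Percentages are rounded half away from zero to one decimal for reporting;
raw precision is preserved in JSON.

## Variance components (reproducibility study)

The reproducibility design is a balanced crossed layout: 33 samples (six
controls) × 3 runs × 3 replicates per cell, samples fixed, runs random. The
model is

    score_ijk = mu_i + run_j + (sample:run)_ij + eps_ijk .

On a balanced layout the variance components have closed-form
expected-mean-squares (method-of-moments) estimators:

    sigma2_intra       = MS_within
    sigma2_interaction = (MS_interaction − MS_within) / r
    sigma2_run         = (MS_run − MS_interaction) / (r · n_samples)

with `sigma_inter = sqrt(sigma2_run + sigma2_interaction)` and
`sigma_total = sqrt(sigma2_intra + sigma2_inter)`. EMS rather than iterative
REML because the studies are balanced by design, the estimator is exact and
oracle-checkable (the unit suite verifies 1e-10 agreement with a brute-force
loop-written sums-of-squares computation), and the three headline SDs of
such studies satisfy the EMS composition identity (e.g. 0.117² + 0.136² =
0.179²). Treating samples as fixed or random does not change these
estimators on a balanced layout. Negative moment solutions are truncated to
zero and flagged — the standard MoM pathology; a silent negative variance
would break every downstream composition.

Unbalanced or single-replicate tables are rejected with an error naming the
violated requirement; there is no silent fallback to an unbalanced
mixed-model fit (out of scope).

**Precision caveat.** With only 3 runs, MS_run has 2 degrees of freedom, so
the run-SD estimate carries ~sqrt(chi2_2/2) relative noise (median |relative
error| ≈ 36%) no matter how many samples are measured. The intra-run SD, by
contrast, rests on 198 df and is tight. Single-study inter-run and total SDs
should therefore be read with wide error bars; the suite tests the
estimator's exactness and unbiasedness, which are the properties the design
can support.

### Bootstrap confidence intervals

CIs are percentile intervals from a residual bootstrap (default
`n_boot = 2000`), applied level-wise: the fitted decomposition yields three
residual sets — run deviations, interaction deviations, within-cell
residuals — each reflated so its resampling second moment equals the
corresponding variance-component estimate, then resampled independently with
replacement and re-added to the fixed sample means before re-estimation.
Reflation matters twice over: residuals from an m-observation mean
under-disperse by the leverage factor (1 − 1/m), and naive resampling of
within-cell residuals alone leaves the realised run/interaction deviations
frozen in every replicate, which both biases the re-estimated interaction
component upward by MS_within/r and collapses the interval below the point
estimate. The level-wise reflated scheme keeps the bootstrap distribution
centred on the point estimates (the interval brackets the estimate, as the
report requires). Composed quantities (inter, total) are bootstrapped on the
composed statistic. Residual sets are sorted into a canonical order before
resampling, so the interval is invariant to input row order.

Even so, resampling three run deviations with replacement cannot reproduce
the heavy chi2_2 sampling distribution of the run component: measured
coverage of the 95% interval for sigma_total at the default design is ~74%,
not 95%. This is a property of any resampling bootstrap at b = 3 runs, and
it is consistent with the narrow intervals such studies print. A parametric
(Gaussian-draw) bootstrap would restore nominal coverage but is not the
resampling method these studies describe; the limitation is documented
rather than papered over.

## Inter-laboratory study

95 samples (six controls) measured in both of two laboratories; the model is
the one-way fixed-means layout `score_ik = mu_i + eps_ik`, and the
inter-laboratory SD is the pooled residual SD with `N_obs − n_samples`
degrees of freedom, CI by the leverage-rescaled residual bootstrap.
Concordance compares paired post-test calls between laboratories: the
discordance rate is tested against a pre-specified acceptance bound (default
15%), and the squared Pearson correlation of paired scores is reported. How
many calls a sample contributes per laboratory is exposed as a parameter
(`replicates_per_lab`) since a calls denominator need not equal the sample
count.

## Interference: condition effects

RNA-input and genomic-DNA interference studies use the blocked model
`score_ijk = mu_i + b_j + eps_ijk` (no sample×condition interaction term),
tested by a two-way balanced ANOVA with samples as blocks:
`F = MS_condition / MS_residual`, where the residual pools within-cell and
sample×level variation, with classical balanced-design degrees of freedom
(numerator L−1, denominator N − a − L + 1). The unit suite checks the exact
identity F = t² against a paired t-test in the two-level single-replicate
case and full agreement with an independent OLS ANOVA. Level effects are
reported as sum-to-zero deviations from the grand mean. Significance is
declared at alpha = 0.05. The default synthetic designs mirror the studies:
4 samples × {10, 15, 20, 36, 50} ng in triplicate with a small negative
shift (−0.05) at the lowest input, and 2 samples × {0, 3, 5, 10}% gDNA with
null effects (the generator uses a common replicate count per cell because
the blocked ANOVA requires balance).

## Interference: admixture (blood) dose–response

A contaminant that scores in the high/malignant region pulls a mixed
sample's score monotonically from the pure-sample score (p = 0) towards the
pure-contaminant score (p = 1). The generator blends the two endpoint scores
through a normalised logistic weight in the mixing proportion (shape
parameter `mixing_k`, default 4; the k → 0 limit is the linear blend), plus
Gaussian replicate noise; the dilution layout is {0, 5, 10, 20, 50, 75,
100}% with triplicates at the lower proportions and duplicates at 50/75%.

Fitting uses the four-parameter logistic in p (inherently monotone),
multi-started over slope magnitudes, with a straight-line candidate kept
when its residual sum of squares is at least as small — so exactly linear
data reproduces the line with zero residual. Fewer than four distinct
proportions fall back to isotone piecewise-linear interpolation of
per-proportion means; per-proportion means that reverse direction by more
than 25% of the observed span raise a warning and the fit proceeds on the
means.

Flip thresholds are read off the noise-free fitted curve, not raw
replicates: for each decision boundary of the base sample's pre-test group,
the smallest p in [0, 1] where the curve crosses the cut (Brent root-finding
to 1e-6; the curve is monotone so the crossing is unique). A boundary never
crossed reports the sentinel "no call change". Text reports round to whole
percent; JSON keeps raw precision. Inverting on the fitted curve makes the
threshold antitone in boundary distance and non-increasing in contaminant
strength, both property-tested.

## Noise-injection tolerance simulation

Two separable stages, repeated `n_reps = 1000` times per noise SD on a
40-point log-spaced grid over [0.01, 10] score units (log spacing resolves
the small-SD region where calls change fastest; the bounds and repeat count
follow the validation protocol): (1) add i.i.d. Gaussian noise of the given
SD to every patient score of a labelled cohort; (2) re-classify and compute
all metrics against the zero-noise baseline calls. Medians across replicates
per SD form the tolerance curve. The maximum allowable SD is the largest SD
at which every product requirement holds on median metrics — default
requirement set: intermediate→high up-classification PPV ≥ 50%, extensible
as a named map — refined between the last passing and first failing grid
points by bisection on freshly simulated medians (fixed derived seed,
tolerance 1e-3 in SD). `first_failure_mode` names the requirement failing at
the smallest SD (declaration order breaks ties). Everything is vectorised
over replicates × patients, so the default grid runs in seconds.

The simulation is validated against closed forms: a single patient a
distance d below a boundary flips with probability Phi(−d/sd) (matched
within 3 Monte-Carlo SEs at 10,000 replicates), and on a two-point-mass
cohort the PPV is a ratio of Gaussian tails whose 50% crossing the bisection
reproduces within 0.01.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (design, seed); one top-level seed
expands into named substreams (`SeedSequence([seed, crc32(label)])`), so
partial re-runs reproduce the full run's draws. Noise is Gaussian at every
level, matching the assumption the validation analyses themselves make.

Default parameters sit at the regimes the studies report: residual SD 0.117;
between-run SD 0.136 split as run 0.11 / interaction 0.08 (total 0.179);
inter-laboratory SD 0.169 over 95 samples; 33-sample reproducibility panel
spanning the score space. The reproducibility layout uses 3 replicates per
run × 3 runs — with both intra- and inter-run SDs reported, within-run
replication must exist, which settles the ambiguity between "triplicate
across three runs" readings. The validation cohort (150/300/150 patients in
low/intermediate/high with prevalences 8%/35%/75%) draws scores from
Gaussian (group, truth) cells placed so that zero-noise calls land in a
realistic regime — high sensitivity and NPV, moderate specificity, PPVs
comfortably above the 50% floor, and the benign intermediate mass closest to
the up-classification boundary so that PPV degrades first as noise grows.

What passing tests on these data do **not** show: real classifier scores are
not Gaussian within cells, run effects need not be additive or homoscedastic
across the score range, admixture in RNA space need not follow a logistic
blend in mixing proportion, and a real cohort's score distributions are
unknown. The synthetic studies validate the *estimators and procedures* —
recovery, calibration, inversion, search — not the published headline
values, which derive from proprietary patient data. Accordingly, the
tolerance limit computed on the default synthetic cohort (~1.6 score units)
is a property of that cohort's wide margins, not a reproduction of any
published limit; only the arithmetic identities (SD composition and
percent-of-range conversions) are reproduced exactly.

## Numerical conventions

Percentile CIs use linear-interpolation quantiles. Variance truncation at
zero is flagged in the output (`flags.truncated`). The 4PL exponent is
clipped at ±700 to avoid overflow at extreme slopes. Classification is
exactly deterministic at boundaries per the boundary rule. JSON output
replaces non-finite floats with null. Reports carry a config hash, the seed
and the package version, and contain no timestamps, so a rerun with the same
config and seed is byte-identical.
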