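# Methods

## The measure

The Implicit Association Test (IAT) asks respondents to sort stimuli under
two key-mapping conditions — Mapping A (e.g., flowers share a key with
positive words) and Mapping B (the reversed pairing) — each administered as
a practice block and a test block. Respondents are faster in the condition
consistent with their automatic association. The D-score standardizes that
latency difference per participant:

    D_practice = (M_practiceB − M_practiceA) / SD_pooled(practice trials)
    D_test     = (M_testB     − M_testA)     / SD_pooled(test trials)
    D          = (D_practice + D_test) / 2

where each `M` is the mean post-treatment latency of a block and each
pooled SD is the sample SD of the concatenated trials of both blocks in the
pair. The default subtraction order is MappingB − MappingA; with it, a
positive score means faster responding under Mapping A. Reversing the
direction (or equivalently swapping the Mapping A/B label assignment) is an
exact sign flip.

## The six algorithms

The variants differ only in error and fast-trial treatment:

| id | error inflation                    | lower tail            |
|----|------------------------------------|-----------------------|
| D1 | built-in correction                | none                  |
| D2 | built-in correction                | delete trials <400 ms |
| D3 | correct-trial mean + 2 SD          | none                  |
| D4 | correct-trial mean + 600 ms        | none                  |
| D5 | correct-trial mean + 2 SD          | delete trials <400 ms |
| D6 | correct-trial mean + 600 ms        | delete trials <400 ms |

Built-in correction (D1/D2) assumes the administration forced respondents
to correct errors, so recorded latencies already contain the penalty and
are used as given. The ex-post strategies (D3–D6) replace each error
latency with the block's correct-trial mean plus the penalty.

Two conventions here are genuinely open in common descriptions of the
family and are fixed as follows:

* **The 2-SD penalty uses the SD of the block's correct trials only**,
  consistent with the "mean (correct responses) + 2 SD" labeling of the
  strategy; both the mean and the SD of a block's error replacement come
  from the same correct-trial set.
* **The pooled SD is computed on post-inflation latencies** — inflated
  error trials are included at their replacement values. Treatments are
  applied first, then the score is computed on the pooled trials of both
  blocks; excluding error trials from the denominator would standardize a
  quantity different from the one in the numerator.
* **Sample SD (n−1) everywhere**, so tiny hand-checkable fixtures have
  unambiguous expected values.

## Cleaning order

The steps run in a fixed order (the counts each step reports are defined
relative to this point in the pipeline):

1. remove trials slower than 10,000 ms;
2. count trials <300 ms and <400 ms, and flag *fast participants* (more
   than 10% of trials under 300 ms) on the remaining trials;
3. flag *inaccurate participants* (error percentage strictly above the
   threshold, default 25%, in either mapping condition) on the same trials;
4. delete trials <400 ms for D2/D5/D6 only;
5. inflate errors and score.

All comparisons are strict, following the usual wording of the rules
("higher than 10,000", "faster than 300", "more than 10%", "exceeding"
the threshold): boundary trials and boundary participants survive.
Exclusion flags never delete rows — flagged participants are scored and
written to the results file, and only the displayed summaries omit them.
The `num.400` diagnostic is always reported, even for algorithms that do
not delete the lower tail; the *removed*-count is marked not applicable
("Not expected for this D") for D1/D3/D4.

A participant who ends up with an empty block, a block with no correct
trials (ex-post penalties), only one correct trial (2-SD penalty), fewer
than two pooled trials, or zero pooled variance gets missing score
components plus a machine-readable `reason` code rather than aborting the
batch or silently scoring zero.

## Degenerate inputs and numerical notes

* Undefined error replacements are NaN and are *propagated*, never
  skipped: group means/SDs use non-skipping reducers, so one undefined
  replacement poisons exactly the affected component.
* Zero pooled variance yields an undefined component (division by zero is
  never reported as ±inf).
* `cond_ord` (which condition the participant saw first) is derived from
  input row order: the condition of the participant's first trial in file
  order. Row order is the only presentation-order signal in the input
  format; this is a documented convention of this package.
* Quartiles in the six-number summaries use linear interpolation between
  order statistics (numpy's default); reliability is the Pearson
  product-moment correlation between D_practice and D_test.
* Descriptive statistics use post-inflation latencies and the same cleaned
  trial set the score consumed, so they describe exactly what was scored.

## Synthetic data generator

Latencies are ex-Gaussian — Normal(mu, sigma) plus Exponential(tau) — the
standard phenomenological model for response times. Defaults are a
conventional desk-scale IAT: 20 trials per practice block, 40 per test
block, mu = 600 ms, sigma = 100 ms, tau = 150 ms, 5% errors per condition,
no contamination, condition order counterbalanced per participant. The
true IAT effect is a constant shift `effect_delta` (default 100 ms) added
to Mapping B latencies, so a positive shift produces a positive
default-direction score and the mean recovered score is monotone in the
shift. Optional contamination replaces trials with anticipations
(uniform 50–299 ms) or lapses (uniform 10,001–15,000 ms); with
`builtin_correction`, error latencies gain a fixed `correction_penalty_ms`
(default 400 ms) emulating forced-correction administrations. Latencies
are rounded to whole milliseconds, as real logging software records them.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequential effects (post-error slowing,
block-order practice effects), between-participant variance in the true
effect (every simulated respondent shares one delta, so the expected
practice–test reliability of synthetic data is near zero, unlike the
0.5–0.8 typical of real IATs), condition-dependent error-latency coupling,
and stimulus-level variability. The generator validates the pipeline's
arithmetic and filtering semantics, not the psychometrics of real
populations.

## Problem sizes

The test suite and the acceptance script use simulation sizes chosen for
stable statistics at desk scale: 500 random micro-tables for the oracle
cross-check, 500 participants for the null-recovery check, and 200
participants per shift for the effect-recovery curve. These sizes put
Monte-Carlo standard errors well below the assertion margins (e.g., the
null-mean check uses a 3-SE band around zero).

## Known limitations

* Only the four-column CSV dialect is read; no Inquisit/SPSS/Excel input.
* Brief-IAT scoring and split-half / test–retest reliability are out of
  scope.
* The density estimator (Gaussian kernel, Scott bandwidth) and histogram
  default of 30 bins are this package's documented choices; interactive
  displays of the same data may use different smoothing defaults.
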