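# Methods

## Scope and data model

The package operates on per-participant, per-workday streams of non-negative
activity counts on a contiguous 15-second epoch grid, the native output of a
wrist accelerometer that aggregates movement into counts. The recording
system emits a count for every epoch while tracking is on and writes 0 when
no data arrive, so data loss appears as zero runs, never as missing rows.
All intervals are half-open `[start, end)` in 0-based epoch indices; all
durations are integer epoch arithmetic (a minutes-valued threshold that is
not a whole number of epochs is rejected at configuration time). Rounding to
one decimal happens only when reports are emitted.

## Validity classification

A maximal run of ≥ `invalid_run_epochs` (default 40 ≙ 10 min) zero-count
epochs is invalid tracking; "40 or more" makes 39 zeros valid and 40
invalid, and runs touching the day boundaries are treated like interior runs
(the convention is otherwise unstated; boundary runs carry the same evidence
of disconnection). A tracking day is any day with a stored stream — the
participant started tracking — independent of validity; this is the minimal
reading consistent with distinguishing tracking days from valid tracking
days. The valid-day rule is strict on both sides (valid > 180 min AND
invalid < 180 min, from "over" / "less than"); the inclusive alternative
would flip only days sitting exactly on a bound and is a one-line config
change for sensitivity analyses.

## Bout segmentation

Movement epochs are those with count ≥ `active_count_threshold` (default 1:
any nonzero count). The original detection algorithm's exact count threshold
and smoothing were never published, so the threshold is declared
configuration, not inference — deployments adjusted it per user. Maximal
movement runs of ≥ `min_ambulatory_epochs` (default 4 ≙ 1 min, the shortest
break the system's feedback displays) become ambulatory bouts; shorter runs
are absorbed into stationary time rather than given a third class, keeping
the two-class stationary/ambulatory scheme of the process measures.
Stationary pools sitting and standing: wrist counts cannot separate
postures, and the outcome definition is "no ambulation". Invalid epochs form
invalid bouts that terminate any open bout — a 60-min stationary stretch
split by a dropout is deliberately *not* prolonged, because counting across
an unobserved gap would fabricate sedentary time. Prolonged bouts use an
inclusive ≥ 60-min cutoff ("60 minutes or above").

## Prompt state machine

Within each stationary bout an inactivity clock starts at the bout onset and
fires amber breathing / red breathing / red flashing at 45 / 55 / 60 min.
A stage fires at the first epoch whose start lies at or beyond the threshold
*and* that is still stationary: a bout of exactly 45.0 min emits nothing,
one of 60.0 min emits amber and red but no flashing (inactivity must
*exceed* 60 min to flash). Ambulatory bouts reset the clock; invalid bouts
reset it and suppress events, since a disconnected LED cannot light up
(whether the deployed clock paused or reset during disconnection is unknown;
reset is the conservative choice). One event is logged per stage crossing,
so a fully ignored hour logs three events — the only granularity that makes
the escalation observable in the log; `prompt_granularity: per_episode`
collapses each episode to its first crossing for the alternative reading.
The response to a prompt is the onset of the next ambulatory bout at or
after it (which may answer several stacked prompts at once), with no attempt
to distinguish prompt-caused from coincidental breaks. Unanswered prompts
have latency "none" and stay in the compliance denominator.

## Process metrics

Compliance uses an inclusive ≤ 15-min window. Latency bins are right-closed
(0,5], (5,10], (10,15] so they union exactly to the complied prompts.
Cohort summaries report pooled ratios (Σ numerators / Σ denominators) and
per-participant distributions separately; pooled and mean-of-ratios differ
whenever denominators differ, and conflating them is a classic reporting
error. Sample SD uses n−1; percentiles use linear interpolation; a single
participant reports SD 0 with an explicit `sd_defined = 0` flag.

## Outcomes

Self-report stationary time = sitting + standing; ambulatory = walking +
heavy labor. Constructs are unweighted item means on the 1–7 scale;
reverse-keyed constructs (e.g. prospective-memory difficulty, barriers) are
analysed in their raw direction with the sign interpreted at reporting,
since published tables report raw-direction means. Paired comparisons are
classical two-sided paired t tests on post − pre (df = n−1), delegated to
`scipy.stats.ttest_rel`; zero-variance differences are handled explicitly
(t = 0, p = 1 for no change; signed infinite t, p = 0 for a constant shift).
Pairs with missing values are dropped and logged. Which intervention days
constitute the "post" phase for objective measures is genuinely open; the
pipeline defaults to first-*k* / last-*k* valid-day windows with both
windows configurable. Published outcome tables from the original feasibility
study are not reproducible — participant-level data were never deposited —
so the outcome module is validated by calibration instead: simulated-null
type-I error at n = 15 and Monte-Carlo power against the closed-form
noncentral-t, which check the test implementation rather than any paper
value.

## Synthetic workday generator

The generator emulates, not reproduces, office workdays: alternating
sitting/break intervals from an alternating-renewal (semi-Markov) process
with gamma durations (shape = 1/dispersion; defaults: sitting mean 50 min,
break mean 5 min, dispersion 0.25 ⇒ shape 4, a realistic right skew), over
480-min days for 15 participants × 30 days — the study-scale conditions.
Sitting texture is zero runs of geometric length (mean ≈ 9 epochs, capped at
`invalid_run_epochs − 1`) separated by single count-1 fidget epochs: ≈ 90%
of sitting epochs are zero, fidgets are absorbed by the segmenter, and an
uninterrupted sitting stretch can never be misread as invalid tracking — by
construction only dropout produces invalid runs, which keeps ground truth
and detected labels in one-to-one correspondence when dropout is off.
Dropout (Bluetooth-style data loss) overwrites runs with zeros at
`dropout_prob_per_epoch = 8e-4` with mean length 15 min, chosen to lose
roughly 20–25 min/day as feasibility deployments report. Behavioural
response is mechanistic: a sitting bout that would cross the 45-min prompt
is truncated, with probability `responsiveness` (default 0.4, in the range
observed compliance suggests), at 45 min plus a uniform latency in (0, 15];
this makes compliance a recoverable parameter. Streams are bit-exact in
(seed, participant, day): integer counts, durations rounded to epochs before
use.

What the generator does *not* model: raw 3-axis signals, posture, diurnal
structure within the workday, weekday effects, between-participant
heterogeneity in bout distributions, or attention/visibility of the LED.
Passing recovery tests therefore shows the pipeline computes its measures
correctly on streams with known structure — not that real wrist data meet
the generator's assumptions.

## Verification strategy and problem sizes

Run-length labelling and segmentation are checked against independent
`groupby`-based brute-force enumerators: exhaustively over all binary
strings up to length 12 with scaled-down thresholds (invalid run 3 epochs,
ambulatory minimum 2 — the same logic exercised at short lengths), and on
1,000 random strings of length 2,000 at default thresholds. The prompt
engine is checked against an epoch-by-epoch clock simulation. Parameter
recovery runs the full pipeline on 15 × 30-day cohorts and compares pooled
compliance (responsiveness 0.3 and 0.8, ±5 percentage points) and mean
daily prolonged-bout count (±0.2 bouts/day) against an independent
continuous-time Monte-Carlo renewal oracle (20,000 simulated days) that
includes multi-stage prompting, coincidental responses and day-end
truncation; recovery experiments disable dropout because they target the
prompt-response mechanism, and dropout is a separate nuisance process with
its own tests. At low responsiveness the expected compliance (≈ 56%) sits
far above the responsiveness itself because ignored prompts are often
answered coincidentally within the window — the oracle, not the raw
parameter, is the correct target. Remaining discrepancies of 1–3 points
come from epoch discretisation and sub-minute breaks absorbed by the
segmenter, both well inside the bands. The t-test calibration uses 2,000
null replicates at n = 15. These sizes keep the full suite under half a
minute of compute while leaving Monte-Carlo error well below every band.

## Known limitations

Counts are the input unit; no step counting, energy expenditure or posture
classification is attempted. No imputation of invalid time — analyses use
valid days only. The prompt replay assumes the LED always showed what the
state machine dictates; real deliveries also failed for visibility and
attention reasons that tabular logs cannot capture.
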