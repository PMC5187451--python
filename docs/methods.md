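# Methods

`smartquit` implements a just-in-time adaptive intervention (JITAI) engine for
smartphone-assisted smoking cessation, together with a synthetic behavioral
cohort generator and a feasibility-metrics pipeline, so the whole system can be
exercised and validated without real participant data. This note documents the
model, its assumptions, the tunable parameters, and the known limitations.

## Protocol model

The study protocol is a 3-week ecological momentary assessment (EMA) period:
a 1-week prequit phase followed by 2 postquit weeks, with the quit date at the
phase boundary. Each active day carries 5 system-prompted EMAs:

- **daily diary** — once per day, 30 minutes after the participant's wake time
  (`diary_offset_min`, default 30). The study day is anchored to waking, not
  midnight: all "today / yesterday" logic in the decision rules uses
  wake-to-wake participant days.
- **random prompts** — `n_random_per_day` (default 4) per day inside the
  waking window. Placement stratifies the window into equal segments and draws
  uniformly within each, rejecting draws that put two prompts (or a prompt and
  the diary) closer than `min_gap_min` (default 30 min); after 200 failed
  draws a deterministic grid fallback guarantees a valid schedule. Stratified
  random placement is standard experience-sampling practice: it keeps prompts
  unpredictable while spreading them over the day.

System prompts cue for `prompt_window_sec` (60 s). The window applies to
*initiating* a response (`response_latency_sec` on the record); the multi-minute
completion duration is `completed_at − presented_at` and feeds the
completion-time statistics. A prompt not answered inside the window is missed,
finally — there is no snooze or re-fire.

Event-contingent assessments: during the prequit week each logged smoking
occasion ("Record Cigarette") is eligible for a full pre-cigarette assessment
while the day's sampled count is under `max_sampled_cigs_per_day` (default 2);
the cap counts completed pre-cigarette assessments. Sampling uses probability
`p_sample_occasion` (default 1.0 — sample every occasion until the cap, the
simplest rule consistent with "up to 2 per day"). A sampled occasion queues the
post-cigarette follow-up 15 min after the pre-cigarette assessment completes.
Postquit, the participant-initiated buttons are Urge, About-to-Slip and
Already-Slipped; only About-to-Slip queues a follow-up (15 min later, asking
whether the participant actually smoked). Follow-ups are system-cued and carry
the same 60-s window.

## Decision algorithm

One message is delivered at the end of every completed EMA. Level precedence:

1. prequit → **Level 0** (untailored preparation content, delivered in the
   bank's predetermined order, cycling);
2. postquit, participant has lapsed and currently reports no further interest
   in quitting → **Level 0** (the flag is sticky until a later lapse-context
   answer reports renewed interest);
3. the EMA records a *new* lapse → **Level 3** (return-to-abstinence);
4. any of: the lapse-risk estimator flags high imminent risk; the participant
   smoked today or yesterday; today's diary forecast a smoking likelihood
   strictly above `diary_risk_threshold_pct` (25); or the EMA is a
   participant-initiated urge/slip assessment → **Level 2**;
5. otherwise → **Level 1** (low-risk maintenance content).

"New lapse" is deliberately precise, because an Already-Slipped EMA could
plausibly be read as Level 2 or Level 3: here the *first* completed EMA
reporting a lapse (Already-Slipped, or a slip follow-up confirming smoking)
with no lapse already on record for today or yesterday classifies Level 3;
subsequent EMAs while smoked-today-or-yesterday holds classify Level 2. This
is one deterministic resolution of a genuinely ambiguous rule, not a claim
about the original app's internals.

Level-2 messages are tailored to the arg-max of four trigger intensities —
negative affect/stress, urge, cigarette availability, and motivation deficit —
with ties broken in that fixed priority order. Motivation deficit is
`item_scale_max − motivation_to_quit`, putting "low motivation to quit" on the
same high-is-bad axis as the other triggers.

The lapse-risk estimator is a pluggable linear score
`intercept + Σ wᵢ·xᵢ` over urge, negative affect/stress, availability,
motivation deficit, and a smoked-since-last indicator, with `high_risk` iff
the score strictly exceeds `threshold`. Defaults (weights 0.3/0.3/0.2/0.2/1.0,
intercept 0, threshold 4) are an explicitly documented placeholder contract:
published momentary lapse-risk estimators are richer fitted models and can be
substituted by swapping the spec without touching the engine.

Message selection within a slot is round-robin, which avoids immediate
repetition whenever a slot holds ≥2 entries; Level-0 follows the bank's
predetermined order. All engine behavior is a deterministic function of the
event log, message bank and configuration.

## Synthetic cohort generator

The generator emulates the statistical structure the engine and metrics
assume, with defaults set to the study conditions:

- `n_participants = 59`; per-prompt completion is independent
  Bernoulli(`p_respond = 0.87`) for all system-cued prompts (missingness is
  marginal by design; a time-of-day adherence modifier is out of scope).
- Latent urge, negative affect/stress, cigarette availability and motivation
  follow AR(1) processes on the 0–10 item scale (persistence `ar_phi = 0.7`,
  innovation SD `ar_sigma = 1.5`, means 5/4/6/7), stepped once per assessment
  epoch and clipped/rounded at read-out. AR(1) is the simplest dynamic giving
  the within-day autocorrelation the JITAI logic needs.
- Prequit smoking: a participant-level cigarettes/day mean drawn from a
  truncated normal (mean 20.3, SD 11.6, floor 5); each cigarette is logged
  with `p_record_cig = 0.12`. Postquit urge/slip button presses arrive at
  `postquit_event_rate = 0.30`/day, becoming Already-Slipped reports when an
  unreported lapse exists. These two defaults were derived analytically so
  the expected self-initiated assessments over 21 days ≈ the declared
  `self_initiated_rate = 15.5` (≈1.6 sampled occasions/day × 7 prequit days
  + 0.30 × 14 postquit days).
- Lapses: at every postquit assessment epoch a Bernoulli draw with logistic
  hazard `logit p = −7.0 + 0.4·urge + 0.2·stress + 0.15·availability +
  0.1·motivation_deficit` on the current latent state. The intercept was
  chosen so a default cohort produces a plausible mix of early lapsers,
  recyclers and maintained abstainers rather than universal daily lapsing.
  Messages do not feed back into the hazard (`message_feedback = 0`): the
  generator makes no treatment-effect claim.
- Visits: attendance Bernoulli per visit (0.92, 0.98, 0.98, 0.90, 0.83, 0.78
  for quit date and weeks 1, 2, 3, 4, 12; the week-3 value is interpolated).
  Within the EMA window, 7-day abstinence is read off the lapse record; weeks
  3, 4 and 12 lie beyond it and use a weekly Markov carry-forward
  (persistence 0.85, recycling 0.08) — a stand-in, not a behavioral model.
  Expired CO is drawn conditionally on status: truncated normal mean 3 ppm
  (SD 1.5) for abstainers, mean 18.6 ppm (SD 13.0) for smokers.
- Reproducibility: the cohort seed spawns independent per-participant
  substreams (`numpy` SeedSequence); identical seeds give byte-identical
  logs.

**What passing tests do and do not show.** The generator reproduces the
declared marginal structure (compliance, self-initiation volume, hazard
signal, CO separation). It does not model time-of-day adherence patterns,
reactive effects of messages, within-person trends across the quit attempt, or
truthful-report bias in self-reported abstinence; calibration tests therefore
validate the pipeline's correctness under the declared model, not behavioral
realism.

## Parameter recovery

`recover_parameters` estimates prompt adherence as completed/prompted over
prompted-origin EMAs (binomial SE) and the hazard coefficients by logistic
regression (`statsmodels` Logit MLE) on the per-epoch (covariates, lapse)
draws the simulator records. With zero observed lapses the dataset is flagged
degenerate and coefficient recovery is skipped. Because the generative hazard
is exactly the fitted model (no unmodeled heterogeneity), MLE recovery within
2 SE is the expected behavior at moderate n; the shipped checks use one
59-participant cohort for calibration and a 236-participant cohort for
coefficient recovery — sizes chosen to make sampling error small relative to
the tolerances while keeping the default suite quick.

## Metrics

- **Compensation**: completion fraction f = completed/prompted over prompted
  EMAs maps through half-open tiers [0, .50)→$0, [.50, .75)→$40,
  [.75, .90)→$80, [.90, 1]→$120. The printed integer-percent tier labels are
  implemented on the real-valued fraction so every fraction maps to exactly
  one tier and the amount is monotone.
- **Compliance**: per-kind completed/prompted rates over prompted-origin
  records, with a parallel `all_cued` scope that also counts system
  follow-ups (published denominators do not always say which was used);
  completion minutes only over records with both presented and completed
  timestamps; self-initiated records tallied separately.
- **Abstinence**: biochemically verified point prevalence — attended AND
  self-reported abstinent AND CO strictly below the cutoff (10 ppm at the
  quit-date visit, 8 ppm otherwise). Missed visits are nonabstinent, and the
  per-visit denominator is the full cohort, not the attendees. An attended
  visit without a CO reading is an error, not a pass-through.
- **Feature use**: per feature and category, user counts, per-participant
  access frequency and tips-per-occasion intensity (mean/SD/median — medians
  matter because intensity is heavy-tailed), plus viewers-not-prescribed
  counts when a prescription table is supplied.

## Degenerate inputs and numeric conventions

Empty logs yield empty reports with a warning rather than errors; a log with
only self-initiated records reports a null prompted rate. Tier boundaries,
the diary threshold and CO cutoffs are all strict/half-open as documented
above, so boundary values are deterministic. Schedules round prompt times to
whole seconds. The countdown message uses the ceiling of the remaining time
in days and handles the singular "1 DAY".

## Limitations

- The lapse-risk estimator default is a placeholder contract, not a validated
  momentary risk model.
- The Level-3 / Level-2 precedence after a lapse is one deterministic
  resolution of an ambiguous rule (see above).
- Abstinence beyond the EMA window is a Markov stand-in; week-12 outcomes in
  simulation are not forecasts.
- Replaying an external event log without a participant table approximates
  the wake-anchored day boundary with a fixed 04:00 boundary.
- No mobile UI, push transport, telephony or persistence beyond flat files.
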