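# Methods

## Model

The generative model is a two-state hidden Markov chain on a 32nd-note
grid. State "metered" emits an onset at grid position t (mod 32) with
probability λ_m(t); state "unmetered" emits onsets with the constant
probability λ_u equal to the mean of λ_m, so the two templates differ only
in *pattern*, never in overall onset density. The state persists between
steps with probability 1 − P_switch and flips with P_switch. Perception is
exact Bayesian filtering of this chain: update by Bayes' rule on each
onset/rest, then propagate through the symmetric transition. The per-step
surprisal −ln P(obs_t | obs_1..t−1) is the model's operationalization of
precision-weighted prediction error, and the sum over a stream equals the
negative log marginal likelihood of the full two-state chain (verified in
the test suite against explicit enumeration of all hidden-state paths for
short streams, and against an independent HMM library's forward pass).

Movement is modeled through its expected sensory feedback: overlaying a
quarter-note metronome (onsets forced at positions 0, 8, 16, 24 of every
measure) on the input stream. Delta surprisal, the drop in mean surprisal
produced by the overlay, indexes how much prediction error on-beat
movement would resolve. The observation stream contains the five-onset
rhythm only; the isochronous eighth-note hi-hat present in the audio
stimuli is *not* merged into the stream. With the hi-hat merged, every
strong position would always carry an onset and on-beat rests could never
generate the surprisal spikes that drive the whole effect; the hi-hat's
role — anchoring the metrical phase — is instead baked into the assumption
that phase and tempo are known (no phase/tempo inference is attempted).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `p_switch` | 0.01 | per-step regime switch probability; sets the drift rate of the prior toward 0.5 (geometric, rate 1 − 2·p_switch) |
| `contrast` (C) | 1.0 | mean-preserving shrink of λ_m toward λ̄; 0 = flat template |
| `initial_prior` | 0.5 | P(metered) before the first observation (unstated in the source material; maximally uncertain, exposed as a parameter) |
| `level_probs` | 0.99, 0.90, 0.80, 0.40, 0.15, 0.05 | onset probability per metric level (whole, half, quarter, eighth, 16th, 32nd) at C = 1 |
| repeats | 4 | measures per stream (128 steps), matching ~10 s presentations at 96 BPM |
| log base | e | surprisal is reported in nats |

The exact level probabilities behind the published template are available
only graphically; the default above preserves the stated strict ordering
across levels and, at the simulation defaults, reproduces every
documented qualitative result: rapid posterior lock-in for unsyncopated
rhythms, mean surprisal increasing with complexity, the inverted-U delta
pattern with a small medium−low and a large medium−high gap, and the
flattening of the delta pattern as P_switch rises or C falls. The nine
reference rhythms span Δ ≈ −0.066..+0.141 nats under this template
(the published range is −0.047..0.093; the scale depends on the graphical
template values and no result here depends on matching it exactly).
Observation probabilities are floored at 1e-12 before logs so degenerate
templates cannot produce infinite surprisal.

## Grid conventions

Positions are 0-based, 0..31 per measure; quarter positions {0, 8, 16,
24}; eighth {4, 12, 20, 28}; 16th the remaining even; 32nd the odd.
Templates cycle with period 32 across the stream. LHL metric weights are
0, −1, −2, −3, −4, −5 from whole to 32nd level.

## Syncopation scoring

The summed LHL index treats the measure as cyclic (rests after the last
onset wrap toward the downbeat, which always carries an onset in every
pattern considered here). Only rests on eighth-note positions or stronger
(weights ≥ −3) can score; a qualifying rest scores when its weight
*strictly* exceeds the preceding note's, contributing the difference. Two
readings of "a note precedes a rest" exist: score **every** qualifying
rest between a note and the next note, or score each note→rest run once
against its **strongest** qualifying rest. Enumeration settles the choice:
under the strongest-rest rule no five-onset pattern can exceed a summed
index of 12 (the strong non-downbeat positions contribute at most
4+3+3+2 once per run), so the documented fixture range 0–18 is attainable
only under the per-rest rule, which is therefore the default
(`rule="per_rest"`); the variant remains available (`rule="strongest_rest"`).

## Reference rhythms

Three per complexity level, five onsets each, onset on the downbeat. The
lows keep all onsets on quarter/eighth positions (index 0); the mediums
are the standard son {0,6,12,20,24}, bossa {0,6,12,20,26}, and rumba
{0,6,14,20,24} claves (indices 4, 6, 6); the highs place every onset but
the downbeat on 32nd positions — {0,9,15,23,31}, {0,7,15,23,31},
{0,3,15,19,31} (indices 13, 16, 18). The set spans 0–18. Encodings are
data (`rhythm._FIXTURE_SPECS`), not logic, and can be edited if a
different transcription is preferred.

## Stimulus generator

Candidates are drawn from a probabilistic template that mixes the metered
and flat templates with a weight sampled uniformly per attempt, so both
regular and irregular patterns arise. The downbeat is forced; the
remaining four onsets are drawn without replacement proportionally to the
template; candidates violating the constraints (five onsets, downbeat,
no onsets on cyclically adjacent grid steps — the strict reading of "no
consecutive 32nd notes") are resampled. A candidate is accepted when its
metric (delta surprisal at the evaluation parameters, default
p_switch 0.01 / C 1.0, or syncopation index) lies within the buffer of
the target (defaults 0.01 and 1 respectively). Unreachable targets are
reported in the manifest and logged, not fatal. Attempt budget: 10,000
per target; candidates are evaluated in vectorized batches for speed.

## Ratings, QC, and fitting

Ratings are 0–100 slider values, one row per (participant, stimulus).
QC drops participants with any failed attention check, all-100/all-1
raters ("extreme-constant"), and near-zero variability (within-participant
SD < 1 slider unit by default; the source threshold is unstated).
Within-participant z-scoring (sample SD, ddof = 1) is provided for
rating-scale normalization, but the parameter fit consumes **raw**
ratings.

Per participant, RMSE between ratings and slope·Δ(p_switch, C) + intercept
is minimized by SLSQP with bounds p_switch, C ∈ [0,1], slope ∈ [−2000,
2000] rating-units/nat, intercept ∈ [0,100] (slope/intercept bounds are
generous defaults; unstated in the source), from 5 random starting points
drawn uniformly within bounds; the best restart wins. Δ vectors are
memoized on (p_switch, C) since the optimizer perturbs one coordinate at
a time. Cohort runs skip (with a log record) participants whose every
restart fails rather than aborting.

The synthetic-rater generator emulates ratings that are exactly linear in
delta surprisal plus i.i.d. Gaussian noise, clipped to the slider range.
It deliberately omits sequence effects, anchoring, drift, and
heteroscedasticity of real slider data, so a green recovery test
establishes identifiability of the fitting pipeline under the model's own
assumptions — not robustness to model misspecification. Recovery is
evaluated on a 60-stimulus battery generated like the rating study's two
sets (30 delta-surprisal targets in −0.047..0.093, 30 syncopation targets
in 0..18): with only the nine reference rhythms the RMSE surface is
nearly flat in C at realistic noise, and since the true C = 1 sits on a
bound, estimation error is one-sided and the cohort median is biased low;
with the 60-stimulus battery (matching the study design) medians recover
the truth to within ±0.05.

## Numerical notes and limitations

- Filtering is vectorized across streams (one Python loop over time
  steps); exact, no approximations beyond the 1e-12 probability floor.
- Determinism: all stochastic components take a `numpy.random.Generator`
  or integer seed; identical seeds give bitwise-identical outputs.
- The model assumes known phase and tempo, a single fused input stream,
  binary onsets (no velocity/timbre/microtiming), and a single candidate
  meter (4/4 at 32nd granularity). Inference over competing meters,
  phase/tempo, and separate motor-feedback streams are out of scope.
- The syncopation index is undefined for all-rest patterns (raises).
- `fit_participant` is a local optimizer with restarts; for pathological
  rating profiles the global minimum is not guaranteed.
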