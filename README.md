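# plumm

Why do some rhythms make us want to move while others leave us still? A
prominent predictive-processing account holds that the pleasurable urge to
move to music (PLUMM, closely related to "groove") peaks for moderately
syncopated rhythms — the inverted-U relation between rhythmic complexity
and the urge to move. `plumm` implements a minimal Bayesian process model
of this account for researchers in music cognition and computational
neuroscience: it infers, step by step, whether a rhythm is generated by a
*metered* or an *unmetered* template, quantifies precision-weighted
prediction error as surprisal, and asks how much of that error could be
discharged by moving along with the beat.

## The model

A rhythm is a binary onset stream on a 32nd-note grid (32 positions per
4/4 measure, tiled over 4 repeats). The listener entertains a belief
P(metered) updated at every grid step t:

- **Observation likelihoods.** Under the metered template an onset occurs
  at position t with probability λ_m(t), patterned by the
  Longuet-Higgins & Lee metric hierarchy (downbeat strongest, 32nd-note
  positions weakest); under the unmetered template with constant
  λ_u = mean(λ_m).
- **Update.** P(obs,t) = prior·P(obs|m) + (1−prior)·P(obs|u); the
  posterior follows by Bayes' rule; the next prior allows a regime switch
  with probability `P_switch`:
  prior(t+1) = post·(1−P_switch) + (1−post)·P_switch.
- **Surprisal.** S(t) = −ln P(obs,t) (nats); the per-rhythm summary is the
  mean over the stream.
- **Metrical contrast** C ∈ [0,1] shrinks λ_m about its mean
  (λ_m ← λ̄ + C·(λ_m−λ̄)), controlling how sharply strong and weak
  positions are distinguished.
- **Delta surprisal** Δ = S̄(rhythm) − S̄(rhythm + quarter-note metronome):
  the metronome stands in for the sensory feedback of on-beat movement, so
  Δ measures the prediction error that moving would resolve. Across the
  nine reference rhythms Δ traces the inverted U that rating studies show.

Syncopation is scored with the summed LHL index: each rest on an
eighth-note-or-stronger position that outweighs the preceding note
contributes the weight difference.

The package also provides the constrained stimulus generator used to build
rating-study sets (five onsets, onset on the downbeat, no adjacent
32nd-note onsets, rejection-sampled to hit target Δ or syncopation
values), and per-participant fitting of (P_switch, C, slope, intercept) to
0–100 urge-to-move ratings by bounded SLSQP with random restarts, plus a
synthetic-rater simulator for parameter-recovery studies.

## Worked example

```sh
$ plumm fixtures --out fixtures.json
low1   low    x...x...x.......x.......x....... sync=0
...
med1   medium x.....x.....x.......x...x....... sync=4
...
high3  high   x..x...........x...x...........x sync=18

$ plumm --quiet surprisal fixtures.json --out-dir out
rhythm  metronome    plain  delta_surprisal
 high1   0.523492 0.457524        -0.065967
 high2   0.523913 0.458072        -0.065841
 high3   0.523799 0.459437        -0.064363
  low1   0.174872 0.174872         0.000000
  low2   0.174848 0.174848         0.000000
  low3   0.174860 0.174860         0.000000
  med1   0.241734 0.351214         0.109481
  med2   0.295833 0.436854         0.141021
  med3   0.283179 0.388325         0.105145
```

Read: mean surprisal (nats per grid step) without the metronome rises with
complexity (0.175 → ~0.39 → ~0.46). The metronome leaves simple rhythms
untouched (their quarter positions already carry onsets, Δ = 0), resolves
a large share of the error in clave-type rhythms (Δ ≈ +0.10..0.14), and
*increases* error for highly syncopated rhythms (Δ ≈ −0.065): the
inverted U. Per-step traces land in `out/trace.csv`, summaries in
`out/summary.csv`, and the resolved configuration in `out/config.yaml`.

The same pipeline is available from Python:

```python
from plumm import build_templates, ModelParams, fixtures, delta_surprisal

templates = build_templates()          # λ_m from the LHL hierarchy, C = 1
params = ModelParams(p_switch=0.01)
son = fixtures()[3]
print(delta_surprisal(son, templates, params))   # 0.10948...
```

Other subcommands: `sweep` (parameter grid + facet plot), `generate`
(targeted stimulus sets with a manifest), `simulate` (synthetic raters),
`fit` (per-participant parameter estimation), `report` (cohort medians,
histograms, predicted-Δ tables). All honor `--seed` and `--config`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-encodes the nine reference rhythms, scores each with the summed LHL
syncopation index (eighth-note-or-higher rest rule), and writes the
maximum (`t1`) and minimum (`t2`) across the set as JSON.

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
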