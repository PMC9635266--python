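# recurlang

Categorical recurrence quantification of annotated child-speech transcripts.

Clinicians and language researchers who study early language — particularly
in autistic children, whose spoken-language profiles range from minimally
verbal to highly fluent — need measures of *productivity*: does a child
creatively combine words and grammatical units, or repeat the same material?
Aggregate measures such as MLU (mean length of utterance, in morphemes)
conflate the two.  This package quantifies repetition directly, treating a
child's transcript as a categorical time series and applying recurrence
quantification analysis (RQA) at two levels (lexical items vs. grammatical
units) within two phrase classes (noun-related vs. verb-related).

## The measures

Each transcript is coded into four integer series — (noun, verb) ×
(lexical, grammar).  Positive symbols identify target material (exact word
forms at the lexical level; codebook category codes, one per annotated
grammatical unit, at the grammar level); everything outside the target class
is masked with a unique non-repeating negative id so it can never recur.
For a series *s₁ … s_N* the recurrence plot marks every ordered pair
(i, j), i ≠ j, with *sᵢ = sⱼ*.  The line of identity (lag zero) is excluded.

- **Recurrence rate** — RR = 100 · |points| / (N² − N)
  = 100 · Σ_c n_c(n_c − 1) / (N(N − 1)), a closed function of symbol
  frequencies n_c: how much *individual* items repeat.
- **Percent determinism** — %DET = 100 · (points on diagonal runs of ≥ 2
  consecutive recurrent cells) / |points|: how much repetition occurs in
  *sequences* (repeated constructions), undefined when the plot is empty.
- **Permutation surrogates** — because RR is frequency-determined, shuffling
  a series preserves it exactly; %DET is therefore tested against 100
  frequency-preserving shuffles per series, flagging children whose observed
  %DET exceeds the 95th percentile of their own chance baseline.
- **Models** — a long table (4 rows per child) feeds a 16-term factorial OLS
  of each metric on effect-coded Type (±0.5) and Level (±0.5), MLU, total
  utterances, and ADOS calibrated severity (2–10), with all two- and
  three-way interactions and Tukey post-hoc cell contrasts.

Because no clinical transcripts ship with the package, a synthetic-transcript
generator (`recurlang.simulate`) produces annotated cohorts with tunable
grammatical repetitiveness (template reuse probability ρ), lexical
repetitiveness (word reuse probability w), utterance counts, MLU, and a
severity score linked to ρ — see `docs/methods.md`.

## Worked example

```python
from recurlang import encode, count_symbol, count_ngram, rqa_profile
from recurlang.examples import frog_excerpt, ball_excerpt

frog = frog_excerpt()          # three "frog" utterances, fully annotated
s = encode(frog, "noun", "grammar")
print(count_symbol(s, "determiner"))      # 5  (determiner used five times)
print(count_symbol(encode(frog, "verb", "grammar"), "verb"))  # 7

ball = ball_excerpt()
b = encode(ball, "noun", "lexical")
print(count_ngram(b, ["the", "ball"]))    # 2  ("the ball" repeated twice)
print(count_ngram(b, ["the", "balls"]))   # 3  ("the balls" three times)

prof = rqa_profile(frog)
r = prof[("noun", "grammar")]
print(round(r.rr, 2), round(r.det, 2))    # 7.61 100.0
```

The last line says that 7.61% of admissible recurrence-plot cells for the
noun-grammar series are recurrent, and every recurrent point lies on a
repeated sequence (the child keeps re-using the same determiner–noun
frames, e.g. "the frog(s)", "the city").

## The analysis pipeline

Numbered drivers under `analysis/` run the full study on a simulated cohort
(each writes its tables under `results/`):

```
python analysis/01_simulate_cohort.py    # 51 annotated transcripts + metadata
python analysis/02_descriptives.py      # MLU, TTR, token/type counts
python analysis/03_rqa_metrics.py       # RR / %DET per child and series
python analysis/04_permutation_tests.py # surrogate tests + cohort summary
python analysis/05_models.py            # factorial OLS + Tukey contrasts
python analysis/06_example_plots.py     # recurrence / sequence plots
```

The same stages are available as a library call (`recurlang.run_pipeline`)
and as a CLI (`recurlang simulate|validate|describe|encode|rqa|permute|model|run`).

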