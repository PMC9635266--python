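# Methods

## Coding transcripts into symbol series

Input transcripts are pre-annotated: one row per spoken token with the
noun-related and verb-related grammatical units an annotator assigned
(automatic morphological tagging is out of scope — the package consumes
annotation, it does not produce it).  Two fixed codebooks ship as versioned
YAML: 14 noun-related categories (10 syntactic — common noun, proper noun,
pronoun, determiner, adjective, adverb, gerund, wh-question, number,
preposition — and 4 bound-morphological — plural, possessive, superlative,
comparative) and 16 verb-related categories (5 syntactic — verb, adverb,
preposition, negative, infinitive — and 11 bound-morphological — person
markers, participles, tenses, modal, progressive, copula, auxiliary).
Verb coding deliberately omits noun-phrase structures, so it is
"verb-related" rather than a full verb phrase.

Each child yields four series — (noun, verb) × (lexical, grammar):

- **Lexical level**: one symbol per token; tokens carrying at least one unit
  of the target type get the positive id of their normalized surface form.
  Identity is exact repetition: surfaces are lower-cased, multiword items
  arrive pre-joined with underscores, and inflected forms are different
  words (`ice_creams` ≠ `ice_cream`).
- **Grammar level**: a target token expands into one symbol per annotated
  unit, in annotated order, using the codebook code.

Everything outside the target class — including unintelligible tokens
(surface `xxx`) — becomes a unique negative mask id, one per out-of-class
*token* also at the grammar level (the printed annotation convention treats
each non-target word as a single opaque slot).  Unique masks occupy time
positions but can never recur, so downstream metrics are provably invariant
to any bijective re-randomization of mask ids (asserted as a test); we
assign −1, −2, … so emitted files are reproducible.  Utterances are
concatenated with no boundary symbols, so deterministic lines may span
utterance boundaries.

MLU counts morphemes: each intelligible token contributes 1 (its free
morpheme) plus one per attached bound-morphology unit (so *frogs* =
noun + plural = 2).  Unintelligible tokens contribute neither morphemes nor
type/token counts (the convention of standard language-sample tooling).
Cohorts are filtered at a 20-utterance minimum before analysis.

## Recurrence quantification

For a series of length N, the recurrence plot marks ordered pairs (i, j),
i ≠ j, with equal positive symbols.  The line of identity is trivially fully
recurrent (its recurrent fraction is exactly 1 for any series) and is
excluded; the RR denominator is therefore N² − N.  %DET is the share of
recurrent points lying on diagonal runs of ≥ `min_len` consecutive recurrent
cells; `min_len` defaults to 2 and is configurable.  No Theiler window
beyond the excluded identity line is applied.  Both triangles of the
symmetric plot are counted; mirror lines scale the %DET numerator and
denominator identically, so results equal a one-triangle computation
(asserted as a test).  A series with no recurrent points has *undefined*
%DET, propagated as missing and excluded from cohort %DET summaries — this
is what produces reduced per-measure n in cohort reports.  Maxline (longest
diagonal line) is computed alongside as an optional metric.

Two routes compute the metrics: a definition-faithful point-set route
(explicit pair sets, run scanning per lag) used for small series and plots,
and a frequency-grouped fast route that never materializes the N × N matrix
(for `min_len` = 2 a recurrent cell lies on a line iff one of its diagonal
neighbours is recurrent, evaluated per symbol group in O(|points|)).  The
test suite asserts exact agreement between the two routes and against an
independent brute-force full-matrix reference.

## Permutation surrogates

Categorical RR equals 100 · Σ n_c(n_c − 1)/(N(N − 1)), a function of symbol
frequencies only, so any frequency-preserving shuffle leaves it unchanged —
surrogate testing is informative only for sequence-sensitive metrics,
i.e. %DET.  Each series gets P = 100 uniform random permutations of its full
masked symbol multiset (masks stay unique, so surrogate length, frequencies
and point count match the original exactly, and surrogate %DET is defined
whenever the observed one is).  The upper-tail empirical p is the proportion
of surrogates with %DET ≥ observed; ties count toward the null
(conservative).  The significance criterion flags observed %DET above the
95th surrogate percentile.  The published phrasing mixes a one-sided
proportion rule with "upper and lower bounds of the 95th percentile"; the
one-sided reading is the default and a `two_sided` tail (2.5th/97.5th
bounds) is available, so neither reading is guessed away.  Per-series seeds
derive from the cohort seed plus child/measure indices and are recorded in
the outputs.

Calibration: on i.i.d. null series the rejection rate at the criterion is
bounded by ~5% plus Monte-Carlo error, and sampled p-values converge to
exhaustive-enumeration values for tiny series (both under test).

## Linear models

The long table has four rows per child — (type, level) cells joined to the
child's MLU, total utterances and ADOS calibrated severity score (2–10).
Type and Level are effect-coded ±0.5 (noun/grammar positive), which makes
them exactly orthogonal to covariates in a balanced table and puts "main
effects" at the grand mean.  Each response (RR, %DET) is fit by OLS on the
16-term design: intercept, 5 main effects, Type:Level, six
factor-by-covariate two-way terms, and three three-way terms; with n
children, residual df = 4n − 16 (204 rows and 188 df at n = 51).  Rows with
undefined %DET are dropped listwise from the %DET model only.  Rows are
treated as independent observations — that is what the 4n − 16 residual df
implies — and a per-child random-intercept variant is available behind a
flag for sensitivity analysis, as is mean-centering of covariates
(covariates enter raw by default).  Post-hoc comparisons of the four cell
means use Tukey's HSD over the six pairwise contrasts, with t computed from
the pooled one-way MSE and df = rows − 4.

## Synthetic cohorts

The generator exists because no clinical transcripts are public; it emulates
the observable signatures of the study population, not the cognition behind
them:

- **Utterance counts** per included child are uniform on 20–260, matching
  the published cohort range; a `low_talker_fraction` (default 0.08) of
  children draw 5–19 utterances to exercise the inclusion filter.
- **Grammatical repetitiveness**: each child owns a library of
  `template_library_size` (default 6) phrase frames with guaranteed
  contiguous noun-phrase and verb-complex chunks
  (determiner-[adjective]-noun, modal/auxiliary-verb, …).  At each utterance
  the child reuses a library frame with probability ρ, else improvises a
  fresh template whose class sequence comes from a sticky Markov chain
  (persistence 0.65 over noun/verb/filler classes) with categories drawn
  from child-speech-weighted inventories.  Reused frames create repeated
  multi-unit category sequences; improvised templates share sub-sequences
  only by chance.  The guaranteed chunk structure of library frames is what
  makes grammar-level %DET a reliable monotone readout of ρ (Spearman ≥ 0.8
  across a ρ ~ U(0,1) cohort, under test) instead of a lottery over template
  composition.
- **Lexical repetitiveness**: each slot's word is a previously used word of
  that category with probability w, else a Zipf(s = 1.1) draw from the
  category vocabulary.  Closed classes (5 determiners, 12 pronouns, 6
  modals, …) are small and open classes large (150), so lexical RR is
  nonzero at realistic vocabularies; `open_class_vocab=None` switches to an
  unbounded vocabulary in which every non-reused draw is a new word (with
  w = 0 lexical RR is exactly 0).
- **MLU** emerges from per-child mean utterance length (uniform 2.0–5.5
  tokens) plus attached morphology; realized cohort means fall in the
  plausible 2–9 morpheme band.
- **Severity** = 2.5 + 5ρ + N(0, 1.2), clipped to [2, 10] — a positive
  repetitiveness–severity linkage that the model stage recovers in sign.
- An **echolalia** knob re-emits the previous utterance verbatim with
  probability e (default 0; echolalia is not modeled, only supported).

Defaults were chosen once against the published cohort descriptives
(utterance range, MLU band, RR magnitudes of roughly 0.3–9%) and the
generator is deterministic given its seed (per-child streams spawn from the
cohort seed; fixed seeds give byte-identical files).  What passing tests on
synthetic cohorts show is that the *pipeline* measures what it claims —
recovering planted repetitiveness, calibrated false-positive rates,
planted regression coefficients.  They do not show that real child speech
follows the template mechanism: English word order, semantics, speaker
interaction, and annotation noise are all absent, and the generator's
severity linkage is a stipulated stand-in, not a clinical claim.

## Numerical and reporting choices

- Symbol series use int64; metric comparisons in tests are exact
  (`abs=1e-12`) because all quantities are ratios of integer counts.
- Empirical p-values use the "≥ observed" convention without the +1
  correction; with P = 100 the smallest reportable p is 0.  The percentile
  criterion uses linear-interpolated percentiles (numpy default).
- The acceptance script scales its cohorts to desk size (50–51 children,
  100 permutations, 1,000 oracle series) — the same sizes the analysis
  drivers use.
- Degenerate inputs: empty cohorts and zero-children simulations return
  empty outputs; N < 2 series raise for RR; all-masked series return
  RR = 0 with undefined %DET; a constant series has exactly one
  permutation arrangement and p = 1.

## Known limitations

- The coding stage trusts its annotations; inter-annotator disagreement
  (e.g. "where" codable as pronoun or wh-question) is an upstream matter —
  both labels are accepted.
- Cohort-level published regression coefficients are not reproducible
  without the original clinical transcripts; the model stage is validated
  by simulation (planted-coefficient recovery) instead.
- The post-hoc df convention (rows − 4 cells) is the standard one-way
  Tukey bookkeeping; alternative conventions exist and would change t
  values slightly, not the adjusted-p ordering.
- Cross-speaker recurrence, block surrogates, and continuous-signal RQA
  (embedding, radius) are out of scope.
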