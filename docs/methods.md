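# Methods

This note documents the models and procedures implemented in `phonogrow`,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Staged lexica and cleaning

A staged lexicon is the cumulative vocabulary of a second-language learner
at six age-of-acquisition (AoA) stages mapped from the CEFR proficiency
levels A1–C2.  Stage membership is cumulative — a form belongs to every
stage from its AoA onward — and each phonological form carries exactly one
AoA.  Cleaning applies three rules:

* **Homophone merging.**  Rows sharing one phonemic form are collapsed into
  a single entry whose raw frequency rate is the arithmetic mean of the
  members' and whose AoA is the earliest member stage (a form is "known"
  once any of its spellings is learned — the corpus does not say which
  spelling licensed the form, so the earliest stage is the only reading
  consistent with cumulative membership).
* **Frequency transform.**  `freq_log = log10(freq_raw + 1)`.  Base 10 is
  used throughout; the +1 offset accommodates zero-frequency forms.
* **Inventory filtering.**  Transcriptions are token sequences over a
  declared segment inventory; multi-character phone symbols (affricates,
  long vowels, rhotic vowels) must be recoded upstream to unique single
  tokens so segment-level and character-level edit distance coincide.  Rows
  containing unknown symbols are dropped and counted in a drop report —
  ingestion never silently repairs a transcription.

Display rounding is one decimal, round-half-to-even (58.65 → 58.6).
Vocabulary accounting reports both raw row counts and post-merge/post-drop
entry counts, since the two can legitimately differ.

## Neighbor detection

Two word forms are phonological neighbors iff their transcriptions are at
segment-level Levenshtein distance exactly 1 (one substitution, deletion, or
addition).  The scan prunes candidate pairs by length — only pairs with
`|len(a) − len(b)| ≤ 1` can be neighbors — and uses an O(len) specialized
check; both steps are provably output-equivalent to the full quadratic scan
with the general DP distance, and the test suite asserts that equivalence on
random lexica.

## Phonetic distance (edge weights)

Edge weights come from a dynamic-programming alignment in the style of
Kondrak's ALINE.  Segments carry numeric feature vectors (place, manner,
syllabicity, voice, nasality, laterality, aspiration, retroflexion, and for
vowels height, backness, rounding, length) with per-feature salience
weights; the pairwise difference δ(p, q) is the salience-weighted sum of
absolute feature differences, computed over the consonantal feature set when
both segments are consonants and over the vocalic set otherwise.  Alignment
operations score

* substitution: `C_sub − δ(p, q) − V(p) − V(q)`,
* skip: `C_skip` (a penalty),
* 1:2 expansion: `C_exp − δ(p, q1) − δ(p, q2) − V(p) − max(V(q1), V(q2))`,

with `V(p) = C_vwl` for vowels and 0 for consonants.  Defaults are
`C_sub = 35, C_exp = 45, C_vwl = 10, C_skip = −10`.  The published
parameterization lists a skip "score" of 10; as a reward that value lets two
skips (20) outscore an identical vowel match (35 − 2·10 = 15), so identical
words would not align with themselves.  The skip cost is therefore a penalty
here, which restores the defining property that the distance is 0 exactly
for segmentally identical forms.

The raw similarity grows with word length, so it is normalized to a distance
`d = 1 − score(a, b) / max(selfscore(a), selfscore(b))`, clamped to [0, 1].
The larger self-alignment score is used rather than "the longer word's":
a vowel-heavy longer word can have a *smaller* self score than a short
consonantal word, and the max keeps the distance bounded and symmetric.
This normalization is the one place where exact numeric agreement with other
ALINE implementations is not expected; orderings (closer vs. more distant
neighbors) are preserved, and only orderings are interpreted downstream.
The rescaled integer edge weight is `round_half_up((1 − d) · 100)` — 100 for
homophones, 0 at maximal distance.

The feature table ships as versioned JSON
(`src/phonogrow/data/feature_table.json`, 38 segments: a lowercase ASCII
core plus common IPA symbols) and is fully overridable.

## Networks and node statistics

The stage-*s* network has the cumulative stage-*s* vocabulary as nodes and
weighted one-segment edges.  Because the edge relation does not depend on
the stage, stage networks are nested, and the implementation builds them as
induced subgraphs of the final network (computing each phonetic weight
once).  Self-loops are impossible (the neighbor relation is irreflexive) and
edges are a set (no parallels).

* **Degree assortativity** is the Pearson correlation between the degrees of
  connected node pairs with each undirected edge counted in both
  orientations (the standard degree-correlation convention).  Zero variance
  in endpoint degrees (a cycle, a single edge class) makes the correlation
  undefined, and the function raises rather than returning 0.
* **Hermit fraction** for a stage is the share of words uniquely acquired at
  that stage that are isolated in a given network.  Passing the final-stage
  network — the default reading used by the pipeline — yields the share of
  entrants that never experience growth; passing the entry-stage network
  yields isolation at acquisition time.  The function takes the judging
  network explicitly so both readings are expressible.

## Growth spurts and dependent variables

A word entering at stage *a* has `7 − a` spurts; spurt 1 comprises the
neighbors already present at entry (forced by the worked example in which a
word's 8 entry-stage neighbors count as its first spurt), and spurt *j* > 1
the neighbors gained from stage *a*+*j*−2 to *a*+*j*−1.  Gains are
conserved: per-word spurt gains sum to the final degree, and proportional
gains to 100%.

* **Proportional degree gain** = gain at the spurt / final (stage-6) degree
  × 100.  Only words with positive final degree ("growing words") enter the
  analysis.
* **Saturation** = cumulative degree / L1 neighborhood density × 100.  Words
  with no L1 benchmark are excluded from the saturation analysis (signalled,
  not silently zeroed).  When the L2 lexicon is a subset of the L1 reference
  — guaranteed for synthetic data — saturation never exceeds 100%.
* **Average weighted degree per neighbor.**  The default ("cumulative")
  convention divides the cumulative weighted degree by the cumulative
  neighbor count after the spurt; a no-growth spurt therefore repeats the
  previous neighborhood average (352/7 = 50.3 twice, then 704/12 = 58.7 in
  the worked trajectory).  An alternative "new" convention — weight added
  per neighbor added during a growth spurt — is exposed via `mode="new"`;
  the two differ in what a growth spurt measures (whole-neighborhood average
  vs. the new cohort's average), and the cumulative reading is the default
  because it is the one the worked numbers instantiate.  The count model
  receives this DV rounded to the nearest integer.

**Growth patterns** (words with ≥ 3 spurts, i.e. early acquirers):
*initial* — growth only at the entry spurt; *continuous* — growth at every
spurt; *delayed* — zero growth in the first one or two post-entry spurts and
growth in every remaining spurt (longer dormancy is *other*); *other* — the
rest.  The labels partition all eligible trajectories.

## Statistical models

Model rows are word × spurt, nested within one AoA per word.  Spurt and AoA
enter as treatment-coded factors against level 1 (matching coefficient
tables that report "Spurt 2", "AoA 2", ... rows); frequency (log) and length
are continuous.

* **Proportional models.**  The two proportion DVs are squeezed into (0, 1)
  with the Smithson–Verkuilen transform `(y(n−1)+0.5)/n`, where *n* is the
  fitted table's row count (recorded in the table metadata).  Fits are
  binomial GLMs with logit link and Pearson-χ² dispersion — i.e.
  quasi-binomial.  Quasi-likelihoods have no true likelihood, so McFadden's
  R² = 1 − llf_model/llf_null is computed from the underlying binomial
  log-likelihood against an intercept-only fit; it is 0 for the null model
  and non-decreasing under added covariates.
* **Count model.**  Zero-inflated negative binomial (NB2, log link) with a
  logistic zero-inflation component on the same design.  The likelihood is
  multimodal: from poor starts the optimizer can park all zeros in the count
  component (inflation intercept → −∞ with inflated dispersion).  The fit
  therefore runs from two starts — the default, and an informed start using
  a plain NB fit for the count part plus the observed excess-zero fraction
  for the inflation intercept — and keeps the better optimum, preferring one
  with a finite covariance.  Degenerate estimates (e.g. an inflation level
  whose cell contains no zeros) are reported as-is with their blown-up
  standard errors, never suppressed.
* **Post-hoc spurt comparisons.**  Estimated marginal proportions per spurt
  are response-scale predictions averaged over AoA levels at mean
  covariates.  Pairwise differences use delta-method standard errors under
  the dispersion-scaled coefficient covariance, with family-wise adjustment
  from the studentized-range distribution over the spurt levels — the
  correction the "Tukey" adjustment applies to all pairwise contrasts of k
  means.
* **Effect sizes.**  Standardized odds ratios multiply continuous
  coefficients by the covariate's SD before exponentiation; categorical
  levels are exponentiated as-is.  Labels follow the conventional
  odds-ratio thresholds (1.68 / 3.47 / 6.71 for small / medium / large),
  applied to 1/OR when OR < 1.
* **Diagnostics.**  Dispersion and variance-inflation factors are reported
  with every fit.

## Synthetic staged lexica

The generator emulates the statistical structure the analysis assumes, so
every downstream stage is testable without a learner corpus.

* **Form pool.**  CV/CVC/CVCC strings (optional onset + vowel rime) over a
  small inventory; shared rimes make one-segment neighborhoods arise
  naturally.  The pool plays the role of the full L1 lexicon: a word's pool
  degree is its L1 neighborhood density, and because the staged lexicon
  samples from the pool, saturation is bounded by 100% by construction.
* **Staged acquisition with obsolescence.**  Words are drawn one at a time.
  A candidate's attachment score sums, over its already-acquired neighbors
  *u*, `(deg(u)+1)^γ · (exp(−α·age(u)) − κ)`, where κ is the mean aging
  factor over the possible node ages 0–5 and γ is the preferential-
  attachment exponent.  Same-stage neighbors (age 0) push a candidate above
  the no-neighbor baseline — acquisition comes in phonologically similar
  bursts, concentrating a word's growth into its entry spurt — while aged
  neighborhoods suppress it.  The centering makes α = 0 the exact
  no-obsolescence null: every attachment term vanishes and, with the static
  biases off, word arrivals are exchangeable across stages, so expected
  per-spurt gains are equal.  Static biases (length bias λ decreasing over
  stages, density bias η on pool degree) make early-acquired words shorter,
  denser-neighborhood forms, as in real learner vocabularies.
* **Frequencies** follow a Zipf law over acquisition order (default
  exponent 1) with lognormal noise (σ = 0.2), so early words are on average
  more frequent.
* **Defaults.**  Stage sizes (60, 90, 134, 166, 95, 94) preserve the rising-
  then-falling unique-words profile of staged learner vocabularies at about
  a tenth of corpus scale, keeping the default pipeline in seconds; pool
  inflation 2.5; α = 1.5 (strong entry-spurt dominance); γ = 1; seed
  recorded in every output.  The generator emits the same TSV schema the
  reader ingests plus a ground-truth JSON (per-word spurt schedule, pattern
  labels, L1 densities) computed from its own bookkeeping, which the test
  suite checks against the pipeline's independent recomputation.

**What the generator does not emulate.**  The CV(C(C)) pool is far denser
than a real phonological lexicon: nearly every synthetic word acquires a
neighbor eventually, so hermit fractions run a few percent rather than the
tens of percent typical of natural lexica, and "continuous" growth patterns
are rare because later spurts are aggressively suppressed at the default α.
There is no phonotactics, no morphology, no semantics, and no part of
speech.  Passing tests on synthetic data therefore demonstrate correctness
of the metrics and models and qualitative reproduction of the growth
dynamics (entry-spurt dominance, positive assortativity, early words
shorter/more frequent/denser), not quantitative agreement with any natural
learner corpus.

## Numerical choices

* Segment edit distance and the alignment DP are exact (integer counts,
  float feature sums); the alignment is property-tested against a full
  recursive enumeration of alignments.
* Percentages are carried at full precision internally and rounded only for
  display (1 dp, half-to-even; the saturation examples print truncated
  integers as in conventional usage).
* The Smithson–Verkuilen *n* is the fitted table's row count; at n = 1 the
  transform degenerates to ½ for any input, which is the correct limit of
  the formula.
* Assortativity on graphs with constant endpoint degree raises; pipelines
  record it as null rather than coercing to 0.
* All randomness flows from one `numpy` Generator seeded from the
  user-facing seed; identical configurations produce byte-identical
  reports (timestamps excluded by design).

## Known limitations

* The phonetic distance is a faithful member of the ALINE family but not a
  numeric clone of any particular implementation (normalization differs; see
  above).  Only orderings and the [0, 1]/[0, 100] contracts are guaranteed.
* The quasi-binomial McFadden R² inherits the binomial working likelihood;
  it is a descriptive fit index, not a likelihood-ratio statistic.
* ZINB standard errors come from the numerical Hessian at the optimum; in
  cells where the inflation component is empirically degenerate the Wald
  statistics are meaningless (reported anyway, flagged by their magnitude).
* The generator's aging kernel freezes degrees and the aging factor at
  stage entry within a stage; this is a modelling simplification, not a
  fitted quantity.
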