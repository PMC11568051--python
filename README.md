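# phonogrow

Growth dynamics of staged second-language phonological networks.

`phonogrow` is for researchers in psycholinguistics and cognitive network
science who study how a learner's mental lexicon wires itself up.  In a
phonological network the nodes are word forms and an edge joins two words
that differ by exactly one segment (substitution, deletion, or addition —
*bat*/*pat*, *eye*/*day*-style neighbors).  Given word lists staged by
age-of-acquisition (AoA stages 1–6, the CEFR proficiency ladder A1–C2), the
package:

* cleans and normalizes the lexica (homophone merging with averaged
  frequency rates, `log10(x+1)` frequency transform, phoneme counting);
* detects one-segment neighbors by segment-level Levenshtein distance and
  weights each edge with a feature-based phonetic similarity: a dynamic-
  programming alignment in the ALINE family scores segment pairs on weighted
  phonetic features, yielding a distance *d* ∈ [0, 1] that is reverse
  rescaled to an integer edge weight `round((1 − d) · 100)`;
* tracks every word's **growth spurts**: a word entering at stage *a* has
  7 − *a* spurts, spurt 1 being the neighbors present at entry and spurt
  *j* > 1 the neighbors gained between stages *a*+*j*−2 and *a*+*j*−1.
  From the spurts come three dependent variables — proportional degree gain
  (gain / final degree × 100), **saturation** (cumulative degree as a
  percentage of the word's neighborhood density in the full first-language
  lexicon), and the average weighted degree per neighbor — plus a growth
  pattern label (initial / continuous / delayed / other);
* fits the three statistical models of those DVs on word × spurt rows:
  quasi-binomial logit GLMs for the two proportions (after the
  Smithson–Verkuilen squeeze `(y(n−1)+0.5)/n`) and a zero-inflated negative
  binomial regression for the count DV, each with the linear predictor
  `Spurt + AoA + Frequency(log) + Length`, reporting dispersion, VIFs,
  McFadden's R², standardized odds ratios, and Tukey-adjusted pairwise spurt
  contrasts re-gridded to the response scale;
* computes network statistics per stage: degree assortativity (Pearson
  correlation of degrees over edge endpoints) and lexical-hermit fractions;
* ships a **synthetic staged-lexicon generator** with a tunable node-aging
  (obsolescence) strength α, so the whole pipeline is testable without any
  proprietary learner corpus: at α = 0 word arrivals are exchangeable across
  stages, while larger α concentrates each word's growth into its entry
  spurt.

## Worked example

The miniature lexicon from `make_worked_example_fixture()` contains three
designated words whose trajectories illustrate the metrics:

```python
>>> import phonogrow as pg
>>> pg.worked_example_numbers()
{'degree_gain_spurt1_pct': 50.0,
 'degree_gain_spurt2_pct': 18.8,
 'cumulative_gain_after_spurt2_pct': 68.8,
 'saturation_spurt1_pct': 13.333333333333334,
 'saturation_spurt2_pct': 13.333333333333334,
 'saturation_spurt3_pct': 26.666666666666668,
 'saturation_max_pct': 33.33333333333333,
 'avg_weighted_degree_spurt1': 50.3,
 'avg_weighted_degree_spurt2': 50.3,
 'avg_weighted_degree_spurt3': 58.7,
 'homophone_mean_freq': 58.6}
```

Reading the numbers: a word that ends with 16 neighbors after gaining 8 at
entry and 3 in its second spurt has spurt gains of 50.0% and 18.8%
(cumulatively 68.8%); a word with 15 neighbors available in the L1 lexicon
that knows 2, then 2 more, then 1 more of them climbs a saturation ladder of
13.3% → 13.3% → 26.7% up to a maximum of 33.3%; a neighborhood of 7 words with
summed edge weight 352 averages 50.3 per neighbor and, after expanding to 12
words of summed weight 704, averages 58.7; and the homophones *plain*
(frequency rate 21.8) and *plane* (95.5) merge into one phonological form at
58.6.

## Command line

```bash
phonogrow simulate --seed 3 --out fixtures/          # synthetic staged lexicon
phonogrow ingest --lists fixtures/lexicon.tsv --out lexicon.tsv
phonogrow neighbors --lexicon lexicon.tsv --stage 3 --out edges.tsv
phonogrow network --lexicon lexicon.tsv --stage 6 --out net.graphml
phonogrow growth --lexicon lexicon.tsv --out trajectories.tsv
phonogrow fit --table model_table.csv --model degree --out results/
phonogrow run --config run.json                      # full pipeline + report
```

Word lists are UTF-8 TSV with columns `orth, stage, freq, phon, l1_density`;
transcriptions must use single-token segments (recode multi-character
symbols first).  See `docs/methods.md` for the model details and design
choices.

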