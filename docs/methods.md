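# Methods

This note documents the models, contracts and numerical choices behind
`speechmarkers`, and what the synthetic cohorts do and do not show
about real clinical data.

## Tokenization and exclusion rules

Transcripts are whitespace-split; punctuation is peeled off word edges
into separate tokens; sentence indices advance at sentence-final
punctuation (`.` `!` `?` and free-standing ellipsis). Three exclusion
categories never reach the analysis: filled pauses from a configurable
closed list (default "eh", "em", "mmm", "mm", "ah", "ehh"); interrupted
fragments, marked by an ellipsis glued to the word ("hospi…"); and
unintelligible spans (default marker `[inaudible]`). All three
conventions are transcription-markup choices, configurable per corpus.
Everything else with at least one alphanumeric character is a word:
digit tokens (times, dates) count toward the total-word denominator,
as do all stop words. Text is NFC-normalized; Spanish diacritics are
preserved and significant (él/el, sí/si).

## Tagging

The tagger is a contract — any callable from cleaned word streams to
(pos, person) tagged tokens can stand behind it; tagging quality is
measured by `tag_agreement` against reference tags. The bundled
reference tagger is deterministic: a surface-form lexicon first, then
ordered verb-suffix rules. For out-of-vocabulary surfaces only
distinctively verbal endings fire (-aba, -ía, -é, -ó, -aré, -amos,
...); anything else degrades to OTHER/person=none and lowers a coverage
statistic (warning below 0.8). This is sufficient for the closed
vocabularies of the synthetic corpora and for worked examples; it is
not a general Spanish morphological analyzer, and no lemmatization is
performed anywhere (inflections are the person signal).

Person is carried by verbs, pronouns, and possessive determiners
("mi" first, "su" third). The clitic "se" is tagged PRON/third.
Ambiguous imperfect endings are resolved in reading order by (1) the
nearest preceding subject pronoun in the sentence, (2) the nearest
preceding person-marked verb in the sentence, (3) the nearest person
marker in the immediately preceding sentence, (4) a logged third-person
default — third person being the unmarked narrative baseline.
Resolution never alters unambiguous tags.

## Features

* Word-class ratios divide by all words (stop words included,
  punctuation excluded) — the ratio denominator is exactly the cleaned
  stream length, a single source of truth shared with the word count.
* Person ratios divide by first+third marker counts. Second-person
  markers are discarded before the ratio by default (they are rare in
  monologue); a config flag restores them to the denominator. Every
  marker counts individually, including pronoun-verb tandems. With the
  default denominator the two ratios are exactly complementary; see
  the ANOVA note below.
* Lexical property means are token-level (repetitions count), over
  content words (NOUN, VERB, ADJ, ADV), skipping lexicon misses and
  reporting coverage. Zero coverage is an error naming the participant.
* Semantic variability: content words in order, deduplicated globally
  by surface (keep first occurrence; adjacent-only collapsing via
  flag), mapped to embeddings (misses skipped, coverage reported);
  cosine distances between successive vectors (Euclidean via flag);
  sample variance with ddof=1 (population via flag). Fewer than three
  embeddable words yields a missing value, not an error — short or
  perseverative transcripts are data, not failures. Cosine distance
  makes the statistic invariant to global rescaling of the embedding
  table.

## Group statistics

The 2x2 mixed (split-plot) ANOVA is computed by an explicit
sums-of-squares decomposition (Type II under unbalanced groups),
vectorized in numpy because it sits inside Monte-Carlo loops; its
output is verified in the test suite against both a definitional
brute-force oracle and pingouin. Effect size is partial eta squared,
SS_effect / (SS_effect + SS_error); all three effects use (1, N−2)
degrees of freedom.

Degenerate person design: with the default person-ratio denominator
the two within-levels sum to exactly 1 for every subject, so every
subject mean is 0.5 and the between-subject error SS is identically
zero. The group main effect is then 0/0 and is reported as F = 0,
p = 1, np² = 0 with a warning; the within and interaction effects —
the scientifically interpreted ones — are unaffected. Including
second-person markers in the denominator removes the degeneracy.

Tukey HSD runs over the four design cells with a single pooled error
convention: MSE = the mean of the between- and within-subject error
mean squares, error df = N − 2, Tukey–Kramer correction for unequal
cells; post-hoc Cohen's d = mean difference / √MSE. One-tailed t tests
use the pooled variance and pooled-SD Cohen's d; default directions
encode the vocabulary-accessibility hypothesis (patients: higher
frequency and neighborhood, lower length and semantic variability) and
are configurable. FDR (Benjamini–Hochberg, via statsmodels) is applied
within each analysis family — word class, person, properties,
correlation grid — not globally. Outlier screening flags values
strictly beyond 3 sample SDs.

Dunnett's many-to-one test works from summary statistics (mean, SD, n
per group): within-group variance is pooled across all groups
(control included), and the two-sided p-value is estimated from the
equicorrelated multivariate-t max-|T| null by seeded Monte Carlo
(default 1e5 draws; cross-checked against scipy's dunnett on
reconstructed raw samples). The sex comparison is Pearson chi-squared
with Yates continuity correction.

Correlations (Pearson or Spearman, default Spearman) use pairwise
deletion and one FDR family per feature-by-test grid; both
patients-only and patients+controls grids are reported, since either
pooling is defensible for cognitive-severity correlates.

## Classification

Linear-kernel SVM, C = 1 (no tuning — eight features, n = 42), positive
class = patients. Each of the (default 1000) iterations re-randomizes a
stratified 5-fold split; min-max scaling is fit on the training folds
only, so held-out values may map outside [0, 1] — accepted, because the
alternative leaks test information. Per iteration, out-of-fold decision
scores are pooled for one AUC (pooling is the stable choice at n = 42;
AUC is rank-based so uncalibrated scores suffice) and pooled hard
predictions give accuracy, precision, recall, F1 and UAR (macro
recall); means and SDs are taken across iterations. Missing feature
values are imputed with the training-fold median rather than dropping
participants. Feature importance is the mean |coefficient| across all
folds and iterations, scale-comparable thanks to the min-max step. The
generalizability protocol fits scaler and SVM once on the entire main
split and evaluates once on the disjoint hold-out; overlapping
participant ids are a hard error.

## Synthetic cohorts

The generator emulates a three-group routine-description study:
21/21/21 participants in the main split plus 11/11/11 held out,
transcript lengths truncated-normal (means 304.14 / 238.57 / 253.95
words for HC / AD / bvFTD, SD 80, floor 80). Narration is a clause
loop over Subject–Verb–Object–Adjunct templates of a pro-drop
language: subjects realized as dropped pronouns (verb-only person
marker), explicit pronoun-verb tandems (two markers), or third-person
noun phrases; object noun phrases appear with probability
`p_nounslot`; clauses without one take a deictic ADP+ADV adjunct
("por allí") with probability 0.9, which keeps clause length — hence
verb share — approximately independent of the noun slot; imperfect
(-aba) verbs always carry their subject pronoun so the tagger's
agreement rules can resolve them. Content words are drawn from a
synthetic lexicon whose frequencies follow log10 f/million = 4.5 −
s·log10(rank) (s = 1 by default, spanning > 2 decades), with
Poisson-shifted word lengths, neighborhood counts decreasing in
length, and unit-norm embeddings clustered by word class. The
generator emits both raw text (with optional fillers, fragments and
unintelligible marks) and gold tags, so the tagger is testable by
round-trip while features can be computed free of tagging error.

Group effects are parameter offsets from the healthy baseline, scaled
per patient by a latent severity factor (truncated normal, mean 1, SD
0.35). Severity induces within-group correlation between a patient's
affected features — clinically realistic, and it keeps the multivariate
separation closer to what single-feature effect sizes suggest than
independent effects would. Offsets were fixed by the package's
Monte-Carlo bisection calibrator (`calibrate_effect`: common random
numbers, 6000 transcripts per evaluation, |realized − target| d <
0.015 at the calibration seed) against the published effect sizes:
noun-ratio d = −1.145 and frequency d = +1.13 for AD; first-person
d = −0.91 (equivalently third-person +0.91, the ratios being
complementary — a published 0.915/0.91 asymmetry is not representable
under this ratio definition) and frequency d = +0.98 for bvFTD.
Frequency offsets were calibrated jointly with the structural offsets
of their profile, because the structure itself moves word frequency
(fewer noun slots mean more high-frequency deictic adverbs). Cognitive
scores (MoCA, IFS) are drawn from group-typical normal distributions
independently of the linguistic features, giving the correlation stage
a true null.

What passing on synthetic cohorts does not show: real transcripts have
open vocabulary (tagger coverage < 1 and tagging errors near 10%),
discourse-level dependencies between clauses, topic structure in the
embedding stream, and demographic confounds — none of which the
generator models. Synthetic results validate the machinery and its
calibration, not clinical performance.

## Problem sizes in the shipped checks

The test suite and the reproduction script keep Monte-Carlo sizes at
the point of diminishing returns for their assertions: 2000 simulated
null datasets for the p-value uniformity check, 200 seeded cohorts for
interaction power (published power: 0.81), 6–12 cohorts with 40–200 CV
iterations wherever a mean AUC is compared against a band or a closed
form (the binormal oracle AUC = Φ(d/√2)), and 200-iteration CV inside
the reproduction script with averages over 6 independent cohorts for
quantities whose single-cohort sampling error at n = 21 per group is
large (realized d ± ~0.3, AUC ± ~0.08).

## Known limitations

* The reference tagger is intentionally minimal; plug a full
  morphological tagger into the contract for real Spanish.
* Dunnett p-values are Monte-Carlo (SE ≈ 0.001 at 1e5 draws); the
  statistic itself is exact given the summary statistics.
* The generator's grammar is a template grammar: it produces
  distributionally plausible token streams, not fluent Spanish.
* Hold-out AUC at n = 22 has a sampling SD of roughly 0.1; single
  hold-out evaluations are illustrative, not precise.
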