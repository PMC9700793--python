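# Methods

## The measurement problem

Action concepts — verbs denoting bodily movement — depend on motor brain
networks and are selectively vulnerable in Parkinson's disease (PD),
especially in patients without mild cognitive impairment (PD-nMCI), whose
deficits are confined to the action domain; patients with MCI (PD-MCI) show
broader semantic decline. A naturalistic probe of this profile is story
retelling: participants read an action-laden text (AT) and a matched
non-action text (nAT) and retell each in their own words. The question the
package answers quantitatively is: *how strongly does a retelling evoke the
semantic field of the reference story's verbs?*

## The P-RSF metric

For one text condition, let the corpus be the m retellings of that story,
preprocessed into lemma sequences (lowercase → de-accent → drop digit
tokens → drop punctuation → drop stopwords → lemmatize, in that fixed
order). The pipeline is:

1. **Bag-of-words LSA.** The m × v document-term matrix X of raw lemma
   counts is factorized by SVD, X = U Σ Vᵀ, with no centering and no tf-idf
   (raw frequencies are the modeled quantity). The encoding matrix U_kΣ_k
   maps documents to topics and the dictionary matrix V_kΣ_k maps words to
   topics; k is the smallest topic count accumulating 95 % of explained
   variance, where component j explains σ_j²/Σσ². Word vectors are
   dictionary rows (σ-scaled on both sides — the standard LSA term space;
   the choice matters because cosine similarity is not invariant to
   per-side rescaling, so it is fixed once). The SVD sign ambiguity is
   resolved per component by making the largest-magnitude dictionary entry
   positive; all downstream cosines are invariant to this.
2. **Reference verbs.** The original story's verb lemmas that are attested
   in the corpus vocabulary (story order, deduplicated) — n of them. In a
   cross-validated setting "the corpus" is the training fold only.
3. **Verb importance.** w_j = mean cosine similarity between reference verb
   j's vector and every vocabulary word's vector: the weight of verb j's
   semantic field within the field the retellings span. Zero-norm vectors
   contribute similarity 0.
4. **Occurrence matrix.** O[i, j] starts as the exact count of verb j in
   retelling i (verbs found by POS tagging the raw token stream, then
   normalizing the lemmas). Every non-reference verb *token* is assigned to
   its nearest reference verb by cosine similarity (ties → lowest index,
   i.e. story order) and adds max(0, cos) to that column — near-synonyms
   earn partial credit; tokens with no vector earn none. The credit rule is
   configurable (`credit_mode`): `similarity` (default), the unclipped
   `one_minus_distance_raw`, or `none`, because the partial-credit
   arithmetic is a modeling choice worth a sensitivity analysis.
5. **P-RSF.** P = O ∘ w (each column scaled by its importance). A
   retelling's scalar score is the row *mean* — mean rather than sum so
   scores remain comparable across folds whose attested n differs. Lower
   scores = weaker evocation of the target concepts.

## Statistical evaluation

Group contrasts ("tandems": all PD vs HC, PD-nMCI vs HC, PD-MCI vs HC,
PD-nMCI vs PD-MCI) are one-way ANCOVAs on the scalar scores with MoCA and
IFS as covariates (cognitive symptom severity). The group effect uses Type
II sums of squares via model comparison — RSS(intercept + covariates) −
RSS(full) — which for a single factor plus covariates matches common
statistical packages (verified against pingouin to 1e-8 in the tests).
Effect size is partial eta squared, SS_effect/(SS_effect+SS_error), equal to
F·df₁/(F·df₁+df₂) for these single-df contrasts. Constant covariates are
dropped with a warning (the model degrades to a plain ANOVA); rank-deficient
designs are an error naming the collinear columns.

Text-matching checks use an equal-expected chi-square goodness of fit on
count pairs, χ² = Σ(o−e)²/e with e = (a+b)/2, df = 1. Exploratory
correlations (e.g. scores vs UPDRS-III motor severity) use Pearson when both
variables pass Shapiro–Wilk at α = 0.05, Spearman otherwise.

## Classification

Binary tandem discrimination uses an RBF-kernel SVM under
participant-independent nested cross-validation: 5 stratified outer folds
over participants; within each outer training set, a randomized search
(default 50 draws; C log-uniform on [1e-2, 1e3], γ log-uniform on
[1e-4, 1e1]) scored by mean 4-fold inner accuracy; the winner is refit on
the full outer-training set and applied to the held-out fold. The P-RSF
feature extractor is refitted inside every outer fold (vocabulary, LSA
space, reference verbs, importance all train-only), so held-out retellings
cannot shape the semantic space; held-out verbs missing from the training
vocabulary are treated as out-of-vocabulary and earn nothing. Features are
standardized with training-fold statistics inside the model pipeline — an
RBF kernel on arbitrarily scaled columns is not meaningful. Held-out
decision scores are pooled across outer folds into a single ROC/AUC
(Mann–Whitney rank form, ties one half), and confusion matrices are summed;
accuracy, sensitivity (patient class positive), specificity and F-score are
reported as percentages. No resampling or class weighting is applied to
unbalanced tandems; stratification only.

Two benchmark feature sets use a user-supplied pre-trained embedding table
(e.g. Spanish GloVe, word2vec-text or GloVe-text format): per-retelling mean
cosine *distance* of its verbs to each original-story verb, and the mean
embedding of all its preprocessed words. Out-of-vocabulary words are skipped
and counted, never zero-filled (zero vectors distort cosines); a document
with no usable word is excluded with a log record.

## Synthetic studies

The generator emulates the study design so the pipeline is testable with no
external data: two reference stories with disjoint 32-verb inventories; each
participant × condition retains each reference verb independently with
probability set by (group, condition); retained verbs surface as the verb
itself or (rate 0.2) as one of two near-synonym paraphrase tokens whose
latent vector sits at cosine 0.85 to the verb's; Poisson(8) off-field
distractor tokens and interleaved function words complete the text.
Covariates are group-conditional normals (MoCA/IFS means ordered
HC > PD-nMCI > PD-MCI, parameters in `default_pd_scenario`), independent of
retention within group by default; a `confound_covariates` switch couples
them for testing covariate adjustment under confounding. UPDRS-III is drawn
for patient groups only. Tokens are letter-only strings with identity
lemmas and a fixed tag map (the dictionary backend), so no real tagger is in
the loop.

The default scenario encodes the qualitative pattern of interest: HC retain
both texts' verbs at 0.8; PD-nMCI drop selectively on the action text
(AT 0.5, nAT 0.8); PD-MCI drop on both (0.5, 0.55). A null scenario sets
every retention to 0.65. What passing tests show is that the pipeline
*recovers planted effects of this kind and stays at chance when none
exists* — synthetic retellings have none of the morphology, syntax,
disfluency or tagger noise of real Spanish speech, so they validate the
computation, not the clinical effect size.

## Numerical and design notes

- Variance-threshold comparisons use a 1e-12 slack so a cumulative ratio
  equal to the threshold up to rounding counts as reaching it; if the
  numerical rank is exhausted first, the full rank is used and logged.
- Nearest-verb ties break to the lowest reference-verb index; duplicate verb
  tokens credit repeatedly (frequency semantics).
- The whole-corpus fit (`pipeline.score_corpus`) serves descriptive
  statistics; only the fold-refitted path is used for classification.
- Determinism: every stochastic step (simulation, fold assignment,
  hyperparameter draws) flows from explicit integer seeds; identical runs
  produce identical reports.
- Problem sizes in the test suite: effect-recovery checks use 40
  participants per group with 20 replicates (10 for the null scenario), the
  ANCOVA calibration uses 1000 simulated null datasets at n = 60, and oracle
  equivalence uses 50 random corpora of ≤ 6 documents and ≤ 12 words.

## Known limitations

- The bundled rule-based Spanish backend (suffix heuristics + small
  stopword list) is a coarse stand-in for a real tagger/lemmatizer and is
  intended for exploratory runs; analyses of real transcripts should inject
  a proper backend. All quantitative guarantees in the tests run on the
  dictionary backend, where tagging is exact.
- P-RSF scores depend on the training corpus: verbs unseen in a training
  fold earn no credit, so small folds understate scores for idiosyncratic
  vocabulary — an inherent property of corpus-fitted semantic fields.
- The equal-expected chi-square treats each count pair in isolation; it is
  a matching diagnostic, not a corpus-level model.
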