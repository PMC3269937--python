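# Methods

This note documents the models behind `gnbench`, the parameter defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical and design decisions that were genuinely
open.

## TAP-k

A submission run maps each document to a ranked list of identifiers with
confidence scores (higher = more confident; rank order must agree with
non-increasing confidence). For a query with gold-positive count *P* and
cutoff *x*:

* `APC_x` — sum over ranks holding a true positive with score ≥ *x* of the
  precision at that rank, divided by *P*;
* `P_x` — precision at the last rank with score ≥ *x* (0 if nothing
  qualifies while *P* > 0);
* `APCP_x = (P·APC_x + P_x) / (P + 1)`.

The APCP form is the weighted average of `APC_x` and `P_x` with weight
*P* on `APC_x`; the single terminal term penalises retrieving a tail of
false positives below the last true positive, which plain average
precision ignores.

The global cutoff for TAP-k is chosen over the multiset of submitted
confidences, scanned in descending order: the largest score at which the
median per-query false-positive count reaches *k*. The first crossing is
used because on discrete data a median of *exactly* k may be unattainable;
the median of an even number of queries is the mean of the two central
values. If no submitted score reaches a median of *k*, everything is
retrieved (`RETRIEVE_ALL` sentinel, −inf). Queries absent from the run
contribute an empty list (0 false positives at every cutoff, APCP 0 when
*P* > 0).

**Queries with no gold positives.** APCP is defined as 1 when nothing is
retrieved at the cutoff and 0 otherwise, rewarding abstention on documents
with no correct identifiers. Because it is ambiguous whether an official
evaluation averages over such documents, `tap_k_score` exposes
`include_unannotated`; the default includes them.

TAP-k depends on confidences only through their order, so it is invariant
under strictly increasing transforms — a property test and the brute-force
oracle equivalence test (exhaustive threshold enumeration on small
instances) pin this down.

Default *k* values are 5, 10 and 20, reflecting low/medium/high curator
error tolerance.

## EM consensus (latent class, two classes)

Model: object *j* (a (document, identifier) pair) is truly correct with
prior probability `pr`; source *i* labels it 1 with probability `as_i` if
correct and `1 − bs_i` if incorrect, independently across sources given
the truth. The M-step uses +1/+2 Laplace smoothing, which is the MAP
update under a Beta(2,2) prior on each rate and keeps every rate strictly
inside (0,1); the E-step is the two-class Bayes posterior with the
likelihood products accumulated in log space (verified to agree with the
direct product formula to 1e−12 at M = 14). The per-iteration objective is
the penalized log-posterior (marginal log-likelihood plus the Beta(2,2)
log-densities), which EM ascends; a test asserts monotonicity to 1e−9.

* **Initialization:** `p_j` = fraction of the M labels that are 1.
* **Convergence:** max_j |Δp_j| < 1e−8, capped at 1000 iterations.
  Non-convergence returns the last state with `converged=False` and a
  warning, never an exception. (Probability-change was chosen over
  likelihood-change as the criterion; either works, and the probability
  criterion is directly interpretable on the quantity consumers use.)
* **Priors:** 0.5 when selecting discriminative documents (no information
  yet about prevalence); 0.01 when inferring a silver standard in the
  regime where only ~1% of returned identifiers are correct. Both are
  exposed as parameters.
* **Silver standard:** identifiers with `p_j ≥ 0.5` (boundary included)
  per document.
* **Entropy scoring:** binary entropy in nats; the ranking of documents is
  invariant to the log base. A document's score is the sum over its
  objects, so it grows both with how many identifiers are reported and
  with how contested they are.
* **Selection:** each trial draws one run per team uniformly (a single
  seeded RNG consumed trial-by-trial, teams visited in lexicographic
  order, so results are reproducible from inputs + seed), runs EM, scores
  documents; scores are averaged over trials (100 by default, matching the
  procedure the method was designed with) and the top-n documents are
  returned with lexicographic tie-breaking.

A caution discovered while testing: a label matrix in which every object
is endorsed by every source carries no specificity information (there are
no negative labels), and the smoothed EM then settles at the symmetric
point p = 0.5. Confident consensus requires contrast — objects some
sources decline to endorse.

## Composite classifier

Candidates per document are the union of the component runs' predictions —
the only set describable by presence features. Features: M presence bits
plus, for stratification depth N ∈ {0, 5, 10}, M·N one-hot bin indicators
(dimension M·(1+N): 14 / 84 / 154 for 14 sources). Bins are **per-source
pooled quantiles** over all of that source's confidences; per-source
because teams' confidence scales are incomparable, pooled (rather than
per-document) because per-document binning would make bins meaningless for
short lists. Ties at a boundary fall to the lower bin; constant
confidences all land in bin 0.

The learner is an L2-regularized linear model with modified-Huber loss
(scikit-learn's `SGDClassifier`; regularization 1e−4, 200 epochs, fixed
shuffling seed — deterministic for fixed data + seed). Any deterministic
minimizer of this loss would satisfy the contract. Under leave-one-
document-out cross-validation each fold trains on the other documents'
labelled candidates and scores the held-out document's; decision scores
become the composite run's confidences (TAP's monotone-transform
invariance makes calibration unnecessary). A fold whose training labels
collapse to one class falls back to vote-count scoring and is recorded.
Per-fold weight hashes are exposed so tests can verify a fold is unchanged
when its own held-out labels change (no leakage). Quantile bins are
computed from the runs' confidences over all documents — unlabelled
test-document scores inform the binning (transductive), but no gold labels
cross folds.

## Break-even point, correlation, Wilcoxon

The break-even point is computed micro: pool all predictions over
documents, sort by descending confidence (ties: document, submitted rank,
identifier), and take precision at pooled rank R = total gold positives
(R-precision), where precision equals recall by construction; with fewer
than R predictions the value is TP/R. Macro (per-document) break-even was
the alternative; micro is the standard single-number reading and is
threshold-free. Pearson correlation is the plain product-moment
coefficient. The Wilcoxon signed-rank comparison drops zero differences,
uses the exact null for n ≤ 25 (falling back to the normal approximation
if ties prevent exactness) and the continuity-corrected normal
approximation otherwise; identical vectors are reported as degenerate with
p = 1.

## Synthetic-data generator

Per document, the number of truly correct identifiers follows a negative
binomial with mean 18 and shape r = 1 (a geometric), giving median 12 —
matching the count statistics of a 507-article benchmark test set (mean
18, median 12, long tail) — plus a configurable pool of decoy
identifiers. Each source labels every pool member independently: correct
ids returned with probability `as_i`, incorrect with `1 − bs_i` — exactly
the EM's observation model, so EM estimates are consistent as the object
count grows (a test checks the error shrinks across corpus sizes).
Returned ids get confidences from Beta(5, 2) (correct) and Beta(2, 5)
(incorrect): informative but overlapping rankings, so TAP and the ensemble
have signal without being trivial. The default source count is 14 with
sensitivities/specificities drawn uniformly in [0.6, 0.95].

The `one_percent_regime_config` preset (2000 decoys per document,
specificity 0.3) reproduces the observed regime in which only about 1% of
all returned identifiers are correct.

Problem sizes used in the routine checks — ~6800 objects × 14 sources for
parameter recovery, a 100-document corpus with 7 teams × 2 runs and
100-trial averaging for selection stability, 500 documents for count
calibration — are large enough for the stated tolerances (rate recovery
within 0.05, top-50 Jaccard ≥ 0.8, mean within [16, 20] and median within
[10, 14]) while keeping the full suite fast.

**What the generator does not emulate:** document text, species structure
or identifier semantics (ids are opaque tokens); correlated errors between
sources (sources are conditionally independent by construction — real
systems share dictionaries and NER tools, so real-world EM consensus will
be somewhat optimistic relative to these tests); per-document confidence
idiosyncrasies (one global confidence model per truth class). Passing
tests therefore demonstrate correctness of the machinery and behaviour
under the model's own assumptions, not performance guarantees on real
submissions.

## Label-matrix scope

`build_label_matrix` follows the evaluation convention: objects are the
union of returned (document, identifier) pairs, so every object has at
least one positive label. For parameter-recovery experiments this
truncation would bias specificity estimates (decoys nobody returned are
exactly the strongest negatives), so `label_matrix_from_pools` builds the
matrix over the full candidate pool; `recovery_experiment` uses it with
the prior set to the realized prevalence.

## File formats

Submissions are UTF-8 TSV, no header, `#` comments ignored:
`document_id, identifier, rank, confidence`; gold files are
`document_id, identifier` with a bare `document_id` line declaring an
empty-annotation document. This dialect is a stand-in — official challenge
syntaxes vary — and readers/writers round-trip canonical files
byte-identically. Non-strict reading collapses duplicate pairs keeping the
highest confidence and renumbers ranks canonically (descending confidence,
ties by submitted rank then identifier); strict mode rejects duplicates
and rank gaps with line numbers, for vetted fixtures.

## Packaged score tables

The three printed run-level score tables ship as TSVs pinned by sha256
checksums. Recomputing summary quantities from them reproduces the
printed precision/recall/F1 (29/32/30%), partial-annotation recall (75%)
and composite-over-best improvement percentages (10/26/28%) exactly at
printed precision. The printed gold-vs-silver Pearson correlations
(0.82/0.87/0.89) are **not** reproducible from the printed tables: the
transcribed 36-run columns give 0.8872/0.8761/0.8876 (silver on the 50
selected articles) or 0.8096/0.8576/0.8794 (silver on all 507). The
package computes and reports the correlation as defined; the corresponding
acceptance test records the discrepancy rather than papering over it. One
plausible cause is that the original summary included a withdrawn 37th
run whose scores were never published.

## Known limitations

* The conditional-independence assumption is untestable from a label
  matrix alone; strongly correlated sources will inflate consensus
  confidence.
* TAP-k's threshold is global across queries; a run evaluated on a
  document subset can receive a different threshold than on the full set,
  so TAP values are comparable only within an evaluation configuration.
* The composite classifier's stratification is transductive (bins use all
  documents' confidences); a strictly prospective deployment would need
  frozen bin boundaries.
* `select_documents` re-runs EM per trial from scratch; very large
  corpora (N in the millions) would need sparse-matrix variants not
  implemented here.
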