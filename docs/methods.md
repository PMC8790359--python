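# Methods

This note documents the statistical procedures implemented in `dreamnet`,
the assumptions behind them, the parameters that matter, and the design
choices made where the methodology was genuinely open.

## 1. Inputs and normalisation

The pipeline consumes condition mentions already extracted from text: a
flat table `(record_id, corpus, condition)` for the waking corpus and a
JSONL file of per-report condition sets for dreams. Conditions are
normalised by lowercasing and whitespace collapsing only. Surface variants
are deliberately **not** merged ("coronavirus", "corona virus" and
"covid19" are three conditions): variant merging would require a synonymy
resource, would be irreproducible across lexicons, and would change every
downstream frequency rank. The bundled lexicon matcher (longest match on
word boundaries) is demonstration plumbing, not a clinical NER system; any
serious deployment should extract mentions with a dedicated model and feed
the tables in.

Frequency is counted differently per corpus shape: raw mention counts for
mention tables (a tweet mentioning "fever" twice contributes two), and
number-of-reports-containing for report collections (presence in a report
counts once, because the network stage is defined on report membership).

## 2. Prevalence classification

Let `r_w(c)` and `r_d(c)` be fractional ranks of condition `c` by
descending frequency in the waking and dream corpora (ties share the mean
of the positions they span, which keeps the procedure deterministic).
Conditions absent from one corpus are assigned to the other corpus's
typical class before any model is fit; this is an assumption, not an
inference — absence from a 10⁴–10⁷-record corpus is strong evidence of
atypicality, but no uncertainty is attached to it.

On the shared conditions, `r_d` is regressed on `r_w` by OLS. The residual
`res_i = r_d(c_i) − fitted_i` is the vertical distance to the line: a
large positive residual means the condition is far less prominent in
dreams than its waking prominence predicts. Residuals beyond
`k_sigma = 1.5` standard deviations of the current residual mean are
peeled off into the waking-typical (positive side) and dream-typical
(negative side) classes, the line is refit on the remainder, and the loop
repeats. μ and σ are recomputed over the surviving points at each
iteration, which makes the labels invariant to any common rescaling of
the residuals.

**Stopping rule.** The loop stops when any of the following holds:

* the surviving scatter already fits an almost straight line, measured as
  R² ≥ `r2_stop` (default **0.95**);
* an iteration removes no points;
* the residual standard deviation collapses to zero (an exactly straight
  line), or fewer than 3 points or a degenerate predictor remain.

The goodness-of-fit stop is load-bearing. Iterative mean ± 1.5σ clipping
on its own never reaches a fixed point on noisy data: after the genuine
outliers are gone the surviving residuals are approximately
bell-shaped, a sample of n of them almost surely contains a point beyond
1.5 sample standard deviations for any n beyond a handful, and the
criterion is scale-free, so the loop keeps shaving ~13% of the remaining
points per iteration regardless of how small the residuals have become.
Empirically this erodes the equally-prevalent class to a few points. The
R² stop formalises "the remaining points lie on an almost straight line"
as an explicit, parameterised condition; `r2_stop = 1.0` restores the pure
zero-removal behaviour for study.

The regression orientation (dream rank as response) and the sign
convention (positive residual → typical of waking) are fixed so that a
condition prominent while awake but rare in dreams gets a positive
residual. The regression is fit on raw ranks, not log-ranks. OLS is not
symmetric in x and y, so swapping the corpus roles swaps the label sets
only approximately (≈92–96% of shared conditions in our validation
regimes); the absent-condition rule swaps exactly.

## 3. Co-occurrence network

With `N` reports, `P_i` reports mentioning condition `i` and `P_ij`
mentioning both `i` and `j`, every co-occurring pair receives:

* relative risk `RR = P_ij·N/(P_i·P_j)`, the observed co-occurrence over
  its expectation under independence, with log-normal 99% bounds
  `RR·exp(±m·σ_ij)`, `σ_ij = sqrt(1/P_ij + 1/(P_i·P_j) − 1/N − 1/N²)` and
  multiplier `m = 2.56`;
* the phi coefficient — the Pearson correlation of the two presence
  indicators — and a two-sided t-test p-value on N−2 degrees of freedom
  (two-sided is the conservative choice; the φ > 0 conjunct in the filter
  already enforces direction). `|φ| = 1` is treated as p = 0.

`RR > 1`, `φ > 0` and `P_ij·N > P_i·P_j` are algebraically the same
event; the test suite asserts this exhaustively over all small
contingency configurations against an independently built 2×2 table.

An edge survives filtering iff `φ > 0` and `p < α` (default α = 0.01) and
`LB(RR) > 1`. Conditions that never co-occur with anything (singletons)
are dropped before filtering, and nodes isolated *by* the filtering are
dropped after it. A pair whose endpoint appears in every report has an
undefined φ (zero denominator); such edges are flagged degenerate,
excluded from filtering and logged — a ubiquitous condition carries no
association information.

On the filtered graph the package computes PageRank (damping 0.85,
transition probabilities proportional to edge weight; an unweighted
variant is available since the choice is not forced by anything in the
data), per-class mean PageRank, Newman attribute assortativity over the
three prevalence classes, connected components, and a "core" defined as
the induced subgraph on nodes with degree ≥ 5 in the full filtered
network — a single-pass threshold, deliberately not an iterated k-core.

**Statistical caveats.** The φ t-test and the log-normal RR interval are
approximations. In very sparse regimes (expected co-occurrence well below
one count per pair) the candidate-edge set conditions on `P_ij ≥ 1`, and a
single joint occurrence of two rare conditions can be genuinely
significant at α = 0.01; the realised false-positive rate *among
candidates* can then slightly exceed α even though each individual test
is valid. With adequately many reports the `LB(RR) > 1` conjunct dominates
and the filter is conservative (measured false-positive fraction ≈ 0.4%
at α = 1% on 1000-report nulls).

## 4. The synthetic generator

`generate_corpora` emulates the statistical shape of real health-mention
corpora without any natural language:

* **Heavy tails.** Condition sampling weights follow a Zipf law
  `w(r) ∝ r^(−s)` (default s = 1.2) over a random permutation of the
  vocabulary; with the default sizes, the majority of conditions observed
  in the dream corpus appear at most twice, while the top conditions
  appear thousands of times in the waking corpus.
* **Planted prevalence structure.** Each condition gets one of five
  labels by largest-remainder apportionment of the class fractions:
  equally prevalent, exclusive to one corpus, or enriched in one corpus.
  Enrichment is implemented by evaluating the condition's weight in the
  *other* corpus at Zipf rank `base + rank_shift`: this suppresses it
  there by a controlled amount while preserving the marginal Zipf shape.
* **Reports.** Dream reports are sets (within-report repetition is
  meaningless for report-membership counts) sized
  `1 + Poisson(report_size_mean − 1)`. Default sizes mirror a realistic
  survey collection: 2 888 reports averaging ≈1.3 conditions each against
  a 50 000-mention waking corpus over a 500-condition vocabulary.
* **Planted clusters.** The vocabulary is partitioned into `n_clusters`
  balanced clusters; each report seeds from the corpus-wide distribution
  and fills its remaining slots from the seed's cluster with probability
  `within_cluster_prob`, otherwise from the whole vocabulary.

Everything derives from a single integer seed; identical specs produce
bit-identical corpora.

What the generator does **not** emulate: natural-language context, bursty
or trending dynamics (mentions are i.i.d. given weights), correlated
surface variants of one underlying condition, bot-like repetition, or any
semantic relationship between conditions beyond cluster membership.
Passing the planted-recovery tests therefore demonstrates that the
algorithms recover the structure they are designed for when it is present
at realistic frequencies — not that real tweets or dream reports satisfy
the generator's independence assumptions.

## 5. Validation regimes and problem sizes

The validation suite and `scripts/acceptance.py` use deliberately
moderate problem sizes so a full run completes in seconds on one core:

* *Strong-separation classification regime*: 250 conditions (80% equally
  prevalent, 8% enriched per side, 2% exclusive per side), 500 000 waking
  mentions, 40 000 reports, `rank_shift = 5000` (enriched conditions are
  pushed beyond the bottom of the base ranking). The classifier recovers
  ≈93–95% of planted labels here; the residual errors are tail conditions
  whose base rank is already near the bottom, for which no rank
  displacement is geometrically possible.
* *Null model*: 20 replicates of 1 000 structureless reports of 4
  conditions over a 100-condition vocabulary.
* *Cluster regime*: 100 conditions in 5 clusters,
  `within_cluster_prob = 0.9`, 4 000 reports of mean size 3; surviving
  cross-cluster edges are essentially absent.

## 6. Numerical choices and degenerate inputs

* Residual σ uses the population convention (ddof = 0); at the sample
  sizes involved the distinction is immaterial, and labels are invariant
  to it.
* σ ≤ 1e-12 is treated as an exactly straight line.
* PageRank is solved to tolerance 1e-12 so reported scores are stable far
  below printed precision; scores sum to 1 within 1e-9.
* Assortativity is undefined (NaN) on graphs with no edges or a single
  class among edge endpoints. The estimator is slightly negatively biased
  under random labeling of small graphs (with exactly n_c nodes per
  class, the chance two distinct endpoints share a class is
  (n_c−1)/(n−1), below n_c/n), which matters when interpreting values
  within ≈0.02 of zero on graphs of fewer than a few hundred nodes.
* Ties in frequency tables receive average ranks; top-k tables break
  count ties lexicographically. Both choices exist purely to make every
  output deterministic.
* Fewer than 3 shared conditions, or a predictor with zero spread, skips
  the regression with a warning and labels the shared conditions equally
  prevalent.

## 7. Limitations

* The absent-condition rule is sensitive to corpus size asymmetry: a
  condition missing from a small corpus may simply be unsampled, yet it
  is classified as typical of the other corpus with no uncertainty.
* Class labels carry no confidence measure, and the 1.5σ threshold,
  while conventional for outlier peeling, is a tuning constant: moving it
  trades the size of the equally-prevalent class against label purity.
* The edge filter controls per-edge error, not family-wise error or FDR
  across the thousands of candidate pairs.
* Only two corpora are supported by the classifier; the network stage is
  single-corpus by construction.
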