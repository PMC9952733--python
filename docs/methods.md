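# Methods

## Model and assumptions

`ddsim` treats drug–drug similarity as a text-similarity problem over
patient-authored review corpora. The underlying assumption is that drugs
with similar pharmacology elicit overlapping patient experiences — side
effects and the vocabulary used to describe them — so the bag-of-n-grams
profiles of per-drug review documents carry a similarity signal. The
pipeline makes no attempt to model sentiment, negation or medical concepts;
it is a deliberately transparent vector-space baseline.

Each drug's document is the concatenation of its reviews' side-effect and
comment fields, in corpus row order, space separated. Concatenation order
is irrelevant to bag-of-n-grams counts except for n-grams that bleed across
review or field boundaries; this bleed is accepted (one spurious bigram or
two per boundary against hundreds of in-review n-grams).

## Preprocessing

Stages, in order: clean → lowercase → whitespace-tokenize → stopword
removal → n-gram expansion (n = 1..3 by default).

* *Cleaning* replaces every character in Unicode categories Nd, No
  (digits/numerals) and P* (punctuation) with a space, then collapses
  whitespace. Symbols (category S*) are left alone; letters are never
  touched, so non-English text survives.
* *Stopwords* default to a standard English list packaged with the code
  (one word per line, user-replaceable). Removal happens before n-gram
  expansion, so an n-gram may bridge the gap left by a removed stopword;
  this matches the stage ordering above and is deterministic.
* *Weighting*: `count` (raw term frequency, the default), `binary`
  (presence), `relfreq` (count / document total, rows of non-empty
  documents sum to 1), `tfidf` (count × ln(N/df)). The Jaccard coefficient
  always uses presence sets regardless of the chosen weighting, since it
  is defined on finite sets.
* A document whose processed token list is empty keeps a zero vector and is
  flagged; cosine and Jaccard raise a named error for it, distances remain
  defined.

## The four measures and rankings

Cosine similarity and Jaccard are oriented as similarities (diagonal 1),
Euclidean and Manhattan as distances (diagonal 0). Manhattan is the
standard city-block sum of absolute differences — the absolute value
matters; without it the quantity is not a distance, and the published
distance tables (symmetric, nonnegative) are only consistent with the
absolute-value form. Matrices are computed in full floating precision
(scikit-learn pairwise kernels for the vector measures, sparse support
algebra for Jaccard), symmetrized, their diagonals set exactly; 2-decimal
rounding happens only at serialization time.

Per-drug rankings assign rank 1..n within each row — descending in
similarity, ascending in distance — with the row drug itself participating
(its exact diagonal makes it rank 1). Ties are broken by label order in
the matrix (stable sort). Ranking is invariant under strictly monotone
transforms of the row values, which is the point: it places all four
measures on one scale.

## Second-order analyses

Pearson's correlation, computed as
(nΣxy − ΣxΣy) / √((nΣx² − (Σx)²)(nΣy² − (Σy)²)), is applied to

* pairs of drugs' **full ranking rows** under one measure (self ranks
  included) — a second-order drug–drug similarity; averaging the four
  per-measure correlation matrices entrywise gives the overall DDS matrix;
* one drug's ranking rows under **two measures** — the agreement analysis,
  over the six unordered measure pairs, with per-pair column means and
  per-drug row means.

On permutation rows Pearson coincides with Spearman's rho, which the test
suite asserts. Correlating the full row rather than the row with the self
rank removed is a deliberate reading choice: it is the only convention
that reproduces the published correlation tables cell for cell, verified
by brute-force evaluation of several independently derived cells.

## Evaluation

Pairs whose averaged correlation is ≥ τ (inclusive — the boundary cell of
the published matrix must count at the headline threshold) are predicted
similar. Ground truth is a pairwise reference table whose drugs are named
by compound; a synonym map joins those names to corpus labels, with the
default mapping Valproic Acid → {Divalproex, Divalproex-ER} and
Klonopin → Clonazepam. Precision counts predicted label pairs
individually; a ground-truth pair is recalled if any of its mapped label
pairs is predicted; F1 = 2PR/(P+R), reported as 0 with a degeneracy flag
when nothing is predicted. The reference table's stored Average column is
validated on load: it is the mean of the structure, target and three
gene-ontology components with missing values skipped — the pathway
component is excluded, the only rule consistent with every stored row
(documented as an erratum-style reading).

## The packaged case-study reproduction

The raw review corpus behind the published 14-drug anti-epileptic study is
not redistributable, so its four printed similarity matrices (2-decimal
precision) are packaged as fixtures and everything downstream is
recomputed and diffed against the printed downstream tables:

* **Rankings** are compared per tie group: the printed rankings were
  evidently computed from unrounded similarities, so neighbors tied at two
  decimals may legally swap; within every tie group the rank multiset must
  match, untied cells must match exactly. Under this rule all 4 × 196
  cells agree.
* **Correlations** from the printed ranking rows reproduce the printed
  per-measure tables except one row that the publication itself prints
  inconsistently (a cosine row duplicating the Manhattan row, contradicting
  both the symmetric cells and recomputation); those 13 cells live in a
  packaged errata file and are reported, never asserted. The implementation
  is symmetric by construction and does not attempt to reproduce the
  asymmetry.
* The **per-drug average column** of the printed agreement table was
  computed from already-rounded cells, so it is checked as the half-up
  rounded mean of the printed 2-decimal cells; all other agreement cells
  and the column means are checked against full-precision recomputation at
  2 decimals.
* The **threshold evaluation** operates on the 2-decimal rounded averaged
  matrix, mirroring the printed matrix the published sweep used. The
  recall column at τ ∈ {0.5, 0.6, 0.7, 0.75}, the full triple at τ = 0.75
  and the position of the best F1 are asserted; published precision at the
  lower thresholds followed a pair-counting convention that is within one
  counted pair of the stated rule but not exactly recoverable, so those
  cells are reported without assertion.

## Synthetic corpora

The generator plants a recoverable class structure: each class owns a
private uniform vocabulary, all drugs share a common vocabulary, and every
token of every review is drawn from the shared pool with probability
`shared_fraction`, otherwise uniformly from the drug's class vocabulary.
Review lengths are Poisson with a configurable mean (clipped to ≥ 1);
tokens are pure-alphabetic lowercase words so they survive cleaning and
are not stopwords. A single seeded generator stream makes corpora
reproducible byte for byte.

Defaults (2 classes × 4 drugs, 200 reviews/drug, mean length 20, class
vocabulary 150 words, shared vocabulary 100 words, shared fraction 0.2)
describe a well-separated corpus at desk scale: small enough that the full
test suite runs in seconds, large enough that class recovery is stable
across seeds. The uniform-multinomial model was chosen as the simplest
generator with one signal-to-noise knob; it emulates corpus *shape* (many
short noisy documents per drug), not real medical language — passing tests
demonstrate that the pipeline recovers planted structure, not that real
review text carries an equally clean signal (it will not: real reviews
have shared drug-domain vocabulary, spelling variance, class-imbalanced
review counts and no uniform token distribution).

## Numerical choices and limitations

* All comparisons against printed values use an absolute tolerance of
  0.005 (half a printed unit in the last place); the reference Average
  column is validated at 3 decimals.
* Ties in ranking are resolved by matrix label order; any strictly
  monotone rescaling of a similarity matrix leaves its rankings unchanged.
* Pearson raises on constant vectors rather than returning NaN.
* The weighting/normalization that produced the published similarity
  matrices is not recoverable from their printed ranges, so the package
  does not claim to regenerate them from raw text; all reproduction starts
  from the printed matrices, and the preprocessing/similarity stages are
  validated by axioms and planted-signal recovery instead.
* Medical-concept normalization, stemming, embedding-based similarity and
  network visualization are out of scope; the measure registry is the
  extension point for additional similarity families.
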