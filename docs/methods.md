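# Methods

## Model

medlink normalizes a free-text medical term to a concept in a reference
dictionary of (concept id, term) pairs.  Each query is expanded into a set
of translation variants (in production, the union over several web
translation engines; here, any provider satisfying the translation
contract).  Every variant is scored against every dictionary term on two
channels, the per-channel score of a candidate is the **maximum over
variants**, and the channels are fused into one ranking score.

**String channel.**  Terms are bags of character n-grams taken over the
full canonical string, spaces included, with no word-boundary padding —
multiword terms stay comparable as character sequences.  Two TF-IDF
dialects are implemented:

* `paper` (default): `tf = count / total n-gram count of the term`,
  `idf = ln(N / df)`.  An n-gram present in every dictionary term gets
  idf 0 and drops out of every vector.
* `smoothed`: `idf = ln((1+N)/(1+df)) + 1`, the common vectorizer
  convention.  Under cosine the per-term tf denominator cancels, so this
  dialect is numerically identical to scikit-learn's `TfidfVectorizer`
  with a char analyzer — a property the test suite uses as an independent
  cross-check while keeping the implementation self-contained.

When several n-gram orders are combined (default n = {2, 3}) they share
one vocabulary and one tf denominator, giving a single sparse vector per
term.  Similarity is the cosine; a vector with no in-vocabulary n-grams
scores 0 against everything by convention.

**Semantic channel.**  Any object with `name`, `dim`, and a deterministic
`embed(texts) -> (len, dim)` matrix is a dense embedder.  Production
vectors come from a biomedical language model (sequence-start token,
final layer) via the precomputed-vector file backend (`term TAB floats`,
header `dim N`); the hashed-3-gram toy backend exists so tests and demos
run with no model: each 3-gram hashes (cryptographically, so results are
identical across processes) to a fixed Gaussian direction and a text
embeds as the normalized sum.  Embedder outputs are not re-normalized at
embed time; the cosine normalizes internally.

**Fusion.**  Six schemes: `string_only`, `semantic_only`, `linear`
(`α·S_semantic + β·S_string` on the raw cosines), and `zscore` / `minmax`
/ `tanh`, which normalize each channel **per query over the candidate
set** before the weighted sum (normalizing across queries would make
min-max degenerate and break query independence).  The tanh scheme uses
the conventional robust form `0.5·(tanh(0.01·z) + 1)`; the 0.01 slope is
exposed as a module constant.  Degenerate (zero-spread) channels map to
all-0 under z-score and all-0.5 under min-max/tanh, preserving order
trivially.  All normalization maps are monotone non-decreasing, so
within-query order is never inverted.

**Combiner training.**  The linear weights are trained on labeled queries
by iterative candidate mining: each epoch takes the current top-k
(default 20) dictionary entries per query, forms the softmax over the
pool's combined scores, and minimizes the negative mean log of the
softmax mass on positive (gold-synonymous) candidates.  Pools whose top-k
contains no positive are dropped for that epoch with a logged count —
their loss is undefined (log 0) — which mirrors the standard practice in
hard-negative mining for entity-linking rankers.  Because only two scalars
are trainable, the optimizer is full-batch gradient descent with the
closed-form gradient

```
dLoss/dα = mean over pools of ( E_p[s_sem] − E_{p|pos}[s_sem] )
```

(and analogously for β with the string channel), where `E_p` is the
softmax expectation and `E_{p|pos}` the expectation under the softmax
renormalized to the positives.  Defaults: init (1, 1), learning rate 0.5,
100 epochs (50 in the acceptance runs), re-mining every epoch.  The run
is exactly reproducible — there is no stochastic machinery to seed — and
the gradient is verified against central finite differences in the test
suite.  Rescaling (α, β) by any c > 0 changes softmax values but no
ranking, so only the weight *ratio* matters at inference.

**Evaluation.**  Acc@n = 100·TP_n/N, where a query counts as a hit if any
of its gold concept ids appears among the top n **distinct** concepts;
duplicate concept ids in the ranking (one concept, many terms) are
collapsed to their best-scoring term before rank counting, because
synonym-rich dictionaries would otherwise let one concept occupy several
of the n slots (`--no-dedup` preserves the raw term-row reading).  A gold
concept outside the retrieved top-n_max is a miss.  Paired strategies are
compared with McNemar's test on the discordant hit counts (b, c): exact
two-sided binomial when b + c < 25, else the continuity-corrected
chi-square `(|b−c|−1)²/(b+c)` with 1 df — standard small-sample practice;
the method used is recorded in the result.

## Synthetic benchmark generator

The generator emulates the computational structure of the real task —
a synonym-rich disorder dictionary, noisy aliases of gold concepts as
"translation variants", and dense vectors in which synonymous terms form
a packed cluster — with all randomness flowing from one seed through
named per-stage generators, so regeneration is byte-identical.

* **Dictionary**: `n_concepts` (default 500) concepts, each a base string
  of 2–4 pseudo-words over a 20-letter alphabet, with
  `synonyms_per_concept` (default 3) variants produced by seeded edit
  operations — per-character substitution, adjacent token swap, affix —
  at rate `string_noise` (default 0.15, a moderate corruption level that
  leaves the string channel informative but not trivially so).
* **Queries**: `n_queries` (default 400) queries pick a concept uniformly
  and present `variant_count` (default 2) independent perturbations of
  one of its synonyms.
* **Vectors**: one latent unit vector per concept; every term and variant
  embeds as latent + per-component Gaussian noise of sd `semantic_noise`
  (default 0.3 at `dim` 64), l2-normalized.  At these defaults the
  within-concept cosine exceeds the between-concept cosine in
  expectation, but the noise norm is comparable to the latent norm, so
  the semantic channel is deliberately the weaker one.

`channel_mode` makes one channel pure noise: `semantic_only` replaces
variant texts with random strings; `string_only` replaces query-side
vectors with random unit vectors.  In `string_only` mode variant texts
are additionally kept distinct from every dictionary term (re-perturbing
on collision), because the vector table is keyed by term text and a
shared key would leak dictionary-side semantic signal into the query
side.  These single-channel benchmarks are what make the combiner's
parameter-recovery tests meaningful: training on them must push the
informative channel's weight above the other's.

What the generator does **not** emulate: real orthography (Chinese or
otherwise), real term-length and synonym-count distributions of UMLS-scale
vocabularies, engine-specific translation error profiles, or semantically
structured embedding geometry beyond one isotropic cluster per concept.
Passing tests therefore demonstrate the correctness and the qualitative
behaviour of the machinery (channel fusion helps, recovery works, metrics
are exact), not the accuracy levels attainable on real data.

## Numerical choices

* Softmax is computed max-shifted; the marginal probability is finite
  whenever a positive exists.
* All rankings break ties by dictionary position under a stable sort, so
  reruns are bit-identical.
* Cosine of an all-zero vector against anything is 0 by convention.
* The sparse encoder persists idf values as hex floats; reload reproduces
  transforms bit-identically.
* Acceptance-scale problem sizes — 500 concepts × 3 synonyms, 400
  queries, 50 training epochs — were chosen as the smallest configuration
  giving stable accuracy estimates and visible loss descent in
  seconds-scale runs.

## Design notes and limitations

* A reference configuration for the linear weights from a production-scale
  run of this method is (α, β) = (33.11, 7.28); the package treats such
  values as loadable configuration, not as a recovery target — trained
  weights depend entirely on the dictionary, the translation quality, and
  the encoder behind the run.
* On the default mixed-signal benchmark the string channel saturates
  (Acc@1 = 100), so the trained-fusion comparison there is a dominance
  check (fusion never loses to the best channel), not an improvement
  measurement; the recovery benchmarks carry the discriminating tests.
* Gold labels are sets: a prediction is correct if it hits any gold id.
* Language tags are carried through but never used for filtering — the
  cross-lingual mode (a multilingual encoder, no translation step) is the
  same code path with a different embedder and no providers.
* MRCONSO reading consults only the CUI, LAT, SAB, STR and SUPPRESS
  columns; suppressed rows are kept by default (`keep_suppressed=False`
  drops flags O/E).
* No approximate nearest-neighbour index: cosine is exact over the whole
  dictionary, which is the right trade-off at desk scale but not at
  UMLS scale.
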