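# Methods

## Representation

Each simulated participant owns a *lexicon*: one base vector per symbol
(the grammar letters, the boundary markers `s`/`e`, and the repetition
symbols `A`/`B`), sampled i.i.d. N(0, sd²) with sd = 1/n and n = 100, plus
two fixed random permutations of the coordinates. A bigram is bound by
*directed* circular convolution: the left operand is permuted by the first
permutation, the right by the second, then the two are circularly convolved
(computed by FFT; the test suite checks it against a direct O(n²) sum).
The permutations make binding non-commutative — `X*T` and `T*X` are
nearly orthogonal — while plain circular convolution would make them
identical. Both permutations live in the lexicon so every binding made by
one participant uses the same pair. Because all downstream similarity is
cosine-based, the scale choice sd = 1/n is cosmetic.

Two operand orders of a directed convolution still share the DC and
Nyquist spectral components, so the expected cosine between `x*y` and
`y*x` is O(1/n), not exactly zero. This is a property of any
permutation-based directed convolution and is harmless at n = 100.

## Encoding schemes

* **bigram** (standard AGL, q = 2): the string is wrapped in `s`/`e` and
  split into adjacent bigrams — a length-m string yields m + 1 components.
* **repetition** (transfer AGL, q = 1): each adjacent letter pair is
  recoded `A` (repetition) or `B` (non-repetition) and wrapped in markers
  (`XXVT → sABBe`); components are the single symbols of the recode.
  The code depends only on *equality* of adjacent letters, so it is exactly
  invariant under bijective letter remapping — this is what carries
  knowledge across a letter-set change.
* **letters** and **trigram** schemes exist on the object-level encoder
  (`encode_trace`) for exploration, but the batch engine and the comparison
  layer use only the two schemes above: single-letter frequency is not
  diagnostic in these designs and trigram encoding mainly adds sampling
  noise at these string lengths.

From a parse, *g* components are sampled — without replacement when the
item has at least g components, with replacement otherwise — bound, and
summed. Degradation is an independent Bernoulli mask per coordinate per
trace: each coordinate survives with probability L, else is set to 0, so a
trace retains an expected proportion L of its features.

## Retrieval and decision

A probe activates stored trace i as a_i = cos(probe, trace_i)³; the echo
is Σ a_i · trace_i and the intensity is cos(echo, probe). The cube is the
classic sign-preserving Minerva-II nonlinearity; it is exposed as
`activation_exponent` (odd values only). Cosine similarity is used
throughout rather than Minerva's relevant-feature-normalized dot product.
All-zero probes, traces or echoes contribute similarity 0 by convention.

Note that intensity has a positive expectation even for probes unrelated
to memory: every term of the echo projects positively on the probe because
activation carries the sign of the similarity. Classification is
unaffected — the criterion is placed *retrospectively*: after a
participant's full intensity distribution over the test list is known, the
top round(rate × N) items (half-up rounding; ties broken by presentation
order, earlier first) are endorsed, matching a target endorsement rate.
The criterion k is reported as the smallest endorsed intensity. Endorsed
proportions therefore never miss the target by more than half an item.

## Trial loop and variants

Per participant: fresh lexicon; each training item encoded at L_train and
stored in presentation order; then the test list in order. For each test
item one component sample and one degradation mask are drawn, shared by
the classification and storage copies:

* **HEM-TC** classifies the degraded probe, then stores it.
* **HEM-T** classifies the intact sum, then stores the degraded copy.
* **HEM-C** classifies the degraded probe and stores nothing.

A test trace is stored only after its own classification, so an item is
never probed against itself. Random draws occur in a variant-independent
order, so with L_test = 1 HEM-TC and HEM-T are identical draw for draw —
a structural equivalence the tests assert exactly. The training list is
presented once per participant.

The trial loop is implemented once, vectorised over a batch of
participants (`engine.simulate_participants`); `run_participant` is the
same loop with a batch of one. The engine's pieces (directed-convolution
component matrix, batched echo intensity) are tested against the
object-level primitives and explicit-loop oracles.

## Synthetic materials

The default grammar is a 5-state finite-state machine over {M, V, X, T, R}
with self-loops on T and X, producing 80 distinct strings of length 3–8,
about half containing immediate repetitions. Defaults: 20 training
strings, 16 grammatical + 16 ungrammatical test strings, all distinct,
train/test disjoint — typical sizes for this paradigm. Ungrammatical items
substitute one interior letter of a grammatical string such that the
result contains a bigram unattested in the whole length-bounded language
and is rejected by the grammar (membership is re-checked, and the tests
verify it with an independent path-enumeration oracle).

Substitutions that *add* a spurious letter doubling are preferred. The
grammar never doubles M, V or R, so such doublings are guaranteed
unattested bigrams, and they shift the item's repetition code away from
the training distribution — which keeps violations detectable under
transfer, where only the repetition code survives the letter remapping.
(The opposite choice — breaking repetitions — makes ungrammatical items
*more* similar to the mostly-`B` training codes and reverses the transfer
effect.) Generation asserts two asymmetries, resampling until they hold:
grammatical test items share more bigram types with the training set than
ungrammatical ones, and their mean repetition rate lies closer to the
training rate.

What the generator does **not** emulate: the item statistics of any
particular behavioral study (chunk-strength balancing, matched
associative strength, human-calibrated violation salience). Passing tests
show the models behave as designed on materials with the stated similarity
asymmetries, not that they fit any specific published data set.

## Model comparison

The grid crosses g ∈ {2, 3, 4, 5} with three index-yoked (dual, single)
learning-rate levels — (.1, .8), (.2, .9), (.3, 1.0) — one level index for
training and one for test: 4 × 3 × 3 = 36 combinations. Conditions within
an experiment share the combination's parameters and differ only in which
member (dual or single) of each pair applies, according to where that
condition places the dual task. The yoked pairing (rather than a free 3×3
per rate) is what makes the grid count come out at 36.

A combination's likelihood is the fraction of iterations (default 100; 20
fresh participants per condition) whose per-condition mean H − Fa values
fall within RMSE ≤ E of the empirical means, E = 0.02 by default. The
window must be small enough to stay close to the data but coarse enough to
respect the resolution of 20-participant means (whose standard error is
~0.03 here); likelihoods are accordingly small numbers. Marginal
likelihood is the unweighted grid mean (uniform prior); Bayes factor the
ratio of marginals; maximum likelihood ratio the ratio of grid maxima.
Ratios with a zero denominator are flagged undefined, never computed.
Posterior predictive checks re-simulate either at the argmax combination
(ties to enumeration order) or at combinations drawn with probability
proportional to likelihood, which under the uniform prior is the
posterior.

The standard experiment compares all four conditions; the transfer
experiment simulates four but compares the three that carry anchors (the
dual-at-both cell is left unanchored by default, matching three-condition
transfer designs). Empirical anchors are config inputs, never package
constants. For self-contained runs the package generates *synthetic*
anchors by simulating HEM-TC at a reference combination (g = 3, levels
(.2, .9)/(.2, .9), 400 participants per condition); results against such
anchors characterize the machinery and the model family's internal
orderings, not any behavioral experiment.

## Reproducibility

Every stochastic stage derives its generator from the run seed through
`numpy.random.SeedSequence` with fixed spawn keys — one child stream per
(model, experiment, combination, condition) — so likelihood surfaces are
bit-reproducible for a given seed and all outputs embed the seed and a
configuration digest. The acceptance script scales the grid comparison to
50 iterations × 20 participants per condition (keeping single-CPU runtime
at a few minutes); the test suite's pipeline check uses 16 iterations.
Marginals at these sizes resolve to 1/(36 × iterations).

## Known limitations

* Encoding levels cannot be mixed (letters + bigrams + trigrams in one
  trace); each scheme is all-or-none, and the engine supports only the two
  schemes the experiments use.
* No forgetting or decay during test, no feedback learning, no
  response-time modeling.
* HEM-C's discrimination does not vanish at the lowest training rate
  (mean H − Fa ≈ 0.07–0.1 at L_train = 0.1 on the default materials):
  cosine activation still exploits the surviving 10% of trace features.
  "Collapse without test learning" is therefore a relative statement —
  below half the model's own single-task performance — not an absolute
  drop to chance.
* Endorsement-rate-to-count conversion uses half-up rounding; with small
  test lists other conventions (floor/ceiling) could shift a single item.
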