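# Methods

## The translation model of retrosynthesis

`fragretro` treats single-step retrosynthesis as machine translation
between sentences of molecular substructures.  A molecule is reduced to
the set of structural keys it switches on — by default the 166-key MACCS
dictionary, alternatively a folded Morgan/ECFP fingerprint — and that set
is written as a sentence of short artificial words, one word per key,
ordered by corpus frequency.  A sequence-to-sequence recurrent network
then learns, from a corpus of product→reactant records, how reactant key
sets differ from product key sets.  Because the model predicts key sets
rather than SMILES strings, its outputs are never syntactically invalid;
the price is that a key set underdetermines the molecule, so a final
lookup stage maps predicted sets back to real structures.

## Key curation and the lettered language

Not all keys carry signal.  Curation drops, in order: keys that never
occur in the reaction corpus; keys whose normalized frequency in that
corpus falls below `rare_primary`; and keys whose frequency in a reference
corpus of drug-like molecules falls below `rare_reference`.  Both
thresholds default to `1e-4` and are configurable, and an explicit
retained-key list can be supplied instead (for reproducing a published key
set).  Over the full MACCS dictionary this procedure is built to leave the
canonical 126-key working set.

Survivors are ranked by reaction-corpus frequency (ties broken toward the
lower key index) and assigned words: ranks 1–21 get the 21 most frequent
English letters (E, T, A, O, I, N, S, H, R, D, L, C, U, M, W, F, G, Y, P,
B, V) uppercase, ranks 22–42 the same letters lowercase, ranks 43–84 those
42 words suffixed with "x", ranks 85–126 suffixed with "z".  Blocked case
(all uppercase, then all lowercase) rather than alternating case is a
design choice; nothing downstream depends on it.  Vocabularies larger than
126 keys fall back to `w<rank>` words.  A molecule's sentence lists its
retained keys' words in ascending rank; two-reactant targets join the two
sentences with "–" (longest first).  Keys outside the retained set are
silently dropped — the deliberate information loss of the representation.

## Dataset curation

Reaction records (`reactants>reagents>products`; reagents always
discarded) pass through a fixed cascade, with every removal tallied in a
telescoping report:

1. keep single-product records only (multi-product records are dropped,
   not split);
2. encode both sides with the curated vocabulary;
3. drop duplicate (source, target) sentence pairs, keeping the first;
4. drop *internal twins* — records whose product and reactant sentences
   are identical because the chemical change is invisible at key
   resolution;
5. drop records with three or more reactants;
6. drop pairs longer than 100 tokens (source + target, separator
   included; the bound is inclusive);
7. collapse one-to-many product→reactant mappings to an injective map,
   keeping the shortest target (ties: lexicographically smallest token
   sequence).

Splits are seeded: 90/10 train/test, then 10% of train held out for
validation, drawn independently for the single-reactant, double-reactant
and combined subsets.

## The network

A stacked LSTM encoder–decoder with Luong attention, implemented directly
on NumPy with the package's own reverse-mode autodiff
(`fragretro.autodiff`: broadcasting arithmetic, batched matmul, a fused
LSTM cell, masked softmax, fused masked cross-entropy; float32 for
training, float64 for gradient checks, everything verified against
numerical derivatives in the test suite).

Architecture choices, where the design was open:

- The bidirectionality flag applies to the encoder.  An autoregressive
  decoder is necessarily unidirectional; the two encoder directions' final
  states are concatenated and linearly bridged (tanh for h, linear for c)
  to initialize each decoder layer.
- Attention uses the "general" bilinear score.  Global mode attends all
  source positions.  Local mode predicts a center position per step
  (`(T−1)·σ(vᵀ tanh(W h))`, treated as non-differentiable), keeps a
  window of `2D+1` positions (default `D = 10`), multiplies the softmax by
  a Gaussian of std `D/2`, and renormalizes so the weights remain a
  probability distribution.
- Teacher forcing during training; no input feeding (the attentional
  hidden state is not fed to the next step — the translation task is
  near-monotonic and the simpler decoder trains faster).
- Special tokens PAD, SOS, EOS, "–" occupy ids 0–3; word ids follow in
  rank order, so id order equals rank order.
- Optional weight tying: encoder and decoder share one embedding
  (both sides speak the same fragment language), and when
  `embedding_dim == hidden_units` the output projection reuses the
  embedding transposed.  Tying pools the evidence for rare words across
  their three roles and is the default in the desk-scale experiments;
  the full-scale configuration leaves it off.

Decoding is greedy argmax — the model is deterministic by design — and by
default constrained to the language's grammar: within a segment, words
must be unique and in ascending rank (equivalently, ascending id), at most
one separator may appear, and only after at least one word.  The argmax is
taken over legal continuations only; an unconstrained decode that already
emits a well-formed sentence is unchanged.  Post-processing truncates at a
second separator and strips trailing separators.

Training is stochastic gradient descent on teacher-forced cross-entropy
(mean over non-pad tokens), with global gradient-norm clipping and a
stepped learning-rate decay.  The full-scale defaults follow the reference
recipe: lr 4.0, decay ×0.85 every 3 epochs, clip 0.25, batch 64, dropout
0.1, ≥30 epochs, 126-dim embeddings, two Bi-LSTM layers of 2000 units.
Classical momentum is available (`momentum`, default 0 — plain SGD) and is
used in the desk-scale presets, where only tens of updates happen per
epoch and undamped SGD with a 0.25-norm step would need thousands of
epochs.  Batches are length-bucketed (sorted by source length, batch order
shuffled per epoch) to keep padding small.  `average_last = k` averages the
end-of-epoch weights over the final k epochs (checkpoint averaging), which
smooths the SGD endpoint at no extra cost; the desk presets use k = 10.

## Evaluation

The score of a prediction against the truth is a matched set-overlap
similarity.  Tanimoto Tc(R,P) = |R∩P| / (|R|+|P|−|R∩P|) is the default;
the Tversky index (α, β) and its Dice special case (α=β=0.5) are
available.  Two conventions resolve ambiguities the metric itself leaves
open:

- Pair matching: with two reactants on both sides, both bijective
  assignments are evaluated and the better **mean** pair similarity wins —
  the mean, so that exactness requires both pairs exact.  With unequal
  counts, all cross pairs are tried and the single best is kept.
- Two empty key sets score 0 (with a warning), not 1.

Corpus summaries report exact matches (score 1.0 **and** matching reactant
count — a 2-vs-1 comparison can score 1.0 on its best cross pair without
being the right answer), the strict "bioactively similar" band
0.85 < Tc < 1.00, the cumulative Tc ≥ 0.85 rate, the mean score
(compensated summation, so the summary is permutation-invariant), and a
histogram over the bands [0, .50), [.50, .70), [.70, .85], (.85, 1.0),
{1.0}, which partition [0, 1].

## Retrieval

A lookup table holds one entry per canonical SMILES: the molecule, its
curated key set, and its sentence.  A predicted sentence first tries an
exact sentence hit; otherwise candidates within `max_discrepancy`
discrepant keys (symmetric-difference size, default 4) are returned in
ascending discrepancy, found via an inverted key→entry index plus a scan
of key-poor entries that could match with zero overlap.  Molecules sharing
one curated key set are re-ranked by Morgan (radius 2, 2048-bit) Tanimoto
against a reference structure — the query product at inference time, the
true reactant in evaluation mode — with a stable sort.  Desk-scale tables
(≤1M entries) are the design point; no large-scale engineering is
attempted.

## Synthetic corpora

The generators in `fragretro.synthetic` stand in for the external reaction
corpus.  Products are real molecules: seeded draws from a packaged list of
~250 small drug-like structures, optionally decorated with random
substituents (attachment at a random H-bearing heavy atom, sanitized, with
fallback to the undecorated molecule).  Reactions are **toy rules** acting
directly on curated key sets — remove a few keys, add a few keys,
optionally split the set into two reactants along a fixed rank partition.
Which rule fires is a deterministic function of the product's keys (the
first rule whose selector key is present, with a default rule last), so
the product→reactant map is a function by construction, mirroring the
injective collapse the real corpus undergoes.  Records that would be
twins, duplicates, key-poor (fewer than 6 retained keys) or over-long
(pair > 96 tokens) are rejected and resampled, so the clean corpus
survives curation untouched; contamination of each kind (duplicates,
twins, 3-reactant records, >100-token pairs, injectivity violations) is
planted at requested per-record rates and the exact planted counts are
returned for comparison against the curation report.

These rules operate on key sets, not on atoms: after encoding, the
translation machinery never inspects chemistry, so key-level rules
exercise it fully.  What passing the synthetic experiments does **not**
show: that real reaction corpora are as clean, as deterministic, or as
evenly distributed over transformation types as the toy corpus; chemical
realism of the rules is explicitly not claimed.

## The desk-scale learnability experiment

`fragretro.experiments.run_learnability` is the standing end-to-end check
that the translator extracts reaction rules from data.  Fixed conditions,
chosen once: products from the packaged list (12,000 draws, corpus seed
3), a 48-key vocabulary — the most frequent keys, so each of the ~52 model
tokens has adequate support in a small corpus — the five standard rules,
2,000 training and 200 held-out pairs, and a tiny model (one Bi-LSTM
layer, 64 hidden units, 64-dim tied embeddings and output, dropout 0.1)
trained for 50 epochs of momentum SGD (lr 1.0, momentum 0.9, decay ×0.9
every 8 epochs, clip 2.0, batch 64).  The bidirectional model must recover
the held-out transformations almost perfectly (≥95% exact matches,
majority over three seeds); the unidirectional variant under the identical
budget quantifies the benefit of the bidirectional encoder.  The same
experiment, at these problem sizes, is what `scripts/acceptance.py`
recomputes.

## Numerical and degenerate-input choices

- MACCS indexing is 1-based (keys 1..166); the toolkit's undefined bit 0
  is always dropped.  The toolkit's SMARTS definitions are the reference;
  no re-derivation is attempted.
- An empty source sentence (every key curated away) is padded to one PAD
  slot so attention normalizes over something; downstream it simply
  translates poorly rather than crashing.
- Attention weights sum to 1 to float tolerance at every step (asserted in
  tests); masked softmax subtracts the row max before exponentiation.
- Unparseable SMILES raise a parse error naming the offending string in
  single-molecule operations and are skipped-and-logged in corpus
  operations; an all-bad corpus is an error.
- Checkpoints are NumPy archives with a JSON header (config, vocabulary
  size, seed); runs write a manifest with the config hash, and rerunning a
  pipeline with an unchanged config reuses cached stage outputs.

## Known limitations

- The full-scale configuration (2×2000 Bi-LSTM on ~350k pairs) is
  supported by the same code paths but is far outside desk-scale budgets;
  published full-corpus accuracies are not reproduced here.
- Greedy decoding emits a single hypothesis; there is no beam search, by
  design (the method's robustness claim is determinism of its one
  prediction).
- The key-set representation cannot distinguish molecules that share a
  curated key set; retrieval re-ranking mitigates but cannot resolve this.
- Toy-rule corpora are a mechanism check, not a chemistry benchmark.
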