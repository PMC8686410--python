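# Methods

## Problem and model

`radner` extracts three entity types from the free-text narrative of
Chinese adverse-drug-event (ADE) reports: **Reason** (the disease,
symptom, or treatment behind the drug use), **Drug** (generic name, trade
name, or abbreviation — including mixed-script forms like `10%GS`), and
**ADR** (the adverse reaction itself). Extraction is cast as
character-level sequence labeling with the BIO scheme, giving a 7-label
alphabet (`O`, `B-/I-` × 3 types).

The tagger scores a character sequence in four stages:

1. **Token features.** Each character receives a vector from a pluggable
   embedding provider. The default is a trainable lookup table (width 64,
   UNK row for unseen characters). A `ContextualAdapter` accepts any
   external encoder producing per-character vectors of a declared width
   (e.g. a pretrained transformer), so contextual representations are an
   integration choice, not an architectural one.
2. **Radical features.** Each character's canonical Kangxi radical
   (1–214; 0 for non-CJK characters and control tokens) indexes a
   trainable embedding table of width 20, initialized uniformly on
   [−0.5/20, +0.5/20]. Radicals act as coarse semantic classes — the
   sickness radical 疒 groups 痛/疹/症/病, the water radical 氵/水 groups
   液/注/滴 — letting the model generalize across characters it has seen
   rarely. Radical identity is the Kangxi *number*, so variant glyph
   forms (氵 for 水, 忄 for 心) collapse onto one identifier.
3. **Bi-LSTM encoder.** The concatenation [token ‖ radical] feeds a
   bidirectional LSTM (128 hidden units per direction). An affine map of
   the concatenated directional states yields per-position emission
   scores over the 7 tags. Inverted dropout (rate 0.1) is applied to the
   encoder output during training only.
4. **Linear-chain CRF.** A path y₁..y_T is scored
   `start[y₁] + Σ e[t,yₜ] + Σ A[yₜ₋₁,yₜ] + end[y_T]`. Training minimizes
   the exact path negative log-likelihood (forward recursion in log
   space; forward–backward marginals give the exact gradients); decoding
   is Viterbi with deterministic lowest-index tie-breaking.

The whole network — embeddings, LSTM, projection, CRF — is implemented in
numpy with hand-derived backpropagation and trained with Adam
(gradient-norm clipping at 5.0). A gradient check against central finite
differences is part of the test suite.

## Input preparation

Sequences are wrapped as `[CLS] text [SEP] [PAD]…` to a fixed maximum
length (512), with a boolean mask marking real characters; the network
consumes only mask-true positions, so control tokens and padding cannot
contribute to the loss or appear in decoded spans (asserted by a
padding-invariance test). Narratives longer than the content limit are
split, preferentially just after Chinese sentence-final punctuation
(。？！；), never through an entity (the split point shifts left to the
entity start); fragment offsets are recorded so predictions map back to
whole-narrative coordinates.

## Training parameters

| parameter | default | notes |
|---|---|---|
| batch size | 16 | sequences per Adam step (gradient accumulation over exact per-sequence recursions, so batched ≡ unbatched) |
| LSTM hidden | 128/direction | |
| radical dim | 20 | uniform init, trainable |
| token dim | 64 | lookup provider default |
| learning rate | 5e-5 | Adam; suits *fine-tuning* a pretrained contextual provider |
| max length | 512 | content limit 510 after [CLS]/[SEP] |
| dropout | 0.1 | encoder output only |
| grad clip | 5.0 | global norm |
| epochs | 20 | |

The from-scratch lookup-embedding configuration is trained at the
conventional Adam rate **1e-3** (set explicitly in the synthetic pipeline
and acceptance script): 5e-5 is a fine-tuning rate and moves a randomly
initialized network far too little in 20 epochs. Illegal-transition
masking (forbidding e.g. `O → I-Drug` with −∞ scores) is available via
`mask_illegal=True` but off by default; transition legality is otherwise
learned.

## Evaluation

Strict matching: a predicted span is correct only if (type, start, end)
all equal a gold span's in the same document. TP/FP/FN are pooled per
type and, for the micro average, across types; P = TP/(TP+FP),
R = TP/(TP+FN), F1 = 2PR/(P+R), with P, R, and F1 defined as 0 when their
denominators vanish. Multi-run aggregation reports mean and *sample*
standard deviation (n−1). The man–machine comparison evaluates several
candidate annotation sets (e.g. model predictions and human extractions)
against one gold standard with the same scorer, plus per-document
disagreement listings.

## Synthetic data

Real ADE corpora are not public, so the generator emulates their
structure: Chinese-character templates with typed slots following the
clinical narrative arc (reason → drug administration → ADR onset →
outcome), filled from closed lexicons (16 Reasons, 18 Drugs including
mixed-script abbreviations, 16 ADRs), with distractor filler sentences
appended at a configurable noise rate (default 0.1) and document lengths
in 20–160 characters. Every placed lexicon item is recorded as a span
whose text slice equals the surface form, so corpora are valid gold
annotations by construction, and identical (config, seed) pairs are
byte-identical.

`corrupt_annotations` simulates an imperfect annotator: each span is
independently corrupted with probability `error_rate` (drop / ±1 boundary
shift / type swap at 0.5/0.3/0.2 relative odds). Every corruption breaks
strict matching, so expected recall is 1 − error_rate. The acceptance
script uses error rate 0.25, chosen to match the reported recall of
manual extraction (~74%) that the comparison emulates.

What passing on synthetic data does **not** show: the generator has a
closed vocabulary, regular templates, and no annotation noise in the
gold standard, so held-out scores here are far above what any tagger
reaches on real clinical narratives with colloquial symptom descriptions,
rare trade names, and annotator disagreement. The synthetic corpus
validates the machinery (representation, optimization, decoding,
scoring), not clinical performance.

## Problem sizes and numerical choices

The default study conditions are 200 training and 50 held-out documents
(disjoint seed streams), 20 epochs — minutes-scale on one CPU while
large enough for the tagger to exceed 0.90 held-out micro-F1. The CRF is
cross-checked against brute-force enumeration of all K^T paths on ≥200
random instances with T ≤ 4, K ≤ 4 (agreement within 1e-8). Log-space
recursions use `scipy.special.logsumexp`; the sigmoid is computed in the
numerically stable split form. Viterbi ties resolve to the lowest tag
index at every backtrace step (with `O` first in the alphabet, the
all-ties path decodes to all-outside). Ill-formed BIO output (possible
when transition masking is off) is repaired on decoding by the conlleval
convention: a stray `I-T` opens a new entity.

## Known limitations

- No pretrained contextual encoder ships with the package; the adapter
  contract is the integration point.
- Only the head Kangxi radical is used — no stroke counts, structure
  decomposition, or glyph features.
- The packaged radical table covers the 214 radical glyphs, common
  variant forms, and the bundled clinical vocabulary (~460 characters);
  characters outside it fall back to the 0 sentinel (logged once each).
- No relaxed/overlap matching modes and no inter-annotator agreement
  statistics; scoring is strict P/R/F1 only.
- Exact CRF inference is O(T·K²) per sequence and the LSTM runs in pure
  numpy; throughput is adequate for corpora of thousands of short
  narratives, not millions.
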