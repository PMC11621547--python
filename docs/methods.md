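# Methods

## Overview

`rnagen` implements a workflow for discovering candidate function-altering
RNA mutations by contrasting two generative sequence models: one
pretrained (PT) on all members of an RNA family and one finetuned (FT) on
a phenotypically defined subpopulation (here, sequences from
hyperthermophiles, defined as organisms with optimal growth temperature
OGT >= 60 °C). Two model families are provided — a decoder-only
autoregressive language model over overlapping n-gram tokens, and a
structure-conditioned autoregressive model over a contact graph — plus
the surrounding machinery: alignment I/O, sequence QC, contact-map
construction, and the two mutation-discovery statistics (per-column
Jensen–Shannon divergence between generated sets, and whole-sequence
ΔΔlogP likelihood scoring).

All neural computation runs on NumPy through a small in-package
reverse-mode autodiff engine (`rnagen._autograd`), checked against
central finite differences in the test suite. The models are deliberately
CPU-sized; the package's claims are about the *method* — tokenization
semantics, masking rules, scoring identities, planted-signal recovery —
not about large-scale perplexities.

## Tokenization and perplexity semantics

Sequences are encoded as overlapping n-grams (n ∈ {1,2,3}) with a step of
one nucleotide, flanked by BOS/EOS; PAD is a distinct token excluded from
every loss and perplexity. Because the step is 1, each predicted token
reveals exactly one new nucleotide, so per-token perplexity is directly a
per-nucleotide perplexity and is comparable across schemes: a model that
has learned nothing beyond the overlap constraint sits at perplexity 4
(uniform over the four consistent continuations), and a perfect model at
1. There is no UNK token — the model alphabet is exactly {A,C,G,U} — so
sequences containing ambiguity codes must be removed by QC before
encoding. Non-overlapping encodings are not implemented.

Decoding inverts encoding exactly; for inconsistent adjacent tokens
(possible in sampled output) the decoder keeps the first character of
each token and counts the disagreements. During generation the
equivalent forward-consistent policy is used — each sampled token
contributes its final character — which guarantees that every output
begins with the seed prefix.

## Language model

A GPT-style causal transformer: RMS normalization in the blocks, rotary
position encoding applied to queries and keys inside every attention
layer (`rope_mode="per_layer"`; an `"overall"` mode rotating the token
embeddings once is available for comparison), GELU feed-forward blocks,
and weight tying between the embedding and the output head. Reference
hyperparameters follow the compact-model recipe the package is built
around (context 384, 18 layers, 6 heads, width 300, AdamW β₂ = 0.998,
batch 18, LR 5e-5 → 5e-6 over 100k iterations); tests and the acceptance
script use tiny instances (2 layers, 2 heads, width 48–64) so everything
runs in minutes on one CPU.

Training batches are left-aligned and PAD-tailed; the loss is next-token
cross entropy over non-PAD targets. The learning rate decays linearly by
default (cosine is switchable); the decay schedule's exact shape is a
design choice, since only the endpoints and duration are prescribed by
the recipe this follows. Early stopping tracks validation NLL and the
best checkpoint is restored. Sequences longer than the context window
are trained on random contiguous crops and *scored* in chunks that
overlap by half a window, each token scored exactly once; results are
flagged `windowed`. Generation divides logits by the temperature T
before the softmax (full softmax, no top-k/top-p), masks PAD/BOS, and
stops at EOS or a nucleotide budget; a KV cache makes batched sampling
linear in length.

Finetuning clones the pretrained model and continues training on the
subpopulation with the same contract, recording the parent checkpoint.
The finetuning split should respect the pretraining train/validation
partition; when row identifiers are supplied, violations are recorded in
the training report rather than silently accepted.

## Structure-conditioned model

Distance matrices are minimum all-atom inter-nucleotide distances in Å,
hydrogens excluded (whether the original computation excluded hydrogens
is not stated anywhere we could verify; excluding them is the
conventional choice). Modified nucleotides map to their parent base.
Matrices are lifted into alignment coordinates in three steps — align
the resolved structure sequence to its full-length sequence and insert
+inf sentinel rows/columns at unresolved positions; spread over MSA
columns via the structure's alignment row; drop columns where the
reference row is gapped — so matrix coordinates match the projected MSA.

Contact maps come in two interchangeable flavors: a symmetric distance
cutoff map, and a per-row k-nearest-neighbor selection (ties broken by
lower column index; masked positions excluded) which stays directed for
message passing and is symmetrized (union) for coverage and correlation
analyses. The structural correlation of two maps is
Corr(A,B) = ΣA·B / √(ΣA²·ΣB²), NaN when either map is empty.
`min_uncovered_distance` reports the smallest finite distance absent
from the symmetrized k-NN map — the quantity that justifies choosing k
so that all short-range contacts are covered.

The model itself is a compact structured transformer: one encoder layer
attending over neighbors with edge features only, then (by default)
three decoder layers in which each node additionally sees the sequence
identity of neighbors at earlier columns (causal masking), then a linear
head over the 6-letter alphabet {A,U,C,G,-,X} (gap is a predictable
symbol; X marks undetermined residues). Edge features concatenate a
sinusoidal encoding of the column offset (16 features by default; the
dimensionality is a config knob, as the lineage architecture does not
pin it) with 16 Gaussian RBFs whose centers are evenly spaced on
0–20 Å and whose width equals the center spacing. Node features are a
learned absolute positional embedding (16 features). All features are
linearly mapped to the hidden dimension (reference 128; tests use
24–32). Attention here is single-headed per layer. Training uses 10%
dropout and 10% label smoothing with early stopping on validation
perplexity. With k = 0 the attention is skipped and the model reduces to
a per-column profile — the baseline used to demonstrate that the contact
graph carries information.

## QC filters

The filter battery runs in order: (1) ambiguity fraction > 5%;
(2) consensus-column coverage < 85% (90% in the broad multi-family
mode); (3) ungapped length more than 2 SD above the mean (1 SD in
rRNA mode) — one-sided, long sequences only; (4) fraction of disrupted
canonical pairs (anything but GC/CG/AU/UA/GU/UG, gap- and N-containing
pairs unscorable) more than 2 SD above the mean, a pseudogene screen.
The source procedure lists the filters as an ordered sequence but does
not state whether the z-score statistics were computed jointly or
running; we compute each filter's mean/SD over the survivors of the
previous filters (population SD, ddof = 0) and record the statistics in
the report so the joint reading can be reproduced by re-applying the
filters with `frozen_stats`. That same mechanism makes the filter
idempotent on its own output.

Identity clustering for train/test splitting is a greedy centroid pass
(longest sequence first, first centroid above the threshold wins), with
pairwise identity computed as 1 − edit distance / max length from a
global alignment (edlib), or over shared columns for aligned input.
Whole clusters are dealt to the test set by seeded shuffle until it
holds the requested nucleotide fraction; no cluster is ever split. This
is a deterministic, oracle-testable stand-in for word-heuristic
clustering tools; it makes no attempt to replicate their internals.

## Mutation discovery

**JSD scan.** Per column, nucleotide frequencies over {A,C,G,U} (gaps
and N excluded from the denominator; a gap-inclusive 5-symbol mode
exists behind a flag because structure-model output contains gaps) are
compared between PT- and FT-generated sets with the Jensen–Shannon
divergence in base 2, so values live in [0,1]. Columns inside the
generation seed are masked — the mask length is seed nucleotides plus
(n − 1) tokens for n-gram models, since the first unconstrained
nucleotide lies that far in — as are columns under 50% occupancy in
either set. Surviving columns are ranked by descending JSD, ties to the
lower index. Top-N rank overlaps between scans are summarized in an
overlap matrix.

**ΔΔlogP.** A candidate mutation set is grafted into the wild-type
sequence (substitutions only) and scored as
(logP_FT(mut) − logP_PT(mut)) − (logP_FT(wt) − logP_PT(wt)); positive
values mean the finetuned model supports the mutant better than the
pretrained model, relative to wild type. Log probabilities sum over all
scored tokens from BOS on (`--skip-seed` exists for sensitivity
analysis). The reference distribution evaluates all 3L single mutants;
percentiles use strict inequality (ties count below), matching the
"better than X% of single mutants" reading. On context-independent
models ΔΔlogP is exactly additive over substitutions — asserted as a
calibration in the tests — and deviation from additivity on contextual
models is precisely why whole-sequence scoring is used.

## Synthetic families

The generator draws a single family consensus (helix pairs jointly from
canonical-pair frequencies, defaults GC/CG 0.28 each, AU/UA 0.16, GU/UG
0.06; unpaired columns from a mildly A/U-rich background) and emits rows
as i.i.d. copies with uniform substitution noise (default rate 0.02).
A seeded fraction of rows (default 20%) is labeled hyperthermophile
(OGT drawn around 75 °C, clipped at 60) and differs in two ways:
planted unpaired columns emit a designated "to" nucleotide with
probability δ (mesophiles keep the consensus), and each helix pair is
redrawn toward G-C with small probability (default 0.05), mimicking
thermophile GC enrichment. Planting is restricted to unpaired columns
because the strongest validated thermostabilizing hits in the motivating
system are loop mutations; paired-column effects are modeled by the GC
shift instead. The default layout (200 columns, four hairpins, five
planted U→C columns) scales to other lengths. A toy distance matrix
consistent with the helices assigns 6 Å to backbone neighbors, 5 Å to
pair partners, and weighted shortest-path lengths elsewhere, so helix
partners are always among the nearest structural neighbors.

`planted_truth` provides closed-form expected PT/FT frequency tables per
planted column (the PT table is the mesophile/thermophile mixture), used
as the oracle for recovery tests. What the generator does *not* emulate:
phylogenetic correlation between rows, realistic indel processes, or
covariance-model emission structure — so passing recovery tests
demonstrates that the pipeline detects planted compositional shifts
under i.i.d. sampling, not performance on real alignments.

## Problem sizes and numerical choices

Tests and the acceptance script use sizes chosen so the full pipeline
runs in minutes per component on a single CPU: random-floor training
uses 2,000 random sequences (length 120 in tests, 300 in the acceptance
script) and tiny models (2 layers, width 48); the planted-recovery
experiment uses the 200-column family with 2,500 rows, a width-48 model
pretrained for 1,500 iterations and finetuned for up to 800, and 500
generated sequences per model; the structure-conditioning comparison
trains width-32 models for 300 iterations on the same family. The
triplet-vs-single tokenization advantage is demonstrated under a
deliberately tight budget (1 layer, width 32, 300 iterations): at full
convergence on these small synthetic tasks all schemes reach the same
entropy floor, so the gap — which reflects that a triplet token carries
its trigram context for free — is only visible while capacity or
optimization is limiting.

Other numerical choices: float32 parameters and activations with
float64 sampling/softmax at the generation boundary; AdamW with
decoupled weight decay 0.01; gradient of the RMS norm taken through the
full expression; attention logits offset by −1e9 for masked entries;
temperature limits handled by max-subtraction so T → 0 recovers greedy
decoding; k-NN ties broken by lower index so toy fixtures with repeated
distances are deterministic; all RNGs are NumPy `default_rng` seeded
from explicit config fields, never from the clock.

## Known limitations

- The engine is not a general autodiff framework: matmul operands must
  be at least 2-D, and only the primitives the models need exist.
- Incremental generation caches absolute rotary positions, so sampling
  beyond the context window falls back to sliding-window recomputation.
- The structure model regenerates full logits per sampled column
  (no incremental path), so its generation is for small widths.
- Windowed log-probability scoring conditions later chunks on a
  half-window overlap rather than full history; scores for sequences
  within the context window are exact.
- `min_atom_distance_matrix` is quadratic in residues and atoms and is
  intended for single chains, not whole ribosome assemblies.
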