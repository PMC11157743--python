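# Methods

## The correction model

Hybrid long-read correction is treated as sequence-to-sequence translation.
For each long read, short-read alignments (SAM, long read as reference) are
normalised to an extended CIGAR over `{M, S, D, I}` anchored at a 1-based
long-read position. `M`/`S` ops vote a base into that column's pileup, `D`
ops vote a gap, and `I` ops vote an inserted string at the junction between
two consecutive long-read positions. A junction collects one vote from
every alignment that spans it, with "no insertion" counted as an explicit
empty vote, so insertion calls are majorities over *covering* reads, not
over reads that happened to report an insertion.

Consensus is a strict majority per column and per junction. Ties and
uncovered columns fall back to the original long-read base, and tied
junctions to no insertion: the consensus layer is deliberately
conservative, because positions it leaves untouched can still be corrected
by the learned model through sequence context. Placeholder filling then
walks the read once: the source emits the raw base at every column and
`$ × len(insertion)` at junctions the consensus inserts into; the target
emits the called base, `$` at deleted columns, and the inserted bases at
junctions. This is the only placeholder orientation under which source and
target remain column-aligned and equal-length while `$`-stripping the
target produces the corrected sequence.

Filled sequences are segmented into adjacent, non-overlapping k-mers
(default k = 3). The vocabulary is always the complete 5^k set over
`{A, C, G, T, $}` plus `<s>`, `</s>`, `<UNK>` — 128 tokens at k = 3 —
rather than the corpus-observed subset, so the dense output layer has an
identical shape in every transfer-learning stage. A trailing remainder
shorter than k is right-padded with `$`, which keeps `$`-stripping lossless
at read ends. Non-ACGT input characters (N, IUPAC codes) are mapped to `A`
at load time with a logged count, keeping the alphabet closed.

The network is an encoder–decoder without attention. The encoder is a
bidirectional LSTM (`hidden_units` per direction, default 256); its final
forward and backward hidden/cell states, gathered at each sequence's true
content length so that batch padding cannot leak into the context, are
concatenated and handed directly to the decoder as its initial state. The
decoder is a single forward LSTM whose width equals the concatenated
encoder state (2 × hidden), followed by a dense softmax over the
vocabulary. A forward-only decoder is the deliberate resolution of an
architectural tension: a bidirectional decoder cannot generate
autoregressively, while the state handoff contract requires matching
widths — both are preserved by widening the forward decoder instead.

Source sentences are fed to the encoder fully reversed (after `<s>`/`</s>`
framing, before padding), so the source's `<s>` sits at the encoder's last
step, adjacent to the decoder's first input `<s>`; this is what makes the
final-state handoff informative about the start of the target. Training is
teacher-forced: the decoder input is the target shifted right, the labels
the target shifted left, and the cross-entropy is multiplied by a mask that
is zero exactly at `<UNK>` label positions, so padding contributes nothing
to loss or accuracy. Token accuracy is measured under teacher forcing —
the fraction of unmasked positions whose argmax equals the label.

## Optimization and numerical choices

Everything is implemented directly on numpy arrays in float64: LSTM
forward passes, backpropagation through time, Adam and RMSProp, global
gradient-norm clipping (5.0 — recurrent training at high learning rates
diverges routinely without it), and Glorot-uniform initialisation with a
forget-gate bias of 1. Analytic gradients are verified against central
finite differences in the test suite. Checkpoints round-trip bitwise
(float64 `.npz` plus vocabulary JSON and config YAML).

Early stopping runs with patience 5 against the *training* loss by default
(`monitor: "loss"`): training is cut off when the loss stops decreasing,
and the best-epoch weights are restored. Monitoring validation loss is
available (`monitor: "val_loss"`) but is not the default because at small
corpus sizes the validation loss of this model rises almost from the first
epoch while the training loss is still far from converged, which freezes a
near-untrained model; the training-loss reading also matches how the
stopping rule interacts with the observation that a successful run drives
the loss to ~0 and accuracy to ~1. Batches are drawn in stable corpus
order (sequential partitioning), each padded to its own longest sentence,
one batch materialized at a time.

Defaults follow the production-scale settings: hidden 256 per direction,
batch 64, Adam at learning rate 0.1, at most 200 epochs. The desk-scale
configuration used throughout the tests is hidden 32, batch 16, learning
rate 0.03: 0.1 is aggressive for Adam on corpora of tens of sentences
(training plateaus immediately), and batch 64 would collapse a 40-sentence
training split into a single update per epoch.

## Transfer learning

Reads are assigned to N chunks by a seeded, platform-stable md5 hash of the
read name, so equal names always land in the same chunk. Stage 0 trains
from scratch on chunk 0; each subsequent stage loads the previous
parameters and trains on its chunk at `learning_rate × finetune_lr_factor`,
with the same early stopping — N − 1 transfer stages in total. All layers
remain trainable in every stage; "unfreezing" amounts to resuming from
checkpoint at a reduced rate. The API default factor is 0.1; desk-scale
runs use 0.5, because a ten-fold cut leaves fine-tuning stages slower to
plateau than the pre-training stage at these corpus sizes, inverting the
speedup the warm start provides. For genome-scale corpora N of several
hundred to a thousand is the intended operating point; chunk sizing below
that is left to configuration.

## Inference

Correction uses batched greedy decoding: encode the source, start the
decoder at `<s>` with the encoder's final state, feed each argmax token
back in, keep one independent hidden state per sequence, stop at `</s>` or
after `source token count + 8` steps (the filled pairs are column-aligned,
so target length tracks source length; the margin absorbs framing tokens).
Source sentences are built at inference by the same consensus/filling path
as training — so `$` slots for insertions exist where the pileup calls
them — and reads without any alignment fall back to their raw tokenized
bases. Every input read yields exactly one output record with its id and
order preserved; specials and `$` are stripped from the emitted tokens.
An empty decode is reported as such (identity 0 in evaluation) and only
stubbed when a FASTA record must be written.

## Synthetic data

The simulator emulates the study conditions end to end: an i.i.d. random
genome with configurable GC; long reads sampled uniformly with a per-base
error channel (substitute to a different base / insert a uniform base after
the current one / delete) at configurable rates, with presets of 13 % total
split indel-dominant for PacBio-CLR-like data (1.6 % sub, 6.6 % ins,
4.8 % del) and 15 % split evenly for ONT-like data; and short reads sampled
from the genome at a requested mean coverage with independent ~1 %
substitution errors (Illumina-like; indels in short reads are not
modelled). Short-read starts are drawn past the genome ends and clipped,
keeping coverage near-uniform at the boundaries.

Because every long read's error trace is recorded, short reads are placed
onto each overlapping long read by coordinate arithmetic, yielding exact
extended CIGARs and a plain-text truth SAM — no aligner in the loop. Two
boundary conventions keep the recorded truth exact rather than ambiguous:
insertions attach after an emitted base (never before a read's first base)
and deletions at a read's extreme ends are folded into the truth interval,
since an indel at the very edge of a read is indistinguishable from the
read simply starting or ending elsewhere.

What the simulator does not model: chimeric reads, adapters, quality
strings, coverage bias, repeats beyond what an i.i.d. genome contains, and
diploid variation. Passing tests on this surface therefore demonstrate the
pipeline's correctness and the method's behaviour in a clean regime, not
performance on real sequencing data.

## Desk-scale experiment sizes

The end-to-end experiment in the acceptance tests uses a 2 kb genome, 50
long reads of 300–500 bp at 10 % total error (split evenly across the
three channels), and 1 %-substitution short reads of 100 bp at 30×
coverage, with k = 3 and hidden 32. Long reads are several-fold longer
than the short reads and give the corpus roughly 10× genome coverage —
correction corpora need multi-fold coverage for the translation model to
pick up the genome's sequence structure; with thinner coverage the model
can only memorise its training split. Under these conditions the mean
per-read truth identity of the corrected reads exceeds that of the inputs
(≈ 0.97 vs ≈ 0.93 at the fixed seed used in the tests). The margin is
genuine but modest at this scale: reads held out of the training split by
the 80/10/10 hash split are corrected noticeably worse (≈ 0.84) than
training-split reads (≈ 1.00), because 40 training sentences are far too
few for the encoder to generalise read-to-position mapping the way a
genome-scale corpus allows.

The transfer check uses the same dataset with two chunks and fine-tune
factor 0.5, comparing epochs-to-stop between the pre-training and
fine-tuning stages and the loss trajectories at matched epochs. At this
corpus size the comparison is noisier than at genome scale (the
warm-started stage first has to re-calibrate an overconfident softmax on
unseen reads before its advantage shows), which is why the check is run at
a fixed seed.

## Evaluation

`truth_identity` scores corrected reads against their known error-free
bases with an optimal unit-cost global alignment (edlib); per-read
identity is matches / corrected-read length, and the panel aggregates
total bases, aligned (matching) bases, identity = aligned/total, mean and
maximum aligned length, and N50 (smallest length whose descending
cumulative sum reaches half the total). Match counts within a minimal-edit
alignment are tie-break-dependent in general; the reported count is the
one on the alignment path edlib returns, and tests assert the bounds the
edit distance implies rather than a specific tie-break. For external
alignments, PAF (minimap2) supplies matches and read-span columns
directly; SAM needs `=`/`X` ops or an NM tag. Per read, the best alignment
by match count is used; unaligned reads count toward total bases only.
Min–max normalization across methods requires at least two distinct
values per metric and errors out otherwise rather than emitting NaN.
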