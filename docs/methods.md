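# Methods

`locusnet` predicts protein-coding gene structures from genomic sequence
alone.  The model has two coupled parts: a CNN–biLSTM sequence-to-sequence
network that emits, for every base, a probability distribution over 15
gene-structure classes, and a small, biologically constrained hidden Markov
model that turns those probabilities into grammatical gene structures.  The
HMM participates in training (differentiable posterior decoding) and in
inference (Viterbi decoding), so the network is optimised under the same
structural constraints it is decoded with.

## The label alphabet and its grammar

Each base carries one of 15 labels: intergenic (IR); three intron states
I0–I2; interior exon states E0–E2; acceptor and donor border states
ASS0–2 / DSS0–2 (the first / last base of an exon adjacent to an intron);
START (the first base of the start codon) and STOP (the last base of the
stop codon).  The frame index of a coding state is the codon position of
the base itself; intron states carry the codon position of the *next*
coding base, which is how reading frame survives an intron.

The directed graph of admissible label adjacencies has exactly 23 edges:

    IR→IR, IR→START, START→E1,
    E0→E1, E1→E2, E2→E0                      (codon cycle)
    E2→DSS0, E0→DSS1, E1→DSS2                (donor exits)
    DSS0→I1, DSS1→I2, DSS2→I0                (intron entry, frame advanced)
    I0→I0, I1→I1, I2→I2                      (intron self-loops)
    I0→ASS0, I1→ASS1, I2→ASS2                (acceptor entry)
    ASS0→E1, ASS1→E2, ASS2→E0                (exon re-entry)
    E1→STOP, STOP→IR

Consequences worth noting: a gene's CDS always starts with a whole ATG and
ends with a whole stop codon inside one exon (spliced start/stop codons are
not representable), and the minimum exon length is 3 — there is no
ASS→DSS edge, so a 2-base exon cannot be expressed.  The label codec skips
(with a warning) reference transcripts that violate these conditions.

## The HMM: 24 untrained parameters

The transition matrix has support on exactly the 23 edges.  Self-loop
probabilities realise geometric length distributions whose means are the
empirical region lengths: IR leaves with probability 1/L_intergenic,
introns with 1/L_intron, and interior exon states exit to a donor with
q = 1/(L_exon − 2) so that the expected exon run (acceptor + interior +
donor) is L_exon.  The E1 row has two exits (DSS2 and STOP); STOP receives
the fraction 3/L_coding of the exit mass (the reciprocal of the mean coding
length in codons), derived from the configured means rather than fitted, so
the free parameters remain 23 transition values plus one emission smoothing
ε — 24 in all, none of them trained.

Emissions map the 15 input classes one-to-one onto the states with a single
smoothing parameter (default ε = 0.01):

    likelihood[i, q] = mask[i, q] · ((1 − ε) · X[i, q] + ε / 15).

The binary mask is computed from the nucleotide sequence: START only at
ATG; STOP only where a stop triplet ends; DSS only where GT follows; ASS
only where AG precedes; E2/DSS2 forbidden where a stop triplet ends
(preventing in-frame stops wholly inside an exon); an N in a signal window
disables that signal; non-coding states are never masked.  Two blind spots
are inherent to per-position masks and are handled downstream by
post-filters: a stop codon spliced across an intron, and a 1-base "intron"
whose GT and AG evidence overlap (an AGT context satisfies both the donor
and the acceptor window).  Predicted genes with either defect are removed
and counted in the run report.

Posterior decoding uses the scaled forward–backward recursions; the
backward pass of the training-time layer replays the recursions in reverse
to propagate exact gradients to the input probabilities (verified against
central finite differences at 1e-4 relative tolerance in the tests).  The
HMM's own parameters receive no gradient.  Decoding pins both path ends
to IR (complete gene structures); training-time posteriors over seamless
windows, which may start or end mid-gene, use free boundaries.

## Segment-parallel Viterbi

The sequential Viterbi recursion is inherently serial in the sequence
position.  The parallel variant partitions the sequence into segments and
computes, independently per segment, a 15×15 max-plus summary M[p, q]: the
best in-segment path score conditioned on the boundary state p (for
non-leading segments the entering transition is folded into M, which makes
plain max-plus matrix multiplication — associative, with the max-plus
identity as neutral element — the combine rule).  A global pass folds the
summaries left to right, one step per segment, producing the exact Viterbi
score vector at every segment border; backtracking re-derives each
in-segment path from its border vector.  Each segment costs 15× the
sequential recursion (one conditioned run per boundary state) — the price
of parallelism.  Ties in every argmax break toward the lowest state index
in both decoders, so parallel and sequential paths are identical, not
merely equal in score; the suite fuzzes this over 1000 instances.

## Training losses

Coding exons are ~1% of a mammalian genome, so cross-entropy alone barely
sees the classes that decide gene structure.  The training loss is, per
sequence,

    CCE-F1 = CCE + λ · { F1-loss  if the sequence contains exon labels
                         FPR̂      otherwise },      λ = 2,

averaged over the batch.  CCE is the position-mean negative log probability
of the true label (floored at 1e-12).  F1-loss = Σ_i (1 − F1̂_i) over the
11 exon classes present in the sequence, with the soft estimator
F1̂_i = 2·TP̂_i / (P̂_i + A_i) built from soft counts (TP̂_i = Σ_j Ŷ[j,i]·Y[j,i];
P̂_i the predicted mass; A_i the true count).  Exon classes absent from a
sequence are excluded from the sum — otherwise every short window would pay
up to 11 units for classes it cannot contain.  For exon-free sequences the
estimated false-positive rate FPR̂ = (1/T)·Σ_i Σ_j Ŷ[j,i] replaces the F1
term.  The exact estimator used by the published method is not in the main
text; the soft-count form here is the standard differentiable choice and
sits behind a single function so it can be swapped.

## The network

Input is the one-hot {A,C,G,T,N} encoding stacked with the softmask repeat
flag (T×6); the reverse strand is predicted from the reverse-complement
encoding.  Two convolutions run at base resolution (the first 15 bp wide, to
span splice-site context); the sequence is then reshaped into blocks of
reshape_factor = 9 bases (both the 9999-base training window and the
500 004-base inference tile divide by 9) and a dense projection feeds a
bidirectional LSTM over blocks, with the raw block encoding concatenated in
as a residual connection.  The head emits 9·15 logits per block, reshaped
back to per-base logits; a per-base skip head from the convolutional
features is added so exon borders are not localised through the block-level
recurrence alone, and the output bias starts at the log of the genomic
label priors (83/16/1 composition).  Published layer sizes are not
available; the presets are reconstructions targeting the published
parameter budgets: `tiny` ≈ 50k parameters for desk-scale experiments,
`small` ≈ 2M and `full` ≈ 8M, related by halving the CNN filter and LSTM
unit sizes (the quadratic LSTM terms make that a quartering of the count).
The `dropout` config field is reserved; the desk-scale runs do not use it.

All layers run on NumPy with a small reverse-mode autodiff; the recurrent
pieces (biLSTM, HMM posteriors) are fused ops with hand-written backward
passes, each verified against finite differences in the tests.

Training is Adam (learning rate 1e-4 by default, as in large-scale
practice; the desk-scale harness uses 3e-3 with cosine decay because its
budget is thousands of steps, not millions), global-norm gradient clipping
at 5, and two phases: pre-HMM training of the raw network output, then
end-to-end fine-tuning in which the loss is applied to the HMM posteriors.
Batches are drawn from seamless windows with gene-containing windows
oversampled (genic_fraction = 0.7 of each batch), because under uniform
sampling ~93% of windows are exon-free and their FPR̂ term only suppresses
exon predictions; a random-crop sampler is also provided for
framing-invariant training.  Checkpoints are selected by combined
validation exon + gene F1 when a validation callback is supplied, else by
recent training loss.

## Whole-genome inference

Each strand of each record is tiled (500 004 bases by default), every tile
is predicted and decoded independently (segment-parallel Viterbi, segment
length 50 000) with both path ends pinned to IR — each tile yields
complete gene structures, so a boundary-straddling gene is necessarily
broken in the first pass — and tiles are stitched.  A boundary "in a
gene" is detected from the network's class probabilities at the boundary
(the decoded paths are IR there by construction); each such boundary
triggers a second pass: the ~1 Mb window formed by the two neighbouring
tiles is re-predicted jointly and the region between the midpoints of the
two tiles (the window's central half, when tiles are equal) replaces the
first-pass labels, which can never change predictions farther than one
tile from the boundary.  The
final label paths are decoded leniently (fragments truncated by stitching
artefacts are dropped with a warning), reverse-strand genes are mapped to
forward coordinates, the spliced-stop and validity post-filters run, and
the result is written as GTF (1-based inclusive, stop codon included in the
CDS, gene ids sequential per sequence).

## The synthetic genome generator

The generator is the package's test bed and defines its study conditions.
Defaults target the composition of the human genome — ~1% coding exon,
~16% intron, ~83% intergenic — from which the mean region lengths are
derived: with 150 bp mean exons and 5 exons per gene, mean intron length
3 000 bp and mean intergenic length 62 250 bp.  These intron/intergenic
scales are one to two orders of magnitude below mammalian reality so that
single-CPU runs remain feasible; the composition fractions are preserved.
Genes get an ATG start, a stop codon (TAA/TAG/TGA at 30/24/46%), GT..AG
introns (minimum 30 bp) and frame-consistent exons with a 30 bp minimum
(shifted geometric) — the spliceosomal minimum; vertebrate micro-exons
below it are rare special cases no local signal could support;
coding sequence is drawn codon-by-codon from a human codon usage table, so
no in-frame stop exists anywhere — spliced or not — and coding regions
carry the period-3 composition bias a classifier can learn.  Intergenic and
intron background is i.i.d. at 41% GC.  Softmasked repeats are random
geometric intervals (mean 500 bp, 10% of the genome) confined to non-coding
sequence; no repeat sequence model is implied.  Extended splice-site
context (branch points, pyrimidine tracts) is not planted.  Labels come
from the same codec used for real annotations, so simulated label
sequences are grammatical by construction.

What passing desk-scale tests therefore shows: the architecture trains end
to end through the HMM, the decoder recovers exact planted structures, and
the tiling machinery is sound.  What they do not show: performance on real
genomes, whose splice signals are weaker, length distributions heavier
tailed, and repeats correlated with genes.

## Desk-scale experiment sizes

The end-to-end experiment (tests and the acceptance script) simulates a
1 Mb default-composition genome (~10 genes), trains the `tiny` preset on
its seamless 9 999-base windows (batch 4, 4 000 pre-HMM steps at lr 3e-3
with cosine decay, then 150 HMM fine-tuning steps at lr 3e-4, float32),
and asks the model to reannotate that genome through the full tiled
pipeline.  The training window matters scientifically: intron interiors
are statistically identical to intergenic background, so only windows
long enough to reach the flanking exons (the mean intron is 3 000 bp) let
the network tell them apart; genes containing introns beyond the window's
reach remain the dominant error mode.  At inference the tiny model is
evaluated in window-aligned 9 999-base chunks (`network_chunk`) while the
HMM decodes whole tiles; full-tile evaluation of so small a recurrent
model degrades it, since its LSTM never saw sequences three orders of
magnitude longer than training.  Gene-level F1 counts a gene only when
every CDS interval matches exactly.

## Numerical choices

Float64 throughout the network and HMM; log-space Viterbi with −inf for
masked entries and no emission renormalisation; scaled linear-space
forward–backward; probability floor 1e-12 inside logs; Viterbi ties break
to the lowest state index; posterior rows renormalised per position.
Degenerate inputs: an all-masked position raises a decoding error naming
the position; records shorter than a network block are padded with N
columns and trimmed after prediction.

## Known limitations

No alternative splicing (one label per base); no UTR or non-coding gene
models; spliced start codons unrepresentable; per-position masks cannot
forbid spliced stops or 1-base pseudo-introns (post-filtered instead); the
desk-scale network is far below published model capacity and is validated
only on synthetic genomes.
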